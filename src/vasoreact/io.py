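"""Readers and writers for the package's delimited-text dialects.

Trace files are UTF-8 CSV with ``# key: value`` metadata comment lines
followed by a ``time_s,diameter_mm,phase`` header; pressure files carry
``time_s,sbp_mmHg,dbp_mmHg`` one row per beat; repeated-measures tables
are long-format ``subject,outcome,rater,day,replicate,value``. These
dialects emulate the kind of export a vascular-ultrasound workstation
produces; they are documented formats of this package, not a parser for
any proprietary vendor file.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .agreement import REPORT_COLUMNS
from .errors import TraceFormatError
from .hemodynamics import PHASES, RawTrace, TRACE_COLUMNS

_TRACE_META_FLOAT = ("deflation_time_s", "baseline_start_s", "baseline_end_s")
PRESSURE_COLUMNS = ["time_s", "sbp_mmHg", "dbp_mmHg"]
LONG_COLUMNS = ["subject", "outcome", "rater", "day", "replicate", "value"]


def _delimiter(dialect_config: Mapping | None) -> str:
    return (dialect_config or {}).get("delimiter", ",")


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

def read_raw_trace(path, dialect_config: Mapping | None = None) -> RawTrace:
    """Parse a trace file into a validated :class:`RawTrace`.

    Raises :class:`TraceFormatError` naming the offending line for
    malformed rows, and lets :class:`RawTrace` validation surface
    coverage/ordering violations.
    """
    path = Path(path)
    delim = _delimiter(dialect_config)
    meta: dict[str, str] = {}
    rows = []
    header = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("# ").partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(delim)
            if header is None:
                header = [p.strip() for p in parts]
                missing = [c for c in TRACE_COLUMNS if c not in header]
                if missing:
                    raise TraceFormatError(
                        f"{path.name}:{lineno}: header missing columns {missing}"
                    )
                idx = {c: header.index(c) for c in TRACE_COLUMNS}
                continue
            if len(parts) != len(header):
                raise TraceFormatError(
                    f"{path.name}:{lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            try:
                t = float(parts[idx["time_s"]])
                d = float(parts[idx["diameter_mm"]])
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path.name}:{lineno}: non-numeric value ({exc})"
                ) from None
            phase = parts[idx["phase"]].strip()
            if phase not in PHASES:
                raise TraceFormatError(
                    f"{path.name}:{lineno}: unknown phase {phase!r} "
                    f"(expected one of {PHASES})"
                )
            rows.append((t, d, phase))
    if header is None:
        raise TraceFormatError(f"{path.name}: no header row found")
    for key in _TRACE_META_FLOAT:
        if key not in meta:
            raise TraceFormatError(f"{path.name}: missing metadata '{key}'")
    try:
        deflation = float(meta["deflation_time_s"])
        window = (float(meta["baseline_start_s"]), float(meta["baseline_end_s"]))
    except ValueError as exc:
        raise TraceFormatError(f"{path.name}: bad metadata ({exc})") from None
    samples = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return RawTrace(
        samples=samples,
        baseline_window=window,
        deflation_time=deflation,
        subject=meta.get("subject", ""),
        session=meta.get("session", ""),
    )


def write_trace(trace: RawTrace, path, dialect_config: Mapping | None = None) -> None:
    """Write a :class:`RawTrace` in the documented dialect."""
    path = Path(path)
    delim = _delimiter(dialect_config)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# deflation_time_s: {trace.deflation_time!r}\n")
        fh.write(f"# baseline_start_s: {trace.baseline_window[0]!r}\n")
        fh.write(f"# baseline_end_s: {trace.baseline_window[1]!r}\n")
        if trace.subject:
            fh.write(f"# subject: {trace.subject}\n")
        if trace.session:
            fh.write(f"# session: {trace.session}\n")
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(TRACE_COLUMNS)
        for t, d, p in trace.samples.itertuples(index=False):
            writer.writerow([repr(float(t)), repr(float(d)), p])


# ---------------------------------------------------------------------------
# pressure files
# ---------------------------------------------------------------------------

def read_pressure(path, dialect_config: Mapping | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter(dialect_config), comment="#")
    except Exception as exc:
        raise TraceFormatError(f"{path.name}: {exc}") from exc
    missing = [c for c in PRESSURE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path.name}: missing columns {missing}")
    return df[PRESSURE_COLUMNS]


def write_pressure(df: pd.DataFrame, path,
                   dialect_config: Mapping | None = None) -> None:
    df[PRESSURE_COLUMNS].to_csv(path, sep=_delimiter(dialect_config),
                                index=False)


# ---------------------------------------------------------------------------
# repeated measures and reports
# ---------------------------------------------------------------------------

def read_repeated_measures(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TraceFormatError(f"{path.name}: {exc}") from exc
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path.name}: missing columns {missing}")
    return df


def write_repeated_measures(df: pd.DataFrame, path) -> None:
    df[LONG_COLUMNS].to_csv(path, index=False)


def write_report(report: pd.DataFrame, path) -> None:
    """Agreement report as TSV mirroring the repeatability-table layout."""
    report[REPORT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bland_altman_points(points: pd.DataFrame, bias: float,
                              loa: tuple[float, float], path) -> None:
    """Per-subject (mean, difference) points plus bias/LOA columns for
    external plotting."""
    out = points.copy()
    out["bias"] = bias
    out["loa_lo"], out["loa_hi"] = loa
    out.to_csv(path, index=True, index_label="subject")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    return loaded or {}
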
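"""Flow-mediated dilation (FMD) and flow-mediated slowing (FMS) from a
phase-labeled brachial-artery diameter trace.

The analysis follows the standard offline FMD workflow: the vasomotion
trace exported by an echo-tracking ultrasound carries one diameter sample
per cardiac extremum, labeled systole or diastole. Samples are paired into
beats, baseline diameter (``D_bas``) and baseline local pulse wave velocity
(``PWV_bas``) are 95%-trimmed means over the last 60 s of the baseline
period, and the post-deflation extremes (``D_peak``, ``PWV_min``) are taken
over 10-s bin averages during the first 3 min after cuff release.

Local (single-site) PWV comes from the beta stiffness index via the
Bramwell-Hill relation::

    beta = ln(SBP / DBP) / ((D_syst - D_diast) / D_diast)
    PWV  = sqrt(beta * DBP_Pa / (2 * rho))          [m s^-1]

with blood density ``rho`` assumed constant at 1050 kg m^-3 and DBP
converted from mmHg to Pa. FMD is the absolute (mm) and relative (%)
diameter increase from baseline to peak; FMS is the absolute (m s^-1) and
relative (%) PWV change from baseline to the post-deflation minimum
(negative values = slowing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: blood density assumed constant, kg m^-3
RHO_BLOOD = 1050.0
#: conversion factor mmHg -> Pa
MMHG_TO_PA = 133.322

PHASE_SYSTOLE = "sys"
PHASE_DIASTOLE = "dias"
PHASES = (PHASE_SYSTOLE, PHASE_DIASTOLE)

TRACE_COLUMNS = ["time_s", "diameter_mm", "phase"]
BEAT_COLUMNS = ["time_s", "d_syst", "d_diast"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawTrace:
    """Phase-labeled diameter samples around one cuff-occlusion maneuver.

    Parameters
    ----------
    samples
        DataFrame with columns ``time_s`` (seconds on the trace clock),
        ``diameter_mm`` and ``phase`` (``"sys"`` / ``"dias"``). Times are
        strictly increasing.
    baseline_window
        ``(start_s, end_s)`` of the baseline summary window on the same
        clock; must end at or before cuff inflation, i.e. before time zero.
    deflation_time
        Trace-clock time of cuff deflation; defines ``t = 0`` for all
        analysis windows. Defaults to 0 (trace clock already centered).
    subject, session
        Opaque identifiers carried through to outputs.
    """

    samples: pd.DataFrame
    baseline_window: tuple[float, float]
    deflation_time: float = 0.0
    subject: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        df = self.samples
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise CoverageError(f"trace samples missing columns {missing}")
        if len(df) == 0:
            raise CoverageError("trace contains no samples")
        t = df["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise CoverageError(
                f"sample times not strictly increasing at row {i + 1}"
            )
        d = df["diameter_mm"].to_numpy(float)
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValidationError("diameters must be finite and > 0")
        bad = ~df["phase"].isin(PHASES)
        if bad.any():
            raise CoverageError(
                f"unknown phase label {df.loc[bad, 'phase'].iloc[0]!r}"
            )
        lo, hi = self.baseline_window
        if not lo < hi:
            raise CoverageError("baseline window start must precede its end")
        if hi - self.deflation_time > 0:
            raise CoverageError(
                "baseline window must end before cuff deflation"
            )
        if t[-1] - self.deflation_time < 180.0:
            raise CoverageError(
                "post-deflation coverage "
                f"{t[-1] - self.deflation_time:.1f} s < 180 s"
            )

    @property
    def times_rel(self) -> np.ndarray:
        """Sample times in seconds relative to cuff deflation."""
        return self.samples["time_s"].to_numpy(float) - self.deflation_time

    @property
    def baseline_window_rel(self) -> tuple[float, float]:
        lo, hi = self.baseline_window
        return (lo - self.deflation_time, hi - self.deflation_time)


@dataclass(frozen=True)
class PressureSummary:
    """Trace-wide brachial pressure summary (95% trimmed means)."""

    sbp: float  # mmHg
    dbp: float  # mmHg

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp > 0:
            raise ValidationError(
                f"need SBP > DBP > 0, got ({self.sbp}, {self.dbp})"
            )

    @property
    def dbp_pa(self) -> float:
        """Diastolic pressure in pascal."""
        return self.dbp * MMHG_TO_PA


@dataclass(frozen=True)
class VascularOutcome:
    """End-point summary of one FMD/FMS analysis.

    ``fmd_mm = d_peak - d_bas``; ``fmd_pct = 100 * fmd_mm / d_bas``;
    ``fms_ms = pwv_min - pwv_bas``; ``fms_pct = 100 * fms_ms / pwv_bas``.
    A post-deflation PWV minimum below baseline makes both FMS measures
    negative (flow-mediated *slowing*).
    """

    d_bas: float
    d_peak: float
    fmd_mm: float
    fmd_pct: float
    pwv_bas: float
    pwv_min: float
    fms_ms: float
    fms_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "d_bas": self.d_bas,
            "d_peak": self.d_peak,
            "fmd_mm": self.fmd_mm,
            "fmd_pct": self.fmd_pct,
            "pwv_bas": self.pwv_bas,
            "pwv_min": self.pwv_min,
            "fms_ms": self.fms_ms,
            "fms_pct": self.fms_pct,
        }


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable options of the offline analysis.

    Defaults reproduce the conventional workflow: 95% trimmed means,
    10-s bins over the first 180 s post-deflation, end-diastolic diameter
    channel, and an artifact gate on per-beat strain.
    """

    trim_fraction: float = 0.95
    bin_s: float = 10.0
    horizon_s: float = 180.0
    baseline_min_beats: int = 5
    channel: Literal["diastolic", "systolic", "mean"] = "diastolic"
    rho: float = RHO_BLOOD
    strain_min: float = 0.0
    strain_max: float = 0.25

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown analysis options: {sorted(unknown)}")
        return cls(**{k: mapping[k] for k in mapping})


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def trimmed_mean(values: Sequence[float], retain_fraction: float = 0.95) -> float:
    """Mean of the central ``retain_fraction`` of the sorted values.

    The number trimmed from *each* tail is ``floor((1 - f) / 2 * n)``, so
    small samples are often left untouched (e.g. n = 4, f = 0.95 trims
    nothing) and ``f = 1`` is the arithmetic mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("trimmed_mean of an empty sequence")
    if not 0 < retain_fraction <= 1:
        raise ValidationError(
            f"retain_fraction must be in (0, 1], got {retain_fraction}"
        )
    n_tail = math.floor((1.0 - retain_fraction) / 2.0 * v.size)
    v = np.sort(v)
    if n_tail:
        v = v[n_tail:-n_tail]
    return float(v.mean())


def beta_stiffness(sbp, dbp, d_syst, d_diast):
    """Beta stiffness index ``ln(SBP/DBP) / ((D_syst - D_diast)/D_diast)``.

    Pressures enter only as a ratio, so the mmHg scale cancels; diameters
    enter only as fractional strain, so beta is invariant to rescaling both
    diameters. Accepts scalars or arrays (broadcast).
    """
    sbp = np.asarray(sbp, float)
    dbp = np.asarray(dbp, float)
    d_syst = np.asarray(d_syst, float)
    d_diast = np.asarray(d_diast, float)
    if np.any(dbp <= 0) or np.any(sbp <= dbp):
        raise ValidationError("need SBP > DBP > 0")
    if np.any(d_diast <= 0) or np.any(d_syst <= d_diast):
        raise ValidationError("need D_syst > D_diast > 0 (degenerate strain)")
    strain = (d_syst - d_diast) / d_diast
    out = np.log(sbp / dbp) / strain
    return float(out) if out.ndim == 0 else out


def local_pwv(beta, dbp, rho: float = RHO_BLOOD):
    """Local pulse wave velocity ``sqrt(beta * DBP_Pa / (2 rho))`` in m/s.

    DBP is supplied in mmHg and converted to Pa internally. The square
    root makes the expression dimensionally a velocity; see module
    docstring.
    """
    beta = np.asarray(beta, float)
    dbp = np.asarray(dbp, float)
    if np.any(beta <= 0) or np.any(dbp <= 0) or rho <= 0:
        raise ValidationError("beta, dbp and rho must all be > 0")
    out = np.sqrt(beta * dbp * MMHG_TO_PA / (2.0 * rho))
    return float(out) if out.ndim == 0 else out


def summarize_pressure(bp_beats, retain_fraction: float = 0.95) -> PressureSummary:
    """Channel-wise trimmed means of per-beat (SBP, DBP) pairs.

    ``bp_beats`` is a DataFrame with ``sbp_mmHg``/``dbp_mmHg`` columns or
    any (n, 2) array-like of (sbp, dbp) rows.
    """
    if isinstance(bp_beats, pd.DataFrame):
        arr = bp_beats[["sbp_mmHg", "dbp_mmHg"]].to_numpy(float)
    else:
        arr = np.atleast_2d(np.asarray(bp_beats, float))
    if arr.size == 0:
        raise ValidationError("no pressure beats")
    if arr.shape[1] != 2:
        raise ValidationError("expected (sbp, dbp) pairs")
    if np.any(arr[:, 0] <= arr[:, 1]):
        i = int(np.argmax(arr[:, 0] <= arr[:, 1]))
        raise ValidationError(f"beat {i}: SBP <= DBP")
    return PressureSummary(
        sbp=trimmed_mean(arr[:, 0], retain_fraction),
        dbp=trimmed_mean(arr[:, 1], retain_fraction),
    )


# ---------------------------------------------------------------------------
# beat pairing and series summaries
# ---------------------------------------------------------------------------

def pair_beats(trace: RawTrace) -> pd.DataFrame:
    """Pair each diastolic sample with the systolic sample of its cycle.

    A cycle is a diastolic sample plus the nearest *following* systolic
    sample, provided it arrives within 1.5x the median inter-diastole
    interval and before the next diastolic sample (robust to dropped
    frames). The beat time is the diastolic sample time, expressed in
    seconds relative to cuff deflation. Unpaired samples are dropped.

    Returns a DataFrame with columns ``time_s, d_syst, d_diast``.
    """
    t = trace.times_rel
    d = trace.samples["diameter_mm"].to_numpy(float)
    phase = trace.samples["phase"].to_numpy()

    dias_mask = phase == PHASE_DIASTOLE
    t_dias, d_dias = t[dias_mask], d[dias_mask]
    t_sys, d_sys = t[~dias_mask], d[~dias_mask]
    if t_dias.size == 0 or t_sys.size == 0:
        raise InsufficientDataError("trace yields zero complete beats")

    if t_dias.size >= 2:
        max_lag = 1.5 * float(np.median(np.diff(t_dias)))
    else:
        max_lag = np.inf

    nxt = np.searchsorted(t_sys, t_dias, side="right")
    rows = []
    for i in range(t_dias.size):
        j = nxt[i]
        if j >= t_sys.size:
            continue  # trailing diastole with no systole after it
        lag = t_sys[j] - t_dias[i]
        next_dias = t_dias[i + 1] if i + 1 < t_dias.size else np.inf
        if lag > max_lag or t_sys[j] >= next_dias:
            continue
        rows.append((t_dias[i], d_sys[j], d_dias[i]))
    if not rows:
        raise InsufficientDataError("trace yields zero complete beats")
    beats = pd.DataFrame(rows, columns=BEAT_COLUMNS)
    logger.debug(
        "paired %d beats from %d dias / %d sys samples",
        len(beats), t_dias.size, t_sys.size,
    )
    return beats


def hemo_series(
    beats: pd.DataFrame,
    pressure: PressureSummary,
    rho: float = RHO_BLOOD,
    strain_bounds: tuple[float, float] = (0.0, 0.25),
) -> tuple[pd.DataFrame, int]:
    """Per-beat beta stiffness and local PWV at trace-constant pressures.

    Beats whose fractional strain falls outside ``strain_bounds`` are
    physiologically impossible (tracking loss) and are excluded; the count
    of exclusions is returned alongside the series.
    """
    ds = beats["d_syst"].to_numpy(float)
    dd = beats["d_diast"].to_numpy(float)
    strain = (ds - dd) / dd
    lo, hi = strain_bounds
    keep = (strain > lo) & (strain <= hi)
    n_excl = int((~keep).sum())
    if n_excl:
        logger.warning("excluded %d beats with strain outside (%g, %g]",
                       n_excl, lo, hi)
    if not keep.any():
        raise InsufficientDataError("no beats with valid strain")
    kept = beats.loc[keep]
    beta = np.log(pressure.sbp / pressure.dbp) / strain[keep]
    pwv = np.sqrt(beta * pressure.dbp_pa / (2.0 * rho))
    out = pd.DataFrame({
        "time_s": kept["time_s"].to_numpy(float),
        "beta": beta,
        "pwv": pwv,
    })
    return out, n_excl


def baseline_summary(
    times,
    values,
    window: tuple[float, float],
    trim_fraction: float = 0.95,
    min_beats: int = 5,
) -> float:
    """Trimmed mean of the per-beat values inside the baseline window.

    The window is half-open ``[start, end)`` on the deflation-relative
    clock; fewer than ``min_beats`` beats inside it is an error.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    lo, hi = window
    mask = (t >= lo) & (t < hi)
    if mask.sum() < min_beats:
        raise InsufficientDataError(
            f"only {int(mask.sum())} beats in baseline window "
            f"[{lo:g}, {hi:g}) (need >= {min_beats})"
        )
    return trimmed_mean(v[mask], trim_fraction)


def binned_extremum(
    times,
    values,
    horizon_s: float = 180.0,
    bin_s: float = 10.0,
    mode: Literal["max", "min"] = "max",
) -> tuple[float, int]:
    """Extremum of fixed-width bin averages over ``[0, horizon_s)``.

    Bins are half-open ``[a, a + bin_s)`` starting at cuff deflation.
    Each bin's value is the arithmetic mean of the beats it contains;
    empty bins are dropped (with a log record). Ties go to the earliest
    bin. Returns ``(extremum value, bin index)``.
    """
    if mode not in ("max", "min"):
        raise ValidationError(f"mode must be 'max' or 'min', got {mode!r}")
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    n_bins = int(round(horizon_s / bin_s))
    mask = (t >= 0) & (t < horizon_s)
    if not mask.any():
        raise InsufficientDataError("no beats in the post-deflation horizon")
    idx = np.floor(t[mask] / bin_s).astype(int)
    vals = v[mask]
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = vals[sel].mean()
    empty = np.isnan(means)
    if empty.all():
        raise InsufficientDataError("all post-deflation bins are empty")
    if empty.any():
        logger.warning("dropping %d empty 10-s bins: %s",
                       int(empty.sum()), np.flatnonzero(empty).tolist())
    if mode == "max":
        best = int(np.nanargmax(means))
    else:
        best = int(np.nanargmin(means))
    return float(means[best]), best


def compute_outcomes(
    d_bas: float, d_peak: float, pwv_bas: float, pwv_min: float
) -> VascularOutcome:
    """Assemble FMD and FMS in absolute and relative units."""
    for name, val in (("d_bas", d_bas), ("d_peak", d_peak),
                      ("pwv_bas", pwv_bas), ("pwv_min", pwv_min)):
        if not val > 0:
            raise ValidationError(f"{name} must be > 0, got {val}")
    fmd_mm = d_peak - d_bas
    fms_ms = pwv_min - pwv_bas
    return VascularOutcome(
        d_bas=d_bas,
        d_peak=d_peak,
        fmd_mm=fmd_mm,
        fmd_pct=100.0 * fmd_mm / d_bas,
        pwv_bas=pwv_bas,
        pwv_min=pwv_min,
        fms_ms=fms_ms,
        fms_pct=100.0 * fms_ms / pwv_bas,
    )


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def _diameter_channel(beats: pd.DataFrame, channel: str) -> np.ndarray:
    if channel == "diastolic":
        return beats["d_diast"].to_numpy(float)
    if channel == "systolic":
        return beats["d_syst"].to_numpy(float)
    if channel == "mean":
        return 0.5 * (beats["d_syst"] + beats["d_diast"]).to_numpy(float)
    raise ValidationError(f"unknown diameter channel {channel!r}")


def analyze_trace(
    trace: RawTrace,
    bp_beats,
    config: AnalysisConfig | None = None,
) -> VascularOutcome:
    """Run the full offline FMD/FMS analysis on one trace.

    Deterministic given inputs and config. Samples recorded during the
    occlusion period never enter any summary: the baseline window ends at
    cuff inflation and the post-deflation bins start at t = 0.
    """
    cfg = config or AnalysisConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    beats = stage("pair_beats", pair_beats, trace)
    logger.info("%s/%s: %d beats paired", trace.subject, trace.session,
                len(beats))
    pressure = stage("summarize_pressure", summarize_pressure,
                     bp_beats, cfg.trim_fraction)
    logger.info("pressure summary: SBP %.1f / DBP %.1f mmHg",
                pressure.sbp, pressure.dbp)

    window = trace.baseline_window_rel
    diam = _diameter_channel(beats, cfg.channel)
    bt = beats["time_s"].to_numpy(float)
    d_bas = stage("baseline_diameter", baseline_summary,
                  bt, diam, window, cfg.trim_fraction, cfg.baseline_min_beats)
    d_peak, peak_bin = stage("peak_diameter", binned_extremum,
                             bt, diam, cfg.horizon_s, cfg.bin_s, "max")

    hemo, n_excl = stage("hemo_series", hemo_series, beats, pressure,
                         cfg.rho, (cfg.strain_min, cfg.strain_max))
    ht = hemo["time_s"].to_numpy(float)
    pwv = hemo["pwv"].to_numpy(float)
    pwv_bas = stage("baseline_pwv", baseline_summary,
                    ht, pwv, window, cfg.trim_fraction, cfg.baseline_min_beats)
    pwv_min, min_bin = stage("min_pwv", binned_extremum,
                             ht, pwv, cfg.horizon_s, cfg.bin_s, "min")

    logger.info(
        "D_bas %.3f mm, D_peak %.3f mm (bin %d); PWV_bas %.3f, PWV_min %.3f "
        "m/s (bin %d); %d beats strain-excluded",
        d_bas, d_peak, peak_bin, pwv_bas, pwv_min, min_bin, n_excl,
    )
    return compute_outcomes(d_bas, d_peak, pwv_bas, pwv_min)
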
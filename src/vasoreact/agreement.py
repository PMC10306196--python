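"""Test-retest and inter-rater agreement statistics.

Implements the repeatability battery conventional in vascular-ultrasound
method studies: within-pair coefficient of variation, the single-measure
absolute-agreement intraclass correlation ICC(2,1) with its F-based 95%
confidence interval, Bland-Altman bias and 95% limits of agreement with a
proportional-bias regression, and the Walter-Eliasziw-Donner sample-size
calculation for ICC hypothesis tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

#: multiplier for 95% limits of agreement
LOA_Z = 1.96

COMPARISON_FAMILIES = (
    "intra_rater_intra_day",
    "intra_rater_inter_day",
    "inter_rater_intra_day",
    "inter_rater_inter_day",
)

REPORT_COLUMNS = [
    "outcome", "comparison", "n", "cv_pct",
    "icc", "icc_lo", "icc_hi", "icc_class",
    "bias", "loa_lo", "loa_hi", "sd_diff",
    "prop_slope", "prop_p",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatedMeasures:
    """One outcome measured under k conditions on n subjects.

    ``data`` is an (n x k) DataFrame: rows indexed by subject id, one
    column per condition (rater, day, or replicate). Missing cells are
    disallowed; remove incomplete subjects upstream (and log it).
    """

    data: pd.DataFrame
    outcome: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValidationError(
                f"need >= 2 subjects and >= 2 conditions, got {self.data.shape}"
            )
        if self.data.isna().any().any():
            raise ValidationError("missing cells are not allowed")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def k_conditions(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)


class IccEstimate(NamedTuple):
    icc: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements."""

    bias: float
    sd_diff: float
    loa: tuple[float, float]
    points: pd.DataFrame  # columns: mean, diff

    @property
    def loa_low(self) -> float:
        return self.loa[0]

    @property
    def loa_high(self) -> float:
        return self.loa[1]


class PropBiasResult(NamedTuple):
    slope: float
    pvalue: float
    significant: bool


@dataclass(frozen=True)
class AgreementResult:
    """All repeatability statistics for one outcome under one comparison."""

    outcome: str
    comparison: str
    n: int
    cv_pct: float
    icc: float
    icc_ci: tuple[float, float]
    icc_class: str
    bias: float
    sd_diff: float
    loa: tuple[float, float]
    prop_slope: float
    prop_p: float

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "comparison": self.comparison,
            "n": self.n,
            "cv_pct": self.cv_pct,
            "icc": self.icc,
            "icc_lo": self.icc_ci[0],
            "icc_hi": self.icc_ci[1],
            "icc_class": self.icc_class,
            "bias": self.bias,
            "loa_lo": self.loa[0],
            "loa_hi": self.loa[1],
            "sd_diff": self.sd_diff,
            "prop_slope": self.prop_slope,
            "prop_p": self.prop_p,
        }


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, RepeatedMeasures):
        return m.values()
    x = np.asarray(m, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError(f"need an (n>=2, k>=2) matrix, got {x.shape}")
    return x


# ---------------------------------------------------------------------------
# coefficient of variation
# ---------------------------------------------------------------------------

def cv_repeatability(m, method: Literal["mean", "rms"] = "mean") -> float:
    """Within-pair coefficient of variation, in percent.

    Per subject: CV_i = SD(replicates) / |mean(replicates)| * 100 with the
    sample (n-1) SD. ``method="mean"`` averages the per-subject CVs
    (default, the common convention in FMD repeatability work);
    ``method="rms"`` returns sqrt(mean(CV_i^2)).
    """
    x = _as_matrix(m)
    means = x.mean(axis=1)
    if np.any(means == 0):
        subj = np.flatnonzero(means == 0)[0]
        label = (m.data.index[subj] if isinstance(m, RepeatedMeasures)
                 else subj)
        raise ValidationError(f"subject {label!r}: pair mean is 0, CV undefined")
    cvs = x.std(axis=1, ddof=1) / np.abs(means) * 100.0
    if method == "mean":
        return float(cvs.mean())
    if method == "rms":
        return float(np.sqrt((cvs ** 2).mean()))
    raise ValidationError(f"unknown CV method {method!r}")


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc_a1(m, alpha: float = 0.05) -> IccEstimate:
    """Two-way, absolute-agreement, single-measures ICC with 95% CI.

    The point estimate comes from the two-way ANOVA mean squares
    (rows = subjects, columns = conditions)::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    The confidence interval is the F-distribution interval of McGraw &
    Wong for ICC(A,1), as implemented in the standard R `irr` routine:
    with a = k*icc / (n*(1-icc)) and b = 1 + k*icc*(n-1)/(n*(1-icc)),
    the Satterthwaite df  v = (a*MS_C + b*MS_E)^2 /
    ((a*MS_C)^2/(k-1) + (b*MS_E)^2/((n-1)(k-1))),  and

        lower = n (MS_R - F_L MS_E) / (F_L (k MS_C + (kn-k-n) MS_E) + n MS_R)
        upper = n (F_U MS_R - MS_E) / (k MS_C + (kn-k-n) MS_E + n F_U MS_R)

    where F_L = F(1-alpha/2; n-1, v) and F_U = F(1-alpha/2; v, n-1).
    """
    x = _as_matrix(m)
    n, k = x.shape
    if n < 5:
        logger.warning("ICC on only %d subjects; estimate will be unstable", n)
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise ValidationError("zero total variance; ICC undefined")
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_err < 1e-12 * ss_total:
        ss_err = 0.0  # guard float cancellation for (near-)exact agreement
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    if icc >= 1.0 - 1e-15:
        # perfect agreement (duplicate columns): interval degenerates
        return IccEstimate(1.0, 1.0, 1.0)

    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return IccEstimate(float(icc), float(lower), float(upper))


def classify_icc(icc: float) -> str:
    """Qualitative repeatability band of an ICC value.

    poor < 0.50; moderate [0.50, 0.74]; good (0.74, 0.90]; excellent
    > 0.90. The printed band edges leave (0.74, 0.75) unassigned; those
    values are classified good so the bands are exhaustive.
    """
    if not np.isfinite(icc):
        raise ValidationError(f"ICC must be finite, got {icc}")
    if icc < 0.50:
        return "poor"
    if icc <= 0.74:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(m) -> BlandAltmanResult:
    """Bias, SD of differences and 95% limits of agreement (k = 2).

    Differences are replicate 1 minus replicate 2; LOA = bias +/- 1.96 SD
    with the sample (n-1) SD. Also returns the (pair mean, difference)
    points for plotting.
    """
    x = _as_matrix(m)
    if x.shape[1] != 2:
        raise ValidationError("Bland-Altman needs exactly 2 conditions")
    d = x[:, 0] - x[:, 1]
    mean = x.mean(axis=1)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    points = pd.DataFrame({"mean": mean, "diff": d})
    if isinstance(m, RepeatedMeasures):
        points.index = m.data.index
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa=(bias - LOA_Z * sd, bias + LOA_Z * sd),
        points=points,
    )


def proportional_bias_test(
    means, diffs=None, alpha: float = 0.05
) -> PropBiasResult:
    """OLS test for magnitude-dependent disagreement.

    Regresses the paired differences on the pair means and tests the
    slope against zero (two-sided t-test). Accepts either two vectors or
    a Bland-Altman ``points`` DataFrame.
    """
    if diffs is None:
        means, diffs = means["mean"], means["diff"]
    mx = np.asarray(means, float)
    dy = np.asarray(diffs, float)
    if mx.size != dy.size or mx.size < 3:
        raise ValidationError("need >= 3 (mean, difference) pairs")
    if np.ptp(mx) == 0:
        raise ValidationError("zero variance in pair means; slope undefined")
    fit = stats.linregress(mx, dy)
    p = float(fit.pvalue)
    return PropBiasResult(float(fit.slope), p, bool(p < alpha))


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def icc_sample_size(
    rho1: float,
    rho0: float = 0.40,
    alpha: float = 0.05,
    power: float = 0.90,
    k: int = 2,
    two_sided: bool = True,
) -> int:
    """Subjects needed to detect ICC ``rho1`` against null ``rho0``.

    Walter-Eliasziw-Donner normal approximation for the one-way ICC
    F-test with k ratings per subject::

        n = 1 + 2 k (z_a + z_b)^2 / ((k - 1) (ln C0)^2),
        C0 = [(1-rho1)(1+(k-1)rho0)] / [(1-rho0)(1+(k-1)rho1)]

    with z_a the two-sided alpha quantile by default and z_b the power
    quantile, rounded to the nearest integer (the convention of the R
    ICC sample-size package this reproduces: rho1=0.80, rho0=0.40,
    alpha=0.05, power=0.90, k=2 gives n=24).
    """
    if not 0 <= rho0 < rho1 < 1:
        raise ValidationError(
            f"need 0 <= rho0 < rho1 < 1, got rho0={rho0}, rho1={rho1}"
        )
    if k < 2:
        raise ValidationError(f"need k >= 2 ratings, got {k}")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2) if two_sided else stats.norm.ppf(1 - alpha)
    z_b = stats.norm.ppf(power)
    c0 = ((1 - rho1) * (1 + (k - 1) * rho0)) / (
        (1 - rho0) * (1 + (k - 1) * rho1)
    )
    n = 1.0 + 2.0 * k * (z_a + z_b) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return int(math.floor(n + 0.5))


# ---------------------------------------------------------------------------
# composite report
# ---------------------------------------------------------------------------

def analyze_agreement(
    m: RepeatedMeasures,
    comparison: str = "",
    alpha: float = 0.05,
    cv_method: Literal["mean", "rms"] = "mean",
) -> AgreementResult:
    """Full agreement battery for one two-condition RepeatedMeasures."""
    cv = cv_repeatability(m, cv_method)
    icc = icc_a1(m, alpha)
    ba = bland_altman(m)
    try:
        pb = proportional_bias_test(ba.points, alpha=alpha)
        slope, pval = pb.slope, pb.pvalue
    except ValidationError as exc:
        logger.warning("proportional-bias test skipped: %s", exc)
        slope, pval = float("nan"), float("nan")
    return AgreementResult(
        outcome=m.outcome,
        comparison=comparison,
        n=m.n_subjects,
        cv_pct=cv,
        icc=icc.icc,
        icc_ci=(icc.ci_low, icc.ci_high),
        icc_class=classify_icc(icc.icc),
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa=ba.loa,
        prop_slope=slope,
        prop_p=pval,
    )


def _pivot_pair(
    long: pd.DataFrame, outcome: str, sel_a: dict, sel_b: dict,
    label_a: str, label_b: str,
) -> RepeatedMeasures:
    """Build an n x 2 matrix from two selections on the long table.

    Each selection fixes some of (rater, day, replicate); the remaining
    axes are averaged per subject. Subjects missing from either column
    are removed listwise (logged).
    """
    sub = long[long["outcome"] == outcome]
    cols = {}
    for label, sel in ((label_a, sel_a), (label_b, sel_b)):
        s = sub
        for axis, val in sel.items():
            s = s[s[axis] == val]
        cols[label] = s.groupby("subject")["value"].mean()
    wide = pd.DataFrame(cols)
    dropped = wide.index[wide.isna().any(axis=1)]
    if len(dropped):
        logger.warning("%s: dropping %d subjects with missing cells: %s",
                       outcome, len(dropped), list(dropped))
        wide = wide.dropna()
    return RepeatedMeasures(wide, outcome=outcome)


def build_comparisons(
    long: pd.DataFrame,
    families: Sequence[str] = COMPARISON_FAMILIES,
) -> list[tuple[str, RepeatedMeasures]]:
    """Expand comparison families into concrete paired datasets.

    Families follow the usual two-rater, two-day, two-replicate design:

    - ``intra_rater_intra_day``: per rater, replicate 1 vs 2 on the first
      day;
    - ``intra_rater_inter_day``: per rater, day 1 vs day 2 (replicates
      averaged);
    - ``inter_rater_intra_day``: per day, rater 1 vs rater 2 (replicates
      averaged);
    - ``inter_rater_inter_day``: rater 1 vs rater 2 with days and
      replicates averaged.

    Raises ConfigError when the long table lacks an axis a requested
    family needs.
    """
    required = {"subject", "outcome", "rater", "day", "replicate", "value"}
    missing = required - set(long.columns)
    if missing:
        raise ConfigError(f"long table missing columns {sorted(missing)}")
    unknown = set(families) - set(COMPARISON_FAMILIES)
    if unknown:
        raise ConfigError(f"unknown comparison families {sorted(unknown)}")

    raters = sorted(long["rater"].unique())
    days = sorted(long["day"].unique())
    reps = sorted(long["replicate"].unique())
    out: list[tuple[str, RepeatedMeasures]] = []
    for outcome in sorted(long["outcome"].unique()):
        for fam in families:
            if fam == "intra_rater_intra_day":
                if len(reps) < 2:
                    raise ConfigError(f"{fam} needs >= 2 replicates")
                for r in raters:
                    name = f"{fam}[rater={r},day={days[0]}]"
                    out.append((name, _pivot_pair(
                        long, outcome,
                        {"rater": r, "day": days[0], "replicate": reps[0]},
                        {"rater": r, "day": days[0], "replicate": reps[1]},
                        "rep1", "rep2")))
            elif fam == "intra_rater_inter_day":
                if len(days) < 2:
                    raise ConfigError(f"{fam} needs >= 2 days")
                for r in raters:
                    name = f"{fam}[rater={r}]"
                    out.append((name, _pivot_pair(
                        long, outcome,
                        {"rater": r, "day": days[0]},
                        {"rater": r, "day": days[1]},
                        "day1", "day2")))
            elif fam == "inter_rater_intra_day":
                if len(raters) < 2:
                    raise ConfigError(f"{fam} needs >= 2 raters")
                for d in days:
                    name = f"{fam}[day={d}]"
                    out.append((name, _pivot_pair(
                        long, outcome,
                        {"rater": raters[0], "day": d},
                        {"rater": raters[1], "day": d},
                        "rater1", "rater2")))
            elif fam == "inter_rater_inter_day":
                if len(raters) < 2:
                    raise ConfigError(f"{fam} needs >= 2 raters")
                name = fam
                out.append((name, _pivot_pair(
                    long, outcome,
                    {"rater": raters[0]}, {"rater": raters[1]},
                    "rater1", "rater2")))
    return out


def agreement_report(
    long: pd.DataFrame,
    families: Sequence[str] = COMPARISON_FAMILIES,
    alpha: float = 0.05,
    cv_method: Literal["mean", "rms"] = "mean",
) -> pd.DataFrame:
    """One agreement row per outcome x comparison, mirroring the usual
    repeatability-table layout (CV, ICC and 95% CI, bias and 95% LOA, SD).
    """
    rows = []
    for name, m in build_comparisons(long, families):
        rows.append(analyze_agreement(m, name, alpha, cv_method).as_row())
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
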
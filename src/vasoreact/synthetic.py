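"""Synthetic hemodynamic data with known ground truth.

Generates (a) phase-labeled brachial diameter traces plus beat-by-beat
finger pressures for the trace-analysis pipeline, and (b) multi-rater /
multi-day repeated-measures tables with a closed-form true ICC for the
agreement statistics.

Population defaults are anchored to the characteristics of a healthy
adult male cohort: D_bas 4.01 (0.56) mm, SBP 125 (14) mmHg, DBP 76 (11)
mmHg, HR 60 (8) bpm, %FMD 6.41 (3.41), %FMS -7.25 (3.82), PWV_bas 8.58
(0.73) m/s; 90 s of baseline, 5 min of cuff occlusion at supra-systolic
pressure, and 4 min of post-deflation recording.

The dilation response is a gamma-variate rising from zero at cuff release
to its peak at a subject-specific time (uniform on 45-75 s) and decaying
thereafter — a smooth unimodal family that exercises the 10-s-bin peak
detection away from the window edges. Reactive hyperemia is modeled
purely as a strain increase at constant pressures, the minimal mechanism
by which the beta-stiffness/Bramwell-Hill equations make local PWV fall;
no shear or flow dynamics are simulated.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .hemodynamics import MMHG_TO_PA, RHO_BLOOD, RawTrace

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationConfig:
    """Population means/SDs and maneuver timing for the generator."""

    d_bas_mm: tuple[float, float] = (4.01, 0.56)
    sbp_mmhg: tuple[float, float] = (125.0, 14.0)
    dbp_mmhg: tuple[float, float] = (76.0, 11.0)
    hr_bpm: tuple[float, float] = (60.0, 8.0)
    fmd_pct: tuple[float, float] = (6.41, 3.41)
    fms_pct: tuple[float, float] = (-7.25, 3.82)
    pwv_bas: tuple[float, float] = (8.58, 0.73)

    baseline_s: float = 90.0
    occlusion_s: float = 300.0
    post_s: float = 240.0
    peak_time_range_s: tuple[float, float] = (45.0, 75.0)
    gamma_shape: float = 2.5

    diameter_noise_mm: float = 0.02
    bp_noise_mmhg: float = 2.0
    rho: float = RHO_BLOOD

    def __post_init__(self) -> None:
        for name in ("d_bas_mm", "sbp_mmhg", "dbp_mmhg", "hr_bpm",
                     "fmd_pct", "fms_pct", "pwv_bas"):
            if getattr(self, name)[1] < 0:
                raise ValidationError(f"{name}: SD must be >= 0")
        if self.dbp_mmhg[0] >= self.sbp_mmhg[0]:
            raise ValidationError("mean DBP must be below mean SBP")
        if self.occlusion_s <= 0 or self.post_s < 180:
            raise ValidationError(
                "need a positive occlusion and >= 180 s post-deflation"
            )


@dataclass(frozen=True)
class VarianceComponents:
    """Additive variance decomposition of one outcome, in outcome units.

    The implied single-measurement absolute-agreement ICC is
    ``sd_subject^2 / (sd_subject^2 + sd_day^2 + sd_rater^2 +
    sd_residual^2)`` — the agreement between two cells sharing nothing
    but the subject.
    """

    sd_subject: float
    sd_day: float = 0.0
    sd_rater: float = 0.0
    sd_residual: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sd_subject, self.sd_day, self.sd_rater,
               self.sd_residual) < 0:
            raise ValidationError("variance-component SDs must be >= 0")

    @property
    def true_icc(self) -> float:
        num = self.sd_subject ** 2
        den = (self.sd_subject ** 2 + self.sd_day ** 2
               + self.sd_rater ** 2 + self.sd_residual ** 2)
        if den == 0:
            raise ValidationError("all variance components are zero")
        return num / den


def true_comparison_icc(
    vc: VarianceComponents,
    comparison: str,
    n_days: int = 2,
    n_replicates: int = 2,
) -> float:
    """Closed-form true absolute-agreement ICC for a comparison family.

    Effects shared by both columns of the comparison count as subject
    variance; averaging over an axis divides its variance by the number
    of levels averaged.
    """
    vs, vd = vc.sd_subject ** 2, vc.sd_day ** 2
    vr, ve = vc.sd_rater ** 2, vc.sd_residual ** 2
    if comparison == "intra_rater_intra_day":
        num, err = vs + vd + vr, ve
    elif comparison == "intra_rater_inter_day":
        num, err = vs + vr, vd + ve / n_replicates
    elif comparison == "inter_rater_intra_day":
        num, err = vs + vd, vr + ve / n_replicates
    elif comparison == "inter_rater_inter_day":
        num, err = vs, vr + vd / n_days + ve / (n_days * n_replicates)
    else:
        raise ValidationError(f"unknown comparison family {comparison!r}")
    return num / (num + err)


def default_variance_components() -> dict[str, VarianceComponents]:
    """Plausible per-outcome components for a trained two-rater study:
    subject SDs from the population table, rater/day/residual spread
    small enough to land ICCs in the good-to-excellent range."""
    return {
        "fmd_pct": VarianceComponents(3.41, sd_day=0.80, sd_rater=0.30,
                                      sd_residual=0.70),
        "fms_pct": VarianceComponents(3.82, sd_day=1.20, sd_rater=0.80,
                                      sd_residual=1.40),
        "d_bas_mm": VarianceComponents(0.56, sd_day=0.05, sd_rater=0.02,
                                       sd_residual=0.06),
        "pwv_bas": VarianceComponents(0.73, sd_day=0.25, sd_rater=0.10,
                                      sd_residual=0.20),
    }


OUTCOME_MEANS = {
    "fmd_pct": 6.41,
    "fms_pct": -7.25,
    "d_bas_mm": 4.01,
    "pwv_bas": 8.58,
}


# ---------------------------------------------------------------------------
# subject truth and trace synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectTruth:
    """Realized per-subject parameters the generator commits to."""

    subject: str
    d_bas: float
    sbp: float
    dbp: float
    hr: float
    fmd_pct: float
    fms_pct: float
    pwv_bas: float
    strain_bas: float
    peak_time_s: float
    gamma_shape: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.strain_bas < 0.25:
            raise ValidationError(
                f"baseline strain {self.strain_bas:.4f} outside (0, 0.25)"
            )

    @property
    def strain_amplitude(self) -> float:
        """Fractional strain gain at the response peak, solved so the
        PWV minimum equals ``pwv_bas * (1 + fms_pct/100)``."""
        r = 1.0 + self.fms_pct / 100.0
        if r <= 0:
            raise ValidationError(f"fms_pct {self.fms_pct} implies PWV <= 0")
        return 1.0 / r ** 2 - 1.0


def invert_baseline_strain(
    pwv_target: float, sbp: float, dbp: float, rho: float = RHO_BLOOD
) -> float:
    """Fractional strain that makes local PWV equal ``pwv_target``.

    Exact algebraic inverse of the beta-stiffness / Bramwell-Hill pair:
    strain = ln(sbp/dbp) * DBP_Pa / (2 rho pwv^2).
    """
    if pwv_target <= 0:
        raise ValidationError("pwv_target must be > 0")
    if not sbp > dbp > 0:
        raise ValidationError("need SBP > DBP > 0")
    strain = math.log(sbp / dbp) * dbp * MMHG_TO_PA / (2.0 * rho * pwv_target ** 2)
    if not 0 < strain <= 0.25:
        raise ValidationError(
            f"implied strain {strain:.4f} outside (0, 0.25]: infeasible "
            "(pwv_target, sbp, dbp) combination"
        )
    return strain


def gamma_variate(t, peak_time_s: float, shape: float = 2.5):
    """Unimodal response curve: 0 for t <= 0, 1 at ``peak_time_s``."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    m = t > 0
    x = t[m] / peak_time_s
    out[m] = x ** shape * np.exp(shape * (1.0 - x))
    return out


def draw_subject(
    pop: PopulationConfig, index: int, seed: int
) -> SubjectTruth:
    """Sample one subject's parameters, rejecting implausible draws.

    Rejection keeps DBP >= 40 mmHg with a >= 10 mmHg pulse pressure,
    HR in (40, 100) bpm, positive dilation, negative slowing, and a
    feasible baseline strain. Reproducible from (seed, index).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, index]))
    for _ in range(1000):
        sbp = rng.normal(*pop.sbp_mmhg)
        dbp = rng.normal(*pop.dbp_mmhg)
        d_bas = rng.normal(*pop.d_bas_mm)
        hr = rng.normal(*pop.hr_bpm)
        fmd = rng.normal(*pop.fmd_pct)
        fms = rng.normal(*pop.fms_pct)
        pwv = rng.normal(*pop.pwv_bas)
        if not (dbp >= 40 and sbp >= dbp + 10):
            continue
        if not (40 < hr < 100 and d_bas > 2.0 and pwv > 4.0):
            continue
        if not (fmd > 0 and fms < 0):
            continue
        try:
            strain = invert_baseline_strain(pwv, sbp, dbp, pop.rho)
        except ValidationError:
            continue
        r = 1.0 + fms / 100.0
        if strain * (1.0 / r ** 2) > 0.25:  # strain at response peak
            continue
        return SubjectTruth(
            subject=f"S{index:03d}", d_bas=d_bas, sbp=sbp, dbp=dbp, hr=hr,
            fmd_pct=fmd, fms_pct=fms, pwv_bas=pwv, strain_bas=strain,
            peak_time_s=rng.uniform(*pop.peak_time_range_s),
            gamma_shape=pop.gamma_shape, seed=seed,
        )
    raise ValidationError("could not draw a feasible subject in 1000 tries")


def simulate_trace(
    truth: SubjectTruth,
    pop: PopulationConfig | None = None,
    session: str = "",
    seed: int | None = None,
) -> tuple[RawTrace, pd.DataFrame]:
    """Synthesize one phase-labeled trace and its per-beat pressures.

    Beats tick at the subject's heart rate from the start of baseline
    through occlusion to the end of the post-deflation window (t = 0 at
    cuff deflation). Per beat, the diastolic sample is placed at the beat
    time and the systolic sample 35% of a period later, with

        d_diast(t) = d_bas * (1 + fmd_pct/100 * g(t))
        strain(t)  = strain_bas * (1 + a * g(t))
        d_syst(t)  = d_diast(t) * (1 + strain(t))

    where g is the subject's gamma-variate (zero during baseline and
    occlusion) and ``a`` the amplitude from :attr:`SubjectTruth.strain_amplitude`.
    Gaussian measurement noise (``pop.diameter_noise_mm``,
    ``pop.bp_noise_mmhg``) is added per sample; pass a noise-free
    ``PopulationConfig`` for exact recovery checks.
    """
    pop = pop or PopulationConfig()
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed,
                                zlib.crc32(truth.subject.encode()),
                                zlib.crc32(session.encode())])
    )
    period = 60.0 / truth.hr
    t0 = -(pop.baseline_s + pop.occlusion_s)
    beat_times = np.arange(t0 + 0.5 * period, pop.post_s, period)

    a = truth.strain_amplitude
    t_sys = beat_times + 0.35 * period
    # one response value per beat: both extrema of a cycle see the beat-time
    # curve; only the sample timestamps are offset within the cycle
    g = gamma_variate(beat_times, truth.peak_time_s, truth.gamma_shape)
    d_diast = truth.d_bas * (1.0 + truth.fmd_pct / 100.0 * g)
    strain = truth.strain_bas * (1.0 + a * g)
    d_syst = d_diast * (1.0 + strain)

    if pop.diameter_noise_mm > 0:
        d_diast = d_diast + rng.normal(0, pop.diameter_noise_mm, d_diast.size)
        d_syst = d_syst + rng.normal(0, pop.diameter_noise_mm, d_syst.size)

    times = np.empty(2 * beat_times.size)
    diam = np.empty_like(times)
    phase = np.empty(times.size, dtype=object)
    times[0::2], times[1::2] = beat_times, t_sys
    diam[0::2], diam[1::2] = d_diast, d_syst
    phase[0::2], phase[1::2] = "dias", "sys"
    samples = pd.DataFrame(
        {"time_s": times, "diameter_mm": diam, "phase": phase}
    )

    sbp = np.full(beat_times.size, truth.sbp)
    dbp = np.full(beat_times.size, truth.dbp)
    if pop.bp_noise_mmhg > 0:
        sbp = sbp + rng.normal(0, pop.bp_noise_mmhg, sbp.size)
        dbp = dbp + rng.normal(0, pop.bp_noise_mmhg, dbp.size)
        dbp = np.minimum(dbp, sbp - 5.0)  # keep every beat's SBP > DBP
    pressures = pd.DataFrame(
        {"time_s": beat_times, "sbp_mmHg": sbp, "dbp_mmHg": dbp}
    )

    trace = RawTrace(
        samples=samples,
        baseline_window=(-pop.occlusion_s - 60.0, -pop.occlusion_s),
        deflation_time=0.0,
        subject=truth.subject,
        session=session,
    )
    return trace, pressures


# ---------------------------------------------------------------------------
# repeated-measures study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyData:
    """Long-format repeated measures plus the generator's ground truth."""

    long: pd.DataFrame  # subject, outcome, rater, day, replicate, value
    subject_truth: pd.DataFrame  # one row per subject x outcome
    variance_components: Mapping[str, VarianceComponents]
    seed: int

    def true_icc(self, outcome: str,
                 comparison: str = "inter_rater_inter_day",
                 n_days: int = 2, n_replicates: int = 2) -> float:
        return true_comparison_icc(
            self.variance_components[outcome], comparison,
            n_days, n_replicates,
        )


def simulate_study(
    pop: PopulationConfig | None = None,
    vc: Mapping[str, VarianceComponents] | None = None,
    n_subjects: int = 24,
    n_days: int = 2,
    n_raters: int = 2,
    n_replicates: int = 2,
    seed: int = 0,
) -> StudyData:
    """Simulate a subject x day x rater x replicate outcome table.

    Per outcome, cell values follow the crossed random-effects model

        y[s,d,r,rep] = mu + S_s + D_{s,d} + R_{s,r} + e[s,d,r,rep]

    with subject, subject-by-day, subject-by-rater and residual effects
    drawn from the outcome's :class:`VarianceComponents`. The true ICC of
    any comparison family follows in closed form
    (:func:`true_comparison_icc`). Fully reproducible from ``seed``.
    """
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    pop = pop or PopulationConfig()
    vc = dict(vc) if vc is not None else default_variance_components()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 902_001]))

    rows = []
    truth_rows = []
    for o_idx, (outcome, comp) in enumerate(sorted(vc.items())):
        mu = OUTCOME_MEANS.get(outcome, 0.0)
        subj_eff = rng.normal(0, comp.sd_subject, n_subjects)
        day_eff = rng.normal(0, comp.sd_day, (n_subjects, n_days))
        rater_eff = rng.normal(0, comp.sd_rater, (n_subjects, n_raters))
        for s in range(n_subjects):
            sid = f"S{s:03d}"
            truth_rows.append({
                "subject": sid, "outcome": outcome,
                "true_value": mu + subj_eff[s],
                "true_icc": comp.true_icc,
            })
            for d in range(n_days):
                for r in range(n_raters):
                    resid = rng.normal(0, comp.sd_residual, n_replicates)
                    for rep in range(n_replicates):
                        rows.append({
                            "subject": sid,
                            "outcome": outcome,
                            "rater": f"R{r + 1}",
                            "day": d + 1,
                            "replicate": rep + 1,
                            "value": mu + subj_eff[s] + day_eff[s, d]
                                     + rater_eff[s, r] + resid[rep],
                        })
    long = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    logger.info("simulated study: %d subjects x %d days x %d raters x %d "
                "replicates, %d outcomes", n_subjects, n_days, n_raters,
                n_replicates, len(vc))
    return StudyData(long=long, subject_truth=truth,
                     variance_components=vc, seed=seed)


def simulate_two_way(
    n: int,
    k: int,
    sd_subject: float,
    sd_condition: float,
    sd_residual: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of the two-way model y_ij = mu + s_i + c_j + e_ij.

    The true absolute-agreement ICC is
    ``sd_subject^2 / (sd_subject^2 + sd_condition^2 + sd_residual^2)``.
    Used for estimator-recovery and CI-coverage simulations.
    """
    return (rng.normal(0, sd_subject, (n, 1))
            + rng.normal(0, sd_condition, (1, k))
            + rng.normal(0, sd_residual, (n, k)))
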
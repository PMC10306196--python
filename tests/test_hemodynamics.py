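"""Unit and property tests for the trace-analysis primitives."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vasoreact as vr
from vasoreact.errors import (
    CoverageError,
    InsufficientDataError,
    ValidationError,
)
from vasoreact.hemodynamics import MMHG_TO_PA, hemo_series


def trimmed_mean_oracle(v, f):
    """Sort-and-slice reference implementation."""
    v = sorted(v)
    n_tail = int(math.floor((1 - f) / 2 * len(v)))
    kept = v[n_tail:len(v) - n_tail] if n_tail else v
    return sum(kept) / len(kept)


class TestTrimmedMean:
    @pytest.mark.parametrize("values,f,expected", [
        ([5, 5, 5, 5], 0.95, 5.0),
        ([1, 2, 3, 4, 100], 0.6, 3.0),  # trims one per tail
        ([3, 1, 2], 1.0, 2.0),
    ])
    def test_examples(self, values, f, expected):
        assert vr.trimmed_mean(values, f) == pytest.approx(expected)

    def test_empty_and_bad_fraction(self):
        with pytest.raises(ValidationError):
            vr.trimmed_mean([], 0.95)
        with pytest.raises(ValidationError):
            vr.trimmed_mean([1.0], 0.0)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
           st.floats(0.1, 1.0))
    def test_matches_oracle_and_is_bounded(self, values, f):
        tm = vr.trimmed_mean(values, f)
        assert tm == pytest.approx(trimmed_mean_oracle(values, f))
        assert min(values) - 1e-9 <= tm <= max(values) + 1e-9

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_full_fraction_is_plain_mean(self, values):
        assert vr.trimmed_mean(values, 1.0) == pytest.approx(
            np.mean(values), rel=1e-12, abs=1e-9)


class TestBetaPwv:
    def test_worked_example(self):
        beta = vr.beta_stiffness(125, 76, 4.13, 4.01)
        assert beta == pytest.approx(16.63, abs=0.01)
        assert vr.local_pwv(beta, 76) == pytest.approx(8.96, abs=0.01)

    def test_beta_vanishes_as_pulse_pressure_closes(self):
        betas = [vr.beta_stiffness(76 + eps, 76, 4.13, 4.01)
                 for eps in (1.0, 0.1, 0.01)]
        assert betas[0] > betas[1] > betas[2]
        assert betas[2] < 0.01

    def test_doubling_strain_halves_beta(self):
        b1 = vr.beta_stiffness(125, 76, 4.01 * 1.03, 4.01)
        b2 = vr.beta_stiffness(125, 76, 4.01 * 1.06, 4.01)
        assert b1 / b2 == pytest.approx(2.0, rel=1e-12)

    def test_quadrupling_density_halves_pwv(self):
        assert vr.local_pwv(16.0, 76, rho=4 * 1050) == pytest.approx(
            vr.local_pwv(16.0, 76, rho=1050) / 2, rel=1e-12)

    @given(st.floats(1.01, 3.0), st.floats(40, 110), st.floats(0.001, 0.24),
           st.floats(2.0, 6.0))
    def test_round_trip_closed_form(self, ratio, dbp, strain, d_diast):
        sbp = dbp * ratio
        d_syst = d_diast * (1 + strain)
        pwv = vr.local_pwv(vr.beta_stiffness(sbp, dbp, d_syst, d_diast), dbp)
        closed = math.sqrt(
            math.log(sbp / dbp) * dbp * MMHG_TO_PA / (2 * 1050 * strain))
        assert pwv == pytest.approx(closed, rel=1e-12)

    @given(st.floats(1.01, 3.0), st.floats(40, 110), st.floats(0.001, 0.24),
           st.floats(0.1, 10.0))
    def test_beta_scale_invariant_in_diameter(self, ratio, dbp, strain, c):
        sbp = dbp * ratio
        b1 = vr.beta_stiffness(sbp, dbp, 4.0 * (1 + strain), 4.0)
        b2 = vr.beta_stiffness(sbp, dbp, c * 4.0 * (1 + strain), c * 4.0)
        assert b1 == pytest.approx(b2, rel=1e-9)

    def test_pwv_decreasing_in_strain(self):
        strains = np.linspace(0.01, 0.2, 25)
        pwv = [vr.local_pwv(vr.beta_stiffness(125, 76, 4 * (1 + s), 4.0), 76)
               for s in strains]
        assert np.all(np.diff(pwv) < 0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValidationError):
            vr.beta_stiffness(125, 76, 4.0, 4.1)
        with pytest.raises(ValidationError):
            vr.beta_stiffness(70, 76, 4.1, 4.0)
        with pytest.raises(ValidationError):
            vr.local_pwv(-1.0, 76)

    def test_unit_sanity_bracket_of_baseline_pwv(self):
        # with cohort-mean pressures, physiologic strains bracket 8.58 m/s
        for strain, lo, hi in [(0.025, 8.58, 10.5), (0.04, 7.0, 8.58)]:
            pwv = vr.local_pwv(
                vr.beta_stiffness(125, 76, 4 * (1 + strain), 4.0), 76)
            assert lo <= pwv <= hi


class TestPressureSummary:
    def test_constant_series(self):
        ps = vr.summarize_pressure([(125.0, 76.0)] * 10)
        assert ps.sbp == 125 and ps.dbp == 76
        assert ps.dbp_pa == pytest.approx(10132.47, abs=0.01)

    def test_single_beat(self):
        ps = vr.summarize_pressure([(118.0, 64.0)])
        assert (ps.sbp, ps.dbp) == (118.0, 64.0)

    def test_spike_excluded_at_95(self, rng):
        sbp = np.full(100, 120.0)
        sbp[42] = 400.0  # artifact
        beats = np.column_stack([sbp, np.full(100, 70.0)])
        ps = vr.summarize_pressure(beats, 0.95)
        # brute-force trimmed mean: drop 2 per tail
        expected = np.mean(np.sort(sbp)[2:-2])
        assert ps.sbp == pytest.approx(expected)
        assert ps.sbp < 125

    def test_inverted_pressures_rejected(self):
        with pytest.raises(ValidationError):
            vr.summarize_pressure([(80.0, 90.0)])


def make_trace(times, diams, phases, window=(-360.0, -300.0)):
    return vr.RawTrace(
        samples=pd.DataFrame(
            {"time_s": times, "diameter_mm": diams, "phase": phases}),
        baseline_window=window,
    )


def alternating_trace(n_cycles=10, start=-390.0, period=1.0, end=200.0):
    times, diams, phases = [], [], []
    t = start
    while t < end:
        times += [t, t + 0.35 * period]
        diams += [4.0, 4.12]
        phases += ["dias", "sys"]
        t += period
    return make_trace(times, diams, phases)


class TestRawTraceInvariants:
    def test_non_monotonic_times_rejected(self):
        with pytest.raises(CoverageError):
            make_trace([0.0, 1.0, 0.5, *np.arange(2, 200.0)],
                       [4.0] * 201, ["dias", "sys"] * 100 + ["dias"])

    def test_short_post_deflation_coverage_rejected(self):
        with pytest.raises(CoverageError):
            alternating_trace(end=100.0)

    def test_baseline_window_must_precede_deflation(self):
        with pytest.raises(CoverageError):
            alternating_trace().__class__(
                samples=alternating_trace().samples,
                baseline_window=(-10.0, 30.0))

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValidationError):
            make_trace([-390, *np.arange(0, 200.0)], [-1.0] + [4.0] * 200,
                       ["dias", "sys"] * 100 + ["dias"])


class TestPairBeats:
    def test_exact_alternation_counts_cycles(self):
        trace = alternating_trace(start=-390.0, end=200.0)
        beats = vr.pair_beats(trace)
        n_dias = (trace.samples["phase"] == "dias").sum()
        assert len(beats) == n_dias
        assert (beats["d_syst"] >= beats["d_diast"]).all()

    def test_trailing_unpaired_diastole_dropped(self):
        trace = alternating_trace()
        df = trace.samples.iloc[:-1]  # ends on a dias sample
        trimmed = vr.RawTrace(samples=df,
                              baseline_window=trace.baseline_window)
        beats = vr.pair_beats(trimmed)
        assert len(beats) == (df["phase"] == "dias").sum() - 1

    def test_beat_time_is_diastolic_time(self):
        beats = vr.pair_beats(alternating_trace())
        dias_times = alternating_trace().samples.query(
            "phase == 'dias'")["time_s"]
        assert np.allclose(beats["time_s"], dias_times.iloc[:len(beats)])

    def test_hr60_yields_one_beat_per_second(self, table_truth, quiet_pop):
        trace, _ = vr.simulate_trace(table_truth, quiet_pop)
        beats = vr.pair_beats(trace)
        post = beats[(beats["time_s"] >= 0) & (beats["time_s"] < 180)]
        assert abs(len(post) - 180) <= 1

    def test_zero_beats_raises(self):
        trace = alternating_trace()
        only_dias = trace.samples[trace.samples["phase"] == "dias"]
        with pytest.raises(InsufficientDataError):
            vr.pair_beats(vr.RawTrace(samples=only_dias,
                                      baseline_window=trace.baseline_window))


class TestWindowsAndBins:
    def test_constant_baseline(self):
        t = np.arange(-360.0, -300.0)
        assert vr.baseline_summary(t, np.full(60, 4.01), (-360, -300)) \
            == pytest.approx(4.01)

    def test_drift_bounded_by_endpoints(self):
        t = np.arange(-360.0, -300.0)
        v = np.linspace(3.9, 4.1, 60)
        est = vr.baseline_summary(t, v, (-360, -300))
        assert v[0] < est < v[-1]

    def test_too_few_beats_raises(self):
        with pytest.raises(InsufficientDataError):
            vr.baseline_summary([-310.0, -305.0], [4.0, 4.0], (-360, -300))

    def test_baseline_estimate_under_noise(self, quiet_pop):
        # pulsatile noise sd 0.02 mm on ~60 baseline beats: trimmed-mean
        # estimate stays within 0.01 mm of truth on average
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(-360.0, -300.0)
            v = 4.01 + rng.normal(0, 0.02, t.size)
            errs.append(vr.baseline_summary(t, v, (-360, -300)) - 4.01)
        assert abs(np.mean(errs)) < 0.01
        assert np.quantile(np.abs(errs), 0.9) < 0.01

    def test_monotone_ramp_peaks_in_last_bin(self):
        t = np.arange(0.5, 180.0)
        v = np.linspace(4.0, 4.3, t.size)
        val, idx = vr.binned_extremum(t, v, mode="max")
        assert idx == 17

    def test_constant_series_ties_to_first_bin(self):
        t = np.arange(0.5, 180.0)
        val, idx = vr.binned_extremum(t, np.full(t.size, 4.0), mode="max")
        assert (val, idx) == (4.0, 0)

    def test_gamma_peak_lands_in_expected_bin(self, table_truth, quiet_pop):
        trace, _ = vr.simulate_trace(table_truth, quiet_pop)
        beats = vr.pair_beats(trace)
        val, idx = vr.binned_extremum(
            beats["time_s"], beats["d_diast"], mode="max")
        assert idx in (5, 6)  # peak at 60 s

    def test_max_dominates_every_bin_mean(self, rng):
        t = rng.uniform(0, 180, 300)
        v = rng.normal(4, 0.1, 300)
        val, _ = vr.binned_extremum(t, v, mode="max")
        bins = np.floor(t / 10).astype(int)
        for b in np.unique(bins):
            assert val >= v[bins == b].mean() - 1e-12

    def test_invariant_to_order_permutation(self, rng):
        t = np.sort(rng.uniform(0, 180, 200))
        v = rng.normal(8, 0.5, 200)
        perm = rng.permutation(200)
        assert vr.binned_extremum(t, v, mode="min") == \
            vr.binned_extremum(t[perm], v[perm], mode="min")


class TestOutcomes:
    def test_fmd_anchored_to_cohort_means(self):
        out = vr.compute_outcomes(4.01, 4.2670, 8.58, 7.9580)
        assert out.fmd_mm == pytest.approx(0.2570, abs=1e-4)
        assert out.fmd_pct == pytest.approx(6.41, abs=0.01)
        assert out.fms_ms == pytest.approx(-0.6220, abs=1e-4)
        assert out.fms_pct == pytest.approx(-7.25, abs=0.01)

    def test_null_response_gives_zero_changes(self):
        out = vr.compute_outcomes(4.01, 4.01, 8.58, 8.58)
        assert out.fmd_mm == out.fmd_pct == out.fms_ms == out.fms_pct == 0

    def test_slowing_sign_convention(self):
        out = vr.compute_outcomes(4.0, 4.2, 8.5, 8.0)
        assert out.fms_pct < 0 and out.fmd_pct > 0


class TestAnalyzeTrace:
    def test_recovers_truth_noise_free(self, mean_trace):
        trace, bp = mean_trace
        out = vr.analyze_trace(trace, bp)
        assert out.fmd_pct == pytest.approx(6.41, abs=0.1)
        assert out.fms_pct == pytest.approx(-7.25, abs=0.1)

    def test_deterministic(self, mean_trace):
        trace, bp = mean_trace
        assert vr.analyze_trace(trace, bp) == vr.analyze_trace(trace, bp)

    def test_occlusion_samples_do_not_affect_result(self, mean_trace):
        trace, bp = mean_trace
        keep = ~((trace.times_rel > -295) & (trace.times_rel < -5))
        stripped = vr.RawTrace(
            samples=trace.samples[keep].reset_index(drop=True),
            baseline_window=trace.baseline_window,
            deflation_time=trace.deflation_time,
        )
        assert vr.analyze_trace(stripped, bp) == vr.analyze_trace(trace, bp)

    def test_strain_artifacts_excluded(self, mean_trace):
        trace, bp = mean_trace
        df = trace.samples.copy()
        # corrupt one systolic sample during baseline to an impossible value
        i = df.index[(df["phase"] == "sys") & (df["time_s"] < -320)][0]
        df.loc[i, "diameter_mm"] = 40.0
        corrupted = vr.RawTrace(samples=df,
                                baseline_window=trace.baseline_window)
        out = vr.analyze_trace(corrupted, bp)
        assert out.pwv_bas == pytest.approx(
            vr.analyze_trace(trace, bp).pwv_bas, rel=1e-6)

    def test_stage_errors_name_the_stage(self, mean_trace):
        trace, _ = mean_trace
        with pytest.raises(ValidationError, match="summarize_pressure"):
            vr.analyze_trace(trace, [(80.0, 90.0)])


class TestHemoSeries:
    def test_positive_beta_and_pwv(self, mean_trace):
        trace, bp = mean_trace
        beats = vr.pair_beats(trace)
        series, n_excl = hemo_series(beats, vr.summarize_pressure(bp))
        assert n_excl == 0
        assert (series["beta"] > 0).all() and (series["pwv"] > 0).all()
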
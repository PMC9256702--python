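"""Ratio computation, normalization, response metrics, population statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_norm_trace, make_pair
from ratiomet import kinetics as kn
from ratiomet import synthgen as sg

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# compute_ratio
# ---------------------------------------------------------------------------

class TestComputeRatio:
    def test_constant_quotient(self):
        i400, i480 = make_pair(np.ones(6), np.full(6, 2.0))
        ratio = kn.compute_ratio(i480, i400)
        assert np.array_equal(ratio.r, np.full(6, 2.0))

    def test_elementwise_quotient_hand_values(self):
        i400, i480 = make_pair([1.0, 2.0, 4.0, 3.0, 3.0], [2.0, 3.0, 4.0, 6.0, 9.0])
        ratio = kn.compute_ratio(i480, i400)
        assert ratio.r == pytest.approx([2.0, 1.5, 1.0, 2.0, 3.0])

    def test_gain_invariance(self):
        vals400 = np.array([1.0, 2.0, 3.0, 4.0])
        vals480 = np.array([2.0, 2.5, 3.5, 5.0])
        r1 = kn.compute_ratio(*make_pair(vals400, vals480)[::-1]).r
        r2 = kn.compute_ratio(*make_pair(3.7 * vals400, 3.7 * vals480)[::-1]).r
        assert np.max(np.abs(r1 - r2)) < 1e-12

    def test_nonpositive_frames_masked(self):
        i400, i480 = make_pair([1.0, -2.0, 0.0, 1.0], [2.0, 2.0, 2.0, -2.0])
        ratio = kn.compute_ratio(i480, i400)
        assert list(ratio.mask) == [False, True, True, True]

    def test_all_masked_is_an_error(self):
        i400, i480 = make_pair([-1.0, -1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="masked"):
            kn.compute_ratio(i480, i400)

    def test_mismatched_rois_rejected(self):
        i400, _ = make_pair(np.ones(4), np.ones(4), roi=1)
        _, i480 = make_pair(np.ones(4), np.ones(4), roi=2)
        with pytest.raises(ValueError, match="ROI"):
            kn.compute_ratio(i480, i400)


# ---------------------------------------------------------------------------
# normalize
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_constant_trace_normalizes_to_one(self):
        i400, i480 = make_pair(np.ones(10), np.full(10, 1.7))
        norm = kn.normalize(kn.compute_ratio(i480, i400))
        assert np.allclose(norm.r_norm, 1.0)
        assert norm.r0 == pytest.approx(1.7)

    def test_two_frame_window_hand_example(self):
        tr = kn.RatioTrace(
            r=np.array([1.0, 1.0, 1.2, 2.0]), dt=1.0, stim_time=2.0, roi=0
        )
        norm = kn.normalize(tr, baseline_window=[0, 1], min_baseline_frames=2)
        assert norm.r0 == pytest.approx(1.0)
        assert norm.r_norm == pytest.approx([1.0, 1.0, 1.2, 2.0])

    def test_baseline_mean_of_r_norm_is_one(self):
        rng = np.random.default_rng(5)
        r = 1.5 + 0.1 * rng.standard_normal(30)
        tr = kn.RatioTrace(r=r, dt=0.5, stim_time=5.0, roi=0)
        norm = kn.normalize(tr)
        assert norm.r_norm[norm.baseline_frames].mean() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        r = np.array([1.0, 1.1, 0.9, 1.0, 2.5, 3.0])
        a = kn.normalize(kn.RatioTrace(r=r, dt=1.0, stim_time=4.0, roi=0))
        b = kn.normalize(kn.RatioTrace(r=2 * r, dt=1.0, stim_time=4.0, roi=0))
        assert np.allclose(a.r_norm, b.r_norm, rtol=1e-14)

    def test_window_overlapping_poststim_rejected(self):
        tr = kn.RatioTrace(r=np.ones(10), dt=1.0, stim_time=5.0, roi=0)
        with pytest.raises(ValueError, match="overlaps"):
            kn.normalize(tr, baseline_window=range(7))

    def test_short_baseline_rejected(self):
        tr = kn.RatioTrace(r=np.ones(10), dt=1.0, stim_time=2.0, roi=0)
        with pytest.raises(ValueError, match="baseline"):
            kn.normalize(tr)   # only 2 pre-stimulus frames, need 3


# ---------------------------------------------------------------------------
# max_ratio_change and t1/2
# ---------------------------------------------------------------------------

class TestMaxRatioChange:
    def test_flat_trace_gives_zero(self):
        assert kn.max_ratio_change(make_norm_trace(np.ones(10))) == 0.0

    def test_peak_value(self):
        vals = np.concatenate([np.ones(5), [1.5, 2.5, 2.0]])
        assert kn.max_ratio_change(make_norm_trace(vals)) == pytest.approx(1.5)

    def test_inhibition_gives_negative_value(self):
        vals = np.concatenate([np.ones(3), [0.8, 0.6, 0.7]])
        tr = make_norm_trace(vals, stim_time=1.5)
        assert kn.max_ratio_change(tr) == pytest.approx(-0.2)

    def test_smoothing_damps_a_single_spike(self):
        vals = np.ones(20)
        vals[10] = 3.0
        tr = make_norm_trace(vals)
        assert kn.max_ratio_change(tr) == pytest.approx(2.0)
        assert kn.max_ratio_change(tr, smooth_window=5) == pytest.approx(0.4)

    def test_even_smoothing_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            kn.max_ratio_change(make_norm_trace(np.ones(5)), smooth_window=4)


class TestTimeToHalfMax:
    def test_step_assigned_to_step_frame(self):
        # step from 1 to 2 at the frame 5.0 min after the stimulus
        vals = np.where(np.arange(16) * 0.5 >= 5.0, 2.0, 1.0)
        tr = make_norm_trace(vals, dt=0.5, stim_time=0.0)
        t_half, ok = kn.time_to_half_max(tr)
        assert ok and t_half == pytest.approx(5.0)

    def test_linear_interpolation_between_bracketing_frames(self):
        # frames at 4.0 / 4.5 min hold 1.4 / 1.6; threshold 1.5 -> 4.25 min
        vals = np.array([1.0, 1.0, 1.05, 1.1, 1.15, 1.2, 1.25, 1.3,
                         1.4, 1.6, 1.8, 2.0, 2.0, 2.0])
        tr = make_norm_trace(vals, dt=0.5, stim_time=0.0)
        t_half, ok = kn.time_to_half_max(tr)
        assert ok and t_half == pytest.approx(4.25)

    @pytest.mark.parametrize("dt", [0.5, 0.05])
    def test_noiseless_exponential_converges_to_ln2_over_k(self, dt):
        k = LN2 / 3.0
        t = np.arange(0.0, 40.0, dt)
        stim = 5.0
        vals = np.where(t >= stim, 1.0 + 1.8 * (1 - np.exp(-k * (t - stim))), 1.0)
        tr = make_norm_trace(vals, dt=dt, stim_time=stim)
        t_half, ok = kn.time_to_half_max(tr)
        assert ok
        # first-crossing with interpolation is accurate to within half a frame
        assert abs(t_half - 3.0) <= 0.5 * dt + 1e-9

    def test_non_responder_flagged_not_raised(self):
        vals = np.concatenate([np.ones(5), np.full(5, 1.05)])
        t_half, ok = kn.time_to_half_max(make_norm_trace(vals, stim_time=2.0))
        assert not ok and math.isnan(t_half)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

class TestSNR:
    def test_direct_quotient(self):
        rng = np.random.default_rng(3)
        base = 1.0 + 0.01 * rng.standard_normal(20)
        vals = np.concatenate([base, np.full(10, 2.2)])
        tr = make_norm_trace(vals, dt=0.5, stim_time=10.0)
        expected = kn.max_ratio_change(tr) / base.std(ddof=1)
        assert kn.snr(tr) == pytest.approx(expected, rel=1e-12)
        assert kn.snr(tr) == pytest.approx(1.2 / base.std(ddof=1), rel=0.05)

    def test_halving_noise_doubles_snr_on_matched_draws(self):
        rng = np.random.default_rng(9)
        eps = rng.standard_normal(60)
        t = np.arange(60) * 0.5
        signal = np.where(t >= 10.0, 2.4, 1.0)
        tr_hi = make_norm_trace(signal + 0.02 * eps, dt=0.5, stim_time=10.0)
        tr_lo = make_norm_trace(signal + 0.01 * eps, dt=0.5, stim_time=10.0)
        assert kn.snr(tr_lo) / kn.snr(tr_hi) == pytest.approx(2.0, rel=0.05)

    def test_zero_baseline_sd_is_an_error(self):
        vals = np.concatenate([np.ones(5), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="baseline SD"):
            kn.snr(make_norm_trace(vals, stim_time=2.0))


# ---------------------------------------------------------------------------
# Z-factor
# ---------------------------------------------------------------------------

class TestZFactor:
    def test_noiseless_ceiling_is_one(self):
        fit = kn.z_factor([2.0, 2.0, 2.0], [1.0, 1.0])
        assert fit.z_factor == 1.0

    def test_hand_computed_value(self):
        # mu/sd chosen to give Z = 1 - 0.66/1.4
        rng = np.random.default_rng(0)

        def sample(mu, sd, n=400000):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mu + sd * x

        fit = kn.z_factor(sample(2.4, 0.2), sample(1.0, 0.02))
        assert fit.z_factor == pytest.approx(1 - 0.66 / 1.4, abs=1e-9)
        assert fit.z_factor == pytest.approx(0.5286, abs=1e-4)

    def test_wide_assay_window_beats_narrow_one(self):
        # populations with mean responses 1.40 vs 0.39 at equal noise mirror
        # the high- vs low-dynamic-range reporter comparison
        rng = np.random.default_rng(4)
        neg = 1.0 + 0.02 * rng.standard_normal(50)
        pos_wide = 2.40 + 0.072 * rng.standard_normal(50)
        pos_narrow = 1.39 + 0.072 * rng.standard_normal(50)
        z_wide = kn.z_factor(pos_wide, neg).z_factor
        z_narrow = kn.z_factor(pos_narrow, neg).z_factor
        assert z_wide > z_narrow

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            kn.z_factor([1.0, 1.2], [1.2, 1.0])

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            kn.z_factor([1.0], [2.0, 2.1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_recomputation(self, seed):
        import statistics

        rng = np.random.default_rng(seed)
        pos = rng.normal(2.0, 0.3, size=rng.integers(2, 40))
        neg = rng.normal(1.0, 0.05, size=rng.integers(2, 40))
        fit = kn.z_factor(pos, neg)
        brute = 1.0 - 3.0 * (statistics.stdev(pos) + statistics.stdev(neg)) / abs(
            statistics.fmean(pos) - statistics.fmean(neg)
        )
        assert fit.z_factor == pytest.approx(brute, abs=1e-12)


# ---------------------------------------------------------------------------
# group summaries / Welch t
# ---------------------------------------------------------------------------

class TestGroupStats:
    def test_sem_hand_value(self):
        import pandas as pd

        # SD of {1,2,3} with the n-1 denominator is 1.0, so SEM = 1/sqrt(3)
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0], "g": ["a"] * 3})
        out = kn.summarize_group(df, "v", "g")
        assert out["sd"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert out["sem"].iloc[0] == pytest.approx(1.0 / math.sqrt(3), abs=1e-12)
        assert out["sem"].iloc[0] == pytest.approx(0.5774, abs=1e-4)
        assert out["n"].iloc[0] == 3

    def test_welch_hand_example(self):
        res = kn.welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == pytest.approx(4.0, abs=1e-9)

    def test_identical_groups(self):
        res = kn.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            kn.welch_t([1.0], [1.0, 2.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_welch_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=rng.integers(2, 30))
        b = rng.normal(0.5, 2.0, size=rng.integers(2, 30))
        res = kn.welch_t(a, b)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        assert res.statistic == pytest.approx(t_hand, rel=1e-10)


# ---------------------------------------------------------------------------
# pipeline-level invariants
# ---------------------------------------------------------------------------

class TestPipelineInvariants:
    def test_metrics_invariant_to_common_channel_gain(self):
        kin = sg.KineticParams(cell_cv=0.0)
        pairs, _ = sg.simulate_trace_population(
            kin, sg.SensorParams(), n_cells=1, seed=21
        )
        i400, i480 = pairs[0]
        m1 = kn.compute_metrics(i480, i400)
        i400.values = 41.0 * i400.values
        i480.values = 41.0 * i480.values
        m2 = kn.compute_metrics(i480, i400)
        assert abs(m1.dr_over_r0 - m2.dr_over_r0) < 1e-12
        assert abs(m1.snr - m2.snr) < 1e-9
        assert abs(m1.t_half - m2.t_half) < 1e-9

    def test_increasing_amplitude_never_decreases_dr(self):
        drs = []
        for amp in (0.3, 0.6, 0.9):
            kin = sg.KineticParams(amplitude=amp, cell_cv=0.0)
            pairs, _ = sg.simulate_trace_population(
                kin, sg.SensorParams(), n_cells=1, seed=33
            )
            i400, i480 = pairs[0]
            drs.append(kn.compute_metrics(i480, i400).dr_over_r0)
        assert drs[0] < drs[1] < drs[2]

    def test_noiseless_recovery_is_exact(self):
        kin = sg.KineticParams(cell_cv=0.0)
        sensor = sg.SensorParams()
        pairs, truth = sg.simulate_trace_population(
            kin, sensor.noiseless(), n_cells=1, t_total=40.0, dt=0.05, seed=0
        )
        i400, i480 = pairs[0]
        m = kn.compute_metrics(i480, i400)
        assert m.dr_over_r0 == pytest.approx(
            truth["true_dr_over_r0"].iloc[0], rel=1e-3
        )
        assert m.t_half == pytest.approx(kin.true_t_half, abs=0.5 * 0.05 + 1e-6)
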
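"""Background subtraction, dF/F0, trial outlier rejection, smoothing, Grubbs."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from retinads.io import RoiTraceSet
from retinads.preprocessing import (DegenerateBaselineError, DffParams,
                                    compute_dff, gaussian_smooth,
                                    grubbs_iterative, reject_outlier_trials,
                                    subtract_background)
from retinads.simulate import TuningGroundTruth, generate_tuned_roi


def _make_set(F, blank, protocol=None):
    return RoiTraceSet(roi_ids=[f"r{i}" for i in range(F.shape[0])],
                       F=F, blank=blank, protocol=protocol)


class TestSubtractBackground:
    def test_constant_blank_shift(self):
        F = np.full((1, 2, 5), 105.0)
        blank = np.full((3, 2, 5), 5.0)
        out = subtract_background(_make_set(F, blank))
        np.testing.assert_allclose(out.F, 100.0)
        assert out.blank is None

    def test_zero_blanks_identity(self):
        F = np.arange(30, dtype=float).reshape(1, 2, 15)
        out = subtract_background(_make_set(F, np.zeros((3, 2, 15))))
        np.testing.assert_allclose(out.F, F)

    def test_matches_elementwise_oracle(self, rng):
        F = rng.uniform(50, 150, size=(5, 4, 20))
        blank = rng.uniform(0, 20, size=(4, 4, 20))
        out = subtract_background(_make_set(F, blank))
        oracle = np.empty_like(F)
        for i in range(5):
            for t in range(4):
                for k in range(20):
                    oracle[i, t, k] = F[i, t, k] - blank[:, t, k].mean()
        np.testing.assert_allclose(out.F, oracle)

    def test_too_few_blanks_rejected(self):
        with pytest.raises(ValueError, match=">= 3 blank"):
            subtract_background(_make_set(np.ones((1, 1, 5)), np.ones((2, 1, 5))))


class TestComputeDff:
    def test_step_response(self, short_protocol):
        """Baseline 10, stimulus peak 20 -> F0 = 10, peak dF/F0 = 1."""
        n = short_protocol.n_frames
        F = np.full((1, 4, n), 10.0)
        stim = short_protocol.epochs[1]
        F[:, :, short_protocol.frames_in(stim)] = 20.0
        traces = compute_dff(_make_set(F, None, short_protocol))
        (tr,) = traces
        np.testing.assert_allclose(tr.F0, 10.0)
        np.testing.assert_allclose(tr.stimulus_dff().max(), 1.0)
        np.testing.assert_allclose(tr.dff[:, tr.baseline_slice].mean(), 0.0,
                                   atol=1e-12)

    def test_soma_offset_denominator(self, short_protocol):
        """Soma mode: F0 = 10, offset = 10, peak F = 30 -> peak 1.0."""
        n = short_protocol.n_frames
        F = np.full((1, 4, n), 10.0)
        F[:, :, short_protocol.frames_in(short_protocol.epochs[1])] = 30.0
        params = DffParams(baseline_mode="soma", offset=10.0)
        (tr,) = compute_dff(_make_set(F, None, short_protocol), params)
        np.testing.assert_allclose(tr.stimulus_dff().max(), 1.0)

    def test_matches_two_pass_oracle(self, short_protocol, rng):
        """Noisy trial equals an independent window-slice-then-arithmetic oracle."""
        n = short_protocol.n_frames
        F = rng.uniform(80, 120, size=(1, 4, n))
        params = DffParams()
        (tr,) = compute_dff(_make_set(F, None, short_protocol), params)
        t = short_protocol.frame_times()
        stim = short_protocol.epochs[1]
        base_mask = (t >= stim.start_s - params.dendrite_baseline_s) & (t < stim.start_s)
        for trial in range(4):
            F0 = F[0, trial, base_mask].mean()
            oracle = (F[0, trial] - F0) / F0
            win_mask = (t >= short_protocol.epochs[0].start_s) & (t < stim.end_s)
            np.testing.assert_allclose(tr.dff[trial], oracle[win_mask], atol=1e-12)

    def test_scale_invariance_dendrite_mode(self, short_protocol, rng):
        """dF/F0 is invariant to multiplying F by any positive constant."""
        n = short_protocol.n_frames
        F = rng.uniform(80, 120, size=(2, 4, n))
        (a0, b0) = compute_dff(_make_set(F, None, short_protocol))
        (a1, b1) = compute_dff(_make_set(3.7 * F, None, short_protocol))
        np.testing.assert_allclose(a0.dff, a1.dff, atol=1e-12)
        np.testing.assert_allclose(b0.dff, b1.dff, atol=1e-12)

    def test_degenerate_baseline_raises(self, short_protocol):
        F = np.zeros((1, 4, short_protocol.n_frames))
        with pytest.raises(DegenerateBaselineError):
            compute_dff(_make_set(F, None, short_protocol))


class TestRejectOutlierTrials:
    def _trace(self, short_protocol, dff_rows):
        F = 100.0 * (1.0 + np.asarray(dff_rows))
        ts = _make_set(F[None], None, short_protocol)
        (tr,) = compute_dff(ts)
        return tr

    def test_identical_trials_all_kept(self, short_protocol, rng):
        n = short_protocol.n_frames
        row = rng.uniform(0, 0.3, size=n)
        tr = self._trace(short_protocol, np.tile(row, (4, 1)))
        out = reject_outlier_trials(tr)
        np.testing.assert_array_equal(out.kept_trials, np.arange(4))

    def test_high_variance_trial_removed(self, short_protocol, rng):
        """3 matching trials + 1 with ~10x stimulus-epoch variance."""
        n = short_protocol.n_frames
        base = rng.normal(0, 0.05, size=(4, n))
        tr0 = self._trace(short_protocol, base)
        stim = tr0.stimulus_slice
        bad = base.copy()
        bad[3, stim] = rng.normal(0, 0.05 * np.sqrt(10), size=stim.stop - stim.start)
        tr = self._trace(short_protocol, bad)
        # oracle: leave-one-out variance spread
        v = tr.stimulus_dff().var(axis=1)
        others = v[:3]
        assert abs(v[3] - others.mean()) > 4 * others.std()
        out = reject_outlier_trials(tr)
        assert 3 not in out.kept_trials
        assert set(out.kept_trials) == {0, 1, 2}

    def test_single_trial_kept(self, short_protocol, rng):
        n = short_protocol.n_frames
        F = 100 + rng.normal(0, 1, size=(1, 1, n))
        ts = RoiTraceSet(roi_ids=["r0"], F=F, protocol=short_protocol)
        (tr,) = compute_dff(ts)
        out = reject_outlier_trials(tr)
        np.testing.assert_array_equal(out.kept_trials, [0])
        assert out.mean_trace is not None

    def test_idempotent(self, short_protocol, rng):
        n = short_protocol.n_frames
        rows = rng.normal(0, 0.05, size=(4, n))
        rows[2] *= 6.0
        tr = self._trace(short_protocol, rows)
        once = reject_outlier_trials(tr)
        twice = reject_outlier_trials(once)
        np.testing.assert_array_equal(once.kept_trials, twice.kept_trials)


class TestGaussianSmooth:
    def test_constant_series_unchanged(self):
        x = np.full(100, 3.14)
        np.testing.assert_allclose(gaussian_smooth(x, 25), x)

    def test_impulse_mass_conserved(self):
        x = np.zeros(101)
        x[50] = 1.0
        assert gaussian_smooth(x, 25).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_convolution_oracle(self, rng):
        """Reflect-padded explicit convolution with the same kernel."""
        x = rng.normal(size=200)
        window = 25
        sigma = window / 5.0
        radius = window // 2
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k /= k.sum()
        padded = np.concatenate([x[radius - 1::-1] if radius else x[:0],
                                 x, x[:-radius - 1:-1]])
        oracle = np.convolve(padded, k, mode="valid")
        np.testing.assert_allclose(gaussian_smooth(x, window), oracle, atol=1e-10)

    @given(st.integers(min_value=2, max_value=49))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_mean_preserved(self, window):
        rng = np.random.default_rng(window)
        x = rng.normal(size=120)
        assert gaussian_smooth(x, window).mean() == pytest.approx(x.mean(),
                                                                  abs=1e-9)

    def test_window_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            out = gaussian_smooth(np.arange(5.0), 25)
        assert out.shape == (5,)


def _grubbs_oracle(values, alpha):
    """Independent brute-force recursion of the two-sided Grubbs test."""
    vals = list(map(float, values))
    removed = []
    while len(vals) >= 3:
        arr = np.asarray(vals)
        mean, sd = arr.mean(), arr.std(ddof=1)
        if sd == 0:
            break
        n = len(vals)
        g = np.abs(arr - mean) / sd
        i = int(np.argmax(g))
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        crit = (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))
        if g[i] > crit:
            removed.append(vals.pop(i))
        else:
            break
    return vals, removed


class TestGrubbsIterative:
    def test_constant_sample_untouched(self):
        kept, removed = grubbs_iterative([5, 5, 5, 5, 5])
        assert removed.size == 0 and kept.size == 5

    def test_below_minimum_n_unchanged(self):
        kept, removed = grubbs_iterative([1.0, 100.0])
        assert removed.size == 0

    def test_matches_bruteforce_oracle_with_planted_outliers(self):
        """500 random small samples with planted 8-SD outliers."""
        rng = np.random.default_rng(42)
        alpha = 1e-4
        for _ in range(500):
            n = int(rng.integers(5, 21))
            x = rng.normal(0, 1, size=n)
            n_out = int(rng.integers(0, 3))
            for _ in range(n_out):
                x[rng.integers(n)] = rng.choice([-8.0, 8.0]) * 1.0
            kept, removed = grubbs_iterative(x, alpha)
            o_kept, o_removed = _grubbs_oracle(x, alpha)
            np.testing.assert_allclose(np.sort(kept), np.sort(o_kept))
            np.testing.assert_allclose(np.sort(removed), np.sort(o_removed))

    def test_removals_nest_across_alpha(self, rng):
        """Stricter alpha removes a subset of what looser alpha removes."""
        for _ in range(50):
            x = rng.normal(0, 1, size=15)
            x[0] = 10.0
            _, strict = grubbs_iterative(x, 1e-4)
            _, loose = grubbs_iterative(x, 1e-2)
            assert set(strict).issubset(set(loose))
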
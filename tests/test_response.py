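"""Qualification, polarity classification, latency."""
import numpy as np
import pytest

from retinads.io import RoiTraceSet
from retinads.preprocessing import compute_dff, reject_outlier_trials
from retinads.protocol import FLASH_OFF_BACKGROUND, FLASH_ON
from retinads.response import (ON, OFF, ON_OFF, NONE, QualificationParams,
                               classify_polarity, qualify_roi, response_latency,
                               soma_response_amplitude)
from retinads.simulate import TuningGroundTruth, generate_flash_roi


def _trace_from_dff(protocol, dff_rows):
    """DffTrace built by running the pipeline on F = 100 * (1 + dff)."""
    F = 100.0 * (1.0 + np.asarray(dff_rows))[None]
    ts = RoiTraceSet(roi_ids=["r0"], F=F, protocol=protocol)
    (tr,) = compute_dff(ts)
    return reject_outlier_trials(tr)


class TestQualifyRoi:
    def test_weak_response_not_qualified(self, short_protocol, rng):
        """Stimulus peak at 3x baseline SD in every trial -> below 5x rule."""
        n = short_protocol.n_frames
        rows = rng.normal(0, 0.01, size=(4, n))
        tr = _trace_from_dff(short_protocol, rows)
        stim = tr.stimulus_slice
        rows2 = rows.copy()
        rows2[:, stim.start:stim.stop] *= 0  # flat stimulus epoch
        rows2[:, (stim.start + stim.stop) // 2] = 3.0 * tr.baseline_sd.mean()
        tr2 = _trace_from_dff(short_protocol, rows2)
        call = qualify_roi(tr2)
        assert not call.qualified
        assert call.representative_dff is None

    def test_strong_response_all_trials(self, short_protocol, rng):
        n = short_protocol.n_frames
        rows = rng.normal(0, 0.01, size=(4, n))
        tr0 = _trace_from_dff(short_protocol, rows)
        mid = (tr0.stimulus_slice.start + tr0.stimulus_slice.stop) // 2
        rows[:, mid] += 10.0 * tr0.baseline_sd.mean()
        call = qualify_roi(_trace_from_dff(short_protocol, rows))
        assert call.qualified
        assert call.n_responsive_trials == 4
        assert call.representative_dff > 0

    def test_min_trials_threshold(self, short_protocol, rng):
        """The same peak crosses 5x baseline SD in only 1 of 4 trials (the
        others have noisier baselines), failing the 2-of-4 rule."""
        n = short_protocol.n_frames
        rows = rng.normal(0, 0.03, size=(4, n))
        tr0 = _trace_from_dff(short_protocol, rows)
        base = tr0.baseline_slice
        stim = tr0.stimulus_slice
        # quiet baseline in trial 0, noisy baselines elsewhere; identical
        # stimulus-epoch statistics so no trial is a variance outlier
        rows[0, base.start:base.stop] = rng.normal(0, 0.005, base.stop - base.start)
        rows[1:, base.start:base.stop] = rng.normal(0, 0.05, (3, base.stop - base.start))
        rows[:, (stim.start + stim.stop) // 2] += 0.1
        tr = _trace_from_dff(short_protocol, rows)
        call = qualify_roi(tr)
        assert call.n_responsive_trials == 1
        assert not call.qualified
        assert qualify_roi(tr, QualificationParams(min_trials=1)).qualified

    def test_monotone_in_amplitude(self, short_protocol, rng):
        """Raising amplitude at fixed noise never un-qualifies an ROI."""
        n = short_protocol.n_frames
        noise = rng.normal(0, 0.02, size=(4, n))
        tr0 = _trace_from_dff(short_protocol, noise)
        stim = tr0.stimulus_slice
        was_qualified = False
        for amp in [0.0, 0.05, 0.2, 0.5, 2.0]:
            rows = noise.copy()
            rows[:, (stim.start + stim.stop) // 2] += amp
            q = qualify_roi(_trace_from_dff(short_protocol, rows)).qualified
            assert q or not was_qualified
            was_qualified = was_qualified or q


class TestSomaAmplitude:
    def test_mean_then_max(self, short_protocol):
        """Two trials peaking 0.2 and 0.4 at the same frame -> 0.3."""
        n = short_protocol.n_frames
        rows = np.zeros((2, n))
        F = 100.0 * (1.0 + rows)[None]
        ts = RoiTraceSet(roi_ids=["r0"], F=F, protocol=short_protocol)
        (tr0,) = compute_dff(ts)
        mid = (tr0.stimulus_slice.start + tr0.stimulus_slice.stop) // 2
        # place peaks in the original frame grid
        stim_frames = short_protocol.frames_in(short_protocol.epochs[1])
        rows[0, :] = 0
        F = 100.0 * np.ones((1, 2, n))
        F[0, 0, stim_frames[3]] = 120.0   # peak dff 0.2
        F[0, 1, stim_frames[3]] = 140.0   # peak dff 0.4
        ts = RoiTraceSet(roi_ids=["r0"], F=F, protocol=short_protocol)
        (tr,) = compute_dff(ts)
        tr = reject_outlier_trials(tr)
        assert soma_response_amplitude(tr) == pytest.approx(0.3)

    def test_staggered_peaks_match_oracle(self, short_protocol, rng):
        n = short_protocol.n_frames
        rows = rng.uniform(0, 0.5, size=(4, n))
        tr = _trace_from_dff(short_protocol, rows)
        oracle = tr.dff[tr.kept_trials].mean(axis=0)[tr.stimulus_slice].max()
        assert soma_response_amplitude(tr) == pytest.approx(oracle)


class TestPolarity:
    def _flash_traces(self, flash_protocol, polarity, seed=3, noise=0.02):
        truth = TuningGroundTruth(roi_id="f0", polarity_true=polarity,
                                  peak_amplitude=1.0, noise_sd=noise,
                                  responsive_true=polarity != NONE)
        ts = generate_flash_roi(flash_protocol, truth, seed=seed)
        traces = {t.condition.kind: reject_outlier_trials(t)
                  for t in compute_dff(ts)}
        return traces[FLASH_ON], traces[FLASH_OFF_BACKGROUND]

    @pytest.mark.parametrize("polarity", [ON, OFF, ON_OFF, NONE])
    def test_polarity_recovered(self, flash_protocol, polarity):
        on_tr, off_tr = self._flash_traces(flash_protocol, polarity)
        assert classify_polarity(on_tr, off_tr) == polarity

    def test_on_off_both_qualify_independently(self, flash_protocol):
        on_tr, off_tr = self._flash_traces(flash_protocol, ON_OFF)
        assert qualify_roi(on_tr).qualified
        assert qualify_roi(off_tr).qualified

    def test_symmetric_under_epoch_swap(self, flash_protocol):
        """Feeding an OFF cell's epochs in swapped order swaps the label."""
        on_tr, off_tr = self._flash_traces(flash_protocol, OFF)
        assert classify_polarity(on_tr, off_tr) == OFF
        assert classify_polarity(off_tr, on_tr) == ON

    def test_on_tail_does_not_masquerade_as_off(self, flash_protocol):
        """The decaying calcium tail of an ON response crossing into the
        post-offset window must not be read as an OFF response."""
        on_tr, off_tr = self._flash_traces(flash_protocol, ON)
        assert off_tr.stimulus_dff().max() > 0.1  # the tail is substantial
        assert classify_polarity(on_tr, off_tr) == ON


class TestLatency:
    def test_crossing_at_onset_frame(self, short_protocol, rng):
        n = short_protocol.n_frames
        rows = rng.normal(0, 0.01, size=(4, n))
        tr0 = _trace_from_dff(short_protocol, rows)
        rows[:, tr0.stimulus_slice.start + np.arange(3)] += 1.0
        lat, mean = response_latency(_trace_from_dff(short_protocol, rows))
        np.testing.assert_allclose(lat, 0.0)
        assert mean == 0.0

    def test_known_frame_offset(self, short_protocol, rng):
        """Crossing at stimulus frame k -> latency k / frame_rate."""
        n = short_protocol.n_frames
        rows = rng.normal(0, 0.01, size=(4, n))
        tr0 = _trace_from_dff(short_protocol, rows)
        k = 8
        rows[:, tr0.stimulus_slice.start + k] += 1.0
        lat, mean = response_latency(_trace_from_dff(short_protocol, rows))
        np.testing.assert_allclose(lat, k / short_protocol.frame_rate_hz)

    def test_never_crossing_trials_excluded(self, short_protocol, rng):
        n = short_protocol.n_frames
        rows = rng.normal(0, 0.01, size=(4, n))
        tr0 = _trace_from_dff(short_protocol, rows)
        rows[:2, tr0.stimulus_slice.start + 4] += 1.0  # only trials 0, 1 cross
        lat, mean = response_latency(_trace_from_dff(short_protocol, rows))
        assert lat.size == 2

    def test_simulated_onset_delay_recovered(self, flash_protocol):
        """Noiseless kernel with onset delay d: latency within one frame of
        the closed-form threshold-crossing time."""
        from retinads.preprocessing import DffParams
        from retinads.simulate import calcium_kernel
        delay = 1.0
        truth = TuningGroundTruth(roi_id="f0", polarity_true=ON,
                                  peak_amplitude=1.0, noise_sd=0.0,
                                  onset_delay_s=delay)
        ts = generate_flash_roi(flash_protocol, truth, seed=0)
        traces = {t.condition.kind: reject_outlier_trials(t)
                  for t in compute_dff(ts)}
        tr = traces[FLASH_ON]
        # noiseless baseline has SD 0: any positive dff crosses; closed-form
        # first positive kernel time is the onset delay itself
        lat, mean = response_latency(tr)
        dt = 1.0 / flash_protocol.frame_rate_hz
        assert abs(mean - delay) <= dt
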
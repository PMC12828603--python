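"""Time-frequency decomposition, baseline normalization, pointwise
contrasts, phase windows, ROI envelopes."""

import numpy as np
import pytest

from ncreann.containers import EpochContainer
from ncreann.tagging import (ACTION_PLANNING, PERCEPTION, PhaseWindow, TFR,
                             extract_phase, morlet_tfr,
                             pointwise_frequency_contrast,
                             relative_power_change, roi_band_envelope)


def _sinusoid_epochs(freq=4.5, amplitude=1.0, sfreq=256.0, dur_s=4.0,
                     n_channels=1, tmin_ms=0.0):
    n = int(dur_s * sfreq)
    t = np.arange(n) / sfreq
    data = amplitude * np.sin(2 * np.pi * freq * t)
    data = np.broadcast_to(data, (1, n_channels, n)).copy()
    return EpochContainer(data=data, sfreq=sfreq,
                          times=tmin_ms + t * 1000.0,
                          channels=[f"c{i}" for i in range(n_channels)])


class TestMorlet:
    def test_sinusoid_power_peaks_at_its_frequency(self):
        ep = _sinusoid_epochs(4.5)
        tfr = morlet_tfr(ep, [4.5, 8.0])
        interior = tfr.valid.all(axis=0)
        p45 = tfr.power[0, 0, 0, interior]
        p8 = tfr.power[0, 0, 1, interior]
        assert p45.mean() > 10 * p8.mean()
        # approximately time-constant away from edges
        assert p45.std() / p45.mean() < 0.05
        # amplitude-normalized: unit sinusoid -> power ~ 1
        assert p45.mean() == pytest.approx(1.0, rel=0.05)

    def test_power_scales_quadratically_with_amplitude(self):
        out = []
        for amp in (1.0, 2.0):
            tfr = morlet_tfr(_sinusoid_epochs(4.5, amplitude=amp), [4.5])
            out.append(tfr.power[0, 0, 0, tfr.valid[0]].mean())
        assert out[1] / out[0] == pytest.approx(4.0, rel=1e-6)

    def test_wavelet_longer_than_epoch_rejected_naming_frequency(self):
        ep = _sinusoid_epochs(4.5, dur_s=0.5)
        with pytest.raises(ValueError, match="4.5"):
            morlet_tfr(ep, [4.5])

    def test_frequency_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_tfr(_sinusoid_epochs(), [128.0])

    def test_matches_mne_wavelet_power_up_to_scale(self, rng):
        mne = pytest.importorskip("mne")
        data = rng.standard_normal((2, 3, 1024))
        ep = EpochContainer(data=data, sfreq=256.0,
                            times=np.arange(1024) / 256.0 * 1000.0,
                            channels=["a", "b", "c"])
        ours = morlet_tfr(ep, [4.5, 8.0], n_cycles=5)
        theirs = mne.time_frequency.tfr_array_morlet(
            data, 256.0, np.array([4.5, 8.0]), n_cycles=5, output="power",
            zero_mean=False)
        for fi in range(2):
            sl = ours.valid[fi]
            a = ours.power[:, :, fi, sl].ravel()
            b = theirs[:, :, fi, sl].ravel()
            assert np.corrcoef(a, b)[0, 1] > 0.99


class TestRelativePower:
    def _flat_tfr(self, base_value, post_value):
        times = np.arange(-500, 1000, 4.0)  # 250 Hz grid
        power = np.full((1, 1, 1, times.size), float(base_value))
        power[..., times >= 0] = post_value
        return TFR(power=power, freqs=np.array([4.5]), times=times,
                   valid=np.ones((1, times.size), bool), sfreq=250.0,
                   channels=["c0"])

    def test_power_equal_to_baseline_gives_zero(self):
        rel = relative_power_change(self._flat_tfr(2.0, 2.0))
        assert np.allclose(rel.power, 0.0)

    def test_power_twice_baseline_gives_plus_one(self):
        rel = relative_power_change(self._flat_tfr(2.0, 4.0))
        assert np.allclose(rel.power[..., rel.times >= 0], 1.0)
        assert rel.baseline_window == (-350.0, -150.0)

    def test_zero_baseline_power_rejected(self):
        with pytest.raises(ValueError, match="zero mean baseline"):
            relative_power_change(self._flat_tfr(0.0, 1.0))

    def test_baseline_after_zero_rejected(self):
        with pytest.raises(ValueError, match="before time 0"):
            relative_power_change(self._flat_tfr(1.0, 2.0),
                                  baseline=(-100.0, 100.0))

    def test_invariant_to_positive_rescaling_of_raw_signal(self, rng):
        data = rng.standard_normal((2, 2, 1024))
        times = np.arange(1024) / 256.0 * 1000.0 - 1500.0
        ep1 = EpochContainer(data=data, sfreq=256.0, times=times,
                             channels=["a", "b"])
        ep2 = EpochContainer(data=3.7 * data, sfreq=256.0, times=times,
                             channels=["a", "b"])
        r1 = relative_power_change(morlet_tfr(ep1, [4.5]))
        r2 = relative_power_change(morlet_tfr(ep2, [4.5]))
        assert np.allclose(r1.power, r2.power)


class TestPointwiseContrast:
    def test_identical_maps_give_zero_t_and_no_significance(self, rng):
        a = rng.standard_normal((10, 3, 50))
        stat = pointwise_frequency_contrast(a, a.copy())
        assert np.all(stat.t == 0.0) and not stat.mask.any()

    def test_injected_offset_detected_and_localized(self, rng):
        n, c, t = 50, 4, 80
        a = rng.standard_normal((n, c, t))
        b = rng.standard_normal((n, c, t))
        a[:, 1, 20:40] += 2.0  # planted effect, channel 1 only
        stat = pointwise_frequency_contrast(a, b, alpha=0.05)
        assert stat.mask[1, 20:40].mean() > 0.9
        other = stat.mask.copy()
        other[1, 20:40] = False
        assert other.mean() <= 0.05

    def test_mask_monotone_in_alpha(self, rng):
        a = rng.standard_normal((20, 3, 40))
        b = rng.standard_normal((20, 3, 40)) + 0.3
        lo = pointwise_frequency_contrast(a, b, alpha=0.01)
        hi = pointwise_frequency_contrast(a, b, alpha=0.05)
        assert np.all(hi.mask[lo.mask])

    def test_adjusted_p_at_least_raw_p(self, rng):
        a = rng.standard_normal((12, 2, 30))
        b = rng.standard_normal((12, 2, 30))
        stat = pointwise_frequency_contrast(a, b)
        assert np.all(stat.p_fdr >= stat.p - 1e-12)

    def test_null_data_false_positive_rate_controlled(self, rng):
        fracs = []
        for _ in range(10):
            a = rng.standard_normal((30, 2, 40))
            b = rng.standard_normal((30, 2, 40))
            fracs.append(pointwise_frequency_contrast(a, b).mask.mean())
        assert np.mean(fracs) <= 0.05

    def test_fewer_than_three_subjects_rejected(self, rng):
        a = rng.standard_normal((2, 2, 10))
        with pytest.raises(ValueError, match=">= 3"):
            pointwise_frequency_contrast(a, a)


class TestPhaseWindows:
    def test_planning_phase_crops_256_samples_at_256hz(self):
        ep = _sinusoid_epochs(sfreq=256.0, dur_s=4.0, tmin_ms=-1000.0)
        cropped = extract_phase(ep, ACTION_PLANNING)
        assert cropped.n_samples == 256
        assert cropped.times[0] >= 0.0 and cropped.times[-1] < 1000.0

    def test_cropping_twice_is_idempotent(self):
        ep = _sinusoid_epochs(tmin_ms=-1000.0)
        once = extract_phase(ep, ACTION_PLANNING)
        twice = extract_phase(once, ACTION_PLANNING)
        assert np.array_equal(once.data, twice.data)

    def test_perception_phase_locked_to_action_effect(self):
        assert PERCEPTION.lock == "action_effect"
        ep = _sinusoid_epochs(tmin_ms=-1000.0)  # cue-locked
        with pytest.raises(ValueError, match="lock"):
            extract_phase(ep, PERCEPTION)

    def test_mismatched_name_lock_combination_rejected(self):
        with pytest.raises(ValueError, match="locked"):
            PhaseWindow("action_planning", "action_effect")


class TestROIEnvelope:
    def test_single_voxel_roi_equals_its_wavelet_power(self, rng):
        series = rng.standard_normal((2, 1, 1024))
        env = roi_band_envelope({"ATL": series}, sfreq=256.0)
        ep = EpochContainer(data=series, sfreq=256.0,
                            times=np.arange(1024) / 256.0 * 1000.0,
                            channels=["v0"])
        direct = morlet_tfr(ep, [4.5])
        assert np.allclose(env.data[:, 0, :], direct.power[:, 0, 0, :])

    def test_duplicated_voxel_changes_nothing(self, rng):
        series = rng.standard_normal((1, 1, 1024))
        dup = np.concatenate([series, series], axis=1)
        a = roi_band_envelope({"IC": series}, sfreq=256.0)
        b = roi_band_envelope({"IC": dup}, sfreq=256.0)
        assert np.allclose(a.data, b.data)

    def test_envelope_tracks_amplitude_modulator(self):
        sfreq, dur = 256.0, 8.0
        t = np.arange(int(sfreq * dur)) / sfreq
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        carrier = mod * np.sin(2 * np.pi * 4.5 * t)
        env = roi_band_envelope({"PTL": carrier[None, None, :]}, sfreq=sfreq)
        interior = slice(300, -300)
        r = np.corrcoef(np.sqrt(env.data[0, 0, interior]),
                        mod[interior])[0, 1]
        assert r > 0.9

    def test_empty_roi_rejected_by_name(self, rng):
        with pytest.raises(ValueError, match="IFC"):
            roi_band_envelope({"IFC": np.empty((1, 0, 100))}, sfreq=256.0)
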
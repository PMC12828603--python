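"""Frequency-tagging analysis: Morlet time-frequency decomposition,
baseline-relative power change, pointwise paired-t/FDR contrasts between
tagged and control frequencies, phase-window cropping, and ROI band-power
envelope extraction.

Conventions: 5-cycle Morlet wavelets with the Gaussian envelope truncated
at 3 standard deviations; relative power change is
``(P - mean(P_baseline)) / mean(P_baseline)`` with the default baseline
-350..-150 ms; samples inside the half-wavelet support at each frequency
are flagged invalid and excluded from statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .containers import EpochContainer

__all__ = [
    "TFR",
    "RelativePowerMap",
    "PointwiseStatMap",
    "PhaseWindow",
    "ACTION_PLANNING",
    "PERCEPTION",
    "morlet_tfr",
    "relative_power_change",
    "pointwise_frequency_contrast",
    "extract_phase",
    "roi_band_envelope",
]

#: Gaussian-envelope truncation, in standard deviations ("wavelet length").
WAVELET_TRUNC_SD = 3.0


def _morlet_wavelet(freq: float, sfreq: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, amplitude-normalized.

    Scaled so that convolution with a real sinusoid of amplitude A at
    ``freq`` yields analytic amplitude ~A (power ~A**2).
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(round(WAVELET_TRUNC_SD * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    envelope = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    wavelet = envelope * np.exp(2.0j * np.pi * freq * t)
    return wavelet * (2.0 / envelope.sum())


@dataclass
class TFR:
    """Per-trial time-frequency power.

    ``power`` has shape (n_trials, n_channels, n_freqs, n_samples);
    ``valid[f, t]`` is False inside the half-wavelet support at frequency f.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # ms
    valid: np.ndarray  # (n_freqs, n_samples) bool
    sfreq: float
    channels: list[str]
    lock: str = "cue"


def morlet_tfr(epochs: EpochContainer, freqs: Sequence[float],
               n_cycles: float = 5.0) -> TFR:
    """Morlet wavelet power of every trial and channel at ``freqs``.

    Raises if any frequency is at/above Nyquist or its wavelet is longer
    than the epoch, naming the offending frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    nyq = epochs.sfreq / 2.0
    if np.any(freqs >= nyq):
        bad = freqs[freqs >= nyq][0]
        raise ValueError(f"frequency {bad} Hz is at/above Nyquist {nyq} Hz")
    n_trials, n_channels, n_samples = epochs.data.shape
    power = np.empty((n_trials, n_channels, len(freqs), n_samples))
    valid = np.ones((len(freqs), n_samples), dtype=bool)
    flat = epochs.data.reshape(n_trials * n_channels, n_samples)
    for fi, f in enumerate(freqs):
        wav = _morlet_wavelet(f, epochs.sfreq, n_cycles)
        if wav.size > n_samples:
            raise ValueError(
                f"wavelet at {f} Hz ({wav.size} samples) is longer than the "
                f"epoch ({n_samples} samples)"
            )
        half = wav.size // 2
        conv = signal.fftconvolve(flat, wav[None, :], mode="same", axes=-1)
        power[:, :, fi, :] = (np.abs(conv) ** 2).reshape(n_trials, n_channels,
                                                         n_samples)
        valid[fi, :half] = False
        if half > 0:
            valid[fi, n_samples - half:] = False
    return TFR(power=power, freqs=freqs, times=epochs.times.copy(),
               valid=valid, sfreq=epochs.sfreq, channels=list(epochs.channels),
               lock=epochs.lock)


@dataclass
class RelativePowerMap:
    """Trial-averaged baseline-normalized power change (unitless).

    ``power`` has shape (n_channels, n_freqs, n_samples); inside the
    baseline window it averages to ~0 by construction.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # ms
    baseline_window: tuple[float, float]  # [ms, ms)
    valid: np.ndarray  # (n_freqs, n_samples) bool
    lock: str = "cue"


def relative_power_change(tfr: TFR,
                          baseline: tuple[float, float] = (-350.0, -150.0),
                          ) -> RelativePowerMap:
    """Baseline-relative power: ``(P - mean_base) / mean_base`` pointwise.

    Trials are averaged first; the baseline mean is taken per channel and
    frequency over valid samples in the half-open window ``baseline``
    (default -350..-150 ms), which must lie before time 0 and inside the
    epoch.
    """
    b0, b1 = baseline
    if b1 > 0:
        raise ValueError("baseline window must end at or before time 0")
    if b0 < tfr.times[0] or b1 > tfr.times[-1]:
        raise ValueError(
            f"baseline [{b0}, {b1}) ms outside epoch "
            f"[{tfr.times[0]}, {tfr.times[-1]}] ms"
        )
    mean_power = tfr.power.mean(axis=0)  # (channels, freqs, samples)
    in_base = (tfr.times >= b0) & (tfr.times < b1)
    rel = np.empty_like(mean_power)
    for fi in range(len(tfr.freqs)):
        use = in_base & tfr.valid[fi]
        if not np.any(use):
            raise ValueError(
                f"no valid baseline samples at {tfr.freqs[fi]} Hz "
                "(baseline inside the wavelet edge)"
            )
        base = mean_power[:, fi, use].mean(axis=-1)  # (channels,)
        if np.any(base == 0):
            raise ValueError("zero mean baseline power: relative change undefined")
        rel[:, fi, :] = (mean_power[:, fi, :] - base[:, None]) / base[:, None]
    return RelativePowerMap(power=rel, freqs=tfr.freqs.copy(),
                            times=tfr.times.copy(), baseline_window=baseline,
                            valid=tfr.valid.copy(), lock=tfr.lock)


@dataclass
class PointwiseStatMap:
    """Pointwise paired-t statistics with BH-FDR over channel x time."""

    t: np.ndarray  # (channels, times)
    p: np.ndarray
    p_fdr: np.ndarray
    mask: np.ndarray  # bool, True where p_fdr <= alpha
    alpha: float
    valid: np.ndarray  # (times,) bool — points entering the FDR family
    times: np.ndarray | None = None


def pointwise_frequency_contrast(a: np.ndarray, b: np.ndarray,
                                 alpha: float = 0.05,
                                 valid: np.ndarray | None = None,
                                 times: np.ndarray | None = None,
                                 ) -> PointwiseStatMap:
    """Paired t-test per (channel, time) between two subject-level maps.

    ``a`` and ``b`` have shape (n_subjects, n_channels, n_times) with
    matched subjects.  BH-FDR is applied across the full channel x time
    family restricted to ``valid`` time points (edge-invalid samples are
    excluded rather than tested).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 paired observations, got {n}")
    n_channels, n_times = a.shape[1], a.shape[2]
    if valid is None:
        valid = np.ones(n_times, dtype=bool)
    res = stats.ttest_rel(a, b, axis=0)
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    p_fdr = np.ones_like(p)
    mask = np.zeros_like(p, dtype=bool)
    family = np.broadcast_to(valid[None, :], (n_channels, n_times))
    if np.any(family):
        rej, adj, _, _ = multipletests(p[family], alpha=alpha, method="fdr_bh")
        p_fdr[family] = adj
        mask[family] = rej
    return PointwiseStatMap(t=t, p=p, p_fdr=p_fdr, mask=mask, alpha=alpha,
                            valid=np.asarray(valid, dtype=bool), times=times)


@dataclass(frozen=True)
class PhaseWindow:
    """A named analysis window relative to a lock event.

    ``action_planning`` is 0..1000 ms relative to the cue onset;
    ``perception`` is 0..1000 ms relative to the action-effect onset.
    """

    name: str
    lock: str
    window: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self) -> None:
        expected = {"action_planning": "cue", "perception": "action_effect"}
        if self.name in expected and self.lock != expected[self.name]:
            raise ValueError(
                f"phase {self.name!r} must be locked to {expected[self.name]!r}, "
                f"got {self.lock!r}"
            )
        if self.window[0] >= self.window[1]:
            raise ValueError("phase window start must be < end")


ACTION_PLANNING = PhaseWindow("action_planning", "cue")
PERCEPTION = PhaseWindow("perception", "action_effect")


def extract_phase(obj, phase: PhaseWindow):
    """Crop an epoch container or relative-power map to a phase window.

    The crop is half-open, ``[start, end)`` ms relative to the phase's lock
    event; cropping twice is idempotent.  The object's lock tag must match
    the phase's.
    """
    lo, hi = phase.window
    if getattr(obj, "lock", phase.lock) != phase.lock:
        raise ValueError(
            f"data locked to {obj.lock!r} cannot be cropped to phase "
            f"{phase.name!r} (locked to {phase.lock!r})"
        )
    if isinstance(obj, EpochContainer):
        return obj.crop(lo, hi)
    if isinstance(obj, RelativePowerMap):
        keep = (obj.times >= lo) & (obj.times < hi)
        if not np.any(keep):
            raise ValueError(f"phase window [{lo}, {hi}) ms outside data range")
        return RelativePowerMap(power=obj.power[:, :, keep].copy(),
                                freqs=obj.freqs.copy(),
                                times=obj.times[keep].copy(),
                                baseline_window=obj.baseline_window,
                                valid=obj.valid[:, keep].copy(), lock=obj.lock)
    raise TypeError(f"cannot extract phase from {type(obj).__name__}")


def roi_band_envelope(roi_series: dict[str, np.ndarray], sfreq: float,
                      centre_freq: float = 4.5, n_cycles: float = 5.0,
                      times: np.ndarray | None = None,
                      lock: str = "trial_start") -> EpochContainer:
    """Per-ROI band-power envelope time series.

    ``roi_series`` maps ROI name -> array (n_trials, n_voxels, n_samples)
    of reconstructed voxel time series.  Each voxel is wavelet-decomposed
    at ``centre_freq`` and power is averaged across voxels within the ROI
    (averaging precedes any standardization).  Returns an epoch container
    whose channels are the ROI names.
    """
    if not roi_series:
        raise ValueError("no ROIs supplied")
    names = list(roi_series)
    envelopes = []
    ref_shape = None
    for name in names:
        arr = np.asarray(roi_series[name], dtype=float)
        if arr.ndim != 3 or arr.shape[1] == 0:
            raise ValueError(f"ROI {name!r} is empty or malformed (shape {arr.shape})")
        if ref_shape is None:
            ref_shape = (arr.shape[0], arr.shape[2])
        elif (arr.shape[0], arr.shape[2]) != ref_shape:
            raise ValueError(f"ROI {name!r} trial/sample shape mismatch")
        n_trials, n_voxels, n_samples = arr.shape
        container = EpochContainer(
            data=arr, sfreq=sfreq,
            times=np.arange(n_samples) / sfreq * 1000.0,
            channels=[f"v{i}" for i in range(n_voxels)], lock=lock)
        tfr = morlet_tfr(container, [centre_freq], n_cycles=n_cycles)
        envelopes.append(tfr.power[:, :, 0, :].mean(axis=1))  # voxel average
    data = np.stack(envelopes, axis=1)  # (trials, rois, samples)
    if times is None:
        times = np.arange(data.shape[2]) / sfreq * 1000.0
    return EpochContainer(data=data, sfreq=sfreq, times=times,
                          channels=names, lock=lock,
                          metadata={"centre_freq": centre_freq,
                                    "n_cycles": n_cycles})
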
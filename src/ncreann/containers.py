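"""Core in-memory containers shared by every pipeline stage.

The universal signal container is :class:`EpochContainer` — a
``trials x channels x samples`` array with an event-relative time axis in
milliseconds.  Source-space power maps live in :class:`VoxelSourceMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["EpochContainer", "VoxelSourceMap"]


@dataclass
class EpochContainer:
    """Epoched multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal values.  Units are arbitrary (scalp-like amplitude or
        band-power, depending on the stage).
    sfreq : float
        Sampling rate in Hz.
    times : ndarray, shape (n_samples,)
        Time axis in milliseconds relative to the lock event.
    channels : list of str
        Channel (or ROI) names.
    lock : str
        Name of the event the time axis is relative to, e.g. ``"cue"`` or
        ``"action_effect"``.
    metadata : dict
        Free-form provenance (condition, phase, subject id, seed, ...).
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    channels: list[str]
    lock: str = "cue"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples), got shape {self.data.shape}"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError(
                f"time axis length {self.times.shape} does not match "
                f"n_samples={self.data.shape[2]}"
            )
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[1]} channels"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochContainer":
        """Return a copy restricted to the half-open window [tmin_ms, tmax_ms)."""
        if tmin_ms < self.times[0] or tmax_ms > self.times[-1] + 1000.0 / self.sfreq:
            raise ValueError(
                f"window [{tmin_ms}, {tmax_ms}) ms outside data range "
                f"[{self.times[0]}, {self.times[-1]}] ms"
            )
        keep = (self.times >= tmin_ms) & (self.times < tmax_ms)
        return EpochContainer(
            data=self.data[:, :, keep].copy(),
            sfreq=self.sfreq,
            times=self.times[keep].copy(),
            channels=list(self.channels),
            lock=self.lock,
            metadata=dict(self.metadata),
        )

    def copy(self) -> "EpochContainer":
        return EpochContainer(
            data=self.data.copy(),
            sfreq=self.sfreq,
            times=self.times.copy(),
            channels=list(self.channels),
            lock=self.lock,
            metadata=dict(self.metadata),
        )


@dataclass
class VoxelSourceMap:
    """Voxel source-power map on a regular millimetre grid.

    Coordinate convention: x right+, y anterior+, z superior+ (MNI-like).
    ``label_id`` carries atlas labels; 0 means unlabelled background.
    """

    coords: np.ndarray  # (N, 3) mm
    power: np.ndarray  # (N,)
    grid_spacing: float  # mm
    brain_mask: np.ndarray  # (N,) bool — True inside the brain
    wm_mask: np.ndarray  # (N,) bool — True inside white matter
    cerebellum_mask: np.ndarray  # (N,) bool — True inside the cerebellum
    label_id: np.ndarray  # (N,) int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        for name in ("power", "brain_mask", "wm_mask", "cerebellum_mask", "label_id"):
            arr = getattr(self, name)
            if arr is None:
                raise ValueError(f"missing required field: {name}")
            if np.shape(arr)[0] != n:
                raise ValueError(f"{name} length {np.shape(arr)[0]} != N={n}")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != n:
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]
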
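"""Synthetic data generators with known ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_nmvar` — coupled M-channel systems with planted directed
  linear (VAR) and nonlinear couplings; the generative twin of the model
  class the estimator fits, ``x(n) = f(x_p) + sigma(n)``.
* :func:`simulate_flicker_eeg` — scalp-like epochs with an entrained
  flicker response (steady-state visual evoked potential) at 4.5 or 8 Hz
  over 1/f background noise.
* :func:`simulate_voxel_map` — voxel source-power maps with planted
  spatial clusters on a synthetic head geometry (synthetic stand-ins for
  template-brain masks and atlas labels).

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import EpochContainer, VoxelSourceMap

__all__ = [
    "NonlinearTerm",
    "CoupledSystemSpec",
    "FlickerEEGSpec",
    "PlantedCluster",
    "VoxelMapSpec",
    "GroundTruth",
    "simulate_nmvar",
    "simulate_flicker_eeg",
    "simulate_voxel_map",
    "ground_truth_adjacency",
    "companion_spectral_radius",
    "DEFAULT_ROI_NAMES",
]

#: Default channel names for 4-channel systems: the theta-band
#: action-effect network nodes (anterior/posterior temporal lobe,
#: insular cortex, inferior frontal cortex).  Purely cosmetic.
DEFAULT_ROI_NAMES = ["ATL", "PTL", "IC", "IFC"]

_NONLINEAR_KINDS = ("quadratic", "product", "threshold")


@dataclass(frozen=True)
class NonlinearTerm:
    """One planted nonlinear coupling from ``source`` into ``target``.

    Functional forms (applied to the lagged sample ``x_s = x[source](n - lag)``):

    * ``quadratic``:  gain * x_s**2
    * ``product``:    gain * x_s * x[target](n - lag)
    * ``threshold``:  tanh(gain * x_s)
    """

    source: int
    target: int
    lag: int
    kind: str
    gain: float

    def __post_init__(self) -> None:
        if self.kind not in _NONLINEAR_KINDS:
            raise ValueError(f"unknown nonlinear kind {self.kind!r}; one of {_NONLINEAR_KINDS}")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix of an (M, M, p) tensor."""
    coeffs = np.asarray(coeffs, dtype=float)
    m, m2, p = coeffs.shape
    if m != m2:
        raise ValueError("linear_coeffs must be (M, M, p)")
    comp = np.zeros((m * p, m * p))
    for k in range(p):
        comp[:m, k * m:(k + 1) * m] = coeffs[:, :, k]
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class CoupledSystemSpec:
    """Specification of a coupled (nonlinear) VAR system.

    ``linear_coeffs[j, i, k]`` is the coefficient from source channel ``i``
    at lag ``k+1`` into target channel ``j`` (row = target, column = source).
    """

    n_channels: int
    order: int
    linear_coeffs: np.ndarray  # (M, M, p)
    nonlinear_terms: list[NonlinearTerm] = field(default_factory=list)
    noise_sd: float | np.ndarray = 1.0
    n_trials: int = 1
    samples_per_trial: int = 1000
    sampling_rate: float = 256.0
    seed: int = 0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.linear_coeffs = np.asarray(self.linear_coeffs, dtype=float)
        m, p = self.n_channels, self.order
        if self.linear_coeffs.shape != (m, m, p):
            raise ValueError(
                f"linear_coeffs must have shape ({m}, {m}, {p}), "
                f"got {self.linear_coeffs.shape}"
            )
        sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (m,))
        if np.any(sd < 0):
            raise ValueError("noise_sd must be >= 0")
        self.noise_sd = sd.copy()
        for t in self.nonlinear_terms:
            if not (0 <= t.source < m and 0 <= t.target < m):
                raise ValueError(
                    f"nonlinear term references channel outside 0..{m - 1}: {t}"
                )
            if t.lag > p:
                raise ValueError(f"nonlinear term lag {t.lag} exceeds order {p}")
        if self.channel_names is None:
            if m == len(DEFAULT_ROI_NAMES):
                self.channel_names = list(DEFAULT_ROI_NAMES)
            else:
                self.channel_names = [f"ch{i}" for i in range(m)]
        elif len(self.channel_names) != m:
            raise ValueError("channel_names length must equal n_channels")

    def validate_stationary(self) -> None:
        rho = companion_spectral_radius(self.linear_coeffs)
        if rho >= 1.0:
            raise ValueError(
                f"linear_coeffs are non-stationary: companion spectral radius "
                f"{rho:.3f} >= 1"
            )


@dataclass
class GroundTruth:
    """Planted directed-coupling support of a :class:`CoupledSystemSpec`.

    ``linear[i, j]`` / ``nonlinear[i, j]`` are True iff any planted
    coefficient or term couples channel ``i`` into channel ``j`` (i != j).
    Self-couplings are reported separately in ``self_linear`` /
    ``self_nonlinear`` and are excluded from recovery scoring.
    """

    linear: np.ndarray  # (M, M) bool, diagonal False
    nonlinear: np.ndarray  # (M, M) bool, diagonal False
    self_linear: np.ndarray  # (M,) bool
    self_nonlinear: np.ndarray  # (M,) bool


def ground_truth_adjacency(spec: CoupledSystemSpec) -> GroundTruth:
    """Directed support matrices (source -> target orientation) of a spec."""
    m = spec.n_channels
    lin = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(m):
            lin[i, j] = bool(np.any(spec.linear_coeffs[j, i, :] != 0.0))
    nonlin = np.zeros((m, m), dtype=bool)
    for t in spec.nonlinear_terms:
        if t.gain != 0.0:
            nonlin[t.source, t.target] = True
    self_lin = np.diag(lin).copy()
    self_nonlin = np.diag(nonlin).copy()
    np.fill_diagonal(lin, False)
    np.fill_diagonal(nonlin, False)
    return GroundTruth(lin, nonlin, self_lin, self_nonlin)


def _nonlinear_drive(spec: CoupledSystemSpec, history: np.ndarray, n: int) -> np.ndarray:
    """Summed nonlinear contribution to sample ``n`` given past ``history``."""
    out = np.zeros(spec.n_channels)
    for t in spec.nonlinear_terms:
        xs = history[t.source, n - t.lag]
        if t.kind == "quadratic":
            out[t.target] += t.gain * xs * xs
        elif t.kind == "product":
            out[t.target] += t.gain * xs * history[t.target, n - t.lag]
        else:  # threshold
            out[t.target] += np.tanh(t.gain * xs)
    return out


def simulate_nmvar(spec: CoupledSystemSpec) -> EpochContainer:
    """Simulate ``n_trials`` independent realizations of a coupled system.

    Each sample is ``x(n) = A_1 x(n-1) + ... + A_p x(n-p) + g(x_past) + e(n)``
    with Gaussian innovations ``e`` and the spec's planted nonlinear terms
    ``g``.  A burn-in of ``max(10 p, 200)`` samples removes dependence on the
    zero initial state.  Non-stationary linear coefficients are rejected
    before simulation.
    """
    spec.validate_stationary()
    m, p = spec.n_channels, spec.order
    burn = max(10 * p, 200)
    total = spec.samples_per_trial + burn + p
    rng = np.random.default_rng(spec.seed)
    data = np.empty((spec.n_trials, m, spec.samples_per_trial))
    lag_mats = [spec.linear_coeffs[:, :, k] for k in range(p)]
    has_nl = len(spec.nonlinear_terms) > 0
    for trial in range(spec.n_trials):
        x = np.zeros((m, total))
        noise = rng.standard_normal((m, total)) * spec.noise_sd[:, None]
        for n in range(p, total):
            acc = noise[:, n].copy()
            for k in range(p):
                acc += lag_mats[k] @ x[:, n - k - 1]
            if has_nl:
                acc += _nonlinear_drive(spec, x, n)
            x[:, n] = acc
        data[trial] = x[:, p + burn:]
    times = np.arange(spec.samples_per_trial) / spec.sampling_rate * 1000.0
    return EpochContainer(
        data=data,
        sfreq=spec.sampling_rate,
        times=times,
        channels=list(spec.channel_names),
        lock="trial_start",
        metadata={"generator": "simulate_nmvar", "seed": spec.seed},
    )


@dataclass
class FlickerEEGSpec:
    """Specification of flicker-entrained scalp-like epochs.

    The flicker response is a sinusoid at ``flicker_freq`` added to
    ``responsive_channels`` from ``flicker_onset`` for ``flicker_duration``
    milliseconds; every channel carries independent 1/f background noise.
    Default frequencies on offer are 4.5 Hz (tagged) and 8 Hz (control).
    """

    flicker_freq: float = 4.5
    flicker_onset: float = 0.0  # ms relative to epoch zero
    flicker_duration: float = 2000.0  # ms
    flicker_amplitude: float = 1.0
    responsive_channels: Sequence[int] = (0,)
    background_exponent: float = 1.0  # 1/f^exponent power spectrum
    background_sd: float = 1.0
    n_trials: int = 20
    n_channels: int = 8
    epoch_window: tuple[float, float] = (-1000.0, 2500.0)  # [start, end) ms
    sampling_rate: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flicker_freq >= self.sampling_rate / 2:
            raise ValueError(
                f"flicker_freq {self.flicker_freq} Hz >= Nyquist "
                f"{self.sampling_rate / 2} Hz"
            )
        start, end = self.epoch_window
        if start >= end:
            raise ValueError("epoch_window start must be < end")
        if not (start <= self.flicker_onset < end):
            raise ValueError(
                f"flicker_onset {self.flicker_onset} ms outside epoch window "
                f"[{start}, {end}) ms"
            )
        for ch in self.responsive_channels:
            if not 0 <= ch < self.n_channels:
                raise ValueError(f"responsive channel {ch} outside 0..{self.n_channels - 1}")


def _one_over_f_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                      exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-free scale sd."""
    white = rng.standard_normal((n_series, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    std = shaped.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std * sd


def simulate_flicker_eeg(spec: FlickerEEGSpec) -> EpochContainer:
    """Simulate epochs with a flicker-entrained response over 1/f noise.

    With ``flicker_amplitude = 0`` the output is bit-identical to
    background-only generation under the same seed (the sinusoid is added
    deterministically after all random draws).
    """
    rng = np.random.default_rng(spec.seed)
    start, end = spec.epoch_window
    n_samples = int(round((end - start) * spec.sampling_rate / 1000.0))
    times = start + np.arange(n_samples) / spec.sampling_rate * 1000.0
    data = np.empty((spec.n_trials, spec.n_channels, n_samples))
    for trial in range(spec.n_trials):
        data[trial] = _one_over_f_noise(
            rng, spec.n_channels, n_samples, spec.background_exponent,
            spec.background_sd,
        )
    on = (times >= spec.flicker_onset) & (
        times < min(spec.flicker_onset + spec.flicker_duration, end))
    t_sec = (times[on] - spec.flicker_onset) / 1000.0
    wave = spec.flicker_amplitude * np.sin(2.0 * np.pi * spec.flicker_freq * t_sec)
    for ch in spec.responsive_channels:
        data[:, ch, on] += wave
    return EpochContainer(
        data=data,
        sfreq=spec.sampling_rate,
        times=times,
        channels=[f"ch{i}" for i in range(spec.n_channels)],
        lock="cue",
        metadata={
            "generator": "simulate_flicker_eeg",
            "seed": spec.seed,
            "flicker_freq": spec.flicker_freq,
            "responsive_channels": list(spec.responsive_channels),
        },
    )


@dataclass(frozen=True)
class PlantedCluster:
    """A spherical high-power blob planted in a voxel map."""

    centre: tuple[float, float, float]  # mm
    radius: float  # mm
    power: float  # added on top of background inside the sphere
    label_id: int = 1


@dataclass
class VoxelMapSpec:
    """Specification of a synthetic voxel source-power map.

    The head geometry is synthetic: brain = axis-aligned ellipsoid with
    ``brain_radii``; white matter = inner sphere of ``wm_radius`` at the
    origin; cerebellum = posterior-inferior block (y < -45 and z < -20 mm).
    Atlas labels are synthetic ids: background voxels get
    ``background_label``, each planted cluster stamps its own ``label_id``.
    """

    grid_spacing: float = 5.0  # mm
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    background_mean: float = 1.0
    background_sd: float = 0.2
    extent: float = 70.0  # grid spans [-extent, extent] mm per axis
    brain_radii: tuple[float, float, float] = (65.0, 80.0, 65.0)
    wm_radius: float = 12.0
    background_label: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")

    def _inside_brain(self, pts: np.ndarray) -> np.ndarray:
        rx, ry, rz = self.brain_radii
        return ((pts[:, 0] / rx) ** 2 + (pts[:, 1] / ry) ** 2
                + (pts[:, 2] / rz) ** 2) <= 1.0


def simulate_voxel_map(spec: VoxelMapSpec) -> VoxelSourceMap:
    """Build a voxel map with planted clusters over noisy background power.

    Planted clusters have strictly higher expected power than background.
    Cluster centres outside the brain mask, or an empty brain mask, are
    rejected.
    """
    ax = np.arange(-spec.extent, spec.extent + 0.5 * spec.grid_spacing,
                   spec.grid_spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    brain = spec._inside_brain(coords)
    if not np.any(brain):
        raise ValueError("empty brain mask: no voxel lies inside brain_radii")
    wm = np.linalg.norm(coords, axis=1) <= spec.wm_radius
    cerebellum = (coords[:, 1] < -45.0) & (coords[:, 2] < -20.0)
    rng = np.random.default_rng(spec.seed)
    power = np.abs(rng.normal(spec.background_mean, spec.background_sd,
                              coords.shape[0]))
    labels = np.full(coords.shape[0], spec.background_label, dtype=int)
    for cl in spec.planted_clusters:
        centre = np.asarray(cl.centre, dtype=float)
        if not spec._inside_brain(centre[None, :])[0]:
            raise ValueError(f"planted cluster centre {cl.centre} outside the brain mask")
        inside = np.linalg.norm(coords - centre, axis=1) <= cl.radius
        power[inside] += cl.power
        labels[inside] = cl.label_id
    return VoxelSourceMap(
        coords=coords,
        power=power,
        grid_spacing=spec.grid_spacing,
        brain_mask=brain,
        wm_mask=wm,
        cerebellum_mask=cerebellum,
        label_id=labels,
    )
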
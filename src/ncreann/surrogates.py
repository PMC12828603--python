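"""Time-shifted surrogate null distributions for the connectivity measures.

Each surrogate dataset circularly shifts every channel of every trial by
an independent random offset, destroying cross-channel temporal alignment
while preserving each channel's marginal autocorrelation structure.  The
estimator is refit on each surrogate with identical hyperparameters, and
per-pair null distributions of lC and NC gate all group-level analysis
(default: 100 surrogates, one-sided 95th-percentile thresholds per pair
and measure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochContainer
from .model import (DirectedConnectivityResult, TrainingConfig,
                    estimate_connectivity, _as_trial_array)

__all__ = ["SurrogateNull", "make_surrogate", "null_distribution",
           "significance_mask"]

logger = logging.getLogger(__name__)


@dataclass
class SurrogateNull:
    """Per-pair surrogate values of lC and NC, shape (n_ok, M, M)."""

    lc_values: np.ndarray
    nc_values: np.ndarray
    percentile: float = 95.0
    n_failures: int = 0
    seeds: list = field(default_factory=list)

    def threshold(self, measure: str) -> np.ndarray:
        """Per-pair one-sided threshold at ``percentile``.

        Uses the 'higher' order-statistic method: with S surrogates the
        threshold is the ceil(q*(S-1))-th order statistic, so under the
        null (exchangeability) the rejection probability is at most
        (1-q) * (S+1)/S -- exact 1/(S+1) when the threshold is the
        surrogate maximum.
        """
        values = {"linear": self.lc_values, "nonlinear": self.nc_values}[measure]
        if values.shape[0] == 0:
            raise ValueError("no successful surrogates")
        return np.percentile(values, self.percentile, axis=0, method="higher")


def make_surrogate(series, p: int, rng: np.random.Generator) -> np.ndarray:
    """Circularly time-shift every channel of every trial independently.

    Offsets are uniform on [p+1, T-p-1]; the minimum shift of p+1 samples
    prevents near-identity surrogates, and offsets are redrawn until every
    pairwise relative circular shift is also at least p+1 (two channels
    shifted by the same amount would keep their alignment intact).  Series
    shorter than 2(p+1) samples are rejected.
    """
    data, _ = _as_trial_array(series)
    n_trials, m, t = data.shape
    if m < 2:
        raise ValueError("surrogates need >= 2 channels")
    if t < 2 * (p + 1):
        raise ValueError(
            f"series of {t} samples too short for time-shift surrogates at "
            f"order {p} (need >= {2 * (p + 1)})"
        )
    out = np.empty_like(data)
    for trial in range(n_trials):
        for _ in range(1000):
            shifts = rng.integers(p + 1, t - p - 1, endpoint=True, size=m)
            rel = np.abs(shifts[:, None] - shifts[None, :])
            rel = np.minimum(rel, t - rel)[np.triu_indices(m, 1)]
            if np.all(rel >= p + 1):
                break
        else:
            raise RuntimeError("could not draw well-separated channel shifts")
        for ch in range(m):
            out[trial, ch] = np.roll(data[trial, ch], shifts[ch])
    return out


def null_distribution(series, config: TrainingConfig, p: int,
                      n_surrogates: int = 100, percentile: float = 95.0,
                      seed: int = 0) -> SurrogateNull:
    """Refit the full estimator on each surrogate and collect lC / NC.

    Identical network hyperparameters are applied to original and
    surrogate data (generalization cross-validation is skipped: only the
    connectivity matrices of the refit model are needed).  Surrogate fits
    that fail are recorded and excluded.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    data, _ = _as_trial_array(series)
    lc_list, nc_list, seeds = [], [], []
    n_failures = 0
    surr_config = TrainingConfig(**{**config.__dict__, "compute_cv": False})
    for s in range(n_surrogates):
        rng = np.random.default_rng((seed, 7001, s))
        surr = make_surrogate(data, p, rng)
        surr_config.seed = int(np.random.default_rng((seed, 7002, s)
                                                     ).integers(2 ** 31))
        try:
            res = estimate_connectivity(surr, surr_config, p)
        except Exception as exc:  # noqa: BLE001 — failures recorded, not fatal
            logger.warning("surrogate %d fit failed: %s", s, exc)
            n_failures += 1
            continue
        lc_list.append(res.lc)
        nc_list.append(res.nc)
        seeds.append(surr_config.seed)
    if not lc_list:
        raise RuntimeError("every surrogate fit failed")
    return SurrogateNull(lc_values=np.stack(lc_list),
                         nc_values=np.stack(nc_list),
                         percentile=percentile, n_failures=n_failures,
                         seeds=seeds)


def significance_mask(result: DirectedConnectivityResult, null: SurrogateNull,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (linear, nonlinear) masks: original value above its per-pair
    null threshold.  Diagonal entries are always False."""
    masks = []
    for measure, values in (("linear", result.lc), ("nonlinear", result.nc)):
        thr = null.threshold(measure)
        if thr.shape != values.shape:
            raise ValueError("null and result pair sets do not match")
        mask = values > thr
        np.fill_diagonal(mask, False)
        masks.append(mask)
    return masks[0], masks[1]
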
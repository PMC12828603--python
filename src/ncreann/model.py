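"""Nonlinear multivariate autoregressive (nMVAR) estimation and the
linear / nonlinear directed-connectivity measures.

The model class is ``x(n) = f(x_p) + e(n)`` where ``x_p`` stacks the past
``p`` samples of all ``M`` channels and ``f`` is a single-hidden-layer
perceptron (six hidden tanh units by default, linear outputs).  The
network's input-output map is split into linear and nonlinear parts by a
first-order Taylor expansion of the hidden units about zero (the mean of
the z-scored inputs):

* linear connectivity ``lC[i, j]`` — the mean absolute Taylor-linear
  coefficient from channel i's past onto channel j, over lags;
* nonlinear connectivity ``NC[i, j]`` — the log ratio of the model's
  mean squared prediction error for channel j when channel i is
  restricted to its linear contribution, over the full model's error.
  Positive NC means channel i exerts genuine nonlinear influence on j.

Training follows the incremental (per-sample) backpropagation protocol:
momentum, an adaptive learning rate (multiplicative increase after an
epoch whose training error falls, decrease otherwise), early stopping on
a validation split, weights initialized uniformly in +-0.5, and 5-fold
permuted cross-validation over an 80/10/10 train/validation/test split
for the generalization metrics.  Autoregressive order is chosen by the
Schwarz Bayesian Criterion on linear VAR fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._train import forward, sgd_epoch
from .containers import EpochContainer

__all__ = [
    "TrainingConfig",
    "NMVARModel",
    "FitMetrics",
    "DirectedConnectivityResult",
    "build_lag_matrix",
    "select_model_order",
    "fit_nmvar",
    "taylor_linear_part",
    "linear_connectivity",
    "nonlinear_connectivity",
    "estimate_connectivity",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the network fit.

    The learning rate is adaptive: multiplied by ``lr_up`` after an epoch
    whose training MSE decreased and by ``lr_down`` otherwise, floored at
    ``lr_floor``.  ``split`` is the train/validation/test partition applied
    to a permuted sample order in each cross-validation fold.
    """

    hidden: int = 6
    activation: str = "tanh"  # "tanh" or "linear"
    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_up: float = 1.05
    lr_down: float = 0.7
    lr_floor: float = 1e-6
    max_epochs: int = 150
    patience: int = 15
    folds: int = 5
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    init_range: float = 0.5
    seed: int = 0
    compute_cv: bool = True

    def __post_init__(self) -> None:
        if self.activation not in ("tanh", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split must sum to 1, got {self.split}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.hidden < 1 or self.max_epochs < 1:
            raise ValueError("hidden and max_epochs must be >= 1")


@dataclass
class NMVARModel:
    """Fitted single-hidden-layer nonlinear MVAR model.

    Input ordering is lag-major: the lag vector is
    ``[x_1(n-1)..x_M(n-1), x_1(n-2)..x_M(n-2), ..., x_M(n-p)]`` on the
    standardized (per-channel z-scored) scale captured at fit time.
    """

    W_in: np.ndarray  # (hidden, M*p)
    b_hidden: np.ndarray  # (hidden,)
    W_out: np.ndarray  # (M, hidden)
    b_out: np.ndarray  # (M,)
    order: int
    activation: str
    channel_means: np.ndarray  # (M,)
    channel_sds: np.ndarray  # (M,)
    channel_names: list[str]

    @property
    def n_channels(self) -> int:
        return self.W_out.shape[0]

    @property
    def linear_act(self) -> bool:
        return self.activation == "linear"

    def predict(self, lag_vector: np.ndarray) -> np.ndarray:
        """Forward map for one standardized lag vector of length M*p."""
        lag_vector = np.asarray(lag_vector, dtype=float)
        expected = self.n_channels * self.order
        if lag_vector.shape != (expected,):
            raise ValueError(
                f"lag vector must have length M*p = {expected}, "
                f"got shape {lag_vector.shape}"
            )
        return forward(lag_vector[None, :], self.W_in, self.b_hidden,
                       self.W_out, self.b_out, self.linear_act)[0]

    def forward_batch(self, X: np.ndarray) -> np.ndarray:
        return forward(X, self.W_in, self.b_hidden, self.W_out, self.b_out,
                       self.linear_act)

    def to_dict(self) -> dict:
        return {
            "W_in": self.W_in.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "W_out": self.W_out.tolist(),
            "b_out": self.b_out.tolist(),
            "order": int(self.order),
            "activation": self.activation,
            "channel_means": self.channel_means.tolist(),
            "channel_sds": self.channel_sds.tolist(),
            "channel_names": list(self.channel_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NMVARModel":
        return cls(
            W_in=np.asarray(d["W_in"], dtype=float),
            b_hidden=np.asarray(d["b_hidden"], dtype=float),
            W_out=np.asarray(d["W_out"], dtype=float),
            b_out=np.asarray(d["b_out"], dtype=float),
            order=int(d["order"]),
            activation=d["activation"],
            channel_means=np.asarray(d["channel_means"], dtype=float),
            channel_sds=np.asarray(d["channel_sds"], dtype=float),
            channel_names=list(d["channel_names"]),
        )


@dataclass
class FitMetrics:
    """Fold-averaged fit quality plus per-fold records."""

    mse_train: float
    mse_val: float
    mse_test: float
    r2_train: float
    r2_test: float
    per_fold: list[dict] = field(default_factory=list)


@dataclass
class DirectedConnectivityResult:
    """M x M directed connectivity matrices; entry [i, j] is i -> j."""

    lc: np.ndarray
    nc: np.ndarray
    fit: FitMetrics
    channels: list[str]
    order: int
    orientation: str = "source->target: entry [i, j] quantifies i -> j"


def _as_trial_array(series) -> tuple[np.ndarray, list[str]]:
    if isinstance(series, EpochContainer):
        return series.data, list(series.channels)
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError("series must be (trials, channels, samples)")
    return arr, [f"ch{i}" for i in range(arr.shape[1])]


def build_lag_matrix(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Pooled lag design across trials; no lag vector straddles a trial.

    Returns ``X`` of shape (N, M*p) in lag-major order and targets ``Y``
    of shape (N, M), with ``N = n_trials * (T - p)``.
    """
    n_trials, m, t = data.shape
    if t <= p:
        raise ValueError(f"trials of {t} samples too short for order {p}")
    rows = []
    targets = []
    for trial in range(n_trials):
        x = data[trial]
        cols = [x[:, p - k:t - k].T for k in range(1, p + 1)]  # lag-major
        rows.append(np.hstack(cols))
        targets.append(x[:, p:].T)
    return np.vstack(rows), np.vstack(targets)


def select_model_order(series, candidates: Sequence[int] = range(1, 11),
                       ) -> int:
    """Schwarz-Bayesian-Criterion order selection on linear VAR fits.

    Each candidate order is fit by least squares on the same effective
    sample (the one feasible for the largest candidate); the SBC-minimizing
    order is returned.  Candidates too long for the data are skipped with
    a warning.
    """
    data, _ = _as_trial_array(series)
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates or candidates[0] < 1:
        raise ValueError("candidate orders must be >= 1")
    m = data.shape[1]
    t = data.shape[2]
    feasible = []
    for p in candidates:
        n_eff = data.shape[0] * (t - p)
        if t <= p or n_eff <= p * m + m:
            warnings.warn(f"order candidate {p} skipped: insufficient samples")
            continue
        feasible.append(p)
    if not feasible:
        raise ValueError("no feasible candidate orders for this series length")
    p_max = feasible[-1]
    X_full, Y = build_lag_matrix(data, p_max)
    n = X_full.shape[0]
    best_p, best_sbc = feasible[0], np.inf
    for p in feasible:
        X = np.hstack([X_full[:, :p * m], np.ones((n, 1))])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        sigma = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            warnings.warn(f"order candidate {p} skipped: degenerate residual covariance")
            continue
        sbc = logdet + np.log(n) / n * (p * m * m + m)
        if sbc < best_sbc:
            best_p, best_sbc = p, sbc
    return best_p


def _init_weights(rng: np.random.Generator, hidden: int, d_in: int, m: int,
                  init_range: float):
    return (rng.uniform(-init_range, init_range, (hidden, d_in)),
            rng.uniform(-init_range, init_range, hidden),
            rng.uniform(-init_range, init_range, (m, hidden)),
            rng.uniform(-init_range, init_range, m))


def _mse(X, Y, weights, linear_act) -> float:
    pred = forward(X, *weights, linear_act)
    return float(np.mean((pred - Y) ** 2))


def _train_run(X, Y, train_idx, val_idx, config: TrainingConfig,
               rng: np.random.Generator, lr_scale: float = 1.0):
    """One training run with adaptive LR and early stopping on val MSE."""
    hidden, d_in, m = config.hidden, X.shape[1], Y.shape[1]
    W1, b1, W2, b2 = _init_weights(rng, hidden, d_in, m, config.init_range)
    vW1, vb1 = np.zeros_like(W1), np.zeros_like(b1)
    vW2, vb2 = np.zeros_like(W2), np.zeros_like(b2)
    linear_act = config.activation == "linear"
    lr = config.learning_rate * lr_scale
    best = {"val": np.inf, "weights": None, "epoch": -1}
    prev_train = np.inf
    wait = 0
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        train_mse = sgd_epoch(X, Y, W1, b1, W2, b2, vW1, vb1, vW2, vb2,
                              lr, config.momentum, order, linear_act)
        if not np.isfinite(train_mse):
            return None, history  # caller retries with halved learning rate
        val_mse = _mse(X[val_idx], Y[val_idx], (W1, b1, W2, b2), linear_act)
        history.append({"epoch": epoch, "train_mse": float(train_mse),
                        "val_mse": val_mse, "lr": lr})
        if val_mse < best["val"] - 1e-12:
            best = {"val": val_mse,
                    "weights": (W1.copy(), b1.copy(), W2.copy(), b2.copy()),
                    "epoch": epoch}
            wait = 0
        else:
            wait += 1
            if wait > config.patience:
                break
        lr = max(lr * (config.lr_up if train_mse < prev_train
                       else config.lr_down), config.lr_floor)
        prev_train = train_mse
    weights = best["weights"] if best["weights"] is not None else (W1, b1, W2, b2)
    return weights, history


def _train_with_retry(X, Y, train_idx, val_idx, config, seed):
    rng = np.random.default_rng(seed)
    weights, history = _train_run(X, Y, train_idx, val_idx, config, rng)
    if weights is None:
        rng = np.random.default_rng(seed)
        weights, history = _train_run(X, Y, train_idx, val_idx, config, rng,
                                      lr_scale=0.5)
        if weights is None:
            raise RuntimeError(
                "training diverged (non-finite loss) even after halving the "
                f"learning rate; last epochs: {history[-3:]}"
            )
    return weights, history


def _r2(X, Y, weights, linear_act) -> float:
    pred = forward(X, *weights, linear_act)
    ss_res = float(np.sum((Y - pred) ** 2))
    ss_tot = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_nmvar(series, config: TrainingConfig, p: int,
              ) -> tuple[NMVARModel, FitMetrics]:
    """Fit the nonlinear MVAR network to per-trial multichannel series.

    Channels are z-scored over the pooled samples before the lag design is
    built; trials are treated as separate sequences.  When
    ``config.compute_cv`` is set, generalization metrics come from 5-fold
    permuted cross-validation (per fold, the sample order is shuffled with
    a fold-specific seed and split 80/10/10); the reported model is always
    a final refit on all data with early stopping against a held-out 10%.
    """
    data, names = _as_trial_array(series)
    means = data.mean(axis=(0, 2))
    sds = data.std(axis=(0, 2))
    if np.any(sds == 0):
        raise ValueError("constant channel: cannot standardize")
    z = (data - means[None, :, None]) / sds[None, :, None]
    X, Y = build_lag_matrix(z, p)
    n = X.shape[0]
    f_train, f_val, _ = config.split
    per_fold = []
    if config.compute_cv:
        for fold in range(config.folds):
            rng = np.random.default_rng((config.seed, 101, fold))
            perm = rng.permutation(n)
            n_tr = int(round(f_train * n))
            n_va = int(round(f_val * n))
            tr, va, te = (perm[:n_tr], perm[n_tr:n_tr + n_va],
                          perm[n_tr + n_va:])
            weights, _ = _train_with_retry(X, Y, tr, va, config,
                                           (config.seed, 202, fold))
            lin = config.activation == "linear"
            per_fold.append({
                "fold": fold,
                "mse_train": _mse(X[tr], Y[tr], weights, lin),
                "mse_val": _mse(X[va], Y[va], weights, lin),
                "mse_test": _mse(X[te], Y[te], weights, lin),
                "r2_train": _r2(X[tr], Y[tr], weights, lin),
                "r2_test": _r2(X[te], Y[te], weights, lin),
            })
    # final refit on all data, early stopping against a held-out 10%
    rng = np.random.default_rng((config.seed, 303))
    perm = rng.permutation(n)
    n_va = max(1, int(round(f_val * n)))
    tr, va = perm[n_va:], perm[:n_va]
    weights, _ = _train_with_retry(X, Y, tr, va, config, (config.seed, 404))
    lin = config.activation == "linear"
    if per_fold:
        metrics = FitMetrics(
            mse_train=float(np.mean([f["mse_train"] for f in per_fold])),
            mse_val=float(np.mean([f["mse_val"] for f in per_fold])),
            mse_test=float(np.mean([f["mse_test"] for f in per_fold])),
            r2_train=float(np.mean([f["r2_train"] for f in per_fold])),
            r2_test=float(np.mean([f["r2_test"] for f in per_fold])),
            per_fold=per_fold,
        )
    else:
        mse_all = _mse(X, Y, weights, lin)
        r2_all = _r2(X, Y, weights, lin)
        metrics = FitMetrics(mse_train=mse_all, mse_val=_mse(X[va], Y[va], weights, lin),
                             mse_test=mse_all, r2_train=r2_all, r2_test=r2_all)
    model = NMVARModel(W_in=weights[0], b_hidden=weights[1],
                       W_out=weights[2], b_out=weights[3], order=p,
                       activation=config.activation, channel_means=means,
                       channel_sds=sds, channel_names=names)
    return model, metrics


def _act_deriv_at_bias(model: NMVARModel) -> np.ndarray:
    """Hidden-unit activation slopes at the expansion point (input 0)."""
    if model.linear_act:
        return np.ones_like(model.b_hidden)
    return 1.0 - np.tanh(model.b_hidden) ** 2


def taylor_linear_part(model: NMVARModel) -> np.ndarray:
    """First-order Taylor coefficients as an (M, M, p) tensor.

    Expansion about input 0 (the mean of the z-scored data):
    ``J = W_out @ diag(act'(b_hidden)) @ W_in``, reshaped so that
    ``A[j, i, k]`` is the coefficient from source i at lag k+1 into
    target j.
    """
    m, p = model.n_channels, model.order
    J = model.W_out @ (_act_deriv_at_bias(model)[:, None] * model.W_in)
    A = np.empty((m, m, p))
    for k in range(p):
        A[:, :, k] = J[:, k * m:(k + 1) * m]
    return A


def linear_connectivity(model: NMVARModel) -> np.ndarray:
    """lC matrix: mean over lags of absolute Taylor-linear coefficients.

    Entry [i, j] quantifies the linear influence of channel i on channel
    j; nonnegative by construction.  The diagonal (self-influence) is
    computed but excluded from inference downstream.
    """
    A = taylor_linear_part(model)
    return np.mean(np.abs(A), axis=2).T


def _taylor_parts(model: NMVARModel, X: np.ndarray):
    act = (lambda a: a) if model.linear_act else np.tanh
    f0 = model.W_out @ act(model.b_hidden) + model.b_out
    J = model.W_out @ (_act_deriv_at_bias(model)[:, None] * model.W_in)
    f_lin = f0[None, :] + X @ J.T
    return f0, J, f_lin


def nonlinear_connectivity(model: NMVARModel, series) -> np.ndarray:
    """NC matrix: log error ratio of linear-restricted vs full model.

    For each ordered pair (i, j), the restricted prediction keeps channel
    i's Taylor-linear contribution but removes it from the nonlinear part
    (channel i's lags are zeroed inside the nonlinear component only —
    zero is the mean of the standardized inputs):

        NC[i, j] = ln( <eps_j^2 restricted> / <eps_j^2 full> )

    Computed on the data the model was fit to, on the standardized scale.
    The diagonal is set to 0 (self-pairs are not interpreted).
    """
    data, _ = _as_trial_array(series)
    z = ((data - model.channel_means[None, :, None])
         / model.channel_sds[None, :, None])
    X, Y = build_lag_matrix(z, model.order)
    m, p = model.n_channels, model.order
    full = model.forward_batch(X)
    _, _, f_lin = _taylor_parts(model, X)
    f_nl = full - f_lin
    eps_full = Y - full
    den = np.mean(eps_full ** 2, axis=0)  # per target j
    if np.any(den == 0):
        raise ValueError("zero residual for some channel: degenerate perfect fit")
    nc = np.zeros((m, m))
    for i in range(m):
        Xi = X.copy()
        Xi[:, i::m] = 0.0  # zero channel i's lags (lag-major layout)
        full_i = model.forward_batch(Xi)
        _, _, f_lin_i = _taylor_parts(model, Xi)
        f_nl_i = full_i - f_lin_i
        restricted = f_lin + f_nl_i
        num = np.mean((Y - restricted) ** 2, axis=0)
        nc[i, :] = np.log(num / den)
    np.fill_diagonal(nc, 0.0)
    return nc


def estimate_connectivity(series, config: TrainingConfig, p: int,
                          ) -> DirectedConnectivityResult:
    """Fit the network and derive both directed-connectivity matrices."""
    model, metrics = fit_nmvar(series, config, p)
    lc = linear_connectivity(model)
    nc = nonlinear_connectivity(model, series)
    _, names = _as_trial_array(series)
    return DirectedConnectivityResult(lc=lc, nc=nc, fit=metrics,
                                      channels=names, order=p)
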
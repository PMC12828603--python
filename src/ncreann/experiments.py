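"""Validation experiments on synthetic data with known ground truth.

Each function runs one self-contained study of the pipeline: recovery of
planted directed couplings, the linear-activation exactness limit,
surrogate-null calibration and specificity, fit generalization quality,
flicker-tagging detection, ROI recovery, and the behaviour of the
contrast battery under a global null.  The default problem sizes are
scaled-down study conditions chosen so each experiment completes on one
CPU in minutes; every source of randomness derives from the ``seed``
argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import derive_seed
from .model import (TrainingConfig, build_lag_matrix, estimate_connectivity,
                    fit_nmvar)
from .roi import (cluster_voxels, filter_voxels, select_top_fraction,
                  select_rois, NOISE)
from .stats import (ContrastSpec, bayes_factor, d_from_t, p_from_t,
                    run_contrast)
from .surrogates import null_distribution, significance_mask
from .synthetic import (CoupledSystemSpec, FlickerEEGSpec, NonlinearTerm,
                        PlantedCluster, VoxelMapSpec,
                        companion_spectral_radius, ground_truth_adjacency,
                        simulate_flicker_eeg, simulate_nmvar,
                        simulate_voxel_map)
from .tagging import (morlet_tfr, pointwise_frequency_contrast,
                      relative_power_change)

__all__ = [
    "printed_statistics",
    "linear_limit",
    "support_recovery",
    "nonlinear_specificity",
    "surrogate_calibration",
    "fit_quality",
    "tagging_detection",
    "roi_recovery",
    "global_null_battery",
]


def printed_statistics() -> dict[str, float]:
    """Worked-example statistics that are pure functions of (t, n).

    Reproduces the p / Cohen's d / BF10 conventions on reported paired
    t-statistics at n = 50 participants.
    """
    return {
        "reaction_time_p": p_from_t(1.58, 49),
        "reaction_time_d": d_from_t(1.58, 50),
        "accuracy_p": p_from_t(1.54, 49),
        "stimulation_contrast_d": d_from_t(3.97, 50),
        "asymmetry_contrast_d": d_from_t(5.68, 50),
        "stimulation_contrast_bf10": bayes_factor(3.97, 50),
        "asymmetry_contrast_bf10": bayes_factor(5.68, 50),
    }


def _fixed_var2_spec(seed: int, t: int = 2000) -> CoupledSystemSpec:
    """A fixed stationary 4-channel VAR(2) with planted cross couplings."""
    m, p = 4, 2
    coeffs = np.zeros((m, m, p))
    for ch in range(m):
        coeffs[ch, ch, 0] = 0.4
    coeffs[1, 0, 0] = 0.35   # 0 -> 1, lag 1
    coeffs[2, 1, 0] = -0.30  # 1 -> 2, lag 1
    coeffs[3, 2, 1] = 0.30   # 2 -> 3, lag 2
    coeffs[0, 3, 1] = 0.25   # 3 -> 0, lag 2
    return CoupledSystemSpec(n_channels=m, order=p, linear_coeffs=coeffs,
                             noise_sd=1.0, samples_per_trial=t, seed=seed)


def _ls_linear_connectivity(data: np.ndarray, p: int) -> np.ndarray:
    """Least-squares VAR fit on z-scored data, aggregated like lC."""
    z = ((data - data.mean(axis=(0, 2))[None, :, None])
         / data.std(axis=(0, 2))[None, :, None])
    X, Y = build_lag_matrix(z, p)
    Xi = np.hstack([X, np.ones((X.shape[0], 1))])
    beta, *_ = np.linalg.lstsq(Xi, Y, rcond=None)
    m = data.shape[1]
    A = np.empty((m, m, p))
    for k in range(p):
        A[:, :, k] = beta[k * m:(k + 1) * m, :].T
    return np.mean(np.abs(A), axis=2).T


def linear_limit(seed: int = 1) -> dict[str, float]:
    """Linear-activation exactness: NC must vanish and lC must match the
    least-squares VAR coefficient magnitudes on a VAR(2) system."""
    spec = _fixed_var2_spec(derive_seed(seed, "linear-limit"))
    epochs = simulate_nmvar(spec)
    # linear problem: long schedule with aggressive decay for a precise optimum
    config = TrainingConfig(activation="linear", learning_rate=0.005,
                            max_epochs=800, patience=150, lr_down=0.5,
                            seed=derive_seed(seed, "linear-limit-fit"),
                            compute_cv=False)
    res = estimate_connectivity(epochs, config, spec.order)
    lc_ls = _ls_linear_connectivity(epochs.data, spec.order)
    rel_err = float(np.linalg.norm(res.lc - lc_ls) / np.linalg.norm(lc_ls))
    return {"max_abs_nc": float(np.max(np.abs(res.nc))),
            "lc_rel_err": rel_err}


def _random_coupled_spec(seed: int, t: int = 2000) -> CoupledSystemSpec:
    """Random 4-channel VAR(2) with 4 planted off-diagonal couplings
    (|a| >= 0.3), rescaled toward stationarity if needed."""
    rng = np.random.default_rng(seed)
    m, p = 4, 2
    coeffs = np.zeros((m, m, p))
    for ch in range(m):
        coeffs[ch, ch, 0] = 0.4
    pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
    chosen = rng.choice(len(pairs), size=4, replace=False)
    for idx in chosen:
        i, j = pairs[idx]
        a = rng.uniform(0.3, 0.45) * rng.choice([-1.0, 1.0])
        coeffs[j, i, rng.integers(p)] = a
    while companion_spectral_radius(coeffs) >= 0.97:
        coeffs *= 0.95
    return CoupledSystemSpec(n_channels=m, order=p, linear_coeffs=coeffs,
                             noise_sd=1.0, samples_per_trial=t,
                             seed=derive_seed(seed, "noise"))


def support_recovery(n_systems: int = 20, seed: int = 1) -> dict[str, float]:
    """Ranking off-diagonal pairs by lC must separate planted from absent
    linear couplings; returns the mean per-system AUC."""
    aucs = []
    for s in range(n_systems):
        spec = _random_coupled_spec(derive_seed(seed, "support", s))
        truth = ground_truth_adjacency(spec)
        epochs = simulate_nmvar(spec)
        config = TrainingConfig(seed=derive_seed(seed, "support-fit", s),
                                compute_cv=False)
        res = estimate_connectivity(epochs, config, spec.order)
        off = ~np.eye(4, dtype=bool)
        aucs.append(roc_auc_score(truth.linear[off], res.lc[off]))
    return {"mean_auc": float(np.mean(aucs)), "n_systems": n_systems}


def _quadratic_pair_spec(seed: int, t: int = 512) -> CoupledSystemSpec:
    """Two channels, one planted quadratic coupling 0 -> 1, no linear
    cross-coupling."""
    coeffs = np.zeros((2, 2, 1))
    coeffs[0, 0, 0] = 0.5
    coeffs[1, 1, 0] = 0.4
    return CoupledSystemSpec(
        n_channels=2, order=1, linear_coeffs=coeffs,
        nonlinear_terms=[NonlinearTerm(0, 1, 1, "quadratic", 0.5)],
        noise_sd=1.0, samples_per_trial=t, seed=derive_seed(seed, "noise"))


def nonlinear_specificity(n_seeds: int = 20, n_surrogates: int = 20,
                          seed: int = 1) -> dict[str, float]:
    """With a quadratic coupling 0 -> 1 only, the nonlinear connectivity
    must exceed its surrogate threshold for 0 -> 1 and not for 1 -> 0."""
    hits = 0
    for s in range(n_seeds):
        spec = _quadratic_pair_spec(derive_seed(seed, "nlspec", s))
        epochs = simulate_nmvar(spec)
        config = TrainingConfig(seed=derive_seed(seed, "nlspec-fit", s),
                                compute_cv=False)
        res = estimate_connectivity(epochs, config, spec.order)
        null = null_distribution(epochs, config, spec.order,
                                 n_surrogates=n_surrogates,
                                 seed=derive_seed(seed, "nlspec-null", s))
        _, nl_mask = significance_mask(res, null)
        if nl_mask[0, 1] and not nl_mask[1, 0]:
            hits += 1
    return {"success_rate": hits / n_seeds, "n_seeds": n_seeds}


def surrogate_calibration(n_datasets: int = 50, n_surrogates: int = 20,
                          seed: int = 1) -> dict[str, float]:
    """Type-I calibration on fully independent channels: the pooled
    per-pair rejection rate at the 95th-percentile threshold."""
    rejections = 0
    tests = 0
    for s in range(n_datasets):
        coeffs = np.zeros((3, 3, 1))
        coeffs[0, 0, 0], coeffs[1, 1, 0], coeffs[2, 2, 0] = 0.3, 0.4, 0.5
        spec = CoupledSystemSpec(n_channels=3, order=1, linear_coeffs=coeffs,
                                 noise_sd=1.0, samples_per_trial=360,
                                 seed=derive_seed(seed, "calib", s))
        epochs = simulate_nmvar(spec)
        config = TrainingConfig(seed=derive_seed(seed, "calib-fit", s),
                                compute_cv=False)
        res = estimate_connectivity(epochs, config, spec.order)
        null = null_distribution(epochs, config, spec.order,
                                 n_surrogates=n_surrogates,
                                 seed=derive_seed(seed, "calib-null", s))
        lin_mask, nl_mask = significance_mask(res, null)
        off = ~np.eye(3, dtype=bool)
        rejections += int(lin_mask[off].sum()) + int(nl_mask[off].sum())
        tests += 2 * int(off.sum())
    return {"rejection_rate": rejections / tests, "n_tests": tests,
            "nominal": 0.05}


def fit_quality(n_subjects: int = 20, seed: int = 1) -> dict[str, float]:
    """Generalization on high-signal subjects of varying predictability:
    mean held-out R^2 and the train/test R^2 correlation."""
    r2_train, r2_test = [], []
    rng = np.random.default_rng(derive_seed(seed, "fitq"))
    for s in range(n_subjects):
        m = 4
        coeffs = np.zeros((m, m, 1))
        diag = rng.uniform(0.96, 0.99)
        for ch in range(m):
            coeffs[ch, ch, 0] = diag
        coeffs[1, 0, 0] = 0.03
        coeffs[3, 2, 0] = 0.03
        spec = CoupledSystemSpec(n_channels=m, order=1, linear_coeffs=coeffs,
                                 noise_sd=1.0, samples_per_trial=1500,
                                 seed=derive_seed(seed, "fitq-noise", s))
        epochs = simulate_nmvar(spec)
        config = TrainingConfig(seed=derive_seed(seed, "fitq-fit", s))
        _, metrics = fit_nmvar(epochs, config, 1)
        r2_train.append(metrics.r2_train)
        r2_test.append(metrics.r2_test)
    corr = float(np.corrcoef(r2_train, r2_test)[0, 1])
    return {"mean_r2_test": float(np.mean(r2_test)),
            "min_r2_test": float(np.min(r2_test)),
            "train_test_r2_corr": corr, "n_subjects": n_subjects}


def tagging_detection(n_subjects: int = 50, seed: int = 1,
                      alpha: float = 0.05) -> dict[str, float]:
    """Flicker-tagging sensitivity and specificity at the group level.

    Each virtual subject sees a 4.5 Hz flicker on three responsive
    channels over 1/f noise; the 4.5-vs-8 Hz pointwise contrast must
    cover the flicker interval on responsive channels and nothing else.
    """
    maps_a, maps_b = [], []
    responsive = [0, 1, 2]
    n_channels = 6
    valid = times = None
    for s in range(n_subjects):
        spec = FlickerEEGSpec(flicker_amplitude=0.6,
                              responsive_channels=responsive,
                              n_trials=20, n_channels=n_channels,
                              seed=derive_seed(seed, "tag", s))
        epochs = simulate_flicker_eeg(spec)
        tfr = morlet_tfr(epochs, [4.5, 8.0])
        rel = relative_power_change(tfr)
        maps_a.append(rel.power[:, 0, :])
        maps_b.append(rel.power[:, 1, :])
        valid = rel.valid.all(axis=0)
        times = rel.times
    stat = pointwise_frequency_contrast(np.stack(maps_a), np.stack(maps_b),
                                        alpha=alpha, valid=valid)
    resp = np.zeros(n_channels, dtype=bool)
    resp[responsive] = True
    # interior of the flicker interval, clear of the wavelet half-support
    inj = valid & (times >= 600.0) & (times < 1400.0)
    coverage = float(stat.mask[resp][:, inj].mean())
    false_rate = float(stat.mask[~resp][:, valid].mean())
    return {"coverage": coverage, "false_rate": false_rate,
            "n_subjects": n_subjects}


def roi_recovery(seed: int = 1) -> dict[str, float]:
    """Planted two-cluster voxel map: cluster count, top-fraction count,
    and the anterior/posterior temporal split."""
    spec = VoxelMapSpec(
        grid_spacing=5.0, extent=40.0, brain_radii=(38.0, 38.0, 38.0),
        wm_radius=12.0,
        planted_clusters=[
            PlantedCluster((20.0, 20.0, 5.0), 9.0, 3.0, label_id=3),   # IC
            PlantedCluster((0.0, -25.0, -5.0), 8.0, 3.0, label_id=1),  # TL
        ],
        background_mean=1.0, background_sd=0.15,
        seed=derive_seed(seed, "voxmap"))
    vmap = simulate_voxel_map(spec)
    valid = filter_voxels(vmap)
    selected = select_top_fraction(vmap, 0.03, valid=valid)
    cluster_ids = cluster_voxels(vmap, selected)
    n_clusters = int(len(set(cluster_ids.tolist()) - {NOISE}))
    expected_k = int(np.ceil(0.03 * valid.sum()))
    roiset = select_rois(vmap, fraction=0.03, temporal_split_y=-21.0)
    split_ok = True
    for name, sign in (("ATL", 1), ("PTL", -1)):
        if name in roiset.rois:
            y = vmap.coords[roiset.rois[name], 1]
            ok = np.all(y > -21.0) if sign > 0 else np.all(y <= -21.0)
            split_ok = split_ok and bool(ok)
    return {"n_clusters": n_clusters, "n_selected": int(selected.size),
            "expected_selected": expected_k,
            "split_correct": float(split_ok),
            "roi_names": ",".join(sorted(roiset.names()))}


def global_null_battery(n_replicates: int = 200, n_subjects: int = 50,
                        seed: int = 1) -> dict[str, float]:
    """Stimulation-contrast battery under a global null: 12 directed
    pairs, two conditions, no planted effects; fraction of FDR-significant
    contrasts."""
    rois = ["ATL", "PTL", "IC", "IFC"]
    pairs = [(a, b) for a in rois for b in rois if a != b]
    n_sig = 0
    n_tests = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(derive_seed(seed, "gnull", rep))
        rows = []
        for cond in ("sham", "active"):
            for a, b in pairs:
                vals = rng.normal(0.25, 0.08, n_subjects)
                for subj, v in enumerate(vals):
                    rows.append((subj, cond, "action_planning", a, b,
                                 "linear", v))
        df = pd.DataFrame(rows, columns=["subject", "condition", "phase",
                                         "source", "target", "measure",
                                         "value"])
        spec = ContrastSpec("stimulation", "linear", "action_planning",
                            conditions=("sham", "active"))
        table = run_contrast(df, spec)
        n_sig += int(table["significant"].sum())
        n_tests += len(table)
    return {"significant_fraction": n_sig / n_tests, "n_tests": n_tests}
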
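"""End-to-end reproducible pipeline over synthetic data.

Stage order: simulate (flicker epochs, voxel map, coupled envelope
systems) -> frequency-tagging statistics -> ROI selection -> model-order
selection and network fits -> surrogate significance -> group-level
contrast batteries.  Every intermediate is persisted under the output
directory; deleting one and rerunning regenerates it identically (all
randomness fans out from the master seed via stable derived seeds).

The demo connectivity stage consumes simulated band-power envelope
systems directly (the coupled-system generator produces exactly the
ROI-envelope-level signal the estimator expects); voxel-level envelope
extraction is exercised by the tagging stage utilities.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig
from .containers import EpochContainer
from .model import TrainingConfig, estimate_connectivity, select_model_order
from .roi import select_rois
from .stats import ContrastSpec, run_contrast
from .surrogates import null_distribution, significance_mask
from .synthetic import (CoupledSystemSpec, FlickerEEGSpec, NonlinearTerm,
                        PlantedCluster, VoxelMapSpec, simulate_flicker_eeg,
                        simulate_nmvar, simulate_voxel_map)
from .tagging import morlet_tfr, pointwise_frequency_contrast, relative_power_change

__all__ = ["run_pipeline", "stage_simulate", "stage_tagging", "stage_roi",
           "stage_connectivity", "stage_surrogate", "stage_stats",
           "coupled_spec_for"]

logger = logging.getLogger(__name__)


def coupled_spec_for(cfg: RunConfig, subject: int, condition: str,
                     phase: str) -> CoupledSystemSpec:
    """Coupled-system spec for one virtual subject/condition/phase.

    The planted network: every channel is self-coupled; directed linear
    couplings 0->1 and 2->3 plus a phase-specific 3->0 link during
    perception; a quadratic coupling 2->0.  In the active condition the
    2->3 coupling is scaled by ``effect_scale`` (a planted stimulation
    effect).  Small per-subject coefficient jitter creates between-subject
    variance.
    """
    sim = cfg["simulate"]
    m, p = int(sim["n_channels"]), int(sim["order"])
    seed = pio.derive_seed(cfg.seed, "simulate", subject, condition, phase)
    rng = np.random.default_rng(seed)
    coeffs = np.zeros((m, m, p))
    a = float(sim["coupling"])
    jitter = 0.05
    for ch in range(m):
        coeffs[ch, ch, 0] = sim["self_coupling"] + rng.normal(0, jitter)
    coeffs[1, 0, 0] = a + rng.normal(0, jitter)  # 0 -> 1
    eff = a + rng.normal(0, jitter)
    if condition == "active":
        eff *= float(sim["effect_scale"])
    coeffs[3, 2, 0] = eff  # 2 -> 3, modulated by stimulation
    if phase == "perception" and m >= 4:
        coeffs[0, 3, 0] = 0.25 + rng.normal(0, jitter)  # 3 -> 0
    terms = [NonlinearTerm(source=2, target=0, lag=1, kind="quadratic",
                           gain=float(sim["nonlinear_gain"]))] if m >= 3 else []
    return CoupledSystemSpec(
        n_channels=m, order=p, linear_coeffs=coeffs, nonlinear_terms=terms,
        noise_sd=1.0, n_trials=int(sim["n_trials"]),
        samples_per_trial=int(sim["samples_per_trial"]),
        sampling_rate=float(sim["sampling_rate"]),
        seed=pio.derive_seed(cfg.seed, "sim-noise", subject, condition, phase),
    )


def _epoch_path(out: Path, subject: int, condition: str, phase: str) -> Path:
    return out / "epochs" / f"sub{subject:03d}_{condition}_{phase}.npz"


def stage_simulate(cfg: RunConfig) -> dict:
    """Generate and persist every synthetic input the later stages read."""
    out = cfg.out_dir
    sim = cfg["simulate"]
    conn = cfg["connectivity"]
    paths = {"epochs": [], "flicker": [], "voxel_map": None}
    for subject in range(int(sim["n_subjects"])):
        for condition in conn["conditions"]:
            for phase in conn["phases"]:
                path = _epoch_path(out, subject, condition, phase)
                if not path.exists():
                    spec = coupled_spec_for(cfg, subject, condition, phase)
                    epochs = simulate_nmvar(spec)
                    epochs.metadata.update(subject=subject,
                                           condition=condition, phase=phase)
                    pio.write_epochs(epochs, path)
                paths["epochs"].append(path)
    fl = sim["flicker"]
    for subject in range(int(fl["n_subjects"])):
        path = out / "flicker" / f"sub{subject:03d}.npz"
        if not path.exists():
            spec = FlickerEEGSpec(
                flicker_freq=float(fl["flicker_freq"]),
                flicker_amplitude=float(fl["amplitude"]),
                responsive_channels=list(fl["responsive_channels"]),
                n_trials=int(fl["n_trials"]),
                n_channels=int(fl["n_channels"]),
                seed=pio.derive_seed(cfg.seed, "flicker", subject),
            )
            pio.write_epochs(simulate_flicker_eeg(spec), path)
        paths["flicker"].append(path)
    vm_path = out / "voxel_map.tsv"
    if not vm_path.exists():
        spec = VoxelMapSpec(
            grid_spacing=float(sim["voxel_map"]["grid_spacing"]),
            planted_clusters=[
                PlantedCluster((55.0, -10.0, -5.0), 12.0, 3.0, label_id=1),
                PlantedCluster((38.0, 8.0, 2.0), 9.0, 3.0, label_id=3),
                PlantedCluster((45.0, 30.0, 10.0), 9.0, 3.0, label_id=4),
            ],
            seed=pio.derive_seed(cfg.seed, "voxel_map"),
        )
        pio.write_voxel_map(simulate_voxel_map(spec), vm_path)
    paths["voxel_map"] = vm_path
    return paths


def stage_tagging(cfg: RunConfig) -> pd.DataFrame:
    """Tagged-vs-control pointwise contrast across virtual subjects."""
    out = cfg.out_dir
    stage_simulate(cfg)
    fl = cfg["simulate"]["flicker"]
    tg = cfg["tagging"]
    freqs = [float(fl["flicker_freq"]), float(fl["control_freq"])]
    maps_a, maps_b = [], []
    valid = times = channels = None
    for subject in range(int(fl["n_subjects"])):
        epochs = pio.read_epochs(out / "flicker" / f"sub{subject:03d}.npz")
        tfr = morlet_tfr(epochs, freqs, n_cycles=float(tg["n_cycles"]))
        rel = relative_power_change(tfr, tuple(tg["baseline"]))
        maps_a.append(rel.power[:, 0, :])
        maps_b.append(rel.power[:, 1, :])
        valid = rel.valid.all(axis=0)
        times = rel.times
        channels = epochs.channels
    stat = pointwise_frequency_contrast(np.stack(maps_a), np.stack(maps_b),
                                        alpha=float(tg["alpha"]), valid=valid,
                                        times=times)
    records = []
    for ci, ch in enumerate(channels):
        for ti, t_ms in enumerate(times):
            if not valid[ti]:
                continue
            records.append({"channel": ch, "time_ms": t_ms,
                            "t": stat.t[ci, ti], "p": stat.p[ci, ti],
                            "p_fdr": stat.p_fdr[ci, ti],
                            "significant": bool(stat.mask[ci, ti])})
    df = pd.DataFrame(records)
    pio.write_tsv(df, out / "tagging_stats.tsv",
                  header_note="# pointwise paired-t contrast, tagged vs control frequency\n",
                  config_hash=cfg.config_hash)
    return df


def stage_roi(cfg: RunConfig):
    """ROI selection on the persisted voxel map."""
    out = cfg.out_dir
    stage_simulate(cfg)
    vmap = pio.read_voxel_map(out / "voxel_map.tsv")
    r = cfg["roi"]
    roiset = select_rois(vmap, fraction=float(r["fraction"]),
                         min_samples=int(r["min_samples"]),
                         temporal_split_y=float(r["temporal_split_y"]))
    pio.write_roiset(roiset, out / "rois.json")
    return roiset


def _training_config(cfg: RunConfig, seed: int, compute_cv: bool = True,
                     ) -> TrainingConfig:
    c = cfg["connectivity"]
    return TrainingConfig(
        hidden=int(c["hidden"]), activation=c["activation"],
        learning_rate=float(c["learning_rate"]), momentum=float(c["momentum"]),
        max_epochs=int(c["max_epochs"]), patience=int(c["patience"]),
        folds=int(c["folds"]), seed=seed, compute_cv=compute_cv,
    )


def _select_order(cfg: RunConfig) -> int:
    c = cfg["connectivity"]
    if c["order"] is not None:
        return int(c["order"])
    epochs = pio.read_epochs(_epoch_path(cfg.out_dir, 0,
                                         c["conditions"][0], c["phases"][0]))
    return select_model_order(epochs, c["order_candidates"])


def stage_connectivity(cfg: RunConfig) -> pd.DataFrame:
    """Fit the estimator for every subject/condition/phase."""
    out = cfg.out_dir
    stage_simulate(cfg)
    conn = cfg["connectivity"]
    p = _select_order(cfg)
    rows = []
    for subject in range(int(cfg["simulate"]["n_subjects"])):
        for condition in conn["conditions"]:
            for phase in conn["phases"]:
                epochs = pio.read_epochs(_epoch_path(out, subject, condition,
                                                     phase))
                tc = _training_config(
                    cfg, pio.derive_seed(cfg.seed, "fit", subject, condition,
                                         phase))
                res = estimate_connectivity(epochs, tc, p)
                frame = pio.connectivity_to_frame(res)
                frame.insert(0, "subject", subject)
                frame.insert(1, "condition", condition)
                frame.insert(2, "phase", phase)
                frame["r2_test"] = res.fit.r2_test
                rows.append(frame)
    df = pd.concat(rows, ignore_index=True)
    df["order"] = p
    pio.write_tsv(df, out / "connectivity.tsv", config_hash=cfg.config_hash)
    return df


def stage_surrogate(cfg: RunConfig) -> pd.DataFrame:
    """Per-run surrogate nulls and significance flags."""
    out = cfg.out_dir
    conn_path = out / "connectivity.tsv"
    if not conn_path.exists():
        stage_connectivity(cfg)
    sur = cfg["surrogate"]
    conn = cfg["connectivity"]
    p = _select_order(cfg)
    rows = []
    for subject in range(int(cfg["simulate"]["n_subjects"])):
        for condition in conn["conditions"]:
            for phase in conn["phases"]:
                epochs = pio.read_epochs(_epoch_path(out, subject, condition,
                                                     phase))
                tc = _training_config(
                    cfg, pio.derive_seed(cfg.seed, "fit", subject, condition,
                                         phase))
                res = estimate_connectivity(epochs, tc, p)
                null = null_distribution(
                    epochs, tc, p, n_surrogates=int(sur["n_surrogates"]),
                    percentile=float(sur["percentile"]),
                    seed=pio.derive_seed(cfg.seed, "surrogate", subject,
                                         condition, phase))
                lin_mask, nl_mask = significance_mask(res, null)
                frame = pio.connectivity_to_frame(res, lin_mask, nl_mask)
                frame.insert(0, "subject", subject)
                frame.insert(1, "condition", condition)
                frame.insert(2, "phase", phase)
                rows.append(frame)
    df = pd.concat(rows, ignore_index=True)
    pio.write_tsv(df, out / "connectivity_masked.tsv",
                  config_hash=cfg.config_hash)
    return df


def _long_values(df: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for measure, col in (("linear", "lC"), ("nonlinear", "NC")):
        part = df[["subject", "condition", "phase", "source", "target",
                   col]].rename(columns={col: "value"})
        part["measure"] = measure
        frames.append(part)
    return pd.concat(frames, ignore_index=True)


def _allowed_pairs(df: pd.DataFrame, phase: str, measure: str,
                   min_fraction: float) -> set[tuple[str, str]]:
    col = {"linear": "significant_linear",
           "nonlinear": "significant_nonlinear"}[measure]
    if col not in df.columns or df[col].isna().all():
        return None
    sel = df[df["phase"] == phase]
    frac = sel.groupby(["source", "target"])[col].mean()
    return set(frac[frac >= min_fraction].index)


def stage_stats(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Full contrast battery over the (masked) connectivity values."""
    out = cfg.out_dir
    masked_path = out / "connectivity_masked.tsv"
    if masked_path.exists():
        df = pd.read_csv(masked_path, sep="\t", comment="#")
    else:
        df = stage_surrogate(cfg)
    values = _long_values(df)
    conn = cfg["connectivity"]
    min_frac = float(cfg["surrogate"]["min_fraction_significant"])
    results: dict[str, pd.DataFrame] = {}
    tables = []
    for measure in ("linear", "nonlinear"):
        for phase in conn["phases"]:
            allowed = _allowed_pairs(df, phase, measure, min_frac)
            for condition in conn["conditions"]:
                spec = ContrastSpec("asymmetry", measure, phase,
                                    condition=condition,
                                    conditions=tuple(conn["conditions"]))
                tables.append(run_contrast(values, spec, allowed))
            for kind in ("stimulation", "net_difference"):
                spec = ContrastSpec(kind, measure, phase,
                                    conditions=tuple(conn["conditions"]))
                tables.append(run_contrast(values, spec, allowed))
    nonempty = [t for t in tables if len(t)]
    all_contrasts = (pd.concat(nonempty, ignore_index=True)
                     if nonempty else pd.DataFrame())
    pio.write_tsv(all_contrasts, out / "contrasts.tsv",
                  config_hash=cfg.config_hash)
    results["contrasts"] = all_contrasts
    results["values"] = values
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the result bundle."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg.dump(out / "config.yaml")
    bundle: dict = {"config_hash": cfg.config_hash, "out_dir": out}
    for name, stage in (("simulate", stage_simulate),
                        ("tagging", stage_tagging),
                        ("roi", stage_roi),
                        ("connectivity", stage_connectivity),
                        ("surrogate", stage_surrogate),
                        ("stats", stage_stats)):
        logger.info("pipeline stage: %s", name)
        try:
            bundle[name] = stage(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return bundle
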
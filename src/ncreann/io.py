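"""File formats and seed derivation.

Epoch containers are stored as a NumPy ``.npz`` (array + time axis) with a
JSON sidecar for metadata; voxel maps and statistics as tab-delimited
UTF-8 tables with a commented header naming units and conventions; models
and ROI sets as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochContainer, VoxelSourceMap
from .roi import ROISet

__all__ = [
    "derive_seed",
    "write_epochs",
    "read_epochs",
    "write_voxel_map",
    "read_voxel_map",
    "write_roiset",
    "read_roiset",
    "connectivity_to_frame",
    "null_to_frame",
    "write_tsv",
]

_ORIENTATION_NOTE = "# orientation: entry/source->target; values unitless\n"


def derive_seed(master: int, *parts) -> int:
    """Stable sub-seed from a master seed and stage/index tags (< 2**31)."""
    key = ":".join([str(int(master))] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_epochs(container: EpochContainer, path: str | Path) -> Path:
    """Write an epoch container: arrays to ``.npz``, metadata to a JSON
    sidecar.  Round-trips bit-identically."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, data=container.data, times=container.times)
    meta = {
        "channels": list(container.channels),
        "sampling_rate": float(container.sfreq),
        "lock": container.lock,
        "metadata": container.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_epochs(path: str | Path) -> EpochContainer:
    """Read an epoch container written by :func:`write_epochs`.

    Missing or inconsistent fields raise, naming the offending field.
    """
    path = Path(path).with_suffix(".npz")
    with np.load(path) as npz:
        data = npz["data"]
        times = npz["times"]
    meta = json.loads(_sidecar(path).read_text())
    for key in ("channels", "sampling_rate", "lock"):
        if key not in meta:
            raise ValueError(f"epoch sidecar missing field: {key}")
    return EpochContainer(data=data, sfreq=meta["sampling_rate"], times=times,
                          channels=meta["channels"], lock=meta["lock"],
                          metadata=meta.get("metadata", {}))


def write_voxel_map(vmap: VoxelSourceMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "x_mm": vmap.coords[:, 0], "y_mm": vmap.coords[:, 1],
        "z_mm": vmap.coords[:, 2], "power": vmap.power,
        "brain": vmap.brain_mask.astype(int),
        "wm": vmap.wm_mask.astype(int),
        "cerebellum": vmap.cerebellum_mask.astype(int),
        "label_id": vmap.label_id,
    })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# voxel source-power map; grid_spacing_mm={vmap.grid_spacing}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_voxel_map(path: str | Path) -> VoxelSourceMap:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if "grid_spacing_mm=" not in header:
            raise ValueError("voxel map file lacks grid_spacing_mm header")
        spacing = float(header.split("grid_spacing_mm=")[1])
        df = pd.read_csv(fh, sep="\t")
    return VoxelSourceMap(
        coords=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        power=df["power"].to_numpy(),
        grid_spacing=spacing,
        brain_mask=df["brain"].to_numpy().astype(bool),
        wm_mask=df["wm"].to_numpy().astype(bool),
        cerebellum_mask=df["cerebellum"].to_numpy().astype(bool),
        label_id=df["label_id"].to_numpy().astype(int),
    )


def write_roiset(roiset: ROISet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "rois": {name: idx.tolist() for name, idx in roiset.rois.items()},
        "provenance": roiset.provenance.to_dict(orient="list"),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_roiset(path: str | Path) -> ROISet:
    payload = json.loads(Path(path).read_text())
    return ROISet(
        rois={k: np.asarray(v, dtype=int) for k, v in payload["rois"].items()},
        provenance=pd.DataFrame(payload.get("provenance", {})),
    )


def connectivity_to_frame(result, lin_mask=None, nonlin_mask=None,
                          ) -> pd.DataFrame:
    """Long-format table (source, target, lC, NC, significance flags)."""
    rows = []
    m = len(result.channels)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            rows.append({
                "source": result.channels[i], "target": result.channels[j],
                "lC": result.lc[i, j], "NC": result.nc[i, j],
                "significant_linear": bool(lin_mask[i, j]) if lin_mask is not None else None,
                "significant_nonlinear": bool(nonlin_mask[i, j]) if nonlin_mask is not None else None,
            })
    return pd.DataFrame(rows)


def null_to_frame(null, channels: list[str]) -> pd.DataFrame:
    """Surrogate null as long format (pair, measure, surrogate_index, value)."""
    rows = []
    for measure, values in (("linear", null.lc_values),
                            ("nonlinear", null.nc_values)):
        for s in range(values.shape[0]):
            for i, src in enumerate(channels):
                for j, tgt in enumerate(channels):
                    if i == j:
                        continue
                    rows.append({"source": src, "target": tgt,
                                 "measure": measure, "surrogate_index": s,
                                 "value": values[s, i, j]})
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path: str | Path,
              header_note: str | None = None, config_hash: str = "") -> Path:
    """UTF-8 tab-delimited table with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header_note or _ORIENTATION_NOTE)
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path
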
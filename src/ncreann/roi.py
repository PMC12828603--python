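"""ROI selection from voxel source-power maps.

Fixed stage order: exclusion filters -> top-fraction selection -> density
clustering -> atlas labelling and anterior/posterior temporal split.  The
module is fully deterministic given the map.

Clustering uses DBSCAN with ``eps = 2 * grid_spacing`` (twice the voxel
edge length) so that diagonal grid neighbours are reachable; isolated
voxels are labelled noise and discarded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .containers import VoxelSourceMap

__all__ = [
    "ROISet",
    "filter_voxels",
    "select_top_fraction",
    "cluster_voxels",
    "split_temporal",
    "assemble_rois",
    "select_rois",
    "NOISE",
    "DEFAULT_MIN_SAMPLES",
    "SYNTHETIC_ATLAS_RECIPE",
    "SYNTHETIC_SUBCORTICAL_LABELS",
    "DEFAULT_TEMPORAL_SPLIT_Y",
]

#: DBSCAN noise label for isolated voxels.
NOISE = -1

#: DBSCAN min_samples (minPts, point itself included): the smallest value
#: that still rejects isolated voxels.
DEFAULT_MIN_SAMPLES = 3

#: Synthetic atlas recipe mapping synthetic label ids to ROI names.  The
#: special value "TL" marks temporal-lobe labels that are split into
#: ATL/PTL by the anterior/posterior rule.  This is a synthetic stand-in
#: for an anatomical-atlas membership table.
SYNTHETIC_ATLAS_RECIPE: dict[int, str] = {1: "TL", 2: "TL", 3: "IC", 4: "IFC"}

#: Synthetic subcortical label ids; member voxels are always discarded.
SYNTHETIC_SUBCORTICAL_LABELS: frozenset[int] = frozenset({9})

#: Reference y (mm) for the anterior/posterior temporal split — the median
#: anterior-posterior coordinate of the transverse temporal (Heschl) region
#: in template space.
DEFAULT_TEMPORAL_SPLIT_Y = -21.0


@dataclass
class ROISet:
    """Named, pairwise-disjoint voxel groups with per-voxel provenance.

    ``rois`` maps ROI name -> voxel indices into the source map;
    ``provenance`` records cluster id and atlas label per member voxel.
    """

    rois: dict[str, np.ndarray]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, idx in self.rois.items():
            idx = np.asarray(idx, dtype=int)
            self.rois[name] = idx
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"ROI {name!r} overlaps another ROI at voxels {sorted(overlap)[:5]}")
            seen.update(idx.tolist())

    def __len__(self) -> int:
        return len(self.rois)

    def names(self) -> list[str]:
        return list(self.rois)


def filter_voxels(vmap: VoxelSourceMap) -> np.ndarray:
    """Validity mask: inside the brain, not white matter, not cerebellum."""
    for name in ("brain_mask", "wm_mask", "cerebellum_mask"):
        mask = getattr(vmap, name, None)
        if mask is None:
            raise ValueError(f"missing mask: {name}")
    return (np.asarray(vmap.brain_mask, bool)
            & ~np.asarray(vmap.wm_mask, bool)
            & ~np.asarray(vmap.cerebellum_mask, bool))


def select_top_fraction(vmap: VoxelSourceMap, fraction: float = 0.03,
                        valid: np.ndarray | None = None) -> np.ndarray:
    """Indices of the ceil(fraction * N_valid) highest-power valid voxels.

    Ties are broken deterministically: power descending, then x, y, z
    ascending.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if valid is None:
        valid = filter_voxels(vmap)
    valid_idx = np.flatnonzero(valid)
    if valid_idx.size == 0:
        raise ValueError("no voxels pass the exclusion filters")
    k = ceil(fraction * valid_idx.size)
    c = vmap.coords[valid_idx]
    order = np.lexsort((c[:, 2], c[:, 1], c[:, 0], -vmap.power[valid_idx]))
    return valid_idx[order[:k]]


def cluster_voxels(vmap: VoxelSourceMap, selected: np.ndarray,
                   eps: float | None = None,
                   min_samples: int = DEFAULT_MIN_SAMPLES) -> np.ndarray:
    """DBSCAN cluster id per selected voxel (noise = -1).

    ``eps`` defaults to twice the voxel edge length (2 * grid_spacing).
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("no voxels to cluster")
    if eps is None:
        eps = 2.0 * vmap.grid_spacing
    if selected.size < min_samples:
        return np.full(selected.size, NOISE, dtype=int)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        vmap.coords[selected])
    return labels.astype(int)


def split_temporal(vmap: VoxelSourceMap, voxels: np.ndarray,
                   reference_y: float = DEFAULT_TEMPORAL_SPLIT_Y,
                   ) -> dict[str, np.ndarray]:
    """Split temporal-lobe voxels into anterior (ATL) and posterior (PTL).

    Voxels with y > reference_y go anterior; y <= reference_y (boundary
    included) go posterior.  Empty partitions are reported, not an error.
    """
    voxels = np.asarray(voxels, dtype=int)
    y = vmap.coords[voxels, 1]
    return {"ATL": voxels[y > reference_y], "PTL": voxels[y <= reference_y]}


def assemble_rois(vmap: VoxelSourceMap, selected: np.ndarray,
                  cluster_ids: np.ndarray,
                  recipe: dict[int, str] | None = None,
                  subcortical_labels: frozenset[int] | set[int] | None = None,
                  temporal_split_y: float = DEFAULT_TEMPORAL_SPLIT_Y,
                  known_labels: set[int] | None = None) -> ROISet:
    """Assemble labelled ROIs from clustered voxels.

    ``recipe`` maps atlas label ids to ROI names; the reserved name "TL"
    is split into ATL/PTL at ``temporal_split_y``.  Noise voxels, voxels
    with labels outside the recipe, and subcortical voxels are discarded.
    A recipe entry outside the atlas's label universe (``known_labels``,
    defaulting to the synthetic atlas plus the map's own labels) is
    rejected.
    """
    if recipe is None:
        recipe = SYNTHETIC_ATLAS_RECIPE
    if subcortical_labels is None:
        subcortical_labels = SYNTHETIC_SUBCORTICAL_LABELS
    selected = np.asarray(selected, dtype=int)
    cluster_ids = np.asarray(cluster_ids, dtype=int)
    if selected.shape != cluster_ids.shape:
        raise ValueError("selected and cluster_ids must align")
    if known_labels is None:
        known_labels = (set(np.unique(vmap.label_id).tolist())
                        | set(SYNTHETIC_ATLAS_RECIPE)
                        | set(SYNTHETIC_SUBCORTICAL_LABELS) | {0})
    for lid in recipe:
        if lid not in known_labels:
            raise ValueError(f"recipe references unknown atlas label id {lid}")
    keep = cluster_ids != NOISE
    vox = selected[keep]
    cids = cluster_ids[keep]
    labels = vmap.label_id[vox]
    in_recipe = np.array([(l in recipe) and (l not in subcortical_labels)
                          for l in labels])
    vox, cids, labels = vox[in_recipe], cids[in_recipe], labels[in_recipe]
    groups: dict[str, list[int]] = {}
    for v, l in zip(vox, labels):
        groups.setdefault(recipe[l], []).append(int(v))
    rois: dict[str, np.ndarray] = {}
    for name, members in groups.items():
        members_arr = np.asarray(sorted(members), dtype=int)
        if name == "TL":
            for sub, idx in split_temporal(vmap, members_arr,
                                           temporal_split_y).items():
                if idx.size:
                    rois[sub] = idx
        else:
            rois[name] = members_arr
    prov = pd.DataFrame({
        "voxel": vox,
        "cluster_id": cids,
        "label_id": labels,
        "x_mm": vmap.coords[vox, 0],
        "y_mm": vmap.coords[vox, 1],
        "z_mm": vmap.coords[vox, 2],
    })
    return ROISet(rois=rois, provenance=prov)


def select_rois(vmap: VoxelSourceMap, fraction: float = 0.03,
                eps: float | None = None,
                min_samples: int = DEFAULT_MIN_SAMPLES,
                recipe: dict[int, str] | None = None,
                subcortical_labels: frozenset[int] | set[int] | None = None,
                temporal_split_y: float = DEFAULT_TEMPORAL_SPLIT_Y) -> ROISet:
    """Full ROI stage: filter -> top-fraction -> cluster -> label/split."""
    valid = filter_voxels(vmap)
    selected = select_top_fraction(vmap, fraction, valid=valid)
    cluster_ids = cluster_voxels(vmap, selected, eps=eps,
                                 min_samples=min_samples)
    return assemble_rois(vmap, selected, cluster_ids, recipe=recipe,
                         subcortical_labels=subcortical_labels,
                         temporal_split_y=temporal_split_y)
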
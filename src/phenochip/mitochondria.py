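"""Mitochondrial (TMRM / MitoTracker live) assay pipeline.

Masks:
  nucleus  raw Hoechst > 100
  cell     raw CellMask > 400 (global)  OR  DoG(100/5 - 100/30) > 10 (local)
  mito     DoG(10/1 - 10/3) > 30, component sizes restricted to [5, 500] px
with device-mask voxels removed from every mask.  Mitochondrial surfaces and
bodies come from 6-connected erosion; network complexity from the skeleton
graph (nodes/links).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chip import ChipMasks
from .records import FeatureRecord
from .skeleton import SkeletonGraph, skeletonize_graph
from .volume_ops import (
    count_components,
    difference_of_gaussians,
    erode_with_surface,
    filter_components_by_size,
)

MITO_MIN_PX = 5
MITO_MAX_PX = 500


@dataclass
class MitoMasks:
    nucleus: np.ndarray
    cell: np.ndarray
    mito: np.ndarray
    mito_body: np.ndarray
    mito_surface: np.ndarray


def segment_mito_assay(stack, chip: ChipMasks) -> MitoMasks:
    nucleus = (stack["hoechst"] > 100) & ~chip.device
    cell_global = stack["cellmask"] > 400
    cell_local = difference_of_gaussians(stack["cellmask"], 100, 5, 100, 30) > 10
    cell = (cell_global | cell_local) & ~chip.device
    mito_rough = (difference_of_gaussians(stack["tmrm"], 10, 1, 10, 3) > 30) & ~chip.device
    mito = filter_components_by_size(mito_rough, MITO_MIN_PX, MITO_MAX_PX)
    body, surface = erode_with_surface(mito)
    return MitoMasks(nucleus, cell, mito, body, surface)


def extract_mito_features(
    masks: MitoMasks,
    graph: SkeletonGraph | None = None,
    bioreactor_id: str = "br0",
    metadata: dict | None = None,
) -> FeatureRecord:
    """Mitochondrial morphology features: MitoCount, voxel totals, the
    surface ("perimeter") and body split, skeleton/node/link counts, mean
    component size, and per-cell normalisations (÷ cell-mask voxels)."""
    if graph is None:
        graph = skeletonize_graph(masks.mito)
    mito_count = count_components(masks.mito)
    mito_px = int(masks.mito.sum())
    cell_px = int(masks.cell.sum())
    feats: dict[str, float] = {
        "mito_count": mito_count,
        "mito_px": mito_px,
        "mito_surface_px": int(masks.mito_surface.sum()),
        "mito_body_px": int(masks.mito_body.sum()),
        "mito_skeleton_px": graph.skeleton_px,
        "mito_node_count": graph.node_count,
        "mito_link_count": graph.link_count,
        "mito_mean_size": mito_px / mito_count if mito_count else float("nan"),
        "nucleus_px": int(masks.nucleus.sum()),
        "cell_px": cell_px,
    }
    for name in ("mito_count", "mito_px", "mito_skeleton_px"):
        feats[name + "_per_cell_px"] = feats[name] / cell_px if cell_px else float("nan")
    return FeatureRecord(bioreactor_id, "mito", feats, metadata or {})
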
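"""Skeletonisation and skeleton-graph statistics.

A mask is thinned to its medial axis (topology-preserving 3D thinning, via
``skimage.morphology.skeletonize``); the thinned voxel set is then read as a
graph: *nodes* are branch points — skeleton voxels with at least three
skeleton neighbours under 26-connectivity, merged when adjacent — and *links*
are the maximal skeleton paths between nodes and/or endpoints.  A simple
path therefore has 0 nodes and 1 link; a Y has 1 node and 3 links.

Node, link and skeleton-pixel counts are the arborisation / network-
complexity readouts for neurite trees and mitochondrial networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .volume_ops import label_mask

__all__ = ["SkeletonGraph", "skeletonize_graph", "analyze_skeleton"]

THINNING_ALGORITHM = "lee94-3d-thinning"  # recorded in output metadata


@dataclass
class SkeletonGraph:
    skeleton_mask: np.ndarray
    node_mask: np.ndarray
    link_labels: np.ndarray
    skeleton_px: int
    node_count: int
    link_count: int
    algorithm: str = THINNING_ALGORITHM


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Number of 26-connected (8-connected in 2D) skeleton neighbours."""
    kernel = np.ones((3,) * skel.ndim)
    counts = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant", cval=0)
    return counts - skel.astype(np.uint8)


def analyze_skeleton(skel: np.ndarray) -> SkeletonGraph:
    """Graph statistics of an already-thinned voxel set."""
    skel = np.asarray(skel, dtype=bool)
    n_px = int(skel.sum())
    if n_px == 0:
        z = np.zeros_like(skel)
        return SkeletonGraph(skel, z, np.zeros(skel.shape, dtype=np.int32), 0, 0, 0)

    neigh = _neighbor_counts(skel)
    node_vox = skel & (neigh >= 3)
    node_labels, n_nodes = label_mask(node_vox)  # adjacent branch voxels merge

    path_vox = skel & ~node_vox
    link_labels, n_paths = label_mask(path_vox)

    # links with no interior voxel: two distinct node clusters directly adjacent
    extra = 0
    if n_nodes > 1:
        se = np.ones((3,) * skel.ndim, dtype=bool)
        dil = ndimage.grey_dilation(node_labels, footprint=se)
        pairs = set()
        touching = node_vox & (dil != node_labels)
        for idx in np.argwhere(touching):
            a = node_labels[tuple(idx)]
            lo = [slice(max(i - 1, 0), i + 2) for i in idx]
            for b in np.unique(node_labels[tuple(lo)]):
                if b > a:
                    pairs.add((a, b))
        extra = len(pairs)

    return SkeletonGraph(skel, node_vox, link_labels, n_px, n_nodes, n_paths + extra)


def skeletonize_graph(mask: np.ndarray) -> SkeletonGraph:
    """Thin `mask` to its medial axis and extract graph statistics."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return analyze_skeleton(mask)
    skel = skeletonize(mask)
    return analyze_skeleton(skel.astype(bool))
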
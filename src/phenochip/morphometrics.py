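"""Morphometric (fixed immunostaining) assay pipeline.

Channels: Hoechst (nuclei), Tuj1/Alexa488 (pan-neuronal), TH/Alexa568
(dopaminergic), plus a fourth stain.  Produces nuclei (normal / pyknotic),
neuron and TH masks, fragmentation surfaces via 6-connected erosion, the TH
skeleton graph, and the per-bioreactor morphometric feature record.

Fixed gray-level thresholds assume raw camera counts:
  nuclei      DoG(10/2 - 60/20) > 10, components >= 200 px
  pyknotic    size-5 average-filtered raw Hoechst > 400 within nuclei
  neuron      lowpass(10/3) > 150 (global)  OR  DoG(10/3 - 20/6) > 3 (local),
              components >= 200 px
  TH          lowpass(10/1) > 100
All cellular masks exclude device-mask voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chip import ChipMasks
from .records import FeatureRecord
from .skeleton import SkeletonGraph, skeletonize_graph
from .volume_ops import (
    average_filter,
    count_components,
    difference_of_gaussians,
    erode_with_surface,
    filter_components_by_size,
    gaussian_lowpass,
)


@dataclass
class MorphoMasks:
    nuclei: np.ndarray
    pyknotic: np.ndarray
    normal: np.ndarray
    neuron: np.ndarray
    neuron_eroded: np.ndarray
    neuron_surface: np.ndarray
    th: np.ndarray
    th_eroded: np.ndarray
    th_surface: np.ndarray


def segment_nuclei_morpho(
    hoechst: np.ndarray, chip: ChipMasks
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nuclei via DoG banding, split into pyknotic (bright) and normal.

    Returns ``(nuclei, pyknotic, normal)``; pyknotic and normal partition
    the nuclei mask.
    """
    dog = difference_of_gaussians(hoechst, 10, 2, 60, 20)
    rough = dog > 10
    rough &= ~chip.device
    nuclei = filter_components_by_size(rough, 200)
    pyknotic = nuclei & (average_filter(hoechst, 5) > 400)
    normal = nuclei & ~pyknotic
    return nuclei, pyknotic, normal


def segment_neurons(tuj1: np.ndarray, chip: ChipMasks) -> np.ndarray:
    """Neuronal mask: union of global (bright somata) and local (thin
    neurites) thresholding, device excluded, components >= 200 px."""
    global_mask = gaussian_lowpass(tuj1, 10, 3) > 150
    local_mask = difference_of_gaussians(tuj1, 10, 3, 20, 6) > 3
    mask = (global_mask | local_mask) & ~chip.device
    return filter_components_by_size(mask, 200)


def segment_th(
    th: np.ndarray, chip: ChipMasks
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """TH (dopaminergic) mask plus its eroded body and fragmentation surface.

    Fragmented objects expose more surface per unit volume, so the
    surface/body split quantifies neurite fragmentation.
    """
    th_mask = (gaussian_lowpass(th, 10, 1) > 100) & ~chip.device
    th_eroded, th_surface = erode_with_surface(th_mask)
    return th_mask, th_eroded, th_surface


def segment_morpho_assay(stack, chip: ChipMasks) -> MorphoMasks:
    nuclei, pyknotic, normal = segment_nuclei_morpho(stack["hoechst"], chip)
    neuron = segment_neurons(stack["tuj1"], chip)
    neuron_eroded, neuron_surface = erode_with_surface(neuron)
    th_mask, th_eroded, th_surface = segment_th(stack["th"], chip)
    return MorphoMasks(
        nuclei, pyknotic, normal, neuron, neuron_eroded, neuron_surface,
        th_mask, th_eroded, th_surface,
    )


def extract_morpho_features(
    masks: MorphoMasks,
    chip: ChipMasks,
    th_graph: SkeletonGraph | None = None,
    bioreactor_id: str = "br0",
    metadata: dict | None = None,
    region: str = "chip",
) -> FeatureRecord:
    """Morphometric feature record for one bioreactor.

    ``region='chip'`` counts voxels anywhere outside the device mask (the
    default); ``region='mc'`` restricts every count to the Matrigel channel.
    Ratio features with a zero denominator are emitted as NaN.
    """
    if th_graph is None:
        th_graph = skeletonize_graph(masks.th)
    if region == "chip":
        sel = ~chip.device
    elif region == "mc":
        sel = chip.matrigel
    else:
        raise ValueError(f"unknown region {region!r}")

    def count(mask: np.ndarray) -> int:
        return int((mask & sel).sum())

    nuclei_px = count(masks.nuclei)
    neuron_px = count(masks.neuron)
    th_px = count(masks.th)
    feats: dict[str, float] = {
        "nuclei_count": count_components(masks.nuclei & sel),
        "pyknotic_count": _overlapping_components(masks.nuclei & sel, masks.pyknotic),
        "nuclei_px": nuclei_px,
        "pyknotic_px": count(masks.pyknotic),
        "neuron_px": neuron_px,
        "neuron_surface_px": count(masks.neuron_surface),
        "neuron_body_px": count(masks.neuron_eroded),
        "th_px": th_px,
        "th_surface_px": count(masks.th_surface),
        "th_body_px": count(masks.th_eroded),
        "th_skeleton_px": th_graph.skeleton_px,
        "th_node_count": th_graph.node_count,
        "th_link_count": th_graph.link_count,
    }
    feats["pyknotic_fraction"] = _ratio(feats["pyknotic_count"], feats["nuclei_count"])
    feats["th_by_tuj1"] = _ratio(th_px, neuron_px)
    feats["cell_by_nuclear_volume"] = _ratio(neuron_px, nuclei_px)
    return FeatureRecord(bioreactor_id, "morpho", feats, metadata or {})


def _ratio(num: float, den: float) -> float:
    return float(num) / float(den) if den else float("nan")


def _overlapping_components(mask: np.ndarray, marker: np.ndarray) -> int:
    """Number of `mask` components containing at least one `marker` voxel."""
    from .volume_ops import label_mask

    labels, n = label_mask(mask)
    if n == 0:
        return 0
    hit = np.unique(labels[marker & (labels > 0)])
    return int(hit.size)
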
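"""Cell-death (Calcein / ethidium homodimer / cleaved caspase-3) pipeline.

Masks, all excluding the device mask:
  nuclei    DoG(10/2 - 60/20) > 50, components >= 200 px
  EH        lowpass(10/3) > 500                      (dead-cell nuclei)
  CC3       lowpass(10/3) > 250, minus nuclei, components >= 20 px
  Calcein   lowpass(10/1) > 50  OR  DoG(20/1 - 20/5) > 10, minus nuclei
  live      Calcein minus nuclei, components >= 200 px
  CC3-live  Calcein AND (NOT nuclei) AND CC3         (apoptotic but alive)

CC3's exclusions are applied before its size filter (the literal recipe
order), so a speck reduced below 20 px by nucleus overlap is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chip import ChipMasks
from .records import FeatureRecord
from .volume_ops import (
    count_components,
    difference_of_gaussians,
    filter_components_by_size,
    gaussian_lowpass,
)


@dataclass
class ViabilityMasks:
    nuclei: np.ndarray
    eh: np.ndarray
    cc3: np.ndarray
    calcein: np.ndarray
    live: np.ndarray
    cc3_live: np.ndarray


def segment_viability_assay(stack, chip: ChipMasks) -> ViabilityMasks:
    keep = ~chip.device
    nuclei = difference_of_gaussians(stack["hoechst"], 10, 2, 60, 20) > 50
    nuclei = filter_components_by_size(nuclei & keep, 200)

    eh = (gaussian_lowpass(stack["eh"], 10, 3) > 500) & keep

    cc3 = (gaussian_lowpass(stack["cc3"], 10, 3) > 250) & keep & ~nuclei
    cc3 = filter_components_by_size(cc3, 20)

    cal_global = gaussian_lowpass(stack["calcein"], 10, 1) > 50
    cal_local = difference_of_gaussians(stack["calcein"], 20, 1, 20, 5) > 10
    calcein = (cal_global | cal_local) & keep & ~nuclei

    live = filter_components_by_size(calcein & ~nuclei, 200)
    cc3_live = calcein & ~nuclei & cc3
    return ViabilityMasks(nuclei, eh, cc3, calcein, live, cc3_live)


def extract_viability_features(
    masks: ViabilityMasks,
    bioreactor_id: str = "br0",
    metadata: dict | None = None,
) -> FeatureRecord:
    """Viability features; `dead_fraction` (EH / (EH + live) voxels) is a
    convenience summary beyond the published mask counts."""
    eh_px = int(masks.eh.sum())
    live_px = int(masks.live.sum())
    cc3_live_px = int(masks.cc3_live.sum())
    feats: dict[str, float] = {
        "nuclei_count": count_components(masks.nuclei),
        "eh_px": eh_px,
        "eh_count": count_components(masks.eh),
        "cc3_px": int(masks.cc3.sum()),
        "cc3_count": count_components(masks.cc3),
        "cc3_live_px": cc3_live_px,
        "calcein_px": int(masks.calcein.sum()),
        "live_px": live_px,
        "live_count": count_components(masks.live),
    }
    denom = eh_px + live_px
    feats["dead_fraction"] = eh_px / denom if denom else float("nan")
    feats["cc3_live_fraction"] = cc3_live_px / live_px if live_px else float("nan")
    return FeatureRecord(bioreactor_id, "viability", feats, metadata or {})
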
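"""Segmentation of the microfluidic device (chip) structures.

Each bioreactor image contains three vertical device blocks — the left wall,
the central phase guide and the right wall — separating the Matrigel channel
(MC, left of the phase guide) from the perfusion channel (PC, right of it).
A rough 2D device mask from max-projected, average-filtered channels is
refined by a fixed morphological chain, the phase guide is identified as the
middle of the three blocks, and MC/PC are recovered by geodesic
reconstruction in the complement of the device mask.

Cellular masks downstream must exclude every device-mask voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume_ops import (
    average_filter,
    disk,
    filter_components_by_size,
    label_mask,
    max_project,
    reconstruct,
    vertical_rod,
)

logger = logging.getLogger(__name__)


class ChipNotFoundError(RuntimeError):
    """No device structure survived the refinement chain."""


class PhaseGuideError(RuntimeError):
    """The refined device mask does not split into exactly three blocks."""


@dataclass
class ChannelStack:
    """One bioreactor's raw multi-channel stack, channels keyed by role."""

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel {role!r} missing; available: {sorted(self.channels)}"
            ) from None


@dataclass
class ChipParams:
    """Structuring-element sizes and thresholds of the device-refinement chain.

    Defaults are the published values; ``scaled()`` derives a variant for
    smaller synthetic images.  Rod heights exceeding the image are clipped to
    the image extent with a logged warning.
    """

    erode_disk_r: int = 5
    min_rough_px: int = 1000
    dilate_disk_r: int = 20
    rod_close_h: int = 101
    rod_erode_h: int = 501
    min_final_px: int = 100_000
    open_disk_r: int | None = None       # cell-death recipe only
    final_dilate_r: int | None = None    # cell-death recipe only
    phaseguide_planes: int = 8
    connectivity: str = "full"
    # morphometric rough mask: per-channel thresholds, combined by OR
    rough_thresholds: dict[str, float] = field(default_factory=dict)
    # mito rule grouping: "(tmrm_range) or (hoechst_range and mito_min)"
    mito_rule_or_of_and: bool = True

    @classmethod
    def morphometric(cls, rough_thresholds: dict[str, float] | None = None) -> "ChipParams":
        return cls(rough_thresholds=dict(rough_thresholds or {}))

    @classmethod
    def mitochondrial(cls) -> "ChipParams":
        return cls()

    @classmethod
    def cell_death(cls) -> "ChipParams":
        return cls(rod_close_h=201, rod_erode_h=3001, open_disk_r=20, final_dilate_r=22)

    def scaled(self, min_rough_px: int, min_final_px: int) -> "ChipParams":
        """Same chain with component-size thresholds suited to a smaller image."""
        return replace(self, min_rough_px=min_rough_px, min_final_px=min_final_px)


@dataclass
class ChipMasks:
    """Device-structure masks for one bioreactor.

    ``device`` is 3D (walls at all planes, phase guide only in the lowest
    ``phaseguide_planes``); ``matrigel`` / ``perfusion`` are the 3D channel
    regions.  Cellular masks must exclude ``device``.
    """

    device: np.ndarray
    phaseguide: np.ndarray
    matrigel: np.ndarray
    perfusion: np.ndarray
    device_2d: np.ndarray
    phaseguide_2d: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.matrigel & self.perfusion):
            raise ValueError("Matrigel and perfusion channel masks overlap")
        if np.any(self.matrigel & self.device) or np.any(self.perfusion & self.device):
            raise ValueError("channel masks overlap the device mask")
        zs = np.flatnonzero(self.phaseguide.any(axis=(1, 2)))
        if zs.size and zs.max() >= 8:
            raise ValueError("phase guide voxels above the lowest eight planes")


def _avg_maxproj(vol: np.ndarray, side: int = 5) -> np.ndarray:
    return max_project(average_filter(vol, side))


def _binary(mask2d, se, op: str) -> np.ndarray:
    if op == "erode":
        # Matlab imerode convention: out-of-image pixels count as foreground,
        # so full-height walls survive tall-rod erosion.
        return ndimage.binary_erosion(mask2d, structure=se, border_value=1)
    return ndimage.binary_dilation(mask2d, structure=se, border_value=0)


def refine_device_mask(rough: np.ndarray, params: ChipParams) -> np.ndarray:
    """The shared refinement chain from rough 2D mask to device blocks."""
    h = rough.shape[0]
    m = _binary(rough, disk(params.erode_disk_r), "erode")
    m = filter_components_by_size(m, params.min_rough_px, connectivity=params.connectivity)
    if not m.any():
        raise ChipNotFoundError("chip not found: nothing survived the rough size filter")
    m = _binary(m, disk(params.dilate_disk_r), "dilate")
    m = _binary(m, vertical_rod(params.rod_close_h, 2 * h - 1), "dilate")
    m = _binary(m, vertical_rod(params.rod_erode_h, 2 * h - 1), "erode")
    m = filter_components_by_size(m, params.min_final_px, connectivity=params.connectivity)
    if not m.any():
        raise ChipNotFoundError("chip not found: nothing survived the final size filter")
    if params.open_disk_r:
        m = ndimage.binary_opening(m, structure=disk(params.open_disk_r))
        if not m.any():
            raise ChipNotFoundError("chip not found: nothing survived the disk opening")
    if params.final_dilate_r:
        m = _binary(m, disk(params.final_dilate_r), "dilate")
    return m


def detect_phaseguide(device_mask_2d: np.ndarray, connectivity: str = "full") -> np.ndarray:
    """Middle of the three left-to-right device blocks (ordered by min x)."""
    labels, n = label_mask(device_mask_2d, connectivity)
    if n != 3:
        raise PhaseGuideError(f"phase-guide ambiguity: expected 3 device blocks, found {n}")
    min_x = [np.flatnonzero((labels == i).any(axis=0)).min() for i in range(1, n + 1)]
    middle = 1 + int(np.argsort(min_x)[1])
    return labels == middle


def derive_channels(
    phaseguide_2d: np.ndarray, device_mask_2d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Matrigel (left of the phase guide) and perfusion (right) channel masks.

    Seeds extend the phase guide one pixel leftward / rightward; the limiting
    mask is the complement of the device mask.
    """
    if not phaseguide_2d.any():
        raise ValueError("empty phase-guide mask")
    limit = ~np.asarray(device_mask_2d, dtype=bool)
    seed_left = phaseguide_2d.copy()
    seed_left[:, :-1] |= phaseguide_2d[:, 1:]   # extend toward smaller x
    seed_right = phaseguide_2d.copy()
    seed_right[:, 1:] |= phaseguide_2d[:, :-1]  # extend toward larger x
    mc = reconstruct(seed_left, limit)
    pc = reconstruct(seed_right, limit)
    overlap = mc & pc
    if overlap.any():  # seed leaked around the phase guide (degenerate chip)
        mc &= ~overlap
        pc &= ~overlap
    if not mc.any():
        logger.warning("Matrigel-channel reconstruction empty (phase guide flush to wall?)")
    if not pc.any():
        logger.warning("perfusion-channel reconstruction empty (phase guide flush to wall?)")
    return mc, pc


def _assemble(rough: np.ndarray, nz: int, params: ChipParams) -> ChipMasks:
    device_2d = refine_device_mask(rough, params)
    pg_2d = detect_phaseguide(device_2d, params.connectivity)
    mc_2d, pc_2d = derive_channels(pg_2d, device_2d)
    npg = params.phaseguide_planes
    device = np.broadcast_to(device_2d & ~pg_2d, (nz,) + device_2d.shape).copy()
    phaseguide = np.zeros((nz,) + device_2d.shape, dtype=bool)
    phaseguide[: min(npg, nz)] = pg_2d
    device |= phaseguide
    mc = np.broadcast_to(mc_2d, (nz,) + mc_2d.shape).copy()
    pc = np.broadcast_to(pc_2d, (nz,) + pc_2d.shape).copy()
    mc &= ~device
    pc &= ~device
    return ChipMasks(device, phaseguide, mc, pc, device_2d, pg_2d)


def segment_chip_morphometric(stack: ChannelStack, params: ChipParams) -> ChipMasks:
    """Chip recipe for the fixed-immunostaining assay.

    Rough mask = OR over all channels of (size-5 average-filtered max
    projection > per-channel threshold); thresholds come from
    ``params.rough_thresholds`` (keys = channel roles).
    """
    if not params.rough_thresholds:
        raise ValueError("morphometric chip segmentation needs per-channel rough thresholds")
    nz = stack.shape[0]
    rough = None
    for role, thr in params.rough_thresholds.items():
        m = _avg_maxproj(stack[role]) > thr
        rough = m if rough is None else (rough | m)
    if not rough.any():
        raise ChipNotFoundError("chip not found: rough thresholding produced an empty mask")
    return _assemble(rough, nz, params)


def segment_chip_mito(stack: ChannelStack, params: ChipParams | None = None) -> ChipMasks:
    """Chip recipe for the live mitochondrial assay.

    Rough rule on size-5 average-filtered max projections:
    ``(10 < TMRM < 30) OR ((30 < Hoechst < 200) AND (MitoTracker > 15))``.
    """
    params = params or ChipParams.mitochondrial()
    tmrm = _avg_maxproj(stack["tmrm"])
    hoechst = _avg_maxproj(stack["hoechst"])
    mito = _avg_maxproj(stack["mitotracker"])
    if params.mito_rule_or_of_and:
        rough = ((tmrm > 10) & (tmrm < 30)) | (((hoechst > 30) & (hoechst < 200)) & (mito > 15))
    else:  # alternative grouping: (range OR range) AND mito
        rough = (((tmrm > 10) & (tmrm < 30)) | ((hoechst > 30) & (hoechst < 200))) & (mito > 15)
    if not rough.any():
        raise ChipNotFoundError("chip not found: rough rule produced an empty mask")
    return _assemble(rough, stack.shape[0], params)


def segment_chip_celldeath(stack: ChannelStack, params: ChipParams | None = None) -> ChipMasks:
    """Chip recipe for the live/dead assay: rough rule ``50 < Calcein < 300``
    on the size-5 average-filtered max projection, refined with rod heights
    201 (close) / 3001 (erode) plus disk opening r=20 and dilation r=22."""
    params = params or ChipParams.cell_death()
    cal = _avg_maxproj(stack["calcein"])
    rough = (cal > 50) & (cal < 300)
    if not rough.any():
        raise ChipNotFoundError("chip not found: rough rule produced an empty mask")
    return _assemble(rough, stack.shape[0], params)
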
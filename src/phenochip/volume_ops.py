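"""Low-level operations on 3D fluorescence volumes.

All volumes are numpy arrays indexed ``(z, y, x)`` with ``z = 0`` the
bottom-most acquired plane.  Smoothing filters act plane-wise (each z-plane
independently), matching per-plane confocal acquisition; a 3D variant can be
selected where noted.  Gray levels are raw, dimensionless camera counts.

Kernel conventions follow the Matlab ``fspecial`` reading: a "Gaussian filter
of size N and standard deviation s" is an N x N truncated Gaussian sampled on
the centred grid ``-(N-1)/2 .. (N-1)/2`` and normalised to sum 1; borders are
replicate-padded.  The 2D kernel is exactly separable, so filtering is done
with two 1D passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "gaussian_kernel_1d",
    "gaussian_kernel_2d",
    "gaussian_lowpass",
    "difference_of_gaussians",
    "average_filter",
    "max_project",
    "filter_components_by_size",
    "erode_with_surface",
    "reconstruct",
    "stitch_mosaic",
    "label_mask",
    "count_components",
    "disk",
    "vertical_rod",
]


def _check_volume(vol: np.ndarray) -> np.ndarray:
    vol = np.asarray(vol)
    if vol.ndim not in (2, 3):
        raise ValueError(f"expected a 2D plane or 3D volume, got ndim={vol.ndim}")
    return vol


def gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    """Truncated 1D Gaussian on the centred grid, normalised to sum 1."""
    if size < 1:
        raise ValueError(f"kernel size must be >= 1, got {size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.arange(size, dtype=float) - (size - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_kernel_2d(size: int, sigma: float) -> np.ndarray:
    """Size x size truncated, sum-normalised Gaussian (separable outer product)."""
    k = gaussian_kernel_1d(size, sigma)
    return np.outer(k, k)


def _filter_planewise_1d(vol: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Correlate every z-plane with `weights` along y then x, replicate borders."""
    out = ndimage.correlate1d(vol, weights, axis=-2, mode="nearest")
    out = ndimage.correlate1d(out, weights, axis=-1, mode="nearest")
    return out


def gaussian_lowpass(vol: np.ndarray, size: int, sigma: float, *, three_d: bool = False) -> np.ndarray:
    """Plane-wise 2D Gaussian smoothing (size x size kernel, std `sigma`).

    With ``three_d=True`` the same 1D kernel is additionally applied along z.
    Constants are preserved exactly (kernel sums to 1).
    """
    vol = _check_volume(vol).astype(float, copy=False)
    k = gaussian_kernel_1d(size, sigma)
    out = _filter_planewise_1d(vol, k)
    if three_d and vol.ndim == 3:
        out = ndimage.correlate1d(out, k, axis=0, mode="nearest")
    return out


def difference_of_gaussians(
    vol: np.ndarray,
    fg_size: int,
    fg_sigma: float,
    bg_size: int,
    bg_sigma: float,
    *,
    three_d: bool = False,
) -> np.ndarray:
    """Band-pass enhancement: foreground blur minus background blur.

    Signed values are retained; a constant volume maps to exactly zero.
    """
    if fg_sigma >= bg_sigma:
        raise ValueError(
            f"foreground sigma ({fg_sigma}) must be smaller than background sigma ({bg_sigma})"
        )
    fg = gaussian_lowpass(vol, fg_size, fg_sigma, three_d=three_d)
    bg = gaussian_lowpass(vol, bg_size, bg_sigma, three_d=three_d)
    return fg - bg


def average_filter(vol: np.ndarray, side: int) -> np.ndarray:
    """Plane-wise mean filter over a side x side square window."""
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    vol = _check_volume(vol).astype(float, copy=False)
    size = (side, side) if vol.ndim == 2 else (1, side, side)
    return ndimage.uniform_filter(vol, size=size, mode="nearest")


def max_project(vol: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z; a 2D input is returned as is."""
    vol = _check_volume(vol)
    if vol.ndim == 2:
        return vol.copy()
    return vol.max(axis=0)


def _conn_structure(ndim: int, connectivity: str | int) -> np.ndarray:
    """Connectivity: 'full' (26/8, the default throughout) or 'minimal' (6/4)."""
    if connectivity in ("full", 26, 8):
        return np.ones((3,) * ndim, dtype=bool)
    if connectivity in ("minimal", 6, 4):
        return ndimage.generate_binary_structure(ndim, 1)
    raise ValueError(f"unknown connectivity {connectivity!r}")


def label_mask(mask: np.ndarray, connectivity: str | int = "full"):
    """Label connected components; returns (labels, n)."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.label(mask, structure=_conn_structure(mask.ndim, connectivity))


def count_components(mask: np.ndarray, connectivity: str | int = "full") -> int:
    return label_mask(mask, connectivity)[1]


def filter_components_by_size(
    mask: np.ndarray,
    min_px: int,
    max_px: int | float | None = None,
    connectivity: str | int = "full",
) -> np.ndarray:
    """Keep connected components whose voxel count lies in [min_px, max_px].

    Both bounds are inclusive: "less than 5 or more than 500 removed" keeps
    exactly-5 and exactly-500 voxel components.
    """
    if min_px < 0:
        raise ValueError(f"min_px must be >= 0, got {min_px}")
    if max_px is None:
        max_px = np.inf
    if min_px > max_px:
        raise ValueError(f"min_px ({min_px}) > max_px ({max_px})")
    mask = np.asarray(mask, dtype=bool)
    labels, n = label_mask(mask, connectivity)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = (sizes >= min_px) & (sizes <= max_px)
    return keep[labels]


def erode_with_surface(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a mask into eroded body and surface shell.

    Erosion uses the 6-connected 3D structuring element (centre voxel plus
    face neighbours; 4-connected in 2D).  Out-of-volume neighbours count as
    background, so voxels on the volume border always erode.  Returns
    ``(eroded, surface)`` with ``surface = mask & ~eroded``.
    """
    mask = np.asarray(mask, dtype=bool)
    se = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=se, border_value=0)
    surface = mask & ~eroded
    return eroded, surface


def reconstruct(seed: np.ndarray, limit: np.ndarray, connectivity: str | int = "full") -> np.ndarray:
    """Geodesic binary reconstruction: components of `limit` that touch `seed`.

    Seed voxels outside `limit` are ignored.  Equivalent to dilating
    ``seed & limit`` inside `limit` until stable.
    """
    seed = np.asarray(seed, dtype=bool)
    limit = np.asarray(limit, dtype=bool)
    if seed.shape != limit.shape:
        raise ValueError("seed and limit shapes differ")
    labels, n = label_mask(limit, connectivity)
    if n == 0:
        return np.zeros_like(limit)
    hit = np.zeros(n + 1, dtype=bool)
    touched = labels[seed & limit]
    if touched.size:
        hit[np.unique(touched)] = True
    hit[0] = False
    return hit[labels]


# ---------------------------------------------------------------------------
# structuring elements

def disk(radius: int) -> np.ndarray:
    """Flat disk-shaped structuring element (Euclidean, origin-centred)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    return yy**2 + xx**2 <= radius**2


def vertical_rod(height: int, max_height: int | None = None) -> np.ndarray:
    """Height x 1 vertical rod; clipped (odd) to `max_height` when it exceeds it."""
    if height < 1:
        raise ValueError("height must be >= 1")
    if max_height is not None and height > max_height:
        clipped = max_height if max_height % 2 == 1 else max_height - 1
        clipped = max(clipped, 1)
        logger.warning("vertical rod of height %d clipped to image extent (%d)", height, clipped)
        height = clipped
    return np.ones((height, 1), dtype=bool)


# ---------------------------------------------------------------------------
# mosaic stitching

@dataclass
class StitchResult:
    """Stitched canvas plus the per-field positions actually used."""

    mosaic: np.ndarray
    positions: list[tuple[int, int]]
    fallbacks: int = 0


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def _pair_offset(
    ref: np.ndarray,
    mov: np.ndarray,
    axis: int,
    overlap: int,
    window: int,
) -> tuple[tuple[int, int], bool]:
    """Offset of `mov` relative to its nominal position next to `ref`.

    NCC is evaluated on max projections of the nominal overlap strips for
    every integer shift in ``[-window, window]^2``; the argmax wins.  Returns
    ``((dy, dx), fell_back)``; a zero-variance strip falls back to (0, 0).
    """
    ref2 = max_project(ref)
    mov2 = max_project(mov)
    h, w = ref2.shape
    best, best_shift = -np.inf, (0, 0)
    found = False
    for dy in range(-window, window + 1):
        for dx in range(-window, window + 1):
            if axis == 1:  # mov to the right of ref
                ov = overlap - dx
                if ov < 1 or ov > w:
                    continue
                a = ref2[:, w - ov:]
                b = mov2[:, :ov]
                if dy > 0:
                    a, b = a[dy:, :], b[: h - dy, :]
                elif dy < 0:
                    a, b = a[: h + dy, :], b[-dy:, :]
            else:  # mov below ref
                ov = overlap - dy
                if ov < 1 or ov > h:
                    continue
                a = ref2[h - ov:, :]
                b = mov2[:ov, :]
                if dx > 0:
                    a, b = a[:, dx:], b[:, : w - dx]
                elif dx < 0:
                    a, b = a[:, : w + dx], b[:, -dx:]
            if a.size == 0:
                continue
            r = _ncc(a, b)
            if np.isnan(r):
                continue
            found = True
            if r > best:
                best, best_shift = r, (dy, dx)
    if not found:
        logger.warning("zero-variance overlap strip; falling back to nominal offset")
        return (0, 0), True
    return best_shift, False


def stitch_mosaic(
    fields: list[np.ndarray],
    grid: tuple[int, int],
    overlap: int,
    *,
    search_frac: float = 0.25,
    blend: str = "max",
) -> StitchResult:
    """Stitch a rows x cols mosaic of equally shaped fields by translation.

    `fields` is row-major.  Each field's shift from its nominal grid position
    is estimated from the normalized cross-correlation of the overlap strips
    against the left (or, for the first column, top) neighbour, searched in a
    window of ``+-max(1, search_frac * overlap)`` px.  Overlapping voxels are
    blended by `blend` ('max' preserves puncta; 'mean' feathers linearly).
    """
    rows, cols = grid
    if len(fields) != rows * cols:
        raise ValueError(f"expected {rows * cols} fields, got {len(fields)}")
    fields = [np.asarray(f, dtype=float) for f in fields]
    shape0 = fields[0].shape
    if any(f.shape != shape0 for f in fields):
        raise ValueError("all fields must share the same shape")
    if len(fields) == 1:
        return StitchResult(fields[0].copy(), [(0, 0)])
    if overlap < 1:
        raise ValueError("overlap strip must be non-empty")
    squeeze = fields[0].ndim == 2
    if squeeze:
        fields = [f[None] for f in fields]
    nz, h, w = fields[0].shape
    window = max(1, int(round(search_frac * overlap)))

    positions: list[tuple[int, int]] = [None] * len(fields)  # type: ignore[list-item]
    fallbacks = 0
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if r == 0 and c == 0:
                positions[i] = (0, 0)
                continue
            if c > 0:
                j, axis = i - 1, 1
                nominal = (positions[j][0], positions[j][1] + w - overlap)
            else:
                j, axis = i - cols, 0
                nominal = (positions[j][0] + h - overlap, positions[j][1])
            (dy, dx), fb = _pair_offset(fields[j], fields[i], axis, overlap, window)
            fallbacks += fb
            positions[i] = (nominal[0] + dy, nominal[1] + dx)

    y0 = min(p[0] for p in positions)
    x0 = min(p[1] for p in positions)
    positions = [(p[0] - y0, p[1] - x0) for p in positions]
    H = max(p[0] for p in positions) + h
    W = max(p[1] for p in positions) + w

    if blend == "max":
        canvas = np.full((nz, H, W), -np.inf)
        for f, (py, px) in zip(fields, positions):
            region = canvas[:, py : py + h, px : px + w]
            np.maximum(region, f, out=region)
        canvas[np.isneginf(canvas)] = 0.0
    elif blend == "mean":
        canvas = np.zeros((nz, H, W))
        weight = np.zeros((1, H, W))
        for f, (py, px) in zip(fields, positions):
            canvas[:, py : py + h, px : px + w] += f
            weight[:, py : py + h, px : px + w] += 1.0
        canvas = np.divide(canvas, weight, out=canvas, where=weight > 0)
    else:
        raise ValueError(f"unknown blend rule {blend!r}")
    if squeeze:
        canvas = canvas[0]
    return StitchResult(canvas, positions, fallbacks)
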
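"""Synthetic 3D chip fixtures with voxel-level ground truth.

The generator renders what the assay pipelines expect to see: a microfluidic
chamber with two autofluorescent walls and a central phase guide (confined
to the lowest planes), a Matrigel channel to the guide's left and a
perfusion channel to its right, and assay-specific cellular objects — nuclei
(normal and bright pyknotic), branching neurite trees, punctate mitochondria
and live/dead/apoptotic cells — drawn on the raw gray-level scale the fixed
segmentation thresholds assume (e.g. pyknotic Hoechst above 400, TH above
100 after smoothing), with at least a 20% margin to every threshold so
noise-free recovery is exact.

What it does not emulate: optics (PSF blur, depth attenuation), illumination
gradients, intensity variation between cells, and touching/overlapping
objects.  Passing tests therefore demonstrate correctness of the mask
recipes and bookkeeping, not robustness to real acquisition artefacts.

Additive Gaussian noise is applied per channel with standard deviation
``noise_frac`` times that channel's maximum drawn intensity.  Everything is
deterministic under ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .chip import ChannelStack, ChipParams


@dataclass
class ChipGeometry:
    """Vertical-block layout along x; walls at both edges, guide centred."""

    nx: int = 256
    ny: int = 256
    nz: int = 20
    wall_w: int = 40
    pg_x0: int = 110
    pg_w: int = 36
    pg_planes: int = 8

    @property
    def mc_span(self) -> tuple[int, int]:
        return (self.wall_w, self.pg_x0)

    @property
    def pc_span(self) -> tuple[int, int]:
        return (self.pg_x0 + self.pg_w, self.nx - self.wall_w)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic bioreactor fixture.

    ``intensities`` maps semantic object classes to raw gray levels;
    ``counts`` maps object classes to how many are placed.  ``margin`` is
    the x-clearance kept between cellular objects and the *refined* device
    mask (which is dilated outward by the refinement chain, +15 px for the
    morphometric/mito recipe and +37 px for the cell-death recipe).
    """

    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    counts: dict[str, int] = field(default_factory=dict)
    intensities: dict[str, float] = field(default_factory=dict)
    noise_frac: float = 0.0
    noise_ref: dict[str, float] = field(default_factory=dict)
    margin: int = 18
    seed: int = 0
    min_spacing: float = 26.0
    mito_size_range: tuple[int, int] = (5, 80)
    tree_branch_depth: int = 1

    @classmethod
    def morpho(cls, seed: int = 0, noise_frac: float = 0.0) -> "FixtureSpec":
        return cls(
            geometry=ChipGeometry(),
            counts={"nuclei": 8, "pyknotic": 3, "trees": 5, "th_trees": 2},
            intensities={
                "wall": 800, "nucleus": 250, "pyknotic": 600,
                "soma": 400, "neurite": 120, "th": 300,
            },
            noise_ref={"hoechst": 600, "tuj1": 400, "th": 300, "stain4": 800},
            noise_frac=noise_frac, seed=seed,
        )

    @classmethod
    def mito(cls, seed: int = 0, noise_frac: float = 0.0) -> "FixtureSpec":
        return cls(
            geometry=ChipGeometry(),
            counts={"mito": 50, "nuclei": 6, "cells": 4},
            intensities={
                "wall_tmrm": 14, "nucleus": 250, "cellmask": 480,
                "mito_tmrm": 250, "mito_green": 100,
            },
            noise_ref={"hoechst": 250, "mitotracker": 100, "tmrm": 250, "cellmask": 480},
            noise_frac=noise_frac, seed=seed, min_spacing=14.0,
        )

    @classmethod
    def viability(cls, seed: int = 0, noise_frac: float = 0.0) -> "FixtureSpec":
        return cls(
            geometry=ChipGeometry(nx=460, ny=400, wall_w=60, pg_x0=220, pg_w=60),
            counts={"live": 10, "dead": 4, "cc3_live": 3},
            intensities={
                "wall_calcein": 150, "calcein": 400, "nucleus": 400,
                "eh": 800, "cc3": 400,
            },
            noise_ref={"hoechst": 400, "calcein": 400, "eh": 800, "cc3": 400},
            noise_frac=noise_frac, seed=seed, margin=42,
        )


@dataclass
class GroundTruth:
    """What the rendered fixture contains, by construction."""

    counts: dict[str, int]
    objects: list[dict] = field(default_factory=list)
    tree_node_count: int = 0
    tree_link_count: int = 0


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap after bounded retries."""


# ---------------------------------------------------------------------------
# drawing primitives

def _draw_ellipsoid(vol: np.ndarray, center, rz: float, rxy: float, value: float) -> int:
    """Paint max(vol, value) inside an axis-aligned ellipsoid; returns voxels."""
    nz, ny, nx = vol.shape
    cz, cy, cx = center
    z0, z1 = max(0, int(cz - rz)), min(nz, int(cz + rz) + 1)
    y0, y1 = max(0, int(cy - rxy)), min(ny, int(cy + rxy) + 1)
    x0, x1 = max(0, int(cx - rxy)), min(nx, int(cx + rxy) + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    inside = ((zz - cz) / rz) ** 2 + ((yy - cy) / rxy) ** 2 + ((xx - cx) / rxy) ** 2 <= 1.0
    region = vol[z0:z1, y0:y1, x0:x1]
    region[inside] = np.maximum(region[inside], value)
    return int(inside.sum())


def _draw_tube(vol: np.ndarray, points: Iterable[tuple[int, int, int]], r: float, value: float) -> None:
    """Paint a tube of xy-radius `r` (single plane per point) along a path."""
    nz, ny, nx = vol.shape
    ri = int(np.ceil(r))
    offs = [
        (dy, dx)
        for dy in range(-ri, ri + 1)
        for dx in range(-ri, ri + 1)
        if dy * dy + dx * dx <= r * r
    ]
    for z, y, x in points:
        if not (0 <= z < nz):
            continue
        for dy, dx in offs:
            yy, xx = y + dy, x + dx
            if 0 <= yy < ny and 0 <= xx < nx:
                vol[z, yy, xx] = max(vol[z, yy, xx], value)


def _place_centers(
    rng: np.random.Generator,
    n: int,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    z_range: tuple[float, float],
    min_spacing: float,
    max_tries: int = 5000,
) -> list[tuple[float, float, float]]:
    """Random non-overlapping (z, y, x) centers, seeded; raises when stuck."""
    centers: list[tuple[float, float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} objects with spacing {min_spacing} "
                f"in x{x_range} y{y_range} (placed {len(centers)})"
            )
        tries += 1
        z = rng.uniform(*z_range)
        y = rng.uniform(*y_range)
        x = rng.uniform(*x_range)
        if all((y - c[1]) ** 2 + (x - c[2]) ** 2 >= min_spacing**2 for c in centers):
            centers.append((z, y, x))
    return centers


def _usable_spans(spec: FixtureSpec) -> list[tuple[int, int]]:
    g = spec.geometry
    spans = []
    for lo, hi in (g.mc_span, g.pc_span):
        lo2, hi2 = lo + spec.margin, hi - spec.margin
        if hi2 > lo2:
            spans.append((lo2, hi2))
    return spans


def _render_chip(channels: dict[str, np.ndarray], spec: FixtureSpec, wall_values: dict[str, float]) -> None:
    """Walls at all planes, phase guide only in the lowest planes."""
    g = spec.geometry
    for role, val in wall_values.items():
        vol = channels[role]
        vol[:, :, : g.wall_w] = val
        vol[:, :, g.nx - g.wall_w :] = val
        vol[: g.pg_planes, :, g.pg_x0 : g.pg_x0 + g.pg_w] = val


def _add_noise(channels: dict[str, np.ndarray], spec: FixtureSpec, rng: np.random.Generator) -> None:
    """Additive Gaussian noise, sigma = noise_frac x the channel's dynamic
    range of cellular signal (``noise_ref``; device autofluorescence is not
    part of the quantified signal).  Clipped at 0 like camera counts."""
    if spec.noise_frac <= 0:
        return
    for role, vol in channels.items():
        ref = spec.noise_ref.get(role, vol.max())
        if ref <= 0:
            continue
        vol += rng.normal(0.0, spec.noise_frac * ref, size=vol.shape)
        np.clip(vol, 0.0, None, out=vol)


# ---------------------------------------------------------------------------
# neurite trees

def _tree_paths(x0: int, y0: int, z: int, depth: int, trunk_len: int = 40, arm_len: int = 20):
    """Binary tree of straight segments: a +y trunk, then diverging arms.

    Returns (segments, node_count, link_count): a full binary branching of
    `depth` levels has 2^depth - 1 branch points and 2^(depth+1) - 1 links.
    """
    segments = []  # each: list of (z, y, x)
    tips = [(x0, y0 + trunk_len)]
    segments.append([(z, y0 + i, x0) for i in range(trunk_len + 1)])
    spread = 0.5  # arms diverge half a pixel in x per step, halved each level
    for level in range(depth):
        new_tips = []
        for tx, ty in tips:
            for sign in (-1, 1):
                pts = [
                    (z, ty + i, int(round(tx + sign * spread * i)))
                    for i in range(1, arm_len + 1)
                ]
                segments.append(pts)
                new_tips.append((pts[-1][2], pts[-1][1]))
        tips = new_tips
        spread /= 2.0
    node_count = 2**depth - 1
    link_count = 2 ** (depth + 1) - 1
    return segments, node_count, link_count


# ---------------------------------------------------------------------------
# assay renderers

def _generate_morpho(spec: FixtureSpec, rng: np.random.Generator):
    g = spec.geometry
    shape = (g.nz, g.ny, g.nx)
    ch = {r: np.zeros(shape) for r in ("hoechst", "tuj1", "th", "stain4")}
    iv = spec.intensities
    _render_chip(ch, spec, {r: iv["wall"] for r in ch})

    spans = _usable_spans(spec)
    n_nuc = spec.counts.get("nuclei", 0)
    n_pyk = spec.counts.get("pyknotic", 0)
    n_tree = spec.counts.get("trees", 0)
    n_th = spec.counts.get("th_trees", 0)

    # trees occupy fixed vertical slots per channel side; nuclei fill the rest
    objects: list[dict] = []
    tree_height = 48 + 20 * spec.tree_branch_depth + 4
    slots = []
    for lo, hi in spans:
        xc = (lo + hi) // 2
        y = 14
        while y + tree_height <= g.ny - 4:
            slots.append((xc, y))
            y += tree_height + 6
    if len(slots) < n_tree:
        raise PlacementError(f"only {len(slots)} tree slots for {n_tree} trees")
    order = rng.permutation(len(slots))[:n_tree]
    zc = g.nz // 2
    total_nodes = total_links = 0
    tree_regions = []
    for i, si in enumerate(order):
        xc, y0 = slots[si]
        is_th = i < n_th
        segments, nodes, links = _tree_paths(xc, y0 + 8, zc, spec.tree_branch_depth)
        _draw_ellipsoid(ch["tuj1"], (zc, y0 + 4, xc), 2, 5, iv["soma"])
        # bright tapering proximal segment keeps the soma (global-mask) and
        # neurite (local-mask) detections connected across the soma's DoG
        # shadow, with a wide margin so noise cannot split the tree
        _draw_tube(ch["tuj1"], segments[0][:13], 2.5, iv["soma"])
        _draw_tube(ch["tuj1"], segments[0][13:19], 2.2, 0.75 * iv["soma"])
        _draw_tube(ch["tuj1"], segments[0][19:25], 1.8, 0.5 * iv["soma"])
        for seg in segments:
            _draw_tube(ch["tuj1"], seg, 1.4, iv["neurite"])
        if is_th:
            _draw_ellipsoid(ch["th"], (zc, y0 + 4, xc), 2, 5, iv["th"])
            for seg in segments:
                _draw_tube(ch["th"], seg, 1.4, iv["th"])
            total_nodes += nodes
            total_links += links
        objects.append({"class": "tree", "x": xc, "y": y0, "th": is_th})
        tree_regions.append((xc, y0))

    # nuclei live in the Hoechst channel only, so they may share space with
    # the Tuj1/TH trees; they only need clearance from each other
    lo, hi = spans[0]
    centers = _place_centers(
        rng, n_nuc, (lo + 8, hi - 8), (10, g.ny - 10), (zc, zc), 24.0
    )
    for i, (z, y, x) in enumerate(centers):
        pyk = i < n_pyk
        val = iv["pyknotic"] if pyk else iv["nucleus"]
        _draw_ellipsoid(ch["hoechst"], (z, y, x), 2, 6, val)
        objects.append({"class": "pyknotic" if pyk else "nucleus", "x": x, "y": y})

    _add_noise(ch, spec, rng)
    gt = GroundTruth(
        counts={
            "nuclei_count": n_nuc,
            "pyknotic_count": n_pyk,
            "neuron_count": n_tree,
            "th_count": n_th,
        },
        objects=objects,
        tree_node_count=total_nodes,
        tree_link_count=total_links,
    )
    return ChannelStack(ch), gt


def _generate_mito(spec: FixtureSpec, rng: np.random.Generator):
    g = spec.geometry
    shape = (g.nz, g.ny, g.nx)
    ch = {r: np.zeros(shape) for r in ("hoechst", "mitotracker", "tmrm", "cellmask")}
    iv = spec.intensities
    _render_chip(ch, spec, {"tmrm": iv["wall_tmrm"]})

    spans = _usable_spans(spec)
    zc = g.nz // 2
    objects: list[dict] = []

    # cells with one nucleus each, in the Matrigel channel
    n_cells = spec.counts.get("cells", 0)
    n_nuc = spec.counts.get("nuclei", 0)
    lo, hi = spans[0]
    cell_xc = (lo + hi) // 2
    cell_centers = [(zc, 35 + i * 66, cell_xc) for i in range(n_cells)]
    for c in cell_centers:
        _draw_ellipsoid(ch["cellmask"], c, 3, 12, iv["cellmask"])
        _draw_ellipsoid(ch["hoechst"], c, 2, 5, iv["nucleus"])
        objects.append({"class": "cell", "y": c[1], "x": c[2]})
    for i in range(max(0, n_nuc - n_cells)):  # extra free nuclei in the PC
        lo2, hi2 = spans[-1]
        c = (zc, 30 + i * 40, (lo2 + hi2) // 2)
        _draw_ellipsoid(ch["hoechst"], c, 2, 5, iv["nucleus"])
        objects.append({"class": "nucleus", "y": c[1], "x": c[2]})

    # mitochondrial puncta: compact blobs, sizes in the detector's regime
    n_mito = spec.counts.get("mito", 0)
    zr = (3, g.nz - 4)
    xr = []
    for lo3, hi3 in spans:
        xr.append((lo3 + 3, hi3 - 3))
    half = (n_mito + 1) // 2
    placed = 0
    for (x0, x1), count in zip(xr, (half, n_mito - half)):
        centers = _place_centers(
            rng, count, (x0, x1), (8, g.ny - 8), zr, spec.min_spacing
        )
        for c in centers:
            rxy = rng.uniform(1.0, 2.4)
            rz = rng.uniform(1.0, 1.6)
            _draw_ellipsoid(ch["tmrm"], c, rz, rxy, iv["mito_tmrm"])
            _draw_ellipsoid(ch["mitotracker"], c, rz, rxy, iv["mito_green"])
            objects.append({"class": "mito", "y": c[1], "x": c[2]})
            placed += 1
    _add_noise(ch, spec, rng)
    gt = GroundTruth(counts={"mito_count": placed, "cell_count": n_cells}, objects=objects)
    return ChannelStack(ch), gt


def _generate_viability(spec: FixtureSpec, rng: np.random.Generator):
    g = spec.geometry
    shape = (g.nz, g.ny, g.nx)
    ch = {r: np.zeros(shape) for r in ("hoechst", "calcein", "eh", "cc3")}
    iv = spec.intensities
    _render_chip(ch, spec, {"calcein": iv["wall_calcein"]})

    lo, hi = _usable_spans(spec)[0]
    zc = g.nz // 2
    n_live = spec.counts.get("live", 0)
    n_dead = spec.counts.get("dead", 0)
    n_cc3 = spec.counts.get("cc3_live", 0)
    n_total = n_live + n_dead + n_cc3
    centers = _place_centers(
        rng, n_total, (lo + 12, hi - 12), (16, g.ny - 16), (zc, zc), spec.min_spacing
    )
    objects: list[dict] = []
    for i, c in enumerate(centers):
        if i < n_live:
            kind = "live"
        elif i < n_live + n_dead:
            kind = "dead"
        else:
            kind = "cc3_live"
        _draw_ellipsoid(ch["hoechst"], c, 2, 6, iv["nucleus"])
        if kind in ("live", "cc3_live"):
            _draw_ellipsoid(ch["calcein"], c, 2, 10, iv["calcein"])
        if kind == "dead":
            _draw_ellipsoid(ch["eh"], c, 2, 6, iv["eh"])
        if kind == "cc3_live":
            # offset into the cytoplasm so the blob survives nucleus exclusion
            _draw_ellipsoid(ch["cc3"], (c[0], c[1] + 6, c[2]), 2, 6, iv["cc3"])
        objects.append({"class": kind, "y": c[1], "x": c[2]})
    _add_noise(ch, spec, rng)
    gt = GroundTruth(
        counts={
            "live_count": n_live + n_cc3,
            "eh_count": n_dead,
            "cc3_count": n_cc3,
            "cc3_live_count": n_cc3,
            "nuclei_count": n_total,
        },
        objects=objects,
    )
    return ChannelStack(ch), gt


def generate_chip_stack(spec: FixtureSpec, assay: str) -> tuple[ChannelStack, GroundTruth]:
    """Render one bioreactor fixture for `assay` in {'morpho','mito','viability'}."""
    rng = np.random.default_rng(spec.seed)
    if assay == "morpho":
        return _generate_morpho(spec, rng)
    if assay == "mito":
        return _generate_mito(spec, rng)
    if assay == "viability":
        return _generate_viability(spec, rng)
    raise ValueError(f"unknown assay {assay!r}")


def chip_params_for(spec: FixtureSpec, assay: str) -> ChipParams:
    """Device-refinement parameters matched to the fixture's scale.

    The published component-size thresholds (1000 / 100 000 px) assume
    full-width mosaics; for desk-scale fixtures they are rescaled to the
    fixture's wall footprint (structuring-element sizes stay at the
    published values, tall rods clipping to the image as designed).
    """
    g = spec.geometry
    wall_px = g.wall_w * g.ny
    min_rough = max(50, wall_px // 8)
    min_final = max(200, wall_px // 2)
    if assay == "morpho":
        thr = {role: 500.0 for role in ("hoechst", "tuj1", "th", "stain4")}
        return ChipParams.morphometric(thr).scaled(min_rough, min_final)
    if assay == "mito":
        return ChipParams.mitochondrial().scaled(min_rough, min_final)
    if assay == "viability":
        return ChipParams.cell_death().scaled(min_rough, min_final)
    raise ValueError(f"unknown assay {assay!r}")


# ---------------------------------------------------------------------------
# synthetic feature tables

def generate_feature_dataset(
    n_per_group: int = 12,
    n_features: int = 12,
    effect_sizes=None,
    rescue: float = 0.5,
    block_size: int = 1,
    rho: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Feature table with planted genotype deficits and treatment rescue.

    Four groups of `n_per_group` bioreactors: WT/vehicle, G2019S/vehicle,
    WT/Inh2, G2019S/Inh2.  Features are unit-variance Gaussians with
    correlation `rho` inside consecutive blocks of `block_size` columns.
    The mutant mean is shifted by ``-effect_sizes[j]`` SD; treatment moves
    the mutant mean back toward wild type by fraction `rescue`.  Returns the
    table plus a truth dict (effects, rescue, correlation structure).
    """
    rng = np.random.default_rng(seed)
    if effect_sizes is None:
        effect_sizes = np.zeros(n_features)
    effect_sizes = np.asarray(effect_sizes, dtype=float)
    if effect_sizes.size != n_features:
        raise ValueError("effect_sizes length must match n_features")
    if not -0.999 < rho < 0.999:
        raise ValueError("rho must keep the block correlation matrix PSD")

    cov = np.eye(n_features)
    for b0 in range(0, n_features, block_size):
        b1 = min(b0 + block_size, n_features)
        cov[b0:b1, b0:b1] = rho
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)

    rows = []
    groups = [("WT", "vehicle"), ("G2019S", "vehicle"), ("WT", "Inh2"), ("G2019S", "Inh2")]
    idx = 0
    for genotype, treatment in groups:
        shift = np.zeros(n_features)
        if genotype == "G2019S":
            shift = -effect_sizes * (1.0 - (rescue if treatment == "Inh2" else 0.0))
        X = rng.standard_normal((n_per_group, n_features)) @ chol.T + shift
        for i in range(n_per_group):
            row = {
                "bioreactor_id": f"br{idx:04d}",
                "assay": "synthetic",
                "line": f"{genotype}-{1 + i % 3}",
                "genotype": genotype,
                "background": "H",
                "treatment": treatment,
                "timepoint": "wk2",
            }
            row.update({f"f{j:03d}": X[i, j] for j in range(n_features)})
            rows.append(row)
            idx += 1
    table = pd.DataFrame(rows)
    truth = {
        "effect_sizes": effect_sizes,
        "rescue": rescue,
        "block_size": block_size,
        "rho": rho,
        "groups": groups,
        "feature_columns": [f"f{j:03d}" for j in range(n_features)],
    }
    return table, truth
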
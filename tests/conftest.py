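"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's accelerated paths: naive
per-voxel loops build surfel sets, and full pairwise distance matrices
stand in for tree queries, so tests compare two genuinely different routes
to the same definition.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from contourdose import ImageGrid, StructureMask
from contourdose.synthetic import OrganTemplate, SimConfig


def make_mask(
    occupancy: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    name: str = "test",
) -> StructureMask:
    occ = np.asarray(occupancy, dtype=bool)
    grid = ImageGrid(dims=occ.shape, spacing=spacing, origin=origin)
    return StructureMask(name=name, grid=grid, occupancy=occ)


def cube_mask(dims, lo, size, spacing=(1.0, 1.0, 1.0), name="cube") -> StructureMask:
    occ = np.zeros(dims, dtype=bool)
    sl = tuple(slice(l, l + s) for l, s in zip(lo, size))
    occ[sl] = True
    return make_mask(occ, spacing=spacing, name=name)


# ---------------------------------------------------------------------------
# brute-force surfel oracle (naive loops, no spatial acceleration)


def naive_surfels(mask: StructureMask) -> tuple[np.ndarray, np.ndarray]:
    """(points, weights): exposed-face centers by explicit 6-neighbour loops."""
    occ = mask.occupancy
    sp = np.asarray(mask.grid.spacing)
    org = np.asarray(mask.grid.origin)
    dims = occ.shape
    pts, wts = [], []
    for i, j, k in itertools.product(*[range(d) for d in dims]):
        if not occ[i, j, k]:
            continue
        for axis, sign in ((0, -1), (0, 1), (1, -1), (1, 1), (2, -1), (2, 1)):
            nb = [i, j, k]
            nb[axis] += sign
            outside = nb[axis] < 0 or nb[axis] >= dims[axis]
            if outside or not occ[tuple(nb)]:
                c = org + np.array([i, j, k]) * sp
                c[axis] += sign * sp[axis] / 2.0
                pts.append(c)
                area = sp[(axis + 1) % 3] * sp[(axis + 2) % 3]
                wts.append(area)
    if not pts:
        return np.empty((0, 3)), np.empty(0)
    return np.asarray(pts, dtype=float), np.asarray(wts, dtype=float)


def _pairwise(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.sqrt(((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=-1))


def brute_surface_dice(a: StructureMask, b: StructureMask, tol: float) -> float:
    pa, wa = naive_surfels(a)
    pb, wb = naive_surfels(b)
    d = _pairwise(pa, pb)
    hit = wa[d.min(axis=1) <= tol].sum() + wb[d.min(axis=0) <= tol].sum()
    return float(hit / (wa.sum() + wb.sum()))


def brute_hausdorff(a: StructureMask, b: StructureMask) -> float:
    pa, _ = naive_surfels(a)
    pb, _ = naive_surfels(b)
    d = _pairwise(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def brute_min_surface_distance(a: StructureMask, b: StructureMask) -> float:
    """Oracle for OAR-to-PTV distance (0 on voxel overlap)."""
    if np.any(a.occupancy & b.occupancy):
        return 0.0
    pa, _ = naive_surfels(a)
    pb, _ = naive_surfels(b)
    return float(_pairwise(pa, pb).min())


def random_blob_mask(
    rng: np.random.Generator,
    dims=(12, 12, 12),
    spacing=(1.0, 1.0, 1.0),
    name="blob",
) -> StructureMask:
    """Union of 1-3 random boxes; guaranteed non-empty."""
    occ = np.zeros(dims, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        lo = [int(rng.integers(0, d - 2)) for d in dims]
        size = [int(rng.integers(1, d - l)) for d, l in zip(dims, lo)]
        size = [min(s, 6) for s in size]
        occ[tuple(slice(l, l + s) for l, s in zip(lo, size))] = True
    return make_mask(occ, spacing=spacing, name=name)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank enumeration oracle


def brute_wilcoxon_p(deltas) -> float:
    """Two-sided p by enumerating all 2^n sign assignments (Pratt zeros)."""
    from scipy.stats import rankdata

    d = np.asarray(deltas, dtype=float)
    ranks_all = rankdata(np.abs(d), method="average")
    nz = d != 0
    ranks = ranks_all[nz]
    w_obs = ranks[d[nz] > 0].sum()
    ws = np.array(
        [
            ranks[np.array(s) > 0].sum()
            for s in itertools.product([-1, 1], repeat=len(ranks))
        ]
    )
    p_le = (ws <= w_obs + 1e-12).mean()
    p_ge = (ws >= w_obs - 1e-12).mean()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# small synthetic worlds


def tiny_sim_config(**overrides) -> SimConfig:
    """A down-scaled phantom world for fast cohort-level tests.

    40x40x30 voxels at 2 mm (78x78x58 mm), a 10 mm PTV, and four organs
    covering the three distance classes.
    """
    defaults = dict(
        dims=(40, 40, 30),
        spacing_mm=(2.0, 2.0, 2.0),
        ptv_center_mm=(40.0, 26.0, 28.0),
        ptv_radius_mm=10.0,
        organ_templates=(
            OrganTemplate("Brain", "ellipsoid", (40.0, 44.0, 28.0), (12.0, 9.0, 9.0), "abut"),
            OrganTemplate("Brainstem", "ellipsoid", (16.0, 26.0, 28.0), (6.0, 6.0, 8.0), "near"),
            OrganTemplate("Parotid_L", "ellipsoid", (62.0, 26.0, 28.0), (7.0, 6.0, 7.0), "near"),
            OrganTemplate("Eye_R", "ellipsoid", (40.0, 68.0, 28.0), (6.0, 6.0, 5.0), "far"),
        ),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240715)
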
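"""Distance from an organ-at-risk to the closest planning target volume.

The distance is the minimum Euclidean surface-to-surface distance in mm
between the OAR's surfel set and each PTV's surfel set, clamped to zero
when the two structures share any voxel.  Records are classified against a
proximity cutoff (default 25 mm = 2.5 cm), inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import EmptyMaskError, extract_surface
from .grid_io import GridMismatchError, StructureMask


@dataclass(frozen=True)
class ProximityResult:
    distance_mm: float
    nearest_ptv: str
    within_cutoff: bool


def distance_to_ptv(
    oar: StructureMask,
    ptvs: Sequence[StructureMask],
    cutoff_mm: float = 25.0,
) -> ProximityResult:
    """Minimum surface distance from an OAR to any PTV (0 on overlap)."""
    if not ptvs:
        raise ValueError("at least one PTV mask is required")
    if oar.is_empty:
        raise EmptyMaskError(f"OAR {oar.name!r} is empty; distance undefined")
    for ptv in ptvs:
        if not oar.grid.same_lattice(ptv.grid):
            raise GridMismatchError(
                f"OAR {oar.name!r} and PTV {ptv.name!r} are on different grids"
            )

    # voxel-wise overlap clamps to zero before any surface computation
    for ptv in ptvs:
        if not ptv.is_empty and np.any(oar.occupancy & ptv.occupancy):
            return ProximityResult(
                distance_mm=0.0, nearest_ptv=ptv.name, within_cutoff=True
            )

    oar_surf = extract_surface(oar)
    best_d = np.inf
    best_name = ""
    for ptv in ptvs:
        if ptv.is_empty:
            continue
        tree = cKDTree(extract_surface(ptv).points)
        d = float(tree.query(oar_surf.points, k=1)[0].min())
        if d < best_d:
            best_d = d
            best_name = ptv.name
    if not np.isfinite(best_d):
        raise EmptyMaskError("all PTV masks are empty; distance undefined")
    return ProximityResult(
        distance_mm=best_d,
        nearest_ptv=best_name,
        within_cutoff=bool(best_d <= cutoff_mm),
    )


def classify_proximity(records: Sequence, cutoff_mm: float = 25.0) -> None:
    """Re-annotate records' within_cutoff flag at a (possibly new) cutoff.

    The cutoff is inclusive: distance == cutoff counts as within. In-place.
    """
    for rec in records:
        if rec.distance_to_ptv_mm is not None:
            rec.within_cutoff = bool(rec.distance_to_ptv_mm <= cutoff_mm)
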
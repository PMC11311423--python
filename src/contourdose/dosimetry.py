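"""Dose statistics over contours and the clinical-objective difference.

One clinical dose grid is transposed over both members of a contour pair;
the pair's dosimetric disagreement is then the difference in D0.01cc
("Dmax": the maximum dose received by at least 0.01 cc of the structure)
and in the volume-weighted mean dose.  Each organ has a clinical-objective
kind (max or mean) fixed by planning practice: mean for larynx,
submandibular glands and parotids, max for everything else; the flagging
rule downstream acts on the absolute difference in that organ's objective
(delta D_CO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .geometry import GeometricAgreement
from .grid_io import OAR_NAMES, DoseGrid, GridMismatchError, StructureMask

log = logging.getLogger(__name__)

DcoKind = Literal["max", "mean"]

#: Organs whose clinical objective is a mean-dose constraint.
MEAN_DCO_ORGANS = frozenset(
    {"Larynx", "Glnd_Submand_L", "Glnd_Submand_R", "Parotid_L", "Parotid_R"}
)


@dataclass(frozen=True)
class OrganPolicy:
    """Mapping organ name -> clinical-objective kind ('max' | 'mean')."""

    mapping: dict[str, DcoKind]

    def kind_for(self, organ: str) -> DcoKind:
        try:
            return self.mapping[organ]
        except KeyError:
            raise KeyError(f"no clinical-objective kind defined for {organ!r}")


DEFAULT_POLICY = OrganPolicy(
    mapping={
        name: ("mean" if name in MEAN_DCO_ORGANS else "max") for name in OAR_NAMES
    }
)


@dataclass(frozen=True)
class DoseStats:
    dmax_cgy: float  # D0.01cc
    dmean_cgy: float
    volume_cc: float


@dataclass
class OARRecord:
    """One contour pair's full result row."""

    patient_id: str
    organ: str
    geometry: Optional[GeometricAgreement]
    auto_stats: Optional[DoseStats]
    clinical_stats: Optional[DoseStats]
    delta_dmax_cgy: Optional[float]
    delta_dmean_cgy: Optional[float]
    dco_kind: DcoKind
    delta_dco_cgy: Optional[float]
    prescription_cgy: float
    distance_to_ptv_mm: Optional[float] = None
    nearest_ptv: Optional[str] = None
    within_cutoff: Optional[bool] = None
    flagged: bool = False
    identical_pair: bool = False
    unevaluable_reason: Optional[str] = None

    @property
    def evaluable(self) -> bool:
        return self.unevaluable_reason is None

    @property
    def abs_delta_dmax_cgy(self) -> Optional[float]:
        return None if self.delta_dmax_cgy is None else abs(self.delta_dmax_cgy)

    @property
    def abs_delta_dmean_cgy(self) -> Optional[float]:
        return None if self.delta_dmean_cgy is None else abs(self.delta_dmean_cgy)

    def to_row(self) -> dict:
        g = self.geometry
        a = self.auto_stats
        c = self.clinical_stats
        return {
            "patient_id": self.patient_id,
            "organ": self.organ,
            "dsc": None if g is None else g.dsc,
            "sdsc": None if g is None else g.sdsc,
            "hd_mm": None if g is None else g.hd_mm,
            "tolerance_mm": None if g is None else g.tolerance_mm,
            "auto_dmax_cgy": None if a is None else a.dmax_cgy,
            "auto_dmean_cgy": None if a is None else a.dmean_cgy,
            "auto_volume_cc": None if a is None else a.volume_cc,
            "clinical_dmax_cgy": None if c is None else c.dmax_cgy,
            "clinical_dmean_cgy": None if c is None else c.dmean_cgy,
            "clinical_volume_cc": None if c is None else c.volume_cc,
            "delta_dmax_cgy": self.delta_dmax_cgy,
            "delta_dmean_cgy": self.delta_dmean_cgy,
            "abs_delta_dmax_cgy": self.abs_delta_dmax_cgy,
            "abs_delta_dmean_cgy": self.abs_delta_dmean_cgy,
            "dco_kind": self.dco_kind,
            "delta_dco_cgy": self.delta_dco_cgy,
            "distance_to_ptv_mm": self.distance_to_ptv_mm,
            "nearest_ptv": self.nearest_ptv,
            "within_cutoff": self.within_cutoff,
            "prescription_cgy": self.prescription_cgy,
            "identical_pair": self.identical_pair,
            "flagged": self.flagged,
        }


def _require_same_grid(dose: DoseGrid, mask: StructureMask) -> None:
    if not dose.grid.same_lattice(mask.grid):
        raise GridMismatchError(
            f"dose grid and mask {mask.name!r} are on different lattices; "
            f"resample the dose first"
        )


def dmax_d001cc(
    dose: DoseGrid, mask: StructureMask, volume_cc: float = 0.01
) -> float:
    """D(volume_cc): minimum dose within the hottest >= `volume_cc` of a mask.

    Whole-voxel accumulation: in-structure voxel doses are sorted descending
    (ties broken by ascending linear voxel index) and voxel volumes
    accumulated until the running total first reaches `volume_cc`; the dose
    of the last voxel included is returned.  Structures smaller than
    `volume_cc` fall back to their minimum in-structure dose (logged), so
    sub-0.01 cc structures such as lenses still evaluate.
    """
    _require_same_grid(dose, mask)
    if mask.is_empty:
        raise ValueError(f"mask {mask.name!r} is empty; D0.01cc undefined")
    vals = dose.dose[mask.occupancy]
    # stable sort on negated dose == descending dose, ascending linear index
    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    vox = mask.grid.voxel_volume_cc
    n_needed = int(np.ceil(volume_cc / vox - 1e-12))
    if n_needed > len(vals):
        log.warning(
            "structure %s volume %.4f cc < %.4f cc; D falls back to in-structure "
            "minimum dose",
            mask.name,
            mask.volume_cc,
            volume_cc,
        )
        return float(vals[-1])
    n_needed = max(n_needed, 1)
    return float(vals[n_needed - 1])


def dmean(dose: DoseGrid, mask: StructureMask) -> float:
    """Volume-weighted mean dose; equal-volume voxels give the plain mean."""
    _require_same_grid(dose, mask)
    if mask.is_empty:
        raise ValueError(f"mask {mask.name!r} is empty; Dmean undefined")
    return float(dose.dose[mask.occupancy].mean())


def dose_stats(
    dose: DoseGrid, mask: StructureMask, dmax_volume_cc: float = 0.01
) -> DoseStats:
    return DoseStats(
        dmax_cgy=dmax_d001cc(dose, mask, dmax_volume_cc),
        dmean_cgy=dmean(dose, mask),
        volume_cc=mask.volume_cc,
    )


def evaluate_pair(
    dose: DoseGrid,
    auto: StructureMask,
    clinical: StructureMask,
    patient_id: str,
    prescription_cgy: float,
    policy: OrganPolicy = DEFAULT_POLICY,
    geometry: Optional[GeometricAgreement] = None,
    dmax_volume_cc: float = 0.01,
) -> OARRecord:
    """Dose statistics for both contours of a pair from one dose grid.

    Signed deltas are auto - clinical; delta D_CO is the absolute delta of
    the organ's objective kind.  A pair with an empty mask is returned as an
    unevaluable record (kept for the audit trail, excluded from summaries).
    """
    organ = auto.name or clinical.name
    kind = policy.kind_for(organ)
    base = dict(
        patient_id=patient_id,
        organ=organ,
        geometry=geometry,
        dco_kind=kind,
        prescription_cgy=prescription_cgy,
    )
    if auto.is_empty or clinical.is_empty:
        which = "auto" if auto.is_empty else "clinical"
        return OARRecord(
            auto_stats=None,
            clinical_stats=None,
            delta_dmax_cgy=None,
            delta_dmean_cgy=None,
            delta_dco_cgy=None,
            unevaluable_reason=f"{which} mask empty",
            identical_pair=bool(geometry and geometry.identical),
            **base,
        )
    a = dose_stats(dose, auto, dmax_volume_cc)
    c = dose_stats(dose, clinical, dmax_volume_cc)
    d_dmax = a.dmax_cgy - c.dmax_cgy
    d_dmean = a.dmean_cgy - c.dmean_cgy
    identical = bool(geometry and geometry.identical)
    if identical:
        # bit-identical contours cannot disagree dosimetrically
        d_dmax = 0.0
        d_dmean = 0.0
    delta_dco = abs(d_dmax) if kind == "max" else abs(d_dmean)
    return OARRecord(
        auto_stats=a,
        clinical_stats=c,
        delta_dmax_cgy=d_dmax,
        delta_dmean_cgy=d_dmean,
        delta_dco_cgy=delta_dco,
        identical_pair=identical,
        **base,
    )
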
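"""Voxel-grid data model and NIfTI / manifest / table I/O.

All spatial quantities are world millimetres on an axis-aligned lattice:
the world position of voxel index ``(i, j, k)`` is ``origin + index * spacing``
and refers to the voxel *center*.  Dose is carried in cGy throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

#: Controlled vocabulary of the 19 head-and-neck organs-at-risk.
OAR_NAMES = (
    "Brain",
    "Brainstem",
    "Cochlea_L",
    "Cochlea_R",
    "Esophagus",
    "Eye_L",
    "Eye_R",
    "Glnd_Submand_L",
    "Glnd_Submand_R",
    "Larynx",
    "Lens_L",
    "Lens_R",
    "OpticChiasm",
    "OpticNrv_L",
    "OpticNrv_R",
    "Parotid_L",
    "Parotid_R",
    "SpinalCord",
    "VertebralColumn",
)


class GridMismatchError(ValueError):
    """Two volumes expected on one lattice are on different lattices."""


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned voxel lattice: dims (voxels), spacing (mm), origin (mm)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("dims, spacing and origin must be length-3")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World-mm coordinates (voxel centers) of an (n, 3) index array."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world-mm corners of the voxel-center bounding box."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.dims) - 1) * np.asarray(self.spacing)
        return lo, hi

    def same_lattice(self, other: "ImageGrid", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class StructureMask:
    """Named binary occupancy volume on a grid."""

    name: str
    grid: ImageGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != tuple(self.grid.dims):
            raise ValueError(
                f"occupancy shape {occ.shape} != grid dims {self.grid.dims}"
            )
        self.occupancy = occ.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()


@dataclass
class DoseGrid:
    """Per-voxel absorbed dose in cGy on a grid."""

    grid: ImageGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        if dose.shape != tuple(self.grid.dims):
            raise ValueError(f"dose shape {dose.shape} != grid dims {self.grid.dims}")
        if not np.isfinite(dose).all():
            raise ValueError("dose values must be finite")
        if (dose < 0).any():
            raise ValueError("dose values must be >= 0")
        self.dose = dose


@dataclass
class OARPairEntry:
    organ: str
    auto_path: str
    clinical_path: str


@dataclass
class PatientEntry:
    patient_id: str
    prescription_cgy: float
    dose_path: str
    ptv_paths: dict[str, str]
    oar_pairs: list[OARPairEntry] = field(default_factory=list)


@dataclass
class CohortManifest:
    """Cohort index: per patient, dose grid, PTVs and auto/clinical OAR pairs."""

    patients: list[PatientEntry]

    def __post_init__(self) -> None:
        for pt in self.patients:
            if not pt.ptv_paths:
                raise ValueError(f"patient {pt.patient_id}: no PTV masks listed")
            for pair in pt.oar_pairs:
                if pair.organ not in OAR_NAMES:
                    raise ValueError(
                        f"patient {pt.patient_id}: organ {pair.organ!r} is not in "
                        f"the 19-OAR vocabulary"
                    )
                if not pair.auto_path or not pair.clinical_path:
                    raise ValueError(
                        f"patient {pt.patient_id}/{pair.organ}: both auto and "
                        f"clinical mask paths are required"
                    )


def _check_axis_aligned(affine: np.ndarray, path: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (spacing, origin); reject rotated or flipped affines."""
    lin = affine[:3, :3]
    off = lin - np.diag(np.diag(lin))
    if np.abs(off).max() > 1e-6 * max(1.0, np.abs(lin).max()):
        raise ValueError(
            f"{path}: affine encodes rotation/shear; only axis-aligned volumes "
            f"are supported"
        )
    diag = np.diag(lin)
    if (diag <= 0).any():
        raise ValueError(
            f"{path}: affine has non-positive diagonal (axis flip); only "
            f"positively oriented axis-aligned volumes are supported"
        )
    return diag, affine[:3, 3]


def _grid_from_nifti(img: nib.Nifti1Image, path: str) -> ImageGrid:
    spacing, origin = _check_axis_aligned(img.affine, path)
    return ImageGrid(
        dims=tuple(int(d) for d in img.shape[:3]),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in origin),
    )


def read_mask(path: str | Path, name: str | None = None) -> StructureMask:
    """Read a binary structure mask from NIfTI (occupancy = value > 0.5)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_nifti(img, str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if name is None:
        name = path.name.split(".")[0]
    return StructureMask(name=name, grid=grid, occupancy=data > 0.5)


def write_mask(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_dose(path: str | Path) -> DoseGrid:
    """Read a dose grid (cGy) from NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_nifti(img, str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return DoseGrid(grid=grid, dose=data)


def write_dose(dose: DoseGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(dose.dose.astype(np.float32), dose.grid.affine)
    nib.save(img, str(path))


def interpolate_dose_to_grid(dose: DoseGrid, target: ImageGrid) -> DoseGrid:
    """Trilinearly resample a dose grid onto a target lattice.

    Target voxels whose centers fall outside the source voxel-center extent
    receive 0 cGy; the out-of-extent count is logged.  Disjoint extents error.
    """
    if dose.grid.same_lattice(target):
        return DoseGrid(grid=target, dose=dose.dose.copy())

    src_lo, src_hi = dose.grid.extent_mm()
    tgt_lo, tgt_hi = target.extent_mm()
    if (tgt_hi < src_lo).any() or (tgt_lo > src_hi).any():
        raise ValueError("dose grid and target grid extents are disjoint")

    ii, jj, kk = np.meshgrid(
        *[np.arange(d, dtype=float) for d in target.dims], indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=0)
    world = np.asarray(target.origin).reshape(3, 1, 1, 1) + idx * np.asarray(
        target.spacing
    ).reshape(3, 1, 1, 1)
    src_idx = (world - np.asarray(dose.grid.origin).reshape(3, 1, 1, 1)) / np.asarray(
        dose.grid.spacing
    ).reshape(3, 1, 1, 1)

    out = ndimage.map_coordinates(
        dose.dose, src_idx, order=1, mode="constant", cval=0.0
    )
    dims_arr = np.asarray(dose.grid.dims).reshape(3, 1, 1, 1)
    outside = ((src_idx < 0) | (src_idx > dims_arr - 1)).any(axis=0)
    n_out = int(outside.sum())
    if n_out:
        log.warning(
            "dose resampling: %d / %d target voxels outside source extent set to 0",
            n_out,
            int(np.prod(target.dims)),
        )
    # order=1 with constant padding can produce tiny negatives from rounding
    return DoseGrid(grid=target, dose=np.clip(out, 0.0, None))


# ---------------------------------------------------------------------------
# manifest I/O


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    base = path.parent
    patients = []
    for p in raw["patients"]:
        pairs = [
            OARPairEntry(
                organ=o["organ"],
                auto_path=str(base / o["auto"]),
                clinical_path=str(base / o["clinical"]),
            )
            for o in p["oars"]
        ]
        patients.append(
            PatientEntry(
                patient_id=str(p["patient_id"]),
                prescription_cgy=float(p["prescription_cgy"]),
                dose_path=str(base / p["dose"]),
                ptv_paths={k: str(base / v) for k, v in p["ptvs"].items()},
                oar_pairs=pairs,
            )
        )
    return CohortManifest(patients=patients)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest with paths relative to the manifest's directory."""
    path = Path(path)
    base = path.parent

    def rel(p: str) -> str:
        try:
            return str(Path(p).relative_to(base))
        except ValueError:
            return str(p)

    payload = {
        "patients": [
            {
                "patient_id": pt.patient_id,
                "prescription_cgy": pt.prescription_cgy,
                "dose": rel(pt.dose_path),
                "ptvs": {k: rel(v) for k, v in pt.ptv_paths.items()},
                "oars": [
                    {
                        "organ": pr.organ,
                        "auto": rel(pr.auto_path),
                        "clinical": rel(pr.clinical_path),
                    }
                    for pr in pt.oar_pairs
                ],
            }
            for pt in manifest.patients
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# record table I/O

RECORD_COLUMNS = [
    "patient_id",
    "organ",
    "dsc",
    "sdsc",
    "hd_mm",
    "tolerance_mm",
    "auto_dmax_cgy",
    "auto_dmean_cgy",
    "auto_volume_cc",
    "clinical_dmax_cgy",
    "clinical_dmean_cgy",
    "clinical_volume_cc",
    "delta_dmax_cgy",
    "delta_dmean_cgy",
    "abs_delta_dmax_cgy",
    "abs_delta_dmean_cgy",
    "dco_kind",
    "delta_dco_cgy",
    "distance_to_ptv_mm",
    "nearest_ptv",
    "within_cutoff",
    "prescription_cgy",
    "identical_pair",
    "flagged",
]


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert OARRecord objects to a DataFrame with the canonical columns."""
    rows = [r.to_row() for r in records]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Sequence, path: str | Path) -> None:
    """Write one CSV row per contour pair (full float precision round trip)."""
    if not records:
        raise ValueError("no records to write")
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
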
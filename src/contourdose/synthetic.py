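"""Synthetic phantom cohorts for end-to-end pipeline testing.

No patient data ship with this package, so every pipeline stage is
exercised on generated phantoms: ellipsoidal and tubular "organs" placed at
controlled distances from a spherical PTV, a prescription-plateau dose
field with exponential fall-off away from the PTV surface, and seeded
auto-vs-clinical contour perturbations with ground-truth labels.

The default stated world: a 2 mm isotropic 100x100x70 lattice
(200x200x140 mm), a 25 mm-radius PTV prescribed 6996 cGy, fall-off length
5 mm with a 30 cGy scatter floor, and eight template organs spanning three
distance classes — abutting/overlapping the PTV, within 25 mm, and beyond
50 mm.  57 % of contour pairs are bit-identical (auto-contour used as-is);
the rest receive morphological dilation/erosion, whole-voxel translation,
axial truncation, or interior slice deletion — the editing patterns
clinical planners actually produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_io import (
    CohortManifest,
    DoseGrid,
    ImageGrid,
    OARPairEntry,
    PatientEntry,
    StructureMask,
    write_dose,
    write_manifest,
    write_mask,
)

log = logging.getLogger(__name__)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class PerturbationEmptiesMask(ValueError):
    """The requested perturbation would leave the mask with no voxels."""


@dataclass(frozen=True)
class OrganTemplate:
    """One phantom organ: shape, placement and intended distance class."""

    name: str
    shape: str  # "ellipsoid" | "tube"
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]  # tube: (r, r, half-length)
    distance_class: str  # "abut" | "near" | "far"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    dims: tuple[int, int, int] = (100, 100, 70)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_patients: int = 30
    prescription_cgy: float = 6996.0
    ptv_center_mm: tuple[float, float, float] = (100.0, 80.0, 70.0)
    ptv_radius_mm: float = 25.0
    falloff_lambda_mm: float = 5.0
    floor_cgy: float = 30.0
    noise_sd_cgy: float = 0.0
    identity_probability: float = 0.57
    #: non-identity perturbation mix: (kind, magnitude, probability)
    perturbation_mix: tuple[tuple[str, float, float], ...] = (
        ("dilate", 1, 0.08),
        ("dilate", 2, 0.06),
        ("erode", 1, 0.08),
        ("erode", 2, 0.06),
        ("translate", 4.0, 0.05),
        ("translate", 8.0, 0.04),
        ("truncate", 0.4, 0.03),
        ("delete_slices", 2, 0.03),
    )
    organ_templates: tuple[OrganTemplate, ...] = (
        # abutting / overlapping the PTV
        OrganTemplate("Brain", "ellipsoid", (100.0, 122.0, 70.0), (30.0, 22.0, 20.0), "abut"),
        OrganTemplate("Parotid_L", "ellipsoid", (140.0, 80.0, 70.0), (16.0, 12.0, 14.0), "abut"),
        # within 25 mm of the PTV surface
        OrganTemplate("Brainstem", "ellipsoid", (100.0, 37.0, 70.0), (8.0, 8.0, 16.0), "near"),
        OrganTemplate("Cochlea_L", "ellipsoid", (132.8, 104.6, 70.0), (6.0, 6.0, 5.0), "near"),
        OrganTemplate("Larynx", "tube", (58.0, 80.0, 70.0), (8.0, 8.0, 40.0), "near"),
        # beyond 50 mm of the PTV surface
        OrganTemplate("Eye_R", "ellipsoid", (188.0, 80.0, 70.0), (6.0, 6.0, 6.0), "far"),
        OrganTemplate("Glnd_Submand_R", "ellipsoid", (12.0, 80.0, 70.0), (9.0, 7.0, 10.0), "far"),
        OrganTemplate("SpinalCord", "tube", (100.0, 168.0, 70.0), (6.0, 6.0, 56.0), "far"),
    )

    def __post_init__(self) -> None:
        if self.falloff_lambda_mm <= 0:
            raise ValueError("falloff_lambda_mm must be > 0")
        p_total = self.identity_probability + sum(
            p for _, _, p in self.perturbation_mix
        )
        if abs(p_total - 1.0) > 1e-9:
            raise ValueError(f"perturbation probabilities sum to {p_total}, not 1")
        grid = self.grid
        lo, hi = grid.extent_mm()
        for t in self.organ_templates:
            c = np.asarray(t.center_mm)
            r = np.asarray(t.radii_mm)
            if ((c - r) < lo - 1e-9).any() or ((c + r) > hi + 1e-9).any():
                raise ValueError(f"organ {t.name} does not fit inside the grid")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(dims=self.dims, spacing=self.spacing_mm)


@dataclass
class SimOrgan:
    clinical: StructureMask
    auto: StructureMask
    perturbation: str  # e.g. "identity", "dilate:2", "translate:8.0"
    magnitude: float
    distance_class: str


@dataclass
class SimCase:
    patient_id: str
    prescription_cgy: float
    dose: DoseGrid
    ptvs: list[StructureMask]
    organs: dict[str, SimOrgan] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry primitives


def _ellipsoid_mask(grid: ImageGrid, center_mm, radii_mm, name: str) -> StructureMask:
    coords = [
        np.arange(d) * s + o
        for d, s, o in zip(grid.dims, grid.spacing, grid.origin)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    occ = (
        ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2
    ) <= 1.0
    return StructureMask(name=name, grid=grid, occupancy=occ)


def _tube_mask(grid: ImageGrid, center_mm, radii_mm, name: str) -> StructureMask:
    """Axial (z-aligned) cylinder: radii_mm = (rx, ry, half_length_z)."""
    coords = [
        np.arange(d) * s + o
        for d, s, o in zip(grid.dims, grid.spacing, grid.origin)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    rx, ry, hz = radii_mm
    occ = (((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0) & (
        np.abs(zz - cz) <= hz
    )
    return StructureMask(name=name, grid=grid, occupancy=occ)


def make_structure(grid: ImageGrid, template: OrganTemplate) -> StructureMask:
    if template.shape == "ellipsoid":
        return _ellipsoid_mask(grid, template.center_mm, template.radii_mm, template.name)
    if template.shape == "tube":
        return _tube_mask(grid, template.center_mm, template.radii_mm, template.name)
    raise ValueError(f"unknown organ shape {template.shape!r}")


def make_ptv(config: SimConfig, name: str = "PTV_70") -> StructureMask:
    r = config.ptv_radius_mm
    return _ellipsoid_mask(config.grid, config.ptv_center_mm, (r, r, r), name)


# ---------------------------------------------------------------------------
# dose field


def make_dose_field(
    grid: ImageGrid,
    ptv: StructureMask,
    prescription_cgy: float,
    lambda_mm: float,
    floor_cgy: float = 0.0,
    noise_sd_cgy: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> DoseGrid:
    """Prescription plateau inside the PTV, exponential fall-off outside.

    dose(x) = Rx inside the PTV and Rx * exp(-d(x)/lambda) outside, with
    d(x) the Euclidean distance (mm, anisotropy-aware) to the nearest PTV
    voxel, clamped below at floor_cgy.  Optional Gaussian noise (truncated
    at zero) emulates calculation grid jitter; the default is noise-free.
    """
    if ptv.is_empty:
        raise ValueError("PTV mask is empty")
    if lambda_mm <= 0:
        raise ValueError("lambda_mm must be > 0")
    d_mm = ndimage.distance_transform_edt(
        ~ptv.occupancy, sampling=grid.spacing
    )
    dose = prescription_cgy * np.exp(-d_mm / lambda_mm)
    dose[ptv.occupancy] = prescription_cgy
    dose = np.maximum(dose, floor_cgy)
    if noise_sd_cgy > 0:
        if rng is None:
            raise ValueError("noise requested but no RNG supplied")
        dose = np.clip(dose + rng.normal(0.0, noise_sd_cgy, dose.shape), 0.0, None)
    return DoseGrid(grid=grid, dose=dose)


# ---------------------------------------------------------------------------
# contour perturbations


def perturb(
    mask: StructureMask,
    kind: str,
    magnitude: float,
    rng: Optional[np.random.Generator] = None,
) -> StructureMask:
    """Apply one contour-editing perturbation; never returns an empty mask.

    Kinds: identity; dilate/erode by `magnitude` iterations of
    face-connected morphology; translate by the whole-voxel shift nearest
    to `magnitude` mm along x; truncate clearing the top `magnitude`
    fraction of occupied axial slices; delete_slices clearing `magnitude`
    randomly chosen interior occupied slices (seeded RNG required).
    """
    occ = mask.occupancy
    if kind == "identity":
        out = occ.copy()
    elif kind == "dilate":
        out = ndimage.binary_dilation(
            occ, structure=_FACE_STRUCT, iterations=int(magnitude)
        )
    elif kind == "erode":
        out = ndimage.binary_erosion(
            occ, structure=_FACE_STRUCT, iterations=int(magnitude)
        )
    elif kind == "translate":
        shift_vox = int(round(magnitude / mask.grid.spacing[0]))
        out = np.zeros_like(occ)
        if shift_vox == 0:
            out = occ.copy()
        elif shift_vox > 0:
            out[shift_vox:] = occ[: occ.shape[0] - shift_vox]
        else:
            out[:shift_vox] = occ[-shift_vox:]
    elif kind == "truncate":
        zs = np.flatnonzero(occ.any(axis=(0, 1)))
        n_cut = int(round(len(zs) * float(magnitude)))
        out = occ.copy()
        if n_cut > 0:
            out[:, :, zs[len(zs) - n_cut:]] = False
    elif kind == "delete_slices":
        if rng is None:
            raise ValueError("delete_slices requires an RNG")
        zs = np.flatnonzero(occ.any(axis=(0, 1)))
        interior = zs[1:-1] if len(zs) > 2 else zs
        k = min(int(magnitude), max(len(interior) - 1, 0))
        out = occ.copy()
        if k > 0:
            chosen = rng.choice(interior, size=k, replace=False)
            out[:, :, chosen] = False
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    if not out.any():
        raise PerturbationEmptiesMask(
            f"{kind}({magnitude}) empties mask {mask.name!r}"
        )
    return StructureMask(name=mask.name, grid=mask.grid, occupancy=out)


def _draw_perturbation(
    config: SimConfig, rng: np.random.Generator
) -> tuple[str, float]:
    kinds = [("identity", 0.0)] + [(k, m) for k, m, _ in config.perturbation_mix]
    probs = [config.identity_probability] + [p for _, _, p in config.perturbation_mix]
    i = rng.choice(len(kinds), p=np.asarray(probs) / np.sum(probs))
    return kinds[i]


def _apply_with_fallback(
    clinical: StructureMask,
    kind: str,
    magnitude: float,
    rng: np.random.Generator,
) -> tuple[StructureMask, str, float]:
    """Perturb, deterministically downgrading if the mask would empty."""
    attempts = [(kind, magnitude)]
    if kind == "erode" and magnitude > 1:
        attempts.append(("erode", 1))
    attempts.append(("identity", 0.0))
    for k, m in attempts:
        try:
            return perturb(clinical, k, m, rng), k, m
        except PerturbationEmptiesMask:
            continue
    raise AssertionError("identity perturbation cannot empty a mask")


# ---------------------------------------------------------------------------
# cohort generation


def generate_case(config: SimConfig, patient_id: str, rng: np.random.Generator) -> SimCase:
    grid = config.grid
    ptv = make_ptv(config)
    dose = make_dose_field(
        grid,
        ptv,
        config.prescription_cgy,
        config.falloff_lambda_mm,
        config.floor_cgy,
        config.noise_sd_cgy,
        rng if config.noise_sd_cgy > 0 else None,
    )
    case = SimCase(
        patient_id=patient_id,
        prescription_cgy=config.prescription_cgy,
        dose=dose,
        ptvs=[ptv],
    )
    for template in config.organ_templates:
        clinical = make_structure(grid, template)
        kind, mag = _draw_perturbation(config, rng)
        auto, kind, mag = _apply_with_fallback(clinical, kind, mag, rng)
        label = "identity" if kind == "identity" else f"{kind}:{mag:g}"
        case.organs[template.name] = SimOrgan(
            clinical=clinical,
            auto=auto,
            perturbation=label,
            magnitude=mag,
            distance_class=template.distance_class,
        )
    return case


def generate_cohort(config: SimConfig) -> list[SimCase]:
    """Seeded, reproducible in-memory phantom cohort.

    Grid and organ-template geometry are fixed by the config; only the
    perturbation draws consume randomness, so changing the seed changes
    which contours get edited and how, never the anatomy.
    """
    rng = np.random.default_rng(config.seed)
    return [
        generate_case(config, f"SYN{idx:03d}", rng)
        for idx in range(config.n_patients)
    ]


def ground_truth_frame(cases: Sequence[SimCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        for organ, sim in case.organs.items():
            rows.append(
                {
                    "patient_id": case.patient_id,
                    "organ": organ,
                    "perturbation": sim.perturbation,
                    "magnitude": sim.magnitude,
                    "distance_class": sim.distance_class,
                    "identical": sim.perturbation == "identity",
                }
            )
    return pd.DataFrame(rows)


def write_cohort(
    cases: Sequence[SimCase], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a cohort as NIfTI volumes + JSON manifest + ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients = []
    for case in cases:
        pdir = out_dir / case.patient_id
        pdir.mkdir(exist_ok=True)
        dose_path = pdir / "dose.nii.gz"
        write_dose(case.dose, dose_path)
        ptv_paths = {}
        for ptv in case.ptvs:
            p = pdir / f"{ptv.name}.nii.gz"
            write_mask(ptv, p)
            ptv_paths[ptv.name] = str(p)
        pairs = []
        for organ, sim in case.organs.items():
            ap = pdir / f"{organ}_auto.nii.gz"
            cp = pdir / f"{organ}_clinical.nii.gz"
            write_mask(sim.auto, ap)
            write_mask(sim.clinical, cp)
            pairs.append(
                OARPairEntry(organ=organ, auto_path=str(ap), clinical_path=str(cp))
            )
        patients.append(
            PatientEntry(
                patient_id=case.patient_id,
                prescription_cgy=case.prescription_cgy,
                dose_path=str(dose_path),
                ptv_paths=ptv_paths,
                oar_pairs=pairs,
            )
        )
    manifest_path = out_dir / "manifest.json"
    write_manifest(CohortManifest(patients=patients), manifest_path)
    truth_path = out_dir / "ground_truth.csv"
    ground_truth_frame(cases).to_csv(truth_path, index=False)
    return manifest_path, truth_path


# ---------------------------------------------------------------------------
# illustrative scenario fixtures


def make_scenario_cases(config: Optional[SimConfig] = None) -> tuple[SimCase, SimCase]:
    """Two single-organ cases where geometry and dose disagree.

    Fixture A: a large organ abutting the PTV whose auto version carries a
    small protrusion into the steep-gradient shell — near-perfect DSC yet a
    >= 200 cGy Dmax difference (the deceptive high-agreement case).

    Fixture B: a small organ about 20 mm from the PTV, in the flat
    far-field, whose auto version is heavily shrunk — DSC < 0.7 yet a
    < 100 cGy Dmax difference (the harmless low-agreement case).
    """
    if config is None:
        config = SimConfig()
    grid = config.grid
    ptv = make_ptv(config)
    dose = make_dose_field(
        grid, ptv, config.prescription_cgy, config.falloff_lambda_mm, config.floor_cgy
    )
    cx, cy, cz = config.ptv_center_mm
    r = config.ptv_radius_mm

    # A: brain-like ellipsoid abutting the PTV; protrusion toward the PTV
    clin_a = _ellipsoid_mask(grid, (cx, cy + r + 23.0, cz), (30.0, 22.0, 20.0), "Brain")
    prot = _ellipsoid_mask(grid, (cx, cy + r + 1.0, cz), (4.0, 6.0, 4.0), "Brain")
    auto_a = StructureMask(
        name="Brain", grid=grid, occupancy=clin_a.occupancy | prot.occupancy
    )
    case_a = SimCase(
        patient_id="FIX_A",
        prescription_cgy=config.prescription_cgy,
        dose=dose,
        ptvs=[ptv],
        organs={
            "Brain": SimOrgan(
                clinical=clin_a,
                auto=auto_a,
                perturbation="protrusion",
                magnitude=6.0,
                distance_class="abut",
            )
        },
    )

    # B: cochlea-like organ 20 mm out, auto heavily eroded
    clin_b = _ellipsoid_mask(grid, (cx + r + 20.0 + 7.0, cy, cz), (7.0, 7.0, 6.0), "Cochlea_R")
    auto_b = perturb(clin_b, "erode", 2)
    case_b = SimCase(
        patient_id="FIX_B",
        prescription_cgy=config.prescription_cgy,
        dose=dose,
        ptvs=[ptv],
        organs={
            "Cochlea_R": SimOrgan(
                clinical=clin_b,
                auto=auto_b,
                perturbation="erode:2",
                magnitude=2.0,
                distance_class="near",
            )
        },
    )
    return case_a, case_b
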
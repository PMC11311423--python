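"""End-to-end evaluation: manifest or in-memory cohort -> OAR records.

Per patient: the clinical dose grid is resampled onto the contour lattice
once (masks are never resampled — that would perturb the very geometry
under study), geometric agreement and dose statistics are computed for each
auto/clinical pair, the distance to the closest PTV is attached, and the
flagging rule is applied.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .cohort import AnalysisConfig, flag_records
from .dosimetry import DEFAULT_POLICY, OARRecord, OrganPolicy, evaluate_pair
from .geometry import EmptyMaskError, compare_pair
from .grid_io import (
    CohortManifest,
    DoseGrid,
    StructureMask,
    interpolate_dose_to_grid,
    read_dose,
    read_manifest,
    read_mask,
)
from .proximity import distance_to_ptv
from .synthetic import SimCase

log = logging.getLogger(__name__)


def evaluate_structures(
    patient_id: str,
    prescription_cgy: float,
    dose: DoseGrid,
    ptvs: Sequence[StructureMask],
    pairs: Sequence[tuple[StructureMask, StructureMask]],
    config: AnalysisConfig,
    policy: OrganPolicy = DEFAULT_POLICY,
) -> list[OARRecord]:
    """Evaluate one patient's auto/clinical pairs against one dose grid."""
    if not pairs:
        return []
    mask_grid = pairs[0][0].grid
    dose_on_grid = interpolate_dose_to_grid(dose, mask_grid)
    records: list[OARRecord] = []
    for auto, clinical in pairs:
        try:
            geom = compare_pair(auto, clinical, config.tolerance_mm)
        except EmptyMaskError as exc:
            log.warning("patient %s: %s", patient_id, exc)
            geom = None
        rec = evaluate_pair(
            dose_on_grid,
            auto,
            clinical,
            patient_id=patient_id,
            prescription_cgy=prescription_cgy,
            policy=policy,
            geometry=geom,
            dmax_volume_cc=config.dmax_volume_cc,
        )
        if geom is None and rec.unevaluable_reason is None:
            rec.unevaluable_reason = "empty mask in pair"
        if rec.evaluable:
            prox = distance_to_ptv(
                clinical, list(ptvs), cutoff_mm=config.proximity_cutoff_mm
            )
            rec.distance_to_ptv_mm = prox.distance_mm
            rec.nearest_ptv = prox.nearest_ptv
            rec.within_cutoff = prox.within_cutoff
        records.append(rec)
    return records


def evaluate_case(
    case: SimCase,
    config: AnalysisConfig,
    policy: OrganPolicy = DEFAULT_POLICY,
) -> list[OARRecord]:
    """Evaluate one in-memory synthetic case."""
    pairs = [(sim.auto, sim.clinical) for sim in case.organs.values()]
    return evaluate_structures(
        case.patient_id,
        case.prescription_cgy,
        case.dose,
        case.ptvs,
        pairs,
        config,
        policy,
    )


def evaluate_cases(
    cases: Sequence[SimCase],
    config: Optional[AnalysisConfig] = None,
    policy: OrganPolicy = DEFAULT_POLICY,
) -> list[OARRecord]:
    """Evaluate an in-memory cohort and apply the flagging rule."""
    config = config or AnalysisConfig()
    records: list[OARRecord] = []
    for case in cases:
        records.extend(evaluate_case(case, config, policy))
    flag_records(records, config)
    return records


def evaluate_manifest(
    manifest: CohortManifest | str,
    config: Optional[AnalysisConfig] = None,
    policy: OrganPolicy = DEFAULT_POLICY,
) -> list[OARRecord]:
    """Evaluate a cohort from disk (manifest path or object); flags applied."""
    config = config or AnalysisConfig()
    if isinstance(manifest, (str,)):
        manifest = read_manifest(manifest)
    records: list[OARRecord] = []
    for pt in manifest.patients:
        log.info("evaluating patient %s (%d pairs)", pt.patient_id, len(pt.oar_pairs))
        dose = read_dose(pt.dose_path)
        ptvs = [read_mask(p, name=label) for label, p in pt.ptv_paths.items()]
        pairs = [
            (
                read_mask(pr.auto_path, name=pr.organ),
                read_mask(pr.clinical_path, name=pr.organ),
            )
            for pr in pt.oar_pairs
        ]
        records.extend(
            evaluate_structures(
                pt.patient_id,
                pt.prescription_cgy,
                dose,
                ptvs,
                pairs,
                config,
                policy,
            )
        )
    flag_records(records, config)
    return records
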
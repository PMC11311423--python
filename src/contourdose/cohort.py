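"""Cohort-level statistics linking geometric and dosimetric agreement.

This is the analysis layer: the >= 200 cGy clinical-objective flagging rule
(absolute, or relative to the prescription), per-organ and pooled summary
tables, pooled 90 %-coverage thresholds, ordinary-least-squares R^2 between
geometric indices and absolute dose differences, a two-sided Wilcoxon
signed-rank test with Pratt zero handling, flag-proportion curves binned on
each geometric index, proximity stratification of the flagged subset, and
the sensitivity scenarios (>= 40 Gy inclusion; 3 % / 5 % relative
thresholds).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import OARRecord
from .grid_io import OAR_NAMES

log = logging.getLogger(__name__)

GEOMETRY_METRICS = ("dsc", "sdsc", "hd_mm")
DELTA_METRICS = ("abs_delta_dmax_cgy", "abs_delta_dmean_cgy")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis; defaults are the study's operating point."""

    tolerance_mm: float = 2.0
    flag_threshold_cgy: float = 200.0
    proximity_cutoff_mm: float = 25.0
    table_cutoff_mm: float = 30.0
    dsc_bin_width: float = 0.1
    sdsc_bin_width: float = 0.1
    hd_bin_width_mm: float = 2.0
    dmax_volume_cc: float = 0.01
    min_plan_dose_cgy: Optional[float] = None
    relative_threshold_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "tolerance_mm",
            "flag_threshold_cgy",
            "proximity_cutoff_mm",
            "table_cutoff_mm",
            "dsc_bin_width",
            "sdsc_bin_width",
            "hd_bin_width_mm",
            "dmax_volume_cc",
        ):
            if getattr(self, name) <= 0 and name != "tolerance_mm":
                raise ValueError(f"{name} must be > 0")
        if self.relative_threshold_pct is not None and self.relative_threshold_pct <= 0:
            raise ValueError("relative_threshold_pct must be > 0")


def pct_of_prescription(delta_cgy: float, prescription_cgy: float) -> float:
    """Express a dose difference as a percentage of the prescription."""
    if prescription_cgy <= 0:
        raise ValueError("prescription must be > 0 cGy")
    return 100.0 * delta_cgy / prescription_cgy


def flag_threshold_for(record: OARRecord, config: AnalysisConfig) -> float:
    """Per-record flag threshold in cGy (absolute, or % of prescription)."""
    if config.relative_threshold_pct is None:
        return config.flag_threshold_cgy
    rx = record.prescription_cgy
    if rx is None or not math.isfinite(rx) or rx <= 0:
        raise ValueError(
            f"relative threshold mode requires a positive prescription; "
            f"patient {record.patient_id} has {rx!r}"
        )
    return config.relative_threshold_pct / 100.0 * rx


def flag_records(
    records: Sequence[OARRecord], config: AnalysisConfig
) -> list[OARRecord]:
    """Set each record's flag (delta D_CO >= threshold, inclusive); return flagged."""
    flagged = []
    for rec in records:
        if not rec.evaluable:
            rec.flagged = False
            continue
        rec.flagged = bool(rec.delta_dco_cgy >= flag_threshold_for(rec, config))
        if rec.flagged:
            flagged.append(rec)
    return flagged


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _pratt_ranks(deltas: np.ndarray) -> np.ndarray:
    """Ranks of the nonzero deltas, with zeros ranked first then dropped."""
    ranks_all = stats.rankdata(np.abs(deltas), method="average")
    return ranks_all[deltas != 0]


def _exact_signed_rank_p(nonzero: np.ndarray, ranks: np.ndarray) -> float:
    """Two-sided exact p via the distribution of W+ over all sign choices.

    Ties give half-integer average ranks, so the convolution runs over
    doubled ranks; equivalent to enumerating all 2^n sign assignments.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n = len(ranks)
    w2 = int(np.rint(2 * ranks[nonzero > 0].sum()))
    denom = 2.0**n
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed(
    signed_deltas: Sequence[float], exact_max_n: int = 15
) -> float:
    """Two-sided Wilcoxon signed-rank p-value with Pratt zero handling.

    Zeros are ranked with the rest of the sample and then dropped from the
    statistic (Pratt), so a large mass of exactly-zero differences — e.g.
    auto-contours used as-is — still counts against significance.  Up to
    `exact_max_n` nonzero values the null distribution is enumerated
    exactly (tie-aware); larger samples use the normal approximation with
    tie correction.
    """
    d = np.asarray(list(signed_deltas), dtype=float)
    if d.size == 0:
        raise ValueError("no deltas supplied")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        log.info("Wilcoxon: all %d deltas are zero; p = 1", d.size)
        return 1.0
    if nonzero.size <= exact_max_n:
        return _exact_signed_rank_p(nonzero, _pratt_ranks(d))
    res = stats.wilcoxon(
        d, zero_method="pratt", correction=False, method="approx",
        alternative="two-sided",
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# linear relationship


def linear_r2(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """R^2 of the ordinary-least-squares line of y on x.

    Constant y (zero variance) is defined as 0; fewer than 3 points gives
    None with a log note.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 3:
        log.info("linear_r2: %d points < 3; returning None", x.size)
        return None
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0
    if np.ptp(x) == 0.0:
        # vertical stack of x: best line is the mean of y
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(1.0 - (resid**2).sum() / ss_tot)


# ---------------------------------------------------------------------------
# summaries


def _evaluable(records: Sequence[OARRecord]) -> list[OARRecord]:
    return [r for r in records if r.evaluable]


def _q(vals: np.ndarray, q: float) -> float:
    """Quantile with linear interpolation between order statistics."""
    return float(np.quantile(vals, q, method="linear"))


@dataclass
class CohortSummary:
    """Per-organ and pooled aggregates of a flagged, annotated cohort."""

    config: AnalysisConfig
    n_total: int
    n_evaluable: int
    n_unevaluable: int
    identical_fraction: float
    per_organ: pd.DataFrame
    pooled: dict
    r2_per_organ: pd.DataFrame
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config": {
                "tolerance_mm": self.config.tolerance_mm,
                "flag_threshold_cgy": self.config.flag_threshold_cgy,
                "relative_threshold_pct": self.config.relative_threshold_pct,
                "min_plan_dose_cgy": self.config.min_plan_dose_cgy,
                "proximity_cutoff_mm": self.config.proximity_cutoff_mm,
                "table_cutoff_mm": self.config.table_cutoff_mm,
            },
            "n_total": self.n_total,
            "n_evaluable": self.n_evaluable,
            "n_unevaluable": self.n_unevaluable,
            "identical_fraction": self.identical_fraction,
            "pooled": self.pooled,
            "per_organ": self.per_organ.reset_index().to_dict(orient="records"),
            "r2_per_organ": self.r2_per_organ.reset_index().to_dict(orient="records"),
        }


def _organ_row(recs: list[OARRecord], config: AnalysisConfig) -> dict:
    if not recs:
        return {"N": 0}
    dsc = np.array([r.geometry.dsc for r in recs])
    sdsc = np.array([r.geometry.sdsc for r in recs])
    hd = np.array([r.geometry.hd_mm for r in recs])
    admax = np.array([r.abs_delta_dmax_cgy for r in recs])
    admean = np.array([r.abs_delta_dmean_cgy for r in recs])
    flagged = [r for r in recs if r.flagged]
    row = {
        "N": len(recs),
        "dco_kind": recs[0].dco_kind,
        "dsc_mean": dsc.mean(),
        "dsc_sd": dsc.std(ddof=1) if len(recs) > 1 else 0.0,
        "sdsc_mean": sdsc.mean(),
        "sdsc_sd": sdsc.std(ddof=1) if len(recs) > 1 else 0.0,
        "hd_mean_mm": hd.mean(),
        "hd_sd_mm": hd.std(ddof=1) if len(recs) > 1 else 0.0,
        "abs_delta_dmax_median_cgy": _q(admax, 0.5),
        "abs_delta_dmax_q90_cgy": _q(admax, 0.9),
        "abs_delta_dmean_median_cgy": _q(admean, 0.5),
        "abs_delta_dmean_q90_cgy": _q(admean, 0.9),
        "n_flagged": len(flagged),
        "flagged_fraction": len(flagged) / len(recs),
    }
    if flagged:
        dists = np.array(
            [r.distance_to_ptv_mm for r in flagged if r.distance_to_ptv_mm is not None]
        )
        dco = np.array([r.delta_dco_cgy for r in flagged])
        row["flagged_within_table_cutoff_fraction"] = (
            float((dists <= config.table_cutoff_mm).mean()) if dists.size else None
        )
        row["flagged_dco_min_cgy"] = float(dco.min())
        row["flagged_dco_max_cgy"] = float(dco.max())
    else:
        row["flagged_within_table_cutoff_fraction"] = None
        row["flagged_dco_min_cgy"] = None
        row["flagged_dco_max_cgy"] = None
    return row


def summarize(records: Sequence[OARRecord], config: AnalysisConfig) -> CohortSummary:
    """Per-organ and pooled cohort aggregates (flags must be set already).

    Pooled coverage thresholds are the 10th percentile of DSC and sDSC and
    the 90th percentile of HD over all evaluable pairs (the levels at least
    90 % of contours reach).  All quantiles use linear interpolation between
    order statistics, on absolute dose differences.
    """
    records = list(records)
    ev = _evaluable(records)
    if not ev:
        raise ValueError("no evaluable records to summarize")

    by_organ: dict[str, list[OARRecord]] = {name: [] for name in OAR_NAMES}
    for r in ev:
        by_organ.setdefault(r.organ, []).append(r)

    per_organ = pd.DataFrame(
        {name: _organ_row(recs, config) for name, recs in by_organ.items()}
    ).T
    per_organ.index.name = "organ"
    per_organ["N"] = per_organ["N"].astype(int)

    dsc = np.array([r.geometry.dsc for r in ev])
    sdsc = np.array([r.geometry.sdsc for r in ev])
    hd = np.array([r.geometry.hd_mm for r in ev])
    admax = np.array([r.abs_delta_dmax_cgy for r in ev])
    admean = np.array([r.abs_delta_dmean_cgy for r in ev])
    sdmax = np.array([r.delta_dmax_cgy for r in ev])
    sdmean = np.array([r.delta_dmean_cgy for r in ev])
    dco = np.array([r.delta_dco_cgy for r in ev])
    kinds = np.array([r.dco_kind for r in ev])
    thr = np.array([flag_threshold_for(r, config) for r in ev])
    n_flagged = sum(r.flagged for r in ev)

    def _frac_below(vals: np.ndarray, sel: np.ndarray) -> Optional[float]:
        return float((vals[sel] < thr[sel]).mean()) if sel.any() else None

    all_sel = np.ones(len(ev), dtype=bool)
    pooled = {
        "N": len(ev),
        "coverage_dsc_p10": _q(dsc, 0.1),
        "coverage_sdsc_p10": _q(sdsc, 0.1),
        "coverage_hd_p90_mm": _q(hd, 0.9),
        "frac_abs_delta_dmax_below_threshold": _frac_below(admax, all_sel),
        "frac_abs_delta_dmean_below_threshold": _frac_below(admean, all_sel),
        "frac_dco_below_threshold_max_organs": _frac_below(dco, kinds == "max"),
        "frac_dco_below_threshold_mean_organs": _frac_below(dco, kinds == "mean"),
        "n_flagged": int(n_flagged),
        "flagged_fraction": n_flagged / len(ev),
        "wilcoxon_p_dmax": wilcoxon_signed(sdmax),
        "wilcoxon_p_dmean": wilcoxon_signed(sdmean),
        "r2": {
            f"{m}_vs_{d}": linear_r2([getattr(r.geometry, m) for r in ev],
                                     [getattr(r, d) for r in ev])
            for m in GEOMETRY_METRICS
            for d in DELTA_METRICS
        },
    }

    r2_rows = {}
    for name, recs in by_organ.items():
        row = {}
        for m in GEOMETRY_METRICS:
            for d in DELTA_METRICS:
                row[f"{m}_vs_{d}"] = (
                    linear_r2(
                        [getattr(r.geometry, m) for r in recs],
                        [getattr(r, d) for r in recs],
                    )
                    if len(recs) >= 3
                    else None
                )
        r2_rows[name] = row
    r2_per_organ = pd.DataFrame(r2_rows).T
    r2_per_organ.index.name = "organ"

    n_identical = sum(r.identical_pair for r in ev)
    curves = {
        m: binned_flag_proportions(ev, m, config) for m in ("dsc", "sdsc", "hd")
    }
    return CohortSummary(
        config=config,
        n_total=len(records),
        n_evaluable=len(ev),
        n_unevaluable=len(records) - len(ev),
        identical_fraction=n_identical / len(ev),
        per_organ=per_organ,
        pooled=pooled,
        r2_per_organ=r2_per_organ,
        curves=curves,
    )


# ---------------------------------------------------------------------------
# binned curves and stratification


def binned_flag_proportions(
    records: Sequence[OARRecord], metric: str, config: AnalysisConfig
) -> pd.DataFrame:
    """Flagged proportion per geometric-index bin.

    Bins are half-open [lo, lo + w); for DSC/sDSC the final bin is closed at
    1.0 so perfect agreement lands in [0.9, 1.0].  Empty bins are reported
    with a null fraction so the curve's support is explicit.
    """
    ev = _evaluable(records)
    if metric in ("dsc", "sdsc"):
        width = config.dsc_bin_width if metric == "dsc" else config.sdsc_bin_width
        vals = np.array([getattr(r.geometry, metric) for r in ev])
        n_bins = int(round(1.0 / width))
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    elif metric in ("hd", "hd_mm"):
        width = config.hd_bin_width_mm
        vals = np.array([r.geometry.hd_mm for r in ev])
        top = max(width, math.ceil((vals.max() + 1e-12) / width) * width) if len(ev) else width
        edges = np.arange(0.0, top + width / 2, width)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    flags = np.array([r.flagged for r in ev], dtype=bool)

    idx = np.digitize(vals, edges[1:], right=False)  # [lo, hi) bins
    idx = np.minimum(idx, len(edges) - 2)  # close the top bin
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        nf = int(flags[sel].sum())
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "bin_center": (edges[b] + edges[b + 1]) / 2,
                "n": n,
                "n_flagged": nf,
                "flagged_fraction": nf / n if n else None,
            }
        )
    return pd.DataFrame(rows)


def proximity_stratified_flags(
    records: Sequence[OARRecord], config: AnalysisConfig
) -> dict:
    """Among flagged records: how many sit close to a PTV.

    Also reports the high-geometric-agreement substrata (DSC > 0.90;
    sDSC > 0.90 or HD < 5 mm) — the deceptive cases where a good-looking
    contour still carries a meaningful dose difference.
    """
    flagged = [r for r in _evaluable(records) if r.flagged]

    def _stratum(recs: list[OARRecord]) -> dict:
        n = len(recs)
        if n == 0:
            return {"n": 0, "n_within_cutoff": 0, "fraction_within_cutoff": None}
        within = sum(
            1
            for r in recs
            if r.distance_to_ptv_mm is not None
            and r.distance_to_ptv_mm <= config.proximity_cutoff_mm
        )
        return {
            "n": n,
            "n_within_cutoff": within,
            "fraction_within_cutoff": within / n,
        }

    high_dsc = [r for r in flagged if r.geometry.dsc > 0.90]
    high_surf = [
        r for r in flagged if r.geometry.sdsc > 0.90 or r.geometry.hd_mm < 5.0
    ]
    return {
        "cutoff_mm": config.proximity_cutoff_mm,
        "flagged": _stratum(flagged),
        "flagged_dsc_gt_0.90": _stratum(high_dsc),
        "flagged_sdsc_gt_0.90_or_hd_lt_5mm": _stratum(high_surf),
    }


# ---------------------------------------------------------------------------
# sensitivity scenarios


def sensitivity_run(
    records: Sequence[OARRecord], config: AnalysisConfig
) -> dict[str, CohortSummary]:
    """Re-run flagging and summaries under the robustness scenarios.

    (a) restrict to patients prescribed at least 40 Gy; (b)/(c) replace the
    absolute 200 cGy threshold with 3 % and 5 % of each patient's
    prescription.  Returns one summary per scenario (baseline included);
    each scenario works on copies so records' flags are not clobbered.
    """
    scenarios: dict[str, tuple[AnalysisConfig, Optional[float]]] = {
        "baseline": (config, None),
        "min_plan_dose_40gy": (
            replace(config, min_plan_dose_cgy=4000.0),
            4000.0,
        ),
        "relative_3pct": (
            replace(config, relative_threshold_pct=3.0),
            None,
        ),
        "relative_5pct": (
            replace(config, relative_threshold_pct=5.0),
            None,
        ),
    }
    out: dict[str, CohortSummary] = {}
    for name, (cfg, min_rx) in scenarios.items():
        recs = [copy.copy(r) for r in records]
        if min_rx is not None:
            recs = [r for r in recs if r.prescription_cgy >= min_rx]
        if not any(r.evaluable for r in recs):
            log.warning("sensitivity scenario %s: no evaluable records", name)
            continue
        flag_records(recs, cfg)
        out[name] = summarize(recs, cfg)
    return out
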
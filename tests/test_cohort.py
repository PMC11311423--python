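"""Flagging rule, summaries, R^2, Wilcoxon, binned curves, sensitivity."""

import numpy as np
import pytest

from contourdose import (
    AnalysisConfig,
    GeometricAgreement,
    OARRecord,
    binned_flag_proportions,
    flag_records,
    linear_r2,
    pct_of_prescription,
    proximity_stratified_flags,
    sensitivity_run,
    summarize,
    wilcoxon_signed,
)
from contourdose.cohort import flag_threshold_for
from contourdose.dosimetry import DoseStats

from conftest import brute_wilcoxon_p


def make_record(
    organ="Brainstem",
    patient="P1",
    dsc=0.9,
    sdsc=0.95,
    hd=3.0,
    delta_dmax=0.0,
    delta_dmean=0.0,
    dco_kind="max",
    prescription=6996.0,
    distance=10.0,
    identical=False,
) -> OARRecord:
    geom = GeometricAgreement(
        dsc=dsc, sdsc=sdsc, hd_mm=hd, tolerance_mm=2.0, identical=identical
    )
    stats = DoseStats(dmax_cgy=5000.0, dmean_cgy=3000.0, volume_cc=10.0)
    delta_dco = abs(delta_dmax) if dco_kind == "max" else abs(delta_dmean)
    return OARRecord(
        patient_id=patient,
        organ=organ,
        geometry=geom,
        auto_stats=stats,
        clinical_stats=stats,
        delta_dmax_cgy=delta_dmax,
        delta_dmean_cgy=delta_dmean,
        dco_kind=dco_kind,
        delta_dco_cgy=delta_dco,
        prescription_cgy=prescription,
        distance_to_ptv_mm=distance,
        identical_pair=identical,
    )


class TestFlagging:
    def test_inclusive_200_boundary(self):
        recs = [make_record(delta_dmax=v) for v in (0.0, 199.0, 200.0, 350.0)]
        flagged = flag_records(recs, AnalysisConfig())
        assert [r.flagged for r in recs] == [False, False, True, True]
        assert len(flagged) == 2

    def test_relative_threshold_3pct_of_6996(self):
        rec = make_record(prescription=6996.0)
        cfg = AnalysisConfig(relative_threshold_pct=3.0)
        assert flag_threshold_for(rec, cfg) == pytest.approx(209.88)

    def test_all_identical_cohort_zero_flagged(self):
        recs = [make_record(identical=True, dsc=1.0, sdsc=1.0, hd=0.0) for _ in range(10)]
        assert flag_records(recs, AnalysisConfig()) == []

    def test_relative_mode_without_prescription_errors(self):
        rec = make_record(prescription=float("nan"))
        with pytest.raises(ValueError, match="prescription"):
            flag_threshold_for(rec, AnalysisConfig(relative_threshold_pct=3.0))

    def test_raising_threshold_never_increases_flags(self):
        rng = np.random.default_rng(7)
        recs = [make_record(delta_dmax=float(d)) for d in rng.gamma(1.0, 150.0, 100)]
        counts = []
        for thr in (50.0, 100.0, 200.0, 400.0, 800.0):
            counts.append(len(flag_records(recs, AnalysisConfig(flag_threshold_cgy=thr))))
        assert counts == sorted(counts, reverse=True)


class TestPctOfPrescription:
    def test_200_of_6996_rounds_to_3pct(self):
        pct = pct_of_prescription(200.0, 6996.0)
        assert pct == pytest.approx(2.8588, abs=1e-4)
        assert round(pct) == 3

    def test_zero_and_identity(self):
        assert pct_of_prescription(0.0, 5000.0) == 0.0
        assert pct_of_prescription(6996.0, 6996.0) == 100.0

    def test_nonpositive_prescription_errors(self):
        with pytest.raises(ValueError):
            pct_of_prescription(100.0, 0.0)


class TestLinearR2:
    def test_exact_line(self):
        x = np.arange(10.0)
        assert linear_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_constant_response_defined_as_zero(self):
        assert linear_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) == 0.0

    def test_three_point_closed_form(self):
        # OLS of y={1,3,2} on x={1,2,3}: slope 0.5, R^2 = 0.25
        assert linear_r2([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]) == pytest.approx(0.25)

    def test_fewer_than_three_points_is_none(self):
        assert linear_r2([1.0, 2.0], [1.0, 2.0]) is None

    def test_constant_x_defined_as_zero(self):
        assert linear_r2([2.0, 2.0, 2.0], [1.0, 3.0, 2.0]) == 0.0


class TestWilcoxon:
    def test_antisymmetric_center_p_one(self):
        assert wilcoxon_signed([-3.0, -1.0, 1.0, 3.0]) == pytest.approx(1.0)

    def test_all_zero_deltas_p_one(self):
        assert wilcoxon_signed([0.0] * 8) == 1.0

    def test_all_positive_five(self):
        # one-sided tail 1/32 -> two-sided 1/16
        assert wilcoxon_signed([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(1.0 / 16)

    def test_exact_path_matches_enumeration(self, rng):
        """Exact DP agrees with full sign enumeration for n <= 8, with ties/zeros."""
        for n in range(1, 9):
            for _ in range(8):
                d = rng.integers(-4, 5, size=n).astype(float)
                if not np.any(d):
                    continue
                assert wilcoxon_signed(d) == pytest.approx(
                    brute_wilcoxon_p(d), abs=1e-12
                ), f"n={n}, d={d}"

    def test_large_sample_uses_consistent_approximation(self, rng):
        # exact vs approx agree reasonably at the crossover size
        d = rng.normal(0.4, 1.0, size=15)
        p_exact = wilcoxon_signed(d, exact_max_n=15)
        p_approx = wilcoxon_signed(d, exact_max_n=1)
        assert p_approx == pytest.approx(p_exact, abs=0.05)

    def test_zeros_with_pratt_damp_significance(self):
        # the same positives with a large zero mass are less significant
        p_no_zeros = wilcoxon_signed([1.0, 2.0, 3.0, 4.0, 5.0])
        p_zeros = wilcoxon_signed([1.0, 2.0, 3.0, 4.0, 5.0] + [0.0] * 10)
        assert p_zeros >= p_no_zeros


class TestSummarize:
    def test_single_record_is_its_own_summary(self):
        rec = make_record(dsc=0.8, delta_dmax=150.0, delta_dmean=-30.0)
        cfg = AnalysisConfig()
        flag_records([rec], cfg)
        s = summarize([rec], cfg)
        row = s.per_organ.loc["Brainstem"]
        assert row["N"] == 1
        assert row["dsc_mean"] == pytest.approx(0.8)
        assert row["abs_delta_dmax_median_cgy"] == pytest.approx(150.0)
        assert row["abs_delta_dmax_q90_cgy"] == pytest.approx(150.0)
        assert s.pooled["coverage_dsc_p10"] == pytest.approx(0.8)

    def test_quantiles_linear_interpolation(self):
        # |delta| in {0, 0, 100, 400}: median 50, Q90 310
        recs = [make_record(patient=f"P{i}", delta_dmax=v) for i, v in enumerate([0.0, 0.0, 100.0, 400.0])]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        s = summarize(recs, cfg)
        row = s.per_organ.loc["Brainstem"]
        assert row["abs_delta_dmax_median_cgy"] == pytest.approx(50.0)
        assert row["abs_delta_dmax_q90_cgy"] == pytest.approx(310.0)

    def test_absent_organ_reported_with_zero_n(self):
        recs = [make_record()]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        s = summarize(recs, cfg)
        assert s.per_organ.loc["OpticChiasm", "N"] == 0
        assert s.per_organ["N"].sum() == s.pooled["N"]

    def test_median_never_exceeds_q90(self, rng):
        recs = [
            make_record(patient=f"P{i}", delta_dmax=float(v))
            for i, v in enumerate(rng.gamma(1.5, 100.0, 40))
        ]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        s = summarize(recs, cfg)
        row = s.per_organ.loc["Brainstem"]
        assert row["abs_delta_dmax_median_cgy"] <= row["abs_delta_dmax_q90_cgy"]

    def test_identical_fraction_reported(self):
        recs = [make_record(patient=f"P{i}", identical=(i < 3), dsc=1.0 if i < 3 else 0.7) for i in range(4)]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        s = summarize(recs, cfg)
        assert s.identical_fraction == pytest.approx(0.75)


class TestBinnedCurves:
    def test_single_bin_half_flagged(self):
        recs = [make_record(patient=f"P{i}", dsc=0.55, delta_dmax=300.0 * (i % 2)) for i in range(8)]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        curve = binned_flag_proportions(recs, "dsc", cfg)
        populated = curve[curve["n"] > 0]
        assert len(populated) == 1
        assert populated.iloc[0]["flagged_fraction"] == pytest.approx(0.5)

    def test_dsc_one_lands_in_top_bin(self):
        recs = [make_record(dsc=1.0)]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        curve = binned_flag_proportions(recs, "dsc", cfg)
        top = curve.iloc[-1]
        assert top["bin_lo"] == pytest.approx(0.9) and top["n"] == 1

    def test_two_bin_fractions(self):
        recs = [make_record(patient=f"A{i}", dsc=0.42, delta_dmax=300.0 if i < 3 else 0.0) for i in range(4)]
        recs += [make_record(patient=f"B{i}", dsc=0.88, delta_dmax=0.0) for i in range(6)]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        curve = binned_flag_proportions(recs, "dsc", cfg)
        by_lo = curve.set_index("bin_lo")
        assert by_lo.loc[0.4, "flagged_fraction"] == pytest.approx(0.75)
        assert by_lo.loc[0.8, "flagged_fraction"] == pytest.approx(0.0)

    def test_bins_partition_the_records(self, rng):
        recs = [
            make_record(patient=f"P{i}", dsc=float(v), hd=float(h))
            for i, (v, h) in enumerate(zip(rng.random(50), rng.random(50) * 30))
        ]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        for metric in ("dsc", "sdsc", "hd"):
            curve = binned_flag_proportions(recs, metric, cfg)
            assert curve["n"].sum() == len(recs)

    def test_empty_bins_have_null_fraction(self):
        recs = [make_record(dsc=0.95)]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        curve = binned_flag_proportions(recs, "dsc", cfg)
        assert curve[curve["n"] == 0]["flagged_fraction"].isna().all()


class TestProximityStratification:
    def test_three_of_four_flagged_within(self):
        recs = [
            make_record(patient=f"P{i}", delta_dmax=400.0, distance=d)
            for i, d in enumerate([5.0, 10.0, 20.0, 40.0])
        ]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        rep = proximity_stratified_flags(recs, cfg)
        assert rep["flagged"]["n"] == 4
        assert rep["flagged"]["fraction_within_cutoff"] == pytest.approx(0.75)

    def test_zero_flagged_reports_null_denominators(self):
        recs = [make_record(delta_dmax=0.0)]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        rep = proximity_stratified_flags(recs, cfg)
        assert rep["flagged"]["n"] == 0
        assert rep["flagged"]["fraction_within_cutoff"] is None

    def test_high_dsc_substratum(self):
        recs = [
            make_record(patient=f"P{i}", delta_dmax=400.0, dsc=0.95, distance=5.0)
            for i in range(3)
        ]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        rep = proximity_stratified_flags(recs, cfg)
        assert rep["flagged_dsc_gt_0.90"]["n"] == 3
        assert rep["flagged_dsc_gt_0.90"]["fraction_within_cutoff"] == pytest.approx(1.0)


class TestSensitivity:
    def _cohort(self):
        recs = [
            make_record(patient="HI", delta_dmax=190.0, prescription=6000.0),
            make_record(patient="HI2", delta_dmax=250.0, prescription=6000.0),
            make_record(patient="LO", delta_dmax=500.0, prescription=3000.0),
        ]
        return recs

    def test_scenarios_emitted(self):
        recs = self._cohort()
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        out = sensitivity_run(recs, cfg)
        assert set(out) == {"baseline", "min_plan_dose_40gy", "relative_3pct", "relative_5pct"}

    def test_min_dose_filter_drops_low_prescriptions(self):
        recs = self._cohort()
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        out = sensitivity_run(recs, cfg)
        assert out["baseline"].pooled["N"] == 3
        assert out["min_plan_dose_40gy"].pooled["N"] == 2

    def test_all_above_40gy_filter_is_noop(self):
        recs = [make_record(patient=f"P{i}", delta_dmax=250.0, prescription=6996.0) for i in range(4)]
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        out = sensitivity_run(recs, cfg)
        assert out["min_plan_dose_40gy"].pooled == out["baseline"].pooled

    def test_relative_3pct_flags_190_at_6000(self):
        # threshold 3% of 6000 = 180 cGy: delta 190 flags in relative
        # mode but not at the absolute 200 cGy rule
        recs = self._cohort()
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        out = sensitivity_run(recs, cfg)
        base_flags = out["baseline"].pooled["n_flagged"]
        rel_flags = out["relative_3pct"].pooled["n_flagged"]
        assert base_flags == 2  # 250 and 500
        assert rel_flags == 3  # 190 >= 180 joins

    def test_original_flags_untouched_by_scenarios(self):
        recs = self._cohort()
        cfg = AnalysisConfig()
        flag_records(recs, cfg)
        before = [r.flagged for r in recs]
        sensitivity_run(recs, cfg)
        assert [r.flagged for r in recs] == before
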
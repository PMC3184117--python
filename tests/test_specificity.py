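"""Specificity: detection calls, FP-rate curves, thresholds, enrichment."""

import numpy as np
import pandas as pd
import pytest

from mirspike.model import CtTable, PlatformConfig, SpikeDesign
from mirspike.homology import AlignmentParams, HomologyMap
from mirspike.simulate import SimulatorParams, default_profiles
from mirspike.specificity import (
    detect_calls,
    enrichment_test,
    fp_rate_curve,
    fp_rate_pct,
    mismatch_stratified_fp,
    suggest_threshold,
)

from _oracles import binomial_upper_tail_oracle


def _table(rows):
    return CtTable(
        pd.DataFrame(rows, columns=["sample_id", "replicate_id", "assay_id", "ct"])
    )


class TestDetectCalls:
    def test_any_rule_detects_on_single_good_replicate(self):
        t = _table([("S", "r1", "a", 25.0), ("S", "r2", "a", 26.0)])
        calls = detect_calls(t, "S", PlatformConfig(30.0))
        assert bool(calls.loc["a", "detected"])
        assert calls.loc["a", "representative_ct"] == 25.0

    def test_all_rule_requires_every_replicate(self):
        t = _table([("S", "r1", "a", 25.0), ("S", "r2", "a", np.nan)])
        cfg = PlatformConfig(30.0, detection_rule="all_replicates")
        assert not bool(detect_calls(t, "S", cfg).loc["a", "detected"])
        assert bool(detect_calls(t, "S", PlatformConfig(30.0)).loc["a", "detected"])

    def test_late_signals_fail_both_rules(self):
        t = _table([("S", "r1", "a", 39.0), ("S", "r2", "a", 39.5)])
        for rule in ("any_replicate", "all_replicates"):
            cfg = PlatformConfig(38.0, detection_rule=rule)
            assert not bool(detect_calls(t, "S", cfg).loc["a", "detected"])

    def test_threshold_is_inclusive(self):
        t = _table([("S", "r1", "a", 38.0), ("S", "r2", "a", 38.0)])
        cfg = PlatformConfig(38.0, detection_rule="all_replicates")
        assert bool(detect_calls(t, "S", cfg).loc["a", "detected"])


class TestFpRateCurve:
    @pytest.fixture()
    def toy(self, small_catalogs):
        # 10 absent-target assays of one platform, 3 with early signals
        cat = small_catalogs["mircury_like"]
        absent = [r.assay_id for r in cat if r.target_mirna_id.startswith("off-")][:10]
        rows = []
        for i, a in enumerate(absent):
            ct = 25.0 if i < 3 else np.nan
            rows += [("S", "r1", a, ct), ("S", "r2", a, ct)]
        table = _table(rows)
        design = SpikeDesign({("S", "syn-mir-001"): 1e6})
        sub = cat.subset(absent)
        hmap = HomologyMap({a: [] for a in absent}, AlignmentParams())
        return table, design, sub, hmap

    def test_toy_rates(self, toy):
        table, design, cat, hmap = toy
        curve = fp_rate_curve(table, "S", design, cat, [20.0, 30.0], hmap)
        assert curve.loc[0, "n_false_positive"] == 0
        assert curve.loc[0, "fp_rate"] == 0.0
        assert curve.loc[1, "n_false_positive"] == 3
        assert curve.loc[1, "fp_rate"] == pytest.approx(0.3)

    def test_unsorted_thresholds_rejected(self, toy):
        table, design, cat, hmap = toy
        with pytest.raises(ValueError):
            fp_rate_curve(table, "S", design, cat, [30.0, 20.0], hmap)

    def test_curve_invariants_on_simulated_study(self, small_study):
        thresholds = list(np.arange(20.0, 40.5, 0.5))
        for name, table in small_study.tables.items():
            curve = fp_rate_curve(
                table, "synthetic_1", small_study.design,
                small_study.catalogs[name], thresholds, small_study.homology[name],
            )
            fp = curve["n_false_positive"].to_numpy()
            tn = curve["n_true_negative"].to_numpy()
            assert (np.diff(fp) >= 0).all()  # monotone in threshold
            assert len(set(fp + tn)) == 1    # FP + TN constant
            assert curve["fp_rate"].between(0, 1).all()
            assert (curve["n_homology_related"] <= curve["n_false_positive"]).all()

    def test_crossreactive_fps_exceed_expected_fraction_at_low_thresholds(self, small_study):
        """With cross-reaction on, early false positives are homology driven."""
        from mirspike.homology import expected_homology_fraction

        name = "mircury_like"
        table = small_study.tables[name]
        present = small_study.design.present_mirnas("synthetic_1")
        _, _, frac = expected_homology_fraction(
            small_study.catalogs[name], small_study.panel, present,
            homology_map=small_study.homology[name],
        )
        curve = fp_rate_curve(
            table, "synthetic_1", small_study.design,
            small_study.catalogs[name], [30.0, 34.0], small_study.homology[name],
        )
        low = curve.iloc[-1]
        assert low["n_false_positive"] > 0
        assert low["n_homology_related"] / low["n_false_positive"] > frac


class TestSuggestThreshold:
    def test_late_no_rt_signals_floor_to_38(self):
        rows = [("N", "r1", f"a{i}", ct) for i, ct in enumerate(np.linspace(38.2, 40.0, 30))]
        assert suggest_threshold(_table(rows), 0.01, PlatformConfig(38.0)) == 38.0

    def test_silent_no_rt_returns_run_length(self):
        rows = [("N", "r1", "a0", np.nan), ("N", "r1", "a1", np.nan)]
        assert suggest_threshold(_table(rows), 0.01, PlatformConfig(38.0)) == 40.0
        assert suggest_threshold(None, 0.01, PlatformConfig(38.0)) == 40.0

    def test_single_signal_median_floors(self):
        rows = [("N", "r1", "a0", 39.7)]
        assert suggest_threshold(_table(rows), 0.5, PlatformConfig(38.0)) == 39.0

    def test_quantile_validated(self):
        with pytest.raises(ValueError):
            suggest_threshold(None, 0.0, PlatformConfig(38.0))


class TestEnrichment:
    def test_zero_observed_is_certain(self):
        assert enrichment_test(0, 10, 0.2).p_value == 1.0

    def test_poisson_tail_hand_case(self):
        # lambda = 8 * 0.25 = 2, observe 4
        res = enrichment_test(4, 8, 0.25, mode="poisson")
        assert res.p_value == pytest.approx(0.142877, abs=1e-6)

    def test_zero_fp_returns_one_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mirspike.specificity"):
            res = enrichment_test(0, 0, 0.2)
        assert res.p_value == 1.0
        assert any("zero false positives" in r.message for r in caplog.records)

    def test_binomial_mode_matches_exact_tail(self):
        from fractions import Fraction

        for n_fp in (5, 12, 20):
            for k in range(n_fp + 1):
                got = enrichment_test(k, n_fp, 0.25, mode="binomial").p_value
                want = float(binomial_upper_tail_oracle(k, n_fp, Fraction(1, 4)))
                assert got >= want - 1e-12
                assert got == pytest.approx(want, abs=1e-12)


class TestMismatchStratified:
    def test_printed_count_rates(self):
        assert fp_rate_pct(17, 18) == 94
        assert fp_rate_pct(33, 57) == 58
        assert fp_rate_pct(0, 5) == 0

    def test_strata_partition_and_monotonicity(self, small_study_factory, profiles):
        """Cross-reaction decays with mismatch distance, so stratified FP
        rates are monotone non-increasing in nearly every seeded run."""
        good = 0
        for seed in range(10):
            study = small_study_factory(seed + 100, profiles)
            name = "mircury_like"
            table = mismatch_stratified_fp(
                study.tables[name], "synthetic_1", study.design,
                study.catalogs[name], study.homology[name],
                profiles[name].config,
            )
            assert (table["n_false_positive"] <= table["n_assays"]).all()
            rates = table["fp_rate_pct"].to_numpy()
            if (np.diff(rates) <= 0).all():
                good += 1
        assert good >= 9

    def test_toy_stratum_rate(self, small_study):
        name = "taqman_like"
        table = mismatch_stratified_fp(
            small_study.tables[name], "synthetic_1", small_study.design,
            small_study.catalogs[name], small_study.homology[name],
            small_study.profiles[name].config,
        )
        # every stratified assay is an absent-target assay with a homolog
        assert (table["mismatches"] >= 0).all()
        assert table["n_assays"].sum() > 0
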
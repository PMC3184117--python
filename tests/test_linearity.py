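"""Reproducibility, dilution-series detection, and linearity."""

import numpy as np
import pandas as pd
import pytest

from mirspike.linearity import (
    DilutionSeries,
    assay_linearity,
    detection_comparison,
    dilution_detection,
    replicate_correlation,
)
from mirspike.model import (
    AssayCatalog,
    AssayRecord,
    CtTable,
    MirspikeError,
    PlatformConfig,
    SpikeDesign,
    ValidationError,
)
from mirspike.simulate import (
    PlatformProfile,
    SimulatorParams,
    simulate_study,
)

from _oracles import hypergeom_detection_oracle

CFG = PlatformConfig(38.0)


def _table(rows):
    return CtTable(
        pd.DataFrame(rows, columns=["sample_id", "replicate_id", "assay_id", "ct"])
    )


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        rows = []
        for i, v in enumerate([20.0, 24.0, 28.0, 31.0]):
            rows += [("S", "r1", f"a{i}", v), ("S", "r2", f"a{i}", v)]
        r, n = replicate_correlation(_table(rows), "S", CFG)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_constant_offset_still_perfect(self):
        rows = []
        for i, v in enumerate([20.0, 24.0, 28.0, 31.0]):
            rows += [("S", "r1", f"a{i}", v), ("S", "r2", f"a{i}", v + 0.7)]
        r, _ = replicate_correlation(_table(rows), "S", CFG)
        assert r == pytest.approx(1.0)

    def test_too_few_detected_is_flagged_na(self):
        rows = [("S", "r1", "a0", 20.0), ("S", "r2", "a0", 20.5),
                ("S", "r1", "a1", np.nan), ("S", "r2", "a1", 21.0)]
        r, n = replicate_correlation(_table(rows), "S", CFG)
        assert r is None
        assert n == 1

    def test_requires_exactly_two_replicates(self):
        rows = [("S", "r1", "a0", 20.0)]
        with pytest.raises(MirspikeError, match="two replicates"):
            replicate_correlation(_table(rows), "S", CFG)

    def test_simulated_regime_matches_study_values(self, small_study_factory, profiles):
        """Spiked plasma at noise_sd 0.3 over a ~10-cycle Ct range gives
        duplicate correlations above 0.97, the regime the study reports."""
        good = 0
        for seed in range(5):
            study = small_study_factory(seed + 300, profiles)
            for name in study.tables:
                cfg = profiles[name].config.with_rule("all_replicates")
                r, n = replicate_correlation(study.tables[name], "spiked_plasma_1", cfg)
                assert n >= 20
                if r > 0.97:
                    good += 1
        assert good >= 9  # of 10 platform-runs


class TestDilutionSeries:
    def test_validates_dilution_factor(self):
        design = SpikeDesign({("p1", "m"): 100.0, ("p2", "m"): 50.0})
        rows = [("p1", "r1", "a", 20.0), ("p2", "r1", "a", 23.3)]
        with pytest.raises(ValidationError, match="dilution factor"):
            DilutionSeries(_table(rows), ["p1", "p2"], design)

    def test_detection_counts_non_increasing_across_seeds(self, small_study_factory, profiles):
        good = 0
        for seed in range(10):
            study = small_study_factory(seed + 500, profiles)
            det = dilution_detection(study.dilution_series("mircury_like"),
                                     profiles["mircury_like"].config)
            if (np.diff(det["n_detected"].to_numpy()) <= 0).all():
                good += 1
        assert good >= 9

    def test_all_rule_detects_no_more_than_any_rule(self, small_study):
        for name, table in small_study.tables.items():
            cfg_all = small_study.profiles[name].config.with_rule("all_replicates")
            cfg_any = small_study.profiles[name].config
            for sample in ("synthetic_1", "dil_2", "dil_4"):
                from mirspike.specificity import detect_calls

                n_all = int(detect_calls(table, sample, cfg_all)["detected"].sum())
                n_any = int(detect_calls(table, sample, cfg_any)["detected"].sum())
                assert n_all <= n_any

    def test_exclusion_list_mechanism(self, small_study):
        name = "taqman_like"
        series = small_study.dilution_series(name)
        cfg = small_study.profiles[name].config
        full = dilution_detection(series, cfg)
        some = series.ct.assays[:5]
        trimmed = dilution_detection(series, cfg, exclude_assays=some)
        assert (trimmed["n_detected"] <= full["n_detected"]).all()


class TestDetectionComparison:
    def test_reported_sensitivity_gap_is_significant(self):
        assert detection_comparison(93, 59, 125).p_value <= 0.001

    def test_equal_counts_tie(self):
        assert detection_comparison(60, 60, 125).p_value == pytest.approx(1.0)

    def test_small_case_matches_enumeration(self):
        got = detection_comparison(3, 1, 5).p_value
        want = float(hypergeom_detection_oracle(3, 1, 5))
        assert got == pytest.approx(want, abs=1e-12)

    def test_exhaustive_agreement_small_totals(self):
        for n_total in (4, 7, 12):
            for d1 in range(n_total + 1):
                for d2 in range(n_total + 1):
                    got = detection_comparison(d1, d2, n_total).p_value
                    want = float(hypergeom_detection_oracle(d1, d2, n_total))
                    assert got == pytest.approx(want, abs=1e-12)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            detection_comparison(6, 1, 5)


def _mini_series(ct_by_point, copies_by_point, assay="a"):
    rows = []
    design = {}
    points = sorted(ct_by_point)
    for p in points:
        design[(p, "m")] = copies_by_point[p]
        for i, v in enumerate(ct_by_point[p]):
            rows.append((p, f"r{i+1}", assay, v))
    catalog = AssayCatalog([AssayRecord(assay, "p", "m", "ACGTACGTACGTACGTACGTAC")])
    return (
        DilutionSeries(_table(rows), points, SpikeDesign(design)),
        catalog,
    )


class TestAssayLinearity:
    def test_perfect_log_linear_assay(self):
        # Ct rises by log2(10) per 10-fold dilution
        copies = {"p1": 1e5, "p2": 1e4, "p3": 1e3, "p4": 1e2, "p5": 1e1}
        cts = {p: [20.0 + np.log2(10) * i] * 2 for i, p in enumerate(sorted(copies))}
        series, catalog = _mini_series(cts, copies)
        table, summary = assay_linearity(series, CFG, catalog)
        assert table.iloc[0]["r_squared"] == pytest.approx(1.0)
        assert summary["n_assays_r2_ge_cutoff"] == 1

    def test_never_detected_assay_scores_zero_and_is_flagged(self):
        copies = {"p1": 1e5, "p2": 1e4, "p3": 1e3, "p4": 1e2, "p5": 1e1}
        cts = {p: [np.nan, np.nan] for p in copies}
        series, catalog = _mini_series(cts, copies)
        table, summary = assay_linearity(series, CFG, catalog)
        assert table.iloc[0]["r_squared"] == 0.0
        assert table.iloc[0]["flag"] == "zero_variance"

    def test_imputed_values_never_exceed_threshold(self):
        copies = {"p1": 1e5, "p2": 1e4, "p3": 1e3, "p4": 1e2, "p5": 1e1}
        cts = {p: [30.0 + 2 * i, np.nan] for i, p in enumerate(sorted(copies))}
        series, catalog = _mini_series(cts, copies)
        # imputation target equals the platform threshold by definition;
        # a run must not fail even when all imputations are at the bound
        table, _ = assay_linearity(series, CFG, catalog)
        assert 0.0 <= table.iloc[0]["r_squared"] <= 1.0

    def test_lowest_point_dropped_by_default(self):
        copies = {"p1": 1e5, "p2": 1e4, "p3": 1e3, "p4": 1e2, "p5": 1e1}
        cts = {p: [20.0 + np.log2(10) * i] * 2 for i, p in enumerate(sorted(copies))}
        cts["p5"] = [np.nan, np.nan]  # garbage at the weakest point
        series, catalog = _mini_series(cts, copies)
        table, _ = assay_linearity(series, CFG, catalog)
        assert table.iloc[0]["r_squared"] == pytest.approx(1.0)  # p5 unused
        table5, _ = assay_linearity(series, CFG, catalog, points_used=5)
        assert table5.iloc[0]["r_squared"] < 1.0

    def test_dropout_degrades_linear_fraction(self, small_panel, small_catalogs, small_homology):
        """An occupancy-dropout profile yields fewer linear assays than the
        same profile with dropout disabled, across seeds."""
        wins = 0
        for seed in range(10):
            fractions = {}
            for dropout in (True, False):
                params = SimulatorParams(occupancy_dropout=dropout, seed=seed)
                profiles = {n: PlatformProfile(params, PlatformConfig(38.0))
                            for n in small_catalogs}
                study = simulate_study(small_panel, small_catalogs, profiles,
                                       seed=seed + 700, n_endogenous=0,
                                       homology=small_homology)
                table, summary = assay_linearity(
                    study.dilution_series("mircury_like"),
                    PlatformConfig(38.0), study.catalogs["mircury_like"],
                )
                fractions[dropout] = summary["n_assays_r2_ge_cutoff"] / summary["n_assays"]
            if fractions[False] >= fractions[True]:
                wins += 1
        assert wins >= 9
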
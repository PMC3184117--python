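"""Ct generator: Ct model, cross-reaction, dropout, determinism."""

import io

import numpy as np
import pytest

from mirspike.homology import AlignmentParams, AlignmentSummary, HomologyMap, align_pair
from mirspike.io import write_ct_table
from mirspike.model import (
    AssayCatalog,
    AssayRecord,
    PlatformConfig,
    SpikeDesign,
    ValidationError,
    expected_delta_ct,
)
from mirspike.simulate import (
    DILUTION_POINTS,
    PlatformProfile,
    SimulatorParams,
    build_study_design,
    effective_template,
    expected_ct,
    make_panel,
    simulate_ct_table,
    simulate_study,
)

EMPTY_MAP = HomologyMap({}, AlignmentParams())


class TestExpectedCt:
    def test_reference_anchor(self):
        p = SimulatorParams()
        assert expected_ct(1e6, p) == pytest.approx(20.0)

    def test_fourfold_is_two_cycles(self):
        p = SimulatorParams()
        assert expected_ct(4e6, p) == pytest.approx(18.0)

    def test_tenfold_dilution_is_log2_ten_cycles(self):
        p = SimulatorParams()
        assert expected_ct(1e5, p) == pytest.approx(20.0 + np.log2(10))

    def test_preamp_shifts_down(self):
        p = SimulatorParams(preamp_cycles=12)
        assert expected_ct(1e6, p) == pytest.approx(8.0)

    def test_efficiency_below_one_stretches_the_slope(self):
        p = SimulatorParams(efficiency=0.9)
        assert expected_ct(1e7, p) == pytest.approx(20.0 - np.log(10) / np.log(1.9))

    def test_nonpositive_copies_rejected(self):
        with pytest.raises(ValidationError):
            expected_ct(0.0, SimulatorParams())


class TestEffectiveTemplate:
    def _assay(self):
        return AssayRecord("a", "p", "t", "ACGTACGTACGTACGTACGTAC")

    def test_no_homologs_is_own_copies(self):
        design = SpikeDesign({("S", "t"): 123.0})
        assert effective_template(self._assay(), "S", design, EMPTY_MAP,
                                  SimulatorParams()) == 123.0

    def test_two_mismatch_homolog_leaks_scaled_template(self):
        design = SpikeDesign({("S", "h"): 1e6})
        hmap = HomologyMap(
            {"a": [("h", AlignmentSummary(2, 0, 0, 22, 18.0))]}, AlignmentParams()
        )
        got = effective_template(self._assay(), "S", design, hmap, SimulatorParams())
        assert got == pytest.approx(5e3)  # 1e6 * 0.5 * 10^-2

    def test_infinite_penalty_limit_keeps_only_own_target(self):
        design = SpikeDesign({("S", "t"): 42.0, ("S", "h"): 1e6})
        hmap = HomologyMap(
            {"a": [("h", AlignmentSummary(1, 0, 0, 22, 20.0))]}, AlignmentParams()
        )
        p = SimulatorParams(crossreact_log10_penalty_per_mismatch=300.0)
        assert effective_template(self._assay(), "S", design, hmap, p) == pytest.approx(42.0)


class TestSimulateCtTable:
    def _catalog(self, n):
        return AssayCatalog(
            [AssayRecord(f"a{i:04d}", "p", f"m{i:04d}", "ACGTACGTACGTACGTACGTAC")
             for i in range(n)]
        )

    def test_same_seed_is_bit_identical(self):
        catalog = self._catalog(50)
        design = SpikeDesign({("S", f"m{i:04d}"): 1e4 for i in range(50)})
        params = SimulatorParams(seed=99)
        t1 = simulate_ct_table(design, catalog, EMPTY_MAP, params)
        t2 = simulate_ct_table(design, catalog, EMPTY_MAP, params)
        buf1, buf2 = io.StringIO(), io.StringIO()
        write_ct_table(t1, buf1)
        write_ct_table(t2, buf2)
        assert buf1.getvalue() == buf2.getvalue()

    def test_noiseless_fourfold_design_gives_exact_deltas(self):
        catalog = self._catalog(30)
        design = SpikeDesign(
            {("S1", f"m{i:04d}"): 1e6 for i in range(30)}
            | {("S2", f"m{i:04d}"): 0.25e6 for i in range(30)}
        )
        params = SimulatorParams(noise_sd=0.0, occupancy_dropout=False,
                                 background_rate=0.0)
        table = simulate_ct_table(design, catalog, EMPTY_MAP, params)
        w1 = table.pivot_replicates("S1")
        w2 = table.pivot_replicates("S2")
        deltas = w2.mean(axis=1) - w1.mean(axis=1)
        assert np.allclose(deltas.to_numpy(), 2.0)

    def test_occupancy_dropout_matches_poisson_occupancy(self):
        """Noise-free detection at 0.5 copies within 3 binomial SD of
        1 - e^{-0.5} (noise isolated so the occupancy bound is what is
        measured: a single copy sits at Ct 39.93, just inside the run)."""
        n = 1000
        catalog = self._catalog(n)
        design = SpikeDesign({("S", f"m{i:04d}"): 0.5 for i in range(n)})
        params = SimulatorParams(noise_sd=0.0, background_rate=0.0, seed=12)
        table = simulate_ct_table(design, catalog, EMPTY_MAP, params, n_replicates=1)
        frac = float(table.df["ct"].notna().mean())
        want = 1.0 - np.exp(-0.5)
        sd = np.sqrt(want * (1 - want) / n)
        assert abs(frac - want) <= 3 * sd

    def test_background_rate_reproduced_in_no_rt(self):
        n = 800
        catalog = self._catalog(n)
        design = SpikeDesign({})
        params = SimulatorParams(background_rate=0.1, seed=4)
        table = simulate_ct_table(design, catalog, EMPTY_MAP, params,
                                  samples=["no_rt"], n_replicates=1)
        frac = float(table.df["ct"].notna().mean())
        sd = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) <= 3 * sd
        values = table.df["ct"].dropna()
        assert ((values >= 38.0) & (values <= 40.0)).all()

    def test_outlier_wells_shift_or_drop(self):
        n = 500
        catalog = self._catalog(n)
        design = SpikeDesign({("S", f"m{i:04d}"): 1e6 for i in range(n)})
        params = SimulatorParams(noise_sd=0.0, occupancy_dropout=False,
                                 outlier_well_rate=0.1, outlier_shift=6.0, seed=8)
        table = simulate_ct_table(design, catalog, EMPTY_MAP, params, n_replicates=1)
        shifted = (table.df["ct"] > 25.0).sum()
        assert 0.05 * n <= shifted <= 0.15 * n
        params_drop = SimulatorParams(noise_sd=0.0, occupancy_dropout=False,
                                      outlier_well_rate=0.1, outlier_shift=None, seed=8)
        dropped = simulate_ct_table(design, catalog, EMPTY_MAP, params_drop,
                                    n_replicates=1).df["ct"].isna().sum()
        assert 0.05 * n <= dropped <= 0.15 * n


class TestStudyDesign:
    def test_pool_mixing_gives_plus_minus_two(self, small_panel):
        design = build_study_design(small_panel)
        for sp in small_panel:
            want = 2.0 if sp.pool == "B" else -2.0
            assert expected_delta_ct(
                design, "synthetic_1", "synthetic_2", sp.mirna_id
            ) == pytest.approx(want)

    def test_dilution_series_reaches_half_copy(self, small_panel):
        design = build_study_design(small_panel)
        pool_a = small_panel.pool_members("A")[0].mirna_id
        pool_b = small_panel.pool_members("B")[0].mirna_id
        assert design.copies("dil_1", pool_a) == pytest.approx(5000.0)
        assert design.copies("dil_1", pool_b) == pytest.approx(20000.0)
        assert design.copies("dil_5", pool_a) == pytest.approx(0.5)
        assert design.copies("dil_5", pool_b) == pytest.approx(2.0)

    def test_study_determinism_is_byte_identical(self, small_panel, small_catalogs,
                                                 profiles, small_homology):
        def dump(study):
            out = {}
            for name, table in study.tables.items():
                buf = io.StringIO()
                write_ct_table(table, buf)
                out[name] = buf.getvalue()
            return out

        s1 = simulate_study(small_panel, small_catalogs, profiles, seed=42,
                            n_endogenous=10, homology=small_homology)
        s2 = simulate_study(small_panel, small_catalogs, profiles, seed=42,
                            n_endogenous=10, homology=small_homology)
        assert dump(s1) == dump(s2)
        assert s1.endogenous_ids == s2.endogenous_ids

    def test_all_tables_pass_validation(self, small_study):
        for table in small_study.tables.values():
            table.validate()  # raises on any invariant violation
            assert set(DILUTION_POINTS) <= set(table.samples)


class TestPanelFactory:
    def test_pool_counts_and_length(self):
        panel = make_panel(n_pool_a=10, n_pool_b=8, length=21, seed=3)
        assert panel.pool_counts() == {"A": 10, "B": 8}
        assert all(len(sp.sequence) == 21 for sp in panel)

    def test_planted_pairs_are_homologous(self):
        panel = make_panel(n_pool_a=6, n_pool_b=6, seed=3,
                           planted_homolog_pairs=2, planted_mismatches=2)
        species = list(panel)
        for k in range(2):
            s = align_pair(species[2 * k].sequence, species[2 * k + 1].sequence)
            assert s.mismatches == 2

    def test_unplanted_panel_is_mutually_nonhomologous(self, small_panel):
        from mirspike.homology import is_homologous

        species = list(small_panel)
        for i in range(0, len(species), 5):
            for j in range(i + 1, len(species)):
                s = align_pair(species[i].sequence, species[j].sequence)
                assert not is_homologous(s)


def test_params_validation():
    with pytest.raises(ValidationError):
        SimulatorParams(background_rate=1.2)
    with pytest.raises(ValidationError):
        SimulatorParams(noise_sd=-0.1)
    with pytest.raises(ValidationError):
        SimulatorParams(efficiency=0.0)
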
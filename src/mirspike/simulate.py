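"""Parametric generator of Ct tables with the structure the analysis assumes.

The generator emulates a spike-in benchmarking study end to end:

* a panel of synthetic miRNAs in two pools (default 88 + 86), mixed 4:1 and
  1:4 into two samples so every miRNA differs four-fold (expected ΔCt ±2);
* spiked plasma samples adding endogenous miRNAs of unknown abundance;
* a five-point 10-fold dilution series of spiked sample #1;
* a no-RT control carrying only template-independent background signals;
* duplicate replicates per sample (two RT + qPCR reactions).

The Ct model is the standard log-linear one: Ct = ct_at_ref −
log(copies/ref_copies)/log(1+efficiency) − preamp_cycles, plus Gaussian
cycle noise.  Stochastic dropout at low input is mechanistic: the template
molecules that actually enter a well are Poisson-distributed with mean
equal to the nominal copies, so the detected fraction at mean λ is bounded
by 1 − e^(−λ).  Cross-reactive amplification adds, per sequence homolog of
the assay's target, ``copies × crossreact_base_fraction ×
10^(−penalty × mismatches)`` effective template.  Pre-amplification is a
pure Ct offset.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .homology import AlignmentParams, HomologyMap, build_homology_map
from .io import write_catalog, write_ct_table, write_design, write_panel
from .linearity import DilutionSeries
from .model import (
    AssayCatalog,
    AssayRecord,
    CtTable,
    MiRNAPanel,
    MiRNASpecies,
    PlatformConfig,
    SpikeDesign,
    ValidationError,
)

__all__ = [
    "SimulatorParams",
    "PlatformProfile",
    "SimulatedStudy",
    "HIGH_COPIES",
    "LOW_COPIES",
    "SAMPLE_ROSTER",
    "DILUTION_POINTS",
    "expected_ct",
    "effective_template",
    "simulate_ct_table",
    "make_panel",
    "make_catalog",
    "default_catalogs",
    "default_profiles",
    "build_study_design",
    "simulate_study",
    "write_study",
]

#: Copies per reaction of the high- and low-abundance pool in each sample.
HIGH_COPIES = 1.0e6
LOW_COPIES = 0.25e6

#: Scaling from the low-abundance pool (0.25e6 copies) to the top dilution
#: point (5000 copies per PCR), i.e. 5000/20000 pool A/B at point 1 down to
#: 0.5/2 at point 5.
DILUTION_TOP_FACTOR = 5000.0 / LOW_COPIES

DILUTION_POINTS = ["dil_1", "dil_2", "dil_3", "dil_4", "dil_5"]
SAMPLE_ROSTER = [
    "synthetic_1",
    "synthetic_2",
    "spiked_plasma_1",
    "spiked_plasma_2",
    "plasma",
    "no_rt",
    *DILUTION_POINTS,
]


@dataclass(frozen=True)
class SimulatorParams:
    """Tunable parameters of the Ct generator (defaults in cycles/copies).

    ct_at_ref / ref_copies
        Anchor of the log-linear Ct model: Ct 20 at 1e6 copies.
    efficiency
        Per-cycle amplification factor minus one, in (0, 1].
    noise_sd
        Gaussian cycle noise per well (0.3 cycles covers RT + qPCR).
    preamp_cycles
        Cycles of pre-amplification, subtracted from every Ct.
    crossreact_base_fraction / crossreact_log10_penalty_per_mismatch
        Cross-reaction weight at 0 mismatches and its 10-fold decay per
        additional mismatch.
    background_rate / background_ct_range
        Probability per well of a template-independent signal, and the Ct
        range in which it appears.
    outlier_well_rate / outlier_shift
        Rate of sporadic poorly amplifying wells; shift in cycles, or None
        to render the well undetected.
    occupancy_dropout
        Draw the template molecules per well from Poisson(copies).
    """

    ct_at_ref: float = 20.0
    ref_copies: float = 1.0e6
    efficiency: float = 1.0
    noise_sd: float = 0.3
    preamp_cycles: int = 0
    crossreact_log10_penalty_per_mismatch: float = 1.0
    crossreact_base_fraction: float = 0.5
    background_rate: float = 0.05
    background_ct_range: tuple[float, float] = (38.0, 40.0)
    outlier_well_rate: float = 0.0
    outlier_shift: float | None = 6.0
    occupancy_dropout: bool = True
    max_cycles: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossreact_base_fraction", "background_rate", "outlier_well_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 < self.efficiency <= 1.0):
            raise ValidationError("efficiency must be in (0, 1]")


@dataclass(frozen=True)
class PlatformProfile:
    """A simulator parameter set plus the matching detection config."""

    sim: SimulatorParams
    config: PlatformConfig


def default_profiles(seed: int = 0) -> dict[str, PlatformProfile]:
    """Two platform profiles emulating the study's qRT-PCR platforms.

    ``mircury_like``: no pre-amplification, detection threshold Ct 38, and
    a ~10% per-well no-RT background rate (66 of 689 assays).
    ``taqman_like``: 12 cycles of pre-amplification, threshold Ct 30, and
    essentially no template-independent background.
    No claims about the real products' parameters are implied.
    """
    return {
        "mircury_like": PlatformProfile(
            SimulatorParams(background_rate=66.0 / 689.0, seed=seed),
            PlatformConfig(38.0, 40.0),
        ),
        "taqman_like": PlatformProfile(
            SimulatorParams(background_rate=0.0, preamp_cycles=12, seed=seed),
            PlatformConfig(30.0, 40.0),
        ),
    }


def expected_ct(copies: float | np.ndarray, params: SimulatorParams):
    """Noise-free Ct of a well containing ``copies`` template molecules."""
    copies = np.asarray(copies, dtype=float)
    if np.any(copies <= 0):
        raise ValidationError("expected_ct requires copies > 0")
    ct = (
        params.ct_at_ref
        - np.log(copies / params.ref_copies) / np.log(1.0 + params.efficiency)
        - params.preamp_cycles
    )
    return float(ct) if ct.ndim == 0 else ct


def effective_template(
    assay: AssayRecord,
    sample_id: str,
    design: SpikeDesign,
    homology_map: HomologyMap,
    params: SimulatorParams,
) -> float:
    """Copies available to an assay: its own target plus homolog leakage."""
    total = 0.0
    if assay.target_mirna_id is not None:
        total += design.copies(sample_id, assay.target_mirna_id)
    for mirna_id, summary in homology_map.homologs(assay.assay_id):
        c = design.copies(sample_id, mirna_id)
        if c > 0:
            total += (
                c
                * params.crossreact_base_fraction
                * 10.0 ** (-params.crossreact_log10_penalty_per_mismatch * summary.mismatches)
            )
    return total


def simulate_ct_table(
    design: SpikeDesign,
    catalog: AssayCatalog,
    homology_map: HomologyMap,
    params: SimulatorParams,
    samples: Iterable[str] | None = None,
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
) -> CtTable:
    """Simulate one Ct table over ``samples`` (default: design samples).

    Per well: template molecules are Poisson(effective template) when
    occupancy dropout is on; empty wells are undetected unless a background
    signal fires; occupied wells get the log-linear Ct plus Gaussian noise;
    sporadic outlier wells are shifted (or dropped); any Ct beyond
    ``max_cycles`` becomes undetected.  Bit-identical for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    samples = list(samples) if samples is not None else design.samples
    records = list(catalog)
    n = len(records)
    frames = []
    for sample in samples:
        lam = np.array(
            [effective_template(rec, sample, design, homology_map, params) for rec in records]
        )
        for rep in range(1, n_replicates + 1):
            occ = rng.poisson(lam).astype(float) if params.occupancy_dropout else lam.copy()
            bg_u = rng.random(n)
            lo, hi = params.background_ct_range
            bg_ct = rng.uniform(lo, hi, n)
            noise = rng.normal(0.0, params.noise_sd, n)
            out_u = rng.random(n)
            ct = np.full(n, np.nan)
            occupied = occ > 0
            if occupied.any():
                ct[occupied] = expected_ct(occ[occupied], params) + noise[occupied]
            background = ~occupied & (bg_u < params.background_rate)
            ct[background] = bg_ct[background]
            if params.outlier_well_rate > 0:
                hit = (out_u < params.outlier_well_rate) & ~np.isnan(ct)
                if params.outlier_shift is None:
                    ct[hit] = np.nan
                else:
                    ct[hit] += params.outlier_shift
            ct[ct > params.max_cycles] = np.nan
            ct = np.maximum(ct, 0.01)  # Ct is by definition positive
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "replicate_id": f"r{rep}",
                        "assay_id": [rec.assay_id for rec in records],
                        "ct": ct,
                    }
                )
            )
    return CtTable(pd.concat(frames, ignore_index=True), max_cycles=params.max_cycles)


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _nonhomologous_seq(
    rng: np.random.Generator,
    length: int,
    existing: list[str],
    align_params: AlignmentParams,
    max_tries: int = 200,
) -> str:
    """Random sequence rejected until non-homologous to every existing one.

    Keeps the generated homology structure fully controlled: only planted
    homolog pairs pass the screen, never accidental ones (random same-length
    pairs do clear the default mismatch/overhang bound at a non-negligible
    rate).
    """
    from .homology import align_pair, is_homologous

    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if all(
            not is_homologous(align_pair(seq, other, align_params), align_params)
            for other in existing
        ):
            return seq
    raise ValidationError("could not generate a non-homologous sequence")


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Apply k substitutions at interior positions (>= 2 bases from ends).

    Interior placement guarantees the local alignment keeps the substituted
    positions as mismatches instead of trimming them into overhangs.
    """
    L = len(seq)
    if k > L - 4:
        raise ValidationError(f"cannot place {k} interior substitutions in length {L}")
    positions = rng.choice(np.arange(2, L - 2), size=k, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def make_panel(
    n_pool_a: int = 88,
    n_pool_b: int = 86,
    length: int = 22,
    seed: int = 7,
    planted_homolog_pairs: int = 0,
    planted_mismatches: int = 1,
) -> MiRNAPanel:
    """Random miRNA panel with pool labels and controlled pairwise homology.

    Members are mutually non-homologous by construction (rejection
    sampling against the default homology bound), so the panel's homology
    structure is fully controlled; ``planted_homolog_pairs`` optionally
    replaces the sequence of every (2k+1)-th member with a
    ``planted_mismatches``-substitution copy of the preceding member,
    creating known intra-panel homologs.
    """
    rng = np.random.default_rng(seed)
    align_params = AlignmentParams()
    sequences: list[str] = []
    species = []
    for i in range(n_pool_a + n_pool_b):
        pool = "A" if i < n_pool_a else "B"
        seq = _nonhomologous_seq(rng, length, sequences, align_params)
        sequences.append(seq)
        species.append(MiRNASpecies(f"syn-mir-{i + 1:03d}", seq, pool))
    for k in range(planted_homolog_pairs):
        i = 2 * k + 1
        if i >= len(species):
            break
        donor = species[i - 1]
        species[i] = MiRNASpecies(
            species[i].mirna_id,
            _mutate(rng, donor.sequence, planted_mismatches),
            species[i].pool,
        )
    return MiRNAPanel(species)


def make_catalog(
    panel: MiRNAPanel,
    platform_id: str,
    covered_ids: Iterable[str],
    homolog_counts: Mapping[int, int],
    n_random_offtarget: int,
    rng: np.random.Generator,
    offtarget_length: int = 22,
) -> AssayCatalog:
    """One platform's assay catalog.

    ``covered_ids``: panel miRNAs with a matching assay.  Off-target assays
    (targets absent from the panel) come in two kinds: planted homologs of
    random panel members at a given mismatch distance (``homolog_counts``
    maps mismatches -> count; distance 0 means an identical core with a
    one-base terminal trim), and fully random sequences.
    """
    records = []
    for mid in covered_ids:
        sp = panel[mid]
        records.append(
            AssayRecord(f"{platform_id}:{mid}", platform_id, mid, sp.sequence)
        )
    panel_ids = panel.ids
    for mm in sorted(homolog_counts):
        for i in range(homolog_counts[mm]):
            donor = panel[panel_ids[int(rng.integers(len(panel_ids)))]]
            if mm == 0:
                seq = donor.sequence[:-1]
            else:
                seq = _mutate(rng, donor.sequence, mm)
            tid = f"off-{platform_id}-hom{mm}-{i + 1:02d}"
            records.append(AssayRecord(f"{platform_id}:{tid}", platform_id, tid, seq))
    panel_seqs = [sp.sequence for sp in panel]
    align_params = AlignmentParams()
    for i in range(n_random_offtarget):
        tid = f"off-{platform_id}-rnd-{i + 1:03d}"
        records.append(
            AssayRecord(
                f"{platform_id}:{tid}", platform_id, tid,
                _nonhomologous_seq(rng, offtarget_length, panel_seqs, align_params),
            )
        )
    return AssayCatalog(records)


#: Homologous off-target assay counts per mismatch distance, one third of
#: the study-scale numbers per platform.
DEFAULT_HOMOLOG_COUNTS = {
    "mircury_like": {0: 1, 1: 6, 2: 11, 3: 17, 4: 20},
    "taqman_like": {0: 1, 1: 6, 2: 10, 3: 15, 4: 19},
}


def default_catalogs(
    panel: MiRNAPanel,
    seed: int = 0,
    n_offtarget_total: int = 120,
    coverage: Mapping[str, int] | None = None,
    n_common: int = 125,
) -> dict[str, AssayCatalog]:
    """Catalogs for the two default profiles.

    Panel coverage mirrors the study's bookkeeping at full scale (143 and
    155 of 174 panel miRNAs, 125 on both platforms) and is shrunk
    proportionally for smaller panels.
    """
    coverage = dict(coverage or {"mircury_like": 143, "taqman_like": 155})
    scale = len(panel) / 174.0
    if scale != 1.0:
        coverage = {k: max(1, round(v * scale)) for k, v in coverage.items()}
        n_common = max(0, min(round(n_common * scale), min(coverage.values())))
    # distinct stream key: a panel built from the same integer seed must not
    # share the catalog's random draws (shifted sequence replays otherwise)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCA7]))
    ids = list(panel.ids)
    rng.shuffle(ids)
    common = ids[:n_common]
    rest = ids[n_common:]
    catalogs = {}
    offset = 0
    for name in sorted(coverage):
        extra = coverage[name] - n_common
        own = common + rest[offset : offset + extra]
        offset += extra
        hom = DEFAULT_HOMOLOG_COUNTS.get(name, {1: 5, 2: 10, 3: 15, 4: 20})
        if scale != 1.0:
            hom = {k: max(1, round(v * scale)) for k, v in hom.items()}
        n_random = max(0, round(n_offtarget_total * scale) - sum(hom.values()))
        catalogs[name] = make_catalog(panel, name, sorted(own), hom, n_random, rng)
    return catalogs


def build_study_design(
    panel: MiRNAPanel,
    endogenous_copies: Mapping[str, float] | None = None,
    high_copies: float = HIGH_COPIES,
    low_copies: float = LOW_COPIES,
    dilution_top_factor: float = DILUTION_TOP_FACTOR,
    dilution_factor: float = 10.0,
    n_dilution_points: int = 5,
) -> SpikeDesign:
    """The full-study spike design.

    Sample #1 carries pool A at the low and pool B at the high copy number,
    sample #2 the reverse, so every panel miRNA differs four-fold between
    the samples.  Spiked plasma samples add the endogenous content; the
    dilution series scales spiked sample #1 down to 5000/20000 (pool A/B)
    copies per PCR at the top point and 10-fold per step after that.
    """
    entries: dict[tuple[str, str], float] = {}
    for sp in panel:
        low_in_1 = sp.pool == "A"
        entries[("synthetic_1", sp.mirna_id)] = low_copies if low_in_1 else high_copies
        entries[("synthetic_2", sp.mirna_id)] = high_copies if low_in_1 else low_copies
        entries[("spiked_plasma_1", sp.mirna_id)] = entries[("synthetic_1", sp.mirna_id)]
        entries[("spiked_plasma_2", sp.mirna_id)] = entries[("synthetic_2", sp.mirna_id)]
    for mid, c in (endogenous_copies or {}).items():
        for s in ("spiked_plasma_1", "spiked_plasma_2", "plasma"):
            entries[(s, mid)] = c
    base = {m: c for (s, m), c in entries.items() if s == "spiked_plasma_1"}
    for k in range(n_dilution_points):
        factor = dilution_top_factor / dilution_factor**k
        for m, c in base.items():
            entries[(f"dil_{k + 1}", m)] = c * factor
    return SpikeDesign(entries)


@dataclass
class SimulatedStudy:
    """All tables of a simulated study plus the ground truth behind them."""

    panel: MiRNAPanel
    catalogs: dict[str, AssayCatalog]
    profiles: dict[str, PlatformProfile]
    design: SpikeDesign
    homology: dict[str, HomologyMap]
    tables: dict[str, CtTable]
    seed: int
    endogenous_ids: list[str] = field(default_factory=list)

    def dilution_series(self, platform: str) -> DilutionSeries:
        return DilutionSeries(self.tables[platform], list(DILUTION_POINTS), self.design)

    def no_rt(self, platform: str) -> CtTable:
        return self.tables[platform].sample("no_rt")


def simulate_study(
    panel: MiRNAPanel,
    catalogs: Mapping[str, AssayCatalog],
    profiles: Mapping[str, PlatformProfile],
    seed: int,
    n_endogenous: int = 60,
    endogenous_copy_range: tuple[float, float] = (1.0e2, 1.0e5),
    alignment_params: AlignmentParams | None = None,
    n_replicates: int = 2,
    homology: Mapping[str, HomologyMap] | None = None,
) -> SimulatedStudy:
    """Simulate the full sample roster for every platform profile.

    Endogenous plasma content is a random subset of the off-target assay
    targets with log-uniform copies per reaction.  Precomputed homology
    maps can be passed to skip the alignment screen (it is deterministic in
    the catalog and panel).
    """
    if set(catalogs) != set(profiles):
        raise ValidationError("catalogs and profiles must cover the same platforms")
    ss = np.random.SeedSequence(seed)
    endo_rng = np.random.default_rng(ss.spawn(1)[0])
    offtargets = sorted(
        {
            rec.target_mirna_id
            for cat in catalogs.values()
            for rec in cat
            if rec.target_mirna_id is not None and rec.target_mirna_id not in panel
        }
    )
    n_endo = min(n_endogenous, len(offtargets))
    endo_ids = sorted(
        endo_rng.choice(np.array(offtargets), size=n_endo, replace=False).tolist()
    ) if n_endo else []
    lo, hi = np.log10(endogenous_copy_range[0]), np.log10(endogenous_copy_range[1])
    endo_copies = {
        mid: float(10.0 ** endo_rng.uniform(lo, hi)) for mid in endo_ids
    }
    design = build_study_design(panel, endo_copies)
    hom = dict(homology) if homology else {}
    tables = {}
    for name in sorted(catalogs):
        if name not in hom:
            hom[name] = build_homology_map(catalogs[name], panel, alignment_params)
        table_rng = np.random.default_rng(ss.spawn(1)[0])
        tables[name] = simulate_ct_table(
            design,
            catalogs[name],
            hom[name],
            profiles[name].sim,
            samples=SAMPLE_ROSTER,
            n_replicates=n_replicates,
            rng=table_rng,
        )
    return SimulatedStudy(
        panel=panel,
        catalogs=dict(catalogs),
        profiles=dict(profiles),
        design=design,
        homology=hom,
        tables=tables,
        seed=seed,
        endogenous_ids=list(endo_ids),
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Write a study directory: panel, catalogs, design, Ct tables, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_panel(study.panel, outdir / "panel.fa")
    write_design(study.design, outdir / "design.tsv")
    for name in sorted(study.catalogs):
        write_catalog(study.catalogs[name], outdir / f"catalog_{name}.tsv")
        write_ct_table(study.tables[name], outdir / f"ct_{name}.tsv")
        study.homology[name].write_tsv(outdir / f"homology_{name}.tsv", study.catalogs[name])
    truth = {
        "seed": study.seed,
        "samples": SAMPLE_ROSTER,
        "endogenous_ids": study.endogenous_ids,
        "profiles": {
            name: {
                "sim": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(prof.sim).items()
                },
                "config": asdict(prof.config),
            }
            for name, prof in study.profiles.items()
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
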
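"""Sequence-homology screening between assay targets and panel miRNAs.

Mature miRNAs can differ by a single nucleotide, so an assay can amplify a
close homolog of its intended target.  The screen aligns every assay target
sequence against every panel miRNA with a Smith-Waterman local alignment and
calls the pair homologous when the best alignment has at most
``max_mismatches`` differences (substitutions plus, by default, indel
positions inside the aligned core) and at most ``max_overhang`` unaligned
terminal bases at each end.  Defaults: up to 4 mismatches and 8-nt
overhangs, bounds inclusive.

No thermodynamic (ΔG/Tm) modeling — the screen is purely sequence-count
based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from . import _align
from .model import (
    AssayCatalog,
    MiRNAPanel,
    UndefinedFractionError,
    ValidationError,
    normalize_sequence,
)

__all__ = [
    "AlignmentParams",
    "AlignmentSummary",
    "HomologyMap",
    "align_pair",
    "is_homologous",
    "build_homology_map",
    "expected_homology_fraction",
    "homology_fraction_pct",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and bound parameters of the homology screen.

    ``gap_score=None`` disables gaps entirely (the alignment becomes a pure
    offset slide).  ``count_indels_as_mismatches`` controls whether internal
    indel positions count toward the mismatch bound (default: they do).
    """

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float | None = -1.0
    max_mismatches: int = 4
    max_overhang: int = 8
    count_indels_as_mismatches: bool = True

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValidationError("match_score must be > 0")
        if self.max_mismatches < 0 or self.max_overhang < 0:
            raise ValidationError("bounds must be >= 0")


@dataclass(frozen=True)
class AlignmentSummary:
    """Summary of the best local alignment of a sequence pair.

    ``mismatches`` counts substitutions (plus internal indel positions under
    the default parameters) inside the aligned core; ``overhang_left`` /
    ``overhang_right`` count the unaligned terminal bases of both sequences
    at the respective end; ``aligned_length`` is the number of alignment
    columns.
    """

    mismatches: int
    overhang_left: int
    overhang_right: int
    aligned_length: int
    score: float


def align_pair(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> AlignmentSummary:
    """Best-scoring local alignment summary of two nucleotide sequences.

    Ties between equal-scoring alignments are broken by fewest mismatches,
    then smallest total overhang (largest aligned span), then first end
    position in row-major order — deterministic output.

    When no positive-scoring alignment exists the empty alignment is
    reported with both overhangs set to ``max(len(a), len(b))`` so that it
    never passes a realistic homology bound.
    """
    params = params or AlignmentParams()
    seq_a = normalize_sequence(seq_a)
    seq_b = normalize_sequence(seq_b)
    if not seq_a or not seq_b:
        raise ValidationError("align_pair requires non-empty sequences")
    gap = _align.GAP_DISABLED if params.gap_score is None else float(params.gap_score)
    score, mis, span, cols, end_i, end_j = _align.sw_summary(
        _align.encode(seq_a),
        _align.encode(seq_b),
        float(params.match_score),
        float(params.mismatch_score),
        gap,
        params.count_indels_as_mismatches,
    )
    n, m = len(seq_a), len(seq_b)
    if cols == 0:
        far = max(n, m)
        return AlignmentSummary(0, far, far, 0, 0.0)
    left = (end_i + end_j) - span  # start_a + start_b
    right = (n - end_i) + (m - end_j)
    return AlignmentSummary(int(mis), int(left), int(right), int(cols), float(score))


def is_homologous(summary: AlignmentSummary, params: AlignmentParams | None = None) -> bool:
    """Inclusive mismatch/overhang bound: <= 4 mismatches, <= 8 nt per end."""
    params = params or AlignmentParams()
    return (
        summary.mismatches <= params.max_mismatches
        and summary.overhang_left <= params.max_overhang
        and summary.overhang_right <= params.max_overhang
    )


class HomologyMap:
    """Per assay, the panel miRNAs within the homology bound.

    An assay's own intended target is excluded — entries model potential
    cross-reaction, not intended detection.
    """

    def __init__(self, entries: Mapping[str, list[tuple[str, AlignmentSummary]]],
                 params: AlignmentParams):
        self._entries = {k: list(v) for k, v in entries.items()}
        self.params = params

    def homologs(self, assay_id: str) -> list[tuple[str, AlignmentSummary]]:
        return self._entries.get(assay_id, [])

    def assay_ids(self) -> list[str]:
        return sorted(self._entries)

    def has_homolog_in(self, assay_id: str, present: set[str]) -> bool:
        return any(m in present for m, _ in self.homologs(assay_id))

    def min_mismatches_to(self, assay_id: str, present: set[str]) -> int | None:
        mm = [s.mismatches for m, s in self.homologs(assay_id) if m in present]
        return min(mm) if mm else None

    def write_tsv(self, path: str | Path, catalog: AssayCatalog) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["assay_id", "platform_id", "homolog_mirna_id", "mismatches",
                 "overhang_left", "overhang_right"]
            )
            for assay_id in self.assay_ids():
                platform = catalog[assay_id].platform_id if assay_id in catalog else ""
                for mirna_id, s in self.homologs(assay_id):
                    writer.writerow(
                        [assay_id, platform, mirna_id, s.mismatches,
                         s.overhang_left, s.overhang_right]
                    )


def build_homology_map(
    catalog: AssayCatalog, panel: MiRNAPanel, params: AlignmentParams | None = None
) -> HomologyMap:
    """Screen every assay against every panel miRNA.

    Entries are ordered by mismatch count, then miRNA id.  The assay's own
    target (matched by id) is never listed.
    """
    params = params or AlignmentParams()
    if len(catalog) == 0 or len(panel) == 0:
        raise ValidationError("catalog and panel must be non-empty")
    entries: dict[str, list[tuple[str, AlignmentSummary]]] = {}
    for rec in catalog:
        hits = []
        for sp in panel:
            if rec.target_mirna_id is not None and sp.mirna_id == rec.target_mirna_id:
                continue
            summary = align_pair(rec.target_sequence, sp.sequence, params)
            if is_homologous(summary, params):
                hits.append((sp.mirna_id, summary))
        hits.sort(key=lambda t: (t[1].mismatches, t[0]))
        entries[rec.assay_id] = hits
    return HomologyMap(entries, params)


def homology_fraction_pct(n_homologous: int, n_potential_fp: int) -> int:
    """Expected homology fraction as the rounded integer percentage."""
    if n_potential_fp == 0:
        raise UndefinedFractionError("no potential false positives")
    return round(100.0 * n_homologous / n_potential_fp)


def expected_homology_fraction(
    catalog: AssayCatalog,
    panel: MiRNAPanel,
    sample_mirnas: Iterable[str],
    params: AlignmentParams | None = None,
    homology_map: HomologyMap | None = None,
) -> tuple[int, int, float]:
    """Expected fraction of false positives attributable to homology.

    Potential false positives are the assays whose intended target is not in
    the sample; of those, the homologous ones have at least one homolog
    among the present miRNAs.  Returns
    ``(n_potential_fp, n_homologous, fraction)``.
    """
    present = set(sample_mirnas)
    if homology_map is None:
        homology_map = build_homology_map(catalog, panel, params)
    potential = [
        rec.assay_id
        for rec in catalog
        if rec.target_mirna_id is None or rec.target_mirna_id not in present
    ]
    if not potential:
        raise UndefinedFractionError("no assay targets an absent miRNA")
    n_hom = sum(1 for a in potential if homology_map.has_homolog_in(a, present))
    return len(potential), n_hom, n_hom / len(potential)
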
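"""Specificity: false-positive-rate curves over Ct detection thresholds.

With a sample of known content, any assay whose intended target is absent
but which still yields a signal below a candidate detection threshold is a
false positive; absent-target assays without such a signal are true
negatives.  The false positive rate FP / (FP + TN) equals 1 − specificity
and is non-decreasing in the threshold.

False positives are attributed to cross-reaction when the assay has a
sequence homolog (per the homology screen) among the miRNAs actually in the
sample, and the homology-related count is tested for enrichment against the
expected fraction with a Poisson (or binomial) upper tail.  Stratifying the
absent-target assays by their minimum mismatch distance to a present miRNA
yields the cross-reaction tendency table.

Detection-rule conventions: false-positive counting uses ``any_replicate``
(a single stray replicate signal is a false positive); "n detected"
summaries elsewhere use ``all_replicates``.  Both live in
:class:`~mirspike.model.PlatformConfig`.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AssayCatalog, CtTable, PlatformConfig, SpikeDesign
from .homology import HomologyMap
from .stats import TestResult, count_tail

__all__ = [
    "detect_calls",
    "fp_rate_curve",
    "suggest_threshold",
    "enrichment_test",
    "mismatch_stratified_fp",
    "fp_rate_pct",
]

logger = logging.getLogger(__name__)


def detect_calls(ct: CtTable, sample_id: str, config: PlatformConfig) -> pd.DataFrame:
    """Per-assay detection calls for one sample.

    Returns a DataFrame indexed by assay_id with columns ``detected`` and
    ``representative_ct`` (min numeric Ct under ``any_replicate``, mean of
    the replicate Cts under ``all_replicates``; NaN when undetected).
    """
    wide = ct.pivot_replicates(sample_id)
    t = config.detection_threshold_ct
    below = wide.le(t)  # NaN compares False
    if config.detection_rule == "any_replicate":
        detected = below.any(axis=1)
        rep = wide.min(axis=1)
    else:
        detected = below.all(axis=1) & wide.notna().all(axis=1)
        rep = wide.mean(axis=1)
    rep = rep.where(detected, np.nan)
    return pd.DataFrame({"detected": detected, "representative_ct": rep})


def _absent_target_assays(catalog: AssayCatalog, present: set[str]) -> list[str]:
    return [
        rec.assay_id
        for rec in catalog
        if rec.target_mirna_id is None or rec.target_mirna_id not in present
    ]


def fp_rate_curve(
    ct: CtTable,
    sample_id: str,
    design: SpikeDesign,
    catalog: AssayCatalog,
    thresholds: Sequence[float],
    homology: HomologyMap,
) -> pd.DataFrame:
    """False-positive counts and rates over a sweep of detection thresholds.

    One row per threshold: ``threshold, n_false_positive, n_true_negative,
    fp_rate, n_homology_related``.  FP + TN is the absent-target assay count
    and is constant across thresholds.  Assays measured in the table but
    missing from the catalog are excluded with a warning.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    present = design.present_mirnas(sample_id)
    wide = ct.pivot_replicates(sample_id)
    unknown = [a for a in wide.index if a not in catalog]
    if unknown:
        logger.warning(
            "%d assay(s) in the Ct table are absent from the catalog and were "
            "excluded: %s", len(unknown), ", ".join(sorted(unknown)[:5]),
        )
        wide = wide.drop(index=unknown)
    absent = _absent_target_assays(catalog, present)
    min_ct = wide.min(axis=1).reindex(absent)  # NaN -> never detected
    homologous = np.array([homology.has_homolog_in(a, present) for a in absent])
    rows = []
    for t in thresholds:
        fp_mask = (min_ct <= t).to_numpy()
        n_fp = int(fp_mask.sum())
        rows.append(
            {
                "threshold": float(t),
                "n_false_positive": n_fp,
                "n_true_negative": len(absent) - n_fp,
                "fp_rate": n_fp / len(absent) if absent else np.nan,
                "n_homology_related": int((fp_mask & homologous).sum()),
            }
        )
    return pd.DataFrame(rows)


def suggest_threshold(
    no_rt: CtTable | None, quantile: float, config: PlatformConfig
) -> float:
    """Detection threshold from no-RT control signals.

    Takes the given lower quantile of the numeric no-RT Cts and floors it to
    a whole cycle, so essentially all template-independent signals land
    above the threshold.  With no numeric no-RT signal at all the full run
    length is usable and ``max_cycles`` is returned.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")
    if no_rt is None:
        return config.max_cycles
    values = no_rt.df["ct"].dropna().to_numpy()
    if len(values) == 0:
        return config.max_cycles
    return float(math.floor(np.quantile(values, quantile)))


def enrichment_test(
    n_homology_fp: int, n_fp: int, expected_fraction: float, mode: str = "poisson"
) -> TestResult:
    """Are homology-related false positives enriched above expectation?

    Upper-tail probability of observing at least ``n_homology_fp`` homology
    related false positives among ``n_fp`` under the expected fraction;
    Poisson mode uses lambda = n_fp * expected_fraction, binomial mode uses
    Binomial(n_fp, expected_fraction).
    """
    if not (0 <= n_homology_fp <= n_fp):
        raise ValueError("need 0 <= n_homology_fp <= n_fp")
    if not (0.0 < expected_fraction < 1.0):
        raise ValueError("expected_fraction must be in (0, 1)")
    if n_fp == 0:
        logger.warning("enrichment_test with zero false positives: p = 1.0")
        return TestResult(0.0, 1.0, f"count_tail_{mode}", "one")
    if mode == "poisson":
        p = count_tail(n_homology_fp, "poisson", lam=n_fp * expected_fraction)
    elif mode == "binomial":
        p = count_tail(n_homology_fp, "binomial", n=n_fp, p=expected_fraction)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(float(n_homology_fp), p, f"count_tail_{mode}", "one")


def fp_rate_pct(n_false_positive: int, n_assays: int) -> int:
    """False positive rate as nearest-integer percent (table convention)."""
    if n_assays <= 0:
        raise ValueError("n_assays must be > 0")
    return round(100.0 * n_false_positive / n_assays)


def mismatch_stratified_fp(
    ct: CtTable,
    sample_id: str,
    design: SpikeDesign,
    catalog: AssayCatalog,
    homology: HomologyMap,
    config: PlatformConfig,
) -> pd.DataFrame:
    """Cross-reaction tendency by mismatch distance.

    Absent-target assays with at least one homolog among the present miRNAs
    are grouped by their *minimum* mismatch count to any present homolog
    (each assay appears in exactly one stratum).  Per stratum: number of
    assays, number of false positives at the platform threshold, and the
    rate as integer percent.
    """
    present = design.present_mirnas(sample_id)
    calls = detect_calls(ct, sample_id, config)
    strata: dict[int, list[str]] = {}
    for assay_id in _absent_target_assays(catalog, present):
        mm = homology.min_mismatches_to(assay_id, present)
        if mm is not None:
            strata.setdefault(mm, []).append(assay_id)
    rows = []
    for mm in sorted(strata):
        assays = strata[mm]
        n_fp = int(
            calls.reindex(assays)["detected"].fillna(False).sum()
        )
        rows.append(
            {
                "mismatches": mm,
                "n_assays": len(assays),
                "n_false_positive": n_fp,
                "fp_rate_pct": fp_rate_pct(n_fp, len(assays)),
            }
        )
    return pd.DataFrame(rows, columns=["mismatches", "n_assays", "n_false_positive", "fp_rate_pct"])
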
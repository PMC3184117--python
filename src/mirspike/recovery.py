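"""Recovery: how well observed ΔCt reproduces designed fold changes.

Two samples containing the same miRNAs at four-fold different copy numbers
should differ by exactly two cycles per miRNA.  Per assay, ΔCt is the
difference between the replicate-mean Cts of the two samples, with the sign
convention ΔCt = Ct(sample_b) − Ct(sample_a): a miRNA more abundant in
sample_a amplifies earlier there, so ΔCt is positive.

An assay is excluded when any of its measurements, in either sample, is
undetected or falls beyond the detection threshold — one stray replicate
disqualifies the assay.  Summaries (n, median, interquartile range,
variance) are reported per expected-direction group, and platforms are
compared on the common assay set via Mann-Whitney (medians), a variance
ratio test (spread), and the correlation of their observed-minus-expected
residuals (whether the poorly recovered miRNAs coincide).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import (
    AssayCatalog,
    ComparisonRefusedError,
    CtTable,
    PlatformConfig,
    SpikeDesign,
    UndefinedFoldChangeError,
    expected_delta_ct,
)
from .stats import TestResult, mann_whitney_u, pearson_r, variance_ratio_test

__all__ = [
    "Excluded",
    "RecoveryComparison",
    "delta_ct_per_assay",
    "expected_deltas",
    "sign_groups",
    "recovery_summary",
    "compare_recovery",
]


@dataclass(frozen=True)
class Excluded:
    """Marker for an assay dropped from the recovery analysis."""

    reason: str

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return f"EXCLUDED({self.reason})"


def delta_ct_per_assay(
    ct: CtTable,
    sample_a: str,
    sample_b: str,
    assays: Iterable[str],
    config: PlatformConfig,
) -> dict[str, float | Excluded]:
    """ΔCt = mean(Ct of sample_b replicates) − mean(Ct of sample_a replicates).

    Excluded (with reason) when the assay is missing from either sample or
    any single measurement is undetected or beyond the detection threshold.
    """
    wide_a = ct.pivot_replicates(sample_a)
    wide_b = ct.pivot_replicates(sample_b)
    t = config.detection_threshold_ct
    out: dict[str, float | Excluded] = {}
    for assay in assays:
        if assay not in wide_a.index or assay not in wide_b.index:
            missing_in = sample_a if assay not in wide_a.index else sample_b
            out[assay] = Excluded(f"missing from sample {missing_in}")
            continue
        va = wide_a.loc[assay].to_numpy(dtype=float)
        vb = wide_b.loc[assay].to_numpy(dtype=float)
        both = np.concatenate([va, vb])
        if np.isnan(both).any():
            out[assay] = Excluded("undetected measurement")
        elif (both > t).any():
            out[assay] = Excluded(f"measurement beyond threshold {t}")
        else:
            out[assay] = float(vb.mean() - va.mean())
    return out


def expected_deltas(
    design: SpikeDesign,
    sample_a: str,
    sample_b: str,
    catalog: AssayCatalog,
    assays: Iterable[str],
) -> dict[str, float]:
    """Design-implied ΔCt per assay (skips assays with undefined fold change)."""
    out = {}
    for assay in assays:
        target = catalog[assay].target_mirna_id
        if target is None:
            continue
        try:
            out[assay] = expected_delta_ct(design, sample_a, sample_b, target)
        except UndefinedFoldChangeError:
            continue
    return out


def sign_groups(expected: Mapping[str, float]) -> dict[str, list[str]]:
    """Partition assays by the sign of their expected ΔCt (labels +, -, 0)."""
    groups: dict[str, list[str]] = {}
    for assay, e in expected.items():
        label = "+" if e > 0 else ("-" if e < 0 else "0")
        groups.setdefault(label, []).append(assay)
    return {k: sorted(v) for k, v in groups.items()}


def recovery_summary(
    deltas: Mapping[str, float | Excluded],
    groups: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-group summary: n included, median, interquartile range, variance.

    Quartiles use linear interpolation; variance uses the n−1 denominator.
    Empty groups get n_included 0 and NaN statistics.
    """
    rows = []
    for label in sorted(groups):
        values = np.array(
            [deltas[a] for a in groups[label]
             if a in deltas and not isinstance(deltas[a], Excluded)],
            dtype=float,
        )
        n = len(values)
        rows.append(
            {
                "group": label,
                "n_included": n,
                "median": float(np.median(values)) if n else np.nan,
                "iqt": float(np.subtract(*np.percentile(values, [75, 25]))) if n else np.nan,
                "variance": float(values.var(ddof=1)) if n >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_included", "median", "iqt", "variance"])


@dataclass(frozen=True)
class RecoveryComparison:
    """Between-platform recovery comparison on the common assay set.

    ``p_median`` holds one two-sided Mann-Whitney p per expected-direction
    group; ``p_variance`` is a two-sided variance-ratio test on the pooled
    observed-minus-expected residuals; ``discordance_r`` is the Pearson
    correlation of the two platforms' residuals (near zero when the poorly
    recovered miRNAs differ between platforms).
    """

    p_median: dict[str, TestResult]
    p_variance: TestResult
    discordance_r: float
    n_common: int


def compare_recovery(
    deltas_platform1: Mapping[str, float | Excluded],
    deltas_platform2: Mapping[str, float | Excluded],
    expected: Mapping[str, float],
) -> RecoveryComparison:
    """Compare two platforms' recovered ΔCt distributions.

    Restricted to assays included (non-excluded) on both platforms; refuses
    the comparison below 3 common assays.
    """
    common = sorted(
        a
        for a in expected
        if not isinstance(deltas_platform1.get(a, Excluded("absent")), Excluded)
        and not isinstance(deltas_platform2.get(a, Excluded("absent")), Excluded)
    )
    if len(common) < 3:
        raise ComparisonRefusedError(
            f"only {len(common)} common included assays (need >= 3)"
        )
    d1 = np.array([deltas_platform1[a] for a in common], dtype=float)
    d2 = np.array([deltas_platform2[a] for a in common], dtype=float)
    exp = np.array([expected[a] for a in common], dtype=float)
    p_median: dict[str, TestResult] = {}
    for label, members in sign_groups({a: expected[a] for a in common}).items():
        idx = [common.index(a) for a in members]
        if len(idx) >= 1:
            p_median[label] = mann_whitney_u(d1[idx], d2[idx])
    res1 = d1 - exp
    res2 = d2 - exp
    p_var = variance_ratio_test(res1, res2)
    r = pearson_r(res1, res2)
    return RecoveryComparison(p_median, p_var, float(r), len(common))
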
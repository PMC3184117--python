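"""Reproducibility, dilution-series sensitivity, and per-assay linearity.

Reproducibility is the Pearson correlation of the two replicate Ct vectors
of a sample over the assays detected in both replicates.  Sensitivity is
tracked along a dilution series (default: five 10-fold steps) as the number
of assays still detected at each point, compared between platforms with
Fisher's exact test.  Linearity fits no model: per assay, it is the squared
Pearson correlation of all replicate Ct measurements against log10 input
copies across the retained dilution points, with undetected measurements
imputed to the platform's detection threshold (the background level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    AssayCatalog,
    CtTable,
    MirspikeError,
    PlatformConfig,
    SpikeDesign,
    ValidationError,
    ZeroVarianceError,
)
from .stats import TestResult, fisher_exact_2x2, pearson_r

__all__ = [
    "DilutionSeries",
    "replicate_correlation",
    "dilution_detection",
    "detection_comparison",
    "assay_linearity",
]


@dataclass
class DilutionSeries:
    """An ordered dilution series of one base sample.

    ``points`` are sample ids in the Ct table, ordered from highest to
    lowest input; ``design`` gives copies per reaction for every point.
    Validates that copies decrease by ``dilution_factor`` between
    consecutive points for every miRNA present in both.
    """

    ct: CtTable
    points: list[str]
    design: SpikeDesign
    dilution_factor: float = 10.0

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValidationError("a dilution series needs at least 2 points")
        for hi, lo in zip(self.points, self.points[1:]):
            shared = self.design.present_mirnas(hi) & self.design.present_mirnas(lo)
            if not shared:
                raise ValidationError(f"points {hi} and {lo} share no miRNAs")
            for m in shared:
                ratio = self.design.copies(hi, m) / self.design.copies(lo, m)
                if not np.isclose(ratio, self.dilution_factor, rtol=1e-6):
                    raise ValidationError(
                        f"{m}: {hi} -> {lo} ratio {ratio:g} != "
                        f"dilution factor {self.dilution_factor:g}"
                    )


def _detected_wide(
    ct: CtTable,
    sample_id: str,
    config: PlatformConfig,
    restrict_assays: Iterable[str] | None,
) -> pd.DataFrame:
    """Two-replicate wide table restricted to fully detected assays."""
    wide = ct.pivot_replicates(sample_id)
    if wide.shape[1] != 2:
        raise MirspikeError(
            f"sample {sample_id}: need exactly two replicates, "
            f"found {wide.shape[1]}"
        )
    if restrict_assays is not None:
        wide = wide.loc[wide.index.intersection(set(restrict_assays))]
    detected = wide.notna().all(axis=1) & wide.le(config.detection_threshold_ct).all(axis=1)
    return wide.loc[detected]


def replicate_correlation(
    ct: CtTable,
    sample_id: str,
    config: PlatformConfig,
    restrict_assays: Iterable[str] | None = None,
) -> tuple[float | None, int]:
    """Pearson r of duplicate measurements over detected assays.

    Detection uses the ``all_replicates`` rule (both replicates numeric and
    at or below the threshold).  Returns ``(r, n_detected)``; r is ``None``
    ("na") below 3 detected assays or when a replicate vector is constant.
    """
    wide = _detected_wide(ct, sample_id, config, restrict_assays)
    n = len(wide)
    if n < 3:
        return None, n
    try:
        r = pearson_r(wide.iloc[:, 0].to_numpy(), wide.iloc[:, 1].to_numpy())
    except ZeroVarianceError:
        return None, n
    return r, n


def dilution_detection(
    series: DilutionSeries,
    config: PlatformConfig,
    restrict_assays: Iterable[str] | None = None,
    exclude_assays: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per dilution point: assays detected in both replicates, duplicate r.

    ``exclude_assays`` reproduces explicit manual outlier-well exclusions;
    no heuristic outlier removal is ever applied.
    """
    restrict = None if restrict_assays is None else set(restrict_assays)
    if exclude_assays is not None:
        if restrict is None:
            restrict = set(series.ct.assays)
        restrict -= set(exclude_assays)
    rows = []
    for point in series.points:
        r, n = replicate_correlation(series.ct, point, config, restrict)
        rows.append({"point_id": point, "n_detected": n, "r": np.nan if r is None else r})
    return pd.DataFrame(rows)


def detection_comparison(n_detected_1: int, n_detected_2: int, n_total: int) -> TestResult:
    """Two-sided Fisher's exact test of two detection counts out of n_total."""
    if not (0 <= n_detected_1 <= n_total and 0 <= n_detected_2 <= n_total):
        raise ValueError("detection counts must lie in [0, n_total]")
    return fisher_exact_2x2(
        n_detected_1, n_total - n_detected_1, n_detected_2, n_total - n_detected_2
    )


def assay_linearity(
    series: DilutionSeries,
    config: PlatformConfig,
    catalog: AssayCatalog,
    points_used: int | None = None,
    restrict_assays: Iterable[str] | None = None,
    cutoff: float = 0.9,
) -> tuple[pd.DataFrame, dict]:
    """Per-assay linearity of Ct versus log10 input copies.

    Uses the first ``points_used`` dilution points (default: all but the
    lowest, which neither platform measures acceptably).  All replicate
    measurements enter as separate observations; undetected measurements
    are imputed to the detection threshold, representing background — the
    imputed value never exceeds the threshold by construction.  Assays
    whose Ct is constant after imputation (e.g. undetected everywhere) get
    r² = 0 and are flagged.

    Returns (per-assay DataFrame with r_squared / n_points_used / flag,
    summary dict with ``n_assays_r2_ge_cutoff`` and ``cutoff``).
    """
    if points_used is None:
        points_used = len(series.points) - 1
    if not (2 <= points_used <= len(series.points)):
        raise ValueError(f"points_used must be in [2, {len(series.points)}]")
    points = series.points[:points_used]
    wides = {p: series.ct.pivot_replicates(p) for p in points}
    assays = set(series.ct.assays) if restrict_assays is None else set(restrict_assays)
    rows = []
    for assay in sorted(assays):
        if assay not in catalog or catalog[assay].target_mirna_id is None:
            continue
        target = catalog[assay].target_mirna_id
        xs: list[float] = []
        ys: list[float] = []
        for p in points:
            copies = series.design.copies(p, target)
            if copies <= 0:
                break
            wide = wides[p]
            if assay not in wide.index:
                continue
            values = wide.loc[assay].to_numpy(dtype=float)
            values = np.where(np.isnan(values), config.detection_threshold_ct, values)
            xs.extend([np.log10(copies)] * len(values))
            ys.extend(values.tolist())
        else:
            if len(xs) < 3:
                continue
            try:
                r = pearson_r(xs, ys)
                rows.append({"assay_id": assay, "r_squared": r * r,
                             "n_points_used": points_used, "flag": ""})
            except ZeroVarianceError:
                rows.append({"assay_id": assay, "r_squared": 0.0,
                             "n_points_used": points_used, "flag": "zero_variance"})
    table = pd.DataFrame(rows, columns=["assay_id", "r_squared", "n_points_used", "flag"])
    summary = {
        "cutoff": cutoff,
        "n_assays": len(table),
        "n_assays_r2_ge_cutoff": int((table["r_squared"] >= cutoff).sum()) if len(table) else 0,
    }
    return table, summary
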
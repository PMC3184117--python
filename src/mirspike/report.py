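"""Assembly of the machine-readable evaluation report.

The report is a JSON document with four sections — specificity, recovery,
reproducibility, sensitivity_linearity — plus provenance (config snapshot,
SHA-256 digests of every input file, seed if any, tool version).  Each
tabular result is stored as a list of records and can additionally be
rendered to one TSV per table.  Analysis stages are fully deterministic:
running twice on identical inputs yields identical reports.

``run_evaluate`` orchestrates the stages from a YAML config; see the
docstring for the schema.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .homology import AlignmentParams, build_homology_map, expected_homology_fraction
from .io import read_catalog, read_ct_table, read_design, read_panel
from .linearity import (
    DilutionSeries,
    assay_linearity,
    detection_comparison,
    dilution_detection,
    replicate_correlation,
)
from .model import ComparisonRefusedError, MirspikeError, PlatformConfig
from .recovery import (
    Excluded,
    compare_recovery,
    delta_ct_per_assay,
    expected_deltas,
    recovery_summary,
    sign_groups,
)
from .specificity import (
    enrichment_test,
    fp_rate_curve,
    mismatch_stratified_fp,
    suggest_threshold,
)

__all__ = ["EvaluationReport", "write_report", "read_report", "run_evaluate"]

ALL_STAGES = ["specificity", "recovery", "reproducibility", "sensitivity_linearity"]


def _sanitize(obj: Any) -> Any:
    """Make a nested structure JSON-native; NaN becomes null."""
    if isinstance(obj, Mapping):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _sanitize(obj.to_dict("records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class EvaluationReport:
    """Nested, JSON-native analysis results plus provenance."""

    sections: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"sections": _sanitize(self.sections), "provenance": _sanitize(self.provenance)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "EvaluationReport":
        return cls(sections=dict(d.get("sections", {})), provenance=dict(d.get("provenance", {})))


def _iter_tables(prefix: str, obj: Any):
    if isinstance(obj, list) and obj and all(isinstance(r, Mapping) for r in obj):
        yield prefix, obj
    elif isinstance(obj, Mapping):
        for k, v in obj.items():
            yield from _iter_tables(f"{prefix}__{k}" if prefix else str(k), v)


def write_report(report: EvaluationReport, path: str | Path, tsv_dir: str | Path | None = None) -> None:
    """Write the JSON report; optionally render every table to a TSV.

    TSV cells are numeric or the sentinel ``NA``; file names join the
    nesting path with double underscores.
    """
    path = Path(path)
    doc = report.to_dict()
    path.write_text(json.dumps(doc, indent=2, allow_nan=False) + "\n")
    if tsv_dir is not None:
        tsv_dir = Path(tsv_dir)
        tsv_dir.mkdir(parents=True, exist_ok=True)
        for name, records in _iter_tables("", doc["sections"]):
            df = pd.DataFrame(records)
            df.to_csv(tsv_dir / f"{name}.tsv", sep="\t", index=False, na_rep="NA")


def read_report(path: str | Path) -> EvaluationReport:
    return EvaluationReport.from_dict(json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve(base: Path, p: str) -> Path:
    q = Path(p)
    return q if q.is_absolute() else base / q


def _threshold_grid(spec) -> list[float]:
    if isinstance(spec, (list, tuple)) and len(spec) == 3:
        start, stop, step = map(float, spec)
        return list(np.round(np.arange(start, stop + step / 2, step), 10))
    return [float(t) for t in spec]


def _test_result_dict(res) -> dict:
    return {"statistic": res.statistic, "p_value": res.p_value,
            "method": res.method, "sidedness": res.sidedness}


def run_evaluate(config: str | Path | Mapping[str, Any]) -> EvaluationReport:
    """Run the requested stages and assemble the report.

    Config schema (YAML; paths relative to the config file)::

        panel: panel.fa                  # FASTA with pool=A/B tokens
        design: design.tsv
        platforms:
          mircury_like:
            ct: ct_mircury_like.tsv
            catalog: catalog_mircury_like.tsv
            detection_threshold_ct: 38.0
            max_cycles: 40.0
        stages: [specificity, recovery, reproducibility, sensitivity_linearity]
        homology: {max_mismatches: 4, max_overhang: 8}
        specificity:
          sample: synthetic_1
          no_rt_sample: no_rt            # optional
          thresholds: [20, 40, 0.5]      # start, stop, step (or explicit list)
          no_rt_quantile: 0.01
          enrichment_mode: poisson
        recovery: {samples: [synthetic_1, synthetic_2]}
        reproducibility:
          samples: [synthetic_1, synthetic_2, spiked_plasma_1, spiked_plasma_2, plasma]
        sensitivity_linearity:
          dilution_points: [dil_1, dil_2, dil_3, dil_4, dil_5]
          points_used: 4
          r2_cutoff: 0.9
          exclude_assays: []
        seed: null                       # recorded in provenance only
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        if not config_path.exists():
            raise FileNotFoundError(config_path)
        cfg = yaml.safe_load(config_path.read_text())
        base = config_path.parent
    else:
        cfg = dict(config)
        base = Path(cfg.get("base_dir", "."))
    stages = cfg.get("stages", ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise MirspikeError(f"unknown stage(s): {sorted(unknown)}")

    inputs: dict[str, str] = {}

    def load_path(p: str) -> Path:
        path = _resolve(base, p)
        if not path.exists():
            raise FileNotFoundError(path)
        inputs[str(path)] = _sha256(path)
        return path

    panel = read_panel(load_path(cfg["panel"]), cfg.get("panel_pools"))
    design = read_design(load_path(cfg["design"]))
    hom_cfg = cfg.get("homology", {})
    align_params = AlignmentParams(
        max_mismatches=int(hom_cfg.get("max_mismatches", 4)),
        max_overhang=int(hom_cfg.get("max_overhang", 8)),
    )

    platforms: dict[str, dict] = {}
    for name, pcfg in cfg["platforms"].items():
        config_p = PlatformConfig(
            detection_threshold_ct=float(pcfg.get("detection_threshold_ct", 38.0)),
            max_cycles=float(pcfg.get("max_cycles", 40.0)),
        )
        catalog = read_catalog(load_path(pcfg["catalog"]))
        ct = read_ct_table(load_path(pcfg["ct"]), max_cycles=config_p.max_cycles)
        platforms[name] = {
            "config": config_p,
            "catalog": catalog,
            "ct": ct,
            "homology": build_homology_map(catalog, panel, align_params),
        }

    sections: dict[str, Any] = {}
    counts_log: dict[str, Any] = {}

    if "specificity" in stages:
        scfg = cfg.get("specificity", {})
        sample = scfg.get("sample", "synthetic_1")
        thresholds = _threshold_grid(scfg.get("thresholds", [20, 40, 0.5]))
        quantile = float(scfg.get("no_rt_quantile", 0.01))
        mode = scfg.get("enrichment_mode", "poisson")
        out = {}
        for name, p in platforms.items():
            curve = fp_rate_curve(p["ct"], sample, design, p["catalog"], thresholds, p["homology"])
            present = design.present_mirnas(sample)
            n_pot, n_hom, frac = expected_homology_fraction(
                p["catalog"], panel, present, homology_map=p["homology"]
            )
            no_rt_sample = scfg.get("no_rt_sample")
            suggested = None
            if no_rt_sample is not None and no_rt_sample in p["ct"].samples:
                suggested = suggest_threshold(p["ct"].sample(no_rt_sample), quantile, p["config"])
            at_t = curve[curve["threshold"] <= p["config"].detection_threshold_ct].iloc[-1]
            enr = enrichment_test(
                int(at_t["n_homology_related"]), int(at_t["n_false_positive"]), frac, mode
            )
            per_threshold_enrichment = [
                enrichment_test(int(r["n_homology_related"]), int(r["n_false_positive"]), frac, mode).p_value
                for _, r in curve.iterrows()
            ]
            curve = curve.assign(p_enrichment=per_threshold_enrichment)
            mm_table = mismatch_stratified_fp(
                p["ct"], sample, design, p["catalog"], p["homology"], p["config"]
            )
            out[name] = {
                "sample": sample,
                "detection_threshold_ct": p["config"].detection_threshold_ct,
                "suggested_threshold": suggested,
                "expected_fraction": {
                    "n_potential_fp": n_pot, "n_homologous": n_hom, "fraction": frac,
                },
                "enrichment_at_threshold": {
                    "n_false_positive": int(at_t["n_false_positive"]),
                    "n_homology_related": int(at_t["n_homology_related"]),
                    **_test_result_dict(enr),
                },
                "curve": curve,
                "mismatch_table": mm_table,
            }
            counts_log[f"specificity:{name}:n_fp_at_threshold"] = int(at_t["n_false_positive"])
        sections["specificity"] = out

    common_targets = None
    if len(platforms) >= 2:
        target_sets = [
            {r.target_mirna_id for r in p["catalog"] if r.target_mirna_id in panel}
            for p in platforms.values()
        ]
        common_targets = sorted(set.intersection(*target_sets))

    if "recovery" in stages:
        rcfg = cfg.get("recovery", {})
        sample_a, sample_b = rcfg.get("samples", ["synthetic_1", "synthetic_2"])
        out = {}
        per_platform_deltas = {}
        expected_by_target: dict[str, float] = {}
        for name, p in platforms.items():
            assay_ids = [r.assay_id for r in p["catalog"] if r.target_mirna_id in panel]
            deltas = delta_ct_per_assay(p["ct"], sample_a, sample_b, assay_ids, p["config"])
            expected = expected_deltas(design, sample_a, sample_b, p["catalog"], assay_ids)
            groups = sign_groups(expected)
            summary = recovery_summary(deltas, groups)
            records = []
            for a in assay_ids:
                d = deltas[a]
                excluded = isinstance(d, Excluded)
                records.append(
                    {
                        "assay_id": a,
                        "target_mirna_id": p["catalog"][a].target_mirna_id,
                        "delta_ct": None if excluded else d,
                        "expected": expected.get(a),
                        "included": "N" if excluded else "Y",
                        "exclusion_reason": d.reason if excluded else "",
                    }
                )
            out[name] = {
                "sample_a": sample_a, "sample_b": sample_b,
                "per_assay": records, "summary": summary,
            }
            by_target = {
                p["catalog"][a].target_mirna_id: d for a, d in deltas.items()
            }
            per_platform_deltas[name] = by_target
            for a, e in expected.items():
                expected_by_target[p["catalog"][a].target_mirna_id] = e
            counts_log[f"recovery:{name}:n_included"] = int(summary["n_included"].sum())
        if common_targets is not None and len(platforms) == 2:
            n1, n2 = sorted(platforms)
            expected_common = {
                t: expected_by_target[t] for t in common_targets if t in expected_by_target
            }
            try:
                cmpres = compare_recovery(
                    {t: per_platform_deltas[n1].get(t, Excluded("absent")) for t in expected_common},
                    {t: per_platform_deltas[n2].get(t, Excluded("absent")) for t in expected_common},
                    expected_common,
                )
                out["comparison"] = {
                    "platform_1": n1, "platform_2": n2, "n_common": cmpres.n_common,
                    "p_median": {g: _test_result_dict(r) for g, r in cmpres.p_median.items()},
                    "p_variance": _test_result_dict(cmpres.p_variance),
                    "discordance_r": cmpres.discordance_r,
                }
            except ComparisonRefusedError as exc:
                out["comparison"] = {"refused": str(exc)}
        sections["recovery"] = out

    if "reproducibility" in stages:
        pcfg = cfg.get("reproducibility", {})
        samples = pcfg.get(
            "samples",
            ["synthetic_1", "synthetic_2", "spiked_plasma_1", "spiked_plasma_2", "plasma"],
        )
        out = {}
        for name, p in platforms.items():
            rule_cfg = p["config"].with_rule("all_replicates")
            rows = []
            for s in samples:
                if s not in p["ct"].samples:
                    continue
                r, n = replicate_correlation(p["ct"], s, rule_cfg)
                rows.append({"sample_id": s, "r": np.nan if r is None else r, "n_detected": n})
                if common_targets is not None:
                    restrict = [
                        rec.assay_id for rec in p["catalog"]
                        if rec.target_mirna_id in common_targets
                    ]
                    rc, nc = replicate_correlation(p["ct"], s, rule_cfg, restrict)
                    rows[-1]["r_common"] = np.nan if rc is None else rc
                    rows[-1]["n_detected_common"] = nc
            out[name] = rows
        sections["reproducibility"] = out

    if "sensitivity_linearity" in stages:
        lcfg = cfg.get("sensitivity_linearity", {})
        points = lcfg.get("dilution_points", ["dil_1", "dil_2", "dil_3", "dil_4", "dil_5"])
        points_used = lcfg.get("points_used")
        cutoff = float(lcfg.get("r2_cutoff", 0.9))
        exclude = lcfg.get("exclude_assays") or None
        out = {}
        per_platform_detect = {}
        per_platform_linear = {}
        for name, p in platforms.items():
            series = DilutionSeries(p["ct"], list(points), design,
                                    float(lcfg.get("dilution_factor", 10.0)))
            restrict = None
            if common_targets is not None:
                restrict = [
                    rec.assay_id for rec in p["catalog"]
                    if rec.target_mirna_id in common_targets
                ]
            det = dilution_detection(series, p["config"], restrict, exclude)
            lin_table, lin_summary = assay_linearity(
                series, p["config"], p["catalog"], points_used, restrict, cutoff
            )
            out[name] = {
                "dilution": det,
                "linearity_summary": lin_summary,
                "linearity_per_assay": lin_table,
            }
            per_platform_detect[name] = det
            per_platform_linear[name] = lin_summary
        if common_targets is not None and len(platforms) == 2:
            n1, n2 = sorted(platforms)
            n_total = len(common_targets)
            comp_rows = []
            for i, point in enumerate(points):
                d1 = int(per_platform_detect[n1]["n_detected"].iloc[i])
                d2 = int(per_platform_detect[n2]["n_detected"].iloc[i])
                res = detection_comparison(d1, d2, n_total)
                comp_rows.append(
                    {"point_id": point, f"n_detected_{n1}": d1, f"n_detected_{n2}": d2,
                     "n_total": n_total, "p_value": res.p_value}
                )
            out["detection_comparison"] = comp_rows
            lin_res = detection_comparison(
                per_platform_linear[n1]["n_assays_r2_ge_cutoff"],
                per_platform_linear[n2]["n_assays_r2_ge_cutoff"],
                n_total,
            )
            out["linearity_comparison"] = {
                f"n_linear_{n1}": per_platform_linear[n1]["n_assays_r2_ge_cutoff"],
                f"n_linear_{n2}": per_platform_linear[n2]["n_assays_r2_ge_cutoff"],
                "n_total": n_total,
                "p_value": lin_res.p_value,
            }
        sections["sensitivity_linearity"] = out

    provenance = {
        "tool": "mirspike",
        "version": __version__,
        "config": _sanitize(cfg),
        "inputs_sha256": inputs,
        "seed": cfg.get("seed"),
        "stage_counts": counts_log,
    }
    return EvaluationReport(sections=sections, provenance=provenance)
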
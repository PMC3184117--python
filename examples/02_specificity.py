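"""Specificity: false-positive rates over Ct detection thresholds.

For a sample of known content, an assay whose target is absent but which
still fires below the threshold is a false positive.  The example sweeps
thresholds, picks a threshold from the no-RT control, attributes false
positives to sequence homology, and tests that attribution for enrichment.
"""

import numpy as np

from mirspike import default_catalogs, default_profiles, make_panel, simulate_study
from mirspike.homology import expected_homology_fraction
from mirspike.specificity import (
    enrichment_test,
    fp_rate_curve,
    mismatch_stratified_fp,
    suggest_threshold,
)

panel = make_panel(seed=7)
catalogs = default_catalogs(panel, seed=7)
profiles = default_profiles()
study = simulate_study(panel, catalogs, profiles, seed=17)

for name in sorted(study.tables):
    cfg = profiles[name].config
    ct = study.tables[name]
    hmap = study.homology[name]
    suggested = suggest_threshold(ct.sample("no_rt"), 0.01, cfg)
    print(f"\n{name}: suggested Ct threshold from no-RT control = {suggested:g} "
          f"(configured {cfg.detection_threshold_ct:g})")

    thresholds = list(np.arange(24.0, 40.5, 2.0))
    curve = fp_rate_curve(ct, "synthetic_1", study.design, catalogs[name],
                          thresholds, hmap)
    print("  threshold  n_FP  FP_rate  homology-related")
    for _, row in curve.iterrows():
        print(f"  {row['threshold']:9g}  {int(row['n_false_positive']):4d}  "
              f"{row['fp_rate']:7.2f}  {int(row['n_homology_related']):4d}")

    present = study.design.present_mirnas("synthetic_1")
    n_pot, n_hom, frac = expected_homology_fraction(
        catalogs[name], panel, present, homology_map=hmap)
    at = curve[curve["threshold"] <= cfg.detection_threshold_ct].iloc[-1]
    res = enrichment_test(int(at["n_homology_related"]),
                          int(at["n_false_positive"]), frac)
    print(f"  expected homology fraction {n_hom}/{n_pot} = {100 * frac:.0f}%; "
          f"enrichment p = {res.p_value:.2g} ({res.method})")
    # p << 0.05 means homologous assays fire far more often than chance
    # placement among the potential false positives would allow.

    table = mismatch_stratified_fp(ct, "synthetic_1", study.design,
                                   catalogs[name], hmap, cfg)
    print("  cross-reaction by mismatch distance "
          "(n assays / n FP / FP rate %):")
    for _, row in table.iterrows():
        print(f"    {int(row['mismatches'])} mm: {int(row['n_assays']):3d} / "
              f"{int(row['n_false_positive']):3d} / {int(row['fp_rate_pct']):3d}%")
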
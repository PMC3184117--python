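"""Sequence-homology screening of assay targets against a miRNA panel.

Mature miRNAs can differ by one nucleotide; an assay may therefore amplify
a close homolog of its intended target.  The screen aligns every assay
target to every panel miRNA and keeps pairs within 4 mismatches and 8-nt
overhangs per end.
"""

from mirspike.homology import AlignmentParams, align_pair, build_homology_map, is_homologous
from mirspike.model import AssayCatalog, AssayRecord, MiRNAPanel, MiRNASpecies

# two panel miRNAs: the second is the first with a single substitution
a = "TGAGGTAGTAGGTTGTATAGTT"
b = "TGAGGTAGTAGGTTGTGTAGTT"
panel = MiRNAPanel([MiRNASpecies("mir-x", a, "A"), MiRNASpecies("mir-y", b, "B")])

summary = align_pair(a, b)
print(f"mir-x vs mir-y: {summary.mismatches} mismatch(es), overhangs "
      f"{summary.overhang_left}/{summary.overhang_right}, "
      f"aligned length {summary.aligned_length}")
print(f"within the homology bound: {is_homologous(summary)}")

catalog = AssayCatalog([
    AssayRecord("assay-x", "demo", "mir-x", a),       # targets mir-x
    AssayRecord("assay-z", "demo", "mir-z",           # targets an absent miRNA
                "ACCGATTTCAGGCATCGAAGTC"),
])
hmap = build_homology_map(catalog, panel, AlignmentParams())
for assay in hmap.assay_ids():
    hits = hmap.homologs(assay)
    shown = ", ".join(f"{m} ({s.mismatches} mm)" for m, s in hits) or "none"
    print(f"{assay}: cross-reaction candidates -> {shown}")
# assay-x lists mir-y (1 mismatch) but never its own target mir-x: the map
# models potential cross-reaction, not intended detection.  assay-z is
# unrelated to the panel and lists nothing.
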
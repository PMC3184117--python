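# Methods

This note documents the models, conventions and numerical choices behind
`mirspike`, in the order the pipeline uses them.

## Study design model

The evaluation assumes a spike-in design with two pools of synthetic miRNAs
(defaults: 88 in pool A, 86 in pool B, miRNA-like 22-mers) mixed 1:4 and
4:1 into two samples. With defaults, sample 1 carries pool A at
0.25×10⁶ and pool B at 10⁶ copies per reaction and sample 2 the reverse, so
every panel miRNA differs exactly four-fold between the samples. ΔCt is
reported as Ct(sample 2) − Ct(sample 1): a miRNA more abundant in sample 1
amplifies earlier there, giving ΔCt = log2(c₁/c₂) = +2 for pool B members
and −2 for pool A members. Spiked plasma samples add endogenous miRNAs on
top of the same spike content; the dilution series scales spiked sample 1
down to 5000/20000 (pool A/B) copies per PCR at the top point and 10-fold
per step, reaching 0.5/2 copies at point five. Copies are parameterized
per reaction throughout; volumetric bookkeeping upstream of the reaction is
deliberately out of scope.

## Ct model and simulator

Simulated Ct values follow the standard log-linear qPCR model

    Ct = ct_at_ref − log(copies / ref_copies) / log(1 + efficiency) − preamp_cycles

with defaults ct_at_ref = 20 cycles at ref_copies = 10⁶ and efficiency = 1
(perfect doubling, so 2 cycles per four-fold and log2(10) ≈ 3.32 cycles per
10-fold step). Per-well Gaussian noise (default sd 0.3 cycles) lumps RT and
qPCR variability. Stochastic mechanisms, in simulation order:

* **Occupancy dropout** (default on): the template molecules entering a
  well are Poisson-distributed with mean equal to the nominal copies, so
  the probability of any template at mean λ is 1 − e^(−λ). An empty well
  is undetected. This is mechanistic and parameter-free, and analytically
  checkable at low input.
* **Cross-reaction**: each sequence homolog of an assay's target
  contributes `copies × crossreact_base_fraction × 10^(−penalty × mismatches)`
  effective template (defaults 0.5 and 1 decade per mismatch). With the
  default anchor this keeps even 4-mismatch homologs of a 10⁶-copy spike
  detectable at a Ct-38 threshold, so simulated cross-reaction rates sit
  near 100% in every mismatch stratum; the monotone decay of effective
  template with distance is what the stratified table tests.
* **Background**: with probability `background_rate` per well, an empty
  well emits a template-independent signal uniform in Ct 38–40, emulating
  no-RT artifacts. Background is independent of template and never fires
  in occupied wells.
* **Outlier wells** (default off): sporadic poorly amplifying wells are
  shifted by a fixed number of cycles or rendered undetected.
* Any Ct beyond `max_cycles` (default 40) becomes undetected.

Pre-amplification is modeled as a pure Ct offset, not re-sampled template;
that is sufficient to reproduce the observation that a pre-amplified
platform's signals (true and false) appear at lower Ct. Two profiles ship
as presets: `mircury_like` (threshold Ct 38, no pre-amplification,
background rate 66/689 ≈ 0.096) and `taqman_like` (threshold Ct 30, 12
pre-amplification cycles, no background). They emulate the two platform
archetypes' detection settings and no-RT behaviour; no claims about the
real products' physical parameters are implied.

All randomness flows from one integer seed through spawned generator
streams (endogenous content first, then one stream per platform table in
sorted order), making studies byte-identical per seed. Analysis stages
contain no randomness at all.

### What the generator does not emulate

Real Ct data add assay-specific efficiencies and offsets, correlated
replicate structure (shared RT aliquots), RNA-extraction and carrier
effects, plasma inhibitors, and sequence-dependent chemistry differences.
Passing tests on simulated data therefore demonstrate that the *analysis*
recovers the quantities the generator encodes under realistic noise,
dropout and cross-reaction — not that any real platform has those values.

## Homology screen

Assay targets are aligned to panel miRNAs with a Smith–Waterman local
alignment (linear gap costs; default scores +1 match, −1 mismatch, −1 gap).
A pair is homologous when the best-scoring alignment has at most 4
mismatches — substitutions plus, by default, internal indel columns — and
at most 8 unaligned terminal bases at each end (both bounds inclusive;
overhangs count unaligned bases of *both* sequences at that end). Both the
indel-counting rule and per-end overhang semantics are flags. Ties among
equal-scoring alignments are broken by fewest mismatches, then smallest
total overhang (largest aligned span), then first end cell in row-major
order, making output deterministic. The DP tracks score, mismatches and
span lexicographically per cell (numba-compiled); with gaps disabled it
reduces exactly to an offset-sliding alignment, which is how the test suite
oracles it.

Two properties deserve care. The left/right overhang *split* of co-optimal
tiny alignments depends on the scan order, so the argument-swap invariant
is stated on mismatches and total overhang. And adding a substitution can
legitimately *reduce* reported mismatches when it ties the full alignment
with a trimmed one (the fewest-mismatch tie-break then trims); mismatch
monotonicity holds, and is tested, for well-separated interior edits.

Under these lenient default scores, randomly generated same-length 22-mers
pass the bound at roughly 5×10⁻³ per pair (a trimmed 17-column alignment
with 4 mismatches scores as well as anything else). Real panels curated
from mature miRNAs show much lower accidental rates, so the panel and
catalog generators use rejection sampling: every non-planted sequence is
regenerated until non-homologous to the whole panel. The generated homology
structure is therefore exactly the planted one (per-platform planted
homolog counts follow a one-third-scale version of the study-size
cross-reaction table; platform coverages 143/155 of the panel with a
125-assay intersection mirror the published assay bookkeeping).

## Detection and specificity conventions

A numeric Ct ≤ threshold is detected (inclusive: a threshold "of 38"
admits 38.0). Two replicate rules coexist: `any_replicate` for
false-positive counting (one stray replicate signal is a false positive)
and `all_replicates` for "n detected" summaries and recovery inclusion.
The FP rate is FP/(FP+TN) over assays whose target is absent from the
sample; FP+TN is constant across thresholds. Threshold suggestion takes
the 1% quantile of numeric no-RT Cts floored to a whole cycle (run length
if the no-RT control is silent). Homology-related false positives are
tested for enrichment with an upper-tail Poisson test at
λ = n_FP × expected fraction (default, with the exact binomial tail as the
labeled alternative), where the expected fraction is the homologous share
of all potential false positives. The cross-reaction table stratifies
absent-target assays by their *minimum* mismatch distance to any present
miRNA, so each assay occupies exactly one stratum; rates are rounded to
integer percent.

## Recovery, reproducibility, sensitivity, linearity

Recovery ΔCt uses replicate means; an assay is excluded if any of its four
measurements is undetected or beyond the threshold, and exclusion reasons
are reported. Summaries use linear-interpolation quartiles and the n−1
variance. Between-platform comparisons run per expected-direction group
(Mann–Whitney, two-sided; exact enumeration when min(n, m) ≤ 8 without
ties, tie- and continuity-corrected normal approximation otherwise, and
p = 1 for identical samples), a two-sided variance-ratio F test on pooled
observed-minus-expected residuals, and the Pearson correlation of those
residuals between platforms; comparisons are refused below three common
included assays.

Reproducibility is the Pearson r of the two replicate vectors over assays
detected under the `all_replicates` rule, reported as "na" below three
assays or for constant vectors. Dilution-series detection uses the same
rule per point with Fisher's exact two-sided test (sum of tables as or
less probable) between platforms. Linearity regresses nothing: per assay,
r² is the squared Pearson correlation of all replicate Ct measurements
against log10 copies over the retained points (default: all but the lowest,
which neither platform profile measures acceptably), with undetected wells
imputed to the detection threshold as background; a constant post-imputation
Ct yields r² = 0, flagged. Outlier handling is never heuristic — the only
mechanism is an explicit exclusion list.

## Numerical and scale choices

* Sequences are stored DNA-alphabet (U→T); normalization is idempotent; N
  never matches, not even itself.
* "Undetermined" is the canonical undetected token; "NA" and the empty
  string are accepted on read. In memory the sentinel is NaN inside the Ct
  table and an explicit singleton at the API surface.
* Ct values must lie in (0, max_cycles]; out-of-range values are errors,
  never clamped, because silent clamping would mask instrument-export bugs.
* Exact-versus-approximate switchovers (Mann–Whitney at min(n, m) = 8) are
  fixed, documented constants.
* Test and acceptance runs use a full-scale panel (174 miRNAs, ~270 assays
  per platform) for single-run checks and a 34-miRNA panel for the
  many-seed property checks, with homology maps cached per catalog since
  the screen is deterministic. The occupancy closed-form check runs with
  noise_sd = 0: at the default anchor a single copy sits at Ct ≈ 39.93,
  and well noise would otherwise push a predictable fraction of single-copy
  wells past the run length, confounding the 1 − e^(−λ) bound being
  verified.

## Known limitations

* The homology screen is purely sequence-count based; no ΔG/Tm
  cross-hybridization model.
* Cross-reaction from endogenous (non-panel) species into panel assays is
  not simulated; endogenous miRNAs only feed their own assays.
* At the default Ct anchor the lowest dilution point (0.5/2 copies) is
  essentially undetectable for the non-pre-amplified profile under its
  Ct-38 threshold; the detection-count monotonicity this produces is
  realistic, but absolute counts at that point are anchor-dependent.
* Recovery of fold changes below four-fold is not validated — the design
  contains none.
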
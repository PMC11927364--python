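# Methods

This note documents the models implemented in `meioloop`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical/design decisions that were genuinely open.

## Coordinates and containers

All coordinates are 0-based half-open internally; BED-family files are read
and written in the same convention. Loops are stored canonically as the two
anchor midpoints plus an anchor half-width at export time (BEDPE column 8
carries the predicted probability or the PET count). Overlap counting counts
*query regions* overlapping ≥ 1 target region — the statistic used by the
permutation machinery — and is implemented on merged-interval arrays with
`searchsorted`; a brute-force all-pairs oracle cross-checks it in the tests.

## Loop classifier

Candidate pairs are all same-chromosome ordered CTCF site pairs with
motif-midpoint distance in [10 kb, 2 Mb] (inclusive). Orientation
(convergent / tandem / divergent) is a categorical feature, not a hard
filter: convergence is biology of true anchors and the classifier should be
allowed to learn it.

Signal features use three point tracks: fragments, accessibility peaks
(weight = strength percentile at the peak center) and scaled expression
(weight at the TSS). Fragments carry no strand, so each fragment is counted
once at `start + shift` with `shift` = half the median fragment length
(136/2 = 68 bp by default), which places the counted position at the
midpoint of a median-length fragment. Anchor windows are 4 kb centered on
the motif midpoint — the window size is not dictated by the method itself;
4 kb keeps anchors sub-loop-scale at the 10 kb minimum loop length. Flank
windows are equal-width and abut the anchor windows outward; the in-between
feature is the per-kb density between the inner anchor edges (a density, so
it is comparable across loop lengths). Anchor summaries are the mean and the
standard deviation of the two per-anchor values. Windows clipped at
chromosome ends are truncated and logged.

Labelling: a candidate is positive iff both midpoints fall within the anchor
tolerance (default 1 kb) of the same truth loop's midpoints. Negatives are
sampled 1:1 from the unlabeled candidates, matched to the positive length
distribution by decile bins with a fixed seed; balanced classes justify the
default 0.5 probability threshold (ties at the threshold are included).

Training uses a random forest with 100 trees, unbounded depth and
`max_features="sqrt"`. Two CV schemes are provided: five iterations of
shuffled stratified 10-fold CV, and 5-fold chromosome-grouped CV in which no
chromosome contributes rows to both sides of a fold (the leakage-free
robustness check; it requires ≥ 5 chromosomes). Fold metrics are ROC-AUC and
average precision on held-out folds only; the returned model is refit on all
rows, with mean-decrease-impurity importances (non-negative, summing to 1).
The reduced "CTCF-only" model keeps peak strength, conservation and
orientation (loop length optionally retained) — deliberately *not* the motif
score, mirroring the reduced-input robustness variant.

Predicted and ground-truth loops are compared as midpoint-to-midpoint spans
under a reciprocal-overlap criterion (default 99%), optionally sweeping the
minimum PET support of the truth set; support fractions are monotone in that
sweep by construction.

## Circular permutations and profiles

Each permutation rotates all regions of the query set on a chromosome by one
shared uniform offset with wrap-around; regions crossing the origin are split
in two and count once. One offset per chromosome preserves intra-chromosomal
spacing, which is the point of circular randomization. The p-value uses the
+1 correction, so p ∈ (0, 1]; `alternative="auto"` tests on the side of the
observed value (note that under a true null this side-selection doubles the
nominal tail mass, so calibration checks use a fixed one-sided alternative).
The shifted-Z profile recomputes Z after displacing the query set circularly
by each signed offset, with the same permutation seed so that shift 0
reproduces the unshifted Z exactly.

Loop meta-profiles cut each loop span ±20% of its length into 140 equal bins
(20 flank + 100 body + 20 flank), so anchor midpoints fall exactly at the
bin-20/21 and bin-120/121 boundaries; per-bin scores are the covered
fraction, averaged across loops with SEM and a normal 95% CI. The bin count
is exposed as a parameter. Fixed-width profiles resize peaks to 6 kb about
their centers with 100-bp bins.

## Telomere statistics

The distance of a feature to the nearest telomere is the minimum of the four
end-to-end distances, divided by chromosome length, hence ≤ 0.5 with an
exact uniform expectation of 1/4 (E[min(U, 1−U)] = 1/4). Bin distributions
assign features to 100 equal chromosome bins by midpoint and fold symmetric
bins by telomeric distance; both folded and unfolded tables are emitted
because the aggregation convention is a presentation choice.

## Window models

Windows tile each chromosome on a fixed 1-kb grid; trailing remainder bases
are dropped rather than padded, and windows touching a blacklist or missing
any predictor are removed. Loop geometry: anchor blocks are 5 kb centered on
anchor midpoints; interiors are the loop span pruned by 2.5 kb per end minus
*every* overlapping anchor block (this excises anchors of nested loops);
loops shorter than 5 kb yield empty interiors (logged, not an error). The
window features are GC and replication timing (coverage-weighted track
means), absolute telomere distance of the window midpoint, gene count and
summed scaled expression, loop/anchor overlap counts, interior overlap, the
maximum anchor peak strength (0 where no anchor overlaps — a defined fill
value) and fragment counts as the accessibility signal. Outcomes are binary
any-overlap indicators, with an optional coverage-fraction threshold.

Model selection follows a 70/30 stratified split; 10 random draws of
(n_estimators ∈ [50, 200], max_depth ∈ [1, 20]) are scored by 5-fold CV
ROC-AUC on the training split only, and the best configuration is refit and
evaluated once on the untouched test split.

## Loop/expression statistics

Loop equivalence across cell types uses both anchor midpoints within 5 kb
(the anchor-block radius); a loop is private when no other type matches it.
Promoters are TSS ± 2 kb; anchor overlap uses anchor midpoint ± 1 kb; the
in-loop and at-anchor classes are reported independently. The
expression-shift comparison between two disjoint gene groups is an unpaired
two-sample rank-sum (Mann-Whitney) test — the groups are disjoint gene sets,
so a paired signed-rank contract would not apply. Per-loop expression is the
mean scaled expression over TSS-in-loop genes (sum available as an option);
loops without a TSS score 0 and are flagged. The progression odds ratio is
(a·d)/(b·c) on the {recombination ±} × {loop overlap ±} table with a Woolf
CI (log-OR ± 1.96·√Σ1/cell); zero cells trigger a 0.5 continuity correction,
flagged in the result.

## Synthetic data generator

The generator emulates the *statistical structure* of the pipeline's inputs,
not their molecular detail. Defaults (a 5 × 4 Mb genome, 50 true loops,
25 decoy CTCF sites/Mb, fragment midpoint rate 0.01/bp with median length
136 bp, 5-fold fragment enrichment within ±1 kb of true anchors, ssDNA and
crossover hotspots of 1–2 kb at 3.5-fold anchor enrichment and ~1.2-fold
in-loop enrichment, 8 ssDNA and 4 crossover hotspots per Mb, haplotype-block
boundaries snapped to anchors with probability 0.5, no telomere bias) are
the baseline study conditions: the anchor folds match the measured
anchor-versus-ssDNA/crossover enrichments (~3.5×), the decoy density matches
the genome-wide density of active CTCF sites (~70 k sites / 3 Gb ≈ 23/Mb),
and hotspot widths match the typical 1–2 kb hotspot scale. Loop lengths are
log-uniform on [10 kb, 2 Mb]. Everything is driven by one seeded generator;
a fixed seed reproduces the output files bit for bit.

Two modelling choices deserve emphasis:

* **Fold semantics.** Hotspot folds are defined relative to the *realized
  genome-average* density: the background density is solved so the
  genome-wide mean equals the configured per-Mb rate while anchor-dilated
  blocks sit at fold × that mean. This is the quantity the
  circular-permutation ratio estimates; defining folds against the
  background instead would make the planted value unrecoverable once
  enriched regions occupy a non-trivial genome share. Infeasible
  combinations (background ≤ 0) raise a configuration error.
* **Telomere bias** is a single knob: placement density ∝
  (relative telomere distance + ε)^(−β), β = 0 giving uniform placement.

What the generator does **not** emulate: per-cell sparsity and barcodes, raw
reads, sequence content beyond a smooth GC track, mappability structure,
centromeres/acrocentric arms, length-dependent signal structure inside
loops, and realistic linkage-disequilibrium block geometry. Passing tests
therefore demonstrate correctness of the *computational chain* under planted
conditions, not biological fidelity. One known consequence: because signal
features are conditionally independent of loop length and negatives are
length-matched by decile, loop length carries almost no class signal in the
synthetic benchmark and ranks low in forest importance — on real data, where
signal structure varies with loop size, length can rank at the top.

## Problem sizes and Monte-Carlo resolution

Validation runs use sizes chosen so sampling error resolves the property
being checked: the telomere expectation uses 100 k uniform points
(SE ≈ 0.0005); null calibration uses 50 seeds of two independent 500 × 8 kb
region sets on 20 Mb with 1000 rotations (the ~165 expected overlaps give
~6% ratio error, small against the ±20% calibration band); planted-fold
recovery uses twenty 20 Mb chromosomes with 1000 loops (≈ 330 anchor/ssDNA
overlap events) because a single 20 Mb genome yields only ~15–20 events and
~20% ratio noise; the classifier benchmark plants 200 loops on 20 Mb
(≈ 64 k candidates, ~500 training rows); the window benchmark uses the
20 000 1-kb windows of the default genome. The measured enrichment ratio
sits slightly below the planted fold (≈ 3.3 for 3.5) because overlap
probabilities saturate mildly at realistic hotspot densities
(P(hit) = 1 − e^(−λ)) — a property of the statistic, not an estimator bug.

## Known limitations

* The permutation test rotates over the full chromosome length; masked-gap
  handling is limited to a user-supplied blacklist at window level.
* The peak-activity percentile is computed genome-wide, not per chromosome.
* Haplotype-block generation is a renewal process with anchor snapping; it
  reproduces boundary-at-anchor enrichment but not realistic LD decay.
* `alternative="auto"` is convenient for reporting but anti-conservative
  under the null; use a fixed alternative for calibration work.
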
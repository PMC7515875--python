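# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `mei`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Gene model and singular counting

A gene is the union of its annotated exons across all transcripts
(0-based half-open internally; GTF converted at the parser). "Intron"
means a position inside the gene span covered by no transcript's exon —
the conservative partition that never mislabels exonic sequence as
intronic. Exons and introns tile the span exactly (property-tested with a
per-base coverage oracle). Genes annotated on multiple chromosomes or
strands are excluded, not repaired.

Counting is deliberately model-free. A read (single-end semantics; mates
count as independent placements) contributes only when

* its MAPQ is at least `mapq_min` (default 40), and
* it overlaps exactly one gene — reads touching two genes are discarded
  rather than redistributed (no multi-mapper rescue or EM, by design).

A read overlapping any exonic base is exonic; junction/boundary reads are
therefore exonic, because they evidence the spliced exon. Strand is
ignored (unstranded default; library strandedness is rarely knowable from
archived data). Per gene and sample, reads below the MAPQ cutoff that hit
the gene accumulate as "alternative" counts; a gene is **singular** in a
sample when alternatives are ≤ `alt_frac_max` (default 1%) of its total
and it has at least one high-quality read. The audit is per-sample, and
matrices keep only genes singular in every sample — the stricter of the
two readings of the rule, flagged in the audit output so users can relax
it. Gene ids annotated at several loci are kept only when exactly one
locus passes the audit.

## Calibration

One size factor per library, applied to exon and intron counts alike.

**ERCC route** — model `log2(count_ij + 0.5) = a_j + b·log2(nominal_i)`:
one intercept per sample, a single shared slope. The shared slope encodes
that spike response is proportional — samples differ by scale, not by
response curve. The fit is IRLS (Tukey bisquare); after each fit,
observations with |residual| > 2×MAD are excluded and the model refit
until the excluded set stabilises (≤ 20 iterations), absorbing pipetting
and amplification outliers. Size factors are `2^(a_j − ā)`,
geometric-mean normalised. At least 8 spike-ins nonzero in every sample
are required; otherwise the error message points at the median route.
The 0.5 pseudocount avoids log(0) but makes scale-equivariance exact only
up to ~0.5/count relative error — negligible at real spike depths.

**Median route** — per-gene median reference across samples, per-sample
median of count/reference ratios over genes with nonzero reference,
geometric-mean normalised. Equivariance to rescaling one sample is
approximate here (the reference itself moves); planted-factor recovery
on NB cohorts is the property we rely on (≤ 5% error, seeded test).

Calibration happens after counting and before statistics.

## Per-gene statistics

**Gini.** `G = Σᵢⱼ|xᵢ−xⱼ| / (2n(n−1)x̄)` — the unbiased (n(n−1)) form,
computed via the sorted-order identity in O(n log n) and verified against
the O(n²) double sum to 1e−12. Scale invariance (gini(cx) = gini(x))
makes gene-length normalisation irrelevant for it. Zero mean ⇒ NaN
("not evaluable"), never a fabricated zero. The variability differential
is the case/control Gini ratio; twofold change **in either direction**
(max(r, 1/r) ≥ 2) counts, since variability reductions are as meaningful
as gains.

**NB test.** Likelihood-ratio test of a shared vs group-specific NB mean,
variance µ + αµ². The common dispersion α is estimated under the
alternative by **Cox–Reid adjusted profile likelihood** (for the
two-group design the adjustment is ½·Σ_g log(n_g µ_g/(1+αµ_g))): plain ML
dispersion is biased low at a dozen samples per group, which makes the
LRT liberal precisely in the high-dispersion, low-mean corner. With the
adjustment, Monte-Carlo null rejection at p < 0.001 sits inside
[0.0002, 0.003] across µ ∈ {20, 100, 500} × α ∈ {0.01, 0.1, 0.5} with
12 vs 46 samples (acceptance suite), and power for a twofold shift at
µ = 100, α = 0.05 exceeds 0.95. α is optimised on a log grid
(bounded Brent, xatol 1e−4) and floored at 0, where the exact Poisson
log-likelihood is used — evaluating the NB form at α → 0 cancels
catastrophically in `gammaln`. Calibrated (real-valued) inputs are
rounded to integers for the likelihood only; the fold change `E_m` uses
unrounded means with a 0.5 pseudocount in both numerator and denominator.
All-zero genes return p = 1.

**Correlation differential.** Pearson r between a gene's exon and intron
counts within each group (Spearman available for monotone checks), then
the classical Fisher z statistic with two-sided normal p; |r| = 1 is
clipped to 1 − 1e−7. No small-sample correction; each group needs n ≥ 4.
Null p-values are uniform under bivariate-normal simulation (KS-tested).

**Min-rescaling and the +1 guard.** Profiles divide by the gene's
smallest count. When the minimum is zero the literal rule divides by
zero, so one count is added to **all** values of that gene's vector
before rescaling — the only reading that keeps the operation defined;
it is the package-wide zero-mitigation and is config-visible.

**Robust slope.** Aggregate exon:intron relationships use Huber IRLS
regression of rescaled intron on rescaled exon with the intercept fixed
at zero (the ratio relationship passes through the origin); slope
differences are tested with a two-sided normal statistic on
(s₁−s₂)/√(se₁²+se₂²). Perfect fits short-circuit to least squares since
the IRLS scale estimate degenerates at zero residuals.

**Multiplicity.** Benjamini–Hochberg q-values accompany `E_p` and `I_p`,
and `fdr_threshold_check` reports the largest p cutoff honoured by BH at
the target FDR (default 0.1) on both vectors — a diagnostic to read next
to the fixed `ep_alpha = 0.001` gate, mirroring how that gate was chosen
from an FDR-0.1 calculation in the first place.

## Co-expression clustering

Features are per-gene, per-sample profiles: min-rescaled exon counts
(mode `exon_only`) or the ratio of min-rescaled exon to min-rescaled
intron counts (mode `exon_intron_ratio`), log₂-transformed and z-scored
per gene (zero-variance genes dropped and listed). Z-scoring makes
correlation distance and Euclidean geometry agree —
`1 − r(x,y) = ‖x−y‖²/2d` — so Lloyd's mean-update step is exact for
K-means under `d = 1 − r`. Centroids are cluster means re-z-scored;
empty clusters are re-seeded from the farthest point; best of `restarts`
seeded initialisations wins.

The number of clusters minimises a Gaussian-sphere information
criterion: `n·d·ln(WCSS/(n·d)) + ln(n·d)·k·d` with ties to the smaller
k. The Schwarz weight `ln(n·d)` on the k·d centroid parameters, rather
than the constant 2 of a textbook AIC, is load-bearing: on pure noise an
extra centroid buys a chance WCSS reduction of roughly (2/π)·n in the
`n ≫ d` regime, which exceeds a constant-weight penalty and would split
unstructured data indefinitely. **Regime limitation:** because that
chance reduction grows linearly in the number of genes while the penalty
does not, no fixed-weight criterion selects k universally; this one is
validated for matrices near the analysis geometry (hundreds of genes ×
tens of samples — planted k ∈ {2,3,4} at 5σ separation recovered in
100% of seeded runs, pure noise yielding k = 1). For much larger gene
sets, cluster a subsample or pre-filter to variable genes.

Partitions are compared with the Hubert–Arabie adjusted Rand index
(delegated to scikit-learn; tested against a brute-force pair-counting
oracle over all partitions of ≤ 6 elements).

## Selection

`standard_hit = Ep ∧ Em`; `mei_hit = Ep ∧ (Em ∨ Ip ∨ Cd ∨ Ge ∨ Gi)` with
defaults `ep_alpha = ip_alpha = 0.001`, `cd_alpha = 0.005`,
`fold_min = gini_fold_min = 2`. The exon-significance gate is mandatory;
genes with only secondary evidence are reported on a watch list. The
report sorts by number of satisfied criteria, then `E_p`, so a gene
flagged by every measure leads the table. Relaxing any threshold can
only grow the MEI set (monotonicity is property-tested), and the
standard set is a subset of the MEI set by construction. Undefined
measures (zero control Gini, degenerate correlations) are NaN, flag
False, and are listed as not evaluable — they can never create a hit.

## Synthetic cohorts

`simulate_counts` draws matched exon/intron counts per gene from NB
marginals coupled by a **Gaussian copula**: the planted ρ is the latent
normal correlation (monotonically related to, and slightly above, the
Pearson r realised on counts — the truth table stores both). Per-sample
technical scale factors are log-normal (sd 0.2 by default) and multiply
all of a sample's means; ERCC spike counts are NB around
nominal × scale, over a synthetic 92-spike mix spanning ~4.5 decades.

The default cohort reflects the archived two-group study design the
method targets: 12 control vs 46 case samples and 2,000 genes — roughly
half the ~4,300-gene singular set, keeping the default test run fast
while leaving multiplicity behaviour intact. Effect classes: 5% mean
shift (fourfold — a strong, unambiguous expression change), 5%
variability shift (dispersion 0.05 → 0.8, i.e. a ~3× Gini ratio at these
means, comfortably past the 2× flag), 5% correlation break
(ρ 0.95 → 0), 85% null (ρ 0.9, α 0.05, fold 1); exon means log-uniform
over 50–500 with intron means at 30–70% of the exon mean. Each effect
size was fixed once as a clear instance of its mechanism.

What the generator does **not** emulate: GC/length bias, sample-quality
gradients, correlated gene-gene co-expression modules (null genes are
independent), batch structure, zero-inflation beyond NB, or multi-mapping
ambiguity in count space (that is exercised separately by
`simulate_alignments`, which places reads deterministically inside exon
or intron regions with controllable low-MAPQ and two-gene-overlap
fractions). Passing tests therefore demonstrate correctness of the
estimators and decision rules under the stated model, not robustness to
every artefact of real libraries.

## Problem sizes and determinism

All simulations are seeded and byte-reproducible. The sizes used by the
test and acceptance runs — 10⁴ replicates per NB null grid cell, 10⁴
Fisher-z null replicates, 20 seeds × 3 planted k for clustering, one
2,000-gene end-to-end cohort — were chosen to keep Monte-Carlo error
well below the asserted margins while completing a full run in a few
minutes on one CPU core.

## Known limitations

* The NB test assumes a common dispersion across the two groups; a
  dispersion change is deliberately read as a variability signal (Gini),
  not folded into the mean test.
* No empirical-Bayes dispersion moderation across genes (unlike
  DESeq2/edgeR) — genes are tested independently, matching the
  method's model-free stance.
* The Ep gate means pure variability or correlation effects without any
  mean shift land on the watch list, not in the hit set.
* k-selection regime limitation above.
* The 2× Gini-change threshold is applied as a fixed rule; its null
  distribution is not re-derived here.
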
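# Methods

This note documents the models, defaults and numerical choices behind
`ifnsynergy`, and what its synthetic generators do and do not emulate.

## Count model and interaction test

Counts are modelled per gene as negative binomial,
`K_gj ~ NB(mean μ_gj, dispersion α_g)` with `var = μ + α μ²`. The full
mean model over the 2×2 knockdown × cytokine design is

    log2 μ_gj = β0 + βA x_A + βB x_B + βAB x_A x_B + log2 s_j

Coefficients are kept on the log2 scale so the non-additive effect δ used
by the classifier equals β̂AB directly and all thresholds can be stated in
log2 units. Because the full model is saturated in the four condition
means, its MLE factorises into four independent one-dimensional problems,
solved by Newton iteration in log-mean space (closed-form weighted mean in
the Poisson limit α ≤ 1e-12); the additive (reduced) model is fit by IRLS
(max 100 iterations, tolerance 1e-8 on coefficient change; non-convergence
is flagged, not fatal, and flagged genes carry missing p-values). The
interaction is tested by Λ = 2(ℓ_full − ℓ_reduced) against χ²(1); Λ is
clipped at 0 against round-off. Contrast p-values (single factors and the
combination against the double control) are Wald tests using per-condition
Fisher information `I_c = Σ_j μ_j/(1+α μ_j)`. Multiple testing is handled
by Benjamini–Hochberg step-up; missing p-values propagate and are excluded
from the number of tests.

**Size factors** are median-of-ratios: the reference is the per-gene
geometric mean over genes with nonzero counts in every sample; if no such
gene exists an explicit `pseudo_reference=True` switches to library-size
ratios (normalised to geometric mean 1) instead of guessing silently.

**Dispersion** is estimated per gene by maximising the Cox–Reid adjusted
profile likelihood — the profile likelihood with condition means re-fit at
each candidate α, minus ½·log det of the expected information of the mean
parameters (block-diagonal over conditions for the saturated model) — over
a log-spaced grid around a method-of-moments start, then a finer local
grid (final grid resolution ≈ 4% in α, well inside the estimator's
sampling noise). Gene-wise estimates are then moderated by an
empirical-Bayes log-normal prior centred on the across-gene median log
dispersion, with prior variance equal to the spread of the gene-wise
estimates in excess of their expected sampling variance
(trigamma((m−p)/2); m samples, p = 4 mean parameters), floored at 0.25;
the returned value is the posterior mode. This moderation is required, not
cosmetic: with three replicates per condition the unmoderated estimates
are noisy enough that the interaction LRT rejects true additive genes at
roughly 2–3× the nominal rate, while with moderation the empirical type-I
error at nominal 0.05 sits near 0.05–0.07 — matching what the reference
NB GLM engine achieves on identical simulated data (we verified parity
directly). Estimates are floored at 1e-8; constant genes land on the
floor.

Deliberately **not** implemented: dispersion–mean trend fitting, outlier
replacement (Cook's distance), independent filtering, and shrunken
fold-change estimators. The downstream classification logic depends only
on coefficients, LRT p-values and fold-changes, and a transparent engine
keeps every rule checkable against closed forms. Consequently gene counts
from any specific published dataset processed with a full-featured DE
stack are not expected to be bit-reproducible here.

## Non-additive classification

δ = log2FC_AB − (log2FC_A + log2FC_B) = β̂AB. A gene is non-additive iff
its BH-adjusted interaction p < 0.05 **and** |δ| > 1 (both strict, so a
boundary gene at exactly 1.0 is excluded). Emergence categories come from
the single-factor responder flags (adjusted p < 0.05 against the double
control): neither / knockdown-only / cytokine-only / both; the four
categories are disjoint and partition the non-additive set. Direction is
the sign of δ: positive synergism above the additive expectation,
antagonism below. Finer interaction taxonomies (e.g. antagonism relative
to each single effect) are intentionally not encoded; the per-gene
(expected, observed) pair is exposed so they can be layered on. By default
classification is restricted to the response-gene set (significant in some
contrast, max TPM ≥ 2, max |log2 FC| ≥ 1); the restriction is a flag.

## Enrichment

Ranking uses the signal-to-noise statistic (μ1−μ2)/(σ1′+σ2′) on per-gene
z-scores, with each group SD floored at max(σ, 0.2·|μ|, 0.2) to avoid
low-variance blow-ups; ties are broken lexicographically by gene id for
determinism. The enrichment score is the classic weighted running sum
(weight exponent 1, exposed as config): hits add |score|/Σ_hits|score|,
misses subtract 1/(N−N_hit), ES is the signed maximal deviation. If all
hit scores are exactly zero the hit increments fall back to equal steps.

Significance uses gene-set permutation (not phenotype permutation):
null ES from random same-size sets, cached per set size within a run.
p = (1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null}).
NES divides ES by the mean |null ES| of matching sign. The FDR q is a
simplified sign-stratified ratio — fraction of pooled null |NES| at least
as large over the fraction of observed same-sign |NES| at least as large,
clamped to [0, 1]; the historical tool's exact q machinery has
undocumented details, so this documented deterministic variant is used
instead and should not be read as a reimplementation of it. The
annotation-style overlap analysis is an upper-tail hypergeometric test
with BH q-values — a documented stand-in for hosted tools whose
permutation internals are unspecified.

Leading edges are the set members at or before (ES > 0) / at or after
(ES < 0) the peak; ES = 0 yields an empty, flagged leading edge. Core
genes are those present in ≥ 3 leading-edge subsets (count-desc, then id).

## Normalisation conventions

- TPM_i = FPKM_i / Σ_j FPKM_j · 1e6 per sample; every output column sums
  to 1e6 (rel. tol 1e-6). An all-zero sample is an error naming the sample.
- Expression filter: genes with TPM < 3 in **every** sample are excluded —
  strict-less reading, so a gene reaching exactly 3.0 anywhere is kept.
- z-scores use the sample SD (divisor n−1); constant genes are returned as
  zeros and flagged. z-scores are recomputed after every subsetting step.
- "Top expressed" ranks by mean across all samples (tie-break by gene id);
  the original analyses do not define the statistic, this is pinned here.
- qPCR: technical replicates are averaged per sample × gene before
  ΔΔCT = (CT_t − CT_hk)_sample − (CT_t − CT_hk)_calibrator; relative
  expression is 2^−ΔΔCT, exactly 1 for the calibrator.

## Cohort stratification

Halves assign the median element of an odd-sized panel to the lower group
(45 lines → 22 upper / 23 lower); quartile extremes take ⌈n/4⌉ lines each
(45 → 12/12). Both conventions are forced by the published group sizes
they must reproduce. Ties in marker expression are resolved by line id and
logged. The PD-L1 high/low split has no published cut rule; the default
cuts at the largest adjacent gap in the sorted values, with explicit
threshold and median alternatives, all logged. Group statistics are
two-sided (Mann–Whitney U, Kruskal–Wallis with hand-rolled tie-corrected
Dunn z post-hoc under BH, paired Wilcoxon; all-zero paired differences are
flagged with p = 1). Correlation matrices adjust the k(k−1)/2 off-diagonal
tests (Bonferroni or BH) and order columns by average-linkage clustering
on 1−r (the published clustering default is unspecified; this one is
documented). PCA selects the top 2,000 expressed genes, centres each gene,
and decomposes by SVD; components are sign-fixed so each loading vector's
first nonzero entry is positive.

## Synthetic generators: what a green test establishes

The factorial generator draws baselines log-uniform (default 20–2,000
expected counts), plants eight disjoint gene classes (fractions
largest-remainder allocated, then shuffled), gives every non-null effect
the configured magnitude (default 2 log2 units, signs Bernoulli(0.5),
recorded), draws size factors log-uniform in [0.7, 1.4] so normalisation
is actually exercised, and samples NB counts under exactly the model the
fitter assumes (Poisson when α = 0). Defaults mirror the emulated design:
3 replicates, dispersion 0.05 (no empirical dispersion was published for
the emulated cell line; this is a testability choice typical of cell-line
RNA-seq).

The cohort generator draws a latent dedifferentiation score u ~ U(0,1) per
line and couples it to: MITF-like log2 expression (slope −5·coupling),
amplification of interferon-stimulated gene induction (×(1+coupling·u)),
and PD-L1-like induced expression (+3·coupling·u log2 units), with
Gaussian log2 noise (SD 0.2) and per-sample renormalisation to TPM scale.
Defaults (45 lines, couplings 0.8) give detectable but noisy gradients.

Neither generator simulates reads, sequencing error, dispersion–mean
trends, outliers, batch structure, correlated genes or single-cell
sparsity. A green recovery test therefore establishes correctness of the
estimators and rules **under the assumed model**, not robustness to
model misspecification. One subtlety the cohort generator does reproduce:
TPM renormalisation makes gene shares compositional, so amplified ISG
induction depresses other genes' TPM in treated high-u lines — null
couplings should be asserted on within-gene induction, not on raw shares.

## Pipelines

Both pipelines write all intermediates as files plus a `manifest.json`
(config, seed, package version, SHA-256 of inputs and of the payload);
identical inputs and seeds give identical manifests. Thresholds default to
the stated analysis values (padj 0.05, |δ| 1, min TPM 2 and 3, top-k
2,000, 1,000 permutations, core occurrence 3) and are overridable via a
single YAML config. The factorial pipeline, lacking a TPM matrix for
simulated counts, applies the expression filter to pseudo-TPM
(median-of-ratios-normalised counts rescaled per sample to 1e6). Stages
never mutate inputs; failures abort naming the stage.

## Known limitations

- The simplified DE engine (above) trades exact parity with full-featured
  reference stacks for transparency; its empirical type-I error at three
  replicates is ~0.05–0.07 at nominal 0.05, on par with the reference
  engine but not below it.
- The FDR q for enrichment is a documented variant, not the historical
  tool's exact procedure; q-values should be compared across sets within a
  run, not across tools.
- Cohort input from arbitrary external matrices is supported through the
  library API (`CohortTable`); the CLI cohort path currently runs the
  synthetic generator.
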
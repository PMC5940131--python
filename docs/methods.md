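# Methods

This note documents the statistical models implemented in `crstrains`, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions that a
user reproducing or extending the analysis should know about.

## Detection calls and expression filtering

Above-background detection uses the perfect-match/mismatch convention of
oligonucleotide arrays: per probe set, a one-sided Wilcoxon signed-rank test
of PM > MM. The test is one-sided because "above background" is a directional
claim — PM must exceed its paired mismatch control. Zero differences are
dropped before ranking (standard signed-rank convention) and tied absolute
differences receive midranks. For ≤ 25 nonzero pairs the null distribution is
computed exactly by a generating-function convolution over doubled midranks,
which equals brute-force enumeration of all 2^n sign patterns conditional on
the observed ranks and therefore remains exact under ties; above 25 pairs a
normal approximation with tie-corrected variance and a 0.5 continuity
correction takes over. `scipy.stats.wilcoxon` declines exact computation in
the presence of ties, so the exact path is implemented here (and
cross-checked against enumeration and against scipy in the tie-free case).

A gene is *detectable* in a sample when at least 50% of its probe sets reach
P < 0.05. Differential testing within one CR-vs-CTL comparison is restricted
to genes detectable in at least one third of that comparison's samples; the
threshold is an exact fraction evaluated with integer arithmetic, so 5 of 15
samples sits precisely on the boundary and is retained ("33%" is read as 1/3
of the 16-sample comparisons, where 33/100 and 1/3 coincide on every
attainable count). The filter may also consume a precomputed boolean
detection matrix directly, which is how gene-level workflows (including the
simulator's) bypass probe-level data. Interaction scans use the same rule
over *all* samples of a tissue rather than one strain's comparison.

Probe-to-gene collapsing keeps, per gene, the probe with the highest mean
expression across all samples; ties break toward the lexicographically
smallest probe identifier so the operation is deterministic.

## Moderated t-statistics

Per-gene ordinary least squares against a shared design matrix yields β̂_g,
residual variance s²_g and d_g = n − rank(X). The empirical-Bayes prior
(d₀, s₀²) is estimated by the closed-form moment estimator on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of the sample variance of
e over the mean of ψ′(d_g/2) is inverted through the trigamma function
(monotone Newton iteration, tolerance 1e-8, ≤ 50 steps) to give d₀, and
s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)). Non-positive excess dispersion gives
d₀ = ∞ and every posterior variance collapses to s₀². Genes with s² = 0 are
excluded from prior estimation but still moderated. The implementation
reproduces the R reference implementation (limma) to ~1e-14 on a shared
fixture, which the test suite verifies by invoking `Rscript`.

Moderated t-statistics are referred to t with d_g + d₀ df (normal when
d₀ = ∞). p-values are two-sided; a zero coefficient reports p = 1 even when
the posterior variance is degenerate. BH adjustment is delegated to
statsmodels and is applied separately within each strain-tissue contrast and
within each interaction scan, matching the per-comparison FDR control of the
analysis design. DEG status requires FDR < 0.10 *and* linear FC > 1.50 or
< 0.67 (FC thresholds applied after exponentiation; all computation is in
log2 units). Interaction significance is reported at FDR < 0.10 with a
configurable secondary threshold (default 0.15) for the more permissive
convention used when screening strain-specific candidates.

## Factor dominance and response vectors

Dominance compares nested Gaussian models per gene: full (intercept + strain
+ diet) versus each single-factor reduction, with LRT statistic
n·ln(RSS_reduced/RSS_full) against χ² with df equal to the parameters
dropped. A χ² rather than F reference is used because the procedure is
defined as a likelihood-ratio test; with ≥ 100 samples per tissue the
difference is immaterial. The factor with the larger −log10 p is dominant;
exact ties (measure zero in practice) break toward strain, which carries more
parameters. −log10 p is computed through the log survival function, so very
strong effects do not underflow to infinity.

PC response vectors are computed on the gene-centered (not standardized)
matrix by SVD; standardization is deliberately avoided so that
high-variance genes drive the projection as they do the fold-change
analyses. The sign convention makes each component's gene loadings sum
positive. Arrows run from the CTL bivariate mean to the CR bivariate mean of
the sample scores; by linearity these equal projections of the group-mean
expression vectors, which the tests assert.

Fold-change correlation matrices use Spearman rank correlation on complete
pairs (genes non-missing in both tables); entries with fewer than three
shared genes are NaN and logged. Strain clustering is agglomerative with
average linkage on 1 − ρ (scipy), with the dendrogram also serialized as
Newick with branch lengths equal to height differences.

## Shared CR responses and the permutation null

A gene "responds" in a strain when its raw p < α (default 0.05) and its
log2FC is nonzero; it is tallied at k = number of responding strains only
when all responding strains share one direction, with direction-conflicted
genes counted separately. Counts are reported both for exactly-k and
at-least-k; headline "all strains" numbers are the k = S entry.

The null hypothesis is random association of CR responses among strains:
each permutation independently shuffles each strain's (p, direction) pairs
jointly across the common gene universe, preserving every strain's marginal
distribution exactly (including the within-strain dependence between
significance and direction) while destroying cross-strain association.
Empirical p-values use the (1 + exceedances)/(B + 1) convention, computed on
the at-least-k counts (the scientifically relevant tail); exact-k p-values
are reported alongside. Against data constructed with exact marginals, the
permutation means agree with the closed-form binomial-direction expectation
N·C(S,k)·α^k(1−α)^(S−k)·(1/2)^(k−1), which the acceptance suite checks at
N = 10000, S = 7, B = 1000 within 3 Monte-Carlo SE.

Quadrant proportion tests exclude pairs with either FC = 1, assign quadrants
by the signs of the two log2FCs, and test each quadrant's occupancy against
a 25% expectation with a df = 1 goodness-of-fit chi-square without
continuity correction; only over-represented quadrants (proportion > 25%,
p < 0.05) are flagged.

## Human meta-signature

Per experiment, the lowest-expressed 15% of genes (mean over all baseline
and post samples; floor convention; ties removed in lexicographic order) are
excluded; per-gene paired log2 differences (post − baseline, positive =
increased by CR) are summarized by their mean and standard error, with a
moderated one-sample test (d_g = n − 1) reusing the machinery above. The
experiment-level average standard error is computed over the retained genes
— i.e. after the low-expression exclusion, the reading adopted for the
ambiguous ordering of ranking and filtering — and ranks experiments for the
independence filter, which keeps exactly one experiment per baseline sample
set (ties toward the lexicographically smallest experiment id, logged).

Genes measured in at least 6 retained experiments enter the
DerSimonian–Laird synthesis on the mean-difference (fold-change) scale, not
the standardized-mean-difference scale, because the target estimand is a
meta fold-change. Fixed weights w = 1/se² give Cochran's Q; τ̂² is the
standard moment estimate truncated at zero (exactly zero whenever
Q ≤ k − 1); random-effects weights 1/(se² + τ̂²) give μ̂, its standard error
and a two-sided normal p. Experiments contributing a zero standard error for
some gene have it floored at the 1st percentile of that experiment's
positive SEs to avoid infinite weight. BH runs once over the final
synthesized gene set. The implementation matches both hand-evaluated
formulas and R's metafor (`method="DL"`) to 1e-6 in the tests.

## Cross-species concordance

Mouse and human symbols are matched only through an explicit one-to-one
ortholog map — no case-folding heuristics — with unmapped genes dropped and
counted. Concordance grids are Spearman correlations per (strain,
experiment) cell on complete pairs, with per-strain median and quartile
summaries and an additional correlation against the meta-signature.

The running-overlap enrichment statistic is this package's own definition
(outputs label it as such): with O(i) the overlap of an m-gene set with the
top-i genes of the human ranking and E(i) = m·i/H, D⁺ = max(O − E),
D⁻ = max(E − O) (maxima over i = 0..H), and the statistic (D⁺ − D⁻)/m. It
is exactly antisymmetric under ranking reversal and its permutation p-value
draws random same-size sets. Human ranking ties (equal meta-FC) order by
meta p then symbol. Median-FC tests of mouse-defined gene sets in the human
data use the two-sided one-sample signed-rank test of log2 FC against zero
(the exact small-sample machinery above); a two-sample rank-sum test against
the constant 1.00 would be degenerate, so the one-sample form is the
implemented reading, two-sided since no direction is privileged a priori.

## The synthetic-data generator

The generator's defaults emulate the reference multi-strain design: 7
strains × 4 tissues × 2 diets × 8 replicates = 448 arrays with 12 QC-flagged
samples, and 28 paired human experiments over 18 baseline sample sets with
3–40 subjects each (sex mix 10 male / 15 female / 3 unknown per 28,
durations 4–52 weeks). The default gene count is 2000 — enough for stable
FDR and prior estimation at desk scale; real studies carry ~19k genes but
the per-gene models are independent, so scale affects runtime, not validity.

Expression is baseline + strain offset + diet·effect + Gaussian noise on the
log2 scale. Default effect structure: 10% of genes share a CR effect
N(0, 0.6) across strains (typical |FC| ≈ 1.5, matching the DEG threshold
regime); 5% carry a strain-specific effect N(0, 0.8) confined to one focal
strain (these are the planted interactions; the focal pool defaults to all
strains and can be restricted, e.g. to B6, where real data concentrates
strain-specific responses); strain offsets N(0, 0.5) make strain the
dominant factor for most genes, as observed in real tissues. Per-gene
residual variances are drawn from a scaled inverse-chi-square prior
(s₀ = 0.5, d₀ = 4) so that variance moderation has a correctly specified
target whose recovery the tests verify. Detection flags are thresholded at
log2 intensity 6.0 against baselines N(8, 1.5), giving realistic ~90%
detectable universes.

True human effects are ρ·z(mouse shared effect) + √(1−ρ²)·ε rescaled to sd
0.4, with ρ = −0.3 by default — the sign and rough magnitude regime of the
observed mouse–human opposition (the resulting *estimated* rank correlations
attenuate to ≈ −0.1, comparable to reported per-strain averages).
Between-experiment heterogeneity is exposed as τ² (default 0.02) since
within-experiment heterogeneity of the real studies is not documented.
Missing genes (10% per baseline set) and baseline matrices are drawn per
baseline set, so dependent experiments share identical baseline samples and
coverage, exactly as repeated-measures experiments on one platform do.

What the generator does *not* emulate: probe-level correlation structure
within genes, array batch effects, intensity-dependent variance trends,
gene–gene correlation, and non-Gaussian outliers. Passing tests therefore
demonstrate correctness of the statistical machinery under a well-specified
generative model, not robustness to those real-data pathologies.

## Numerical and reproducibility conventions

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline derives per-stage child seeds by
hashing (seed, stage name) and records the seed and a SHA-256 configuration
hash in every output. Reruns with an identical configuration are
byte-identical, which an acceptance test asserts file by file; output
location and plotting toggles are excluded from the hash because they do not
influence results. Permutation p-values are never zero by construction.
Empirical-Bayes estimation requires ≥ 10 genes with positive variance;
designs are rejected (with the offending columns named) when rank-deficient.

Problem sizes used by the test and acceptance suites — 5000-gene null
calibrations, B = 1000 permutation batteries at 10000 genes × 7 strains, 20
seeds for effect-recovery and 6 for concordance-recovery — were chosen as
the smallest sizes at which the Monte-Carlo error bands in the checks are
meaningful. The concordance-recovery experiment is run at deliberately low
noise (residual sd 0.01, tight variance prior, no missing genes, full shared
fraction) because it compares estimated rank correlations against the
correlation induced on the ground truth: estimator noise attenuates rank
correlations toward zero, and the low-noise calibration keeps that
attenuation (~2e-5) far inside the 3-MC-SE comparison band. The same check
evaluates human fold-changes on the full gene universe, since the 15%
low-expression filter selects partly on the planted human effect (post =
baseline + effect) and would range-restrict it — a property of the filter
worth knowing when interpreting real-data correlations, not an estimator
artifact.

## Known limitations

- The Gaussian LRT dominance analysis ignores the estimated per-gene
  variance moderation; it is a descriptive screen, as intended.
- DerSimonian–Laird treats within-experiment standard errors as known;
  with few subjects this is mildly anticonservative, though the null
  calibration at 12–20 subjects passes a KS uniformity check at 5000 genes.
- The running-overlap enrichment statistic is a definition of convenience
  (the field's figure-level "enrichment statistic" is not standardized);
  treat cross-study comparisons of its magnitude with care.
- The pipeline is single-threaded; `--threads` exists for interface
  compatibility and results are independent of it.
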
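# Methods

## Problem and model

`envscan` asks whether environmental variation — climate, subsistence
strategy, or pathogen species richness — explains the geographic
distribution of allele frequencies beyond what shared population history
already explains. Two complementary readouts are implemented.

### Per-SNP UVE-PLS prediction accuracy

Each SNP's vector of folded minor allele frequencies over populations is
regressed on the population × variable environment matrix with
single-response partial least squares (PLS). PLS is used because the
environmental predictors are strongly collinear (correlated continental
climates, co-varying pathogen groups); it projects the predictors onto a
few latent components oriented toward covariance with the response. The
implementation is a deterministic NIPALS: components are extracted by
weight vectors w ∝ Xᵀy on the deflated design, and the coefficients after
k components are W(PᵀW)⁻¹q. Because PᵀW is upper triangular, a single
factorization yields the whole coefficient path, and the leave-one-out
folds are fitted as one batched array operation; the implementation is
validated against scikit-learn's `PLSRegression` to machine precision.

Model quality is the leave-one-out prediction accuracy Q² = 1 − PRESS/SS
(PRESS over left-out populations, SS the centered sum of squares). Q² can
be negative; it is large only when environmentally distant populations are
also distant in allele frequency. Predictors are z-scored within each
training fold; the response is centered only. The component count is chosen
per SNP by maximizing Q² over 1–3 components (ties toward fewer); 3 is a
deliberate ceiling given ≤16 predictors and ~55 observations.

For the full model, Uninformative Variable Elimination (UVE) precedes the
regression: 100 standard-normal noise columns are appended, PLS submodels
are fitted on every leave-one-out fold, and a real variable is retained
only if its coefficient reliability |mean(b)/sd(b)| over folds exceeds that
of every noise column. A scan draws one noise matrix (seeded) shared by all
SNPs so the elimination threshold is comparable across the genome. If
nothing survives, all variables are kept (logged). Category-restricted
models (pathogen / subsistence / climate / climate-range) skip UVE.

### Genic enrichment with a moving block bootstrap

The Q² axis is cut into fixed 0.125-wide bins starting at 0 (negative Q²
pools into the lowest bin); bins holding fewer than 100 SNPs are merged
downward. Within bin b, the enrichment of a SNP class is
(n_class,b/n_b)/(n_class/n), so the SNP-count-weighted mean over bins is
exactly 1 — an identity the tests verify on observed data and on every
bootstrap replicate. Confidence intervals come from a circular moving block
bootstrap: per chromosome, ⌈n/b⌉ blocks of b consecutive SNPs (default 40)
are drawn uniformly with wrap-around and concatenated, and the enrichment
is recomputed per replicate on the bin edges fixed by the observed data
(re-merging per replicate would make bins incomparable). Block resampling
keeps neighbouring, LD-correlated SNPs together, so the intervals are wider
and honest compared with an iid bootstrap; with b = 1 the two coincide.

### Per-gene partial Mantel I(R²)

Three population distance matrices enter per gene: Y, the gene's Reynolds
coancestry distances; X, an environmental dissimilarity; Z, the genome-wide
Reynolds distances pooled over all loci (the demography covariate; an
averaged-per-gene mode exists for data where per-locus information is
heterogeneous). The Reynolds distance is the sample-size-uncorrected
ratio-of-sums coancestry form — linear in divergence time under drift,
which is what makes Z an effective stand-in for shared history; no
−ln(1−θ) linearization is applied. Loci monomorphic for the same allele in
both populations contribute nothing to either sum. Environmental distances
z-score each variable over the analyzed populations, take per-variable
|Δz|, and average within a category; a drop-one option removes one pathogen
group before averaging.

With Pearson correlations over the strict upper triangles,
r_XY·Z = (r_XY − r_XZ r_YZ)/√((1−r_XZ²)(1−r_YZ²)), R² = r_YZ² +
(1−r_YZ²)r_XY·Z², and I(R²) = R² − r_YZ² ∈ [0, 1−r_YZ²] is the improvement
in explained variance from adding environment on top of demography. Exact
collinearity of the covariate (|r_XZ| = 1, e.g. X = Z) is rejected rather
than reported as 0: the self-partialling limit is a 0/0 whose sample value
is not small.

Significance: Y's rows and columns are permuted simultaneously, but only
within continental strata, so the null preserves broad-scale structure; X
and Z are never permuted. p = (1 + #{permuted ≥ observed})/(1 + n_perm) —
the +1 convention keeps p > 0 (required by the GPD and FDR machinery) and
ties count as exceedances, which is conservative. A row-and-column
permutation of Y induces a Y-independent permutation of the pair vector, so
one permutation set per run serves every gene and the scan reduces to two
matrix products; per-gene p-values are unaffected, and the induced
cross-gene dependence is covered by the Benjamini–Yekutieli correction,
which is valid under arbitrary dependence.

For p-values below the permutation resolution, a generalized Pareto
distribution is fitted by maximum likelihood to the n_exc largest permuted
statistics in excess of a threshold t (midpoint between the n_exc-th and
(n_exc+1)-th largest; n_exc starts at min(250, n_perm/4)). The fit is
screened by an Anderson–Darling test against the Choulakian–Stephens
asymptotic 5% critical values (both parameters estimated), halving n_exc on
rejection and falling back to the empirical p if no fit is acceptable; when
at least 10 permuted values reach the observed statistic, the empirical p
is returned unchanged. Estimated tail p-values are floored at the smallest
positive double rather than reported as 0.

In per-variable mode each variable is tested separately, FDR is applied
within each variable's scan, and the gene × category result is the variable
with the largest I(R²).

## Synthetic panel generator

The generator emulates a worldwide genotyping panel with known ground
truth. Neutral frequencies follow two-level hierarchical drift
(Balding–Nichols-style truncated-normal perturbations): ancestral
p ~ U(0.05, 0.95); continental p_c = p + N(0, F_c·p(1−p)); population
p_cp = p_c + N(0, F_p·p_c(1−p_c)); each truncated to [0,1]. Defaults
F_continent = 0.1, F_population = 0.05 give a mean Weir–Cockerham F_ST
around 0.12–0.15, in the range of worldwide human panels; they are
calibration knobs, not estimates. Environment: continental means drawn from
a multivariate normal with pairwise correlation 0.3 (to exercise the
collinearity handling), plus population noise (sd 0.5 vs continental sd
1.0, so environment — like drift — is mostly continental); pathogen
variables are mapped to non-negative integer species richness (~60 ± 20
species), subsistence to activity percentages. 14 core variables
(5 climate, 5 subsistence, 4 pathogen groups) plus two optional
climate-range variables. Optionally a chosen number of populations lacks
subsistence values (`NA`), reproducing the listwise-dropping path.

Selected genes have all their SNP frequencies shifted by
effect_size × standardized driving variable *before* truncation and
folding — the observable is the folded minor allele frequency throughout,
so a shift across 0.5 can fold back, which genuinely attenuates the signal
at large effects. SNPs are laid out in contiguous gene blocks (genes inside
transcribed intervals, intergenic runs inside >100 kb gene-free gaps, so
the layout is consistent with the classifier's rules), and a smooth
positive AR(1)-lognormal covariate stands in for a recombination-rate
track.

Reference scenario (the study conditions): 55 populations in 6 continents
(10,9,9,9,9,9), 10,000 SNPs, 10 SNPs/gene → 500 genes, 20 genes driven by
helminth richness at effect 0.2, 3 populations missing subsistence. Ten
SNPs per gene reflects the ~15 genotyped SNPs per gene of worldwide panels
at desk scale. Null scenario for calibration: 30 populations in 5
continents, 500 genes, effect 0.

What the generator does **not** emulate: coalescent genealogies, LD beyond
gene-block grouping, ascertainment bias of genotyping arrays, migration or
admixture clines within continents, and realistic environmental geography
(values are exchangeable within continents, which is exactly what the
stratified permutation null assumes). Passing tests therefore demonstrate
the statistical machinery — calibration under a structured null, power
against planted frequency–environment coupling, demography correction — not
robustness to every feature of real data.

## Numerical and design notes

- Degenerate inputs: zero-variance responses raise; zero-variance
  predictors/variables are dropped with a warning; monomorphic loci return
  missing F_ST; genes with zero-variance distance triangles are skipped.
- Classification: "upstream" of the TSS is strand-aware by default (a flag
  disables it); coordinates are 1-based inclusive internally, BED converts
  at the boundary; gaps at chromosome flanks count as unbounded (>100 kb).
- Quantile stratification orders SNPs with a stable sort (ties broken by
  input order) and cuts equal-rank chunks, so class sizes differ by at most
  one up to tie-group granularity.
- All tables are plain text (TSV/CSV, `NA` missing token); identical
  configuration and seed reproduce byte-identical outputs.
- Scan sizes in the test suite and acceptance script (10k-SNP panels,
  n_perm = 999–1999 with GPD acceleration, 1000 bootstrap replicates) are
  the package's desk-scale defaults; all statistics scale linearly in SNPs
  and permutations.

## Known limitations

- The NIPALS component ceiling (3) and the UVE noise-column count (100) are
  conventions, exposed as arguments.
- GPD tail p-values extrapolate beyond the permutation support; at
  n_perm ≈ 2000 an extrapolation to p ≈ 1e-6 rests on ~250 order
  statistics. The Anderson–Darling screen catches gross misfit, not mild
  bias; q-values near the 0.05 boundary should be read accordingly.
- With correlated environmental variables, dropping a non-driving pathogen
  group can shift I(R²) for driven genes slightly (the remaining groups'
  weights change); the driving group's depression is the strongest
  signature, not the only one.
- Power depends on the ratio of within- to between-continent environmental
  variation: when environment is almost purely continental, the demography
  covariate (and the stratified null) absorb most of the signal — by
  design.
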
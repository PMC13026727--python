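# Methods

## The polygenic model and its estimation

Each quantitative trait y over n related individuals is modeled as
y = Xβ + g + e with Cov(g) = σ²g·A and Cov(e) = σ²e·I, where A = 2Φ is the
additive relationship matrix. Heritability is h² = σ²g/(σ²g + σ²e). The
model assumes additivity (no dominance or shared-household components),
multivariate normality of g and e, and a correctly specified A.

Estimation uses the spectral trick: with A = U Λ Uᵀ computed once per
roster, the rotated data ỹ = Uᵀy have independent entries with variance
σ²·(h²λᵢ + 1 − h²). For fixed h², β is weighted least squares and σ²
profiles out in closed form, leaving a one-dimensional likelihood in h²
maximized by bounded Brent search on [0, 1] (tolerance 1e−8). This
parameterization is derivative-free and cannot step outside the feasible
region, which matters because many expression traits sit at or near the
h² = 0 boundary. The default estimator is ML, with REML available; the two
agree to O(1/n) (verified at n ≈ 600 in the tests). The eigendecomposition
is cached and shared across all traits and genes scanned on the same
roster, so a scan costs O(n²) per trait after the one-time O(n³) factorization.
Rows with missing values are dropped and the rotation is recomputed
exactly on the reduced roster, cached by missingness pattern — no
imputation anywhere.

The standard error of ĥ² comes from the curvature of the profile
likelihood by central finite differences (step 1e−4, one-sided second
difference adjacent to a boundary; no SE is reported when ĥ² is pinned at
a bound). Fits flag `boundary` when ĥ² is within 1e−6 of 0 or 1 and
`identifiable = False` when the profile is flat to within 1e−9 per
observation across [0, 1] — the A = I case, where only σ²g + σ²e is
estimable.

Testing h² = 0 places σ²g on the boundary of its parameter space, so the
likelihood-ratio statistic follows the equal mixture ½χ²₀ + ½χ²₁ rather
than χ²₁; p = ½·P(χ²₁ ≥ Λ), giving p = 0.5 at Λ = 0. Calibration is
checked empirically (400 null replicates in the acceptance suite).

## BLUP endophenotypes

The genetic value of each individual for each expression trait is the
best linear unbiased prediction ĝ = σ̂²g·A·V̂⁻¹(y − Xβ̂), evaluated in the
rotated basis as a per-eigenvector shrinkage λᵢσ̂²g/(λᵢσ̂²g + σ̂²e) of the
fixed-effect residual — no explicit inverse. ĝ is exactly zero when
σ̂²g = 0 and exactly the residual when σ̂²e = 0. These predictions are the
"endophenotypes": estimates of the heritable component of expression,
stripped of environmental noise. Note that the realized prediction ĝ and
the realized residual y − Xβ̂ − ĝ are positively correlated by
construction (they share the rotated residual, weighted k and 1 − k); the
orthogonality property of BLUP concerns the prediction error g − ĝ, which
is uncorrelated with ĝ and is what the tests check against simulated truth.

## Association scan and joint tests

Endophenotypes enter the clinical-trait polygenic model as fixed-effect
covariates (the measured-predictor approach); the Wald statistic β̂/SE with
a normal reference gives the per-pair p-value, and Benjamini–Hochberg
adjustment runs within phenotype across genes. Negating an endophenotype
flips β and leaves p unchanged, which is how opposite-signed effect pairs
across genes present in the output.

Evidence across a phenotype set (default: AST, ALT, AST/ALT, CAP, FAST,
BDI-II) is combined per gene with Fisher's statistic −2Σln p ~ χ²₂ₖ. The
statistic assumes independent p-values; liver-injury traits are strongly
inter-correlated, so combined p-values are anti-conservative and reported
joint significance levels should be read as bounds. A permutation-calibrated
variant (`fisher_combine_permutation`) is provided as an optional robustness
mode: it conditions on each phenotype's fitted variance components, permutes
the endophenotype column across individuals (preserving the trait
correlation under the null of no association), and refers the observed
combined statistic to its permutation distribution. Genome-wide
multiplicity for combined tests is reported as Bonferroni (primary) and
BH (alongside) across genes.

The multivariate model vec(Y) ~ N((I_T⊗X)β, Σg⊗A + Σe⊗I) decouples, after
the same rotation, into n independent T-variate normals with covariance
λᵢΣg + Σe. Σg and Σe are parameterized through Cholesky factors (keeping
them PSD), β profiles out by GLS, and L-BFGS-B with three seeded starts
maximizes the likelihood; the trait count is capped at 6 to bound the
parameter count. With T = 1 this reduces exactly to the univariate fit,
and with cross-covariances pinned at zero the log-likelihood equals the
sum of the univariate ones — both are regression-tested. The joint
endophenotype test is a likelihood-ratio test (χ²_T) between multivariate
fits with and without the endophenotype as a fixed effect for every trait.

## Kinship

Pedigree relationships use the recursive (tabular) method: founders have
Φii = ½ and Φij = 0 among themselves; processing parents before children,
Φii = ½(1 + Φ(f, m)) and Φij = ½(Φ(f, j) + Φ(m, j)). The container stores
A = 2Φ so that σ²g·A gives h² its standard meaning; conversion happens
only at I/O. Externally estimated relationship matrices load from square
TSV or GCTA-style lower triplets; slight asymmetry (> 1e−6) is averaged
with a logged warning rather than rejected, eigenvalues above
−1e−8·trace are clipped to zero, and larger negativity is an error —
empirical GRMs are near-PSD but rarely exactly so. Whether a loaded GRM's
diagonal was inbreeding-adjusted is taken as-is.

## Normalization

Counts are converted to reads per kilobase (RPK), scaled across samples
by TMM factors computed on the RPK matrix, put on a per-million scale and
logged as log2(x + 0.5); the 0.5 offset keeps zeros finite and is
configurable. TMM details: the reference sample is the one whose
upper-quartile fraction is closest to the mean of those fractions; M and
A values are computed over genes expressed in both sample and reference;
the top and bottom 30% of M and 5% of A are discarded (doubly trimmed);
the factor is 2 to the inverse-variance weighted mean of the surviving M
values, and factors are rescaled to geometric mean 1. The gene weights
use the fraction-scale asymptotic variance (1 − p)/p per sample rather
than the depth-dependent count-scale form: this choice makes the
normalized output exactly invariant to rescaling any single library
(the depth factors otherwise shift factors by a few tenths of a percent),
and the two weightings coincide when depths are equal. Genes with zero
counts in every sample are dropped from factor computation with a logged
count.

Batch correction is a per-gene least-squares fit on [intercept, protected
covariates, sum-to-zero batch contrasts] with only the fitted batch terms
subtracted — exact for additive shifts, idempotent, and rank-checked
against confounding with protected covariates. Because the cohort design
this emulates is ambiguous about whether its final matrices were batch
corrected, the pipeline makes correction a config switch (default on) and
always writes before/after PCA score diagnostics so the instrument
clustering can be inspected either way.

## Phenotype preparation

Traits are regressed on [1, age, sex, age², sex·age, sex·age²]
(sex coded female 0 / male 1), and residuals are mapped to normal scores
z = Φ⁻¹((r − 3/8)/(n + 1/4)) with average ranks for ties. The Blom offset
3/8 is the default and configurable, since rank-based inverse-normal
conventions differ only in this constant; average-rank tie handling is
deterministic, which the byte-identical-rerun contract requires. BMI and
other liver-correlated clinical covariates are deliberately not
adjustment candidates. Missing trait values propagate pairwise per trait.
The sex-difference check is a Mann–Whitney U test: exact enumeration of
all C(n, n_a) relabelings for pooled n ≤ 12 (refused above 20), otherwise
a tie-corrected normal approximation with continuity correction.

## Enrichment

One-sided hypergeometric over-representation, p = P(X ≥ k) by exact pmf
summation, BH FDR across tested terms, significance flagged at
FDR < 0.05. The universe defaults to all annotated genes (configurable to
all scanned genes); query genes outside the universe are logged and
dropped. Depletion testing is out of scope.

## Synthetic data: what it emulates and what it does not

The generator produces disjoint outbred extended families: a founding
couple, each non-final-generation member marrying one immigrant founder,
and Poisson(mean sibship) offspring per couple. The default geometry —
20 families, 3 generations, mean sibship 4.5 — yields roughly 30 members
per family (n ≈ 600), the scale of a mid-sized family cohort; the actual
family-size distribution of any real cohort is not estimated, these are
plausible stand-ins. Expression traits are drawn as g + e with
Cov(g) = h²·σ²·A via a symmetric factorization of A; sequencing counts
are negative binomial (one global dispersion, default 0.1) with mean
proportional to exp(latent + batch offset)·length_kb·library size,
emulating a two-instrument batch structure; phenotypes add causal-gene
effects, an own polygenic term, age/sex covariate terms (ages uniform
18–80, sex Bernoulli ½) and noise, with optional missing-data injection
(default off).

What passing tests on these data show: the estimators recover the
parameters that generated the data, the tests are calibrated under the
generating model, and the algebraic identities (rotated vs dense
likelihoods, BLUP formulas, kinship recursion vs gene dropping) hold.
What they do not show: robustness to non-normal expression distributions,
assortative mating or inbreeding loops, misspecified relatedness,
genotype-level effects, or real batch artifacts beyond additive
log-scale shifts.

## Problem sizes and numerical choices

Simulation-based checks use 25 replicate traits at n ≈ 600 for
heritability recovery, 400 null replicates at n ≈ 300 for heritability-test
calibration, 500 null genes at n ≈ 600 for scan calibration, and 10⁵
allele drops for the kinship Monte-Carlo — sizes at which Monte-Carlo
error is well inside the asserted bands while the full suite stays fast.
Optimizer tolerances: 1e−8 on h²; 1e−12 relative function tolerance for
the multivariate quasi-Newton. Ties in TMM trimming are resolved by
average ranks. Degenerate inputs (constant traits, zero-variance
endophenotype columns, all-zero samples, confounded designs) raise typed
errors rather than propagating NaNs; zero-variance endophenotype columns
are skipped and counted during scans so one bad gene cannot halt a run.

## Known limitations

No dominance, household, or gene–environment interaction components; no
genotype or sequence simulation (relatedness is the only genetic
substrate); the default Fisher combination is anti-conservative under
trait correlation (use the permutation mode when that matters);
the multivariate model is capped at six traits; loaded GRMs are trusted
as supplied apart from symmetrization and the PSD tolerance.
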
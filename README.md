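# famendo

Family-based endophenotype analysis for quantitative traits measured on
related individuals — liver-injury markers (AST, ALT, AST/ALT, CAP, FAST,
kPa), depressive-symptom scores (BDI-II), and bulk gene-expression traits
on extended pedigrees.

The package is aimed at statistical geneticists working with family
cohorts: it estimates heritability by variance components on a
relationship matrix, extracts each individual's additive genetic value for
every expression trait by BLUP ("endophenotypes"), scans those
endophenotypes for association with clinical phenotypes while accounting
for relatedness, and combines evidence across phenotype sets with Fisher's
method. A synthetic-data generator produces pedigrees, counts and
phenotypes with known ground truth so the whole pipeline is testable
without access to any cohort.

## Model

For a trait **y** on *n* relatives with additive relationship matrix
**A** = 2Φ (Φ the kinship matrix):

```
y = Xβ + g + e,   g ~ N(0, σ²g A),   e ~ N(0, σ²e I),   h² = σ²g / (σ²g + σ²e)
```

A single eigendecomposition **A** = U Λ Uᵀ rotates the model into
independent observations with variances σ²·(h²λᵢ + 1 − h²); β and the
total variance profile out in closed form and h² is found by bounded
scalar maximization of the profiled (restricted) likelihood. The same
rotation gives

* the boundary-corrected likelihood-ratio test of h² = 0
  (p = ½·P(χ²₁ ≥ Λ), the equal mixture of χ²₀ and χ²₁),
* BLUP genetic values ĝ = σ̂²g A V̂⁻¹(y − Xβ̂) without forming V̂⁻¹,
* and a multivariate extension vec(Y) ~ N((I⊗X)β, Σg⊗A + Σe⊗I) for joint
  phenotype-level tests.

Around the core sit geTMM normalization of counts (reads per kilobase,
then trimmed-mean-of-M-values scaling), linear batch-effect removal with
protected covariates, covariate residualization
(age, sex, age², sex·age, sex·age²) with rank-based inverse-normal
scores, Fisher's combined test (−2Σln p ~ χ²₂ₖ), Benjamini–Hochberg FDR,
and hypergeometric gene-set over-representation.

## Worked example

```python
import numpy as np
import famendo as fm

ped = fm.simulate_pedigree(n_families=20, n_generations=3, mean_sibship=4.5, seed=11)
A = fm.kinship_from_pedigree(ped)
expr, truth = fm.simulate_expression(ped, A, n_genes=1, h2=0.6, total_var=1.0, seed=101)

y = expr.iloc[:, 0].to_numpy()
X = np.ones((len(ped), 1))
fit = fm.fit_polygenic(y, X, A)
null = fm.fit_polygenic(y, X, A, h2_fixed=0.0)
print(f"n = {fit.n}, h2 = {fit.h2:.3f} (SE {fit.se_h2:.3f}), p = {fm.h2_test(fit, null):.2e}")

g = fm.blup(fit, y, X, A)
r = np.corrcoef(g, truth.true_genetic_values[:, 0])[0, 1]
print(f"BLUP vs true genetic values: r = {r:.3f}")

res = fm.fisher_combine([0.05, 4.9e-4, 5.2e-3, 3.0e-2, 1.0, 2.3e-3])
print(f"Fisher combined: chi2 = {res.chi2:.1f} on {res.df} df, p = {res.p_combined:.2e}")
```

prints

```
n = 548, h2 = 0.534 (SE 0.082), p = 1.28e-14
BLUP vs true genetic values: r = 0.771
Fisher combined: chi2 = 50.9 on 12 df, p = 9.64e-07
```

A 548-member, 20-family pedigree gives an h² estimate of 0.53 for a trait
simulated at h² = 0.6 (the boundary-corrected test rejects h² = 0
decisively), the BLUP genetic values correlate 0.77 with the simulated
truth, and combining six per-trait p-values — here the published
ADAMTS7 associations across five liver traits and BDI-II — yields a joint
p of about 10⁻⁶, far below the conventional 0.05.

The full pipeline (normalize → prep → heritability → endophenotypes →
scan → combine → enrich) runs from a YAML config:

```
famendo simulate --out-dir inputs --seed 42
famendo run --config config.yaml
```

Every output TSV carries the tool version, config hash and seed in its
header, and reruns with the same config are byte-identical.

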
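"""Synthetic family data with known ground truth.

Generates multigenerational outbred pedigrees, heritable gene-expression
traits on a relationship matrix, negative-binomial sequencing counts with
batch and library-size structure, and pleiotropic phenotypes driven by
designated causal genes.  Every downstream stage of the pipeline can be
exercised against the stored truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "0"

__all__ = [
    "MISSING",
    "Individual",
    "Pedigree",
    "SimTruth",
    "simulate_pedigree",
    "simulate_expression",
    "simulate_counts",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None
    mother: str | None
    sex: str  # "male" | "female"
    generation: int


@dataclass
class Pedigree:
    """An ordered collection of individuals with parent links.

    Invariants (enforced by :meth:`validate`): unique ids, both parents
    missing for founders, named parents present with the correct sex, and
    no individual among its own ancestors.
    """

    individuals: list[Individual]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def validate(self) -> None:
        ids = self.ids
        if len(set(ids)) != len(ids):
            raise ValueError("pedigree ids are not unique")
        by_id = {ind.id: ind for ind in self.individuals}
        for ind in self.individuals:
            if (ind.father is None) != (ind.mother is None):
                raise ValueError(f"{ind.id}: one parent known, one missing")
            if ind.sex not in ("male", "female"):
                raise ValueError(f"{ind.id}: sex must be male or female")
            for parent, want in ((ind.father, "male"), (ind.mother, "female")):
                if parent is not None:
                    if parent not in by_id:
                        raise ValueError(f"{ind.id}: unknown parent {parent!r}")
                    if by_id[parent].sex != want:
                        raise ValueError(
                            f"{ind.id}: parent {parent!r} has sex "
                            f"{by_id[parent].sex}, expected {want}"
                        )
        # acyclicity by explicit ancestor traversal
        for ind in self.individuals:
            seen: set[str] = set()
            stack = [p for p in (ind.father, ind.mother) if p is not None]
            while stack:
                a = stack.pop()
                if a == ind.id:
                    raise ValueError(f"{ind.id} is its own ancestor")
                if a in seen:
                    continue
                seen.add(a)
                anc = by_id[a]
                stack.extend(p for p in (anc.father, anc.mother) if p is not None)

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.father is None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "father": [ind.father or MISSING for ind in self.individuals],
                "mother": [ind.mother or MISSING for ind in self.individuals],
                "sex": [ind.sex for ind in self.individuals],
                "generation": [ind.generation for ind in self.individuals],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().drop(columns="generation").to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str)
        required = {"id", "father", "mother", "sex"}
        if not required.issubset(df.columns):
            raise ValueError(f"pedigree CSV needs columns {sorted(required)}")
        inds = []
        # generation recovered as longest ancestor path
        parents = {
            r.id: (None if r.father == MISSING else r.father,
                   None if r.mother == MISSING else r.mother)
            for r in df.itertuples()
        }
        depth: dict[str, int] = {}

        def gen_of(i: str) -> int:
            if i in depth:
                return depth[i]
            f, m = parents[i]
            depth[i] = 0 if f is None else 1 + max(gen_of(f), gen_of(m))
            return depth[i]

        for r in df.itertuples():
            f, m = parents[r.id]
            inds.append(Individual(r.id, f, m, r.sex, gen_of(r.id)))
        return cls(inds)


@dataclass
class SimTruth:
    """Ground truth stored by the simulators for parameter-recovery tests."""

    true_h2: np.ndarray                       # per gene, in [0, 1]
    true_genetic_values: np.ndarray           # individuals x genes
    gene_ids: list[str]
    causal_genes: list[tuple[str, str, float]] = field(default_factory=list)
    batch_offsets: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_h2 = np.asarray(self.true_h2, dtype=float)
        if np.any((self.true_h2 < 0) | (self.true_h2 > 1)):
            raise ValueError("true_h2 must lie in [0, 1]")
        for gene, _pheno, _eff in self.causal_genes:
            if gene not in self.gene_ids:
                raise ValueError(f"causal gene {gene!r} not among simulated genes")


def simulate_pedigree(
    n_families: int,
    n_generations: int,
    mean_sibship: float,
    seed: int,
) -> Pedigree:
    """Simulate disjoint outbred extended families.

    Each family starts from a founding couple (generation 0).  Every
    non-final-generation individual born into the family marries one
    immigrant founder and the couple has ``Poisson(mean_sibship)``
    children, so no inbreeding loops arise and closed-form kinship values
    apply.  Reproducible for a fixed seed.
    """
    if n_families <= 0 or n_generations < 1 or mean_sibship <= 0:
        raise ValueError("n_families, n_generations, mean_sibship must be positive")
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []
    for fam in range(n_families):
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"F{fam + 1}-{counter}"

        father = Individual(new_id(), None, None, "male", 0)
        mother = Individual(new_id(), None, None, "female", 0)
        inds += [father, mother]
        couples = [(father, mother)]
        for gen in range(1, n_generations):
            next_couples = []
            for f, m in couples:
                n_kids = rng.poisson(mean_sibship)
                for _ in range(n_kids):
                    sex = "male" if rng.random() < 0.5 else "female"
                    child = Individual(new_id(), f.id, m.id, sex, gen)
                    inds.append(child)
                    if gen < n_generations - 1:
                        spouse_sex = "female" if sex == "male" else "male"
                        spouse = Individual(new_id(), None, None, spouse_sex, gen)
                        inds.append(spouse)
                        pair = (child, spouse) if sex == "male" else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples
    return Pedigree(inds)


def simulate_expression(
    pedigree: Pedigree,
    A,
    n_genes: int,
    h2,
    total_var: float,
    seed: int,
    gene_prefix: str = "GENE",
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw latent expression traits ``y = g + e`` on the relatedness structure.

    For gene j, the genetic value g is multivariate normal with covariance
    ``h2[j] * total_var * A`` (through a symmetric eigen-factorisation of A)
    and e is i.i.d. normal with variance ``(1 - h2[j]) * total_var``.  The
    simulated genetic values are stored in the returned :class:`SimTruth`.
    """
    from .kinship import RelationshipMatrix

    if not isinstance(A, RelationshipMatrix):
        raise TypeError("A must be a RelationshipMatrix")
    if list(A.roster) != pedigree.ids:
        A = A.reindex(pedigree.ids)
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), (n_genes,)).copy()
    if np.any((h2 < 0) | (h2 > 1)):
        raise ValueError("h2 must lie in [0, 1]")
    if total_var <= 0:
        raise ValueError("total_var must be positive")
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    L = A.sqrt_factor()  # raises if A not PSD within tolerance
    z = rng.standard_normal((n, n_genes))
    g = (L @ z) * np.sqrt(h2 * total_var)
    e = rng.standard_normal((n, n_genes)) * np.sqrt((1.0 - h2) * total_var)
    gene_ids = [f"{gene_prefix}{j + 1}" for j in range(n_genes)]
    latent = pd.DataFrame(g + e, index=pedigree.ids, columns=gene_ids)
    truth = SimTruth(
        true_h2=h2, true_genetic_values=g, gene_ids=gene_ids, seed=seed
    )
    return latent, truth


def simulate_counts(
    latent: pd.DataFrame,
    gene_lengths,
    library_sizes,
    batch,
    batch_offsets: dict[str, float],
    dispersion: float,
    seed: int,
) -> pd.DataFrame:
    """Negative-binomial read counts from latent log-scale expression.

    Expected count for gene j in sample i is proportional to
    ``exp(latent[i, j] + batch_offset[batch[i]]) * length_kb[j] * library_sizes[i]``;
    the dispersion parameter d gives variance ``mu + d * mu**2`` (the
    Poisson limit as d -> 0).  Returns a genes x samples integer frame.
    """
    gene_lengths = np.asarray(gene_lengths, dtype=float)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(gene_lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(library_sizes <= 0):
        raise ValueError("library sizes must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    n_samples, n_genes = latent.shape
    if gene_lengths.shape != (n_genes,) or library_sizes.shape != (n_samples,):
        raise ValueError("dimension mismatch between latent, lengths, libraries")
    batch = list(batch)
    if len(batch) != n_samples:
        raise ValueError("one batch label per sample required")
    offsets = np.array([batch_offsets[b] for b in batch], dtype=float)
    rng = np.random.default_rng(seed)
    mu = (
        np.exp(latent.to_numpy() + offsets[:, None])
        * (gene_lengths / 1000.0)[None, :]
        * library_sizes[:, None]
    )
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts.T, index=latent.columns, columns=latent.index)


def simulate_phenotypes(
    pedigree: Pedigree,
    A,
    truth: SimTruth,
    pheno_h2: float,
    covariate_effects: dict[str, float] | None = None,
    causal_genes: list[tuple[str, str, float]] | None = None,
    phenotype_names: list[str] | None = None,
    noise_var: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pleiotropic phenotypes with a polygenic term and age/sex covariates.

    Each phenotype is the sum of its causal genes' true genetic values
    (scaled by the stated effects), its own polygenic term with heritability
    ``pheno_h2`` on A, covariate terms in age, sex, age^2, sex*age and
    sex*age^2, and i.i.d. noise.  Ages are uniform on 18-80; sex is
    Bernoulli(0.5).  Returns a samples x columns table including ``age``
    and ``sex``.
    """
    from .kinship import RelationshipMatrix

    if not isinstance(A, RelationshipMatrix):
        raise TypeError("A must be a RelationshipMatrix")
    if list(A.roster) != pedigree.ids:
        A = A.reindex(pedigree.ids)
    if not 0.0 <= pheno_h2 <= 1.0:
        raise ValueError("pheno_h2 must lie in [0, 1]")
    covariate_effects = dict(covariate_effects or {})
    unknown = set(covariate_effects) - {"age", "sex", "age2", "sex_age", "sex_age2"}
    if unknown:
        raise ValueError(f"unknown covariate effect names: {sorted(unknown)}")
    causal = list(causal_genes if causal_genes is not None else truth.causal_genes)
    gene_index = {g: j for j, g in enumerate(truth.gene_ids)}
    for gene, _pheno, _eff in causal:
        if gene not in gene_index:
            raise ValueError(f"causal gene {gene!r} not in truth")
    if phenotype_names is None:
        phenotype_names = sorted({p for _g, p, _e in causal}) or ["TRAIT"]

    rng = np.random.default_rng(seed)
    n = len(pedigree)
    age = rng.uniform(18.0, 80.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)  # 1 = male
    L = A.sqrt_factor()
    out = pd.DataFrame(index=pedigree.ids)
    out["age"] = age
    out["sex"] = np.where(sex == 1.0, "male", "female")
    cov_term = (
        covariate_effects.get("age", 0.0) * age
        + covariate_effects.get("sex", 0.0) * sex
        + covariate_effects.get("age2", 0.0) * age**2
        + covariate_effects.get("sex_age", 0.0) * sex * age
        + covariate_effects.get("sex_age2", 0.0) * sex * age**2
    )
    for pheno in phenotype_names:
        y = cov_term.copy()
        for gene, target, eff in causal:
            if target == pheno:
                y = y + eff * truth.true_genetic_values[:, gene_index[gene]]
        if pheno_h2 > 0:
            y = y + np.sqrt(pheno_h2 * noise_var) * (L @ rng.standard_normal(n))
        y = y + np.sqrt((1.0 - pheno_h2) * noise_var) * rng.standard_normal(n)
        if missing_rate > 0.0:
            y = np.where(rng.random(n) < missing_rate, np.nan, y)
        out[pheno] = y
    truth.causal_genes = causal
    return out
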
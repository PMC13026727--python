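"""Phenotype preparation: covariate residualization, rank-based
inverse-normal transformation, and the nonparametric sex-difference test.

Traits are regressed on age, sex, age^2, sex*age and sex*age^2; residuals
are then mapped to normal scores.  Missing values propagate through every
step (pairwise per trait, no imputation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm, rankdata

__all__ = [
    "residualize",
    "inverse_normal",
    "mann_whitney",
    "prepare_phenotypes",
    "PhenotypeTable",
]

BLOM_OFFSET = 3.0 / 8.0
EXACT_LIMIT = 20  # enumeration above this is refused

TRAIT_COLUMNS = ["AST", "ALT", "AST/ALT", "CAP", "FAST", "kPa", "BDI-II"]


class DesignError(ValueError):
    pass


@dataclass
class PhenotypeTable:
    """Sample phenotype/covariate table with age, sex and trait columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("sample ids are not unique")
        for col in ("age", "sex"):
            if col not in df.columns:
                raise ValueError(f"phenotype table requires column {col!r}")
        if (df["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad_sex = set(df["sex"].dropna()) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unrecognized sex labels: {sorted(bad_sex)}")
        if {"AST", "ALT", "AST/ALT"}.issubset(df.columns):
            ok = df[["AST", "ALT", "AST/ALT"]].notna().all(axis=1)
            ratio = df.loc[ok, "AST"] / df.loc[ok, "ALT"]
            if not np.allclose(ratio, df.loc[ok, "AST/ALT"], rtol=1e-6, atol=1e-8):
                raise ValueError("AST/ALT column inconsistent with AST and ALT")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("age", "sex")]

    @classmethod
    def read_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0, comment="#"))

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.to_csv(fh, sep="\t")


def _design(age: np.ndarray, sex01: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(age), age, sex01, age**2, sex01 * age, sex01 * age**2]
    )


def residualize(trait, age, sex) -> np.ndarray:
    """OLS residuals of a trait on [1, age, sex, age^2, sex*age, sex*age^2].

    Sex is coded {female: 0, male: 1}.  Missing trait values are propagated;
    rows with missing covariates are treated as missing.
    """
    trait = np.asarray(trait, dtype=float)
    age = np.asarray(age, dtype=float)
    sex01 = _sex_to_01(sex)
    mask = ~(np.isnan(trait) | np.isnan(age) | np.isnan(sex01))
    if mask.sum() < 10:
        raise ValueError("need at least 10 non-missing observations")
    if len(set(sex01[mask])) < 2:
        raise DesignError("both sexes must be present")
    X = _design(age[mask], sex01[mask])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("rank-deficient covariate design (constant age?)")
    coef, *_ = np.linalg.lstsq(X, trait[mask], rcond=None)
    out = np.full_like(trait, np.nan)
    out[mask] = trait[mask] - X @ coef
    return out


def _sex_to_01(sex) -> np.ndarray:
    arr = np.asarray(sex, dtype=object)
    out = np.full(arr.shape, np.nan)
    out[arr == "male"] = 1.0
    out[arr == "female"] = 0.0
    numeric = np.array([isinstance(v, (int, float)) and v in (0, 1) for v in arr.ravel()])
    out.ravel()[numeric] = [float(v) for v in arr.ravel()[numeric]]
    return out.astype(float)


def inverse_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse-normal scores z_i = ndtri((r_i - c)/(n - 2c + 1)).

    Average ranks for ties; the Blom constant c = 3/8 is the default.
    Missing entries propagate.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    v = values[mask]
    if np.all(v == v[0]):
        raise ValueError("all values identical: inverse-normal undefined")
    ranks = rankdata(v, method="average")
    z = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    out = np.full_like(values, np.nan)
    out[mask] = z
    return out


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(a, b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U and two-sided p for a vs b.

    Exact mode enumerates every C(n_a + n_b, n_a) relabeling of the pooled
    sample (required for n <= 12, refused above 20); normal mode uses the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    if mode == "auto":
        mode = "exact" if n_a + n_b <= 12 else "normal"
    U = _u_statistic(a, b)
    if mode == "exact":
        if n_a + n_b > EXACT_LIMIT:
            raise ValueError(
                f"exact enumeration refused for n={n_a + n_b} > {EXACT_LIMIT}; "
                "use mode='normal'"
            )
        pooled = np.concatenate([a, b])
        idx = range(n_a + n_b)
        us = np.array(
            [
                _u_statistic(pooled[list(comb)], np.delete(pooled, list(comb)))
                for comb in itertools.combinations(idx, n_a)
            ]
        )
        p_lo = float(np.mean(us <= U))
        p_hi = float(np.mean(us >= U))
        return U, min(1.0, 2.0 * min(p_lo, p_hi))
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    N = n_a + n_b
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var == 0:
        return U, 1.0
    mean = n_a * n_b / 2.0
    z = (U - mean - 0.5 * np.sign(U - mean)) / math.sqrt(var) if U != mean else 0.0
    return U, float(2.0 * norm.sf(abs(z)))


def prepare_phenotypes(
    table: PhenotypeTable,
    traits: list[str] | None = None,
    offset: float = BLOM_OFFSET,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residualize and inverse-normal transform each trait.

    Returns the prepared trait matrix (aligned to the input index) and a
    per-trait report: n used, regression coefficients, and the
    Mann-Whitney U and p for the raw sex difference.
    """
    df = table.data
    traits = traits if traits is not None else table.traits
    prepared = pd.DataFrame(index=df.index)
    rows = []
    sex01 = _sex_to_01(df["sex"])
    for trait in traits:
        y = df[trait].to_numpy(dtype=float)
        resid = residualize(y, df["age"].to_numpy(dtype=float), df["sex"])
        prepared[trait] = inverse_normal(resid, offset=offset)
        males = y[(sex01 == 1.0) & ~np.isnan(y)]
        females = y[(sex01 == 0.0) & ~np.isnan(y)]
        U, p = mann_whitney(males, females, mode="normal")
        rows.append(
            {"trait": trait, "n": int(np.sum(~np.isnan(resid))),
             "mw_U": U, "mw_p": p}
        )
    return prepared, pd.DataFrame(rows)
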
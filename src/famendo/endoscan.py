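"""Endophenotype association scans and joint tests.

Each gene's BLUP genetic value enters the polygenic model of a prepared
phenotype as a fixed-effect covariate (measured-predictor approach); the
Wald test on that coefficient gives the per-pair association.  Evidence is
combined across a phenotype set with Fisher's method, multiplicity is
controlled per phenotype by Benjamini-Hochberg, and a multivariate mixed
model with Kronecker-structured covariance supplies the joint
phenotype-level test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from .kinship import RelationshipMatrix
from .polygenic import EigenA, FitError, fit_polygenic

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "CombinedTestResult",
    "MultivariateFit",
    "assoc_scan",
    "fisher_combine",
    "bh_adjust",
    "fit_multivariate",
    "joint_endophenotype_test",
]

MAX_TRAITS = 6  # parameter-count guard for the multivariate model
DEFAULT_TRAIT_SET = ["AST", "ALT", "AST/ALT", "CAP", "FAST", "BDI-II"]

# Published per-trait association p-values for the two headline genes of the
# family study this pipeline models (liver-injury markers plus depressive
# symptoms), used as worked-example inputs to fisher_combine.  The reported
# joint significance levels are upper bounds: the traits are strongly
# inter-correlated, so the independence-based combination is anti-conservative.
REPORTED_PVALUES = {
    "ADAMTS7": {
        "AST": 0.05, "ALT": 4.9e-4, "AST/ALT": 5.2e-3,
        "CAP": 3.0e-2, "FAST": 1.0, "BDI-II": 2.3e-3,
    },
    "THRAP3": {
        "AST": 5.6e-2, "ALT": 8.8e-4, "AST/ALT": 9.1e-3,
        "CAP": 2.2e-2, "FAST": 5.6e-2, "BDI-II": 1.4e-1,
    },
}
REPORTED_JOINT_BOUNDS = {"ADAMTS7": 2e-2, "THRAP3": 3.0e-2}


@dataclass
class AssociationRecord:
    gene_id: str
    phenotype: str
    beta: float
    se: float
    p: float
    q: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if self.se <= 0:
            raise ValueError("se must be positive")


@dataclass
class CombinedTestResult:
    gene_id: str
    trait_set: tuple[str, ...]
    chi2: float
    df: int
    p_combined: float

    def __post_init__(self) -> None:
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if self.df <= 0 or self.df % 2:
            raise ValueError("df must be a positive even integer")


def fisher_combine(
    pvalues, gene_id: str = "", trait_set: tuple[str, ...] = ()
) -> CombinedTestResult:
    """Fisher's combined probability test: -2 * sum(ln p) ~ chi2 on 2k df.

    Assumes independent p-values; for strongly correlated traits the
    combined p is anti-conservative and should be read as a bound.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("at least one p-value required")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return CombinedTestResult(
        gene_id=gene_id,
        trait_set=tuple(trait_set),
        chi2=stat,
        df=df,
        p_combined=float(chi2.sf(stat, df)),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def assoc_scan(
    endo: pd.DataFrame,
    phenos: pd.DataFrame,
    A: RelationshipMatrix | EigenA,
    covariates: np.ndarray | None = None,
    method: str = "ML",
) -> pd.DataFrame:
    """Kinship-aware association of every endophenotype with every phenotype.

    ``endo`` is samples x genes (BLUP genetic values), ``phenos`` samples x
    prepared traits, both indexed by the roster of ``A``.  For each pair
    the phenotype's polygenic model is refitted with the endophenotype as
    an extra fixed effect; the Wald statistic beta/se gives p, and q is BH
    within phenotype across genes.  Zero-variance endophenotype columns
    are recorded as errors and skipped.
    """
    eig = A if isinstance(A, EigenA) else EigenA(A)
    roster = eig.A.roster
    endo = endo.reindex(roster)
    phenos = phenos.reindex(roster)
    n = len(roster)
    base = [np.ones((n, 1))]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        base.append(cov)
    X0 = np.hstack(base)

    rows = []
    skipped = 0
    for pheno in phenos.columns:
        y = phenos[pheno].to_numpy(dtype=float)
        for gene in endo.columns:
            g = endo[gene].to_numpy(dtype=float)
            finite = g[~np.isnan(g)]
            if finite.size == 0 or np.var(finite) == 0.0:
                skipped += 1
                continue
            X = np.column_stack([X0, g])
            try:
                fit = fit_polygenic(y, X, eig, method=method)
            except (FitError, ValueError) as exc:
                logger.warning("scan %s x %s failed: %s", gene, pheno, exc)
                skipped += 1
                continue
            beta = float(fit.beta[-1])
            se = float(fit.beta_se[-1])
            p = float(2.0 * norm.sf(abs(beta / se))) if se > 0 else 1.0
            rows.append(
                {"gene_id": gene, "phenotype": pheno, "beta": beta,
                 "se": se, "p": max(p, np.finfo(float).tiny), "n": fit.n}
            )
    if skipped:
        logger.info("assoc_scan: %d gene x phenotype pairs skipped", skipped)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    for pheno, grp in out.groupby("phenotype"):
        out.loc[grp.index, "q"] = bh_adjust(grp["p"].to_numpy())
    return out


def fisher_combine_permutation(
    endo_col,
    phenos: pd.DataFrame,
    A: RelationshipMatrix | EigenA,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation-calibrated combined test for one endophenotype.

    Fisher's statistic assumes independent p-values, which correlated
    traits violate.  This robustness mode conditions on each phenotype's
    fitted variance components, recomputes the per-trait Wald p-values
    with the endophenotype column permuted across individuals, and
    compares the observed combined statistic to its permutation
    distribution — preserving the trait correlation under the null of no
    association.  Returns (observed chi2, permutation p).
    """
    eig = A if isinstance(A, EigenA) else EigenA(A)
    n = eig.n
    g = np.asarray(endo_col, dtype=float)
    if g.shape != (n,):
        raise ValueError("endophenotype must align with the roster")
    if np.var(g) == 0.0:
        raise ValueError("endophenotype has zero variance")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    parts = [np.ones((n, 1))]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        parts.append(cov)
    X0 = np.hstack(parts)

    rng = np.random.default_rng(seed)
    # observed column plus permuted replicates, rotated in one product
    G = np.empty((n, n_perm + 1))
    G[:, 0] = g
    for r in range(n_perm):
        G[:, r + 1] = g[rng.permutation(n)]
    Gt = eig.U.T @ G
    X0t = eig.U.T @ X0

    chi2_all = np.zeros(n_perm + 1)
    for pheno in phenos.columns:
        y = phenos.reindex(eig.A.roster)[pheno].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(
                f"phenotype {pheno!r} has missing values; complete cases only"
            )
        base = fit_polygenic(y, X0, eig)
        w = base.h2 * eig.lam + (1.0 - base.h2)
        wi = 1.0 / w
        yt = eig.U.T @ y
        for r in range(n_perm + 1):
            Xt = np.column_stack([X0t, Gt[:, r]])
            XtW = Xt * wi[:, None]
            Gram = Xt.T @ XtW
            beta = np.linalg.solve(Gram, XtW.T @ yt)
            resid = yt - Xt @ beta
            s2 = float(resid @ (resid * wi)) / n
            se = math.sqrt(np.linalg.inv(Gram)[-1, -1] * s2)
            z = beta[-1] / se
            p = max(float(2.0 * norm.sf(abs(z))), np.finfo(float).tiny)
            chi2_all[r] += -2.0 * math.log(p)
    observed = float(chi2_all[0])
    p_perm = float((1 + np.sum(chi2_all[1:] >= observed)) / (n_perm + 1))
    return observed, p_perm


# ---------------------------------------------------------------------------
# multivariate linear mixed model with Kronecker covariance
# ---------------------------------------------------------------------------


@dataclass
class MultivariateFit:
    """ML fit of vec(Y) ~ N((I_T kron X) beta, Sg kron A + Se kron I)."""

    Sigma_g: np.ndarray
    Sigma_e: np.ndarray
    beta: np.ndarray  # p x T coefficient matrix
    loglik: float
    n: int
    traits: list[str]
    converged: bool

    @property
    def genetic_correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.Sigma_g))
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.Sigma_g / np.outer(d, d)


def _chol_params_to_matrix(theta: np.ndarray, T: int) -> np.ndarray:
    L = np.zeros((T, T))
    idx = np.tril_indices(T)
    L[idx] = theta
    return L @ L.T


def _matrix_to_chol_params(S: np.ndarray) -> np.ndarray:
    T = S.shape[0]
    jitter = 1e-8 * max(np.trace(S) / T, 1.0)
    L = np.linalg.cholesky(S + jitter * np.eye(T))
    return L[np.tril_indices(T)]


def _mv_profile_loglik(
    Sg: np.ndarray,
    Se: np.ndarray,
    Yt: np.ndarray,
    Xt: np.ndarray,
    lam: np.ndarray,
) -> tuple[float, np.ndarray]:
    """ML log-likelihood with beta profiled out, in the rotated basis.

    Rotated observation i is a T-vector with covariance
    C_i = lambda_i * Sg + Se and mean B' x_i; the GLS solution for the
    p x T coefficient matrix B is computed by accumulating the normal
    equations over the n decoupled T-dimensional problems.
    """
    n, p = Xt.shape
    T = Yt.shape[1]
    C = lam[:, None, None] * Sg[None] + Se[None]  # (n, T, T)
    try:
        Lc = np.linalg.cholesky(C)
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros((p, T))
    logdets = 2.0 * float(np.sum(np.log(np.diagonal(Lc, axis1=1, axis2=2))))
    # normal equations of the GLS problem, block (a, b) weighted by Ci[:, a, b]
    lhs = np.einsum("nab,ni,nj->aibj", Ci, Xt, Xt).reshape(T * p, T * p)
    rhs = np.einsum("nab,nb,ni->ai", Ci, Yt, Xt).reshape(T * p)
    try:
        vecB = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros((p, T))
    B = vecB.reshape(T, p).T
    R = Yt - Xt @ B
    quad = float(np.einsum("na,nab,nb->", R, Ci, R))
    ll = -0.5 * (n * T * math.log(2.0 * math.pi) + logdets + quad)
    return ll, B


def fit_multivariate(
    Y: pd.DataFrame,
    X,
    A: RelationshipMatrix | EigenA,
    diagonal: bool = False,
    n_starts: int = 3,
    seed: int = 0,
) -> MultivariateFit:
    """Multivariate polygenic model by ML over Cholesky-parameterized
    genetic and environmental covariance matrices.

    Complete cases across all traits are used (listwise deletion).  With
    ``diagonal=True`` the cross-trait covariances are pinned at zero, in
    which case the likelihood factorizes into the univariate ones.
    Multi-start quasi-Newton guards against local optima.
    """
    eig = A if isinstance(A, EigenA) else EigenA(A)
    traits = list(Y.columns)
    T = len(traits)
    if T < 1:
        raise ValueError("at least one trait required")
    if T > MAX_TRAITS:
        raise ValueError(f"multivariate model limited to {MAX_TRAITS} traits")
    Yv = Y.reindex(eig.A.roster).to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != Yv.shape[0]:
        X = X.T
    mask = ~(np.isnan(Yv).any(axis=1) | np.isnan(X).any(axis=1))
    sub = eig.subset(mask)
    Yv, Xv = Yv[mask], X[mask]
    n, p = Xv.shape
    zero_var = np.flatnonzero(np.nanvar(Yv, axis=0) == 0.0)
    if zero_var.size:
        raise ValueError(f"trait {traits[zero_var[0]]!r} has zero variance")
    Yt = sub.U.T @ Yv
    Xt = sub.U.T @ Xv
    lam = sub.lam

    # moment starts: split each trait's variance between g and e
    var0 = Yv.var(axis=0, ddof=1)
    rng = np.random.default_rng(seed)

    if diagonal:
        def unpack(theta):
            return np.diag(theta[:T] ** 2), np.diag(theta[T:] ** 2)

        def pack(fg, fe):
            return np.concatenate([np.sqrt(np.diag(fg)), np.sqrt(np.diag(fe))])
    else:
        k = T * (T + 1) // 2

        def unpack(theta):
            return (
                _chol_params_to_matrix(theta[:k], T),
                _chol_params_to_matrix(theta[k:], T),
            )

        def pack(fg, fe):
            return np.concatenate(
                [_matrix_to_chol_params(fg), _matrix_to_chol_params(fe)]
            )

    def neg_ll(theta):
        Sg, Se = unpack(theta)
        ll, _ = _mv_profile_loglik(Sg, Se, Yt, Xt, lam)
        return -ll if math.isfinite(ll) else 1e12

    best = None
    for start in range(n_starts):
        frac = [0.5, 0.2, 0.8][start % 3]
        Sg0 = np.diag(var0 * frac)
        Se0 = np.diag(var0 * (1.0 - frac))
        theta0 = pack(Sg0, Se0)
        if start > 0:
            theta0 = theta0 * (1.0 + 0.1 * rng.standard_normal(theta0.shape))
        res = minimize(neg_ll, theta0, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):
        raise FitError("multivariate fit did not converge from any start")
    Sg, Se = unpack(best.x)
    ll, B = _mv_profile_loglik(Sg, Se, Yt, Xt, lam)
    return MultivariateFit(
        Sigma_g=Sg, Sigma_e=Se, beta=B, loglik=ll, n=n, traits=traits,
        converged=bool(best.success) or math.isfinite(ll),
    )


def joint_endophenotype_test(
    Y: pd.DataFrame,
    endo_gene,
    A: RelationshipMatrix | EigenA,
    covariates: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Phenotype-level joint test of one endophenotype across all traits.

    Likelihood-ratio test between multivariate fits with and without the
    endophenotype as a fixed effect for every trait; the statistic is
    referred to chi2 on T degrees of freedom.
    """
    eig = A if isinstance(A, EigenA) else EigenA(A)
    n = eig.n
    g = np.asarray(endo_gene, dtype=float)
    if g.shape != (n,):
        raise ValueError("endophenotype must align with the roster")
    if np.nanvar(g) == 0.0:
        raise ValueError("endophenotype has zero variance")
    parts = [np.ones((n, 1))]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        parts.append(cov)
    X0 = np.hstack(parts)
    X1 = np.column_stack([X0, g])
    fit0 = fit_multivariate(Y, X0, eig, seed=seed)
    fit1 = fit_multivariate(Y, X1, eig, seed=seed)
    T = len(Y.columns)
    lrt = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    return float(chi2.sf(lrt, df=T))


def combine_scan(
    scan: pd.DataFrame,
    trait_set: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher-combine each gene's p-values over a trait set, with
    Bonferroni and BH columns across genes."""
    trait_set = trait_set if trait_set is not None else DEFAULT_TRAIT_SET
    sub = scan[scan["phenotype"].isin(trait_set)]
    rows = []
    for gene, grp in sub.groupby("gene_id"):
        res = fisher_combine(grp["p"].to_numpy(), gene_id=gene,
                             trait_set=tuple(trait_set))
        rows.append(
            {"gene_id": gene, "trait_set": "|".join(trait_set),
             "chi2": res.chi2, "df": res.df, "p_combined": res.p_combined}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p_combined"] * m, 1.0)
    out["p_bh"] = bh_adjust(out["p_combined"].to_numpy())
    return out
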
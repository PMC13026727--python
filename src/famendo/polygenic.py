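"""Univariate polygenic mixed model on a relationship matrix.

The model for a quantitative trait y over n related individuals is

    y = X beta + g + e,   g ~ N(0, sigma2_g * A),   e ~ N(0, sigma2_e * I),

with A the additive relationship matrix.  A single eigendecomposition
A = U diag(lambda) U' rotates the problem into independent observations
with variances sigma2_total * (h2 * lambda_i + 1 - h2), so the fixed
effects and the total variance profile out in closed form and the
likelihood is maximized over h2 alone by bounded scalar search.  The same
rotation yields BLUP genetic values without forming any explicit inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .kinship import RelationshipMatrix

__all__ = ["PolygenicFit", "fit_polygenic", "h2_test", "blup", "EigenA"]

BOUNDARY_EPS = 1e-6
H2_XATOL = 1e-8
SE_STEP = 1e-4
FLAT_TOL = 1e-9  # profile range below this (per observation) => unidentifiable


class FitError(RuntimeError):
    pass


@dataclass
class EigenA:
    """Cached eigendecomposition of a relationship matrix.

    Reused across every trait and gene fitted on the same roster, so a
    scan costs O(n^2) per trait after one O(n^3) decomposition.  Subsets
    for missing-data patterns are recomputed exactly and cached keyed on
    the pattern.
    """

    A: RelationshipMatrix
    lam: np.ndarray = field(init=False)
    U: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lam, self.U = self.A.eigendecompose()
        self._subsets: dict[bytes, "EigenA"] = {}

    @property
    def n(self) -> int:
        return len(self.A)

    def subset(self, mask: np.ndarray) -> "EigenA":
        mask = np.asarray(mask, dtype=bool)
        if mask.all():
            return self
        key = np.packbits(mask).tobytes()
        if key not in self._subsets:
            ids = [s for s, keep in zip(self.A.roster, mask) if keep]
            self._subsets[key] = EigenA(self.A.reindex(ids))
        return self._subsets[key]


@dataclass
class PolygenicFit:
    """Variance components, heritability and fixed effects for one trait."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    beta: np.ndarray
    beta_se: np.ndarray
    loglik: float
    method: str
    n: int
    converged: bool
    boundary: bool
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.converged and not math.isfinite(self.loglik):
            raise ValueError("converged fit must have finite log-likelihood")


def _profile_loglik(
    h2: float,
    yt: np.ndarray,
    Xt: np.ndarray,
    lam: np.ndarray,
    method: str,
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Log-likelihood profiled over beta and total variance at fixed h2.

    Returns (loglik, beta_hat, sigma2_total_hat, XtWX_inv) in the rotated
    basis where observation i has variance sigma2_total * w_i with
    w_i = h2 * lambda_i + (1 - h2).
    """
    n, p = Xt.shape
    w = h2 * lam + (1.0 - h2)
    if np.any(w <= 0):
        return -np.inf, np.zeros(p), np.nan, np.full((p, p), np.nan)
    wi = 1.0 / w
    XtW = Xt * wi[:, None]
    G = Xt.T @ XtW
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(p), np.nan, np.full((p, p), np.nan)
    beta = Ginv @ (XtW.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid * wi))
    logdet_w = float(np.sum(np.log(w)))
    if method == "ML":
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet_w + n)
    elif method == "REML":
        sigma2 = rss / (n - p)
        sign, logdet_G = np.linalg.slogdet(G)
        if sign <= 0:
            return -np.inf, beta, sigma2, Ginv
        ll = -0.5 * (
            (n - p) * math.log(2 * math.pi * sigma2)
            + logdet_w
            + logdet_G
            + (n - p)
        )
    else:
        raise ValueError(f"method must be ML or REML, got {method!r}")
    return ll, beta, sigma2, Ginv


def fit_polygenic(
    y,
    X,
    A: RelationshipMatrix | EigenA,
    method: str = "ML",
    h2_fixed: float | None = None,
) -> PolygenicFit:
    """Fit the polygenic model by profiled (restricted) maximum likelihood.

    Rows of ``y`` and ``X`` must be aligned to the roster of ``A``; rows
    with missing values are dropped and the rotation recomputed on the
    reduced roster (exact, no imputation).  ``h2_fixed`` pins the
    heritability (used for null fits in the likelihood-ratio test).
    """
    eig = A if isinstance(A, EigenA) else EigenA(A)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if y.shape[0] != eig.n or X.shape[0] != eig.n:
        raise ValueError("y and X must be aligned to the relationship roster")
    mask = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    eig = eig.subset(mask)
    y, X = y[mask], X[mask]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")

    yt = eig.U.T @ y
    Xt = eig.U.T @ X
    lam = eig.lam

    def neg_ll(h2: float) -> float:
        return -_profile_loglik(h2, yt, Xt, lam, method)[0]

    if h2_fixed is not None:
        h2_hat = float(h2_fixed)
        converged = True
    else:
        res = minimize_scalar(
            neg_ll, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": H2_XATOL},
        )
        converged = bool(res.success)
        if not converged:
            raise FitError(f"h2 optimization failed: {res.message}")
        h2_hat = float(res.x)
        # bounded search never returns the exact endpoints; snap if better
        for edge in (0.0, 1.0):
            if neg_ll(edge) <= neg_ll(h2_hat) + 1e-12:
                h2_hat = edge

    ll, beta, sigma2, Ginv = _profile_loglik(h2_hat, yt, Xt, lam, method)
    if not math.isfinite(ll):
        raise FitError("log-likelihood not finite at the optimum")
    sigma2_g = h2_hat * sigma2
    sigma2_e = (1.0 - h2_hat) * sigma2
    beta_se = np.sqrt(np.diag(Ginv) * sigma2)

    boundary = h2_hat < BOUNDARY_EPS or h2_hat > 1.0 - BOUNDARY_EPS
    ll0 = _profile_loglik(0.0, yt, Xt, lam, method)[0]
    ll1 = _profile_loglik(1.0, yt, Xt, lam, method)[0]
    identifiable = (max(ll, ll0, ll1) - min(ll, ll0, ll1)) > FLAT_TOL * n

    se_h2 = _h2_standard_error(neg_ll, h2_hat) if h2_fixed is None else float("nan")
    return PolygenicFit(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        h2=h2_hat,
        se_h2=se_h2,
        beta=beta,
        beta_se=beta_se,
        loglik=ll,
        method=method,
        n=n,
        converged=converged,
        boundary=boundary,
        identifiable=identifiable,
    )


def _h2_standard_error(neg_ll, h2: float, step: float = SE_STEP) -> float:
    """Curvature-based SE by finite differences, one-sided at the bounds."""
    lo, hi = max(0.0, h2 - step), min(1.0, h2 + step)
    if hi - lo < step:  # pinned at a boundary
        return float("nan")
    f0, flo, fhi = neg_ll(h2), neg_ll(lo), neg_ll(hi)
    if h2 - lo == hi - h2:
        d2 = (flo - 2.0 * f0 + fhi) / step**2
    else:  # one-sided second difference near a boundary
        h = hi - lo
        mid = neg_ll((lo + hi) / 2.0)
        d2 = (flo - 2.0 * mid + fhi) / (h / 2.0) ** 2
    if d2 <= 0:
        return float("inf")
    return 1.0 / math.sqrt(d2)


def h2_test(fit_full: PolygenicFit, fit_null: PolygenicFit) -> float:
    """Boundary-corrected likelihood-ratio p-value for h2 = 0.

    The null pins sigma2_g at zero, which sits on the boundary of the
    parameter space, so the LRT statistic follows an equal mixture of
    chi2_0 and chi2_1: p = 0.5 * P(chi2_1 >= Lambda), and p = 0.5 when
    Lambda = 0.
    """
    if fit_full.n != fit_null.n:
        raise ValueError("full and null fits use different sample sets")
    if fit_full.method != fit_null.method:
        raise ValueError("full and null fits use different methods")
    lrt = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    return float(0.5 * chi2.sf(lrt, df=1))


def blup(
    fit: PolygenicFit,
    y,
    X,
    A: RelationshipMatrix | EigenA,
) -> np.ndarray:
    """Best linear unbiased prediction of the additive genetic values.

    g_hat = sigma2_g * A * V^{-1} * (y - X beta_hat) with
    V = sigma2_g * A + sigma2_e * I, evaluated in the rotated basis as
    U diag(sigma2_g * lambda / (sigma2_g * lambda + sigma2_e)) U' applied
    to the fixed-effect residual.  Entries for individuals dropped as
    missing are returned as NaN.
    """
    if not fit.converged:
        raise FitError("BLUP requires a converged fit")
    eig = A if isinstance(A, EigenA) else EigenA(A)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    mask = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    sub = eig.subset(mask)
    if mask.sum() != fit.n:
        raise ValueError("data passed to blup do not match the fit's sample set")
    if fit.sigma2_g == 0.0 and fit.sigma2_e == 0.0:
        raise FitError("both variance components are zero: V is singular")
    if fit.sigma2_g == 0.0:
        out = np.full(eig.n, np.nan)
        out[mask] = 0.0
        return out
    resid = y[mask] - X[mask] @ fit.beta
    rt = sub.U.T @ resid
    shrink = fit.sigma2_g * sub.lam / (fit.sigma2_g * sub.lam + fit.sigma2_e)
    out = np.full(eig.n, np.nan)
    out[mask] = sub.U @ (shrink * rt)
    return out
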
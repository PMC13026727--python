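"""RNA-seq normalization and batch diagnostics.

Implements gene-length-corrected TMM (geTMM): counts are first converted to
reads per kilobase (RPK), then scaled across samples with trimmed-mean-of-
M-values factors, and finally put on a log2 per-million scale.  Instrument
batch effects are removed by per-gene linear adjustment with sum-to-zero
batch contrasts, leaving protected covariate contributions untouched, and a
PCA diagnostic exposes the batch structure before and after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "tmm_factors",
    "getmm_normalize",
    "remove_batch",
    "pca_scores",
]

LOG_OFFSET = 0.5  # keeps zeros finite on the log2 scale


class NormalizationError(ValueError):
    pass


class DesignError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values at a declared processing scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str  # counts | rpk | getmm_log | batch_corrected
    gene_lengths_bp: np.ndarray | None = None

    _SCALES = ("counts", "rpk", "getmm_log", "batch_corrected")

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if self.scale not in self._SCALES:
            raise ValueError(f"scale must be one of {self._SCALES}")
        if self.scale in ("counts", "rpk") and (self.values < 0).any():
            raise ValueError(f"negative entries not allowed at scale={self.scale}")
        if self.gene_lengths_bp is not None:
            self.gene_lengths_bp = np.asarray(self.gene_lengths_bp, dtype=float)
            if self.gene_lengths_bp.shape != (len(self.gene_ids),):
                raise ValueError("one gene length per gene required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_counts_tsv(cls, path) -> "ExpressionMatrix":
        """Counts TSV: first column gene id, second gene length bp, then samples."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if df.shape[1] < 3:
            raise ValueError("counts TSV needs gene id, length and >=1 sample column")
        gene_ids = df.iloc[:, 0].astype(str).tolist()
        lengths = df.iloc[:, 1].to_numpy(dtype=float)
        vals = df.iloc[:, 2:].to_numpy(dtype=float)
        return cls(gene_ids, list(df.columns[2:]), vals, "counts", lengths)

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# scale={self.scale}\n")
            cols = ["gene_id"]
            if self.gene_lengths_bp is not None:
                cols.append("length_bp")
            cols += self.sample_ids
            fh.write("\t".join(cols) + "\n")
            for i, g in enumerate(self.gene_ids):
                row = [g]
                if self.gene_lengths_bp is not None:
                    row.append(f"{self.gene_lengths_bp[i]:.10g}")
                row += [f"{v:.10g}" for v in self.values[i]]
                fh.write("\t".join(row) + "\n")


def _rpk(counts: ExpressionMatrix) -> ExpressionMatrix:
    if counts.gene_lengths_bp is None:
        raise ValueError("gene lengths required to compute RPK")
    if (counts.gene_lengths_bp <= 0).any():
        bad = counts.gene_ids[int(np.argmax(counts.gene_lengths_bp <= 0))]
        raise ValueError(f"non-positive gene length for {bad}")
    vals = counts.values / (counts.gene_lengths_bp[:, None] / 1000.0)
    return replace(counts, values=vals, scale="rpk")


def tmm_factors(
    rpk: ExpressionMatrix, trim_M: float = 0.30, trim_A: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile fraction is closest
    to the mean of those fractions.  For each sample, per-gene log2 ratios M
    and average log2 abundances A are formed against the reference over
    genes expressed in both; the top/bottom ``trim_M`` of M and ``trim_A``
    of A are discarded and the factor is 2**(inverse-variance weighted mean
    of the surviving M values).
    """
    if rpk.scale != "rpk":
        raise ValueError("tmm_factors expects scale='rpk'")
    Y = rpk.values
    n_samples = Y.shape[1]
    if n_samples < 2:
        raise ValueError("at least 2 samples required")
    libsize = Y.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise NormalizationError(
            f"sample {rpk.sample_ids[zero[0]]} has all-zero values"
        )
    # drop genes never expressed
    expressed = Y.sum(axis=1) > 0
    n_dropped = int((~expressed).sum())
    if n_dropped:
        logger.info("tmm_factors: dropping %d all-zero genes", n_dropped)
    Y = Y[expressed]

    uq_frac = np.array(
        [np.quantile(Y[:, s][Y[:, s] > 0], 0.75) / libsize[s] for s in range(n_samples)]
    )
    ref = int(np.argmin(np.abs(uq_frac - uq_frac.mean())))

    factors = np.ones(n_samples)
    for s in range(n_samples):
        if s == ref:
            factors[s] = 1.0
            continue
        factors[s] = 2.0 ** _trimmed_weighted_mean_M(
            Y[:, s], Y[:, ref], libsize[s], libsize[ref], trim_M, trim_A
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _trimmed_weighted_mean_M(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_M: float,
    trim_A: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    p_obs, p_ref = obs[both] / n_obs, ref[both] / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    if M.size == 0:
        return 0.0
    if np.max(np.abs(M)) < 1e-10:
        return 0.0
    # doubly trimmed: keep genes inside both the M and the A trim windows
    n = M.size
    lo_M, hi_M = np.floor(n * trim_M) + 1, n - np.floor(n * trim_M)
    lo_A, hi_A = np.floor(n * trim_A) + 1, n - np.floor(n * trim_A)
    rank_M = _rank(M)
    rank_A = _rank(A)
    keep = (rank_M >= lo_M) & (rank_M <= hi_M) & (rank_A >= lo_A) & (rank_A <= hi_A)
    if not keep.any():
        return 0.0
    # inverse asymptotic-variance weights on the fraction scale,
    # (1-p)/p per sample; dropping the per-sample depth factor keeps the
    # factors exactly invariant to rescaling any one library
    w = 1.0 / ((1.0 - p_obs) / p_obs + (1.0 - p_ref) / p_ref)
    return float(np.sum(w[keep] * M[keep]) / np.sum(w[keep]))


def _rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def getmm_normalize(
    counts: ExpressionMatrix, trim_M: float = 0.30, trim_A: float = 0.05
) -> ExpressionMatrix:
    """geTMM: RPK, TMM scaling of the per-million denominator, then log2(x+0.5)."""
    if counts.scale != "counts":
        raise ValueError("getmm_normalize expects scale='counts'")
    rpk = _rpk(counts)
    if len(counts.sample_ids) == 1:
        factors = np.ones(1)
    else:
        factors = tmm_factors(rpk, trim_M=trim_M, trim_A=trim_A)
    colsum = rpk.values.sum(axis=0)
    per_million = rpk.values / (colsum * factors)[None, :] * 1e6
    vals = np.log2(per_million + LOG_OFFSET)
    return replace(counts, values=vals, scale="getmm_log")


def remove_batch(
    expr: ExpressionMatrix,
    batch,
    protect: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Subtract per-gene fitted batch terms (sum-to-zero contrasts).

    A least-squares fit on [intercept, protected covariates, batch
    contrasts] is computed per gene and only the batch part is removed, so
    contributions of the protected covariates survive.  Idempotent, and
    exact for purely additive batch shifts.
    """
    if expr.scale not in ("getmm_log", "batch_corrected"):
        raise ValueError("remove_batch expects log-scale expression")
    batch = np.asarray(list(batch))
    n_samples = len(expr.sample_ids)
    if batch.shape != (n_samples,):
        raise ValueError("one batch label per sample required")
    levels = sorted(set(batch.tolist()))
    if len(levels) < 2:
        return replace(expr, scale="batch_corrected")
    # sum-to-zero contrasts: last level is minus the sum of the others
    B = np.zeros((n_samples, len(levels) - 1))
    for k, lev in enumerate(levels[:-1]):
        B[batch == lev, k] = 1.0
    B[batch == levels[-1], :] = -1.0
    parts = [np.ones((n_samples, 1))]
    if protect is not None:
        protect = np.atleast_2d(np.asarray(protect, dtype=float))
        if protect.shape[0] != n_samples:
            protect = protect.T
        if protect.shape[0] != n_samples:
            raise ValueError("protect must have one row per sample")
        parts.append(protect)
    parts.append(B)
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("batch is confounded with a protected covariate")
    coef, *_ = np.linalg.lstsq(X, expr.values.T, rcond=None)
    batch_part = B @ coef[-B.shape[1]:, :]
    return replace(expr, values=expr.values - batch_part.T, scale="batch_corrected")


def pca_scores(expr: ExpressionMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores and variance-explained fractions from gene-centered SVD."""
    n_genes, n_samples = expr.values.shape
    if k > min(n_genes, n_samples) - 1:
        raise ValueError("k exceeds min(genes, samples) - 1")
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    total = float(np.sum(centered**2))
    if total == 0.0:
        raise ValueError("constant expression matrix: PCA undefined")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    scores = (Vt[:k].T * s[:k])  # samples x k
    var_explained = s[:k] ** 2 / total
    return scores, var_explained
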
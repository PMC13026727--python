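"""Additive relationship matrices: recursive pedigree kinship and GRM I/O.

The container stores A = 2*Phi (the additive relationship), so the polygenic
covariance is written ``sigma2_g * A`` and h2 keeps its standard meaning.
Externally supplied GRMs (square TSV or GCTA-style lower triplets) stand in
for marker-based empirical relatedness estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pedsim import Pedigree

logger = logging.getLogger(__name__)

__all__ = ["RelationshipMatrix", "kinship_from_pedigree", "read_grm", "write_grm"]

# eigenvalues above -PSD_TOL * trace are treated as numerical zero
PSD_TOL = 1e-8
ASYMMETRY_WARN = 1e-6


class MatrixFormatError(ValueError):
    """A relationship-matrix file violates its format contract."""


@dataclass
class RelationshipMatrix:
    """Symmetric PSD additive relationship matrix over an ordered roster."""

    roster: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.roster = list(self.roster)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roster)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match roster length")
        if len(set(self.roster)) != n:
            raise ValueError("roster ids are not unique")
        asym = float(np.max(np.abs(self.values - self.values.T), initial=0.0))
        if asym > ASYMMETRY_WARN:
            logger.warning("relationship matrix asymmetry %.3g; symmetrizing", asym)
        self.values = 0.5 * (self.values + self.values.T)
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.roster)

    def reindex(self, ids) -> "RelationshipMatrix":
        ids = list(ids)
        pos = {s: i for i, s in enumerate(self.roster)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"ids not in roster: {missing[:5]}")
        idx = np.array([pos[s] for s in ids])
        return RelationshipMatrix(ids, self.values[np.ix_(idx, idx)])

    def check_psd(self) -> float:
        """Return the smallest eigenvalue; raise if negativity exceeds tolerance."""
        w = np.linalg.eigvalsh(self.values)
        lo = float(w[0])
        tol = PSD_TOL * max(float(np.trace(self.values)), 1.0)
        if lo < -tol:
            raise MatrixFormatError(
                f"matrix is not positive semidefinite: min eigenvalue {lo:.3g}"
            )
        return lo

    def eigendecompose(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition with small negative eigenvalues clipped."""
        if self._eig is None:
            w, U = np.linalg.eigh(self.values)
            tol = PSD_TOL * max(float(np.trace(self.values)), 1.0)
            if w[0] < -tol:
                raise MatrixFormatError(
                    f"matrix is not positive semidefinite: min eigenvalue {w[0]:.3g}"
                )
            w = np.clip(w, 0.0, None)
            self._eig = (w, U)
        return self._eig

    def sqrt_factor(self) -> np.ndarray:
        """Symmetric factor L with L @ L.T = A."""
        w, U = self.eigendecompose()
        return U * np.sqrt(w)


def kinship_from_pedigree(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the recursive (tabular) kinship method.

    Founders have Phi_ii = 1/2 and Phi_ij = 0 among themselves; processing
    parents before children,

        Phi_ii = 1/2 * (1 + Phi(father, mother))
        Phi_ij = 1/2 * (Phi(father, j) + Phi(mother, j))

    and the returned matrix is A = 2*Phi in pedigree roster order.
    """
    ids = ped.ids
    pos = {s: i for i, s in enumerate(ids)}
    by_id = {ind.id: ind for ind in ped}
    # topological order: parents first (generation is a valid topological key)
    order = sorted(ids, key=lambda s: by_id[s].generation)
    n = len(ids)
    phi = np.zeros((n, n))
    done: list[str] = []
    for s in order:
        i = pos[s]
        ind = by_id[s]
        if ind.father is None:
            phi[i, i] = 0.5
        else:
            fi, mi = pos[ind.father], pos[ind.mother]
            phi[i, i] = 0.5 * (1.0 + phi[fi, mi])
            for t in done:
                j = pos[t]
                val = 0.5 * (phi[fi, j] + phi[mi, j])
                phi[i, j] = phi[j, i] = val
        done.append(s)
    return RelationshipMatrix(ids, 2.0 * phi)


def _read_square_tsv(path: Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if list(map(str, df.index)) != ids:
        raise MatrixFormatError(f"{path}: row ids do not match column header ids")
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any():
        r, c = np.argwhere(np.isnan(vals))[0]
        raise MatrixFormatError(f"{path}: NaN entry at row {ids[r]}, column {ids[c]}")
    return ids, vals


def _read_lower_triplets(path: Path) -> tuple[list[str], np.ndarray]:
    # GCTA text convention: <path> has "i j nsnp value" rows (1-based, lower
    # triangle incl. diagonal); <path>.id carries the roster, one id per line
    # (family/individual columns allowed; the last column is used).
    id_path = Path(str(path) + ".id")
    if not id_path.exists():
        raise MatrixFormatError(f"id file {id_path} not found")
    ids = [line.split()[-1] for line in id_path.read_text().splitlines() if line.strip()]
    n = len(ids)
    vals = np.full((n, n), np.nan)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise MatrixFormatError(f"{path}:{lineno}: expected 4 columns")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        v = float(parts[3])
        if np.isnan(v):
            raise MatrixFormatError(f"{path}:{lineno}: NaN value")
        if not (0 <= j <= i < n):
            raise MatrixFormatError(f"{path}:{lineno}: index out of range")
        vals[i, j] = vals[j, i] = v
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise MatrixFormatError(f"{path}: missing entry for ({ids[i]}, {ids[j]})")
    return ids, vals


def read_grm(path, format: str = "square_tsv") -> RelationshipMatrix:
    """Read a relationship matrix, symmetrize by averaging, and PSD-check it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "square_tsv":
        ids, vals = _read_square_tsv(path)
    elif format == "lower_triplets":
        ids, vals = _read_lower_triplets(path)
    else:
        raise ValueError(f"unknown GRM format {format!r}")
    A = RelationshipMatrix(ids, vals)
    A.check_psd()
    return A


def write_grm(A: RelationshipMatrix, path, format: str = "square_tsv") -> None:
    """Write a relationship matrix as stable text with 10 significant digits."""
    path = Path(path)
    if format == "square_tsv":
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(A.roster) + "\n")
            for i, s in enumerate(A.roster):
                row = "\t".join(f"{v:.10g}" for v in A.values[i])
                fh.write(f"{s}\t{row}\n")
    elif format == "lower_triplets":
        with open(str(path) + ".id", "w") as fh:
            for s in A.roster:
                fh.write(f"{s}\t{s}\n")
        with open(path, "w") as fh:
            for i in range(len(A)):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t0\t{A.values[i, j]:.10g}\n")
    else:
        raise ValueError(f"unknown GRM format {format!r}")
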
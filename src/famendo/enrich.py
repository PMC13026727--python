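"""Over-representation analysis of a query gene set.

One-sided hypergeometric tests of a query list against annotation terms
(GMT format), with Benjamini-Hochberg FDR across tested terms and a
significance flag at FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .endoscan import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "hypergeom_enrich"]

FDR_THRESHOLD = 0.05


@dataclass
class GeneSetCollection:
    """Annotation terms with member genes over a gene universe.

    The universe defaults to all genes carrying at least one annotation;
    members outside a supplied universe are dropped at harmonization.
    """

    terms: dict[str, tuple[str, frozenset[str]]]  # id -> (name, members)
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(
                *(m for _name, m in self.terms.values())
            ) if self.terms else frozenset()
        self.terms = {
            tid: (name, members & self.universe)
            for tid, (name, members) in self.terms.items()
        }


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read tab-separated GMT: term id, description, member genes."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 fields")
            tid, name, members = parts[0], parts[1], frozenset(parts[2:])
            if tid in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {tid!r}")
            terms[tid] = (name, members)
    return GeneSetCollection(
        terms, frozenset(universe) if universe is not None else frozenset()
    )


def hypergeom_enrich(
    query,
    sets: GeneSetCollection,
    min_term_size: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation p = P(X >= k) per term, BH FDR.

    Query genes outside the universe are logged and dropped.  Terms
    smaller than ``min_term_size`` are skipped.  Sorted by FDR.
    """
    query = set(query)
    outside = query - sets.universe
    if outside:
        logger.warning(
            "hypergeom_enrich: dropping %d query genes outside the universe",
            len(outside),
        )
    query &= sets.universe
    if not query:
        raise ValueError("query is empty after harmonization with the universe")
    N = len(sets.universe)
    n = len(query)
    rows = []
    for tid, (name, members) in sets.terms.items():
        K = len(members)
        if K < min_term_size:
            continue
        k = len(query & members)
        # exact upper tail by pmf summation
        ks = np.arange(k, min(K, n) + 1)
        p = float(np.sum(hypergeom.pmf(ks, N, K, n))) if ks.size else 1.0
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append(
            {"term_id": tid, "term_name": name, "k": k, "K": K,
             "n": n, "N": N, "p": p}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["fdr"] < FDR_THRESHOLD
    return out.sort_values("fdr", kind="stable").reset_index(drop=True)
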
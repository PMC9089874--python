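"""Gene-set over-representation with Benjamini-Hochberg control.

The statistic is the exact one-sided hypergeometric tail: drawing the
``n`` query genes uniformly from a universe of ``N`` genes of which ``K``
belong to the set, the p-value is P(X >= k) for the observed overlap
``k``.  Q-values come from the Benjamini-Hochberg step-up procedure; a
set is called significant when q < alpha (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["GeneSet", "EnrichmentResult", "read_gmt", "parse_gmt",
           "hypergeom_pvalue", "bh_adjust", "enrich", "results_to_frame"]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    k: int   # overlap with query
    K: int   # set size within the universe
    n: int   # query size
    N: int   # universe size
    p_value: float
    q_value: float
    significant: bool

    @property
    def coverage(self) -> str:
        return f"{self.k}/{self.K}"


def parse_gmt(text: str) -> list[GeneSet]:
    """Parse GMT text: one set per line, tab-delimited
    ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.  Member lists are
    deduplicated; sets with no members are dropped."""
    sets = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"GMT line {lineno}: expected >= 2 tab-separated columns")
        members = frozenset(g for g in fields[2:] if g)
        if not members:
            continue
        sets.append(GeneSet(set_id=fields[0], name=fields[1], members=members))
    return sets


def read_gmt(path: str) -> list[GeneSet]:
    with open(path) as fh:
        return parse_gmt(fh.read())


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, take q(i) = min over j >= i of p(j) * m / j, cap at 1,
    and return in the original input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def enrich(
    query_genes,
    gene_sets: list[GeneSet],
    universe,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of a query gene list against each gene set.

    Query genes outside the universe are dropped (with the effective query
    size reflecting the drop); each set is intersected with the universe
    first and sets that vanish are skipped.  Results are sorted by
    (q, p, set_id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    n, N = len(query), len(universe)
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        rows.append((gs, k, K, hypergeom_pvalue(k, K, n, N)))
    if not rows:
        return []
    q = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(
            set_id=gs.set_id, name=gs.name, k=k, K=K, n=n, N=N,
            p_value=p, q_value=float(qv), significant=bool(qv < alpha),
        )
        for (gs, k, K, p), qv in zip(rows, q)
    ]
    return sorted(results, key=lambda r: (r.q_value, r.p_value, r.set_id))


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id, "name": r.name, "k": r.k, "K": r.K,
                "n": r.n, "N": r.N, "p_value": r.p_value, "q_value": r.q_value,
                "coverage": r.coverage, "significant": r.significant,
            }
            for r in results
        ],
        columns=["set_id", "name", "k", "K", "n", "N", "p_value", "q_value",
                 "coverage", "significant"],
    )
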
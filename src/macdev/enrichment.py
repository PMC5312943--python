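"""Hypergeometric over-representation tests with Benjamini-Hochberg correction.

Used for GO terms, protein domains, and curated gene lists within a gene set
drawn from a declared universe. The test statistic is the upper tail
P(X >= k) of the hypergeometric distribution, evaluated in log space so that
p-values far below double-precision epsilon (the printed bounds reach 1e-16)
remain meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Natural log of P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size; K: annotated genes in the universe; n: genes drawn
    (the query set); k: annotated genes observed in the draw.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 0.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(logsumexp(log_terms), 0.0))


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    return float(np.exp(log_hypergeom_upper(k, K, n, N)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AnnotationTable:
    """term ID -> gene set, with a class per term (GO / domain / curated)."""

    terms: dict[str, set[str]]
    term_class: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.terms) ^ set(self.term_class)
        if unknown:
            raise ValueError(f"terms without class (or vice versa): {sorted(unknown)}")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "AnnotationTable":
        """Build from a long table with columns term_id, term_class, gene_id."""
        terms: dict[str, set[str]] = {}
        klass: dict[str, str] = {}
        for r in table.itertuples():
            terms.setdefault(str(r.term_id), set()).add(str(r.gene_id))
            klass[str(r.term_id)] = str(r.term_class)
        return cls(terms, klass)

    def classes(self) -> list[str]:
        return sorted(set(self.term_class.values()))


def enrich(gene_set, annotations: AnnotationTable, universe) -> pd.DataFrame:
    """Per-term over-representation of ``gene_set`` within ``universe``.

    Terms are restricted to the universe; every term with at least one
    universe member is reported (k = 0 terms included at p = 1 so the BH
    denominator is reproducible). BH adjustment is applied within each term
    class separately. Results are sorted by raw p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene set is not contained in the universe")
    N, n = len(universe), len(gene_set)
    rows = []
    for term, genes in annotations.terms.items():
        in_universe = genes & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & gene_set)
        rows.append(
            {
                "term_id": term,
                "term_class": annotations.term_class[term],
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_upper(k, K, n, N),
                "log_p_raw": log_hypergeom_upper(k, K, n, N),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["term_id", "term_class", "k", "K", "n", "N", "p_raw", "log_p_raw"],
    )
    if result.empty:
        result["p_adj"] = []
        return result
    result["p_adj"] = np.nan
    for klass, idx in result.groupby("term_class").groups.items():
        result.loc[idx, "p_adj"] = bh_adjust(result.loc[idx, "p_raw"].to_numpy())
    return result.sort_values("p_raw", kind="stable").reset_index(drop=True)
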
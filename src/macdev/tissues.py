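"""Projection of an ortholog gene set onto a tissue expression compendium.

Abundances are log2(x+1)-transformed, mean-centered per gene across samples,
and collapsed to per-site means. A gene set's relative expression is compared
across body sites via per-site ECDFs: a site is flagged as shifted when the
median of the set's values there exceeds the pooled median of all other sites
by a threshold (default 0.5 log2 units) with a two-sided Mann-Whitney
p < 0.01. Tissue-specific genes are those whose centered value at one site
strictly exceeds every other site by > log2(fold) (default 2-fold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def normalize_tissue(raw: pd.DataFrame, site_map: dict[str, str]) -> pd.DataFrame:
    """log2(x+1), per-gene mean-centering over samples, then per-site means.

    ``site_map`` maps every sample (column) to a body site. Returns a
    gene x site matrix of relative log2 expression.
    """
    unmapped = [c for c in raw.columns if c not in site_map]
    if unmapped:
        raise ValueError(f"samples without a site assignment: {unmapped}")
    logged = np.log2(raw + 1.0)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    sites = pd.Index([site_map[c] for c in centered.columns], name="site")
    return centered.T.groupby(sites).mean().T


@dataclass
class SiteShift:
    """Per-site ECDF and shift statistics for a projected gene set."""

    table: pd.DataFrame  # index site; median_shift, p, flagged
    ecdfs: dict[str, np.ndarray]  # site -> sorted relative values


def site_cdf_shift(
    tm: pd.DataFrame,
    gene_set,
    shift_threshold: float = 0.5,
    alpha: float = 0.01,
) -> SiteShift:
    """Detect body sites where a gene set's expression distribution is shifted.

    For each site: shift statistic = median of the set's values at that site
    minus the pooled median over all other sites; flagged when the statistic
    exceeds ``shift_threshold`` and a two-sided Mann-Whitney test against the
    pooled values gives p < ``alpha``.
    """
    gene_set = [g for g in gene_set if g in tm.index]
    missing = len(list(gene_set)) == 0
    if missing:
        raise ValueError("gene set has no members in the tissue matrix")
    if len(gene_set) < 10:
        logger.warning("gene set has only %d members; shift test is weak", len(gene_set))
    if tm.shape[1] < 2:
        raise ValueError("need at least 2 sites")
    sub = tm.loc[gene_set]
    rows = []
    ecdfs: dict[str, np.ndarray] = {}
    for site in sub.columns:
        here = sub[site].to_numpy()
        others = sub.drop(columns=site).to_numpy().ravel()
        shift = float(np.median(here) - np.median(others))
        if len(here) >= 1 and len(others) >= 1:
            p = float(stats.mannwhitneyu(here, others, alternative="two-sided").pvalue)
        else:
            p = 1.0
        rows.append({"site": site, "median_shift": shift, "p": p,
                     "flagged": shift > shift_threshold and p < alpha})
        ecdfs[site] = np.sort(here)
    return SiteShift(pd.DataFrame(rows).set_index("site"), ecdfs)


def tissue_specific_genes(tm: pd.DataFrame, fold: float = 2.0) -> dict[str, str]:
    """Genes whose expression at one site strictly dominates all others.

    A gene is assigned to site s iff its value at s exceeds its value at
    every other site by more than log2(fold) (strict). The strict dominance
    rule forces at most one site per gene.
    """
    if tm.shape[1] < 2:
        raise ValueError("need at least 2 sites")
    margin = np.log2(fold)
    vals = tm.to_numpy()
    order = np.argsort(vals, axis=1)
    top, second = order[:, -1], order[:, -2]
    rows = np.arange(len(tm))
    called = vals[rows, top] > vals[rows, second] + margin
    sites = tm.columns.to_numpy()
    return {
        gene: sites[top[i]]
        for i, (gene, hit) in enumerate(zip(tm.index, called))
        if hit
    }
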
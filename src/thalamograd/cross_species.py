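"""Homologue filtering and cross-species comparison of gene loadings.

Gene pairs are retained when they (i) appear in the homology table, (ii)
are on the protein-expression list for the first species' thalamus, and
(iii) exceed an aggregated-expression cutoff in the second species (top 75%
by default, i.e. strictly above the 25th percentile). One-to-many
homologies are collapsed to the partner with the highest aggregated
expression (ties by gene id). Component loadings of the mapped pairs are
then compared by Pearson correlation with an analytic Fisher-z interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .axis_genes import fisher_ci


@dataclass
class HomologueMap:
    pairs: pd.DataFrame     # all input pairs with filter flags
    retained: pd.DataFrame  # one-to-one pairs passing every filter
    quantile_cutoff: float  # aggregated-expression boundary value

    def __len__(self) -> int:
        return len(self.retained)


@dataclass
class CorrelationResult:
    r: float
    ci: tuple[float, float]
    p: float
    n: int


def filter_homologues(
    homology: pd.DataFrame,
    protein_genes,
    expression_aggregate: pd.Series,
    top_fraction: float = 0.75,
    gene_a_col: str = "gene_a",
    gene_b_col: str = "gene_b",
) -> HomologueMap:
    """Apply the homologue filters and collapse to a one-to-one map.

    ``expression_aggregate`` is keyed by the second species' gene ids
    (aggregated UMI counts across cell types); ``top_fraction=0.75`` keeps
    genes strictly above the 25th percentile of that aggregate. The result
    is order-independent in the input rows.
    """
    for col in (gene_a_col, gene_b_col):
        if col not in homology.columns:
            raise ValueError(f"homology table missing key column {col!r}")
    pairs = homology[[gene_a_col, gene_b_col]].rename(
        columns={gene_a_col: "gene_a", gene_b_col: "gene_b"}
    )
    pairs = pairs.drop_duplicates().sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    protein = set(protein_genes)
    # empirical-rank boundary: the cutoff is the largest value whose CDF is
    # <= (1 - top_fraction); genes strictly above it are kept, so "top 75%"
    # of 10 genes keeps the 8 highest
    vals = np.sort(expression_aggregate.to_numpy(float))
    k = int(np.floor((1.0 - top_fraction) * len(vals)))
    cutoff = float(vals[k - 1]) if k > 0 else -np.inf
    expr = expression_aggregate
    pairs["has_homologue"] = True
    pairs["protein_expressed"] = pairs["gene_a"].isin(protein)
    pairs["aggregated_expression"] = pairs["gene_b"].map(expr)
    pairs["above_expression_quantile"] = pairs["aggregated_expression"] > cutoff
    passing = pairs[
        pairs["protein_expressed"]
        & pairs["above_expression_quantile"]
        & pairs["aggregated_expression"].notna()
    ].copy()
    # collapse one-to-many: keep the partner with highest aggregated
    # expression, ties by gene_b id (ascending) for determinism
    passing = passing.sort_values(
        ["gene_a", "aggregated_expression", "gene_b"],
        ascending=[True, False, True],
    )
    retained = passing.drop_duplicates("gene_a").reset_index(drop=True)
    return HomologueMap(pairs=pairs, retained=retained, quantile_cutoff=cutoff)


def loading_correlation(
    hmap: HomologueMap, loadings_a: pd.Series, loadings_b: pd.Series
) -> CorrelationResult:
    """Pearson correlation of component loadings over mapped gene pairs."""
    pairs = hmap.retained
    common = pairs[
        pairs["gene_a"].isin(loadings_a.index) & pairs["gene_b"].isin(loadings_b.index)
    ]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} mapped pairs with loadings; need >= 3")
    a = loadings_a.loc[common["gene_a"]].to_numpy(float)
    b = loadings_b.loc[common["gene_b"]].to_numpy(float)
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(r=float(r), ci=fisher_ci(r, len(a)), p=float(p), n=len(a))


def score_vs_hierarchy(
    nucleus_scores: pd.Series, hierarchy_values: pd.Series
) -> CorrelationResult:
    """Plain Pearson correlation of nucleus-level scores with an external
    hierarchy measure (non-spatial test, as appropriate for nucleus data)."""
    if set(nucleus_scores.index) != set(hierarchy_values.index):
        raise ValueError("nucleus labels do not match between scores and hierarchy")
    h = hierarchy_values.reindex(nucleus_scores.index)
    r, p = stats.pearsonr(nucleus_scores.to_numpy(float), h.to_numpy(float))
    return CorrelationResult(
        r=float(r), ci=fisher_ci(r, len(h)), p=float(p), n=len(h)
    )
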
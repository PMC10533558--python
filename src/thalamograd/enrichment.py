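"""Hypergeometric overrepresentation analysis with signed enrichment ratios.

Given an axis-gene selection (positive and negative lists) and a family of
annotated marker sets, each set is tested for overrepresentation in each
list with the upper-tail hypergeometric probability P(X >= x), the fold
enrichment (x/n) / (K/N), and Benjamini-Hochberg FDR across the family. The
signed medial-lateral ratio is +ratio when the set is enriched in the
positive-axis (lateral) list and -ratio for the negative-axis (medial) list.

All set sizes are computed after intersecting with an explicit background
universe; the universe is a parameter, never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentInput:
    """Sizes for one hypergeometric test.

    N: background size; K: annotated-set size within the background;
    n: selection size within the background; x: overlap of selection with
    the annotated set.
    """

    N: int
    K: int
    n: int
    x: int

    def validate(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError("K and n must lie within the background size N")
        if not (0 <= self.x <= min(self.K, self.n)):
            raise ValueError("overlap x must satisfy 0 <= x <= min(K, n)")


def hypergeometric_tail(inp: EnrichmentInput) -> float:
    """Upper-tail probability P(X >= x) under Hypergeometric(N, K, n).

    The probability of drawing x or more annotated genes when n genes are
    sampled without replacement from a background of N containing K
    annotated ones; computed as the survival function at x - 1.
    """
    inp.validate()
    if inp.x == 0:
        return 1.0
    return float(hypergeom.sf(inp.x - 1, inp.N, inp.K, inp.n))


def enrichment_ratio(inp: EnrichmentInput) -> float:
    """Fold enrichment (x/n) / (K/N) of the selection's overlap rate over
    the background rate of the annotated set."""
    if inp.K == 0 or inp.n == 0:
        raise ValueError("enrichment ratio undefined for K = 0 or n = 0")
    inp.validate()
    return (inp.x / inp.n) / (inp.K / inp.N)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def celltype_enrichment(
    positive_genes,
    negative_genes,
    marker_sets: dict[str, set],
    background,
    min_set_size: int | None = None,
    max_set_size: int | None = None,
) -> pd.DataFrame:
    """Overrepresentation of each marker set in each axis-direction list.

    Returns one row per (set, direction) with the test sizes, p, ratio,
    BH-FDR q (one family per direction across all sets), and the signed
    ratio (+ for the positive-axis list, - for the negative-axis list).
    Sets disjoint from the background (or outside the optional size
    filters) are flagged ``skipped`` and excluded from the FDR family.
    """
    bg = set(background)
    pos = set(positive_genes) & bg
    neg = set(negative_genes) & bg
    rows = []
    for name in sorted(marker_sets):
        members = set(marker_sets[name]) & bg
        K = len(members)
        skip_reason = ""
        if K == 0:
            skip_reason = "disjoint_from_background"
        elif min_set_size is not None and K < min_set_size:
            skip_reason = "below_min_set_size"
        elif max_set_size is not None and K > max_set_size:
            skip_reason = "above_max_set_size"
        for direction, selection in (("positive", pos), ("negative", neg)):
            if skip_reason:
                rows.append(
                    {
                        "set_name": name,
                        "direction": direction,
                        "N": len(bg),
                        "K": K,
                        "n": len(selection),
                        "x": np.nan,
                        "p": np.nan,
                        "ratio": np.nan,
                        "skipped": True,
                        "reason": skip_reason,
                    }
                )
                continue
            x = len(members & selection)
            inp = EnrichmentInput(N=len(bg), K=K, n=len(selection), x=x)
            rows.append(
                {
                    "set_name": name,
                    "direction": direction,
                    "N": inp.N,
                    "K": inp.K,
                    "n": inp.n,
                    "x": x,
                    "p": hypergeometric_tail(inp),
                    "ratio": enrichment_ratio(inp),
                    "skipped": False,
                    "reason": "",
                }
            )
    columns = [
        "set_name", "direction", "N", "K", "n", "x", "p", "ratio", "skipped", "reason",
    ]
    table = pd.DataFrame(rows, columns=columns)
    table["skipped"] = table["skipped"].astype(bool)
    table["q"] = np.nan
    for direction in ("positive", "negative"):
        mask = (table["direction"] == direction) & (~table["skipped"])
        if mask.any():
            table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"].to_numpy())
    table["signed_ratio"] = np.where(
        table["direction"] == "positive", table["ratio"], -table["ratio"]
    )
    return table


def summed_signed_ratio(table: pd.DataFrame) -> pd.Series:
    """Summed signed enrichment ratio per set, ordered descending.

    The ordering used to arrange neuronal subclusters along the
    medial-lateral axis: ratio in the positive list minus ratio in the
    negative list.
    """
    ok = table[~table["skipped"]]
    return (
        ok.groupby("set_name")["signed_ratio"].sum().sort_values(ascending=False)
    )
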
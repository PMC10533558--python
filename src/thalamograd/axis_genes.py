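"""Axis-gene selection and map comparisons against component scores.

Each gene's expression is correlated with a component's seed scores; the
significance of each correlation is assessed against variogram-matched
surrogates of the score map, and the strongest significant positive and
negative genes (100 each by default) define the axis gene sets. Companion
utilities correlate scores with Cartesian coordinate axes and component
loadings with external parcel maps under the spin test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nulls import SpinTestResult, SurrogateEnsemble, ensemble_correlations, spin_pvalue


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Analytic Fisher-z confidence interval for a Pearson correlation."""
    if n < 4:
        return (np.nan, np.nan)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


@dataclass
class GeneAxisSelection:
    table: pd.DataFrame            # gene, r, p_spin, excluded, reason
    selected_positive: list[str]
    selected_negative: list[str]
    top_k: int
    alpha: float


def gene_axis_correlation(
    expression: pd.DataFrame,
    pc_scores: pd.Series,
    ensemble: SurrogateEnsemble,
    top_k: int = 100,
    alpha: float = 0.05,
) -> GeneAxisSelection:
    """Select the top positively and negatively correlated significant genes.

    The empirical Pearson r between each gene and the component scores is
    compared to the correlations of the score-map surrogates with that gene;
    p_spin = (#{|r_null| >= |r_emp|} + 1) / (count + 1). Among genes with
    p_spin < alpha, the ``top_k`` strongest by |r| are returned per sign
    (ties broken by gene id). Constant genes are excluded with a reason.
    """
    if not expression.index.equals(pc_scores.index):
        raise ValueError("expression and scores are indexed by different seeds")
    X = expression.to_numpy(dtype=float)
    y = pc_scores.to_numpy(dtype=float)
    sd = X.std(axis=0)
    ok = sd > 0
    r = np.full(X.shape[1], np.nan)
    Xc = X[:, ok] - X[:, ok].mean(axis=0)
    yc = y - y.mean()
    r[ok] = (Xc.T @ yc) / (np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc))

    null = ensemble_correlations(ensemble, y, X[:, ok])  # (count, n_ok)
    count = null.shape[0]
    p = np.full(X.shape[1], np.nan)
    p[ok] = (np.sum(np.abs(null) >= np.abs(r[ok])[None, :], axis=0) + 1.0) / (count + 1.0)

    table = pd.DataFrame(
        {
            "gene": expression.columns,
            "r": r,
            "p_spin": p,
            "excluded": ~ok,
            "reason": np.where(ok, "", "constant_gene"),
        }
    )
    sig = table[(~table["excluded"]) & (table["p_spin"] < alpha)]
    pos = sig[sig["r"] > 0].sort_values(["r", "gene"], ascending=[False, True])
    neg = sig[sig["r"] < 0].sort_values(["r", "gene"], ascending=[True, True])
    if len(pos) < top_k or len(neg) < top_k:
        warnings.warn(
            f"fewer than top_k={top_k} significant genes available "
            f"(positive: {len(pos)}, negative: {len(neg)})",
            stacklevel=2,
        )
    return GeneAxisSelection(
        table=table,
        selected_positive=list(pos["gene"].head(top_k)),
        selected_negative=list(neg["gene"].head(top_k)),
        top_k=top_k,
        alpha=alpha,
    )


@dataclass
class AxisAlignment:
    table: pd.DataFrame  # axis, r, ci_low, ci_high, p
    dominant_axis: str
    weak: bool


def coordinate_alignment(
    pc_scores: pd.Series, coords: pd.DataFrame, weak_threshold: float = 0.1
) -> AxisAlignment:
    """Pearson correlation of component scores with each Cartesian axis.

    The dominant axis maximises |r|; when even the dominant |r| falls below
    ``weak_threshold`` the alignment is flagged weak.
    """
    y = pc_scores.to_numpy(dtype=float)
    rows = []
    for axis in ("x", "y", "z"):
        v = coords[axis].to_numpy(dtype=float)
        r, p = stats.pearsonr(y, v)
        lo, hi = fisher_ci(r, len(y))
        rows.append({"axis": axis, "r": r, "ci_low": lo, "ci_high": hi, "p": p})
    table = pd.DataFrame(rows)
    dom = table.loc[table["r"].abs().idxmax(), "axis"]
    weak = bool(table["r"].abs().max() < weak_threshold)
    return AxisAlignment(table=table, dominant_axis=dom, weak=weak)


def map_comparison(
    loadings: pd.Series,
    external_maps: pd.DataFrame,
    ensemble: SurrogateEnsemble,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Spin-test comparison of cortical loadings against external parcel maps.

    Returns one row per map with r, p_spin and a significance flag; per-map
    p_spin values are reported without family-wise correction by default,
    with an optional Benjamini-Hochberg column.
    """
    if not loadings.index.equals(external_maps.index):
        raise ValueError("parcel indexing differs between loadings and maps")
    rows = []
    for name in external_maps.columns:
        res: SpinTestResult = spin_pvalue(
            loadings.to_numpy(float),
            external_maps[name].to_numpy(float),
            ensemble_a=ensemble,
            ensemble_b=ensemble,
        )
        rows.append({"map": name, "r": res.r_empirical, "p_spin": res.p_spin})
    out = pd.DataFrame(rows)
    out["significant"] = out["p_spin"] < alpha
    if bh_correct:
        from .enrichment import bh_fdr

        out["q"] = bh_fdr(out["p_spin"].to_numpy())
    return out
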
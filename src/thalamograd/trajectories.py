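"""Developmental-window differential expression and age-trajectory models.

Two stages mirror the developmental analysis:

* :func:`classify_window_de` labels genes prenatal- or postnatal-enriched
  from pairwise comparisons of expression across nine ordered developmental
  windows (Welch t-tests, BH-corrected within each gene's 36 pairs; at
  least three significant prenatal-vs-postnatal differences in the same
  direction are required).
* :func:`fit_trajectory` models a gene's expression as a smooth function of
  age -- a natural cubic spline with four knots evenly spaced over the
  observed age span -- with sex and RIN as fixed effects and a per-donor
  random intercept, fit with statsmodels MixedLM. AIC/BIC (from maximum
  likelihood refits) compare the spline model against a linear-age null.

Prenatal ages are encoded as negative years from birth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .enrichment import bh_fdr


# ---------------------------------------------------------------------------
# natural cubic spline basis
# ---------------------------------------------------------------------------

def natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (without intercept) at the given knots.

    With K knots the natural-spline space has dimension K; excluding the
    constant, the returned basis has K - 1 columns: x itself plus K - 2
    truncated-cubic contrasts that are linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = len(knots)
    if K < 3:
        raise ValueError("need at least three knots")

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def even_knots(age: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Knots evenly spaced across the observed age span."""
    a = np.asarray(age, dtype=float)
    return np.linspace(a.min(), a.max(), n_knots)


# ---------------------------------------------------------------------------
# developmental-window differential expression
# ---------------------------------------------------------------------------

def classify_window_de(
    expression: pd.DataFrame,
    windows: pd.Series,
    prenatal_windows=(1, 2, 3),
    alpha: float = 0.05,
    min_significant: int = 3,
) -> pd.DataFrame:
    """Classify genes as prenatal-enriched, postnatal-enriched, or neither.

    For each gene, all pairwise window comparisons (36 for nine windows) are
    Welch t-tests, BH-corrected within the gene. Significant pairs linking a
    prenatal to a postnatal window count toward the side with the higher
    mean; a gene is labelled for a side when it accumulates at least
    ``min_significant`` such pairs and strictly more than the other side.
    Windows with fewer than two samples are dropped from the pairing.

    Returns a table with the class and the directional counts per gene.
    """
    if not expression.index.equals(windows.index):
        raise ValueError("expression and window labels have different samples")
    prenatal = set(prenatal_windows)
    labels = sorted(windows.unique())
    usable = []
    for w in labels:
        if (windows == w).sum() >= 2:
            usable.append(w)
        else:
            warnings.warn(f"window {w} has < 2 samples; excluded from pairs", stacklevel=2)
    groups = {w: expression.loc[windows == w].to_numpy(float) for w in usable}
    means = {w: g.mean(axis=0) for w, g in groups.items()}
    pairs = list(combinations(usable, 2))
    n_genes = expression.shape[1]
    pvals = np.empty((len(pairs), n_genes))
    for i, (w1, w2) in enumerate(pairs):
        pvals[i] = stats.ttest_ind(groups[w1], groups[w2], equal_var=False, axis=0).pvalue
    rows = []
    for j, gene in enumerate(expression.columns):
        q = bh_fdr(np.nan_to_num(pvals[:, j], nan=1.0))
        n_pre = n_post = 0
        for i, (w1, w2) in enumerate(pairs):
            if q[i] >= alpha:
                continue
            cross = (w1 in prenatal) != (w2 in prenatal)
            if not cross:
                continue
            pre_w, post_w = (w1, w2) if w1 in prenatal else (w2, w1)
            if means[pre_w][j] > means[post_w][j]:
                n_pre += 1
            else:
                n_post += 1
        if n_pre >= min_significant and n_pre > n_post:
            cls = "prenatal-enriched"
        elif n_post >= min_significant and n_post > n_pre:
            cls = "postnatal-enriched"
        else:
            cls = "neither"
        rows.append({"gene": gene, "class": cls, "n_prenatal": n_pre, "n_postnatal": n_post})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectory fitting
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFit:
    gene: str
    knots: np.ndarray
    fixed_effects: pd.Series          # REML estimates of the preferred model
    fixed_effects_se: pd.Series
    random_intercept_var: float
    aic_spline: float
    bic_spline: float
    aic_linear: float
    bic_linear: float
    preferred: str                    # 'spline' or 'linear' by BIC
    age_corrected: pd.Series          # expression with non-age effects removed
    dropped_covariates: list[str] = field(default_factory=list)
    _predict_state: dict = field(default_factory=dict, repr=False)

    def predict(self, age: np.ndarray) -> np.ndarray:
        """Population trajectory at reference covariates (mean RIN, balanced
        sex, zero random effect)."""
        st = self._predict_state
        X = _age_design(np.asarray(age, float), st["knots"], st["model_kind"])
        out = st["intercept"] + X @ st["age_coefs"]
        return out + st["reference_offset"]


def _age_design(age: np.ndarray, knots: np.ndarray, kind: str) -> np.ndarray:
    if kind == "spline":
        return natural_cubic_basis(age, knots)
    return age[:, None]


def _ml_ic(endog, exog, groups) -> tuple[float, float, object]:
    model = sm.MixedLM(endog, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    k = exog.shape[1] + 2  # fixed effects + random-intercept var + resid var
    llf = res.llf
    n = len(endog)
    return (-2 * llf + 2 * k, -2 * llf + np.log(n) * k, res)


def fit_trajectory(
    expression: pd.Series,
    age: pd.Series,
    sex: pd.Series,
    rin: pd.Series,
    donor: pd.Series,
    n_knots: int = 4,
    gene: str | None = None,
) -> TrajectoryFit:
    """Fit the mixed-effects age-trajectory model for one gene.

    Requires at least 20 samples and two donors. Degenerate covariates (a
    single sex, constant RIN) are dropped with a warning. Variance
    components are estimated by REML for the reported coefficients; AIC/BIC
    comparisons between the spline and linear-age models use maximum
    likelihood refits.
    """
    y = np.asarray(expression, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 samples to fit a trajectory")
    groups = np.asarray(donor)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two donors for a random intercept")
    a = np.asarray(age, dtype=float)
    knots = even_knots(a, n_knots)

    covars = {}
    dropped = []
    sex_codes = pd.Categorical(np.asarray(sex))
    if len(sex_codes.categories) > 1:
        covars["sex"] = (sex_codes.codes == 1).astype(float)
    else:
        dropped.append("sex")
        warnings.warn("single sex in sample; dropping sex covariate", stacklevel=2)
    r = np.asarray(rin, dtype=float)
    if np.std(r) > 0:
        covars["RIN"] = r
    else:
        dropped.append("RIN")
        warnings.warn("constant RIN; dropping RIN covariate", stacklevel=2)

    def _design(kind: str) -> tuple[np.ndarray, list[str]]:
        Xage = _age_design(a, knots, kind)
        age_names = [f"age_s{i + 1}" for i in range(Xage.shape[1])] if kind == "spline" else ["age"]
        parts = [np.ones((n, 1)), Xage] + [covars[c][:, None] for c in covars]
        names = ["intercept"] + age_names + list(covars)
        return np.column_stack(parts), names

    Xs, names_s = _design("spline")
    Xl, names_l = _design("linear")
    aic_s, bic_s, _ = _ml_ic(y, Xs, groups)
    aic_l, bic_l, _ = _ml_ic(y, Xl, groups)
    preferred = "spline" if bic_s < bic_l else "linear"

    X, names = (Xs, names_s) if preferred == "spline" else (Xl, names_l)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    fe = pd.Series(res.fe_params, index=names)
    fe_se = pd.Series(np.asarray(res.bse_fe), index=names)
    re_var = float(np.asarray(res.cov_re).ravel()[0])

    # age-corrected relative expression: remove sex/RIN effects and donor
    # intercepts, leaving the age trajectory plus residual noise
    covar_cols = [i for i, nm in enumerate(names) if nm in covars]
    covar_part = X[:, covar_cols] @ fe.iloc[covar_cols].to_numpy() if covar_cols else 0.0
    try:
        re_map = {g: float(np.asarray(v).ravel()[0]) for g, v in res.random_effects.items()}
    except (ValueError, np.linalg.LinAlgError):
        # degenerate fit: zero random-intercept variance
        re_map = {g: 0.0 for g in np.unique(groups)}
    donor_part = np.array([re_map[g] for g in groups])
    corrected = pd.Series(
        y - covar_part - donor_part, index=expression.index, name="age_corrected"
    )

    n_age = Xs.shape[1] - 1 - len(covars) if preferred == "spline" else 1
    age_cols = list(range(1, 1 + n_age))
    ref_offset = 0.0
    if "sex" in covars:
        ref_offset += 0.5 * fe["sex"]
    if "RIN" in covars:
        ref_offset += float(np.mean(covars["RIN"])) * fe["RIN"]
    return TrajectoryFit(
        gene=gene or (expression.name or "gene"),
        knots=knots,
        fixed_effects=fe,
        fixed_effects_se=fe_se,
        random_intercept_var=re_var,
        aic_spline=aic_s,
        bic_spline=bic_s,
        aic_linear=aic_l,
        bic_linear=bic_l,
        preferred=preferred,
        age_corrected=corrected,
        dropped_covariates=dropped,
        _predict_state={
            "knots": knots,
            "model_kind": preferred,
            "intercept": fe["intercept"],
            "age_coefs": fe.iloc[age_cols].to_numpy(),
            "reference_offset": ref_offset,
        },
    )


def fit_trajectory_table(
    table: pd.DataFrame, gene_columns, meta=("age", "sex", "RIN", "donor"), n_knots: int = 4
) -> dict[str, TrajectoryFit]:
    """Fit trajectories for several genes from one developmental sample table."""
    age_c, sex_c, rin_c, donor_c = meta
    return {
        g: fit_trajectory(
            table[g], table[age_c], table[sex_c], table[rin_c], table[donor_c],
            n_knots=n_knots, gene=g,
        )
        for g in gene_columns
    }
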
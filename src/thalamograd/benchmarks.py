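"""End-to-end property benchmarks on synthetic data with known ground truth.

Each function runs one self-contained experiment -- generating its inputs,
executing the relevant pipeline stages, and measuring the result -- and
returns a dictionary of named quantities. They back both the acceptance
test suite and the reproduction script; the problem sizes used (seed
counts, replicate counts, ensemble sizes) are fixed here as the package's
reference conditions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .axis_genes import coordinate_alignment, gene_axis_correlation
from .decomposition import VARIANTS, decompose_variant, joint_pca
from .enrichment import EnrichmentInput, celltype_enrichment, hypergeometric_tail
from .nulls import VariogramGeometry, build_spin_ensemble, spin_pvalue, variogram_surrogates
from .prep import FeatureMatrix, average_connectivity, concatenate, normalise_sigmoid, qc_participants, qc_seeds
from .stability import bootstrap_decomposition, loocv_seeds
from .synthetic import (
    SyntheticConfig,
    dev_trajectory_value,
    fibonacci_sphere,
    generate_autocorrelated_field,
    generate_dataset,
)
from .trajectories import classify_window_de, fit_trajectory


def _prepared(ds):
    """Run QC + assembly on a generated dataset; returns (joint, coords, keep)."""
    qc = qc_participants(ds.inclusion)
    retained_p = list(qc.loc[qc["retained"], "participant"])
    keep = qc_seeds(ds.inclusion.loc[retained_p], ds.has_expression)
    pids = list(ds.inclusion.index)
    mats = [ds.participant_connectivity[pids.index(p)] for p in retained_p]
    avg = average_connectivity(mats, retained_seeds=keep)
    conn = normalise_sigmoid(avg, kind="cortical_region")
    genes = normalise_sigmoid(ds.expression.loc[keep], kind="gene")
    joint = concatenate(conn, genes)
    coords = ds.seeds.set_index("seed_id").loc[keep, ["x", "y", "z"]]
    return joint, conn, genes, coords, keep


# ---------------------------------------------------------------------------
# gradient recovery (default dataset)
# ---------------------------------------------------------------------------

def gradient_recovery(seed: int = 0) -> dict:
    """Recover the planted gradient from the default dataset via joint PCA."""
    ds = generate_dataset(SyntheticConfig(), rng_seed=seed)
    joint, _, _, coords, keep = _prepared(ds)
    dec = joint_pca(joint, k=10, coords=coords.to_numpy())
    g = ds.truth.gradient_values.loc[keep].to_numpy()
    r = float(np.corrcoef(dec.scores.iloc[:, 0], g)[0, 1])
    align = coordinate_alignment(dec.scores.iloc[:, 0], coords)
    return {
        "r_pc1_gradient": abs(r),
        "dominant_axis": align.dominant_axis,
        "r_pc1_x": float(align.table.set_index("axis").loc["x", "r"]),
        "pc1_variance_pct": float(100 * dec.variance_fraction[0]),
        "n_seeds": int(joint.n_seeds),
    }


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def pca_oracle_max_error(seed: int = 0, n_matrices: int = 50) -> dict:
    """Joint PCA vs an independent covariance-eigendecomposition oracle."""
    rng = np.random.default_rng(seed)
    worst_scores = 0.0
    worst_lam = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(5, 12))
        m = int(rng.integers(3, 9))
        X = rng.random((n, m))
        fm = FeatureMatrix(
            values=pd.DataFrame(X),
            feature_kind=pd.Series("gene", index=pd.RangeIndex(m)),
            normalised=True,
        )
        k = min(n, m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank-deficient k is intended here
            dec = joint_pca(fm, k=k)
        # oracle: eigendecomposition of the sample covariance matrix
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (n - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        scores_oracle = Xc @ evecs
        lam_err = np.max(np.abs(dec.variance - np.clip(evals[:k], 0, None)))
        sc = dec.scores.to_numpy()
        sc_err = 0.0
        for j in range(k):
            if dec.variance[j] < 1e-12:
                continue  # null-space components: direction arbitrary
            a, b = sc[:, j], scores_oracle[:, j]
            sc_err = max(sc_err, min(np.max(np.abs(a - b)), np.max(np.abs(a + b))))
        worst_scores = max(worst_scores, sc_err)
        worst_lam = max(worst_lam, lam_err)
    return {"max_scores_error": worst_scores, "max_lambda_error": worst_lam, "n": n_matrices}


def hypergeometric_enumeration_error(max_N: int = 12) -> dict:
    """Hypergeometric upper tail vs exhaustive enumeration of all draws."""
    from itertools import combinations

    worst = 0.0
    checked = 0
    for N in range(1, max_N + 1):
        universe = range(N)
        for K in range(0, N + 1):
            annotated = set(range(K))
            for n in range(0, N + 1):
                draws = list(combinations(universe, n))
                overlaps = np.array([len(annotated & set(d)) for d in draws])
                for x in range(0, min(K, n) + 1):
                    p_enum = np.mean(overlaps >= x)
                    p_impl = hypergeometric_tail(EnrichmentInput(N=N, K=K, n=n, x=x))
                    worst = max(worst, abs(p_impl - p_enum))
                    checked += 1
    return {"max_abs_error": worst, "n": checked}


# ---------------------------------------------------------------------------
# conservation laws
# ---------------------------------------------------------------------------

def conservation_checks(seed: int = 0, n_matrices: int = 25) -> dict:
    """Variance conservation, sigmoid range, spin multiset preservation."""
    rng = np.random.default_rng(seed)
    worst_var = 0.0
    worst_sig = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(6, 30))
        m = int(rng.integers(3, 15))
        X = rng.normal(size=(n, m)) * rng.lognormal(size=m)
        fm = normalise_sigmoid(pd.DataFrame(X))
        v = fm.values.to_numpy()
        worst_sig = max(
            worst_sig,
            float(np.max([np.abs(v.min(0)).max(), np.abs(v.max(0) - 1).max()])),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = joint_pca(fm, k=min(n, m))
        col_var = ((v - v.mean(0)) ** 2).sum(0) / (n - 1)
        worst_var = max(worst_var, abs(dec.variance.sum() - col_var.sum()))
    cent = fibonacci_sphere(60)
    ens = build_spin_ensemble(cent, n_perm=50, rng=rng)
    vals = rng.normal(size=60)
    spun = ens.surrogates(vals)
    multiset_ok = all(np.allclose(np.sort(row), np.sort(vals)) for row in spun)
    return {
        "max_variance_conservation_error": worst_var,
        "max_sigmoid_bound_error": worst_sig,
        "spin_multiset_preserved": float(multiset_ok),
        "n": n_matrices,
    }


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_calibration(
    seed: int = 0,
    n_spin_pairs: int = 300,
    n_vario_pairs: int = 200,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the spatial tests on independent autocorrelated maps.

    Spin: pairs of Gaussian-process maps (length scale 80 mm) on 100 parcel
    centroids of a 100 mm sphere, 500 spins. Variogram: pairs of GP maps
    (length scale 15 mm) on 150 lattice seeds, 500 surrogates per map. The
    naive parametric Pearson test is evaluated on the same maps.
    """
    rng = np.random.default_rng(seed)
    cent = fibonacci_sphere(100)
    spin = build_spin_ensemble(cent, n_perm=n_perm, rng=rng)
    F = generate_autocorrelated_field(cent, 80.0, rng, size=2 * n_spin_pairs)
    rej_spin = rej_param_spin = 0
    for i in range(n_spin_pairs):
        a, b = F[2 * i], F[2 * i + 1]
        rej_spin += spin_pvalue(a, b, spin, spin).p_spin < alpha
        rej_param_spin += stats.pearsonr(a, b).pvalue < alpha

    from .synthetic import EllipsoidMask, generate_seed_lattice

    lat = generate_seed_lattice(EllipsoidMask((15, 10, 8)), 2.5)
    coords = lat[["x", "y", "z"]].to_numpy()[:150]
    geom = VariogramGeometry(coords)
    G = generate_autocorrelated_field(coords, 15.0, rng, size=2 * n_vario_pairs)
    rej_vario = rej_param_vario = 0
    for i in range(n_vario_pairs):
        a, b = G[2 * i], G[2 * i + 1]
        ens = variogram_surrogates(a, coords, n_surr=n_perm, rng=rng, geometry=geom)
        rej_vario += spin_pvalue(a, b, ens).p_spin < alpha
        rej_param_vario += stats.pearsonr(a, b).pvalue < alpha
    return {
        "spin_type1_rate": rej_spin / n_spin_pairs,
        "variogram_type1_rate": rej_vario / n_vario_pairs,
        "parametric_rate_spin_maps": rej_param_spin / n_spin_pairs,
        "parametric_rate_seed_maps": rej_param_vario / n_vario_pairs,
        "n_spin_pairs": n_spin_pairs,
        "n_vario_pairs": n_vario_pairs,
    }


# ---------------------------------------------------------------------------
# selection recovery and enrichment power
# ---------------------------------------------------------------------------

def selection_recovery(seed: int = 0, n_surr: int = 500) -> dict:
    """Fraction of selected axis genes that are planted, on the default set."""
    ds = generate_dataset(SyntheticConfig(), rng_seed=seed)
    joint, _, _, coords, keep = _prepared(ds)
    dec = joint_pca(joint, k=10, coords=coords.to_numpy())
    pc1 = dec.scores.iloc[:, 0]
    ens = variogram_surrogates(
        pc1.to_numpy(), coords.to_numpy(), n_surr=n_surr,
        rng=np.random.default_rng(seed + 1),
    )
    sel = gene_axis_correlation(ds.expression.loc[keep], pc1, ens, top_k=40)
    pos, neg = set(ds.truth.aligned_positive), set(ds.truth.aligned_negative)
    tp = len(set(sel.selected_positive) & pos) + len(set(sel.selected_negative) & neg)
    n_sel = len(sel.selected_positive) + len(sel.selected_negative)
    return {
        "selection_precision": tp / n_sel if n_sel else 0.0,
        "n_selected": n_sel,
        "n_planted": len(pos) + len(neg),
    }


def enrichment_power(seed: int = 0, n_reps: int = 100) -> dict:
    """Detection of marker sets with planted 60% overlap at a 10% base rate.

    Per replicate, marker sets are redrawn with the configured overlap to the
    planted positive/negative gene sets (60%) or at chance (10%); power is
    the fraction of replicates in which both enriched sets reach q < 0.05 in
    their planted direction.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(400)]
    pos, neg, rest = genes[:40], genes[40:80], genes[80:]
    hits = 0
    ratios = []
    for _ in range(n_reps):
        def draw(n_pos, n_neg, size=50):
            s = list(rng.choice(pos, n_pos, replace=False))
            s += list(rng.choice(neg, n_neg, replace=False))
            s += list(rng.choice(rest, size - len(s), replace=False))
            return set(s)

        sets = {
            "enriched_pos": draw(30, 0),   # 60% overlap with the positive list
            "enriched_neg": draw(0, 30),
            "chance_set": draw(5, 0),      # 10%: the background rate
        }
        table = celltype_enrichment(pos, neg, sets, background=genes)
        t = table.set_index(["set_name", "direction"])
        ok = (
            t.loc[("enriched_pos", "positive"), "q"] < 0.05
            and t.loc[("enriched_neg", "negative"), "q"] < 0.05
        )
        hits += ok
        ratios.append(
            (
                t.loc[("enriched_pos", "positive"), "signed_ratio"],
                t.loc[("enriched_neg", "negative"), "signed_ratio"],
                t.loc[("chance_set", "positive"), "signed_ratio"],
            )
        )
    ratios = np.array(ratios)
    return {
        "power_q05": hits / n_reps,
        "mean_signed_ratio_pos": float(ratios[:, 0].mean()),
        "mean_signed_ratio_neg": float(ratios[:, 1].mean()),
        "mean_ratio_chance": float(np.abs(ratios[:, 2]).mean()),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# stability machinery
# ---------------------------------------------------------------------------

def stability_checks(seed: int = 0) -> dict:
    """Bootstrap on identical participants and LOOCV on a noiseless fixture."""
    cfg = SyntheticConfig(
        n_seeds=120, n_genes=80, n_regions=40, n_participants=6,
        conn_noise_sd=0.0, gene_noise_sd=0.5, marker_specs={},
    )
    ds = generate_dataset(cfg, rng_seed=seed)
    identical = [ds.participant_connectivity[0]] * 6
    genes = normalise_sigmoid(ds.expression, kind="gene")
    rep = bootstrap_decomposition(
        identical, genes, B=20, rng=np.random.default_rng(seed), k=5
    )
    min_r = float(
        min(rep.replicates["r_pc1_scores"].min(), rep.replicates["r_pc1_loadings"].min())
    )
    lam_spread = float(
        np.ptp(rep.replicates["lambda_frac_1"].to_numpy())
    )
    # rank-1 noiseless fixture for LOOCV
    rng = np.random.default_rng(seed + 1)
    g = np.sort(rng.normal(size=60))
    w = rng.normal(size=8)
    X = np.outer(g, w)
    fm = FeatureMatrix(
        values=pd.DataFrame(X + 10.0),
        feature_kind=pd.Series("gene", index=pd.RangeIndex(8)),
        normalised=True,
    )
    loo = loocv_seeds(fm, k=1)
    return {
        "bootstrap_min_abs_r": min_r,
        "bootstrap_lambda1_spread": lam_spread,
        "loocv_max_rmse": float(loo.replicates["rmse_pc1_scores"].max()),
    }


# ---------------------------------------------------------------------------
# trajectory recovery
# ---------------------------------------------------------------------------

def trajectory_recovery(seed: int = 0, n_effect_genes: int = 200) -> dict:
    """Recovery of planted cubic trajectories and sex effects; null control.

    Fits the mixed-effects spline model to ``n_effect_genes`` genes with
    planted prenatal/postnatal cubic trajectories (plus an equal-rate flat
    null contingent) and reports the fraction with fitted-vs-true curve
    correlation above 0.95, the fraction with the sex coefficient within two
    standard errors of truth, and the window-DE misclassification rate on
    the flat genes.
    """
    n_total = n_effect_genes * 3 // 2  # generator cycles prenatal/postnatal/flat
    cfg = SyntheticConfig(n_dev_genes=n_total)
    ds = generate_dataset(cfg, rng_seed=seed)
    tab = ds.dev_samples
    gene_cols = [c for c in tab.columns if c not in ds.dev_meta_columns]
    grid = np.linspace(tab["age"].min(), tab["age"].max(), 50)
    n_curve = n_sex = n_eff = 0
    for g in gene_cols:
        kind = g.split("_")[1]
        if kind == "flat":
            continue
        fit = fit_trajectory(tab[g], tab["age"], tab["sex"], tab["RIN"], tab["donor"], gene=g)
        true = dev_trajectory_value(grid, kind)
        n_curve += np.corrcoef(fit.predict(grid), true)[0, 1] > 0.95
        n_sex += abs(fit.fixed_effects["sex"] - cfg.dev_sex_effect) <= 2 * fit.fixed_effects_se["sex"]
        n_eff += 1
    de = classify_window_de(tab[gene_cols], tab["window"])
    de = de.set_index("gene")
    flat = [g for g in gene_cols if g.endswith("_flat")]
    null_rate = float((de.loc[flat, "class"] != "neither").mean())
    effect = [g for g in gene_cols if not g.endswith("_flat")]
    de_sens = float(
        (
            de.loc[effect, "class"]
            == [f"{g.split('_')[1]}-enriched" for g in effect]
        ).mean()
    )
    return {
        "curve_recovery_rate": n_curve / n_eff,
        "sex_effect_within_2se_rate": n_sex / n_eff,
        "window_de_null_rate": null_rate,
        "window_de_sensitivity": de_sens,
        "n": n_eff,
    }


# ---------------------------------------------------------------------------
# sensitivity-variant concordance
# ---------------------------------------------------------------------------

def variant_concordance(seed: int = 0) -> dict:
    """|r| of each sensitivity variant's first component with joint PC1 on a
    low-noise dataset (halved expression noise, reduced count noise)."""
    cfg = SyntheticConfig(gene_noise_sd=0.25, conn_noise_sd=10.0)
    ds = generate_dataset(cfg, rng_seed=seed)
    joint, conn, genes, coords, keep = _prepared(ds)
    dec = joint_pca(joint, k=10, coords=coords.to_numpy())
    pc1 = dec.scores.iloc[:, 0].to_numpy()
    out = {}
    for name in VARIANTS:
        kw = {}
        if name == "pca_restricted":
            kw["restricted_genes"] = ds.truth.aligned_gene_ids
        res = decompose_variant(name, conn, genes, k=10, coords=coords.to_numpy(), **kw)
        if isinstance(res, dict):
            for sub, d in res.items():
                out[f"r_{name}_{sub}"] = float(
                    abs(np.corrcoef(d.scores.iloc[:, 0], pc1)[0, 1])
                )
        else:
            out[f"r_{name}"] = float(abs(np.corrcoef(res.scores.iloc[:, 0], pc1)[0, 1]))
    out["min_abs_r"] = min(v for k, v in out.items() if k.startswith("r_"))
    return out
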
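"""End-to-end orchestration of the synthetic gradient analysis.

``run_pipeline`` executes the enabled stages in dependency order on a
generated dataset -- matrix assembly, joint decomposition, stability,
spatial nulls, axis-gene selection, map comparison, enrichment,
cross-species correlation and developmental trajectories -- writing each
stage's outputs as TSV/JSON into a run directory together with a manifest
(config hash, per-file checksums, seeds, stage timings). Re-running with an
identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axis_genes import coordinate_alignment, gene_axis_correlation, map_comparison
from .config import PipelineConfig
from .decomposition import joint_pca, zscore_components
from .enrichment import celltype_enrichment, summed_signed_ratio
from .cross_species import filter_homologues, loading_correlation
from .nulls import build_spin_ensemble, variogram_surrogates
from .prep import average_connectivity, concatenate, normalise_sigmoid, qc_participants, qc_seeds
from .stability import bootstrap_decomposition, loocv_seeds
from .synthetic import SyntheticConfig, generate_dataset, write_dataset
from .trajectories import classify_window_de, fit_trajectory_table

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _synthetic_config(cfg: PipelineConfig) -> SyntheticConfig:
    from .synthetic import MarkerSetSpec

    known = {f.name for f in dc_fields(SyntheticConfig)}
    unknown = set(cfg.synthetic) - known
    if unknown:
        raise ValueError(f"unknown synthetic-config keys: {sorted(unknown)}")
    opts = dict(cfg.synthetic)
    if "marker_specs" in opts:
        # YAML configs carry marker specs as plain mappings
        opts["marker_specs"] = {
            name: spec if isinstance(spec, MarkerSetSpec) else MarkerSetSpec(**spec)
            for name, spec in opts["marker_specs"].items()
        }
    return SyntheticConfig(**opts)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages and return the manifest dictionary."""
    config.validate()
    seeds = config.resolved_seeds()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    state: dict = {}

    def _w(df: pd.DataFrame, name: str, index=True):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    def _wj(obj, name: str):
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
        written.append(path)

    stage_fns = {
        "simulate": _stage_simulate,
        "prepare": _stage_prepare,
        "decompose": _stage_decompose,
        "stability": _stage_stability,
        "nulls": _stage_nulls,
        "genes": _stage_genes,
        "maps": _stage_maps,
        "enrich": _stage_enrich,
        "xspecies": _stage_xspecies,
        "trajectories": _stage_trajectories,
    }
    order = [s for s in stage_fns if s in config.stages]
    for stage in order:
        t0 = time.perf_counter()
        try:
            stage_fns[stage](config, seeds, state, out, _w, _wj)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise StageError(stage, exc) from exc
        timings[stage] = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", stage, timings[stage])

    manifest = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "config": json.loads(json.dumps(_jsonify_obj(config))),
        "seeds": seeds,
        "stage_timings_s": timings,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _jsonify_obj(config: PipelineConfig):
    from dataclasses import asdict

    return asdict(config)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, seeds, state, out, _w, _wj):
    ds = generate_dataset(_synthetic_config(cfg), rng_seed=seeds["simulate"])
    state["dataset"] = ds
    write_dataset(ds, out / "data")


def _stage_prepare(cfg, seeds, state, out, _w, _wj):
    ds = state["dataset"]
    qc = qc_participants(ds.inclusion, threshold=cfg.participant_r_threshold)
    retained_p = list(qc.loc[qc["retained"], "participant"])
    retained_s = qc_seeds(
        ds.inclusion.loc[retained_p],
        ds.has_expression,
        presence_fraction=cfg.seed_presence_fraction,
    )
    pids = list(ds.inclusion.index)
    mats = [ds.participant_connectivity[pids.index(p)] for p in retained_p]
    avg = average_connectivity(mats, retained_seeds=retained_s)
    conn = normalise_sigmoid(avg, kind="cortical_region")
    genes = normalise_sigmoid(ds.expression.loc[retained_s], kind="gene")
    joint = concatenate(conn, genes)
    state.update(
        retained_participants=retained_p,
        retained_seeds=retained_s,
        conn_block=conn,
        gene_block=genes,
        joint=joint,
        coords=ds.seeds.set_index("seed_id").loc[retained_s, ["x", "y", "z"]],
        raw_matrices=[m.loc[retained_s] for m in mats],
    )
    _w(qc, "qc_participants.tsv", index=False)
    _w(joint.values, "matrix.tsv")
    _wj(
        {
            "n_seeds": joint.n_seeds,
            "n_features": joint.n_features,
            "sigmoid": joint.sigmoid.to_frame().to_dict(orient="index") if joint.sigmoid else None,
            "retained_participants": retained_p,
        },
        "matrix_meta.json",
    )


def _stage_decompose(cfg, seeds, state, out, _w, _wj):
    joint = state["joint"]
    coords = state["coords"].to_numpy()
    k = min(cfg.k, joint.n_seeds - 1, joint.n_features)
    dec = joint_pca(joint, k=k, coords=coords)
    decz = zscore_components(dec)
    state["decomposition"] = dec
    state["decomposition_z"] = decz
    _w(decz.scores, "pc_scores.tsv")
    _w(decz.loadings, "pc_loadings.tsv")
    _w(
        pd.DataFrame(
            {
                "singular_value": dec.singular_values,
                "lambda": dec.variance,
                "variance_fraction": dec.variance_fraction,
            },
            index=dec.scores.columns,
        ),
        "variance_explained.tsv",
    )


def _stage_stability(cfg, seeds, state, out, _w, _wj):
    rng = np.random.default_rng(seeds["bootstrap"])
    rep = bootstrap_decomposition(
        state["raw_matrices"],
        state["gene_block"],
        B=cfg.bootstrap_B,
        rng=rng,
        k=min(cfg.k, state["joint"].n_features),
        coords=state["coords"].to_numpy(),
    )
    _w(rep.replicates, "bootstrap_report.tsv", index=False)
    if cfg.run_loocv:
        loo = loocv_seeds(state["joint"], coords=state["coords"].to_numpy())
        _w(loo.replicates, "loocv_report.tsv", index=False)


def _stage_nulls(cfg, seeds, state, out, _w, _wj):
    coords = state["coords"].to_numpy()
    pc1 = state["decomposition"].scores.iloc[:, 0].to_numpy()
    ens = variogram_surrogates(
        pc1, coords, n_surr=cfg.n_variogram, rng=np.random.default_rng(seeds["nulls"])
    )
    state["variogram_ensemble"] = ens
    _wj(
        {
            "method": ens.method,
            "count": ens.count,
            "fit_sse_median": float(np.median(ens.fit_sse)),
            "params": ens.params,
        },
        "variogram_ensemble_meta.json",
    )


def _stage_genes(cfg, seeds, state, out, _w, _wj):
    ds = state["dataset"]
    dec = state["decomposition"]
    expr = ds.expression.loc[state["retained_seeds"]]
    sel = gene_axis_correlation(
        expr,
        dec.scores.iloc[:, 0],
        state["variogram_ensemble"],
        top_k=cfg.top_k,
        alpha=cfg.alpha,
    )
    align = coordinate_alignment(dec.scores.iloc[:, 0], state["coords"])
    state["selection"] = sel
    state["alignment"] = align
    _w(sel.table, "gene_axis_table.tsv", index=False)
    _wj(
        {
            "selected_positive": sel.selected_positive,
            "selected_negative": sel.selected_negative,
            "dominant_axis": align.dominant_axis,
            "axis_table": align.table.to_dict(orient="records"),
        },
        "axis_selection.json",
    )


def _stage_maps(cfg, seeds, state, out, _w, _wj):
    ds = state["dataset"]
    dec = state["decomposition"]
    spin = build_spin_ensemble(
        ds.region_centroids.to_numpy(),
        n_perm=cfg.n_spin,
        rng=np.random.default_rng(seeds["spin"]),
    )
    state["spin_ensemble"] = spin
    loadings = dec.loadings.loc[dec.feature_kind == "cortical_region", dec.scores.columns[0]]
    maps = pd.DataFrame({"planted_cortical_axis": ds.truth.cortical_axis})
    table = map_comparison(loadings, maps, spin, alpha=cfg.alpha)
    _w(table, "map_comparison.tsv", index=False)
    state["map_table"] = table


def _stage_enrich(cfg, seeds, state, out, _w, _wj):
    ds = state["dataset"]
    sel = state["selection"]
    table = celltype_enrichment(
        sel.selected_positive,
        sel.selected_negative,
        ds.marker_sets,
        background=list(ds.expression.columns),
    )
    _w(table, "enrichment.tsv", index=False)
    _w(summed_signed_ratio(table).rename("summed_signed_ratio").reset_index(),
       "enrichment_ordering.tsv", index=False)
    state["enrichment"] = table


def _stage_xspecies(cfg, seeds, state, out, _w, _wj):
    ds = state["dataset"]
    dec = state["decomposition"]
    sp = ds.species_pair
    hmap = filter_homologues(
        sp["homologue_table"], sp["protein_genes"], sp["expression_aggregate"]
    )
    gene_loadings = dec.loadings.loc[dec.feature_kind == "gene", dec.scores.columns[0]]
    res = loading_correlation(hmap, gene_loadings, sp["loadings_b"])
    _wj(
        {"r": res.r, "ci": list(res.ci), "p": res.p, "n_pairs": res.n,
         "n_retained_homologues": len(hmap)},
        "xspecies.json",
    )
    state["xspecies"] = res


def _stage_trajectories(cfg, seeds, state, out, _w, _wj):
    ds = state["dataset"]
    gene_cols = [c for c in ds.dev_samples.columns if c not in ds.dev_meta_columns]
    table = ds.dev_samples
    de = classify_window_de(
        table[gene_cols], table["window"], alpha=cfg.alpha
    )
    _w(de, "window_de.tsv", index=False)
    fits = fit_trajectory_table(table, gene_cols)
    _wj(
        {
            g: {
                "preferred": f.preferred,
                "aic_spline": f.aic_spline,
                "bic_spline": f.bic_spline,
                "aic_linear": f.aic_linear,
                "bic_linear": f.bic_linear,
                "fixed_effects": f.fixed_effects.to_dict(),
                "random_intercept_var": f.random_intercept_var,
            }
            for g, f in fits.items()
        },
        "trajectory_fits.json",
    )
    state["trajectory_fits"] = fits
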
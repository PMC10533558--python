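"""Synthetic datasets with a planted medial-lateral gradient.

Every downstream stage of the pipeline (matrix assembly, joint decomposition,
spatial nulls, gene-axis selection, enrichment, cross-species comparison,
developmental trajectories) can be exercised against data generated here,
where the ground truth -- the planted spatial gradient ``g``, the gene sets
aligned with it, the cortical target axis ``a`` -- is known exactly.

The generator emulates the statistical structure of the real inputs:

* a regular seed lattice inside a thalamus-shaped mask (the study scale is
  ~1800 seeds at 1.75 mm spacing),
* spatially autocorrelated gene-expression fields, a subset of which align
  positively or negatively with ``g``,
* per-participant nonnegative streamline-count matrices whose cortical
  target position shifts monotonically with seed position on ``g``,
* marker-gene sets overlapping the planted sets at configurable rates,
* developmental samples with smooth age trajectories plus sex/RIN/donor
  effects, and
* a second-species gene-loading table linked by a homologue map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# masks and seed lattices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipsoidMask:
    """Axis-aligned ellipsoid used as a stand-in thalamic volume.

    The default semi-axes give a thalamus-like aspect ratio and a volume that
    yields roughly 1800 lattice points at 1.75 mm spacing.
    """

    semi_axes: tuple[float, float, float] = (20.0, 12.7, 9.1)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = (np.asarray(points, dtype=float) - np.asarray(self.center)) / np.asarray(
            self.semi_axes
        )
        return (p**2).sum(axis=1) <= 1.0

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.semi_axes, dtype=float)
        return c - s, c + s

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class BoxMask:
    """Axis-aligned box, mainly for exact lattice-counting checks."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        return np.all((p >= lo) & (p <= hi), axis=1)

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lower, dtype=float), np.asarray(self.upper, dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        lo, hi = self.bounding_box
        return (lo + hi) / 2.0


class VoxelMask:
    """Binary voxel mask with an affine, e.g. read from a NIfTI image."""

    def __init__(self, data: np.ndarray, affine: np.ndarray):
        self.data = np.asarray(data).astype(bool)
        self.affine = np.asarray(affine, dtype=float)
        if not self.data.any():
            raise ValueError("voxel mask is empty")

    @classmethod
    def from_nifti(cls, img) -> "VoxelMask":
        return cls(np.asarray(img.dataobj) > 0, img.affine)

    def contains(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        p = np.asarray(points, dtype=float)
        vox = np.floor(inv[:3, :3] @ p.T + inv[:3, 3:4]).astype(int).T
        ok = np.all((vox >= 0) & (vox < np.array(self.data.shape)), axis=1)
        out = np.zeros(len(p), dtype=bool)
        out[ok] = self.data[tuple(vox[ok].T)]
        return out

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.array(np.nonzero(self.data)).T
        corners = np.concatenate([idx, idx + 1.0])
        world = (self.affine[:3, :3] @ corners.T + self.affine[:3, 3:4]).T
        return world.min(axis=0), world.max(axis=0)

    @property
    def centroid(self) -> np.ndarray:
        idx = np.array(np.nonzero(self.data), dtype=float).T + 0.5
        world = (self.affine[:3, :3] @ idx.T + self.affine[:3, 3:4]).T
        return world.mean(axis=0)


def generate_seed_lattice(mask, spacing: float, offset: str = "centroid") -> pd.DataFrame:
    """Regular 3-D lattice of seed points inside ``mask``.

    Parameters
    ----------
    mask:
        Object with ``contains``, ``bounding_box`` and ``centroid``
        (:class:`EllipsoidMask`, :class:`BoxMask` or :class:`VoxelMask`).
    spacing:
        Lattice spacing in mm; nearest-neighbour distance of the result.
    offset:
        Lattice anchoring convention. ``"centroid"`` places a lattice point
        on the mask centroid; ``"half"`` anchors the lattice half a spacing
        inside the bounding-box lower corner (so a [0, 1] box at spacing 0.5
        yields points at 0.25/0.75 per axis).

    Returns
    -------
    DataFrame with columns ``seed_id, x, y, z`` (mm).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo, hi = mask.bounding_box
    if np.any(hi - lo < spacing):
        raise ValueError("mask extent is smaller than the lattice spacing")
    if offset == "centroid":
        anchor = mask.centroid
    elif offset == "half":
        anchor = lo + spacing / 2.0
    else:
        raise ValueError(f"unknown offset convention: {offset!r}")

    axes = []
    for d in range(3):
        n_lo = int(np.floor((anchor[d] - lo[d]) / spacing + 1e-9))
        n_hi = int(np.floor((hi[d] - anchor[d]) / spacing + 1e-9))
        axes.append(anchor[d] + spacing * np.arange(-n_lo, n_hi + 1))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[mask.contains(pts)]
    if len(pts) == 0:
        raise ValueError("mask contains no lattice points at this spacing")
    # deterministic ordering: x, then y, then z
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    pts = pts[order]
    ids = [f"seed{i:04d}" for i in range(len(pts))]
    return pd.DataFrame({"seed_id": ids, "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]})


# ---------------------------------------------------------------------------
# Gaussian-process fields
# ---------------------------------------------------------------------------

def generate_autocorrelated_field(
    coords: np.ndarray,
    length_scale: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with exponential covariance.

    The covariance between two seeds at distance ``d`` is
    ``exp(-d / length_scale)``; marginal variance is 1 at every seed.
    Returns an array of shape ``(size, n_seeds)`` (``(n_seeds,)`` when
    ``size == 1``).
    """
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = len(coords)
    dist = cdist(coords, coords)
    cov = np.exp(-dist / length_scale)
    cov[np.diag_indices_from(cov)] += 1e-10  # jitter for Cholesky
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, size))
    fields = (chol @ z).T
    return fields[0] if size == 1 else fields


def empirical_variogram_oracle(dist: np.ndarray, length_scale: float) -> np.ndarray:
    """Closed-form variogram 2(1 - exp(-d/l)) of the exponential model."""
    return 2.0 * (1.0 - np.exp(-np.asarray(dist) / length_scale))


def fibonacci_sphere(n: int, radius: float = 100.0) -> np.ndarray:
    """Nearly uniform points on a sphere (golden-spiral construction),
    ordered by z. Emulates spherical surface centroids of cortical parcels."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(1.0 - z**2)
    pts = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return pts[np.argsort(pts[:, 2])]


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class MarkerSetSpec:
    """Recipe for one synthetic marker-gene set.

    ``frac_positive``/``frac_negative`` are the fractions of the set's
    members drawn from the planted positively/negatively aligned gene sets;
    the remainder is drawn uniformly from non-aligned genes.
    """

    size: int
    frac_positive: float = 0.0
    frac_negative: float = 0.0


def default_marker_specs() -> dict[str, MarkerSetSpec]:
    # Emulates the cell-class workflow: one set enriched for lateral
    # (positive-axis) genes, one for medial (negative-axis) genes, and two
    # unenriched background sets drawn at the base rate.
    return {
        "lateral_like": MarkerSetSpec(size=50, frac_positive=0.6),
        "medial_like": MarkerSetSpec(size=50, frac_negative=0.6),
        "background_a": MarkerSetSpec(size=50),
        "background_b": MarkerSetSpec(size=50),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the desk-scale analogue of the study: 500 seeds, 400 genes
    of which 80 (20%) align with the planted gradient (40 positive, 40
    negative), 100 cortical regions, 20 participants.
    """

    n_seeds: int = 500
    n_genes: int = 400
    aligned_fraction: float = 0.2
    n_regions: int = 100
    n_participants: int = 20
    spacing: float = 1.75
    mask: EllipsoidMask = field(default_factory=EllipsoidMask)
    # expression model: aligned gene = amplitude * (+/-g) + noise field
    gene_amplitude: float = 1.0
    gene_noise_sd: float = 0.5
    noise_length_scale: float = 5.0
    # connectivity model: W_ij = scale * exp(-(g_i - a_j)^2 / (2 tau^2)) + noise
    coupling_width: float = 0.5
    conn_scale: float = 100.0
    conn_noise_sd: float = 30.0
    # participant-level seed inclusion (for QC): a shared base pattern in
    # which the most peripheral seeds are excluded, plus per-participant flips
    base_exclusion_fraction: float = 0.15
    inclusion_flip_rate: float = 0.03
    n_corrupt_participants: int = 0
    corrupt_flip_rate: float = 0.5
    missing_expression_fraction: float = 0.0
    # marker sets
    marker_specs: dict[str, MarkerSetSpec] = field(default_factory=default_marker_specs)
    # developmental samples
    n_dev_genes: int = 12
    n_donors: int = 20
    samples_per_donor: int = 6
    dev_noise_sd: float = 0.5
    dev_sex_effect: float = 0.6
    dev_rin_effect: float = 0.3
    dev_donor_sd: float = 0.4
    # cross-species table
    xspecies_noise_sd: float = 0.3

    def validate(self) -> None:
        n_aligned = int(round(self.n_genes * self.aligned_fraction))
        if n_aligned % 2 != 0:
            raise ValueError("aligned gene count must be even (split +/-)")
        if n_aligned > self.n_genes:
            raise ValueError("aligned_fraction implies more aligned genes than genes")
        n_other = self.n_genes - n_aligned
        for name, spec in self.marker_specs.items():
            if spec.frac_positive + spec.frac_negative > 1.0:
                raise ValueError(f"marker set {name}: overlap fractions exceed 1")
            n_pos = int(round(spec.size * spec.frac_positive))
            n_neg = int(round(spec.size * spec.frac_negative))
            if (
                n_pos > n_aligned // 2
                or n_neg > n_aligned // 2
                or spec.size - n_pos - n_neg > n_other
            ):
                raise ValueError(
                    f"marker set {name}: size {spec.size} inconsistent with the "
                    "planted gene-set sizes"
                )
        if min(self.n_seeds, self.n_genes, self.n_regions, self.n_participants) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class GroundTruth:
    gradient_values: pd.Series          # planted primary axis g per seed
    secondary_gradients: pd.DataFrame   # orthogonal planted axes per seed
    aligned_positive: list[str]
    aligned_negative: list[str]
    cortical_axis: pd.Series            # planted target-position axis a
    noise_spec: dict
    rng_seed: int

    @property
    def aligned_gene_ids(self) -> list[str]:
        return list(self.aligned_positive) + list(self.aligned_negative)


@dataclass
class SyntheticDataset:
    seeds: pd.DataFrame                       # seed_id, x, y, z
    participant_connectivity: list[pd.DataFrame]  # seeds x regions, nonneg
    expression: pd.DataFrame                  # seeds x genes
    region_centroids: pd.DataFrame            # regions x (x, y, z) on a sphere
    inclusion: pd.DataFrame                   # participants x seeds, {0,1}
    has_expression: pd.Series                 # bool per seed
    marker_sets: dict[str, set[str]]
    dev_samples: pd.DataFrame                 # sample meta + dev-gene columns
    dev_meta_columns: list[str]
    species_pair: dict
    truth: GroundTruth
    config: SyntheticConfig


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def _dev_window_edges() -> np.ndarray:
    # nine developmental windows; prenatal ages are negative years from birth
    return np.array([-0.75, -0.5, -0.25, 0.0, 1.0, 6.0, 12.0, 20.0, 40.0, 80.0])


def generate_dataset(config: SyntheticConfig | None = None, rng_seed: int = 0) -> SyntheticDataset:
    """Generate a fully specified dataset with known ground truth.

    Identical ``rng_seed`` (and config) gives an identical dataset.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(rng_seed)

    # --- seeds and planted axes -------------------------------------------
    lattice = generate_seed_lattice(cfg.mask, cfg.spacing)
    if len(lattice) < cfg.n_seeds:
        raise ValueError(
            f"mask yields only {len(lattice)} lattice points at spacing "
            f"{cfg.spacing}, fewer than the requested {cfg.n_seeds} seeds"
        )
    keep = np.sort(rng.choice(len(lattice), size=cfg.n_seeds, replace=False))
    seeds = lattice.iloc[keep].reset_index(drop=True)
    seeds["seed_id"] = [f"seed{i:04d}" for i in range(cfg.n_seeds)]
    coords = seeds[["x", "y", "z"]].to_numpy()

    g = _zscore(coords[:, 0])
    # secondary axes: y and z residualised against g, then z-scored
    secondary = {}
    for name, col in (("g2", 1), ("g3", 2)):
        v = coords[:, col].astype(float)
        v = v - v.mean()
        v = v - (v @ g) / (g @ g) * g
        secondary[name] = _zscore(v)
    g_series = pd.Series(g, index=seeds["seed_id"], name="g")
    secondary_df = pd.DataFrame(secondary, index=seeds["seed_id"])

    # --- gene expression ---------------------------------------------------
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    n_aligned = int(round(cfg.n_genes * cfg.aligned_fraction))
    pos_genes = gene_ids[: n_aligned // 2]
    neg_genes = gene_ids[n_aligned // 2 : n_aligned]
    fields = generate_autocorrelated_field(
        coords, cfg.noise_length_scale, rng, size=cfg.n_genes
    )
    expr = np.empty((cfg.n_seeds, cfg.n_genes))
    for j, gid in enumerate(gene_ids):
        if gid in pos_genes:
            expr[:, j] = cfg.gene_amplitude * g + cfg.gene_noise_sd * fields[j]
        elif gid in neg_genes:
            expr[:, j] = -cfg.gene_amplitude * g + cfg.gene_noise_sd * fields[j]
        else:
            expr[:, j] = fields[j]
    expression = pd.DataFrame(expr, index=seeds["seed_id"], columns=gene_ids)

    # --- connectivity ------------------------------------------------------
    region_ids = [f"ctx{i:03d}" for i in range(cfg.n_regions)]
    a = np.linspace(g.min(), g.max(), cfg.n_regions)
    cortical_axis = pd.Series(a, index=region_ids, name="a")
    # sphere centroids ordered with the cortical axis, so the planted map is
    # spatially smooth on the sphere (as real parcel maps are)
    region_centroids = pd.DataFrame(
        fibonacci_sphere(cfg.n_regions), index=region_ids, columns=["x", "y", "z"]
    )
    kernel = cfg.conn_scale * np.exp(
        -((g[:, None] - a[None, :]) ** 2) / (2.0 * cfg.coupling_width**2)
    )
    participant_connectivity = []
    for _ in range(cfg.n_participants):
        noise = rng.normal(0.0, cfg.conn_noise_sd, size=kernel.shape)
        w = np.clip(kernel + noise, 0.0, None)  # streamline counts are nonneg
        participant_connectivity.append(
            pd.DataFrame(w, index=seeds["seed_id"], columns=region_ids)
        )

    # --- participant inclusion vectors (for QC) ----------------------------
    # shared base pattern: the most peripheral seeds (relative to the mask
    # shape) register inconsistently, as at the thalamic border in vivo
    radial = np.linalg.norm(
        (coords - np.asarray(cfg.mask.centroid)) / np.asarray(cfg.mask.semi_axes), axis=1
    ) if isinstance(cfg.mask, EllipsoidMask) else np.linalg.norm(coords - coords.mean(0), axis=1)
    n_excl = int(round(cfg.base_exclusion_fraction * cfg.n_seeds))
    base = np.ones(cfg.n_seeds, dtype=int)
    if n_excl > 0:
        base[np.argsort(radial)[-n_excl:]] = 0
    incl = np.empty((cfg.n_participants, cfg.n_seeds), dtype=int)
    for p in range(cfg.n_participants):
        rate = (
            cfg.corrupt_flip_rate
            if p >= cfg.n_participants - cfg.n_corrupt_participants
            else cfg.inclusion_flip_rate
        )
        flips = rng.random(cfg.n_seeds) < rate
        incl[p] = np.where(flips, 1 - base, base)
    inclusion = pd.DataFrame(
        incl,
        index=[f"sub{p:03d}" for p in range(cfg.n_participants)],
        columns=seeds["seed_id"],
    )
    has_expression = pd.Series(
        rng.random(cfg.n_seeds) >= cfg.missing_expression_fraction,
        index=seeds["seed_id"],
        name="has_expression",
    )

    # --- marker sets -------------------------------------------------------
    other_genes = gene_ids[n_aligned:]
    marker_sets: dict[str, set[str]] = {}
    for name, spec in cfg.marker_specs.items():
        n_pos = int(round(spec.size * spec.frac_positive))
        n_neg = int(round(spec.size * spec.frac_negative))
        n_rest = spec.size - n_pos - n_neg
        members = []
        members += list(rng.choice(pos_genes, size=n_pos, replace=False))
        members += list(rng.choice(neg_genes, size=n_neg, replace=False))
        members += list(rng.choice(other_genes, size=n_rest, replace=False))
        marker_sets[name] = set(members)

    # --- developmental samples ---------------------------------------------
    dev_samples, dev_meta_cols = _generate_dev_samples(cfg, rng)

    # --- cross-species loading table ---------------------------------------
    true_loading = np.where(
        np.isin(gene_ids, pos_genes), 1.0, np.where(np.isin(gene_ids, neg_genes), -1.0, 0.0)
    ) + 0.1 * rng.standard_normal(cfg.n_genes)
    mouse_ids = [f"m_{gid}" for gid in gene_ids]
    loadings_b = pd.Series(
        true_loading + cfg.xspecies_noise_sd * rng.standard_normal(cfg.n_genes),
        index=mouse_ids,
        name="loading_b",
    )
    homologue_table = pd.DataFrame({"gene_a": gene_ids, "gene_b": mouse_ids})
    expression_aggregate = pd.Series(
        rng.gamma(shape=2.0, scale=50.0, size=cfg.n_genes), index=mouse_ids, name="umi"
    )
    protein_genes = list(rng.choice(gene_ids, size=int(0.9 * cfg.n_genes), replace=False))
    species_pair = {
        "true_loading_a": pd.Series(true_loading, index=gene_ids, name="loading_a"),
        "loadings_b": loadings_b,
        "homologue_table": homologue_table,
        "expression_aggregate": expression_aggregate,
        "protein_genes": protein_genes,
    }

    truth = GroundTruth(
        gradient_values=g_series,
        secondary_gradients=secondary_df,
        aligned_positive=list(pos_genes),
        aligned_negative=list(neg_genes),
        cortical_axis=cortical_axis,
        noise_spec={
            "gene_noise_sd": cfg.gene_noise_sd,
            "conn_noise_sd": cfg.conn_noise_sd,
            "noise_length_scale": cfg.noise_length_scale,
            "expression_noise": "gaussian",
            "connectivity_noise": "gaussian truncated at zero",
        },
        rng_seed=rng_seed,
    )
    return SyntheticDataset(
        seeds=seeds,
        participant_connectivity=participant_connectivity,
        expression=expression,
        region_centroids=region_centroids,
        inclusion=inclusion,
        has_expression=has_expression,
        marker_sets=marker_sets,
        dev_samples=dev_samples,
        dev_meta_columns=dev_meta_cols,
        species_pair=species_pair,
        truth=truth,
        config=cfg,
    )


def dev_trajectory_value(age: np.ndarray, kind: str) -> np.ndarray:
    """Smooth ground-truth age trajectory for a developmental gene.

    Trajectories are cubic polynomials in age scaled to [-1, 1] over the
    window span: ``prenatal`` genes are elevated before birth and decline,
    ``postnatal`` genes rise with age, ``flat`` genes have no age effect.
    Ages are in years with prenatal ages negative.
    """
    t = np.asarray(age, dtype=float)
    lo, hi = _dev_window_edges()[0], _dev_window_edges()[-1]
    s = 2.0 * (t - lo) / (hi - lo) - 1.0  # age span scaled to [-1, 1]
    if kind == "prenatal":
        return 2.0 - 1.5 * s + 0.5 * s**3
    if kind == "postnatal":
        return 2.0 + 1.5 * s - 0.5 * s**3
    if kind == "flat":
        return np.full_like(t, 2.0)
    raise ValueError(f"unknown trajectory kind: {kind!r}")


def _generate_dev_samples(cfg: SyntheticConfig, rng: np.random.Generator):
    edges = _dev_window_edges()
    n_samples = cfg.n_donors * cfg.samples_per_donor
    # cycle windows so each gets >= 2 samples, then sample age uniform in it
    windows = (np.arange(n_samples) % 9) + 1
    lo = edges[windows - 1]
    hi = edges[windows]
    ages = lo + rng.random(n_samples) * (hi - lo)
    donors = np.repeat([f"donor{d:02d}" for d in range(cfg.n_donors)], cfg.samples_per_donor)
    sexes = rng.choice(["F", "M"], size=n_samples)
    rins = np.clip(rng.normal(8.0, 1.0, size=n_samples), 5.0, 10.0)
    donor_fx = dict(
        zip(
            sorted(set(donors)),
            rng.normal(0.0, cfg.dev_donor_sd, size=cfg.n_donors),
        )
    )
    kinds = ["prenatal", "postnatal", "flat"]
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n_samples)],
            "donor": donors,
            "age": ages,
            "window": windows,
            "sex": sexes,
            "RIN": rins,
        }
    )
    gene_cols = {}
    gene_kinds = {}
    for j in range(cfg.n_dev_genes):
        kind = kinds[j % 3]
        gid = f"d{j:03d}_{kind}"
        y = dev_trajectory_value(ages, kind)
        y = y + cfg.dev_sex_effect * (sexes == "M")
        y = y + cfg.dev_rin_effect * (rins - 8.0)
        y = y + np.array([donor_fx[d] for d in donors])
        y = y + rng.normal(0.0, cfg.dev_noise_sd, size=n_samples)
        gene_cols[gid] = y
        gene_kinds[gid] = kind
    table = pd.concat([meta, pd.DataFrame(gene_cols)], axis=1)
    table.attrs["gene_kinds"] = gene_kinds
    return table, list(meta.columns)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir) -> list[str]:
    """Write the dataset as plain TSV files; returns the file list."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df: pd.DataFrame, name: str, index: bool):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        written.append(str(path))

    _w(ds.seeds, "seed_coords.tsv", index=False)
    _w(ds.region_centroids, "region_centroids.tsv", index=True)
    _w(ds.expression, "expression.tsv", index=True)
    for p, (pid, mat) in enumerate(
        zip(ds.inclusion.index, ds.participant_connectivity)
    ):
        _w(mat, f"connectivity_{pid}.tsv", index=True)
    _w(ds.inclusion, "inclusion.tsv", index=True)
    marker_rows = [
        {"set_name": name, "gene_id": gid}
        for name, members in ds.marker_sets.items()
        for gid in sorted(members)
    ]
    _w(pd.DataFrame(marker_rows), "marker_sets.tsv", index=False)
    _w(ds.dev_samples, "dev_samples.tsv", index=False)
    truth = ds.seeds[["seed_id"]].copy()
    truth["g"] = ds.truth.gradient_values.to_numpy()
    truth[["g2", "g3"]] = ds.truth.secondary_gradients.to_numpy()
    _w(truth, "ground_truth.tsv", index=False)
    _w(ds.species_pair["homologue_table"], "homologues.tsv", index=False)
    return written
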
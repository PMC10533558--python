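"""Spatial-autocorrelation-preserving permutation nulls.

Two null models are provided, matching the two geometries in the pipeline:

* **Spin test** for parcel-level cortical maps: parcel centroids on the
  spherical surface projection are rotated by a uniform random rotation and
  greedily re-assigned to original parcels, yielding a permutation that
  approximately preserves spatial contiguity (and exactly preserves the
  value multiset).
* **Variogram-matched surrogates** for volumetric seed maps: values are
  randomly permuted, smoothed over k nearest neighbours at several
  bandwidths, and affinely rescaled so the surrogate's empirical variogram
  matches the original map's, imposing the original spatial autocorrelation
  on otherwise random data.

p-values use the (count + 1) / (n_perm + 1) estimator, two-tailed on |r|;
when both maps have an ensemble the two directional p-values are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import special_ortho_group

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rotations and spin assignment
# ---------------------------------------------------------------------------

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Proper rotation matrix drawn uniformly from SO(3)."""
    return special_ortho_group.rvs(dim=3, random_state=rng)


def spin_assignment(original: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """Greedy bijection of rotated parcel centroids onto original parcels.

    Iteratively, the rotated region with the minimal mean distance to all
    remaining original regions is selected and mapped to the remaining
    original region most distant from it; both are removed and the process
    repeats until every rotated region is mapped to a unique original one.
    Ties are broken by lowest index.

    Returns ``perm`` with ``perm[original_index] = rotated_index``, so a map
    ``v`` spins to ``v[perm]``.
    """
    original = np.asarray(original, dtype=float)
    rotated = np.asarray(rotated, dtype=float)
    m = len(original)
    if len(rotated) != m:
        raise ValueError("original and rotated centroid counts differ")
    D = cdist(rotated, original)
    perm = np.full(m, -1, dtype=int)
    rowsum = D.sum(axis=1)
    r_alive = np.ones(m, dtype=bool)
    o_alive = np.ones(m, dtype=bool)
    n_rem = m
    for _ in range(m):
        means = np.where(r_alive, rowsum / n_rem, np.inf)
        r = int(np.argmin(means))  # argmin takes the lowest index on ties
        dr = np.where(o_alive, D[r], -np.inf)
        o = int(np.argmax(dr))
        perm[o] = r
        r_alive[r] = False
        o_alive[o] = False
        rowsum = rowsum - D[:, o]
        n_rem -= 1
    return perm


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class SurrogateEnsemble:
    """Ensemble of spatially constrained permutations of a map.

    ``spin`` ensembles store index bijections applicable to any map on the
    same parcels; ``variogram`` ensembles store surrogate value vectors tied
    to the base map they were built from.
    """

    method: str
    geometry: np.ndarray
    permutations: np.ndarray | None = None      # (count, n) int, spin only
    surrogate_values: np.ndarray | None = None  # (count, n), variogram only
    base_values: np.ndarray | None = None
    rng_seed: int | None = None
    fit_sse: np.ndarray | None = None           # variogram match quality
    params: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        arr = self.permutations if self.method == "spin" else self.surrogate_values
        return 0 if arr is None else arr.shape[0]

    @property
    def n_units(self) -> int:
        return self.geometry.shape[0]

    def surrogates(self, values: np.ndarray | None = None) -> np.ndarray:
        """Surrogate maps as a (count, n) array.

        For spin ensembles ``values`` is the map to permute; for variogram
        ensembles the stored surrogates of the base map are returned (and
        ``values``, if given, must equal the base map).
        """
        if self.method == "spin":
            if values is None:
                raise ValueError("spin ensembles need the map values to permute")
            values = np.asarray(values, dtype=float)
            if values.shape[0] != self.n_units:
                raise ValueError("map length does not match ensemble geometry")
            return values[self.permutations]
        if values is not None and not np.allclose(values, self.base_values):
            raise ValueError("variogram surrogates are tied to their base map")
        return self.surrogate_values


def build_spin_ensemble(
    centroids: np.ndarray, n_perm: int = 10_000, rng=None
) -> SurrogateEnsemble:
    """Ensemble of ``n_perm`` spin permutations of sphere-projected parcels."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    centroids = np.asarray(centroids, dtype=float)
    perms = np.empty((n_perm, len(centroids)), dtype=np.int32)
    for i in range(n_perm):
        R = random_rotation(rng)
        perms[i] = spin_assignment(centroids, centroids @ R.T)
    return SurrogateEnsemble(method="spin", geometry=centroids, permutations=perms)


# ---------------------------------------------------------------------------
# variogram surrogates
# ---------------------------------------------------------------------------

class VariogramGeometry:
    """Precomputed pairwise geometry for fast repeated variogram evaluation.

    Pairs are binned into ``n_bins`` equal-width distance bins up to the
    ``pct``-th percentile of pairwise distances; smoothing matrices use a
    Gaussian kernel over the ``k`` nearest neighbours with bandwidth equal
    to the k-th neighbour distance.
    """

    def __init__(self, coords, n_bins: int = 25, pct: float = 70.0, ks=None):
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        self.n = n
        D = cdist(coords, coords)
        iu = np.triu_indices(n, k=1)
        d = D[iu]
        h_max = np.percentile(d, pct)
        keep = d <= h_max
        self.pair_i = iu[0][keep]
        self.pair_j = iu[1][keep]
        edges = np.linspace(0.0, h_max, n_bins + 1)
        raw_idx = np.clip(np.digitize(d[keep], edges) - 1, 0, n_bins - 1)
        counts = np.bincount(raw_idx, minlength=n_bins).astype(float)
        # on lattice geometries some distance bins are empty; drop them so
        # they do not enter the variogram-matching regression as zeros
        occupied = counts > 0
        remap = np.cumsum(occupied) - 1
        self.bin_idx = remap[raw_idx]
        self.bin_counts = counts[occupied]
        self.n_bins = int(occupied.sum())
        self.bin_centers = (0.5 * (edges[:-1] + edges[1:]))[occupied]
        if ks is None:
            fracs = (0.05, 0.1, 0.2, 0.3, 0.5)
            ks = sorted({max(3, int(round(n * f))) for f in fracs})
        ks = [k for k in ks if k < n]
        if not ks:
            raise ValueError("fewer seeds than the smallest neighbour parameter")
        self.ks = ks
        self.smoothers = {}
        order = np.argsort(D, axis=1)
        for k in ks:
            nbr = order[:, :k]  # includes self at distance 0
            dk = D[np.arange(n), order[:, k - 1]]
            w = np.exp(-((D[np.arange(n)[:, None], nbr] / dk[:, None]) ** 2))
            w = w / w.sum(axis=1, keepdims=True)
            S = np.zeros((n, n))
            np.put_along_axis(S, nbr, w, axis=1)
            self.smoothers[k] = S

    def variogram(self, fields: np.ndarray) -> np.ndarray:
        """Binned empirical variogram of one (n,) or many (m, n) fields."""
        F = np.atleast_2d(np.asarray(fields, dtype=float))
        out = np.empty((F.shape[0], self.n_bins))
        chunk = max(1, int(2e7 / max(len(self.pair_i), 1)))
        for s in range(0, F.shape[0], chunk):
            block = F[s : s + chunk]
            sq = 0.5 * (block[:, self.pair_i] - block[:, self.pair_j]) ** 2
            for r in range(block.shape[0]):
                out[s + r] = np.bincount(
                    self.bin_idx, weights=sq[r], minlength=self.n_bins
                ) / np.maximum(self.bin_counts, 1.0)
        return out[0] if np.ndim(fields) == 1 else out


def empirical_variogram(values, coords, n_bins: int = 25, pct: float = 70.0):
    """Convenience wrapper: (bin centres, binned variogram) of one map."""
    geom = VariogramGeometry(coords, n_bins=n_bins, pct=pct)
    return geom.bin_centers, geom.variogram(np.asarray(values, dtype=float))


def variogram_surrogates(
    values: np.ndarray,
    coords: np.ndarray,
    n_surr: int = 1000,
    rng=None,
    geometry: VariogramGeometry | None = None,
    n_bins: int = 25,
    pct: float = 70.0,
    ks=None,
    resample: bool = False,
) -> SurrogateEnsemble:
    """Surrogate maps matching the base map's empirical variogram.

    Per surrogate the base values are randomly permuted, smoothed over k
    nearest neighbours for each candidate k, and the candidate whose
    affinely rescaled variogram (``alpha * gamma_k + beta``, ``alpha`` and
    ``beta`` fit by least squares) best matches the base variogram is kept:
    the surrogate is ``sqrt(alpha) * smoothed + sqrt(beta) * z`` (z white
    noise), recentred to the base mean. The per-surrogate squared deviation
    between the surrogate-model and empirical variograms is stored in
    ``fit_sse``. With ``resample=True``, surrogates are rank-remapped to the
    original value multiset.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("map values must be finite")
    if n_surr < 1:
        raise ValueError("n_surr must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(values)
    geom = geometry or VariogramGeometry(coords, n_bins=n_bins, pct=pct, ks=ks)
    gamma_emp = geom.variogram(values)

    perms = np.array([rng.permutation(n) for _ in range(n_surr)])
    F0 = values[perms]
    best_sse = np.full(n_surr, np.inf)
    best_field = np.empty((n_surr, n))
    noise = rng.standard_normal((n_surr, n))
    y = gamma_emp
    ybar = y.mean()
    for k in geom.ks:
        S = geom.smoothers[k]
        Fk = F0 @ S.T
        gam = geom.variogram(Fk)  # (n_surr, n_bins)
        xbar = gam.mean(axis=1, keepdims=True)
        xc = gam - xbar
        denom = (xc**2).sum(axis=1)
        alpha = np.where(denom > 0, (xc @ (y - ybar)) / np.maximum(denom, 1e-300), 0.0)
        alpha = np.clip(alpha, 0.0, None)
        beta = np.clip(ybar - alpha * xbar[:, 0], 0.0, None)
        sse = ((alpha[:, None] * gam + beta[:, None] - y) ** 2).sum(axis=1)
        better = sse < best_sse
        if better.any():
            cand = (
                np.sqrt(alpha[better, None]) * Fk[better]
                + np.sqrt(beta[better, None]) * noise[better]
            )
            best_field[better] = cand
            best_sse[better] = sse[better]
    best_field += values.mean() - best_field.mean(axis=1, keepdims=True)
    if resample:
        ranks = np.argsort(np.argsort(best_field, axis=1), axis=1)
        best_field = np.sort(values)[ranks]
    return SurrogateEnsemble(
        method="variogram",
        geometry=np.asarray(coords, dtype=float),
        surrogate_values=best_field,
        base_values=values,
        fit_sse=best_sse,
        params={"n_bins": geom.n_bins, "pct": pct, "ks": list(geom.ks), "resample": resample},
    )


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------

@dataclass
class SpinTestResult:
    r_empirical: float
    null_rs: np.ndarray
    p_spin: float
    n_permutations: int
    direction: str = "two-tailed"


def _corr_rows(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r of each row of A with b."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.linalg.norm(Ac, axis=1) * np.linalg.norm(bc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Ac @ bc) / denom


def _tail_p(null_rs: np.ndarray, r_emp: float) -> float:
    return (np.sum(np.abs(null_rs) >= abs(r_emp)) + 1.0) / (len(null_rs) + 1.0)


def spin_pvalue(
    map_a: np.ndarray,
    map_b: np.ndarray,
    ensemble_a: SurrogateEnsemble,
    ensemble_b: SurrogateEnsemble | None = None,
) -> SpinTestResult:
    """Two-tailed spatial-permutation p-value for the correlation of two maps.

    The empirical Pearson r is compared to the distribution of correlations
    between surrogates of one map and the empirical other; when ensembles
    for both maps are given, each direction's p is computed and their mean
    is reported (making the test symmetric in the two maps).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant map: correlation undefined")
    r_emp = float(np.corrcoef(a, b)[0, 1])
    null_a = _corr_rows(ensemble_a.surrogates(a), b)
    p = _tail_p(null_a, r_emp)
    nulls = [null_a]
    if ensemble_b is not None:
        null_b = _corr_rows(ensemble_b.surrogates(b), a)
        p = 0.5 * (p + _tail_p(null_b, r_emp))
        nulls.append(null_b)
    null_rs = np.concatenate(nulls)
    return SpinTestResult(
        r_empirical=r_emp,
        null_rs=null_rs,
        p_spin=float(p),
        n_permutations=ensemble_a.count,
    )


def ensemble_correlations(
    ensemble: SurrogateEnsemble, base_map: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Null correlations of each surrogate of ``base_map`` with each target.

    ``targets`` is (n_units, n_targets); the result is (count, n_targets).
    Used to test many features (e.g. all genes) against one surrogated map.
    """
    S = ensemble.surrogates(np.asarray(base_map, dtype=float))
    T = np.asarray(targets, dtype=float)
    Sc = S - S.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=0, keepdims=True)
    Sn = np.linalg.norm(Sc, axis=1)
    Tn = np.linalg.norm(Tc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Sc @ Tc) / np.outer(Sn, Tn)
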
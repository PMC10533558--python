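"""Joint PCA via SVD, diffusion-map embedding, and sensitivity variants.

The centred seed-by-feature matrix M is factored as M = U S V^T. PC scores
are US (one value per thalamic seed, defining a spatial gradient), loadings
are V (one coefficient per gene / cortical region), and the variance
explained by component k is lambda_k = s_k^2 / (n - 1).

Component signs are indeterminate under SVD; here each component is oriented
so that its seed scores correlate positively with the +x coordinate when
seed coordinates are supplied (the convention under which the principal
medial-lateral axis comes out positive laterally), falling back to making
the largest-magnitude loading positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import FeatureMatrix


@dataclass
class Decomposition:
    scores: pd.DataFrame            # seeds x k (US)
    loadings: pd.DataFrame          # features x k (V)
    singular_values: np.ndarray     # s_k (or eigenvalues for diffusion)
    variance: np.ndarray            # lambda_k
    variance_fraction: np.ndarray   # lambda_k / total variance of centred M
    total_variance: float
    column_means: pd.Series
    feature_kind: pd.Series
    z_scored: bool = False
    method: str = "pca"

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def variance_explained(singular_value, n: int):
    """lambda = s^2 / (n - 1) for a singular value of the centred matrix."""
    if n < 2:
        raise ValueError("need at least two seeds (n >= 2)")
    s = np.asarray(singular_value, dtype=float)
    return s**2 / (n - 1)


def _component_names(k: int, prefix: str = "PC") -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


def _orient(scores: np.ndarray, loadings: np.ndarray, coords=None) -> tuple[np.ndarray, np.ndarray]:
    """Fix component signs: seed-score correlation with +x positive, else
    largest-|loading| feature positive."""
    for j in range(scores.shape[1]):
        flip = False
        sc = scores[:, j]
        if coords is not None and sc.std() > 0:
            x = np.asarray(coords)[:, 0]
            r = float(np.corrcoef(sc, x)[0, 1]) if x.std() > 0 else 0.0
            if abs(r) > 1e-12:
                flip = r < 0
            else:
                flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            scores[:, j] = -scores[:, j]
            loadings[:, j] = -loadings[:, j]
    return scores, loadings


def joint_pca(matrix: FeatureMatrix, k: int = 10, coords=None) -> Decomposition:
    """PCA of the (column-centred) concatenated matrix via thin SVD.

    Parameters
    ----------
    matrix:
        Normalised :class:`~thalamograd.prep.FeatureMatrix`.
    k:
        Number of components to keep; must not exceed min(n, m). Components
        beyond the numerical rank are kept with lambda ~= 0 and a warning.
    coords:
        Optional seed coordinates (n x 3) used only for the sign convention.
    """
    if not matrix.normalised:
        raise ValueError("matrix must be normalised before decomposition")
    X = matrix.values.to_numpy(dtype=float)
    n, m = X.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n, m)={min(n, m)}")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam_all = variance_explained(s, n)
    total = float(lam_all.sum())
    rank = int(np.sum(s > s[0] * max(n, m) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        warnings.warn(
            f"k={k} exceeds numerical rank {rank}; trailing components have lambda ~= 0",
            stacklevel=2,
        )
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    scores, loadings = _orient(scores, loadings, coords)
    names = _component_names(k)
    return Decomposition(
        scores=pd.DataFrame(scores, index=matrix.values.index, columns=names),
        loadings=pd.DataFrame(loadings, index=matrix.values.columns, columns=names),
        singular_values=s[:k],
        variance=lam_all[:k],
        variance_fraction=lam_all[:k] / total,
        total_variance=total,
        column_means=pd.Series(mu, index=matrix.values.columns),
        feature_kind=matrix.feature_kind.copy(),
        method="pca",
    )


def zscore_components(dec: Decomposition) -> Decomposition:
    """Z-score each component independently over three blocks: seed scores,
    cortical-region loadings, and gene loadings (mean 0, sd 1 per block).

    Idempotent; rank order within each block is unchanged.
    """
    def _z(df: pd.DataFrame) -> pd.DataFrame:
        arr = df.to_numpy(dtype=float)
        sd = arr.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant block: cannot z-score")
        return pd.DataFrame(
            (arr - arr.mean(axis=0)) / sd, index=df.index, columns=df.columns
        )

    scores = _z(dec.scores)
    parts = []
    for kind in pd.unique(dec.feature_kind):
        block = dec.loadings.loc[dec.feature_kind == kind]
        parts.append(_z(block) if len(block) > 1 else block)
    loadings = pd.concat(parts).reindex(dec.loadings.index)
    return Decomposition(
        scores=scores,
        loadings=loadings,
        singular_values=dec.singular_values,
        variance=dec.variance,
        variance_fraction=dec.variance_fraction,
        total_variance=dec.total_variance,
        column_means=dec.column_means,
        feature_kind=dec.feature_kind,
        z_scored=True,
        method=dec.method,
    )


# ---------------------------------------------------------------------------
# diffusion-map embedding
# ---------------------------------------------------------------------------

def cosine_affinity(X: np.ndarray) -> np.ndarray:
    """Cosine similarity between rows; rows must be non-zero."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("rows of the input must be non-zero for cosine affinity")
    A = (X / norms[:, None]) @ (X / norms[:, None]).T
    np.fill_diagonal(A, 1.0)
    return np.clip(A, -1.0, 1.0)


def _check_connected(A: np.ndarray) -> None:
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix

    n_comp, labels = connected_components(csr_matrix(A > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected: {n_comp} components with sizes {sizes.tolist()}"
        )


def diffusion_embedding(
    matrix,
    k: int = 10,
    alpha: float = 0.5,
    affinity: np.ndarray | None = None,
    coords=None,
) -> Decomposition:
    """Diffusion-map embedding of seeds from a cosine affinity matrix.

    The affinity is anisotropically normalised with exponent ``alpha``
    (0.5 by default, approximating Fokker-Planck diffusion), the diffusion
    operator is eigen-decomposed, and the ``k`` non-trivial eigenvectors,
    scaled by lambda/(1 - lambda) (diffusion time 0), form the embedding.
    Eigenvalues are stored in place of singular values and their normalised
    mass in place of variance fractions.
    """
    if isinstance(matrix, FeatureMatrix):
        index = matrix.values.index
        kinds = matrix.feature_kind
        X = matrix.values.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(X.shape[0])
        kinds = pd.Series("feature", index=pd.RangeIndex(X.shape[1]))
    A = cosine_affinity(X) if affinity is None else np.asarray(affinity, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("affinity entries must be finite")
    A = np.clip(A, 0.0, None)  # diffusion operator needs nonnegative weights
    _check_connected(A)
    d = A.sum(axis=1)
    W = A / np.outer(d**alpha, d**alpha)
    dW = W.sum(axis=1)
    Ms = W / np.sqrt(np.outer(dW, dW))
    evals, evecs = np.linalg.eigh(Ms)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(dW)[:, None]
    psi = psi / psi[:, [0]]  # normalise against the trivial eigenvector
    lam = np.clip(evals[1 : k + 1], None, 1 - 1e-12)
    emb = psi[:, 1 : k + 1] * (lam / (1 - lam))
    loadings = np.zeros((X.shape[1], emb.shape[1]))
    # nominal loadings: correlation of each feature with each embedding axis
    Xc = X - X.mean(axis=0)
    embc = emb - emb.mean(axis=0)
    denom = np.outer(np.linalg.norm(Xc, axis=0), np.linalg.norm(embc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        loadings = np.where(denom > 0, (Xc.T @ embc) / denom, 0.0)
    emb, loadings = _orient(emb, loadings, coords)
    names = _component_names(emb.shape[1], prefix="DC")
    frac = np.abs(lam) / np.abs(evals[1:]).sum() if evals.size > 1 else np.array([])
    return Decomposition(
        scores=pd.DataFrame(emb, index=index, columns=names),
        loadings=pd.DataFrame(loadings, index=kinds.index, columns=names),
        singular_values=lam,
        variance=lam,
        variance_fraction=frac,
        total_variance=float(np.abs(evals[1:]).sum()),
        column_means=pd.Series(X.mean(axis=0), index=kinds.index),
        feature_kind=kinds,
        method="diffusion",
    )


# ---------------------------------------------------------------------------
# sensitivity variants
# ---------------------------------------------------------------------------

VARIANTS = (
    "pca_restricted",
    "pca_separate",
    "pca_concat_top10",
    "diffusion",
    "diffusion_avg_affinity",
)


def decompose_variant(
    name: str,
    conn: FeatureMatrix,
    genes: FeatureMatrix,
    k: int = 10,
    coords=None,
    restricted_genes=None,
    alpha: float = 0.5,
):
    """Run one of the five sensitivity-analysis decomposition variants.

    * ``pca_restricted`` -- joint PCA using only a restricted gene subset
      plus the connectivity block.
    * ``pca_separate`` -- per-modality PCA; returns a dict with keys
      ``connectivity`` and ``gene``.
    * ``pca_concat_top10`` -- PCA on the 20-column concatenation of each
      modality's top-10 PC scores.
    * ``diffusion`` -- diffusion embedding of the joint matrix.
    * ``diffusion_avg_affinity`` -- diffusion embedding on the mean of the
      two per-modality cosine affinity matrices.
    """
    from .prep import concatenate

    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
    if name == "pca_restricted":
        if restricted_genes is None:
            raise ValueError("pca_restricted requires restricted_genes")
        sub = FeatureMatrix(
            values=genes.values.loc[:, list(restricted_genes)],
            feature_kind=genes.feature_kind.loc[list(restricted_genes)],
            normalised=genes.normalised,
        )
        dec = joint_pca(concatenate(conn, sub), k=k, coords=coords)
        dec.method = name
        return dec
    if name == "pca_separate":
        dc = joint_pca(conn, k=min(k, conn.n_features, conn.n_seeds), coords=coords)
        dg = joint_pca(genes, k=min(k, genes.n_features, genes.n_seeds), coords=coords)
        dc.method = dg.method = name
        return {"connectivity": dc, "gene": dg}
    if name == "pca_concat_top10":
        sep = decompose_variant("pca_separate", conn, genes, k=10, coords=coords)
        blocks = []
        kinds = []
        for label, dec in (("conn", sep["connectivity"]), ("gene", sep["gene"])):
            sc = dec.scores.iloc[:, :10].copy()
            sc.columns = [f"{label}_{c}" for c in sc.columns]
            blocks.append(sc)
            kinds += [f"{label}_pc"] * sc.shape[1]
        concat = pd.concat(blocks, axis=1)
        # standardise the 20 columns so neither modality dominates by scale
        concat = (concat - concat.mean()) / concat.std(ddof=1)
        fm = FeatureMatrix(
            values=concat,
            feature_kind=pd.Series(kinds, index=concat.columns),
            normalised=True,
        )
        dec = joint_pca(fm, k=min(k, concat.shape[1]), coords=coords)
        dec.method = name
        return dec
    if name == "diffusion":
        joint = concatenate(conn, genes)
        dec = diffusion_embedding(joint, k=k, alpha=alpha, coords=coords)
        dec.method = name
        return dec
    # diffusion_avg_affinity
    A = 0.5 * (
        cosine_affinity(conn.values.to_numpy(float))
        + cosine_affinity(genes.values.to_numpy(float))
    )
    joint = concatenate(conn, genes)
    dec = diffusion_embedding(joint, k=k, alpha=alpha, affinity=A, coords=coords)
    dec.method = name
    return dec
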
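"""Stability of the decomposition: participant bootstrap and seed LOOCV.

Replicate components are compared to the original after sign alignment
(sign chosen to make the correlation with the original positive) and, for
score RMSE, after z-scoring both, since PCA components carry arbitrary sign
and scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import Decomposition, joint_pca
from .prep import FeatureMatrix, average_connectivity, concatenate, normalise_sigmoid


@dataclass
class StabilityReport:
    method: str
    replicates: pd.DataFrame  # one row per replicate / left-out seed
    original: Decomposition
    rng_seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.replicates)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(abs(np.corrcoef(a, b)[0, 1]))


def _zs(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def bootstrap_decomposition(
    participant_matrices: list[pd.DataFrame] | dict[str, pd.DataFrame],
    gene_block: FeatureMatrix | None,
    B: int = 100,
    rng: np.random.Generator | int | None = None,
    k: int = 10,
    coords=None,
) -> StabilityReport:
    """Bootstrap the decomposition over participants.

    Each replicate resamples participants with replacement, averages the raw
    connectivity matrices, sigmoid-normalises the average, concatenates the
    (fixed, already normalised) gene block if given, decomposes, and records
    the variance-explained fractions plus the sign-aligned |r| of replicate
    PC1 scores and loadings against the original decomposition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(participant_matrices, dict):
        mats = list(participant_matrices.values())
    else:
        mats = list(participant_matrices)
    if len(mats) < 2:
        raise ValueError("need at least two participants to bootstrap")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def _decompose(ms: list[pd.DataFrame]) -> Decomposition:
        avg = average_connectivity(ms)
        conn = normalise_sigmoid(avg, kind="cortical_region")
        joint = concatenate(conn, gene_block)
        return joint_pca(joint, k=min(k, joint.n_seeds, joint.n_features), coords=coords)

    original = _decompose(mats)
    o_scores = original.scores.iloc[:, 0].to_numpy()
    o_load = original.loadings.iloc[:, 0].to_numpy()
    rows = []
    for b in range(B):
        idx = rng.integers(0, len(mats), size=len(mats))
        rep = _decompose([mats[i] for i in idx])
        r_scores = _abs_corr(rep.scores.iloc[:, 0].to_numpy(), o_scores)
        # loadings comparable only where the feature sets coincide (they do:
        # resampling changes values, not features)
        r_load = _abs_corr(rep.loadings.iloc[:, 0].to_numpy(), o_load)
        row = {"replicate": b, "r_pc1_scores": r_scores, "r_pc1_loadings": r_load}
        for j, f in enumerate(rep.variance_fraction):
            row[f"lambda_frac_{j + 1}"] = f
        rows.append(row)
    return StabilityReport(
        method="bootstrap",
        replicates=pd.DataFrame(rows),
        original=original,
        rng_seed=None,
    )


def loocv_seeds(matrix: FeatureMatrix, k: int = 1, coords=None) -> StabilityReport:
    """Leave-one-seed-out cross-validation of PC1 scores.

    For each left-out seed the decomposition is recomputed on the remaining
    n-1 rows; the RMSE between the remaining seeds' PC1 scores and the
    corresponding original scores is recorded after sign alignment and
    z-scoring of both score vectors.
    """
    n = matrix.n_seeds
    if n < 3:
        raise ValueError("need at least three seeds for leave-one-out")
    coords_arr = None if coords is None else np.asarray(coords)
    original = joint_pca(matrix, k=k, coords=coords_arr)
    o_scores = original.scores.iloc[:, 0].to_numpy()
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        sub = FeatureMatrix(
            values=matrix.values.iloc[keep],
            feature_kind=matrix.feature_kind,
            normalised=matrix.normalised,
        )
        sub_coords = None if coords_arr is None else coords_arr[keep]
        rep = joint_pca(sub, k=k, coords=sub_coords)
        a = _zs(rep.scores.iloc[:, 0].to_numpy())
        b = _zs(o_scores[keep])
        if np.corrcoef(a, b)[0, 1] < 0:
            a = -a
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        rows.append({"left_out_seed": matrix.values.index[i], "rmse_pc1_scores": rmse})
    return StabilityReport(method="loocv", replicates=pd.DataFrame(rows), original=original)
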
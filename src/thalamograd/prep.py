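"""Matrix assembly: QC, expression assignment, averaging, normalisation.

Produces the concatenated seed-by-feature matrix ``M`` that the joint
decomposition consumes. The order of operations mirrors the study design:
participant QC -> seed QC -> cross-participant averaging of raw streamline
counts -> per-feature scaled-sigmoid normalisation -> column concatenation
of the connectivity and gene blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

log = logging.getLogger(__name__)


@dataclass
class SigmoidParams:
    """Per-feature parameters of the scaled sigmoid transform.

    The transform is S(x) = 1 / (1 + exp(-(x - mean)/sd)) followed by a
    linear rescale of each feature to attain exactly 0 and 1. ``sd`` is the
    sample standard deviation (n-1 denominator).
    """

    feature_mean: pd.Series
    feature_sd: pd.Series
    post_rescale_min: pd.Series
    post_rescale_max: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.feature_mean,
                "sd": self.feature_sd,
                "sigmoid_min": self.post_rescale_min,
                "sigmoid_max": self.post_rescale_max,
            }
        )


@dataclass
class FeatureMatrix:
    """Seeds x features matrix with per-feature kind metadata."""

    values: pd.DataFrame
    feature_kind: pd.Series  # 'gene' or 'cortical_region' per feature
    normalised: bool = False
    sigmoid: SigmoidParams | None = None

    def __post_init__(self):
        if not self.values.columns.equals(self.feature_kind.index):
            raise ValueError("feature metadata does not match matrix columns")

    @property
    def n_seeds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, kind: str) -> pd.DataFrame:
        return self.values.loc[:, self.feature_kind == kind]


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_participants(inclusion: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Retain participants whose binary seed-inclusion vector agrees with the rest.

    For each participant the mean pairwise Pearson correlation (phi
    coefficient on {0,1} vectors) with all other participants is computed; a
    participant is retained iff that mean is >= ``threshold``. Participants
    with a zero-variance vector (all seeds in, or all out) have undefined
    correlations and are excluded with reason ``constant_vector``.

    Returns a report with columns ``participant, mean_r, retained, reason``.
    """
    if inclusion.shape[0] < 2:
        raise ValueError("need at least two participants")
    vals = inclusion.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    constant = sd == 0.0
    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals)
    for i, pid in enumerate(inclusion.index):
        if constant[i]:
            rows.append((pid, np.nan, False, "constant_vector"))
            continue
        others = [j for j in range(len(inclusion)) if j != i and not constant[j]]
        if not others:
            rows.append((pid, np.nan, False, "no_valid_comparisons"))
            continue
        mean_r = float(np.mean(corr[i, others]))
        ok = mean_r >= threshold
        rows.append((pid, mean_r, ok, "" if ok else "low_mean_correlation"))
    return pd.DataFrame(rows, columns=["participant", "mean_r", "retained", "reason"])


def qc_seeds(
    inclusion: pd.DataFrame,
    has_expression: pd.Series,
    presence_fraction: float = 0.85,
) -> pd.Index:
    """Retain seeds present in strictly more than ``presence_fraction`` of
    the (already QC'd) participants and located where expression is available.
    """
    if not (0 < presence_fraction <= 1):
        raise ValueError("presence_fraction must be in (0, 1]")
    has_expression = has_expression.reindex(inclusion.columns)
    if has_expression.isna().any():
        raise ValueError("has_expression missing entries for some seeds")
    presence = inclusion.mean(axis=0)
    keep = (presence > presence_fraction) & has_expression.astype(bool)
    return inclusion.columns[keep]


# ---------------------------------------------------------------------------
# expression assignment
# ---------------------------------------------------------------------------

def assign_expression(img, seeds: pd.DataFrame, gene_names=None, missing=np.nan):
    """Assign each seed the expression value of the voxel containing it.

    ``img`` is a nibabel spatial image, 3-D (one gene; returns a Series) or
    4-D (one gene per volume; returns a DataFrame). World coordinates map to
    voxel indices via the inverse affine with a floor (half-open voxel
    convention): a seed exactly on the upper boundary of a voxel belongs to
    the lower one. Voxels holding the ``missing`` sentinel mark the seed
    ``has_expression = False``.

    Returns ``(values, has_expression)``.
    """
    data = np.asarray(img.dataobj, dtype=float)
    inv = np.linalg.inv(img.affine)
    pts = seeds[["x", "y", "z"]].to_numpy(dtype=float)
    vox = np.floor(inv[:3, :3] @ pts.T + inv[:3, 3:4] + 1e-9).astype(int).T
    shape = np.array(data.shape[:3])
    bad = np.any((vox < 0) | (vox >= shape), axis=1)
    if bad.any():
        first = seeds["seed_id"].iloc[int(np.argmax(bad))]
        raise ValueError(f"seed {first} falls outside the volume bounds")
    idx = tuple(vox.T)
    seed_ids = pd.Index(seeds["seed_id"], name="seed_id")
    if data.ndim == 3:
        vals = data[idx]
        miss = np.isnan(vals) if np.isnan(missing) else (vals == missing)
        return (
            pd.Series(vals, index=seed_ids, name="expression"),
            pd.Series(~miss, index=seed_ids, name="has_expression"),
        )
    if data.ndim == 4:
        vals = data[idx]  # seeds x genes
        cols = gene_names if gene_names is not None else [
            f"gene{i:04d}" for i in range(data.shape[3])
        ]
        miss = np.isnan(vals) if np.isnan(missing) else (vals == missing)
        return (
            pd.DataFrame(vals, index=seed_ids, columns=cols),
            pd.Series(~miss.any(axis=1), index=seed_ids, name="has_expression"),
        )
    raise ValueError("expression image must be 3-D or 4-D")


# ---------------------------------------------------------------------------
# averaging and normalisation
# ---------------------------------------------------------------------------

def average_connectivity(
    matrices: dict[str, pd.DataFrame] | list[pd.DataFrame],
    retained_participants=None,
    retained_seeds=None,
) -> pd.DataFrame:
    """Arithmetic mean of raw per-participant count matrices.

    Restricted to ``retained_participants`` and rows ``retained_seeds`` when
    given; averaging happens on raw counts, before any normalisation.
    """
    if isinstance(matrices, dict):
        keys = list(matrices.keys()) if retained_participants is None else list(retained_participants)
        mats = [matrices[k] for k in keys]
    else:
        mats = list(matrices)
        if retained_participants is not None:
            mats = [mats[i] for i in retained_participants]
    if not mats:
        raise ValueError("no participant matrices to average")
    ref = mats[0]
    for m in mats[1:]:
        if m.shape != ref.shape or not m.index.equals(ref.index) or not m.columns.equals(ref.columns):
            raise ValueError("participant matrices do not conform in shape/labels")
    mean = sum(m.to_numpy(dtype=float) for m in mats) / len(mats)
    out = pd.DataFrame(mean, index=ref.index, columns=ref.columns)
    if retained_seeds is not None:
        out = out.loc[retained_seeds]
    return out


def normalise_sigmoid(
    matrix: pd.DataFrame,
    kind: str = "gene",
    on_constant: str = "error",
) -> FeatureMatrix:
    """Scaled sigmoid normalisation of each feature (column) to [0, 1].

    Per feature x: S(x) = 1/(1 + exp(-(x - <x>)/sd(x))) with the sample
    standard deviation, then a linear rescale so the feature attains exactly
    0 and 1. The transform is strictly increasing, so within-feature rank
    order is preserved; relative to plain min-max scaling it compresses
    outliers.

    ``on_constant``: ``"error"`` (default) raises on a zero-variance
    feature; ``"half"`` passes such features through as all-0.5 (logged).
    """
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    const = sd == 0.0
    if const.any():
        names = list(matrix.columns[const])
        if on_constant == "error":
            raise ValueError(f"constant feature(s), sigma_x = 0: {names[:5]}")
        if on_constant != "half":
            raise ValueError("on_constant must be 'error' or 'half'")
        log.warning("passing %d constant feature(s) through as 0.5: %s", const.sum(), names[:5])
    with np.errstate(divide="ignore", invalid="ignore"):
        s = expit((x - mean) / np.where(const, 1.0, sd))
    s[:, const] = 0.5
    smin = s.min(axis=0)
    smax = s.max(axis=0)
    span = np.where(const, 1.0, smax - smin)
    out = (s - smin) / span
    out[:, const] = 0.5
    values = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    params = SigmoidParams(
        feature_mean=pd.Series(mean, index=matrix.columns),
        feature_sd=pd.Series(sd, index=matrix.columns),
        post_rescale_min=pd.Series(smin, index=matrix.columns),
        post_rescale_max=pd.Series(smax, index=matrix.columns),
    )
    return FeatureMatrix(
        values=values,
        feature_kind=pd.Series(kind, index=matrix.columns),
        normalised=True,
        sigmoid=params,
    )


def concatenate(conn: FeatureMatrix, genes: FeatureMatrix | None) -> FeatureMatrix:
    """Column-wise concatenation of the connectivity and gene blocks.

    Both blocks must be normalised and share the same seed order. A missing
    or empty gene block yields a connectivity-only matrix (used by the
    per-modality sensitivity variant).
    """
    if not conn.normalised:
        raise ValueError("connectivity block must be normalised")
    if genes is None or genes.n_features == 0:
        return conn
    if not genes.normalised:
        raise ValueError("gene block must be normalised")
    if not conn.values.index.equals(genes.values.index):
        raise ValueError("seed order differs between connectivity and gene blocks")
    values = pd.concat([conn.values, genes.values], axis=1)
    kind = pd.concat([conn.feature_kind, genes.feature_kind])
    sigmoid = None
    if conn.sigmoid is not None and genes.sigmoid is not None:
        sigmoid = SigmoidParams(
            feature_mean=pd.concat([conn.sigmoid.feature_mean, genes.sigmoid.feature_mean]),
            feature_sd=pd.concat([conn.sigmoid.feature_sd, genes.sigmoid.feature_sd]),
            post_rescale_min=pd.concat(
                [conn.sigmoid.post_rescale_min, genes.sigmoid.post_rescale_min]
            ),
            post_rescale_max=pd.concat(
                [conn.sigmoid.post_rescale_max, genes.sigmoid.post_rescale_max]
            ),
        )
    return FeatureMatrix(values=values, feature_kind=kind, normalised=True, sigmoid=sigmoid)
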
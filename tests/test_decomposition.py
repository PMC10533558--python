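"""Joint PCA, variance accounting, diffusion embedding, sensitivity variants."""

import numpy as np
import pandas as pd
import pytest

from thalamograd.decomposition import (
    VARIANTS,
    cosine_affinity,
    decompose_variant,
    diffusion_embedding,
    joint_pca,
    variance_explained,
    zscore_components,
)
from thalamograd.prep import FeatureMatrix, normalise_sigmoid

from conftest import prepare


def _fm(X, kind="gene"):
    X = pd.DataFrame(X)
    return FeatureMatrix(
        values=X, feature_kind=pd.Series(kind, index=X.columns), normalised=True
    )


class TestJointPca:
    def test_rank_one_identity(self, rank1_matrix):
        fm, g = rank1_matrix
        dec = joint_pca(fm, k=2)
        assert dec.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        r = np.corrcoef(dec.scores.iloc[:, 0], g)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        from thalamograd.benchmarks import pca_oracle_max_error

        res = pca_oracle_max_error(seed=5, n_matrices=50)
        assert res["max_scores_error"] < 1e-10
        assert res["max_lambda_error"] < 1e-10

    def test_variance_conservation(self, rng):
        X = rng.random((12, 7))
        dec = joint_pca(_fm(X), k=7)
        col_var = X.var(axis=0, ddof=1).sum()
        assert dec.variance.sum() == pytest.approx(col_var, abs=1e-8)
        assert dec.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_at_full_rank(self, rng):
        X = rng.random((10, 6))
        dec = joint_pca(_fm(X), k=6)
        recon = dec.scores.to_numpy() @ dec.loadings.to_numpy().T
        Xc = X - X.mean(axis=0)
        assert np.linalg.norm(Xc - recon) < 1e-8

    def test_lambda_non_increasing_and_orthonormal_loadings(self, rng):
        X = rng.random((15, 8))
        dec = joint_pca(_fm(X), k=8)
        assert (np.diff(dec.variance) <= 1e-12).all()
        V = dec.loadings.to_numpy()
        assert np.allclose(V.T @ V, np.eye(8), atol=1e-10)

    def test_feature_reorder_invariance_and_seed_equivariance(self, rng):
        X = rng.random((10, 5))
        dec = joint_pca(_fm(X), k=3)
        perm = rng.permutation(5)
        dec_p = joint_pca(_fm(X[:, perm]), k=3)
        for j in range(3):
            a, b = dec.scores.iloc[:, j], dec_p.scores.iloc[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-10
        sperm = rng.permutation(10)
        dec_s = joint_pca(_fm(X[sperm]), k=3)
        for j in range(3):
            a = dec.scores.iloc[:, j].to_numpy()[sperm]
            b = dec_s.scores.iloc[:, j].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-10

    def test_sign_convention_follows_x(self, rng):
        x = np.linspace(-1, 1, 20)
        X = np.column_stack([-x, -2 * x, rng.normal(0, 0.01, 20)])
        coords = np.column_stack([x, np.zeros(20), np.zeros(20)])
        dec = joint_pca(_fm(X), k=1, coords=coords)
        assert np.corrcoef(dec.scores.iloc[:, 0], x)[0, 1] > 0

    def test_k_exceeding_rank_warns(self, rng):
        X = np.outer(rng.random(8), rng.random(4))
        with pytest.warns(UserWarning, match="rank"):
            dec = joint_pca(_fm(X), k=4)
        assert dec.variance[-1] == pytest.approx(0.0, abs=1e-12)

    def test_unnormalised_matrix_rejected(self, rng):
        fm = _fm(rng.random((5, 3)))
        fm.normalised = False
        with pytest.raises(ValueError):
            joint_pca(fm, k=2)


class TestVarianceExplained:
    def test_direct_substitution(self):
        assert variance_explained(2.0, 5) == pytest.approx(1.0)
        assert variance_explained(0.0, 7) == 0.0

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            variance_explained(1.0, 1)


class TestZscore:
    def test_blockwise_moments_and_idempotence(self, small_prepared):
        joint, *_ = small_prepared
        dec = joint_pca(joint, k=3)
        z = zscore_components(dec)
        for df, kinds in ((z.scores, None), (z.loadings, z.feature_kind)):
            if kinds is None:
                blocks = [df]
            else:
                blocks = [df.loc[kinds == k] for k in kinds.unique()]
            for block in blocks:
                assert np.allclose(block.mean(axis=0), 0, atol=1e-12)
                assert np.allclose(block.std(axis=0, ddof=1), 1, atol=1e-12)
        z2 = zscore_components(z)
        pd.testing.assert_frame_equal(z.scores, z2.scores)
        # rank order within blocks unchanged
        assert (z.scores.rank() == dec.scores.rank()).all().all()

    def test_constant_block_errors(self):
        fm, _ = _fm(np.ones((6, 3)) + np.arange(6)[:, None]), None
        dec = joint_pca(fm, k=1)
        dec.scores.iloc[:, 0] = 1.0
        with pytest.raises(ValueError):
            zscore_components(dec)


class TestDiffusion:
    def test_cosine_affinity_basics(self, rng):
        X = rng.random((8, 5))
        A = cosine_affinity(X)
        assert np.allclose(np.diag(A), 1.0)
        assert np.allclose(A, A.T)
        with pytest.raises(ValueError):
            cosine_affinity(np.vstack([X, np.zeros(5)]))

    def test_duplicate_rows_embed_identically(self, rng):
        X = rng.random((10, 6)) + 0.5
        X[7] = X[2]
        dec = diffusion_embedding(_fm(X), k=3)
        assert np.allclose(dec.scores.iloc[7], dec.scores.iloc[2], atol=1e-8)

    def test_tracks_pc1_on_gradient_data(self, small_prepared):
        joint, *_ = small_prepared
        pca = joint_pca(joint, k=2)
        dm = diffusion_embedding(joint, k=2)
        r = np.corrcoef(pca.scores.iloc[:, 0], dm.scores.iloc[:, 0])[0, 1]
        assert abs(r) > 0.95


class TestVariants:
    def test_identical_modalities_degenerate(self, rng):
        X = normalise_sigmoid(pd.DataFrame(rng.random((15, 6))), kind="cortical_region")
        Y = FeatureMatrix(
            values=X.values.copy(),
            feature_kind=pd.Series("gene", index=X.values.columns),
            normalised=True,
        )
        joint = joint_pca(X, k=2)
        sep = decompose_variant("pca_separate", X, Y, k=2)
        for dec in sep.values():
            r = np.corrcoef(dec.scores.iloc[:, 0], joint.scores.iloc[:, 0])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_averaged_affinity_of_identical_inputs(self, rng):
        X = rng.random((10, 4)) + 0.2
        A = cosine_affinity(X)
        assert np.allclose(0.5 * (A + A), A)

    def test_unknown_variant_errors(self, small_prepared):
        _, conn, genes, *_ = small_prepared
        with pytest.raises(ValueError, match="unknown variant"):
            decompose_variant("varimax", conn, genes)

    def test_all_variants_track_joint_pc1(self, small_prepared, small_dataset):
        joint, conn, genes, coords, keep = small_prepared
        dec = joint_pca(joint, k=5, coords=coords.to_numpy())
        pc1 = dec.scores.iloc[:, 0].to_numpy()
        for name in VARIANTS:
            kw = {}
            if name == "pca_restricted":
                kw["restricted_genes"] = small_dataset.truth.aligned_gene_ids
            res = decompose_variant(
                name, conn, genes, k=5, coords=coords.to_numpy(), **kw
            )
            decs = res.values() if isinstance(res, dict) else [res]
            for d in decs:
                r = abs(np.corrcoef(d.scores.iloc[:, 0], pc1)[0, 1])
                assert r > 0.9, name
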
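"""Matrix assembly: QC rules, expression assignment, sigmoid normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from thalamograd.prep import (
    FeatureMatrix,
    assign_expression,
    average_connectivity,
    concatenate,
    normalise_sigmoid,
    qc_participants,
    qc_seeds,
)


def _inclusion(rows, participants=None, seeds=None):
    arr = np.asarray(rows)
    return pd.DataFrame(
        arr,
        index=participants or [f"p{i}" for i in range(arr.shape[0])],
        columns=seeds or [f"s{i}" for i in range(arr.shape[1])],
    )


class TestQcParticipants:
    def test_identical_vectors_all_retained(self):
        rep = qc_participants(_inclusion([[1, 1, 0, 0]] * 4))
        assert rep["retained"].all()
        assert np.allclose(rep["mean_r"], 1.0)

    def test_anticorrelated_outlier_excluded(self):
        rep = qc_participants(_inclusion([[1, 1, 0, 0]] * 5 + [[0, 0, 1, 1]]))
        assert not rep["retained"].iloc[5]
        assert rep["mean_r"].iloc[5] == pytest.approx(-1.0)
        # the identical five each see four perfect partners and the outlier
        assert np.allclose(rep["mean_r"].iloc[:5], 0.6)

    def test_constant_vector_flagged(self):
        rep = qc_participants(_inclusion([[1, 1, 1, 1], [1, 0, 1, 0], [1, 0, 0, 1]]))
        assert rep.loc[0, "reason"] == "constant_vector"
        assert not rep.loc[0, "retained"]
        assert np.isnan(rep.loc[0, "mean_r"])

    def test_corrupted_participant_detected(self):
        # shared balanced base vector with 5% flips; one participant at 50%
        rng = np.random.default_rng(11)
        base = (np.arange(400) % 2).astype(int)
        rows = []
        for p in range(20):
            rate = 0.5 if p == 19 else 0.05
            flips = rng.random(400) < rate
            rows.append(np.where(flips, 1 - base, base))
        rep = qc_participants(_inclusion(rows), threshold=0.7)
        assert list(rep.loc[~rep["retained"]].index) == [19]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        inc = _inclusion(rng.integers(0, 2, size=(6, 30)))
        rep = qc_participants(inc).set_index("participant")
        perm = rng.permutation(6)
        rep_p = qc_participants(inc.iloc[perm]).set_index("participant")
        pd.testing.assert_frame_equal(rep.sort_index(), rep_p.sort_index())

    def test_needs_two_participants(self):
        with pytest.raises(ValueError):
            qc_participants(_inclusion([[1, 0, 1]]))


class TestQcSeeds:
    def test_strict_presence_boundary(self):
        # 100 participants: seed A present in 86, seed B in exactly 85
        inc = _inclusion(
            np.column_stack(
                [
                    (np.arange(100) < 86).astype(int),
                    (np.arange(100) < 85).astype(int),
                    np.ones(100, dtype=int),
                ]
            ),
            seeds=["a", "b", "c"],
        )
        has_expr = pd.Series([True, True, False], index=["a", "b", "c"])
        kept = qc_seeds(inc, has_expr, presence_fraction=0.85)
        assert list(kept) == ["a"]  # b at exactly 85% dropped; c lacks expression

    def test_full_presence_with_expression_retained(self):
        inc = _inclusion(np.ones((4, 2), dtype=int), seeds=["a", "b"])
        kept = qc_seeds(inc, pd.Series([True, True], index=["a", "b"]))
        assert list(kept) == ["a", "b"]


class TestAssignExpression:
    @pytest.fixture
    def volume(self):
        nib = pytest.importorskip("nibabel")
        data = np.arange(4 * 4 * 4, dtype=float).reshape(4, 4, 4)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])  # voxel size 2 mm, origin 0
        return nib.Nifti1Image(data, affine)

    def test_voxel_centre_and_boundary(self, volume):
        seeds = pd.DataFrame(
            {"seed_id": ["centre", "boundary"], "x": [1.0, 2.0], "y": [1.0, 0.0], "z": [1.0, 0.0]}
        )
        vals, has = assign_expression(volume, seeds)
        assert vals["centre"] == 0.0  # voxel (0,0,0)
        assert vals["boundary"] == 16.0  # floor rule: x=2.0 -> voxel index 1
        assert has.all()

    def test_constant_volume(self, volume):
        nib = pytest.importorskip("nibabel")
        img = nib.Nifti1Image(np.full((4, 4, 4), 7.0), volume.affine)
        seeds = pd.DataFrame({"seed_id": ["a", "b"], "x": [1, 5], "y": [1, 5], "z": [1, 5]})
        vals, _ = assign_expression(img, seeds)
        assert (vals == 7.0).all()

    def test_out_of_bounds_names_seed(self, volume):
        seeds = pd.DataFrame({"seed_id": ["bad"], "x": [99.0], "y": [0.0], "z": [0.0]})
        with pytest.raises(ValueError, match="bad"):
            assign_expression(volume, seeds)

    def test_missing_marks_has_expression(self, volume):
        nib = pytest.importorskip("nibabel")
        data = np.ones((4, 4, 4))
        data[0, 0, 0] = np.nan
        img = nib.Nifti1Image(data, volume.affine)
        seeds = pd.DataFrame({"seed_id": ["m", "ok"], "x": [1.0, 5.0], "y": [1.0, 5.0], "z": [1.0, 5.0]})
        _, has = assign_expression(img, seeds)
        assert not has["m"] and has["ok"]

    def test_4d_volume(self, volume):
        nib = pytest.importorskip("nibabel")
        data = np.stack([np.zeros((4, 4, 4)), np.ones((4, 4, 4))], axis=-1)
        img = nib.Nifti1Image(data, volume.affine)
        seeds = pd.DataFrame({"seed_id": ["a"], "x": [1.0], "y": [1.0], "z": [1.0]})
        vals, _ = assign_expression(img, seeds, gene_names=["g1", "g2"])
        assert vals.loc["a", "g1"] == 0.0 and vals.loc["a", "g2"] == 1.0


class TestSigmoid:
    def test_symmetric_three_points(self):
        out = normalise_sigmoid(pd.DataFrame({"f": [1.0, 2.0, 3.0]}))
        assert np.allclose(out.values["f"], [0.0, 0.5, 1.0])
        assert out.sigmoid.feature_mean["f"] == 2.0
        assert out.sigmoid.feature_sd["f"] == 1.0

    def test_outlier_compression(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 100.0])
        out = normalise_sigmoid(pd.DataFrame({"f": x})).values["f"].to_numpy()
        minmax = (x - x.min()) / (x.max() - x.min())
        # gap between the bulk and the outlier shrinks relative to min-max
        assert (out[4] - out[:4].max()) < (minmax[4] - minmax[:4].max())

    @given(
        st.lists(st.integers(-10**6, 10**6), min_size=3, max_size=30, unique=True)
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_rank_preservation(self, values):
        values = np.asarray(values, dtype=float)
        out = normalise_sigmoid(pd.DataFrame({"f": values})).values["f"].to_numpy()
        assert out.min() == 0.0 and out.max() == 1.0
        rho = spearmanr(values, out).statistic
        assert rho == pytest.approx(1.0)

    def test_constant_feature_error_and_half_mode(self):
        df = pd.DataFrame({"c": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            normalise_sigmoid(df)
        out = normalise_sigmoid(df, on_constant="half")
        assert (out.values["c"] == 0.5).all()


class TestAverageAndConcatenate:
    def test_mean_examples(self):
        a = pd.DataFrame([[2.0]], index=["s"], columns=["r"])
        b = pd.DataFrame([[4.0]], index=["s"], columns=["r"])
        assert average_connectivity([a])["r"]["s"] == 2.0
        assert average_connectivity([a, b])["r"]["s"] == 3.0

    def test_shape_mismatch_errors(self):
        a = pd.DataFrame(np.ones((2, 2)), index=["s1", "s2"], columns=["r1", "r2"])
        b = pd.DataFrame(np.ones((2, 3)), index=["s1", "s2"], columns=["r1", "r2", "r3"])
        with pytest.raises(ValueError):
            average_connectivity([a, b])

    def test_mean_converges_to_kernel(self, rng):
        kernel = np.abs(rng.normal(5, 1, size=(20, 5)))
        mses = []
        for k in (2, 8, 32):
            mats = [
                pd.DataFrame(np.clip(kernel + rng.normal(0, 2, kernel.shape), 0, None))
                for _ in range(k)
            ]
            avg = average_connectivity(mats).to_numpy()
            mses.append(((avg - kernel) ** 2).mean())
        assert mses[0] > mses[1] > mses[2]

    def test_concatenate_dims_and_metadata(self, rng):
        conn = normalise_sigmoid(
            pd.DataFrame(rng.random((10, 3)), columns=["r1", "r2", "r3"]),
            kind="cortical_region",
        )
        genes = normalise_sigmoid(pd.DataFrame(rng.random((10, 4))), kind="gene")
        joint = concatenate(conn, genes)
        assert joint.values.shape == (10, 7)
        assert (joint.feature_kind == "cortical_region").sum() == 3
        assert (joint.feature_kind == "gene").sum() == 4

    def test_concatenate_empty_gene_block(self, rng):
        conn = normalise_sigmoid(pd.DataFrame(rng.random((5, 2))), kind="cortical_region")
        assert concatenate(conn, None) is conn

    def test_seed_order_mismatch_errors(self, rng):
        conn = normalise_sigmoid(
            pd.DataFrame(rng.random((5, 2)), index=list("abcde")), kind="cortical_region"
        )
        genes = normalise_sigmoid(
            pd.DataFrame(rng.random((5, 2)), index=list("abced")), kind="gene"
        )
        with pytest.raises(ValueError, match="seed order"):
            concatenate(conn, genes)
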
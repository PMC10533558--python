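"""Generator: lattices, Gaussian fields, dataset structure and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist, pdist

from thalamograd.decomposition import joint_pca
from thalamograd.synthetic import (
    BoxMask,
    EllipsoidMask,
    MarkerSetSpec,
    SyntheticConfig,
    empirical_variogram_oracle,
    generate_autocorrelated_field,
    generate_dataset,
    generate_seed_lattice,
)

from conftest import prepare, small_config


class TestSeedLattice:
    def test_unit_box_half_offset_counts(self):
        # half-spacing anchoring: [0,1] box at spacing 0.5 -> 2 points/axis
        lat = generate_seed_lattice(BoxMask((0, 0, 0), (1, 1, 1)), 0.5, offset="half")
        assert len(lat) == 8
        assert sorted(set(lat["x"])) == [0.25, 0.75]

    def test_points_inside_and_spacing(self):
        lat = generate_seed_lattice(EllipsoidMask((10, 8, 6)), 2.0)
        pts = lat[["x", "y", "z"]].to_numpy()
        assert EllipsoidMask((10, 8, 6)).contains(pts).all()
        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        assert np.allclose(d.min(axis=1).min(), 2.0)

    def test_default_ellipsoid_matches_study_scale(self):
        lat = generate_seed_lattice(EllipsoidMask(), 1.75)
        assert 1500 <= len(lat) <= 2100  # ~1800 seeds at 1.75 mm

    def test_degenerate_mask_errors(self):
        with pytest.raises(ValueError):
            generate_seed_lattice(EllipsoidMask((0.1, 0.1, 0.1)), 1.75)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_spacing_errors(self, bad):
        with pytest.raises(ValueError):
            generate_seed_lattice(EllipsoidMask(), bad)


class TestAutocorrelatedField:
    @pytest.fixture(scope="class")
    def coords(self):
        lat = generate_seed_lattice(EllipsoidMask((8, 6, 5)), 2.0)
        return lat[["x", "y", "z"]].to_numpy()

    def test_white_noise_limit(self, coords, rng):
        # length scale far below lattice spacing: fields are i.i.d.
        fields = generate_autocorrelated_field(coords, 1e-3, rng, size=200)
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        r = np.corrcoef(fields[:, i], fields[:, j])[0, 1]
        assert abs(r) < 0.2

    def test_smooth_limit(self, coords, rng):
        fields = generate_autocorrelated_field(coords, 1e4, rng, size=50)
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        assert np.corrcoef(fields[:, i], fields[:, j])[0, 1] > 0.9

    def test_variogram_matches_exponential_model(self, coords, rng):
        ls = 5.0
        fields = generate_autocorrelated_field(coords, ls, rng, size=100)
        d = pdist(coords)
        iu = np.triu_indices(len(coords), k=1)
        sq = ((fields[:, iu[0]] - fields[:, iu[1]]) ** 2).mean(axis=0)
        bins = np.linspace(0, np.percentile(d, 70), 10)
        which = np.digitize(d, bins) - 1
        for b in range(9):
            mask = which == b
            if mask.sum() < 30:
                continue
            expected = empirical_variogram_oracle(d[mask].mean(), ls)
            assert sq[mask].mean() == pytest.approx(expected, rel=0.2)

    def test_invalid_inputs(self, coords, rng):
        with pytest.raises(ValueError):
            generate_autocorrelated_field(coords, 0.0, rng)
        bad = coords.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            generate_autocorrelated_field(bad, 1.0, rng)


class TestDataset:
    def test_determinism_and_seed_sensitivity(self):
        cfg = small_config()
        a = generate_dataset(cfg, rng_seed=7)
        b = generate_dataset(cfg, rng_seed=7)
        c = generate_dataset(cfg, rng_seed=8)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(
            a.participant_connectivity[0], b.participant_connectivity[0]
        )
        pd.testing.assert_frame_equal(a.dev_samples, b.dev_samples)
        assert not np.allclose(a.expression, c.expression)

    def test_ground_truth_invariants(self, small_dataset):
        t = small_dataset.truth
        assert not set(t.aligned_positive) & set(t.aligned_negative)
        g = t.gradient_values.to_numpy()
        for col in t.secondary_gradients:
            r = np.corrcoef(g, t.secondary_gradients[col])[0, 1]
            assert abs(r) < 1e-10

    def test_matrices_finite_and_nonnegative(self, small_dataset):
        assert np.isfinite(small_dataset.expression.to_numpy()).all()
        for m in small_dataset.participant_connectivity:
            assert (m.to_numpy() >= 0).all()

    def test_zero_noise_recovers_gradient_exactly(self):
        # noiseless planted model: every aligned gene is exactly +/-g, so
        # PCA on the raw gene block returns scores proportional to g
        from thalamograd.prep import FeatureMatrix

        cfg = small_config(aligned_fraction=1.0, gene_noise_sd=1e-15)
        ds = generate_dataset(cfg, rng_seed=0)
        fm = FeatureMatrix(
            values=ds.expression,
            feature_kind=pd.Series("gene", index=ds.expression.columns),
            normalised=True,
        )
        dec = joint_pca(fm, k=2)
        g = ds.truth.gradient_values.to_numpy()
        r = np.corrcoef(dec.scores.iloc[:, 0], g)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert dec.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_noise_full_pipeline_near_exact(self):
        # through sigmoid normalisation and the topographic connectivity
        # kernel (whose bump-shaped columns are non-monotone in g, a mild
        # horseshoe effect) the recovery is distorted but still strong
        cfg = small_config(
            gene_noise_sd=1e-12,
            conn_noise_sd=0.0,
            aligned_fraction=1.0,
            inclusion_flip_rate=0.0,
            base_exclusion_fraction=0.1,
        )
        ds = generate_dataset(cfg, rng_seed=0)
        joint, _, _, coords, keep = prepare(ds)
        dec = joint_pca(joint, k=3, coords=coords.to_numpy())
        g = ds.truth.gradient_values.loc[keep].to_numpy()
        assert abs(np.corrcoef(dec.scores.iloc[:, 0], g)[0, 1]) > 0.95

    def test_marker_overlap_rates(self):
        specs = {"m": MarkerSetSpec(size=40, frac_positive=0.5, frac_negative=0.25)}
        cfg = SyntheticConfig(marker_specs=specs)
        ds = generate_dataset(cfg, rng_seed=3)
        members = ds.marker_sets["m"]
        n_pos = len(members & set(ds.truth.aligned_positive))
        n_neg = len(members & set(ds.truth.aligned_negative))
        assert n_pos == 20 and n_neg == 10  # drawn without replacement, exact

    def test_inconsistent_marker_spec_errors(self):
        cfg = small_config(marker_specs={"m": MarkerSetSpec(size=60, frac_positive=0.9)})
        with pytest.raises(ValueError):
            generate_dataset(cfg, rng_seed=0)

    def test_recovery_degrades_with_noise(self):
        medians = []
        for noise in (0.25, 1.0, 4.0):
            rs = []
            for rep in range(5):
                cfg = small_config(gene_noise_sd=noise, conn_noise_sd=30.0 * noise)
                ds = generate_dataset(cfg, rng_seed=100 + rep)
                joint, _, _, coords, keep = prepare(ds)
                dec = joint_pca(joint, k=2, coords=coords.to_numpy())
                g = ds.truth.gradient_values.loc[keep].to_numpy()
                rs.append(abs(np.corrcoef(dec.scores.iloc[:, 0], g)[0, 1]))
            medians.append(np.median(rs))
        assert medians[0] > medians[1] > medians[2]
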
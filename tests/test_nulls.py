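"""Spatial nulls: rotations, spin assignment, variogram surrogates, p-values."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from thalamograd.nulls import (
    VariogramGeometry,
    build_spin_ensemble,
    empirical_variogram,
    random_rotation,
    spin_assignment,
    spin_pvalue,
    variogram_surrogates,
)
from thalamograd.synthetic import (
    EllipsoidMask,
    fibonacci_sphere,
    generate_autocorrelated_field,
    generate_seed_lattice,
)


@pytest.fixture(scope="module")
def seed_coords():
    lat = generate_seed_lattice(EllipsoidMask((12, 9, 7)), 2.5)
    return lat[["x", "y", "z"]].to_numpy()


class TestRotations:
    def test_group_membership(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            R = random_rotation(rng)
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_preserves_length(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(100, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        R = random_rotation(rng)
        assert np.allclose(np.linalg.norm(v @ R.T, axis=1), 1.0, atol=1e-12)

    def test_angle_density_uniform_so3(self):
        # rotation angle of a uniform SO(3) draw has density (1 - cos t)/pi
        rng = np.random.default_rng(2)
        angles = np.array(
            [
                np.arccos(np.clip((np.trace(random_rotation(rng)) - 1) / 2, -1, 1))
                for _ in range(2000)
            ]
        )
        cdf = lambda t: (t - np.sin(t)) / np.pi
        stat = stats.ks_1samp(angles, cdf)
        assert stat.pvalue > 0.01


def _brute_force_assignment(original, rotated):
    """Literal re-implementation of the greedy rule with explicit set logic."""
    D = cdist(rotated, original)
    m = len(original)
    rot_left = list(range(m))
    orig_left = list(range(m))
    perm = {}
    while rot_left:
        means = [(np.mean([D[r, o] for o in orig_left]), r) for r in rot_left]
        _, r_star = min(means)
        dists = [(D[r_star, o], o) for o in orig_left]
        dmax = max(d for d, _ in dists)
        o_star = min(o for d, o in dists if d == dmax)
        perm[o_star] = r_star
        rot_left.remove(r_star)
        orig_left.remove(o_star)
    return np.array([perm[o] for o in range(m)])


class TestSpinAssignment:
    def test_matches_brute_force_trace(self):
        pts = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        R = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])  # 90 deg about z
        rotated = pts @ R.T
        assert np.array_equal(
            spin_assignment(pts, rotated), _brute_force_assignment(pts, rotated)
        )

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(3)
        pts = fibonacci_sphere(12)
        for _ in range(5):
            rot = pts @ random_rotation(rng).T
            assert np.array_equal(
                spin_assignment(pts, rot), _brute_force_assignment(pts, rot)
            )

    def test_bijection_and_determinism(self):
        rng = np.random.default_rng(4)
        pts = fibonacci_sphere(40)
        rot = pts @ random_rotation(rng).T
        p1 = spin_assignment(pts, rot)
        p2 = spin_assignment(pts, rot)
        assert np.array_equal(p1, p2)
        assert sorted(p1) == list(range(40))

    def test_identity_rotation_still_bijection(self):
        pts = fibonacci_sphere(15)
        p = spin_assignment(pts, pts.copy())
        assert sorted(p) == list(range(15))


class TestSpinEnsemble:
    def test_reproducible_and_multiset_preserving(self):
        cent = fibonacci_sphere(30)
        a = build_spin_ensemble(cent, n_perm=20, rng=7)
        b = build_spin_ensemble(cent, n_perm=20, rng=7)
        assert np.array_equal(a.permutations, b.permutations)
        vals = np.random.default_rng(0).normal(size=30)
        for row in a.surrogates(vals):
            assert np.allclose(np.sort(row), np.sort(vals))

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            build_spin_ensemble(fibonacci_sphere(10), n_perm=0)


class TestVariogramSurrogates:
    def test_surrogates_match_base_variogram(self, seed_coords):
        rng = np.random.default_rng(8)
        base = generate_autocorrelated_field(seed_coords, 8.0, rng)
        ens = variogram_surrogates(base, seed_coords, n_surr=100, rng=rng)
        geom = VariogramGeometry(seed_coords)
        g_emp = geom.variogram(base)
        g_sur = geom.variogram(ens.surrogate_values).mean(axis=0)
        # average surrogate variogram tracks the empirical one
        assert np.abs(g_sur - g_emp).mean() < 0.3 * g_emp.mean()
        assert ens.fit_sse is not None and np.isfinite(ens.fit_sse).all()

    def test_white_noise_base_stays_flat(self, seed_coords):
        rng = np.random.default_rng(9)
        base = rng.normal(size=len(seed_coords))
        ens = variogram_surrogates(base, seed_coords, n_surr=100, rng=rng)
        geom = VariogramGeometry(seed_coords)
        g_sur = geom.variogram(ens.surrogate_values).mean(axis=0)
        # flat variogram at the white-noise level var(base)
        assert np.abs(g_sur - base.var()).max() < 0.2 * base.var()

    def test_permutation_actually_applied(self, seed_coords):
        rng = np.random.default_rng(10)
        base = generate_autocorrelated_field(seed_coords, 8.0, rng)
        ens = variogram_surrogates(base, seed_coords, n_surr=20, rng=rng)
        assert not any(np.allclose(s, base) for s in ens.surrogate_values)

    def test_resample_mode_preserves_multiset(self, seed_coords):
        rng = np.random.default_rng(11)
        base = generate_autocorrelated_field(seed_coords, 8.0, rng)
        ens = variogram_surrogates(
            base, seed_coords, n_surr=10, rng=rng, resample=True
        )
        for s in ens.surrogate_values:
            assert np.allclose(np.sort(s), np.sort(base))

    def test_mean_and_variance_roughly_preserved(self, seed_coords):
        rng = np.random.default_rng(12)
        base = 5.0 + 2.0 * generate_autocorrelated_field(seed_coords, 8.0, rng)
        ens = variogram_surrogates(base, seed_coords, n_surr=50, rng=rng)
        assert np.allclose(ens.surrogate_values.mean(axis=1), base.mean(), atol=1e-9)
        sds = ens.surrogate_values.std(axis=1)
        assert 0.5 * base.std() < np.median(sds) < 2.0 * base.std()

    def test_too_few_seeds_errors(self):
        with pytest.raises(ValueError):
            VariogramGeometry(np.zeros((2, 3)), ks=[10])


class TestSpinPvalue:
    @pytest.fixture(scope="class")
    def sphere_setup(self):
        cent = fibonacci_sphere(60)
        ens = build_spin_ensemble(cent, n_perm=199, rng=0)
        rng = np.random.default_rng(1)
        f = generate_autocorrelated_field(cent, 60.0, rng, size=4)
        return cent, ens, f

    def test_identical_maps_minimal_p(self, sphere_setup):
        _, ens, f = sphere_setup
        res = spin_pvalue(f[0], f[0].copy(), ens, ens)
        assert res.r_empirical == pytest.approx(1.0)
        assert res.p_spin <= 2.0 / 200.0

    def test_symmetry_under_map_exchange(self, sphere_setup):
        _, ens, f = sphere_setup
        p_ab = spin_pvalue(f[0], f[1], ens, ens).p_spin
        p_ba = spin_pvalue(f[1], f[0], ens, ens).p_spin
        assert p_ab == pytest.approx(p_ba)

    def test_p_in_unit_interval_and_nulls_bounded(self, sphere_setup):
        _, ens, f = sphere_setup
        res = spin_pvalue(f[2], f[3], ens)
        assert 0 < res.p_spin <= 1
        assert np.all(np.abs(res.null_rs) <= 1 + 1e-12)

    def test_constant_map_errors(self, sphere_setup):
        _, ens, f = sphere_setup
        with pytest.raises(ValueError):
            spin_pvalue(np.ones(60), f[0], ens)


def test_empirical_variogram_wrapper(seed_coords):
    rng = np.random.default_rng(2)
    base = generate_autocorrelated_field(seed_coords, 8.0, rng)
    centers, gamma = empirical_variogram(base, seed_coords)
    assert len(centers) == len(gamma) <= 25
    assert (np.diff(centers) > 0).all()
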
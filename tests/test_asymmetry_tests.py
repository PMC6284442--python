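import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapesym import (SyntheticConfig, compare_subspaces, generate_population,
                      location_d, mirror_sagittal, perm_p_value,
                      permutation_test, principal_angles, projection_metric,
                      projection_metric_set, scale_d, top_k_basis)


def rotation_2d_embedded(alpha, dim=6):
    """1-D basis in `dim` dims rotated by alpha inside the (e1, e2) plane."""
    v = np.zeros(dim)
    v[0], v[1] = np.cos(alpha), np.sin(alpha)
    return v[:, None]


def side_matrices(cfg):
    pairs, _ = generate_population(cfg)
    L = np.stack([p[0].points.reshape(-1) for p in pairs])
    R = np.stack([mirror_sagittal(p[1].points).reshape(-1) for p in pairs])
    return L, R


class TestLocationD:
    def test_identical_groups(self):
        g = np.random.default_rng(0).normal(size=(6, 4))
        assert location_d(g, g.copy()) == 0.0

    def test_closed_form(self):
        assert location_d([[0.0, 0.0, 0.0]], [[3.0, 4.0, 0.0]]) == 5.0

    def test_brute_force_oracle_4x2(self):
        left = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]]
        right = [[0.0, 1.0], [2.0, 2.0], [4.0, 3.0], [6.0, 4.0]]
        # element-wise hand computation, no vectorised shortcuts
        ml = [sum(r[j] for r in left) / 4 for j in range(2)]
        mr = [sum(r[j] for r in right) / 4 for j in range(2)]
        expected = (sum((a - b) ** 2 for a, b in zip(ml, mr))) ** 0.5
        assert location_d(left, right) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            location_d(np.zeros((2, 3)), np.zeros((2, 4)))


class TestScaleD:
    def test_identical_groups(self):
        g = np.random.default_rng(1).normal(size=(5, 3))
        assert scale_d(g, g.copy()) == 0.0

    def test_closed_form_1d(self):
        assert scale_d([[-1.0], [1.0]], [[-2.0], [2.0]]) == pytest.approx(1.0)

    def test_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        left = rng.normal(size=(9, 5))
        right = 2.0 * rng.normal(size=(7, 5))
        def avg_residual(g):
            mean = [sum(row[j] for row in g) / len(g) for j in range(5)]
            dists = [sum((row[j] - mean[j]) ** 2 for j in range(5)) ** 0.5
                     for row in g]
            return sum(dists) / len(g)
        expected = abs(avg_residual(left.tolist()) - avg_residual(right.tolist()))
        assert scale_d(left, right) == pytest.approx(expected, abs=1e-12)


class TestPrincipalAngles:
    def test_identical_bases(self):
        b = top_k_basis(np.random.default_rng(3).normal(size=(10, 6)), 3)
        np.testing.assert_allclose(principal_angles(b, b), 0.0, atol=1e-7)

    def test_orthogonal_1d_bases(self):
        a = np.array([[1.0], [0.0]])
        b = np.array([[0.0], [1.0]])
        assert principal_angles(a, b)[0] == pytest.approx(np.pi / 2)

    def test_planted_rotation(self):
        for alpha in (0.1, 0.7, 1.2):
            theta = principal_angles(rotation_2d_embedded(0.0),
                                     rotation_2d_embedded(alpha))
            assert abs(theta[0] - alpha) < 1e-10

    def test_ascending_order(self):
        rng = np.random.default_rng(4)
        a = top_k_basis(rng.normal(size=(30, 10)), 4)
        b = top_k_basis(rng.normal(size=(30, 10)), 4)
        theta = principal_angles(a, b)
        assert np.all(np.diff(theta) >= 0)
        assert np.all((theta >= 0) & (theta <= np.pi / 2 + 1e-12))

    def test_non_orthonormal_rejected(self):
        bad = np.array([[1.0, 0.5], [0.0, 1.0], [0.0, 0.0]])
        good = np.eye(3)[:, :2]
        with pytest.raises(ValueError, match="orthonormal"):
            principal_angles(bad, good)


class TestProjectionMetric:
    def test_zero_angles(self):
        theta = np.zeros(4)
        assert all(projection_metric(theta, j) == 0.0 for j in range(1, 5))

    def test_right_angle_j1(self):
        assert projection_metric(np.array([np.pi / 2]), 1) == pytest.approx(1.0)

    def test_mixed_angles_j2(self):
        theta = np.array([0.0, np.pi / 2])
        assert projection_metric(theta, 2) == pytest.approx(1.0)

    def test_squared_form_option(self):
        theta = np.array([0.3, 1.0])
        rooted = projection_metric(theta, 2)
        assert projection_metric(theta, 2, squared=True) == pytest.approx(rooted ** 2)

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="j must be"):
            projection_metric(np.array([0.1]), 2)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, np.pi / 2), min_size=1, max_size=8))
    def test_bounds_and_monotonicity(self, angles):
        theta = np.sort(np.asarray(angles))
        dset = projection_metric_set(theta)
        for j in range(1, len(theta) + 1):
            assert 0.0 <= dset[j - 1] <= np.sqrt(j) + 1e-12
        assert np.all(np.diff(dset) >= -1e-12)

    def test_symmetry_and_identity(self):
        rng = np.random.default_rng(5)
        a = top_k_basis(rng.normal(size=(20, 8)), 3)
        b = top_k_basis(rng.normal(size=(20, 8)), 3)
        dab = projection_metric_set(principal_angles(a, b))
        dba = projection_metric_set(principal_angles(b, a))
        np.testing.assert_allclose(dab, dba, atol=1e-10)
        np.testing.assert_allclose(
            projection_metric_set(principal_angles(a, a)), 0.0, atol=1e-7)

    def test_shared_leading_subspace(self):
        # groups differing only beyond rank r: D_j ~ 0 for j <= r
        rng = np.random.default_rng(6)
        d, r = 12, 2
        shared, _ = np.linalg.qr(rng.normal(size=(d, r)))
        extra = np.linalg.qr(rng.normal(size=(d, d)))[0]
        # pick two different directions orthogonal to the shared plane
        proj = np.eye(d) - shared @ shared.T
        ua, _ = np.linalg.qr(proj @ extra[:, :1])
        ub, _ = np.linalg.qr(proj @ extra[:, 1:2])
        basis_a = np.column_stack([shared, ua[:, 0]])
        basis_b = np.column_stack([shared, ub[:, 0]])
        dset = compare_subspaces(basis_a, basis_b).d_k_set
        np.testing.assert_allclose(dset[:r], 0.0, atol=1e-7)
        assert dset[r] > 0.1


class TestPermPValue:
    def test_eq1_direct(self):
        assert perm_p_value(500, 10_000) == 0.05

    def test_add_one_variant(self):
        assert perm_p_value(0, 100, add_one=True) == pytest.approx(1 / 101)

    def test_bounds(self):
        with pytest.raises(ValueError):
            perm_p_value(11, 10)


@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(7)
    left = rng.normal(size=(12, 4))
    right = rng.normal(size=(12, 4)) + 50.0  # huge location shift
    return left, right


class TestPermutationTest:

    def test_p_zero_at_boundary(self, separated):
        left, right = separated
        res = permutation_test("location", left, right, n_perm=300, seed=1)
        assert np.all(res.d_perm < res.d_observed)
        assert res.p_perm == 0.0

    def test_add_one_at_boundary(self, separated):
        left, right = separated
        res = permutation_test("location", left, right, n_perm=300, seed=1,
                               add_one=True)
        assert res.p_perm == pytest.approx(1 / 301)

    def test_p_equals_exceed_over_nperm_exactly(self):
        rng = np.random.default_rng(8)
        left, right = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        for stat in ("location", "scale"):
            res = permutation_test(stat, left, right, n_perm=500, seed=2)
            assert res.p_perm == res.n_exceed / res.n_perm

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(9)
        left, right = rng.normal(size=(8, 5)), rng.normal(size=(8, 5))
        a = permutation_test("scale", left, right, n_perm=200, seed=3)
        b = permutation_test("scale", left, right, n_perm=200, seed=3)
        np.testing.assert_array_equal(a.d_perm, b.d_perm)

    def test_orientation_returns_vector(self):
        rng = np.random.default_rng(10)
        left, right = rng.normal(size=(15, 20)), rng.normal(size=(15, 20))
        res = permutation_test("orientation", left, right, k=3, n_perm=150,
                               seed=4)
        assert res.d_observed.shape == (3,)
        assert res.p_perm.shape == (3,)
        assert np.all(np.diff(res.d_observed) >= -1e-12)

    def test_orientation_requires_k(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="requires k"):
            permutation_test("orientation", rng.normal(size=(8, 5)),
                             rng.normal(size=(8, 5)), n_perm=150)

    def test_side_swap_requires_pairing(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="paired"):
            permutation_test("location", rng.normal(size=(8, 3)),
                             rng.normal(size=(9, 3)), n_perm=150)

    def test_free_scheme_allows_unequal_groups(self):
        rng = np.random.default_rng(13)
        res = permutation_test("location", rng.normal(size=(8, 3)),
                               rng.normal(size=(5, 3)), n_perm=150,
                               scheme="free", seed=5)
        assert 0.0 <= res.p_perm <= 1.0

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(14)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_test("location", rng.normal(size=(6, 3)),
                             rng.normal(size=(6, 3)), n_perm=50, seed=6)

    def test_unknown_statistic(self):
        with pytest.raises(ValueError, match="statistic"):
            permutation_test("median", np.zeros((4, 2)), np.zeros((4, 2)),
                             n_perm=150)


class TestCalibrationAndPower:
    """Scaled-down versions of the replicate simulations; the full-size runs
    live in the acceptance suite."""

    def null_config(self, seed):
        return SyntheticConfig(n_subjects=15, n_points=20, n_modes_true=3,
                               eigenvalues_true=(9.0, 4.0, 1.0),
                               icc_per_mode=(0.7, 0.5, 0.3),
                               noise_sd=0.05, seed=seed)

    def test_null_p_values_roughly_uniform(self):
        ps = {"location": [], "scale": []}
        for rep in range(60):
            L, R = side_matrices(self.null_config(3000 + rep))
            for stat in ps:
                res = permutation_test(stat, L, R, n_perm=200, seed=rep)
                ps[stat].append(res.p_perm)
        for stat, values in ps.items():
            values = np.asarray(values)
            # 60 replicates: binomial(60, q) 99% envelopes around each quantile
            assert abs((values <= 0.5).mean() - 0.5) < 0.20, stat
            assert (values <= 0.1).mean() < 0.30, stat

    def test_location_power_monotone_in_offset(self):
        power = []
        for offset in (0.0, 1.0, 3.0):
            rejections = 0
            for rep in range(25):
                cfg = SyntheticConfig(
                    n_subjects=15, n_points=20, n_modes_true=3,
                    eigenvalues_true=(9.0, 4.0, 1.0),
                    icc_per_mode=(0.7, 0.5, 0.3), noise_sd=0.05,
                    directional_offset=(offset, 0.0, 0.0), seed=4000 + rep)
                L, R = side_matrices(cfg)
                res = permutation_test("location", L, R, n_perm=200, seed=rep)
                rejections += res.p_perm < 0.05
            power.append(rejections / 25)
        assert power[0] <= power[1] + 0.1 <= power[2] + 0.2
        assert power[2] > power[0]
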
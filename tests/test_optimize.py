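import numpy as np
import pytest

from hicdyn.mapping import forward_map, laplacian_from_k
from hicdyn.optimize import (
    OptimizationConfig,
    contact_decay,
    cost,
    distance_corrected_cc,
    gradient,
    optimize,
    pearson_cc,
    project_valid,
)
from hicdyn.synthetic import make_noisy_contacts, make_rouse_chain, random_valid_k


class TestCost:
    def test_identical_is_zero(self, tad_contacts):
        assert cost(tad_contacts, tad_contacts) == 0.0

    def test_single_pair_arithmetic(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        B = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert cost(A, B) == pytest.approx(0.005, abs=1e-15)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(1)
        A, B = rng.random((10, 10)), rng.random((10, 10))
        A, B = 0.5 * (A + A.T), 0.5 * (B + B.T)
        brute = 0.5 * sum(
            (A[i, j] - B[i, j]) ** 2
            for i in range(10) for j in range(i + 1, 10)
        )
        assert cost(A, B) == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cost(np.eye(3), np.eye(4))


class TestGradient:
    def test_zero_at_perfect_fit(self, small_random_k):
        g = gradient(small_random_k, forward_map(small_random_k))
        np.testing.assert_allclose(g, 0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_central_finite_differences(self, seed):
        n = 5 + seed
        K = random_valid_k(n, seed=seed)
        C_in = forward_map(random_valid_k(n, seed=seed + 100))
        g = gradient(K, C_in)
        h = 1e-6
        for m in range(n):
            for p in range(m + 1, n):
                Kp, Km = K.copy(), K.copy()
                Kp[m, p] = Kp[p, m] = K[m, p] + h
                Km[m, p] = Km[p, m] = K[m, p] - h
                fd = (cost(forward_map(Kp), C_in)
                      - cost(forward_map(Km), C_in)) / (2 * h)
                assert abs(fd - g[m, p]) <= 1e-4 * max(abs(fd), 1e-8)

    def test_symmetric_zero_diagonal(self, small_random_k, tad_contacts):
        g = gradient(small_random_k, forward_map(random_valid_k(10, seed=9)))
        np.testing.assert_allclose(g, g.T, atol=1e-12)
        assert (np.diag(g) == 0).all()


class TestProjectValid:
    def test_identity_on_valid(self, small_random_k):
        np.testing.assert_allclose(project_valid(small_random_k),
                                   small_random_k, atol=1e-12)

    def test_floors_negative_eigenvalue(self):
        # build K whose Laplacian has a -0.1 eigenvalue by construction
        rng = np.random.default_rng(5)
        n = 6
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        u = np.ones(n) / np.sqrt(n)
        # orthonormal basis with the uniform vector as first column
        basis = np.linalg.qr(
            np.column_stack([u, rng.standard_normal((n, n - 1))])
        )[0]
        lam = np.array([0.0, -0.1, 0.5, 1.0, 1.5, 2.0])
        L = (basis * lam) @ basis.T
        K = -L.copy()
        np.fill_diagonal(K, 0.0)
        delta = 1e-8
        K_proj = project_valid(K, delta)
        lam_proj = np.linalg.eigvalsh(laplacian_from_k(K_proj))
        nonzero = np.sort(lam_proj)[1:]
        assert nonzero.min() == pytest.approx(delta, rel=1e-3)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        K = rng.standard_normal((7, 7))
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 0.0)
        once = project_valid(K)
        np.testing.assert_allclose(project_valid(once), once, atol=1e-9)


class TestOptimize:
    def test_inverse_init_immediate_recovery(self, tad_k, tad_contacts):
        res = optimize(tad_contacts,
                       OptimizationConfig(init_mode="inverse_transform"))
        assert res.cost_history[min(2, len(res.cost_history) - 1)] < 1e-16
        assert np.abs(res.K_opt - tad_k).max() < 1e-6

    def test_backbone_init_recovery(self, tad_contacts):
        res = optimize(tad_contacts,
                       OptimizationConfig(init_mode="backbone",
                                          backbone_k0=0.5,
                                          max_iterations=5000))
        assert res.pcc >= 0.999
        assert res.distance_corrected_pcc >= 0.99

    def test_noisy_input_monotone_and_converged(self, tad_k):
        C = make_noisy_contacts(tad_k, "lognormal", 0.1, seed=11)
        res = optimize(C, OptimizationConfig(max_iterations=800))
        assert np.all(np.diff(res.cost_history) <= 0)
        assert res.converged or res.n_iterations == 800

    def test_deterministic(self, tad_k):
        C = make_noisy_contacts(tad_k, "lognormal", 0.1, seed=2)
        cfg = OptimizationConfig(max_iterations=50)
        r1, r2 = optimize(C, cfg), optimize(C, cfg)
        np.testing.assert_array_equal(r1.cost_history, r2.cost_history)
        np.testing.assert_array_equal(r1.K_opt, r2.K_opt)

    def test_c_opt_is_forward_map_of_k_opt(self, tad_k):
        C = make_noisy_contacts(tad_k, "lognormal", 0.1, seed=4)
        res = optimize(C, OptimizationConfig(max_iterations=30))
        np.testing.assert_allclose(res.C_opt, forward_map(res.K_opt),
                                   atol=1e-10)


class TestSimilarityMetrics:
    def test_pcc_self_is_one(self, tad_contacts):
        assert pearson_cc(tad_contacts, tad_contacts) == pytest.approx(1.0)

    def test_pcc_negated(self, tad_contacts):
        assert pearson_cc(tad_contacts, -tad_contacts) == pytest.approx(-1.0)

    def test_pcc_textbook_formula(self):
        rng = np.random.default_rng(3)
        A = rng.random((6, 6)); A = 0.5 * (A + A.T)
        B = rng.random((6, 6)); B = 0.5 * (B + B.T)
        iu = np.triu_indices(6, 1)
        a, b = A[iu], B[iu]
        r = ((a - a.mean()) * (b - b.mean())).sum() / (
            np.sqrt(((a - a.mean()) ** 2).sum())
            * np.sqrt(((b - b.mean()) ** 2).sum())
        )
        assert pearson_cc(A, B) == pytest.approx(r, abs=1e-12)

    def test_pcc_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_cc(np.ones((3, 3)), np.eye(3))

    def test_dcc_self_is_one(self, tad_contacts):
        assert distance_corrected_cc(tad_contacts, tad_contacts) == (
            pytest.approx(1.0)
        )

    def test_dcc_per_stratum_shift_invariance(self, tad_contacts):
        # adding a constant per diagonal cannot change any stratum r_s
        B = tad_contacts.copy()
        n = B.shape[0]
        for s in range(1, n):
            idx = np.arange(n - s)
            B[idx, idx + s] += 0.01 * s
            B[idx + s, idx] += 0.01 * s
        assert distance_corrected_cc(tad_contacts, B) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_dcc_matches_bruteforce_stratum_loop(self):
        rng = np.random.default_rng(12)
        A = rng.random((5, 5)); A = 0.5 * (A + A.T)
        B = rng.random((5, 5)); B = 0.5 * (B + B.T)
        num = den = 0.0
        for s in range(1, 5):
            a, b = np.diagonal(A, s), np.diagonal(B, s)
            if a.size < 2 or a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            w = a.size * a.std() * b.std()
            num += w * r
            den += w
        assert distance_corrected_cc(A, B) == pytest.approx(num / den,
                                                            abs=1e-12)

    def test_dcc_all_strata_degenerate_raises(self):
        C = forward_map(make_rouse_chain(6, 1.0))
        with pytest.raises(ValueError, match="degenerate"):
            distance_corrected_cc(C, C)


class TestContactDecay:
    def test_all_ones(self):
        s, p = contact_decay(np.ones((5, 5)))
        np.testing.assert_array_equal(p, 1.0)

    def test_dimer_single_pair(self, dimer_k):
        s, p = contact_decay(forward_map(dimer_k))
        assert p[0] == pytest.approx(2 ** -1.5)

    def test_rouse_chain_decreasing(self):
        C = forward_map(make_rouse_chain(40, 1.0))
        _, p = contact_decay(C)
        assert np.all(np.diff(p) < 0)

    def test_null_bins_excluded(self):
        C = np.ones((4, 4))
        C[2, :] = C[:, 2] = 0.0
        valid = np.array([True, True, False, True])
        _, p = contact_decay(C, valid)
        np.testing.assert_array_equal(p[np.isfinite(p)], 1.0)
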
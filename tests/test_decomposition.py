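"""Factorization solvers: oracles, constraints, descent, determinism."""

import itertools

import numpy as np
import pytest

from sparsesynergies import (
    L1SparseCoding,
    StructuredSparseDictionary,
    StructuredSparsePCA,
    SynergyPCA,
    build_joint_groups,
    encode,
    fit_l1,
    fit_pca,
    fit_srssd,
    fit_sspca,
)
from sparsesynergies.decomposition import _data_term, encode_l1


def _svd_objective(X, r):
    """Objective value 1/(2np)||X - X_r||_F^2 of the rank-r truncated SVD."""
    n, p = X.shape
    s = np.linalg.svd(X, compute_uv=False)
    return float(np.sum(s[r:] ** 2)) / (2 * n * p)


class TestSynergyPCA:
    def test_full_rank_reconstruction_error_zero(self, rng):
        X = rng.standard_normal((12, 6))
        est = SynergyPCA(n_atoms=6).fit(X)
        recon = est.mean_ + est.coefficients_ @ est.dictionary_.T
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_explained_variance_non_increasing(self, rng):
        X = rng.standard_normal((30, 8))
        est = SynergyPCA(n_atoms=8).fit(X)
        assert np.all(np.diff(est.explained_variance_) <= 1e-12)

    def test_axis_aligned_toy(self):
        X = np.array([[1.0, 0.0], [0.0, 0.0]])
        est = SynergyPCA(n_atoms=1).fit(X)
        # dominant direction of centered [[1,0],[0,0]] is the first axis
        assert abs(est.dictionary_[0, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_too_many_atoms_rejected(self, rng):
        with pytest.raises(ValueError):
            SynergyPCA(n_atoms=9).fit(rng.standard_normal((4, 8)))

    def test_transform_is_centered_projection(self, rng):
        X = rng.standard_normal((15, 5))
        est = SynergyPCA(n_atoms=3).fit(X)
        np.testing.assert_allclose(est.transform(X),
                                   (X - est.mean_) @ est.dictionary_,
                                   atol=1e-10)


class TestL1SparseCoding:
    def test_huge_eta_zeroes_coefficients(self, rng):
        X = rng.standard_normal((10, 8))
        n, p = X.shape
        est = L1SparseCoding(n_atoms=3, eta=1e6, random_state=0).fit(X)
        assert np.all(est.coefficients_ == 0.0)
        assert est.objective_trace_[-1] == pytest.approx(
            np.sum(X ** 2) / (2 * n * p) + 0.0)

    def test_eta_zero_rank1_matches_svd(self, rng):
        u = rng.standard_normal(12)
        v = rng.standard_normal(7)
        X = np.outer(u, v)
        est = L1SparseCoding(n_atoms=1, eta=0.0, max_iter=500,
                             random_state=0).fit(X)
        assert est.objective_trace_[-1] <= _svd_objective(X, 1) + 1e-6

    def test_atom_norm_constraint(self, rng):
        X = rng.standard_normal((15, 9))
        est = L1SparseCoding(n_atoms=4, eta=1e-3, random_state=1).fit(X)
        assert np.all(np.linalg.norm(est.dictionary_, axis=0) <= 1 + 1e-8)

    def test_encode_matches_exhaustive_grid_on_toy_lasso(self):
        # 2 orthogonal atoms, known signal; brute-force the lasso objective
        V = np.eye(4)[:, :2]
        x = np.array([[0.8, -0.5, 0.0, 0.0]])
        eta = 0.1
        U = encode_l1(x, V, eta, max_iter=2000, tol=1e-14)
        grid = np.linspace(-1.2, 1.2, 241)
        best, best_val = None, np.inf
        for u1, u2 in itertools.product(grid, grid):
            u = np.array([[u1, u2]])
            val = _data_term(x, u, V) + eta * np.abs(u).sum()
            if val < best_val:
                best, best_val = u, val
        np.testing.assert_allclose(U, best, atol=0.011)  # grid resolution


class TestStructuredSparsePCA:
    def test_huge_lambda_zeroes_dictionary(self, rng):
        X = rng.standard_normal((10, 8))
        est = StructuredSparsePCA(n_atoms=3, lambda_=1e6, n_sensors=4,
                                  random_state=0).fit(X)
        assert np.all(est.dictionary_ == 0.0)

    def test_lambda_zero_matches_svd(self, rng):
        X = rng.standard_normal((10, 6))
        est = StructuredSparsePCA(n_atoms=3, lambda_=0.0, n_sensors=3,
                                  max_iter=800, inner_max_iter=100,
                                  random_state=0).fit(X)
        assert est.objective_trace_[-1] <= _svd_objective(X, 3) + 1e-6

    def test_coefficient_column_constraint(self, rng):
        X = rng.standard_normal((20, 8))
        est = StructuredSparsePCA(n_atoms=4, lambda_=1e-3, n_sensors=4,
                                  random_state=0).fit(X)
        assert np.all(np.linalg.norm(est.coefficients_, axis=0) <= 1 + 1e-8)

    def test_support_recovery_on_disjoint_group_data(self, rng):
        # two atoms supported on disjoint joint groups of an s=4 layout
        gs = build_joint_groups(4, 5)
        V_true = np.zeros((20, 2))
        V_true[gs.groups[0], 0] = rng.uniform(1, 2, 5)
        V_true[gs.groups[1], 0] = rng.uniform(1, 2, 5)
        V_true[gs.groups[2], 1] = rng.uniform(1, 2, 5)
        V_true[gs.groups[3], 1] = rng.uniform(1, 2, 5)
        V_true /= np.linalg.norm(V_true, axis=0)
        U_true = rng.uniform(0.5, 1.5, size=(40, 2))
        X = U_true @ V_true.T
        est = StructuredSparsePCA(n_atoms=2, lambda_=1e-4, n_sensors=4,
                                  max_iter=500, random_state=3).fit(X)
        # after best matching, each learned atom lives on the right groups
        C = np.abs(V_true.T @ (est.dictionary_ /
                               np.maximum(np.linalg.norm(est.dictionary_,
                                                         axis=0), 1e-12)))
        order = np.argmax(C, axis=1)
        assert order[0] != order[1]
        for k, true_joints in enumerate([(0, 1), (2, 3)]):
            atom = est.dictionary_[:, order[k]]
            outside = np.setdiff1d(np.arange(4), true_joints)
            off_mass = sum(np.linalg.norm(atom[gs.groups[j]]) for j in outside)
            assert off_mass <= 0.05 * np.linalg.norm(atom)


class TestStructuredSparseDictionary:
    def test_constraints_hold_at_convergence(self, rng):
        X = rng.standard_normal((20, 12))
        est = StructuredSparseDictionary(n_atoms=4, lambda_=1e-3, eta=2.0,
                                         n_sensors=4, random_state=0).fit(X)
        norms = np.linalg.norm(est.dictionary_, axis=0)
        nonzero = norms > 1e-12
        np.testing.assert_allclose(norms[nonzero], 1.0, atol=1e-8)
        assert np.all(np.abs(est.coefficients_).sum(axis=1) <= 2.0 + 1e-8)

    def test_eta_zero_rejected_as_degenerate(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            StructuredSparseDictionary(n_atoms=2, eta=0.0, n_sensors=2).fit(
                rng.standard_normal((6, 4)))


@pytest.mark.parametrize("fit", [
    lambda X, seed: fit_l1(X, 3, 1e-3, random_state=seed),
    lambda X, seed: fit_sspca(X, 3, 1e-3, n_sensors=4, random_state=seed),
    lambda X, seed: fit_srssd(X, 3, 1e-3, 2.0, n_sensors=4, random_state=seed),
])
def test_objective_traces_monotone_and_seeded_deterministic(fit, rng):
    X = rng.standard_normal((18, 12))
    res1 = fit(X, 0)
    res2 = fit(X, 0)
    assert np.all(np.diff(res1.objective_trace) <= 1e-9)
    np.testing.assert_array_equal(res1.dictionary.V, res2.dictionary.V)
    np.testing.assert_array_equal(res1.U, res2.U)


def test_non_finite_input_rejected():
    X = np.ones((5, 4))
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        fit_l1(X, 2, 0.1)


class TestEncode:
    def test_exact_recovery_with_full_rank_dictionary(self, rng):
        V = np.linalg.qr(rng.standard_normal((10, 3)))[0]
        u_star = rng.standard_normal((5, 3))
        X = u_star @ V.T
        res = fit_sspca(X, 3, 0.0, n_sensors=5, random_state=0)
        # least-squares encode with the true dictionary recovers u*
        from sparsesynergies.decomposition import SynergyDictionary
        d = SynergyDictionary(V=V, r=3, group_structure=None, method="sspca")
        np.testing.assert_allclose(encode(X, d), u_star, atol=1e-8)

    def test_zero_rows_give_zero_coefficients_for_penalized_methods(self, rng):
        from sparsesynergies.decomposition import SynergyDictionary
        V = rng.standard_normal((8, 3))
        V /= np.linalg.norm(V, axis=0)
        X = np.zeros((4, 8))
        for method, eta in [("l1", 0.1), ("srssd", 1.0)]:
            d = SynergyDictionary(V=V, r=3, group_structure=None, method=method)
            np.testing.assert_allclose(encode(X, d, eta=eta), 0.0, atol=1e-10)

    def test_l1_encode_agrees_with_sklearn_lasso(self, rng):
        # independent oracle: sklearn's coordinate-descent lasso
        from sklearn.linear_model import Lasso
        n, p, r = 6, 12, 4
        V = rng.standard_normal((p, r))
        V /= np.linalg.norm(V, axis=0)
        X = rng.standard_normal((n, p))
        eta = 0.01
        U = encode_l1(X, V, eta, max_iter=5000, tol=1e-16)
        # per-row problem 1/(2np)||x - V u||^2 + eta ||u||_1 equals sklearn's
        # 1/(2p)||x - V u||^2 + alpha ||u||_1 with alpha = n * eta
        lasso = Lasso(alpha=n * eta, fit_intercept=False, tol=1e-12,
                      max_iter=100000)
        for i in range(n):
            ref = lasso.fit(V, X[i]).coef_
            np.testing.assert_allclose(U[i], ref, atol=1e-5)

    def test_missing_eta_rejected(self, rng):
        from sparsesynergies.decomposition import SynergyDictionary
        d = SynergyDictionary(V=rng.standard_normal((4, 2)), r=2,
                              group_structure=None, method="l1")
        with pytest.raises(ValueError, match="eta"):
            encode(np.zeros((2, 4)), d)
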
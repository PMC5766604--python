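"""The four synergy-representation learners.

Trials (rows of X, n x p) are approximated as X ~ U V^T with a dictionary
V (p x r) of temporal postural synergy atoms and coefficients U (n x r).
Four estimators realize four coding hypotheses:

* :class:`SynergyPCA` — no sparsity (baseline): orthonormal atoms from a
  principal component analysis; every action uses every atom and every
  atom uses every degree of freedom.
* :class:`L1SparseCoding` — sparse combinations: l1-penalized coefficients
  with atoms confined to the unit l2 ball,

      min_{U,V} 1/(2np) ||X - U V^T||_F^2 + eta sum_k ||U_k||_1
      s.t. ||V^j||_2 <= 1 for every atom j.

* :class:`StructuredSparsePCA` — sparse elements: a group-lasso penalty
  over joint groups drives whole joints out of each atom,

      min_{U,V} 1/(2np) ||X - U V^T||_F^2 + lambda sum_k Omega_v(V^k)
      s.t. ||U^j||_2 <= 1 for every coefficient column j,

  with Omega_v(v) = sum_g ||v_g||_2 over the s joint groups.
* :class:`StructuredSparseDictionary` — double sparsity: the group penalty
  on atoms combined with a hard l1 bound on every coefficient row and
  unit-norm atoms,

      min_{U,V} 1/(2np) ||X - U V^T||_F^2 + lambda sum_k Omega_v(V^k)
      s.t. ||U_j||_1 <= eta for every row j, ||V^i||_2 = 1 for every atom.

All penalized/constrained subproblems are solved with a monotone
accelerated proximal-gradient method, so the recorded objective trace is
non-increasing across alternations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ._prox import (
    monotone_fista,
    project_columns_l2_ball,
    project_rows_l1_ball,
    prox_group,
    soft_threshold,
)
from .groups import GroupStructure, build_joint_groups


@dataclass
class SynergyDictionary:
    """A learned atom matrix with its joint-group structure and method tag."""

    V: np.ndarray  # (p, r)
    r: int
    group_structure: GroupStructure | None
    method: str
    mean: np.ndarray | None = None  # centering vector (PCA only)


@dataclass
class FactorizationResult:
    """Output of one factorization fit: dictionary, coefficients, trace."""

    dictionary: SynergyDictionary
    U: np.ndarray  # (n, r)
    lambda_: float
    eta: float
    objective_trace: np.ndarray
    converged: bool
    seed: int | None


def _check_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-d, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _spectral_norm_sq(M: np.ndarray) -> float:
    if M.size == 0 or not np.any(M):
        return 1e-12
    return float(np.linalg.norm(M, 2)) ** 2


def _data_term(X: np.ndarray, U: np.ndarray, V: np.ndarray) -> float:
    n, p = X.shape
    R = X - U @ V.T
    return float(np.sum(R * R)) / (2.0 * n * p)


def _group_norm(V: np.ndarray, groups) -> float:
    """sum over atoms k of Omega_v(V^k) = sum_g ||V[g, k]||_2."""
    total = 0.0
    for g in groups:
        total += float(np.linalg.norm(V[g], axis=0).sum())
    return total


def encode_pca(X: np.ndarray, V: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Projection of centered rows onto the orthonormal atoms."""
    return (_check_matrix(X) - mean) @ V


def encode_sspca(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Least-squares coefficients with the dictionary frozen."""
    X = _check_matrix(X)
    U, *_ = scipy.linalg.lstsq(V, X.T)
    return U.T


def encode_l1(
    X: np.ndarray, V: np.ndarray, eta: float,
    max_iter: int = 500, tol: float = 1e-10, U0: np.ndarray | None = None,
) -> np.ndarray:
    """Lasso coefficients with the dictionary frozen.

    Minimizes 1/(2np)||X - U V^T||_F^2 + eta * sum |U| by monotone FISTA.
    """
    X = _check_matrix(X)
    n, p = X.shape
    U0 = np.zeros((n, V.shape[1])) if U0 is None else U0
    lip = _spectral_norm_sq(V) / (n * p)
    return monotone_fista(
        U0,
        grad=lambda U: (U @ V.T - X) @ V / (n * p),
        lipschitz=lip,
        prox=lambda Z, step: soft_threshold(Z, step * eta),
        objective=lambda U: _data_term(X, U, V) + eta * float(np.abs(U).sum()),
        max_iter=max_iter, tol=tol,
    )


def encode_srssd(
    X: np.ndarray, V: np.ndarray, eta: float,
    max_iter: int = 500, tol: float = 1e-10, U0: np.ndarray | None = None,
) -> np.ndarray:
    """l1-ball-constrained least-squares coefficients, dictionary frozen."""
    X = _check_matrix(X)
    n, p = X.shape
    U0 = np.zeros((n, V.shape[1])) if U0 is None else U0
    lip = _spectral_norm_sq(V) / (n * p)
    return monotone_fista(
        U0,
        grad=lambda U: (U @ V.T - X) @ V / (n * p),
        lipschitz=lip,
        prox=lambda Z, step: project_rows_l1_ball(Z, eta),
        objective=lambda U: _data_term(X, U, V),
        max_iter=max_iter, tol=tol,
    )


class _BaseDictionaryLearner(TransformerMixin, BaseEstimator):
    """Shared alternating-minimization scaffolding for the sparse learners."""

    method: str = ""

    def __init__(self, n_atoms=8, max_iter=200, tol=1e-6,
                 inner_max_iter=50, inner_tol=1e-8, random_state=None):
        self.n_atoms = n_atoms
        self.max_iter = max_iter
        self.tol = tol
        self.inner_max_iter = inner_max_iter
        self.inner_tol = inner_tol
        self.random_state = random_state

    # subclasses implement these three
    def _objective(self, X, U, V) -> float:
        raise NotImplementedError

    def _u_step(self, X, U, V) -> np.ndarray:
        raise NotImplementedError

    def _v_step(self, X, U, V) -> np.ndarray:
        raise NotImplementedError

    def _init_dictionary(self, X, rng) -> np.ndarray:
        """Atoms initialized from n_atoms randomly chosen training rows."""
        n = X.shape[0]
        idx = rng.choice(n, size=self.n_atoms, replace=self.n_atoms > n)
        V = X[idx].T.copy()
        # break exact duplicates / zero rows deterministically
        norms = np.linalg.norm(V, axis=0)
        for k in np.nonzero(norms < 1e-12)[0]:
            V[:, k] = rng.standard_normal(X.shape[1])
        return V

    def fit(self, X, y=None):
        X = _check_matrix(X)
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        V = self._normalize_atoms(self._init_dictionary(X, rng))
        U = np.zeros((n, self.n_atoms))
        trace = [self._objective(X, U, V)]
        converged = False
        for _ in range(self.max_iter):
            U = self._u_step(X, U, V)
            V = self._v_step(X, U, V)
            obj = self._objective(X, U, V)
            trace.append(obj)
            if abs(trace[-2] - obj) <= self.tol * max(abs(trace[-2]), 1e-300):
                converged = True
                break
        self.dictionary_ = V
        self.components_ = V.T
        self.coefficients_ = U
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace) - 1
        self.converged_ = converged
        self.n_features_in_ = p
        return self

    def _normalize_atoms(self, V) -> np.ndarray:
        return V

    def fit_transform(self, X, y=None):
        return self.fit(X).coefficients_


class SynergyPCA(TransformerMixin, BaseEstimator):
    """No-sparsity baseline: principal components as synergy atoms.

    Atoms are the top ``n_atoms`` right singular directions of the
    centered data; coefficients are the centered projections.
    """

    method = "pca"

    def __init__(self, n_atoms=8, random_state=None):
        self.n_atoms = n_atoms
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _check_matrix(X)
        n, p = X.shape
        if self.n_atoms > min(n, p):
            raise ValueError(
                f"n_atoms = {self.n_atoms} exceeds min(n, p) = {min(n, p)}"
            )
        pca = PCA(n_components=self.n_atoms, svd_solver="full",
                  random_state=self.random_state)
        U = pca.fit_transform(X)
        self.dictionary_ = pca.components_.T
        self.components_ = pca.components_
        self.mean_ = pca.mean_
        self.explained_variance_ = pca.explained_variance_
        self.coefficients_ = U
        recon_err = _data_term(X - self.mean_, U, self.dictionary_)
        self.objective_trace_ = np.array([recon_err])
        self.n_iter_ = 1
        self.converged_ = True
        self.n_features_in_ = p
        return self

    def transform(self, X):
        return encode_pca(X, self.dictionary_, self.mean_)


class L1SparseCoding(_BaseDictionaryLearner):
    """Sparse-combination learner: l1-penalized coefficients.

    Parameters
    ----------
    n_atoms : dictionary size r.
    eta : weight of the l1 penalty on the coefficients; larger values use
        fewer atoms per action.
    """

    method = "l1"

    def __init__(self, n_atoms=8, eta=1e-3, max_iter=200, tol=1e-6,
                 inner_max_iter=50, inner_tol=1e-8, random_state=None):
        super().__init__(n_atoms, max_iter, tol, inner_max_iter, inner_tol,
                         random_state)
        self.eta = eta

    def _normalize_atoms(self, V):
        return project_columns_l2_ball(V, 1.0)

    def _objective(self, X, U, V):
        return _data_term(X, U, V) + self.eta * float(np.abs(U).sum())

    def _u_step(self, X, U, V):
        return encode_l1(X, V, self.eta, self.inner_max_iter, self.inner_tol, U0=U)

    def _v_step(self, X, U, V):
        n, p = X.shape
        lip = _spectral_norm_sq(U) / (n * p)
        return monotone_fista(
            V,
            grad=lambda W: (W @ U.T - X.T) @ U / (n * p),
            lipschitz=lip,
            prox=lambda Z, step: project_columns_l2_ball(Z, 1.0),
            objective=lambda W: _data_term(X, U, W),
            max_iter=self.inner_max_iter, tol=self.inner_tol,
        )

    def transform(self, X):
        return encode_l1(X, self.dictionary_, self.eta)


class StructuredSparsePCA(_BaseDictionaryLearner):
    """Sparse-elements learner: group-lasso penalty over joint groups.

    Parameters
    ----------
    n_atoms : dictionary size r.
    lambda_ : weight of the group penalty on atoms; larger values switch
        whole joints off inside each atom.
    groups : a :class:`GroupStructure`; inferred from ``n_sensors`` at fit
        time if omitted.
    n_sensors : number of joint-angle sensors s (used when groups is None).
    """

    method = "sspca"

    def __init__(self, n_atoms=8, lambda_=1e-3, groups=None, n_sensors=10,
                 max_iter=200, tol=1e-6, inner_max_iter=50, inner_tol=1e-8,
                 random_state=None):
        super().__init__(n_atoms, max_iter, tol, inner_max_iter, inner_tol,
                         random_state)
        self.lambda_ = lambda_
        self.groups = groups
        self.n_sensors = n_sensors

    def _resolve_groups(self, p) -> GroupStructure:
        if self.groups is not None:
            return self.groups
        if p % self.n_sensors:
            raise ValueError(f"p = {p} is not a multiple of n_sensors = {self.n_sensors}")
        return build_joint_groups(self.n_sensors, p // self.n_sensors)

    def fit(self, X, y=None):
        self.group_structure_ = self._resolve_groups(np.asarray(X).shape[1])
        return super().fit(X)

    def _objective(self, X, U, V):
        return _data_term(X, U, V) + self.lambda_ * _group_norm(
            V, self.group_structure_.groups)

    def _u_step(self, X, U, V):
        n, p = X.shape
        lip = _spectral_norm_sq(V) / (n * p)
        return monotone_fista(
            U,
            grad=lambda W: (W @ V.T - X) @ V / (n * p),
            lipschitz=lip,
            prox=lambda Z, step: project_columns_l2_ball(Z, 1.0),
            objective=lambda W: _data_term(X, W, V),
            max_iter=self.inner_max_iter, tol=self.inner_tol,
        )

    def _v_step(self, X, U, V):
        n, p = X.shape
        groups = self.group_structure_.groups
        lip = _spectral_norm_sq(U) / (n * p)
        return monotone_fista(
            V,
            grad=lambda W: (W @ U.T - X.T) @ U / (n * p),
            lipschitz=lip,
            prox=lambda Z, step: prox_group(Z, groups, step * self.lambda_),
            objective=lambda W: self._objective(X, U, W),
            max_iter=self.inner_max_iter, tol=self.inner_tol,
        )

    def transform(self, X):
        return encode_sspca(X, self.dictionary_)


class StructuredSparseDictionary(StructuredSparsePCA):
    """Double-sparsity learner: group-sparse unit-norm atoms and
    l1-bounded coefficient rows.

    Parameters
    ----------
    n_atoms : dictionary size r.
    lambda_ : weight of the group penalty on atoms.
    eta : l1 budget of each coefficient row (hard constraint); each action
        spends at most ``eta`` of total absolute coefficient mass.
    """

    method = "srssd"

    def __init__(self, n_atoms=8, lambda_=1e-3, eta=2.0, groups=None,
                 n_sensors=10, max_iter=200, tol=1e-6, inner_max_iter=50,
                 inner_tol=1e-8, random_state=None):
        super().__init__(n_atoms, lambda_, groups, n_sensors, max_iter, tol,
                         inner_max_iter, inner_tol, random_state)
        self.eta = eta

    def _normalize_atoms(self, V):
        norms = np.linalg.norm(V, axis=0)
        return V / np.maximum(norms, 1e-300)

    def fit(self, X, y=None):
        if self.eta <= 0:
            raise ValueError(
                "eta must be > 0: a zero l1 budget forces all-zero "
                "coefficients (degenerate problem)"
            )
        self.n_atom_reinits_ = 0
        return super().fit(X)

    def _u_step(self, X, U, V):
        return encode_srssd(X, V, self.eta, self.inner_max_iter,
                            self.inner_tol, U0=U)

    def _v_step(self, X, U, V):
        """Monotone projected prox-gradient step on the atoms.

        A group-prox gradient step followed by renormalization to the unit
        sphere is accepted only if the full objective does not increase;
        otherwise the step is halved (up to 10 times) and finally the
        previous dictionary is kept.  Atoms driven to zero by the prox are
        re-initialized from the worst-reconstructed training row.
        """
        n, p = X.shape
        groups = self.group_structure_.groups
        lip = _spectral_norm_sq(U) / (n * p)
        V_cur = V
        f_cur = self._objective(X, U, V_cur)
        for _ in range(self.inner_max_iter):
            step = 1.0 / max(lip, 1e-300)
            grad = (V_cur @ U.T - X.T) @ U / (n * p)
            accepted = False
            for _ in range(10):
                cand = prox_group(V_cur - step * grad, groups, step * self.lambda_)
                cand = self._renormalize(X, U, cand)
                f_cand = self._objective(X, U, cand)
                if f_cand <= f_cur + 1e-12:
                    accepted = True
                    break
                step *= 0.5
            if not accepted or f_cur - f_cand <= self.inner_tol * max(abs(f_cur), 1e-300):
                if accepted:
                    V_cur, f_cur = cand, f_cand
                break
            V_cur, f_cur = cand, f_cand
        return V_cur

    def _renormalize(self, X, U, V):
        norms = np.linalg.norm(V, axis=0)
        dead = norms < 1e-12
        V = V / np.maximum(norms, 1e-300)
        if np.any(dead):
            # a dead atom contributed nothing, so silencing its coefficient
            # column keeps the reconstruction unchanged while the atom is
            # re-seeded from the worst-reconstructed training row
            U[:, dead] = 0.0
            R = X - U @ V.T
            worst = int(np.argmax(np.sum(R * R, axis=1)))
            for k in np.nonzero(dead)[0]:
                atom = X[worst].copy()
                nrm = np.linalg.norm(atom)
                V[:, k] = atom / nrm if nrm > 1e-12 else 0.0
                self.n_atom_reinits_ += 1
        return V

    def transform(self, X):
        return encode_srssd(X, self.dictionary_, self.eta)


METHODS = {
    "pca": SynergyPCA,
    "l1": L1SparseCoding,
    "sspca": StructuredSparsePCA,
    "srssd": StructuredSparseDictionary,
}


def make_learner(method: str, n_atoms: int, lambda_: float = 0.0,
                 eta: float = 0.0, n_sensors: int = 10,
                 random_state=None, **opts):
    """Instantiate one of the four learners from its method tag."""
    method = method.lower()
    if method == "pca":
        return SynergyPCA(n_atoms=n_atoms, random_state=random_state)
    if method == "l1":
        return L1SparseCoding(n_atoms=n_atoms, eta=eta,
                              random_state=random_state, **opts)
    if method == "sspca":
        return StructuredSparsePCA(n_atoms=n_atoms, lambda_=lambda_,
                                   n_sensors=n_sensors,
                                   random_state=random_state, **opts)
    if method == "srssd":
        return StructuredSparseDictionary(n_atoms=n_atoms, lambda_=lambda_,
                                          eta=eta, n_sensors=n_sensors,
                                          random_state=random_state, **opts)
    raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")


def _result_from_estimator(est, seed) -> FactorizationResult:
    gs = getattr(est, "group_structure_", None)
    dictionary = SynergyDictionary(
        V=est.dictionary_, r=est.dictionary_.shape[1], group_structure=gs,
        method=est.method, mean=getattr(est, "mean_", None),
    )
    return FactorizationResult(
        dictionary=dictionary, U=est.coefficients_,
        lambda_=getattr(est, "lambda_", 0.0), eta=getattr(est, "eta", 0.0),
        objective_trace=est.objective_trace_, converged=est.converged_,
        seed=seed,
    )


def fit_pca(X_train, r, random_state=None) -> FactorizationResult:
    """Fit the no-sparsity PCA baseline with r components."""
    est = SynergyPCA(n_atoms=r, random_state=random_state).fit(X_train)
    return _result_from_estimator(est, random_state)


def fit_l1(X_train, r, eta, random_state=None, **opts) -> FactorizationResult:
    """Fit the l1 sparse-coding factorization."""
    est = L1SparseCoding(n_atoms=r, eta=eta, random_state=random_state,
                         **opts).fit(X_train)
    return _result_from_estimator(est, random_state)


def fit_sspca(X_train, r, lambda_, n_sensors=10, random_state=None,
              **opts) -> FactorizationResult:
    """Fit the structured-sparse (group-penalized atoms) factorization."""
    est = StructuredSparsePCA(n_atoms=r, lambda_=lambda_, n_sensors=n_sensors,
                              random_state=random_state, **opts).fit(X_train)
    return _result_from_estimator(est, random_state)


def fit_srssd(X_train, r, lambda_, eta, n_sensors=10, random_state=None,
              **opts) -> FactorizationResult:
    """Fit the double-sparsity factorization."""
    est = StructuredSparseDictionary(n_atoms=r, lambda_=lambda_, eta=eta,
                                     n_sensors=n_sensors,
                                     random_state=random_state, **opts).fit(X_train)
    return _result_from_estimator(est, random_state)


def encode(X_new, dictionary: SynergyDictionary, eta: float | None = None) -> np.ndarray:
    """Coefficients for new data with a frozen dictionary.

    Runs the coefficient step of the method that produced the dictionary:
    centered projection (pca), lasso (l1), least squares (sspca) or
    l1-ball-constrained least squares (srssd).
    """
    method = dictionary.method
    if method == "pca":
        return encode_pca(X_new, dictionary.V, dictionary.mean)
    if method == "sspca":
        return encode_sspca(X_new, dictionary.V)
    if eta is None:
        raise ValueError(f"method {method!r} requires eta")
    if method == "l1":
        return encode_l1(X_new, dictionary.V, eta)
    if method == "srssd":
        return encode_srssd(X_new, dictionary.V, eta)
    raise ValueError(f"unknown dictionary method {method!r}")
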
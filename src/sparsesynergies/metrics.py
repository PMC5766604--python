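"""Representation statistics: sparsity, usage, commonality, selectivity.

Given coefficients U (n actions x r atoms) and a dictionary V (p x r),
these statistics summarize how a representation distributes work:

* coefficient sparsity   1 - (1/nr) sum_j ||U_j||_0   — how few atoms each
  action uses (the sparse-combination axis);
* dictionary sparsity    1 - (1/rp) sum_j ||V^j||_0   — how few
  coordinates each atom uses (the sparse-elements axis);
* usage(k, i) — the fraction of class-i actions whose coefficient on atom
  k is nonzero;
* commonality(k) = M / (1 + S) with M, S the mean and spread of atom k's
  usage over classes — close to 1 when an atom serves every class;
* selectivity(k, i) = usage(k, i) * (1 - mean of the other classes'
  usages) — equal to 1 exactly when atom k is used by every action of
  class i and by no other action.

All l0 counts share a single tolerance: |value| > zero_tol is nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_ZERO_TOL = 1e-6


@dataclass
class MetricReport:
    """Per-solution metric bundle; usage/selectivity are (r x C)."""

    coeff_sparsity: float
    dict_sparsity: float
    usage: np.ndarray
    commonality: np.ndarray
    selectivity: np.ndarray
    classes: np.ndarray
    zero_tol: float

    @property
    def mean_commonality(self) -> float:
        return float(self.commonality.mean())

    @property
    def mean_selectivity(self) -> float:
        return float(self.selectivity.max(axis=1).mean())


def _nnz(M: np.ndarray, zero_tol: float) -> int:
    return int(np.count_nonzero(np.abs(M) > zero_tol))


def coeff_sparsity(U: np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL) -> float:
    """Fraction of (numerically) zero entries of the coefficient matrix."""
    U = np.asarray(U, dtype=float)
    if U.size == 0:
        raise ValueError("empty coefficient matrix")
    return 1.0 - _nnz(U, zero_tol) / U.size


def dict_sparsity(V: np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL) -> float:
    """Fraction of (numerically) zero entries of the dictionary."""
    V = np.asarray(V, dtype=float)
    if V.size == 0:
        raise ValueError("empty dictionary")
    return 1.0 - _nnz(V, zero_tol) / V.size


def usage_matrix(
    U: np.ndarray, labels: np.ndarray,
    classes: np.ndarray | None = None,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """(r x C) matrix of per-class atom usage fractions.

    usage[k, i] is the fraction of actions in class i whose coefficient on
    atom k exceeds zero_tol in magnitude.
    """
    U = np.asarray(U, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    out = np.empty((U.shape[1], len(classes)))
    for i, cls in enumerate(classes):
        rows = U[labels == cls]
        if rows.shape[0] == 0:
            raise ValueError(f"class {cls!r} has no actions")
        out[:, i] = np.mean(np.abs(rows) > zero_tol, axis=0)
    return out, np.asarray(classes)


def usage(U, labels, atom: int, class_label,
          zero_tol: float = DEFAULT_ZERO_TOL) -> float:
    """Scalar usage of one atom by one class."""
    mat, classes = usage_matrix(U, labels, zero_tol=zero_tol)
    i = int(np.nonzero(classes == class_label)[0][0])
    return float(mat[atom, i])


def commonality(usage_row: np.ndarray, sd_ddof: int = 0) -> float:
    """M / (1 + S): mean usage over classes discounted by its spread.

    The spread S uses the population (n-denominator) SD by default so that
    an atom with identical usage in every class has commonality exactly
    equal to that usage.
    """
    u = np.asarray(usage_row, dtype=float)
    if u.size < 2:
        raise ValueError("commonality needs usage over >= 2 classes")
    return float(u.mean() / (1.0 + u.std(ddof=sd_ddof)))


def selectivity(usage_row: np.ndarray, class_index: int) -> float:
    """usage(k, i) discounted by the mean usage over the other classes.

    Equals 1 exactly for an atom used by every action of class i and none
    of any other class.
    """
    u = np.asarray(usage_row, dtype=float)
    C = u.size
    if C < 2:
        raise ValueError("selectivity needs >= 2 classes")
    others = np.delete(u, class_index)
    return float(u[class_index] * (1.0 - others.sum() / (C - 1)))


def selectivity_matrix(usage_mat: np.ndarray) -> np.ndarray:
    """(r x C) selectivity of every atom for every class."""
    r, C = usage_mat.shape
    out = np.empty((r, C))
    for k in range(r):
        for i in range(C):
            out[k, i] = selectivity(usage_mat[k], i)
    return out


def metric_report(
    U: np.ndarray, V: np.ndarray, labels: np.ndarray,
    classes: np.ndarray | None = None,
    zero_tol: float = DEFAULT_ZERO_TOL,
    sd_ddof: int = 0,
) -> MetricReport:
    """Compute the full metric bundle for one factorization solution."""
    usage_mat, classes = usage_matrix(U, labels, classes, zero_tol)
    return MetricReport(
        coeff_sparsity=coeff_sparsity(U, zero_tol),
        dict_sparsity=dict_sparsity(V, zero_tol),
        usage=usage_mat,
        commonality=np.array([commonality(row, sd_ddof) for row in usage_mat]),
        selectivity=selectivity_matrix(usage_mat),
        classes=classes,
        zero_tol=zero_tol,
    )
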
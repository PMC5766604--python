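"""Proximal operators and a monotone accelerated proximal-gradient solver.

These primitives back every penalized/constrained subproblem in the
dictionary learners: the elementwise soft threshold (prox of the l1 norm),
the group soft threshold (prox of the l1/l2 group norm), Euclidean
projections onto l1 and l2 balls, and a monotone FISTA loop whose objective
is guaranteed non-increasing iterate to iterate.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def soft_threshold(v: np.ndarray | float, t: float) -> np.ndarray:
    """Elementwise soft threshold: sign(v) * max(|v| - t, 0).

    Prox of ``t * ||.||_1``.
    """
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def prox_group(v: np.ndarray, groups: Sequence[np.ndarray], t: float) -> np.ndarray:
    """Prox of ``t * sum_g ||v_g||_2`` (block soft threshold).

    Each group with norm below ``t`` is zeroed; the others are shrunk
    radially by ``1 - t / ||v_g||_2``.  Groups index the first axis of
    ``v``; a 2-d ``v`` is treated column-by-column (shared groups).
    """
    if t < 0:
        raise ValueError(f"threshold must be nonnegative, got {t}")
    v = np.asarray(v, dtype=float)
    out = np.zeros_like(v)
    for g in groups:
        block = v[g]
        norms = np.linalg.norm(block, axis=0) if block.ndim == 2 else np.linalg.norm(block)
        scale = np.maximum(1.0 - t / np.maximum(norms, 1e-300), 0.0)
        out[g] = block * scale
    return out


def project_l1_ball(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection of a vector onto {x : ||x||_1 <= radius}.

    Sort-based algorithm (Duchi et al. style): O(d log d).
    """
    if radius < 0:
        raise ValueError(f"radius must be nonnegative, got {radius}")
    v = np.asarray(v, dtype=float)
    if np.abs(v).sum() <= radius:
        return v.copy()
    u = np.sort(np.abs(v))[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, len(u) + 1) > (css - radius))[0][-1]
    theta = (css[rho] - radius) / (rho + 1.0)
    return soft_threshold(v, theta)


def project_rows_l1_ball(M: np.ndarray, radius: float) -> np.ndarray:
    """Project every row of ``M`` onto the l1 ball of the given radius.

    Vectorized sort-based projection; rows already inside the ball are
    returned unchanged.
    """
    if radius < 0:
        raise ValueError(f"radius must be nonnegative, got {radius}")
    M = np.asarray(M, dtype=float)
    A = np.abs(M)
    need = A.sum(axis=1) > radius
    out = M.copy()
    if not np.any(need):
        return out
    sub = A[need]
    u = -np.sort(-sub, axis=1)
    css = np.cumsum(u, axis=1)
    k = np.arange(1, u.shape[1] + 1)
    cond = u * k > (css - radius)
    rho = cond.shape[1] - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = (css[np.arange(sub.shape[0]), rho] - radius) / (rho + 1.0)
    out[need] = np.sign(M[need]) * np.maximum(sub - theta[:, None], 0.0)
    return out


def project_columns_l2_ball(M: np.ndarray, radius: float = 1.0) -> np.ndarray:
    """Scale down any column of ``M`` whose l2 norm exceeds ``radius``."""
    norms = np.linalg.norm(M, axis=0)
    scale = np.where(norms > radius, radius / np.maximum(norms, 1e-300), 1.0)
    return M * scale


def monotone_fista(
    x0: np.ndarray,
    grad: Callable[[np.ndarray], np.ndarray],
    lipschitz: float,
    prox: Callable[[np.ndarray, float], np.ndarray],
    objective: Callable[[np.ndarray], float],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> np.ndarray:
    """Accelerated proximal gradient with a monotone safeguard.

    Minimizes ``f(x) + h(x)`` where ``grad`` is the gradient of the smooth
    part ``f`` with Lipschitz constant ``lipschitz`` and ``prox(z, step)``
    is the proximal map of ``step * h``.  The monotone (MFISTA) variant
    keeps the best iterate so far, so ``objective`` never increases along
    the returned sequence — the property the alternating solvers rely on.
    """
    step = 1.0 / max(lipschitz, 1e-300)
    x = x0.copy()
    y = x0.copy()
    f_x = objective(x)
    t_k = 1.0
    restarted = False
    for _ in range(max_iter):
        z = prox(y - step * grad(y), step)
        f_z = objective(z)
        if f_z > f_x:
            if restarted:
                break  # plain descent step made no progress: stationary
            # adaptive restart: drop the momentum and retry from the best point
            y = x.copy()
            t_k = 1.0
            restarted = True
            continue
        rel = (f_x - f_z) / max(abs(f_x), 1e-300)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        y = z + ((t_k - 1.0) / t_next) * (z - x)
        x, f_x, t_k = z, f_z, t_next
        restarted = False
        if rel < tol:
            break
    return x
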
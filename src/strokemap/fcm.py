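"""Fuzzy c-means clustering with Xie-Beni validity and joint (c, m) selection.

The membership update is

    u_ik = [ sum_j ( ||x_i - v_k|| / ||x_i - v_j|| )^(2/(m-1)) ]^(-1)

and the centroid update is the u^m-weighted mean.  The fuzzifier m > 1
controls softness (m -> 1 recovers hard nearest-centroid assignment).  The
Xie-Beni index

    XB = ( sum_i sum_k u_ik^m ||x_i - v_k||^2 ) / ( n * min_{k != l} ||v_k - v_l||^2 )

is a compactness / separation ratio (lower is better); the cluster count c
and fuzzifier m are chosen jointly by minimizing XB over a grid.

Distances are Euclidean throughout, taken on standardized trajectories.
A point coinciding with one or more centroids gets its membership split
equally among the coincident centroids (the formula's singular case,
resolved by symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

_COINCIDENT = 1e-12


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model."""

    centroids: np.ndarray  # (c, n_dims)
    m: float
    c: int
    objective_trace: list = field(default_factory=list)
    xb: float | None = None
    seed: int | None = None
    converged: bool = False
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "c": self.c, "m": self.m, "xb": self.xb, "seed": self.seed,
            "converged": self.converged, "n_iter": self.n_iter,
            "objective": self.objective_trace[-1] if self.objective_trace else None,
            "centroids": self.centroids.tolist(),
        }


def _check_m(m: float) -> None:
    if m <= 1:
        raise ValueError(f"fuzzifier m must exceed 1, got {m}")


def update_memberships(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix U (n x c); rows sum to 1."""
    _check_m(m)
    D = cdist(np.atleast_2d(X), np.atleast_2d(V))
    n, c = D.shape
    U = np.zeros((n, c))
    hit = D <= _COINCIDENT
    singular = hit.any(axis=1)
    if singular.any():
        U[singular] = hit[singular] / hit[singular].sum(axis=1, keepdims=True)
    reg = ~singular
    if reg.any():
        Dr = D[reg]
        # normalize by the row minimum so the largest weight is exactly 1;
        # smaller weights may underflow to 0, which is the correct limit
        W = (Dr / Dr.min(axis=1, keepdims=True)) ** (-2.0 / (m - 1.0))
        U[reg] = W / W.sum(axis=1, keepdims=True)
    return U


def update_centroids(
    X: np.ndarray, U: np.ndarray, m: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Centroids v_k = sum_i u_ik^m x_i / sum_i u_ik^m.

    A cluster whose total weight underflows to zero is re-seeded from the
    point farthest from the current centroids.
    """
    _check_m(m)
    Um = U**m
    weights = Um.sum(axis=0)
    V = np.empty((U.shape[1], X.shape[1]))
    ok = weights > 0
    V[ok] = (Um[:, ok].T @ X) / weights[ok, None]
    if not ok.all():
        D = cdist(X, V[ok])
        far = np.argsort(-D.min(axis=1))
        for rank, k in enumerate(np.flatnonzero(~ok)):
            V[k] = X[far[rank % len(far)]]
    return V


def objective(X: np.ndarray, U: np.ndarray, V: np.ndarray, m: float) -> float:
    """Fuzzy within-cluster scatter J_m = sum_ik u_ik^m ||x_i - v_k||^2."""
    D2 = cdist(X, V) ** 2
    return float((U**m * D2).sum())


def xie_beni(X: np.ndarray, U: np.ndarray, V: np.ndarray, m: float) -> float:
    """Xie-Beni validity index; raises if two centroids coincide."""
    _check_m(m)
    sep = cdist(V, V) ** 2
    np.fill_diagonal(sep, np.inf)
    min_sep = sep.min()
    if min_sep <= _COINCIDENT:
        raise ValueError("duplicate centroids: Xie-Beni separation is zero")
    return objective(X, U, V, m) / (len(X) * min_sep)


def fit_fcm(
    X: np.ndarray,
    c: int,
    m: float,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    n_init: int = 10,
) -> tuple[ClusterModel, np.ndarray]:
    """Fit fuzzy c-means; best of ``n_init`` k-means++-seeded restarts by J_m."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    _check_m(m)
    if c < 2:
        raise ValueError("cluster count c must be at least 2")
    if X.shape[0] <= c:
        raise ValueError("need more points than clusters")

    rng = np.random.default_rng(seed)
    best: tuple[float, ClusterModel, np.ndarray] | None = None
    for restart in range(n_init):
        rs = int(rng.integers(2**31 - 1))
        V, _ = kmeans_plusplus(X, n_clusters=c, random_state=rs)
        U_prev = None
        trace: list[float] = []
        converged = False
        for it in range(1, max_iter + 1):
            U = update_memberships(X, V, m)
            V = update_centroids(X, U, m, rng)
            trace.append(objective(X, U, V, m))
            if U_prev is not None and np.abs(U - U_prev).max() < tol:
                converged = True
                break
            U_prev = U
        model = ClusterModel(centroids=V, m=m, c=c, objective_trace=trace,
                             seed=seed, converged=converged, n_iter=len(trace))
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], model, U)

    _, model, U = best
    try:
        model.xb = xie_beni(X, U, model.centroids, m)
    except ValueError:
        # coincident centroids (over-clustered): infinitely bad validity
        model.xb = float("inf")
    return model, U


def select_parameters(
    X: np.ndarray,
    c_grid=(8, 12, 16, 20),
    m_grid=tuple(np.round(np.arange(1.05, 2.01, 0.05), 2)),
    seed: int = 0,
    n_init: int = 10,
    **fit_kwargs,
) -> tuple[int, float, pd.DataFrame]:
    """Grid search over (c, m) minimizing the Xie-Beni index.

    Ties are broken toward smaller c, then smaller m.  Returns the selected
    (c*, m*) and the full grid table for inspection.
    """
    if len(c_grid) == 0 or len(m_grid) == 0:
        raise ValueError("c_grid and m_grid must be non-empty")
    if any(m <= 1 for m in m_grid):
        raise ValueError("all fuzzifier values in m_grid must exceed 1")
    rows = []
    for ci, c in enumerate(sorted(c_grid)):
        for mi, m in enumerate(sorted(m_grid)):
            sub_seed = (seed * 9973 + ci * 101 + mi) % (2**31 - 1)
            model, _ = fit_fcm(X, c=c, m=float(m), seed=sub_seed,
                               n_init=n_init, **fit_kwargs)
            rows.append({"c": c, "m": float(m), "xb": model.xb,
                         "objective": model.objective_trace[-1],
                         "converged": model.converged})
    table = pd.DataFrame(rows)
    best = table.sort_values(["xb", "c", "m"], kind="stable").iloc[0]
    return int(best["c"]), float(best["m"]), table
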
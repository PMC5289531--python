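"""Regression engines: OLS, NIPALS partial least squares, and the elastic net.

All three fitters operate on *standardized* inputs (see
:mod:`enetbeta.datamodel`) and return a :class:`LinearModel` that carries
both the standardized coefficient vector and its raw-scale equivalent, so
predictions can be made directly on raw spectra.

The elastic net solves the unnormalized penalized least-squares problem

    min_b  ||y - X b||^2 + lambda1 ||b||_1 + lambda2 ||b||_2^2

by cyclic coordinate descent with covariance updates, and reports the
minimizer rescaled by ``(1 + lambda2/n)`` — the "corrected" elastic-net
coefficient that undoes the double shrinkage of the naive estimator. The
objective carries no 1/(2n) factor, so penalty values scale with the
(unnormalized) Gram matrix; with standardized columns ``x_j' x_j = n-1``.

PLS uses the NIPALS recursion with X-deflation (single response), and the
regression vector is recovered as ``W (P'W)^{-1} q``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .datamodel import (
    SpectraDataset,
    StandardizationStats,
    identity_stats,
    standardize,
)

__all__ = [
    "LinearModel",
    "PlsDecomposition",
    "EnetPenalty",
    "fit_ols",
    "fit_pls",
    "fit_enet",
    "predict",
    "enet_grid_search",
    "kkt_residual",
    "default_penalty_grids",
]


@dataclass(frozen=True)
class EnetPenalty:
    """Elastic-net penalty weights: ``lambda1`` (L1), ``lambda2`` (L2)."""

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be nonnegative")


@dataclass(frozen=True)
class PlsDecomposition:
    """NIPALS factorization: scores T (n×h), loadings P (p×h), weights
    W (p×h) and y-loadings q (h,). Score columns are mutually orthogonal
    and the X-reconstruction residual is non-increasing in h."""

    T: np.ndarray
    P: np.ndarray
    W: np.ndarray
    q: np.ndarray

    @property
    def h(self) -> int:
        return self.T.shape[1]


@dataclass(frozen=True)
class LinearModel:
    """A fitted linear calibration model.

    ``beta_std`` lives on the standardized scale; ``beta_raw`` and
    ``intercept_raw`` express the same model on original units, so that
    ``X_raw @ beta_raw + intercept_raw`` equals the standardized pathway.
    """

    beta_std: np.ndarray
    beta_raw: np.ndarray
    intercept_raw: float
    method: str
    hyperparams: dict
    stats: StandardizationStats

    @classmethod
    def from_std(
        cls,
        beta_std: np.ndarray,
        stats: StandardizationStats,
        method: str,
        hyperparams: dict | None = None,
    ) -> "LinearModel":
        beta_std = np.asarray(beta_std, dtype=float)
        beta_raw = beta_std * stats.y_scale / stats.x_scale if beta_std.size else beta_std
        intercept = stats.y_mean - float(beta_raw @ stats.x_mean) if beta_std.size else stats.y_mean
        return cls(beta_std, beta_raw, float(intercept), method, hyperparams or {}, stats)

    @property
    def p(self) -> int:
        return self.beta_std.shape[0]

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta_std))


def predict(model: LinearModel, X_new: np.ndarray) -> np.ndarray:
    """Predict raw-scale responses for raw-scale spectra ``X_new``."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.p:
        raise ValueError(
            f"X_new has {X_new.shape[1] if X_new.ndim == 2 else '?'} columns, "
            f"model expects {model.p}"
        )
    if model.p == 0:
        return np.full(X_new.shape[0], model.intercept_raw)
    yhat_std = model.stats.apply_x(X_new) @ model.beta_std
    return np.asarray(model.stats.invert_y(yhat_std))


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    stats: StandardizationStats | None = None,
    allow_pinv: bool = False,
) -> LinearModel:
    """Ordinary least squares on standardized data.

    Requires a full-column-rank X with n > p unless ``allow_pinv`` is set,
    in which case the minimum-norm pseudo-inverse solution is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not allow_pinv and n <= p:
        raise ValueError(f"OLS needs n > p (got n={n}, p={p}); set allow_pinv to override")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p and not allow_pinv:
        raise ValueError(f"X is rank deficient (rank {rank} < p={p}); set allow_pinv to override")
    return LinearModel.from_std(beta, stats or identity_stats(p), "OLS")


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    h: int,
    stats: StandardizationStats | None = None,
) -> tuple[LinearModel, PlsDecomposition]:
    """NIPALS partial least squares with ``h`` latent components.

    Each component maximizes covariance between an X-score and the current
    y residual; X is deflated after every component. If the y-covariance is
    numerically exhausted before ``h`` components, the achieved number is
    returned with a warning.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    h_max = min(n - 1, p)
    if not 1 <= h <= h_max:
        raise ValueError(f"h must lie in [1, {h_max}], got {h}")

    Ts, Ps, Ws, qs = [], [], [], []
    r = y.copy()
    for _ in range(h):
        w = X.T @ r
        nw = np.linalg.norm(w)
        if nw < 1e-12 * max(1.0, np.linalg.norm(y)):
            warnings.warn(
                f"PLS stopped early at {len(Ts)} of {h} components "
                "(y covariance exhausted)",
                stacklevel=2,
            )
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-30:
            warnings.warn(
                f"PLS stopped early at {len(Ts)} of {h} components "
                "(zero score norm)",
                stacklevel=2,
            )
            break
        p_load = X.T @ t / tt
        q_a = float(r @ t) / tt
        X -= np.outer(t, p_load)
        r = r - q_a * t
        Ts.append(t)
        Ps.append(p_load)
        Ws.append(w)
        qs.append(q_a)
    if not Ts:
        raise ValueError("PLS could not extract any component (y uncorrelated with X)")
    T = np.column_stack(Ts)
    P = np.column_stack(Ps)
    W = np.column_stack(Ws)
    q = np.asarray(qs)
    beta = W @ np.linalg.solve(P.T @ W, q)
    model = LinearModel.from_std(
        beta, stats or identity_stats(p), "PLS", {"h": T.shape[1]}
    )
    return model, PlsDecomposition(T, P, W, q)


# --------------------------------------------------------------------------
# elastic net: coordinate descent on the covariance (Gram) formulation

@njit(cache=True)
def _cd_sweep(G, b, diag, lam1, beta, s):  # pragma: no cover - jitted
    half = lam1 / 2.0
    delta_max = 0.0
    for j in range(b.shape[0]):
        bj = beta[j]
        c = b[j] - s[j] + G[j, j] * bj
        if c > half:
            new = (c - half) / diag[j]
        elif c < -half:
            new = (c + half) / diag[j]
        else:
            new = 0.0
        if new != bj:
            d = new - bj
            for i in range(b.shape[0]):
                s[i] += G[i, j] * d
            beta[j] = new
            ad = abs(d)
            if ad > delta_max:
                delta_max = ad
    return delta_max


@njit(cache=True)
def _cd_solve(G, b, lam1, lam2, beta, tol, max_iter):  # pragma: no cover
    p = b.shape[0]
    diag = np.empty(p)
    for j in range(p):
        diag[j] = G[j, j] + lam2
    s = G @ beta
    for it in range(max_iter):
        delta = _cd_sweep(G, b, diag, lam1, beta, s)
        if delta < tol:
            return it + 1, True
    return max_iter, False


def kkt_residual(
    X: np.ndarray, y: np.ndarray, beta_naive: np.ndarray, pen: EnetPenalty
) -> float:
    """Max subgradient-stationarity violation of a naive-enet solution.

    For the objective ``||y - Xb||^2 + l1||b||_1 + l2||b||_2^2`` the
    optimum satisfies, coordinate-wise with g = 2 X'(Xb - y) + 2 l2 b:
    ``|g_j| <= l1`` where ``b_j = 0`` and ``g_j + l1 sign(b_j) = 0``
    elsewhere. Returns the largest violation across coordinates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    g = 2.0 * (X.T @ (X @ beta_naive - y)) + 2.0 * pen.lambda2 * beta_naive
    zero = beta_naive == 0
    viol = np.where(
        zero,
        np.maximum(np.abs(g) - pen.lambda1, 0.0),
        np.abs(g + pen.lambda1 * np.sign(beta_naive)),
    )
    return float(viol.max()) if viol.size else 0.0


def fit_enet(
    X: np.ndarray,
    y: np.ndarray,
    pen: EnetPenalty,
    stats: StandardizationStats | None = None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    beta0: np.ndarray | None = None,
    kkt_tol: float = 1e-6,
) -> LinearModel:
    """Elastic net on standardized data, rescaled by ``(1 + lambda2/n)``.

    ``beta_std`` is the corrected elastic-net estimator: the naive
    minimizer of the penalized RSS multiplied by ``1 + lambda2/n``. The
    naive minimizer itself is kept in ``hyperparams['beta_naive']`` and is
    certified against the subgradient KKT conditions; non-convergence
    raises with the final KKT residual.

    ``beta0`` provides a warm start (naive scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    G = np.ascontiguousarray(X.T @ X)
    b = X.T @ y
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    # iterate until the subgradient certificate itself passes: the sweep
    # tolerance on coefficient changes is tightened until the KKT residual
    # clears kkt_tol (absolute, on the gradient scale of this objective)
    n_iter = 0
    sweep_tol = tol
    while True:
        it, converged = _cd_solve(G, b, pen.lambda1, pen.lambda2, beta, sweep_tol, max_iter)
        n_iter += it
        resid = kkt_residual(X, y, beta, pen)
        if converged and resid <= kkt_tol:
            break
        if not converged or sweep_tol < 1e-15:
            raise RuntimeError(
                f"elastic net did not converge in {n_iter} sweeps "
                f"(KKT residual {resid:.3e})"
            )
        sweep_tol *= 1e-3
    scale = 1.0 + pen.lambda2 / n
    model = LinearModel.from_std(
        scale * beta,
        stats or identity_stats(p),
        "ENET",
        {
            "lambda1": pen.lambda1,
            "lambda2": pen.lambda2,
            "beta_naive": beta,
            "n_iter": n_iter,
            "kkt_residual": resid,
        },
    )
    return model


def default_penalty_grids(
    X_std: np.ndarray,
    y_std: np.ndarray,
    l1_fractions: Sequence[float] = (0.5, 0.2, 0.1, 0.05, 0.02),
    lambda2_grid: Sequence[float] = (1.0, 10.0, 100.0),
) -> tuple[list[float], list[float]]:
    """Log-spaced default grids anchored at the smallest all-zero L1 weight.

    ``lambda_max = 2 max_j |x_j' y|`` kills every coefficient under this
    objective's scaling; the L1 grid is the given fractions of it.
    """
    lam_max = 2.0 * float(np.abs(np.asarray(X_std).T @ np.asarray(y_std)).max())
    return [f * lam_max for f in l1_fractions], list(lambda2_grid)


def enet_grid_search(
    ds_train: SpectraDataset,
    grid1: Sequence[float],
    grid2: Sequence[float],
    folds: int = 9,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> tuple[EnetPenalty, LinearModel]:
    """Pick ``(lambda1, lambda2)`` by K-fold cross-validated RMSEP.

    Every grid pair is scored with the same seeded fold partition; the
    winner (smallest CV RMSEP, ties broken by smaller lambda1 then smaller
    lambda2 within 1e-12) is refit on the full training set. If the CV
    scores carry no information at all (zero spread with an all-zero best
    model), the largest-penalty point is returned with a warning.
    """
    from .criteria import kfold_cv  # local import to avoid a cycle

    grid1 = list(grid1)
    grid2 = list(grid2)
    if not grid1 or not grid2:
        raise ValueError("penalty grids must be nonempty")

    def make_fitter(pen: EnetPenalty):
        def fitter(ds: SpectraDataset) -> LinearModel:
            std, stats = standardize(ds)
            return fit_enet(std.X, std.y, pen, stats=stats, tol=tol, max_iter=max_iter)

        return fitter

    pairs = [(l1, l2) for l1 in grid1 for l2 in grid2]
    scores = np.array(
        [kfold_cv(ds_train, make_fitter(EnetPenalty(l1, l2)), folds, seed) for l1, l2 in pairs]
    )
    tied = np.flatnonzero(scores <= scores.min() + 1e-12)
    best = min(tied, key=lambda i: (pairs[i][0], pairs[i][1]))
    std, stats = standardize(ds_train)
    pen = EnetPenalty(*pairs[best])
    model = fit_enet(std.X, std.y, pen, stats=stats, tol=tol, max_iter=max_iter)
    if scores.max() - scores.min() < 1e-15 and model.n_nonzero == 0:
        warnings.warn(
            "all grid points gave identical all-zero models; "
            "returning the largest-penalty point",
            stacklevel=2,
        )
        pen = EnetPenalty(max(grid1), max(grid2))
        model = fit_enet(std.X, std.y, pen, stats=stats, tol=tol, max_iter=max_iter)
    return pen, model
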
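"""Coefficient-based variable selection for collinear spectra.

Three selectors share the idea of ranking channels by the magnitude of a
fitted regression coefficient:

* **PLS-BETA** — rank by the PLS regression vector and keep the shortest
  prefix whose coefficient-norm ratio exceeds a threshold ``alpha``.
* **FSS** — greedy forward stepwise OLS; the subset size is chosen by BIC
  along the greedy path.
* **Enet-BETA** — the headline procedure: fit an elastic net on all
  channels, rank by |coefficient|, refit the elastic net on every prefix
  of the ranking, locate the RMSEP-minimizing prefix size ``i*``, then
  relax to the smallest size ``i`` whose RMSEP is within a factor
  ``1/conf`` of the optimum (``RMSEP(i*)/RMSEP(i) >= conf``, the
  "hypothesis testing" rule with confidence level 0.9 by default).

Prefix RMSEP is, by default, a seeded K-fold cross-validated RMSEP on the
training set so no test information enters selection; an alternative
``eval_policy="holdout"`` scores prefixes on a supplied held-out set,
mirroring workflows that report the selection curve on the test set.
"""

from __future__ import annotations

import numpy as np

from .criteria import fold_indices, rmsep
from .datamodel import SpectraDataset, StandardizationStats, standardize
from .linear_core import EnetPenalty, LinearModel, fit_enet, fit_ols, fit_pls, predict

from dataclasses import dataclass, field

__all__ = [
    "SelectionResult",
    "rank_by_coefficient",
    "ht_reduce",
    "pls_beta_select",
    "fss_select",
    "enet_beta_select",
]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a variable-selection run.

    ``ranking`` is a permutation of all channel indices (selection order
    first). ``rmsep_curve`` holds the prefix-RMSEP values for sizes
    ``1…m`` where the method defines such a curve (Enet-BETA), else
    ``None`` — FSS and PLS-BETA record their own path diagnostics in
    ``extras``. ``i_star`` is the optimal subset size, ``i_ht`` the
    relaxed size actually selected (``i_ht <= i_star``), and
    ``final_model`` is refit on ``selected`` only.
    """

    method: str
    ranking: np.ndarray
    rmsep_curve: np.ndarray | None
    i_star: int
    i_ht: int
    selected: np.ndarray
    final_model: LinearModel
    extras: dict = field(default_factory=dict)

    @property
    def novs(self) -> int:
        """Number of selected variables."""
        return int(len(self.selected))

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Predict from raw full-width spectra using the final model."""
        X_raw = np.asarray(X_raw, dtype=float)
        return predict(self.final_model, X_raw[:, self.selected])


def rank_by_coefficient(model: LinearModel) -> np.ndarray:
    """Channel indices in descending |standardized coefficient| order.

    Ties (including all-zero coefficients) break by ascending channel
    index, so the ranking is deterministic.
    """
    beta = np.abs(model.beta_std)
    return np.lexsort((np.arange(beta.size), -beta))


def ht_reduce(curve: np.ndarray, i_star: int, conf: float) -> int:
    """Relax the optimal subset size using the RMSEP-ratio rule.

    Returns the smallest size ``i <= i_star`` with
    ``curve[i_star]/curve[i] >= conf`` (sizes are 1-based into ``curve``),
    or ``i_star`` itself when nothing smaller qualifies. A zero RMSEP at
    ``i`` qualifies only when the optimum is also zero (ratio defined as
    1 there).
    """
    curve = np.asarray(curve, dtype=float)
    if not 1 <= i_star <= curve.size:
        raise ValueError(f"i_star={i_star} out of range for a curve of length {curve.size}")
    if not 0.0 < conf <= 1.0:
        raise ValueError("conf must lie in (0, 1]")
    c_star = curve[i_star - 1]
    for i in range(1, i_star + 1):
        c_i = curve[i - 1]
        if c_i == 0.0:
            ratio = 1.0 if c_star == 0.0 else 0.0
        else:
            ratio = c_star / c_i
        if ratio >= conf:
            return i
    return i_star


def _subset_stats(stats: StandardizationStats, idx: np.ndarray) -> StandardizationStats:
    return StandardizationStats(
        stats.x_mean[idx], stats.x_scale[idx], stats.y_mean, stats.y_scale
    )


def pls_beta_select(ds_train: SpectraDataset, h: int, alpha: float) -> SelectionResult:
    """PLS regression-coefficient selection with a norm-ratio stop rule.

    Channels are taken in descending |beta| order until the selected
    sub-vector carries more than a fraction ``alpha`` of the full
    coefficient 2-norm (``>=`` at the boundary ``alpha = 1`` so selection
    always terminates). The final model is PLS refit on the selected
    channels with at most the original number of components.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    std, stats = standardize(ds_train)
    model, _ = fit_pls(std.X, std.y, h, stats=stats)
    ranking = rank_by_coefficient(model)
    sorted_sq = model.beta_std[ranking] ** 2
    total = float(np.sqrt(sorted_sq.sum()))
    ratios = np.sqrt(np.cumsum(sorted_sq)) / total
    if alpha < 1.0:
        hits = np.flatnonzero(ratios > alpha)
    else:
        hits = np.flatnonzero(ratios >= alpha - 1e-15)
    k = int(hits[0]) + 1 if hits.size else model.p
    selected = ranking[:k]
    h_sel = min(model.hyperparams["h"], k, ds_train.n_samples - 1)
    final, _ = fit_pls(std.X[:, selected], std.y, h_sel, stats=_subset_stats(stats, selected))
    return SelectionResult(
        method="pls-beta",
        ranking=ranking,
        rmsep_curve=None,
        i_star=k,
        i_ht=k,
        selected=selected,
        final_model=final,
        extras={"norm_ratio": ratios, "h": model.hyperparams["h"], "alpha": alpha},
    )


def fss_select(ds_train: SpectraDataset, max_size: int | None = None) -> SelectionResult:
    """Greedy forward stepwise OLS with a BIC-selected subset size.

    Starting from the intercept-only model, each step adds the channel
    giving the largest decrease in residual sum of squares (ties break by
    ascending channel index). The greedy path is computed by progressive
    orthogonalization, so no Gram matrix is ever inverted; its length is
    capped at ``min(p, n-2)`` to keep the OLS fits well-posed with an
    intercept. The final size is the BIC argmin along the path (possibly
    0 = intercept only).
    """
    n, p = ds_train.n_samples, ds_train.n_channels
    if n < 3:
        raise ValueError("forward selection requires at least 3 samples")
    std, stats = standardize(ds_train)
    cap = min(p, n - 2)
    if max_size is not None:
        cap = min(cap, max_size)

    Xp = std.X.copy()
    r = std.y.copy()
    norms2 = (Xp**2).sum(axis=0)
    orig2 = norms2.copy()
    available = np.ones(p, dtype=bool)
    chosen: list[int] = []
    ssr_std = [float(r @ r)]  # size-0 model: y is centred, so SSR = SST
    for _ in range(cap):
        with np.errstate(divide="ignore", invalid="ignore"):
            gains = (Xp.T @ r) ** 2 / norms2
        degenerate = norms2 <= 1e-10 * np.maximum(orig2, 1.0)
        gains[~available | degenerate] = -np.inf
        j = int(np.argmax(gains))  # argmax takes the first = lowest index on ties
        if not np.isfinite(gains[j]):
            break
        q = Xp[:, j] / np.sqrt(norms2[j])
        ssr_std.append(ssr_std[-1] - float(q @ r) ** 2)
        r = r - q * float(q @ r)
        proj = q @ Xp
        Xp -= np.outer(q, proj)
        norms2 = np.maximum(norms2 - proj**2, 0.0)
        available[j] = False
        chosen.append(j)

    from .criteria import aic_bic

    y2 = stats.y_scale**2
    bic_path = np.array(
        [aic_bic(max(s, 0.0) * y2, n, k)[1] for k, s in enumerate(ssr_std)]
    )
    k_best = int(np.argmin(bic_path))
    selected = np.asarray(chosen[:k_best], dtype=int)
    if k_best == 0:
        empty = StandardizationStats(np.zeros(0), np.ones(0), stats.y_mean, stats.y_scale)
        final = LinearModel.from_std(np.zeros(0), empty, "OLS", {"intercept_only": True})
    else:
        final = fit_ols(std.X[:, selected], std.y, stats=_subset_stats(stats, selected))
    ranking = np.concatenate(
        [np.asarray(chosen, dtype=int), np.setdiff1d(np.arange(p), chosen)]
    ).astype(int)
    return SelectionResult(
        method="fss",
        ranking=ranking,
        rmsep_curve=None,
        i_star=k_best,
        i_ht=k_best,
        selected=selected,
        final_model=final,
        extras={
            "bic_path": bic_path,
            "ssr_path": np.asarray(ssr_std) * y2,
            "path": np.asarray(chosen, dtype=int),
        },
    )


def enet_beta_select(
    ds_train: SpectraDataset,
    pen: EnetPenalty,
    conf: float = 0.9,
    eval_policy: str = "cv",
    cv_folds: int = 9,
    seed: int = 0,
    holdout: SpectraDataset | None = None,
    full_path: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> SelectionResult:
    """Elastic-net coefficient ranking with an RMSEP-minimum subset search.

    Procedure: (1) fit the elastic net on all channels of the standardized
    training data; (2) rank channels by |coefficient| descending; (3) for
    every prefix size ``1…m`` (``m`` = elastic-net support size, or ``p``
    with ``full_path=True``) refit the elastic net — same penalties — on
    the prefix and score its RMSEP; (4) ``i*`` = curve argmin (smallest
    size on ties); (5) ``i_ht`` = smallest size whose RMSEP is within a
    factor ``1/conf`` of the optimum; (6) refit on the first ``i_ht``
    ranked channels.

    ``eval_policy="cv"`` (default) scores each prefix by seeded
    ``cv_folds``-fold cross-validated RMSEP on the training set, with
    per-fold standardization; ``eval_policy="holdout"`` refits on the full
    training set and scores on ``holdout``.
    """
    if eval_policy not in ("cv", "holdout"):
        raise ValueError(f"unknown eval_policy {eval_policy!r}")
    if eval_policy == "holdout" and holdout is None:
        raise ValueError("holdout evaluation requires a holdout dataset")
    std, stats = standardize(ds_train)
    full_model = fit_enet(std.X, std.y, pen, stats=stats, tol=tol, max_iter=max_iter)
    if full_model.n_nonzero == 0:
        raise ValueError("penalty too large, no ranking signal (all coefficients zero)")
    ranking = rank_by_coefficient(full_model)
    m = ds_train.n_channels if full_path else full_model.n_nonzero

    if eval_policy == "cv":
        folds = fold_indices(ds_train.n_samples, cv_folds, seed)
        all_rows = np.arange(ds_train.n_samples)
        per_fold = np.empty((len(folds), m))
        for f, held in enumerate(folds):
            train_rows = np.setdiff1d(all_rows, held)
            sub_std, sub_stats = standardize(ds_train.take(train_rows))
            X_held = ds_train.X[held]
            beta_prev = np.zeros(0)
            for i in range(1, m + 1):
                idx = ranking[:i]
                beta0 = np.append(beta_prev, 0.0)
                mdl = fit_enet(
                    sub_std.X[:, idx], sub_std.y, pen,
                    stats=_subset_stats(sub_stats, idx),
                    tol=tol, max_iter=max_iter, beta0=beta0,
                )
                beta_prev = mdl.hyperparams["beta_naive"]
                per_fold[f, i - 1] = rmsep(ds_train.y[held], predict(mdl, X_held[:, idx]))
        curve = per_fold.mean(axis=0)
    else:
        curve = np.empty(m)
        beta_prev = np.zeros(0)
        for i in range(1, m + 1):
            idx = ranking[:i]
            beta0 = np.append(beta_prev, 0.0)
            mdl = fit_enet(
                std.X[:, idx], std.y, pen,
                stats=_subset_stats(stats, idx),
                tol=tol, max_iter=max_iter, beta0=beta0,
            )
            beta_prev = mdl.hyperparams["beta_naive"]
            curve[i - 1] = rmsep(holdout.y, predict(mdl, holdout.X[:, idx]))

    if not np.all(np.isfinite(curve)):
        raise ValueError("non-finite RMSEP encountered on the prefix curve")
    i_star = int(np.argmin(curve)) + 1  # first minimum = smallest size on ties
    i_ht = ht_reduce(curve, i_star, conf)
    selected = ranking[:i_ht]
    final = fit_enet(
        std.X[:, selected], std.y, pen,
        stats=_subset_stats(stats, selected), tol=tol, max_iter=max_iter,
    )
    return SelectionResult(
        method="enet-beta",
        ranking=ranking,
        rmsep_curve=curve,
        i_star=i_star,
        i_ht=i_ht,
        selected=selected,
        final_model=final,
        extras={
            "penalty": pen,
            "conf": conf,
            "eval_policy": eval_policy,
            "support_size": full_model.n_nonzero,
            "full_model": full_model,
        },
    )
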
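"""Evaluation criteria for calibration models: RMSEP, NMSE, R², AIC/BIC, CV.

All criteria are computed on the original (raw) response scale. RMSEP is
the root-mean-square error of prediction, sqrt(SSE/n); a ``no_sqrt``
switch reproduces the plain SSE/n variant for comparability with sources
that typeset the formula without the radical. NMSE divides the SSE by the
response's raw sum of squares (Σy²), so unlike R² it is *not* invariant
to a common shift of y and ŷ.

AIC/BIC use the Gaussian likelihood with the error variance profiled out
and additive constants dropped: only differences between models fitted to
the same data are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .datamodel import SpectraDataset

__all__ = [
    "FitReport",
    "rmsep",
    "nmse",
    "r_squared",
    "aic_bic",
    "fold_indices",
    "kfold_cv",
    "fit_report",
]

#: SSR/n below this floor is clamped before taking the log in AIC/BIC.
VARIANCE_FLOOR = 1e-12


def _check_pair(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty response vector")
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: y has {y.size}, yhat has {yhat.size}")
    return y, yhat


def rmsep(y: np.ndarray, yhat: np.ndarray, no_sqrt: bool = False) -> float:
    """Root-mean-square error of prediction, sqrt(Σ(y−ŷ)²/n).

    ``no_sqrt=True`` returns the mean squared error Σ(y−ŷ)²/n instead.
    """
    y, yhat = _check_pair(y, yhat)
    mse = float(np.mean((y - yhat) ** 2))
    return mse if no_sqrt else float(np.sqrt(mse))


def nmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Normalized mean square error, Σ(y−ŷ)²/Σy²."""
    y, yhat = _check_pair(y, yhat)
    denom = float(y @ y)
    if denom == 0:
        raise ValueError("NMSE undefined for an all-zero response")
    return float(np.sum((y - yhat) ** 2)) / denom


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 − SSR/SST."""
    y, yhat = _check_pair(y, yhat)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R² undefined for a constant response")
    ssr = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssr / sst


def aic_bic(ssr: float, n: int, k: int) -> tuple[float, float]:
    """Gaussian plug-in information criteria from a residual sum of squares.

    With the error variance profiled out and shared constants dropped,
    −2 ln L = n ln(SSR/n), so AIC = n ln(SSR/n) + 2k and
    BIC = n ln(SSR/n) + k ln(n). SSR/n below the variance floor is clamped
    (with a warning) so a perfect interpolant does not produce −inf.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if ssr < 0:
        raise ValueError("ssr must be nonnegative")
    mse = ssr / n
    if mse < VARIANCE_FLOOR:
        warnings.warn(
            f"SSR/n = {mse:.3e} clamped to the variance floor {VARIANCE_FLOOR:.0e}",
            stacklevel=2,
        )
        mse = VARIANCE_FLOOR
    base = n * float(np.log(mse))
    return base + 2.0 * k, base + k * float(np.log(n))


@dataclass(frozen=True)
class FitReport:
    """Summary metrics for one fitted model on one (y, ŷ) pair."""

    rmsep: float
    nmse: float
    r2: float
    n: int
    k: int
    aic: float
    bic: float


def fit_report(y: np.ndarray, yhat: np.ndarray, k: int) -> FitReport:
    """Bundle RMSEP/NMSE/R²/AIC/BIC for predictions ``yhat`` of ``y``.

    ``k`` is the number of selected variables charged by AIC/BIC.
    """
    y, yhat = _check_pair(y, yhat)
    ssr = float(np.sum((y - yhat) ** 2))
    aic, bic = aic_bic(ssr, y.size, k)
    return FitReport(rmsep(y, yhat), nmse(y, yhat), r_squared(y, yhat), y.size, k, aic, bic)


def fold_indices(n: int, K: int, seed: int) -> list[np.ndarray]:
    """Seeded K-fold partition: contiguous blocks of a shuffled index set."""
    if K < 2:
        raise ValueError("K must be at least 2")
    if n < K:
        raise ValueError(f"cannot make {K} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, K)]


def kfold_cv(
    ds: SpectraDataset,
    fitter: Callable[[SpectraDataset], "object"],
    K: int,
    seed: int,
) -> float:
    """Mean held-out RMSEP over a seeded K-fold partition.

    ``fitter`` maps a raw-scale training dataset to a fitted
    :class:`~enetbeta.linear_core.LinearModel`; it is responsible for its
    own standardization, so fold statistics are always estimated on the
    K−1 training folds only.
    """
    from .linear_core import predict  # local import to avoid a cycle

    folds = fold_indices(ds.n_samples, K, seed)
    all_rows = np.arange(ds.n_samples)
    scores = []
    for held in folds:
        train_rows = np.setdiff1d(all_rows, held)
        model = fitter(ds.take(train_rows))
        yhat = predict(model, ds.X[held])
        scores.append(rmsep(ds.y[held], yhat))
    return float(np.mean(scores))
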
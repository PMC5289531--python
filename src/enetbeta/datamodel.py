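"""Core data containers, standardization and delimited-text I/O.

Spectrum calibration data arrive as a numeric matrix ``X`` (n samples ×
p wavelength channels) together with a single response vector ``y``
(a concentration, in whatever physical unit the reference method uses).
All model fitting in this package happens on the *standardized* scale —
each channel and the response centred to zero mean and scaled to unit
sample standard deviation — while every reported error metric is computed
on the original concentration scale after de-standardizing predictions.

The sample standard deviation uses ``ddof=1`` throughout; the convention
is held constant everywhere so fits, cross-validation folds and inverse
transforms stay internally consistent. Standardization statistics are
always estimated on training data only and reused for test data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraDataset",
    "StandardizationStats",
    "standardize",
    "read_dataset",
    "write_dataset",
    "split_train_test",
]


@dataclass(frozen=True)
class SpectraDataset:
    """An (X, y) calibration dataset with channel labels and sample ids.

    Parameters
    ----------
    X : (n, p) float array — predictor matrix, no missing values.
    y : (n,) float array — response (concentration), no missing values.
    channel_labels : p strings (wavelengths or synthetic ``v1…vp``).
    sample_ids : n strings, auto-numbered ``s1…sn`` when omitted.
    """

    X: np.ndarray
    y: np.ndarray
    channel_labels: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {np.shape(self.X)}")
        n, p = X.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got n={n}")
        if p < 1:
            raise ValueError("need at least 1 channel")
        if len(y) != n:
            raise ValueError(f"length(y)={len(y)} != rows(X)={n}")
        if not np.all(np.isfinite(X)):
            i, j = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(f"X has a missing/non-finite value at row {i}, column {j}")
        if not np.all(np.isfinite(y)):
            i = int(np.argwhere(~np.isfinite(y))[0])
            raise ValueError(f"y has a missing/non-finite value at row {i}")
        labels = tuple(self.channel_labels) or tuple(f"v{j + 1}" for j in range(p))
        if len(labels) != p:
            raise ValueError(f"{len(labels)} channel labels for p={p} channels")
        ids = tuple(self.sample_ids) or tuple(f"s{i + 1}" for i in range(n))
        if len(ids) != n:
            raise ValueError(f"{len(ids)} sample ids for n={n} samples")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "channel_labels", labels)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def select_channels(self, indices: Sequence[int]) -> "SpectraDataset":
        """Dataset restricted to the given channel indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraDataset(
            self.X[:, idx],
            self.y,
            tuple(self.channel_labels[j] for j in idx),
            self.sample_ids,
        )

    def take(self, rows: Sequence[int]) -> "SpectraDataset":
        """Dataset restricted to the given sample rows (order kept)."""
        idx = np.asarray(rows, dtype=int)
        return SpectraDataset(
            self.X[idx],
            self.y[idx],
            self.channel_labels,
            tuple(self.sample_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class StandardizationStats:
    """Per-column location/scale for X and scalar location/scale for y.

    ``x_scale`` entries and ``y_scale`` are strictly positive (zero-variance
    columns are rejected before construction), so the transform is
    invertible exactly.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_mean", np.asarray(self.x_mean, dtype=float))
        object.__setattr__(self, "x_scale", np.asarray(self.x_scale, dtype=float))
        if self.x_scale.size and not np.all(self.x_scale > 0):
            raise ValueError("all x_scale entries must be strictly positive")
        if not self.y_scale > 0:
            raise ValueError("y_scale must be strictly positive")

    @property
    def p(self) -> int:
        return self.x_mean.shape[0]

    def apply_x(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale

    def invert_x(self, X_std: np.ndarray) -> np.ndarray:
        return np.asarray(X_std, dtype=float) * self.x_scale + self.x_mean

    def apply_y(self, y: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_scale

    def invert_y(self, y_std: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(y_std, dtype=float) * self.y_scale + self.y_mean


def identity_stats(p: int) -> StandardizationStats:
    """Stats representing 'no transform' (zero means, unit scales)."""
    return StandardizationStats(np.zeros(p), np.ones(p), 0.0, 1.0)


def standardize(ds: SpectraDataset) -> tuple[SpectraDataset, StandardizationStats]:
    """Centre and scale every X column and y to mean 0, sample s.d. 1 (ddof=1).

    Raises
    ------
    ValueError
        If any column (or y) has zero sample standard deviation; the error
        names the offending channel.
    """
    if ds.n_samples < 2:
        raise ValueError("standardize requires at least 2 samples")
    x_mean = ds.X.mean(axis=0)
    x_scale = ds.X.std(axis=0, ddof=1)
    bad = np.flatnonzero(x_scale == 0)
    if bad.size:
        names = ", ".join(ds.channel_labels[j] for j in bad[:5])
        raise ValueError(f"zero-variance channel(s): {names}")
    y_mean = float(ds.y.mean())
    y_scale = float(ds.y.std(ddof=1))
    if y_scale == 0:
        raise ValueError("response y has zero variance")
    stats = StandardizationStats(x_mean, x_scale, y_mean, y_scale)
    std = SpectraDataset(
        stats.apply_x(ds.X), np.asarray(stats.apply_y(ds.y)),
        ds.channel_labels, ds.sample_ids,
    )
    return std, stats


def read_dataset(
    path: str,
    delimiter: str = ",",
    has_header: bool = True,
    response_column: str | int = "response",
) -> SpectraDataset:
    """Read a delimited text file into a :class:`SpectraDataset`.

    All non-response numeric columns become X in file order; channel labels
    are taken from the header when present, else ``v1…vp``. The response
    column may be named (header files) or given as a 0-based column index.
    Ragged rows, non-numeric cells and a missing response column raise
    ``ValueError`` with the row/column location.
    """
    try:
        df = pd.read_csv(
            path, sep=delimiter, header=0 if has_header else None,
            dtype=str, engine="python", skipinitialspace=True,
        )
    except pd.errors.ParserError as exc:  # ragged rows
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    columns = list(df.columns)
    if isinstance(response_column, int):
        if not 0 <= response_column < len(columns):
            raise ValueError(
                f"{path}: response column index {response_column} out of range "
                f"(file has {len(columns)} columns)"
            )
        resp_col = columns[response_column]
    else:
        if not has_header:
            raise ValueError("response column by name requires a header row")
        if response_column not in columns:
            raise ValueError(
                f"{path}: response column {response_column!r} not found; "
                f"columns are {columns}"
            )
        resp_col = response_column

    numeric = {}
    for col in columns:
        raw = df[col].to_numpy(dtype=object)
        try:
            # numpy's strtod is correctly rounded, so values round-trip
            vals = raw.astype(np.float64)
            if np.isnan(vals).any():
                raise ValueError
        except (ValueError, TypeError):
            for row, cell in enumerate(raw):
                if pd.isna(cell):
                    raise ValueError(
                        f"{path}: missing value at row {row}, column {col!r}"
                    ) from None
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at row {row}, column {col!r}"
                    ) from None
            raise ValueError(f"{path}: non-finite value in column {col!r}")
        numeric[col] = vals

    y = numeric.pop(resp_col)
    if not numeric:
        raise ValueError(f"{path}: no predictor columns besides the response")
    X = np.column_stack([numeric[c] for c in columns if c != resp_col])
    if has_header:
        labels = tuple(str(c) for c in columns if c != resp_col)
    else:
        labels = tuple(f"v{j + 1}" for j in range(X.shape[1]))
    return SpectraDataset(X, y, labels)


def write_dataset(
    ds: SpectraDataset,
    path: str,
    delimiter: str = ",",
    response_name: str = "response",
) -> None:
    """Write the dataset as delimited text, response in the last column.

    Floats are written at full ``repr`` precision so a read/write cycle
    round-trips values exactly.
    """
    df = pd.DataFrame(ds.X, columns=list(ds.channel_labels))
    df[response_name] = ds.y
    # %.17g preserves every float64 bit across a write/read cycle
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def split_train_test(
    ds: SpectraDataset, test_fraction: float, seed: int
) -> tuple[SpectraDataset, SpectraDataset]:
    """Seeded random partition of the rows into train and test sets.

    Row order within each side follows the original dataset. The split is
    disjoint and exhaustive, deterministic given the seed. Raises if the
    training side would have fewer than 2 samples or the test side none.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = ds.n_samples
    n_test = int(round(n * test_fraction))
    n_train = n - n_test
    if n_train < 2 or n_test < 1:
        raise ValueError(
            f"degenerate split: {n_train} train / {n_test} test from n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_rows = np.sort(perm[:n_test])
    train_rows = np.sort(perm[n_test:])
    return ds.take(train_rows), ds.take(test_rows)
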
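"""Synthetic spectrum-like datasets with planted sparse truth.

Real NIR calibration data have two properties that make variable
selection hard: the channels trace smooth absorbance curves, so
neighbouring wavelengths are almost collinear (pairwise correlations
routinely above 0.95), and only a small subset of channels carries
quality-related signal. The generator emulates both:

* a handful of latent Gaussian "peak" profiles, shared across samples
  with random loadings, provide the smooth, strongly collinear backbone;
* an AR(1) process across channels (parameter ``rho``) adds
  channel-local structure so adjacent correlations are controlled rather
  than accidental;
* the response is a sparse linear combination of a few channels (the
  planted support, clustered on contiguous channels so the elastic net's
  grouping effect is exercised) plus Gaussian noise scaled to a requested
  signal-to-noise variance ratio.

It is a statistical stand-in, not a physical (Beer–Lambert) forward
model: peak shapes, baselines and channel scales are stylized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import SpectraDataset

__all__ = ["SyntheticTruth", "generate_spectra", "score_recovery"]

#: fraction of each channel's variance carried by the shared smooth peaks
#: (the rest is AR(1) channel noise); chosen so the smooth component
#: dominates, as in real absorbance spectra.
PEAK_WEIGHT = 0.7


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset, for recovery scoring.

    ``beta_true`` is expressed on the raw channel scale of the returned
    ``X`` (so ``y ≈ X @ beta_true + const`` up to noise); it is nonzero
    exactly on ``support``.
    """

    support: np.ndarray
    beta_true: np.ndarray
    snr: float
    peak_centers: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=int)
        beta = np.asarray(self.beta_true, dtype=float)
        if support.size < 1:
            raise ValueError("support must contain at least one channel")
        nz = np.flatnonzero(beta)
        if not np.array_equal(np.sort(support), nz):
            raise ValueError("beta_true must be nonzero exactly on the support")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "beta_true", beta)


def _support_clusters(p: int, k_true: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Split k_true channels into a few contiguous, non-overlapping runs."""
    n_clusters = min(max(1, int(np.ceil(k_true / 4))), 3)
    sizes = np.full(n_clusters, k_true // n_clusters)
    sizes[: k_true % n_clusters] += 1
    clusters: list[np.ndarray] = []
    taken = np.zeros(p, dtype=bool)
    for size in sizes:
        for _ in range(1000):
            start = int(rng.integers(0, p - size + 1))
            block = np.arange(start, start + size)
            # keep one channel of clearance between clusters
            lo, hi = max(0, start - 1), min(p, start + size + 1)
            if not taken[lo:hi].any():
                taken[block] = True
                clusters.append(block)
                break
        else:  # crowded layout (k_true close to p): pack greedily
            free = np.flatnonzero(~taken)[:size]
            taken[free] = True
            clusters.append(free)
    return clusters


def generate_spectra(
    n: int,
    p: int,
    k_true: int,
    rho: float,
    snr: float,
    seed: int,
    n_peaks: int = 6,
) -> tuple[SpectraDataset, SyntheticTruth]:
    """Generate an (X, y) spectrum dataset with a planted sparse truth.

    Parameters
    ----------
    n, p : sample and channel counts (n >= 4, p >= 1).
    k_true : size of the planted support (1 <= k_true <= p).
    rho : AR(1) neighbour-correlation parameter in [0, 1). The smooth peak
        component raises realized adjacent correlations above ``rho``.
    snr : target var(signal)/var(noise) for the response (positive).
    seed : RNG seed; identical seeds give bit-identical datasets.
    """
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if not 1 <= k_true <= p:
        raise ValueError(f"k_true must lie in [1, p={p}], got {k_true}")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)

    # smooth collinear backbone: latent Gaussian peak profiles
    channels = np.arange(p, dtype=float)
    centers = np.linspace(0.05 * p, 0.95 * p, n_peaks) + rng.uniform(
        -0.04 * p, 0.04 * p, n_peaks
    )
    widths = rng.uniform(p / 12.0, p / 6.0, n_peaks)
    profiles = np.exp(-0.5 * ((channels[None, :] - centers[:, None]) / widths[:, None]) ** 2)
    scores = rng.standard_normal((n, n_peaks))
    smooth = scores @ profiles
    sd = smooth.std(axis=0, ddof=1)
    smooth = (smooth - smooth.mean(axis=0)) / np.maximum(sd, 1e-8)

    # AR(1) channel noise with unit marginal variance. Its parameter phi is
    # calibrated so the *mixture* (peaks + AR) realizes a median adjacent
    # correlation of about rho: the smooth peaks alone correlate near 1, so
    # corr ≈ w·c_peak + (1−w)·phi must be solved for phi (clamped to [0,1)).
    if p > 1:
        prof_n = profiles / np.maximum(np.linalg.norm(profiles, axis=0), 1e-12)
        c_peak = float(np.median(np.sum(prof_n[:, :-1] * prof_n[:, 1:], axis=0)))
    else:
        c_peak = 1.0
    phi = float(np.clip((rho - PEAK_WEIGHT * c_peak) / (1.0 - PEAK_WEIGHT), 0.0, 0.999))
    e = rng.standard_normal((n, p))
    ar = np.empty_like(e)
    ar[:, 0] = e[:, 0]
    scale_innov = np.sqrt(1.0 - phi**2)
    for j in range(1, p):
        ar[:, j] = phi * ar[:, j - 1] + scale_innov * e[:, j]

    Z = np.sqrt(PEAK_WEIGHT) * smooth + np.sqrt(1.0 - PEAK_WEIGHT) * ar

    # planted sparse truth: ± uniform magnitudes on contiguous clusters
    clusters = _support_clusters(p, k_true, rng)
    beta_true = np.zeros(p)
    for block in clusters:
        signs = rng.choice([-1.0, 1.0], block.size)
        beta_true[block] = signs * rng.uniform(0.5, 1.5, block.size)
    support = np.sort(np.concatenate(clusters))

    y_signal = Z @ beta_true
    sig_var = float(y_signal.var(ddof=1))
    noise = rng.standard_normal(n) * np.sqrt(sig_var / snr)
    y = y_signal + noise

    # dress the channels in spectrum-like raw units (smooth baseline/scale);
    # the stored truth is re-expressed on this raw scale so that
    # y = X @ beta_raw + const + noise holds exactly
    baseline = 1.0 + 0.5 * np.sin(2.0 * np.pi * channels / max(p, 2))
    gain = 1.0 + 0.5 * np.cos(2.0 * np.pi * channels / max(p, 2))
    amp = 0.25 * gain
    X = baseline + amp * Z
    beta_raw = beta_true / amp

    labels = tuple(f"ch{j}" for j in range(p))
    ds = SpectraDataset(X, y, labels)
    truth = SyntheticTruth(support, beta_raw, snr, centers, seed)
    return ds, truth


def score_recovery(
    selected: np.ndarray, truth: SyntheticTruth
) -> tuple[float, int]:
    """Sensitivity and false-positive count of a selected channel set.

    sensitivity = |selected ∩ support| / |support|;
    false positives = |selected \\ support|.
    """
    sel = set(int(i) for i in np.asarray(selected, dtype=int).ravel())
    sup = set(int(i) for i in truth.support)
    hits = len(sel & sup)
    return hits / len(sup), len(sel - sup)
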
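"""n:m phase-locking statistics and phase-phase diagnostics.

The central quantity is the mean resultant length of the accelerated
phase difference

    dphi_nm(t) = n * phi_gamma(t) - m * phi_theta(t)
    R_nm = | (1/N) * sum_j exp(i * dphi_nm(t_j)) |

which is 1 when the two oscillations keep a fixed n:m phase relation and
0 when the phase difference is uniform on the circle. For finite N of
independent uniform phases, E[R] ~ sqrt(pi)/2 * N**-0.5 — the small-sample
bias that makes R values incomparable across epoch lengths.

Also here: the bias-free pairwise phase consistency (PPC), the per-theta-bin
mean radial distance, and 2D phase-phase histograms with their diagonal
stripe count (the visual signature of maintained n:m relations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import PhaseSeries, wrap_phase

__all__ = [
    "PhaseDifferenceSeries",
    "NMCouplingResult",
    "PhasePhasePlot",
    "phase_difference",
    "rnm",
    "rnm_curve",
    "ppc",
    "binned_radial_distance",
    "phase_phase_histogram",
    "count_stripes",
    "uniform_resultant_expectation",
]


@dataclass
class PhaseDifferenceSeries:
    """Wrapped accelerated phase differences n*phi_gamma - m*phi_theta."""

    values: np.ndarray
    n: int
    m: int
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def N(self) -> int:
        return self.values.size


@dataclass
class NMCouplingResult:
    """R_nm over a grid of m for fixed n."""

    n: int
    m_grid: np.ndarray
    R: np.ndarray
    epoch_length_s: float

    @property
    def peak_m(self) -> int:
        """m with the highest R (ties toward smaller m)."""
        return int(self.m_grid[int(np.argmax(self.R))])


@dataclass
class PhasePhasePlot:
    """Joint histogram of (theta phase, gamma phase) counts.

    ``counts`` holds raw bin counts (theta on axis 0); ``smoothed_counts``
    the circularly Gaussian-smoothed version when smoothing was requested.
    """

    counts: np.ndarray
    theta_edges: np.ndarray
    gamma_edges: np.ndarray
    smoothed: bool = False
    sigma_bins: float = 0.0
    smoothed_counts: np.ndarray | None = field(default=None)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def display_counts(self) -> np.ndarray:
        return self.smoothed_counts if self.smoothed else self.counts


def phase_difference(
    theta: PhaseSeries, gamma: PhaseSeries, n: int, m: int
) -> PhaseDifferenceSeries:
    """Per-sample wrapped n*phi_gamma - m*phi_theta."""
    if len(theta) != len(gamma):
        raise ValueError("phase series must have equal length")
    if theta.fs != gamma.fs:
        raise ValueError("phase series must share the sampling rate")
    d = wrap_phase(n * gamma.phases - m * theta.phases)
    return PhaseDifferenceSeries(d, n, m, theta.fs)


def rnm(d: PhaseDifferenceSeries | np.ndarray) -> float:
    """Mean resultant length of the phase differences, in [0, 1]."""
    values = d.values if isinstance(d, PhaseDifferenceSeries) else np.asarray(d, dtype=float)
    if values.size == 0:
        raise ValueError("empty phase-difference series")
    return float(np.abs(np.mean(np.exp(1j * values))))


def rnm_curve(
    theta: PhaseSeries,
    gamma: PhaseSeries,
    m_range: tuple[int, int] = (1, 25),
    n: int = 1,
) -> NMCouplingResult:
    """R_nm for m over an inclusive integer interval, n fixed (default 1)."""
    m_lo, m_hi = m_range
    if m_hi < m_lo:
        raise ValueError("empty m range")
    ms = np.arange(m_lo, m_hi + 1)
    # one complex accumulation per m, on the shared phase arrays
    R = np.array([rnm(phase_difference(theta, gamma, n, int(m))) for m in ms])
    return NMCouplingResult(n, ms, R, len(theta) / theta.fs)


def ppc(
    d: PhaseDifferenceSeries,
    subsample_n: int | None = None,
    seed: int | None = None,
    spacing: int | None = None,
) -> float:
    """Pairwise phase consistency: mean cosine of all pairwise differences.

    Computed by the closed form ((k*R^2 - 1) / (k - 1)) on k phase values.
    Unlike R, PPC is bias-free: its expectation is 0 for uniform phases at
    any k. Because neighboring filtered-phase samples are dependent,
    either random subsampling (``subsample_n`` values drawn with ``seed``)
    or regular subsampling every ``spacing`` samples should be used to
    approximate the independence the estimator assumes.
    """
    values = d.values
    if spacing is not None:
        if spacing < 1:
            raise ValueError("spacing must be >= 1")
        values = values[::spacing]
    if subsample_n is not None:
        if subsample_n < 2:
            raise ValueError("need at least 2 samples for pairwise consistency")
        if subsample_n > values.size:
            raise ValueError("subsample larger than the series")
        rng = np.random.default_rng(seed)
        values = rng.choice(values, size=subsample_n, replace=False)
    k = values.size
    if k < 2:
        raise ValueError("need at least 2 samples for pairwise consistency")
    R = float(np.abs(np.mean(np.exp(1j * values))))
    return (k * R * R - 1.0) / (k - 1.0)


def binned_radial_distance(
    theta: PhaseSeries, gamma: PhaseSeries, n_bins: int
) -> np.ndarray:
    """Mean resultant length of gamma phases within each theta-phase bin.

    Returns an array of length ``n_bins``; bins that received no samples
    are NaN (undefined, not zero). With independent phases, fewer samples
    per bin (more bins) inflates every per-bin R — the small-sample bias
    again, now per bin.
    """
    if len(theta) != len(gamma):
        raise ValueError("phase series must have equal length")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    idx = _bin_index(theta.phases, n_bins)
    z = np.exp(1j * gamma.phases)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            out[b] = np.abs(np.mean(z[sel]))
    return out


def _bin_index(phases: np.ndarray, n_bins: int) -> np.ndarray:
    """Half-open uniform bins on (-pi, pi]; +pi goes to the last bin."""
    idx = np.floor((phases + np.pi) / (2 * np.pi) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _circular_gaussian_smooth(counts: np.ndarray, sigma_bins: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(counts.astype(float), sigma=sigma_bins, mode="wrap")


def phase_phase_histogram(
    theta: PhaseSeries,
    gamma: PhaseSeries,
    n_bins: int = 120,
    sigma_bins: float = 10.0,
) -> PhasePhasePlot:
    """2D histogram of simultaneous (theta, gamma) phases.

    120 uniform bins per axis by default; when ``sigma_bins > 0`` a
    circularly wrapped Gaussian kernel smooths the counts (phases are
    circular on both axes). Raw counts always sum to the sample count.
    """
    if len(theta) != len(gamma):
        raise ValueError("phase series must have equal length")
    ti = _bin_index(theta.phases, n_bins)
    gi = _bin_index(gamma.phases, n_bins)
    counts = (
        np.bincount(ti * n_bins + gi, minlength=n_bins * n_bins)
        .reshape(n_bins, n_bins)
        .astype(float)
    )
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    smoothed = sigma_bins > 0
    sm = _circular_gaussian_smooth(counts, sigma_bins) if smoothed else None
    return PhasePhasePlot(counts, edges, edges, smoothed, sigma_bins, sm)


def count_stripes(plot: PhasePhasePlot, m_max: int = 25) -> int:
    """Number of diagonal stripes in a phase-phase plot.

    A 1:m phase relation concentrates mass on m parallel diagonals
    gamma = m*theta + c (mod 2pi). The count is recovered as the m in
    1..m_max maximizing the histogram-weighted resultant
    |sum counts * exp(i*(phi_gamma - m*phi_theta))| / sum counts at bin
    centers; ties break toward smaller m.
    """
    counts = plot.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("phase-phase plot has no counts")
    nb = plot.n_bins
    centers = plot.theta_edges[:-1] + np.pi / nb
    th = centers[:, None]
    ga = centers[None, :]
    best_m, best_R = 1, -1.0
    for m in range(1, m_max + 1):
        R = np.abs(np.sum(counts * np.exp(1j * (ga - m * th)))) / total
        if R > best_R + 1e-12:
            best_m, best_R = m, R
    return best_m


def stripe_resultant(plot: PhasePhasePlot, m: int) -> float:
    """Histogram-weighted resultant length along the m-th diagonal family."""
    counts = plot.counts
    total = counts.sum()
    nb = plot.n_bins
    centers = plot.theta_edges[:-1] + np.pi / nb
    return float(
        np.abs(np.sum(counts * np.exp(1j * (centers[None, :] - m * centers[:, None])))) / total
    )


def uniform_resultant_expectation(n: int) -> float:
    """E[R] for n i.i.d. uniform circular samples: sqrt(pi)/2 * n**-0.5."""
    return float(np.sqrt(np.pi) / 2.0 / np.sqrt(n))
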
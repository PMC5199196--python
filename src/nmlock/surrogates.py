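"""Surrogate (mock gamma phase) construction and significance testing.

A surrogate keeps the theta phase intact and replaces the gamma phase
with a version that preserves its marginal statistics but breaks any
coupling to theta:

* ``time_shift`` — the gamma phase window is displaced by a random lag
  of 1-200 ms within the recorded session; phase continuity preserved.
* ``random_permutation`` — a contiguous gamma window of the same length
  is drawn from elsewhere in the session; continuity preserved.
* ``phase_scramble`` — the gamma timestamps are shuffled, destroying
  continuity. This removes the sample-to-sample dependence filtering
  imposes, so scrambled chance values are biased low and original-vs-
  scrambled comparisons produce false positives by construction.

Chance distributions come in two flavors: *single-run* (one R per
surrogate realization — the calibrated choice, matching the original
statistic sample for sample) and *pooled* (one R on the union of many
realizations' phase differences — a longer effective epoch, hence a
deflated chance level and false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .metrics import PhasePhasePlot, phase_difference, phase_phase_histogram, rnm
from .signals import PhaseSeries

__all__ = [
    "SurrogateConfig",
    "SignificanceMap",
    "RnmTestResult",
    "time_shift_surrogate",
    "random_permutation_surrogate",
    "phase_scramble_surrogate",
    "mock_gamma_epoch",
    "surrogate_rnm_distribution",
    "surrogate_phase_phase_plots",
    "test_rnm",
    "phase_phase_significance",
]

_METHODS = ("time_shift", "random_permutation", "phase_scramble")


@dataclass
class SurrogateConfig:
    """Configuration of a surrogate analysis.

    ``n_runs`` is the number of surrogate realizations (the field's usual
    choices: 100 runs per pooled distribution, 300 single-run values per
    condition, 1000 runs for bin-wise plot testing). ``n_pool`` is how
    many pooled R replicates to draw in pooled mode.
    """

    method: str = "time_shift"
    mode: str = "single_run"
    n_runs: int = 300
    shift_min_ms: float = 1.0
    shift_max_ms: float = 200.0
    seed: int = 0
    symmetric: bool = False
    n_pool: int = 10

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.mode not in ("single_run", "pooled"):
            raise ValueError("mode must be 'single_run' or 'pooled'")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 <= self.shift_min_ms <= self.shift_max_ms:
            raise ValueError("need 0 <= shift_min_ms <= shift_max_ms")

    def rng(self, run_index: int) -> np.random.Generator:
        """Per-run generator, deterministic in (seed, run_index)."""
        return np.random.default_rng([self.seed, run_index])


@dataclass
class SignificanceMap:
    """Per-bin significance of a phase-phase plot against surrogates."""

    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    correction: str
    alpha: float
    zero_sd: np.ndarray = field(default=None)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


@dataclass
class RnmTestResult:
    """One-tailed two-sample comparison of original vs surrogate R values."""

    statistic: float
    p: float
    percentile: float
    degenerate: bool = False


def _shift_samples(cfg: SurrogateConfig, fs: float, rng: np.random.Generator) -> int:
    lo = max(int(round(cfg.shift_min_ms * fs / 1000.0)), 1)
    hi = int(round(cfg.shift_max_ms * fs / 1000.0))
    shift = int(rng.integers(lo, hi + 1))
    if cfg.symmetric and rng.integers(0, 2):
        shift = -shift
    return shift


def time_shift_surrogate(
    session_gamma: PhaseSeries,
    epoch_start: int,
    epoch_len: int,
    cfg: SurrogateConfig,
    run_index: int,
    _forced_shift: int | None = None,
) -> PhaseSeries:
    """Gamma phase window displaced by a random 1-200 ms lag."""
    rng = cfg.rng(run_index)
    shift = _forced_shift if _forced_shift is not None else _shift_samples(cfg, session_gamma.fs, rng)
    start = epoch_start + shift
    if start < 0 or start + epoch_len > len(session_gamma):
        raise ValueError("session does not extend far enough beyond the epoch for this shift")
    return session_gamma.slice(start, epoch_len)


def random_permutation_surrogate(
    session_gamma: PhaseSeries,
    epoch_len: int,
    cfg: SurrogateConfig,
    run_index: int,
    exclude_start: int | None = None,
) -> PhaseSeries:
    """Contiguous gamma window at a uniformly random position in the session.

    Overlap with the original window is allowed; the exact original window
    (``exclude_start``) is redrawn.
    """
    if len(session_gamma) <= epoch_len:
        raise ValueError("session must be longer than the epoch")
    rng = cfg.rng(run_index)
    n_starts = len(session_gamma) - epoch_len + 1
    for _ in range(1000):
        start = int(rng.integers(0, n_starts))
        if exclude_start is None or start != exclude_start:
            return session_gamma.slice(start, epoch_len)
    raise RuntimeError("could not draw a window distinct from the original")


def phase_scramble_surrogate(
    gamma: PhaseSeries, cfg: SurrogateConfig, run_index: int
) -> PhaseSeries:
    """Random shuffle of the gamma phase timestamps (continuity destroyed)."""
    rng = cfg.rng(run_index)
    perm = rng.permutation(len(gamma))
    env = None if gamma.envelope is None else gamma.envelope[perm]
    return PhaseSeries(gamma.phases[perm], gamma.fs, env)


def mock_gamma_epoch(
    session_gamma: PhaseSeries,
    epoch_start: int,
    epoch_len: int,
    cfg: SurrogateConfig,
    run_index: int,
) -> PhaseSeries:
    """Dispatch to the configured surrogate method."""
    if cfg.method == "time_shift":
        return time_shift_surrogate(session_gamma, epoch_start, epoch_len, cfg, run_index)
    if cfg.method == "random_permutation":
        return random_permutation_surrogate(
            session_gamma, epoch_len, cfg, run_index, exclude_start=epoch_start
        )
    return phase_scramble_surrogate(
        session_gamma.slice(epoch_start, epoch_len), cfg, run_index
    )


def surrogate_rnm_distribution(
    theta: PhaseSeries,
    session_gamma: PhaseSeries,
    epoch_start: int,
    n: int,
    m: int,
    cfg: SurrogateConfig,
) -> np.ndarray:
    """Chance distribution of R_nm under the configured surrogate scheme.

    ``theta`` is the original theta-phase epoch; mock gamma epochs of the
    same length are cut from ``session_gamma``. Returns ``n_runs`` values
    in single-run mode, or ``n_pool`` values in pooled mode, each pooling
    the phase differences of ``n_runs`` fresh runs before one R. Pooling a
    run set is identical to computing R on the concatenated samples.
    """
    epoch_len = len(theta)
    if cfg.mode == "single_run":
        out = np.empty(cfg.n_runs)
        for r in range(cfg.n_runs):
            g = mock_gamma_epoch(session_gamma, epoch_start, epoch_len, cfg, r)
            out[r] = rnm(phase_difference(theta, g, n, m))
        return out
    out = np.empty(cfg.n_pool)
    run = 0
    for k in range(cfg.n_pool):
        pooled = np.empty(cfg.n_runs * epoch_len)
        for j in range(cfg.n_runs):
            g = mock_gamma_epoch(session_gamma, epoch_start, epoch_len, cfg, run)
            pooled[j * epoch_len : (j + 1) * epoch_len] = phase_difference(
                theta, g, n, m
            ).values
            run += 1
        out[k] = rnm(pooled)
    return out


def surrogate_phase_phase_plots(
    theta: PhaseSeries,
    session_gamma: PhaseSeries,
    epoch_start: int,
    cfg: SurrogateConfig,
    n_bins: int = 120,
    sigma_bins: float = 10.0,
) -> list[PhasePhasePlot]:
    """One phase-phase histogram per surrogate run (theta kept intact)."""
    epoch_len = len(theta)
    plots = []
    for r in range(cfg.n_runs):
        g = mock_gamma_epoch(session_gamma, epoch_start, epoch_len, cfg, r)
        plots.append(phase_phase_histogram(theta, g, n_bins, sigma_bins))
    return plots


def test_rnm(
    original_values: np.ndarray, surrogate_values: np.ndarray
) -> RnmTestResult:
    """One-tailed t-test of original R values exceeding the surrogates.

    Also reports the percentile of the mean original value within the
    surrogate distribution. Degenerate (zero-variance) inputs are flagged
    rather than producing a spurious p-value.
    """
    orig = np.asarray(original_values, dtype=float)
    surr = np.asarray(surrogate_values, dtype=float)
    if orig.size < 2 or surr.size < 2:
        raise ValueError("need at least 2 values per group")
    percentile = float(sstats.percentileofscore(surr, float(np.mean(orig)), kind="mean"))
    if np.var(orig) == 0 and np.var(surr) == 0:
        return RnmTestResult(np.nan, np.nan, percentile, degenerate=True)
    t, p = sstats.ttest_ind(orig, surr, alternative="greater")
    return RnmTestResult(float(t), float(p), percentile)


def phase_phase_significance(
    original: PhasePhasePlot,
    surrogate_plots: Sequence[PhasePhasePlot],
    correction: str = "holm",
    alpha: float = 0.05,
    use_smoothed: bool = True,
    empirical: bool = False,
) -> SignificanceMap:
    """Bin-wise test of a phase-phase plot against surrogate plots.

    Each bin's original count is compared with the mean and SD of the
    surrogate counts in that bin: z = (orig - mean) / sd, upper-tail
    normal p, then ``correction`` in {"none", "holm", "fdr"} applied
    jointly over all bins. ``empirical=True`` switches to rank-based
    p-values (resolution limited to 1/(n_surrogates+1)). Bins with zero
    surrogate SD get p = 1 and are flagged.
    """
    if len(surrogate_plots) < 2:
        raise ValueError("need at least 2 surrogate plots")
    pick = (lambda pl: pl.display_counts) if use_smoothed else (lambda pl: pl.counts)
    orig = pick(original)
    stack = np.stack([pick(pl) for pl in surrogate_plots])
    if stack.shape[1:] != orig.shape:
        raise ValueError("surrogate plots must share the original's binning")
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_sd = sd <= 1e-10 * (1.0 + np.abs(mu))  # degenerate within float noise
    z = np.zeros_like(orig)
    np.divide(orig - mu, sd, out=z, where=~zero_sd)
    if empirical:
        exceed = (stack >= orig[None]).sum(axis=0)
        p = (exceed + 1.0) / (stack.shape[0] + 1.0)
    else:
        p = sstats.norm.sf(z)
    p[zero_sd] = 1.0
    if correction == "none":
        significant = p < alpha
    elif correction in ("holm", "fdr"):
        from statsmodels.stats.multitest import multipletests

        method = "holm" if correction == "holm" else "fdr_bh"
        reject, _, _, _ = multipletests(p.ravel(), alpha=alpha, method=method)
        significant = reject.reshape(p.shape)
    else:
        raise ValueError("correction must be 'none', 'holm' or 'fdr'")
    return SignificanceMap(z, p, significant, correction, alpha, zero_sd)
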
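"""Synthetic signal generators.

The generators produce the canonical test beds for n:m phase-locking
analysis: Gaussian white noise (a signal with no oscillatory structure at
all), pairs of Kuramoto phase oscillators with sine coupling (a system with
genuine n:m locking), variable-frequency sawtooth waves (a non-sinusoidal
oscillation whose harmonics are intrinsically locked to the fundamental),
and pure sinusoids (the perfect-locking control).

Every generator takes an integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import PhaseSeries, TimeSeries, wrap_phase

__all__ = [
    "KuramotoParams",
    "SawtoothParams",
    "gen_white_noise",
    "simulate_kuramoto_pair",
    "gen_sawtooth",
    "gen_sinusoid",
]


@dataclass
class KuramotoParams:
    """Parameters of the coupled two-oscillator Kuramoto system.

    The oscillators obey

        dphi_theta/dt = 2*pi*w_theta(t) + epsilon * sin(n*phi_gamma - m*phi_theta)
        dphi_gamma/dt = 2*pi*w_gamma(t) + epsilon * sin(m*phi_theta - n*phi_gamma)

    where the natural frequencies ``w`` (Hz) are redrawn from a Gaussian at
    every integration step (white frequency noise) and the coupling strength
    ``epsilon`` is in rad/s. With epsilon large enough to lock, the mean
    frequencies align to the n:m ratio; e.g. 8 and 43 Hz at 1:5 pull to
    8.5 and 42.5 Hz.
    """

    epsilon: float = 10.0
    n: int = 1
    m: int = 5
    mean_freq_theta: float = 8.0
    mean_freq_gamma: float = 43.0
    freq_sigma: float = 5.0
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("coupling strength epsilon must be >= 0")
        if self.n < 1 or self.m < 1 or self.n != int(self.n) or self.m != int(self.m):
            raise ValueError("n and m must be integers >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.freq_sigma < 0:
            raise ValueError("freq_sigma must be >= 0")


@dataclass
class SawtoothParams:
    """Parameters of a frequency-jittered sawtooth wave.

    ``freq_sigma`` jitters the instantaneous frequency once per cycle
    (each cycle is a clean linear ramp); draws are truncated at 1 Hz.
    ``noise_sigma`` adds white Gaussian noise to the waveform. The default
    values (mean 8 Hz, sigma 5 Hz, noise 0.1) give a theta-like asymmetric
    wave whose sharp edges project broadband power into the gamma range.
    """

    mean_freq: float = 8.0
    freq_sigma: float = 5.0
    noise_sigma: float = 0.1
    fs: float = 1000.0
    descending: bool = True  # sharp falling edge (ascending ramp)

    def __post_init__(self) -> None:
        if self.mean_freq <= 0:
            raise ValueError("mean_freq must be positive")
        if self.fs <= 2 * self.mean_freq:
            raise ValueError("fs must exceed twice the mean frequency")
        if self.freq_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")


def gen_white_noise(duration_s: float, fs: float, seed: int) -> TimeSeries:
    """Gaussian white noise: i.i.d. standard-normal samples.

    Parameters
    ----------
    duration_s : float
        Duration in seconds; ``duration_s * fs`` must be >= 2.
    fs : float
        Sampling rate in Hz.
    seed : int
        Seed for the random generator; same seed, same samples.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("requested fewer than 2 samples")
    rng = np.random.default_rng(seed)
    return TimeSeries(rng.standard_normal(n), fs)


def simulate_kuramoto_pair(
    params: KuramotoParams, duration_s: float, seed: int
) -> tuple[PhaseSeries, PhaseSeries]:
    """Integrate the coupled phase-oscillator pair by forward Euler.

    Returns the (theta, gamma) wrapped phase series sampled at 1/dt. Natural
    frequencies are drawn i.i.d. Gaussian(mean, freq_sigma) at each step;
    initial phases are uniform on (-pi, pi].
    """
    p = params
    n_steps = int(round(duration_s / p.dt))
    if n_steps < 2:
        raise ValueError("duration too short for the requested dt")
    rng = np.random.default_rng(seed)
    w_th = rng.normal(p.mean_freq_theta, p.freq_sigma, n_steps - 1)
    w_ga = rng.normal(p.mean_freq_gamma, p.freq_sigma, n_steps - 1)
    phi_th = np.empty(n_steps)
    phi_ga = np.empty(n_steps)
    phi_th[0] = rng.uniform(-np.pi, np.pi)
    phi_ga[0] = rng.uniform(-np.pi, np.pi)
    two_pi = 2.0 * np.pi
    eps, n_, m_, dt = p.epsilon, p.n, p.m, p.dt
    if eps == 0.0:
        # uncoupled: plain cumulative sums of the jittered frequencies
        phi_th[1:] = phi_th[0] + np.cumsum(two_pi * w_th * dt)
        phi_ga[1:] = phi_ga[0] + np.cumsum(two_pi * w_ga * dt)
    else:
        for j in range(1, n_steps):
            s = eps * np.sin(n_ * phi_ga[j - 1] - m_ * phi_th[j - 1])
            phi_th[j] = phi_th[j - 1] + dt * (two_pi * w_th[j - 1] + s)
            phi_ga[j] = phi_ga[j - 1] + dt * (two_pi * w_ga[j - 1] - s)
    fs = 1.0 / dt
    return (
        PhaseSeries(wrap_phase(phi_th), fs),
        PhaseSeries(wrap_phase(phi_ga), fs),
    )


def gen_sawtooth(params: SawtoothParams, duration_s: float, seed: int) -> TimeSeries:
    """Sawtooth wave with per-cycle frequency jitter and additive noise.

    Each cycle is a linear ramp of unit peak-to-peak amplitude (values in
    [-0.5, 0.5]) whose duration is 1/f with f ~ Gaussian(mean_freq,
    freq_sigma) truncated at 1 Hz; a sharp edge closes the cycle. White
    Gaussian noise of SD ``noise_sigma`` is added on top.
    """
    p = params
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * p.fs))
    rng = np.random.default_rng(seed)
    # cycle-phase ramp: accumulate per-cycle frequencies until n samples covered
    out = np.empty(n)
    i = 0
    while i < n:
        f = p.mean_freq if p.freq_sigma == 0 else max(rng.normal(p.mean_freq, p.freq_sigma), 1.0)
        n_cyc = max(int(round(p.fs / f)), 2)
        n_take = min(n_cyc, n - i)
        ramp = np.arange(n_take) / n_cyc - 0.5
        out[i : i + n_take] = ramp if p.descending else -ramp
        i += n_take
    if p.noise_sigma > 0:
        out = out + rng.normal(0.0, p.noise_sigma, n)
    return TimeSeries(out, p.fs)


def gen_sinusoid(freq: float, duration_s: float, fs: float, phase0: float = 0.0) -> TimeSeries:
    """Unit-amplitude cosine with initial phase ``phase0`` (radians)."""
    if freq >= fs / 2:
        raise ValueError("frequency must be below Nyquist (fs/2)")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    t = np.arange(int(round(duration_s * fs))) / fs
    return TimeSeries(np.cos(2.0 * np.pi * freq * t + phase0), fs)
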
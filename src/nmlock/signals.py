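"""Core containers for uniformly sampled signals and instantaneous phase.

All phases in this package are wrapped to the half-open interval (-pi, pi],
with phase 0 at the waveform peak of a cosine (analytic-signal convention)
and the trough at +/-pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "PhaseSeries", "wrap_phase"]


def wrap_phase(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (radians) to (-pi, pi].

    The inverse of ``np.unwrap`` up to multiples of 2*pi; -pi maps to +pi so
    the interval is half-open on the left.
    """
    return -np.mod(-np.asarray(x, dtype=float) + np.pi, 2.0 * np.pi) + np.pi


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Signal values, arbitrary units.
    fs : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def slice(self, start: int, length: int) -> "TimeSeries":
        """Contiguous window of `length` samples starting at sample `start`."""
        if start < 0 or start + length > len(self):
            raise ValueError("window outside the series")
        return TimeSeries(self.samples[start : start + length].copy(), self.fs)


@dataclass
class PhaseSeries:
    """Instantaneous phase in radians, wrapped to (-pi, pi].

    Optionally carries the amplitude envelope of the analytic signal the
    phase was extracted from.
    """

    phases: np.ndarray
    fs: float
    envelope: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 1:
            raise ValueError("phases must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.any(self.phases > np.pi) or np.any(self.phases <= -np.pi):
            raise ValueError("phases must lie in (-pi, pi]")
        if self.envelope is not None:
            self.envelope = np.asarray(self.envelope, dtype=float)
            if self.envelope.shape != self.phases.shape:
                raise ValueError("envelope must match phases in length")
            if np.any(self.envelope < 0):
                raise ValueError("envelope must be non-negative")

    def __len__(self) -> int:
        return self.phases.size

    def unwrapped(self) -> np.ndarray:
        return np.unwrap(self.phases)

    def slice(self, start: int, length: int) -> "PhaseSeries":
        """Contiguous phase window of `length` samples starting at `start`."""
        if start < 0 or start + length > len(self):
            raise ValueError("window outside the series")
        env = None if self.envelope is None else self.envelope[start : start + length].copy()
        return PhaseSeries(self.phases[start : start + length].copy(), self.fs, env)

    def drop_edges(self, edge_s: float) -> "PhaseSeries":
        """Discard `edge_s` seconds at each end (filter edge transients)."""
        k = int(round(edge_s * self.fs))
        if 2 * k >= len(self):
            raise ValueError("series shorter than the edges to drop")
        return self.slice(k, len(self) - 2 * k)
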
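"""Optional PNG figures (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .metrics import NMCouplingResult, PhasePhasePlot

__all__ = ["save_phase_phase_png", "save_rnm_curve_png"]


def save_phase_phase_png(plot: PhasePhasePlot, path: str | Path, title: str = "") -> None:
    """Heatmap of the (smoothed) phase-phase histogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4))
    extent = (-np.pi, np.pi, -np.pi, np.pi)
    im = ax.imshow(plot.display_counts.T, origin="lower", extent=extent, aspect="auto")
    ax.set_xlabel("slow phase (rad)")
    ax.set_ylabel("fast phase (rad)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_rnm_curve_png(curve: NMCouplingResult, path: str | Path, title: str = "") -> None:
    """R_nm versus m."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(curve.m_grid, curve.R, "o-", ms=3)
    ax.set_xlabel("m (for n = %d)" % curve.n)
    ax.set_ylabel("$R_{n:m}$")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
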
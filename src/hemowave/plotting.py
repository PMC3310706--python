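"""Quick-look figures: space-time responses, phase maps, fronts, sweeps."""

from __future__ import annotations

import numpy as np

from .analysis import AveragedResponse, PhaseField, WaveFront
from .grids import Field

__all__ = ["plot_response", "plot_phase_fronts", "plot_sweep_gallery"]


def _mpl():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_response(y: Field | AveragedResponse, ax=None, vmax=None):
    """Space-time image of y(x, t) with a symmetric diverging color scale."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    if isinstance(y, AveragedResponse):
        vals, x, t = y.y, y.x, y.t
    else:
        vals = y.values if y.grid.is_1d else y.values[y.grid.ny // 2]
        x, t = y.grid.x, y.grid.t
    vmax = vmax or np.nanmax(np.abs(vals))
    im = ax.pcolormesh(t, x, vals, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       shading="nearest")
    ax.set_xlabel("t (s)")
    ax.set_ylabel("x (mm)")
    plt.colorbar(im, ax=ax, label="signal change (%)")
    return ax


def plot_phase_fronts(phase: PhaseField, fronts: tuple[WaveFront, WaveFront],
                      ax=None):
    """Instantaneous-phase map with the extracted fronts overlaid."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    wrapped = np.angle(np.exp(1j * phase.phi))
    im = ax.pcolormesh(phase.t, phase.x, wrapped, cmap="twilight",
                       shading="nearest")
    for front, color in zip(fronts, ("r", "k")):
        if front.n:
            sgn = 1.0 if front.side == "F" else -1.0
            ax.plot(front.t, sgn * front.x_abs, color + "o-", ms=3,
                    label=front.side)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("x (mm)")
    ax.legend(loc="upper right")
    plt.colorbar(im, ax=ax, label="phase (rad)")
    return ax


def plot_sweep_gallery(sweep, figsize=None):
    """Grid of y(x, t) panels, one per (v_beta, Gamma) pair."""
    plt = _mpl()
    vs = sorted({k[0] for k in sweep.fields})
    gs = sorted({k[1] for k in sweep.fields})
    fig, axes = plt.subplots(len(gs), len(vs), squeeze=False,
                             figsize=figsize or (3 * len(vs), 2.2 * len(gs)))
    for i, G in enumerate(gs):
        for j, v in enumerate(vs):
            y = sweep.fields[(v, G)]
            vals = y.values if y.grid.is_1d else y.values[y.grid.ny // 2]
            vmax = np.max(np.abs(vals))
            axes[i][j].imshow(vals, aspect="auto", cmap="RdBu_r",
                              vmin=-vmax, vmax=vmax, origin="lower",
                              extent=[y.grid.t[0], y.grid.t[-1],
                                      y.grid.x[0], y.grid.x[-1]])
            axes[i][j].set_title(f"v={v} mm/s, Γ={G} 1/s", fontsize=8)
    fig.tight_layout()
    return fig
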
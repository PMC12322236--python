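"""Optional rendering of sweep heat maps and trajectories."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_sweep_heatmaps(sweeps: dict, metric: str = "dq_abs", vmax=None, path=None):
    """One heat map per module over the B0 x B1 deviation grid.

    ``sweeps`` maps module name -> SweepResult; ``metric`` is 'dq_abs',
    'dq_signed', 'dq_s0_abs' or 'rss'.  Returns the figure (and writes a PNG
    when ``path`` is given).
    """
    n = len(sweeps)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.4), squeeze=False)
    for ax, (name, sw) in zip(axes[0], sweeps.items()):
        grid = getattr(sw, metric)
        im = ax.imshow(
            grid.T,
            origin="lower",
            aspect="auto",
            extent=[sw.delta_f0[0], sw.delta_f0[-1], sw.b1_scale[0], sw.b1_scale[-1]],
            vmax=vmax,
        )
        ax.set_title(name)
        ax.set_xlabel(r"$\Delta f_0$ (Hz)")
        ax.set_ylabel("B1 scale")
        fig.colorbar(im, ax=ax, label=metric)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_trajectory(spec, fields, relax, t1rho_true=None, n_dense=200, angle_mode="effective", path=None):
    """|Mz| trajectory with the ideal mono-exponential reference."""
    from .modules import mz_after_prep

    t1 = float(np.asarray(relax.t1rho)) if t1rho_true is None else t1rho_true
    t = np.linspace(0.0, 2.0 * t1, n_dense)
    y = np.abs(mz_after_prep(spec, t, fields, relax, angle_mode))
    fig, ax = plt.subplots(figsize=(5, 3.4))
    ax.plot(1e3 * t, y, "k-", lw=1, label="|Mz| trajectory")
    ax.plot(1e3 * t, np.exp(-t / t1), "r-", lw=1, label="ideal decay")
    ax.set_xlabel("TSL (ms)")
    ax.set_ylabel("|Mz|")
    ax.set_title(spec.name)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
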
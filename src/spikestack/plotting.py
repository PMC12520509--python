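"""Figure helpers: SCFM heatmaps, pentagon performance plots, profiles."""

from __future__ import annotations

import numpy as np

__all__ = ["scfm_heatmap", "pentagon_plot", "resolution_profile_plot"]


def _axes(ax):
    if ax is not None:
        return ax.figure, ax
    import matplotlib.pyplot as plt

    return plt.subplots()


def scfm_heatmap(scfm, ax=None, path: str | None = None):
    """Diverging neurons x time heatmap of a signed SCFM (white = baseline,
    red = above, blue = below)."""
    fig, ax = _axes(ax)
    vmax = float(np.abs(scfm.signed_map).max()) or 1.0
    im = ax.imshow(
        scfm.signed_map,
        aspect="auto",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        extent=[0, scfm.n_grid * scfm.grid_ms, scfm.n_neurons, 0],
    )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    ax.set_title(f"SCFM: {scfm.category}")
    fig.colorbar(im, ax=ax, label="probability vs baseline")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def pentagon_plot(mcc_by_category: dict, ax=None, path: str | None = None):
    """Radar (pentagon) plot of per-category MCCs."""
    import matplotlib.pyplot as plt

    names = list(mcc_by_category)
    values = [mcc_by_category[n] for n in names]
    angles = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
    if ax is None:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    else:
        fig = ax.figure
    closed_a = np.append(angles, angles[0])
    closed_v = values + [values[0]]
    ax.plot(closed_a, closed_v, "k-", linewidth=2)
    ax.fill(closed_a, closed_v, alpha=0.15)
    ax.set_xticks(angles)
    ax.set_xticklabels(names)
    ax.set_ylim(-0.1, 1.0)
    ax.set_title("decoding performance (MCC)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def resolution_profile_plot(profile, ax=None, path: str | None = None):
    """Bar plot of normalized per-resolution contributions (finest last)."""
    fig, ax = _axes(ax)
    ax.bar(np.arange(len(profile)), profile["mean_share"])
    ax.set_xticks(np.arange(len(profile)))
    ax.set_xticklabels(
        [f"{r:g}" for r in profile["resolution_ms"]], rotation=45
    )
    ax.set_xlabel("temporal resolution (ms)")
    ax.set_ylabel("normalized contribution")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return ax
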
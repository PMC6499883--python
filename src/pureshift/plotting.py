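"""Figure builders: thresholded 2D STOCSY, colour-coded 1D STOCSY, PLS
scores with Hotelling ellipses, and the PLS-loading/STOCSY overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .chemometrics import EllipseSpec, PlsModel, hotelling_ellipse
from .stocsy import Stocsy1D, Stocsy2D


def _flip_ppm(ax) -> None:
    ax.invert_xaxis()
    ax.set_xlabel("ppm")


def plot_stocsy_2d(res: Stocsy2D, path=None):
    fig, ax = plt.subplots(figsize=(6, 5))
    masked = np.ma.masked_invalid(res.masked)
    pc = ax.pcolormesh(res.ppm, res.ppm, masked, cmap="RdBu_r", vmin=-1, vmax=1,
                       shading="nearest")
    fig.colorbar(pc, ax=ax, label="r")
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel("ppm")
    ax.set_ylabel("ppm")
    ax.set_title(f"2D STOCSY (r² ≥ {res.threshold_r2})")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_stocsy_1d(res: Stocsy1D, path=None):
    fig, ax = plt.subplots(figsize=(8, 3))
    pts = ax.scatter(res.ppm, res.projection, c=res.r, cmap="jet", s=2,
                     vmin=-1, vmax=1)
    fig.colorbar(pts, ax=ax, label="r")
    _flip_ppm(ax)
    ax.set_ylabel("mean intensity")
    ax.set_title(f"1D STOCSY, driver {res.driver_ppm:.2f} ppm")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_scores(model: PlsModel, groups, level: float = 0.95, path=None):
    fig, ax = plt.subplots(figsize=(5.5, 5))
    t = model.T[:, :2]
    for g in sorted(set(groups)):
        idx = [i for i, x in enumerate(groups) if x == g]
        ax.scatter(t[idx, 0], t[idx, 1], label=g, s=30)
    ell: EllipseSpec = hotelling_ellipse(t, level)
    xy = ell.outline()
    ax.plot(xy[:, 0], xy[:, 1], "k--", lw=1)
    ax.set_xlabel("t1")
    ax.set_ylabel("t2")
    ax.legend(fontsize=7)
    ax.set_title(f"PLS scores, Hotelling T² {level:.0%}")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_overlay(overlay, driver_ppm: float, path=None):
    """PLS-component loading trace colour-coded by 1D-STOCSY r²."""
    fig, ax = plt.subplots(figsize=(8, 3))
    pts = ax.scatter(overlay["ppm"], overlay["coefficient"], c=overlay["r2"],
                     cmap="jet", s=2, vmin=0, vmax=1)
    fig.colorbar(pts, ax=ax, label="r²")
    ax.axhline(0.0, color="k", lw=0.5)
    _flip_ppm(ax)
    ax.set_ylabel("PLS loading")
    ax.set_title(f"PLS-1 loading + 1D STOCSY (driver {driver_ppm:.2f} ppm)")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
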
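"""Diagnostic plots: spectrum marginals and model-fit residuals."""

from __future__ import annotations

import numpy as np

from .sfs import JSFS3

__all__ = ["plot_jsfs_marginals", "plot_fit_residuals"]


def _pair_marginal(jsfs: JSFS3, keep: tuple) -> np.ndarray:
    drop = ({0, 1, 2} - set(keep)).pop()
    m = np.where(jsfs.mask, 0.0, jsfs.counts).sum(axis=drop)
    return m if keep[0] < keep[1] else m.T


def plot_jsfs_marginals(jsfs: JSFS3, ax=None, log: bool = True):
    """Three 2D pairwise marginal heatmaps of a joint spectrum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 3, figsize=(10, 3.2))
    pairs = [(0, 1), (0, 2), (1, 2)]
    for a, (i, j) in zip(np.ravel(ax), pairs):
        m = _pair_marginal(jsfs, (i, j))
        with np.errstate(divide="ignore"):
            img = np.log10(m) if log else m
        im = a.imshow(img.T, origin="lower", aspect="auto", cmap="viridis")
        a.set_xlabel(jsfs.pop_order[i])
        a.set_ylabel(jsfs.pop_order[j])
        a.figure.colorbar(im, ax=a, shrink=0.8)
    ax0 = np.ravel(ax)[0]
    ax0.figure.tight_layout()
    return ax


def plot_fit_residuals(obs: JSFS3, expected: JSFS3, ax=None):
    """Anscombe residuals of a fit, cell by cell, as three pairwise
    marginal panels (positive values: the model predicts too many
    sites in that entry)."""
    import matplotlib.pyplot as plt

    scaled = expected.normalized().counts * obs.total_mass()
    resid = (1.5 * (scaled ** (2 / 3) - np.maximum(obs.counts, 0) ** (2 / 3))
             / np.maximum(scaled, 1e-12) ** (1 / 6))
    resid = np.where(obs.mask | expected.mask, 0.0, resid)
    if ax is None:
        _, ax = plt.subplots(1, 3, figsize=(10, 3.2))
    pairs = [(0, 1), (0, 2), (1, 2)]
    lim = max(np.abs(resid).max(), 1e-6)
    for a, (i, j) in zip(np.ravel(ax), pairs):
        drop = ({0, 1, 2} - {i, j}).pop()
        m = resid.sum(axis=drop)
        im = a.imshow(m.T, origin="lower", aspect="auto", cmap="RdBu_r",
                      vmin=-lim, vmax=lim)
        a.set_xlabel(obs.pop_order[i])
        a.set_ylabel(obs.pop_order[j])
        a.figure.colorbar(im, ax=a, shrink=0.8)
    np.ravel(ax)[0].figure.tight_layout()
    return ax
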
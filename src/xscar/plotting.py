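"""Simple per-output figures: metaprofile lines, heatmaps, density panels."""

from __future__ import annotations

import numpy as np

from .origins import DensityProfile, HeatmapMatrix, MetaProfile


def plot_metaprofile(profile: MetaProfile, ax=None, **kwargs):
    """Mean partition vs. offset from the origin center."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.axvline(0.0, color="0.7", lw=0.8)
    ax.plot(profile.offsets, profile.mean, **kwargs)
    ax.set_xlabel("offset from origin center (bp)")
    ax.set_ylabel("mean partition")
    ax.set_ylim(-1.05, 1.05)
    return ax


def plot_heatmap(matrix: HeatmapMatrix, ax=None, sort_by_score: bool = True, **kwargs):
    """Per-origin partition rows, optionally ordered by firing score."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = matrix.values
    if sort_by_score:
        values = values[np.argsort(-matrix.scores)]
    extent = (matrix.offsets[0], matrix.offsets[-1], len(values), 0)
    im = ax.imshow(
        values, aspect="auto", cmap=kwargs.pop("cmap", "RdBu_r"),
        vmin=-1, vmax=1, extent=extent, interpolation="nearest", **kwargs,
    )
    ax.set_xlabel("offset from origin center (bp)")
    ax.set_ylabel("origin (by firing score)" if sort_by_score else "origin")
    ax.figure.colorbar(im, ax=ax, label="partition")
    return ax


def plot_density(profile: DensityProfile, ax=None, **kwargs):
    """Leading/lagging/unstranded ChIP-over-input density around origins."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for stratum in ("leading", "lagging", "unstranded"):
        ax.plot(profile.offsets, getattr(profile, stratum), label=stratum, **kwargs)
    ax.set_xlabel("offset from origin center (bp)")
    ax.set_ylabel("ChIP CPM / input CPM")
    ax.legend()
    return ax
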
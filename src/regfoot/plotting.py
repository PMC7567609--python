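"""Basic rendering of footprints and sequence logos with matplotlib."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .footprint import ACTIVATING, InformationFootprint, smooth_footprint
from .matrix import SequenceLogo
from .seqs import BASES

__all__ = ["plot_footprint", "plot_logo"]

_LOGO_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_footprint(footprint: InformationFootprint, window: int = 15, ax=None):
    """Bar plot of per-base information, colored by polarity.

    Activator-like positions (mutation lowers expression) are blue,
    repressor-like positions red; the smoothed track is overlaid.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    x = footprint.display_positions()
    colors = np.where(footprint.polarity == ACTIVATING, "#1f77b4", "#d62728")
    ax.bar(x, footprint.info, color=colors, width=1.0)
    ax.plot(x, smooth_footprint(footprint.info, window), color="0.3", lw=1.0)
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel("information (bits)")
    return ax


def plot_logo(logo: SequenceLogo, ax=None):
    """Draw a sequence logo: letters stacked by height, tallest on top."""
    if ax is None:
        _, ax = plt.subplots(figsize=(0.4 * logo.heights.shape[0] + 1, 2))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for pos, column in enumerate(logo.heights):
        y = 0.0
        for b in np.argsort(column):
            h = column[b]
            if h <= 0:
                continue
            letter = BASES[b]
            tp = TextPath((0, 0), letter, size=1.0, prop=font)
            bbox = tp.get_extents()
            scale = Affine2D().translate(-bbox.x0, -bbox.y0).scale(
                0.9 / bbox.width, h / bbox.height
            ).translate(pos + 0.05, y)
            ax.add_patch(PathPatch(scale.transform_path(tp), color=_LOGO_COLORS[letter], lw=0))
            y += h
    ax.set_xlim(0, logo.heights.shape[0])
    ax.set_ylim(0, max(2.0, logo.heights.sum(axis=1).max()))
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    return ax
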
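"""Plot-ready views of the pipeline's statistics (matplotlib required).

Minimal figure helpers: ordered fold-change series on a log axis, entropy /
information-content bar profiles, per-position KL bars, and a simple
sequence-logo-style letter plot where letter heights split the positional
information content by symbol frequency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import EntropyProfile, KLProfile, PositionFrequencyMatrix, information_content


def _require_matplotlib():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "matplotlib is required for plotting (install the 'plot' extra)"
        ) from exc
    return plt


def plot_ordered_fold_changes(series: pd.DataFrame, ax=None, log: bool = True):
    """Sequential plot of the descending fold-change list (log y by default)."""
    plt = _require_matplotlib()
    ax = ax or plt.gca()
    ax.plot(series["rank"], series["fold_change"], lw=1)
    if log:
        ax.set_yscale("log")
    ax.axhline(1.0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("peptide rank")
    ax.set_ylabel("fold change (round 3 / round 0)")
    return ax


def plot_entropy_profile(profile: EntropyProfile, ax=None, what: str = "ic"):
    """Bar profile of per-position information content (or entropy)."""
    plt = _require_matplotlib()
    ax = ax or plt.gca()
    values = profile.ic if what == "ic" else profile.s_obs
    positions = np.arange(1, len(values) + 1)
    ax.bar(positions, values, width=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel(
        "information content (bits)" if what == "ic" else "entropy (bits)"
    )
    ax.set_ylim(0, profile.s_max)
    return ax


def plot_kl_profile(profile: KLProfile, ax=None):
    """Per-position KL divergence bars (round 3 vs round 0)."""
    plt = _require_matplotlib()
    ax = ax or plt.gca()
    positions = np.arange(1, len(profile.d) + 1)
    ax.bar(positions, profile.d, width=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel("KL divergence (bits)")
    return ax


def plot_logo(pfm: PositionFrequencyMatrix, ax=None, min_height: float = 0.01):
    """Sequence-logo-style plot: stacked letters, total height = IC in bits."""
    plt = _require_matplotlib()
    ax = ax or plt.gca()
    profile = information_content(pfm)
    for pos in range(pfm.length):
        heights = pfm.freqs[pos] * profile.ic[pos]
        order = np.argsort(heights)
        y = 0.0
        for idx in order:
            h = heights[idx]
            if h < min_height:
                continue
            ax.text(
                pos + 1,
                y + h / 2,
                pfm.symbols[idx],
                ha="center",
                va="center",
                fontsize=6 + 14 * min(h / profile.s_max, 1.0),
                family="monospace",
            )
            y += h
    ax.set_xlim(0.5, pfm.length + 0.5)
    ax.set_ylim(0, profile.s_max)
    ax.set_xlabel("position")
    ax.set_ylabel("information content (bits)")
    return ax
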
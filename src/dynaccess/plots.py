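"""Minimal plotting helpers for the ratio tables."""

from __future__ import annotations

import pandas as pd


def plot_ratio_curves(ratio_table: pd.DataFrame, x: str, out_path=None):
    """Line plot of over/underestimation ratios per band against ``x``.

    ``x`` is ``"hour"`` (one line per band, hour-of-day layout) or
    ``"month"`` (monthly layout).  A horizontal line at 1 marks parity
    between static and dynamic shares.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = ratio_table.dropna(subset=[x])
    fig, ax = plt.subplots(figsize=(7, 4))
    for band, grp in sub.groupby("band", observed=True):
        grp = grp.sort_values(x)
        ax.plot(grp[x], grp["ratio"], marker="o", ms=3, label=str(band))
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(x)
    ax.set_ylabel("static share / dynamic share")
    ax.legend(title="travel-time band", fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
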
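"""Minimal plotting conveniences (Bland-Altman agreement figure)."""

from __future__ import annotations

from .ibi import BlandAltmanStats


def plot_bland_altman(stats: BlandAltmanStats, ax=None, label: str = ""):
    """Percent-difference Bland-Altman plot: per-pair differences against
    per-pair means, with the bias and 1.96-sd limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(stats.means, stats.percent_diffs, s=14, alpha=0.7)
    ax.axhline(stats.bias, color="k", lw=1, label=f"bias {stats.bias:.1f}%")
    for y in (stats.loa_low, stats.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference (%)")
    if label:
        ax.set_title(label)
    ax.legend(loc="best", frameon=False)
    return ax
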
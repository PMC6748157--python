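"""Basic diagnostic plots (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np


def or_forest(results, ax=None, alpha: float = 0.05):
    """Forest plot of odds ratios with Wald confidence intervals.

    Parameters
    ----------
    results : CumulativeLinkResults
    ax : matplotlib Axes, optional
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.6 * len(results.term_names) + 1))
    tab = results.odds_ratios(alpha=alpha)
    y = np.arange(len(tab))[::-1]
    ax.errorbar(
        tab["or"], y,
        xerr=[tab["or"] - tab["ci_low"], tab["ci_high"] - tab["or"]],
        fmt="o", capsize=3, color="k",
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(tab["term"])
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (log scale)")
    return ax
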
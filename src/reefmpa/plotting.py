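"""Coefficient plot for the top mixed model."""

from __future__ import annotations

import pandas as pd


def plot_partial_effects(effects: pd.DataFrame, ax=None):
    """Horizontal dot-and-CI plot of standardized fixed-effect estimates.

    Expects the frame produced by :func:`reefmpa.model_inference.partial_effects`
    (columns term, estimate, ci95_low, ci95_high, significant); significant
    terms are starred.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * max(len(effects), 4) + 1))
    ys = range(len(effects))
    for y, (_, row) in zip(ys, effects.iterrows()):
        ax.plot([row["ci95_low"], row["ci95_high"]], [y, y], color="steelblue")
        ax.plot(row["estimate"], y, "o", color="steelblue")
    ax.axvline(0.0, linestyle=":", color="grey")
    labels = [
        f"{row['term']}{' *' if row['significant'] else ''}" for _, row in effects.iterrows()
    ]
    ax.set_yticks(list(ys))
    ax.set_yticklabels(labels)
    ax.invert_yaxis()
    ax.set_xlabel("standardized estimate (95% CI)")
    return ax
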
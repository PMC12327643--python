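"""Minimal plotting: the random-feature null distribution histogram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .feature_selection import NullDistribution


def plot_null_distribution(null: NullDistribution, path: str | Path) -> None:
    """Histogram of null CV scores with the observed score as a vertical line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(null.scores, bins=30, color="tab:blue", alpha=0.7, label="random feature sets")
    ax.axvline(null.observed, color="black", linestyle="--",
               label=f"selected set (pct {null.percentile:.0f})")
    ax.set_xlabel("mean CV AUC")
    ax.set_ylabel("frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
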
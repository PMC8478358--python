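"""Through-time scatter of encephalization and size estimates.

A single utilitarian figure: log10 EQ under both scalings, brain mass and
body mass against age (Ma, older to the left is reversed so time flows
rightward).  Publication cosmetics are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_estimates_through_time"]


def plot_estimates_through_time(estimates: pd.DataFrame, path: str | Path) -> Path:
    """Four-panel scatter of the fossil estimate table; returns the path."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    panels = [
        ("log10_EQ_0.56", "log10 EQ (artiodactyl scaling, 0.56)"),
        ("log10_EQ_0.75", "log10 EQ (all-mammal scaling, 0.75)"),
        ("brain_mass_g", "brain mass (g)"),
        ("body_mass_kg", "body mass (kg)"),
    ]
    for ax, (col, label) in zip(axes.ravel(), panels):
        if col in estimates:
            ax.scatter(estimates["age_ma"], estimates[col], s=25)
        ax.set_ylabel(label)
        if col.endswith(("_g", "_kg")):
            ax.set_yscale("log")
    for ax in axes[1]:
        ax.set_xlabel("age (Ma)")
    axes[0, 0].invert_xaxis()  # deep time on the left
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
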
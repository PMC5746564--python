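"""Simple diagnostic plots for WIR tables and population grids."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_wir_by_class", "plot_population_grid"]


def plot_wir_by_class(table: pd.DataFrame, by: str = "class", ax=None):
    """Box plot of WIR grouped by class (or region/country).

    Lower is more important: 0 marks the top-ranked covariate of each
    country's final model.
    """
    t = table[table["testable"]] if "testable" in table.columns else table
    groups = sorted(t[by].unique())
    data = [t.loc[t[by] == g, "wir"].to_numpy() for g in groups]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.4 * len(groups) + 1.5))
    ax.boxplot(data, orientation="horizontal", tick_labels=groups,
               showmeans=True)
    ax.set_xlabel("weighted importance rank (0 = most important)")
    ax.set_xlim(-0.05, 1.05)
    ax.figure.tight_layout()
    return ax


def plot_population_grid(pop: np.ndarray, ax=None):
    """Log-scaled people-per-pixel map."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    shown = np.log10(np.asarray(pop) + 1e-3)
    im = ax.imshow(shown, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, label="log10(people per pixel)")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
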
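"""Basic plotting hooks: trajectory curves and proteomic volcano plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_trajectory_curves", "volcano_plot"]


def plot_trajectory_curves(model, age_grid=None, min_weight: float = 0.01, ax=None):
    """Per-group LVEF and E/A curves vs. age for all effective groups.

    Returns the two matplotlib axes (created when ax is None).
    """
    import matplotlib.pyplot as plt

    from .trajectory import effective_groups, trajectory_curves

    ages = np.arange(55.0, 90.1, 0.5) if age_grid is None else np.asarray(age_grid)
    order, mapping = effective_groups(model, min_weight)
    curves = trajectory_curves(model, ages)
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    for g in order:
        sub = curves[curves["group"] == g]
        label = f"group {mapping[g]} ({100 * model.weights[g]:.0f}%)"
        ax[0].plot(sub["age_years"], sub["lvef"], label=label)
        ax[1].plot(sub["age_years"], sub["ea"], label=label)
    ax[0].set(xlabel="age (years)", ylabel="LVEF (%)")
    ax[1].set(xlabel="age (years)", ylabel="E/A ratio")
    ax[0].legend(fontsize="small")
    return ax


def volcano_plot(scan_results: pd.DataFrame, group: str, q_threshold: float = 0.05,
                 ax=None):
    """Volcano plot (log-odds per SD vs. -log10 p) for one trajectory contrast."""
    import matplotlib.pyplot as plt

    sub = scan_results[(scan_results["group"] == group)
                       & scan_results["converged"]].dropna(subset=["p"])
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sig = sub["q"] < q_threshold
    ax.scatter(sub.loc[~sig, "beta"], -np.log10(sub.loc[~sig, "p"]),
               s=6, c="grey", alpha=0.5)
    ax.scatter(sub.loc[sig, "beta"], -np.log10(sub.loc[sig, "p"]),
               s=8, c="crimson")
    ax.set(xlabel="log-odds per SD of protein",
           ylabel=r"$-\log_{10} p$", title=f"{group} vs. reference")
    return ax
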
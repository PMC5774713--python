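"""Quick-look plots of scenario summaries.

One figure with three panels: land-use fractions of the agricultural
area, mean household consumption, and vegetation carbon stocks, each
drawn as the cross-replicate mean with a +/- 1 SD band.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_PANELS = [
    ("Land-use fractions", [
        ("frac_oilpalm", "tab:red", "oil palm"),
        ("frac_rubber", "tab:orange", "rubber"),
    ], "fraction of agricultural area"),
    ("Mean household consumption", [
        ("mean_consumption", "tab:blue", "consumption"),
    ], "USD per year"),
    ("Vegetation carbon", [
        ("carbon_agri", "black", "agriculture total"),
        ("carbon_op", "tab:red", "oil palm"),
        ("carbon_rubber", "tab:orange", "rubber"),
    ], "t C per ha"),
]


def plot_scenario_summary(summary: pd.DataFrame, path=None, title: str = ""):
    """Plot a ``run_scenario`` summary table; optionally save to ``path``."""
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    years = summary["year"]
    for ax, (panel_title, series, ylabel) in zip(axes, _PANELS):
        for col, color, label in series:
            mean = summary[f"{col}_mean"]
            sd = summary[f"{col}_sd"]
            ax.plot(years, mean, color=color, label=label)
            ax.fill_between(
                years, mean - sd, mean + sd, color=color, alpha=0.2, linewidth=0
            )
        ax.set_title(panel_title)
        ax.set_xlabel("year")
        ax.set_ylabel(ylabel)
        ax.legend(frameon=False, fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
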
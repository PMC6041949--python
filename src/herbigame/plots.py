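"""Optional figure helpers for sweep tables and experiment analyses.

Rendering is side-effect free with the Agg backend; nothing downstream
depends on these images.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_fixed_sweep(table: pd.DataFrame, path=None):
    """lnRR of fruit, shoot and root versus damage, coloured by nitrogen,
    with the no-compensation floor for the attacked tissue."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.4), sharex=True)
    ok = table[table["converged"] & (table["D"] > 0)]
    for ax, col in zip(axes, ("lnRR_fruit", "lnRR_shoot", "lnRR_root")):
        sc = ax.scatter(ok["D"], ok[col], c=ok["N"], s=8, cmap="viridis")
        ax.set_xlabel("damage fraction D")
        ax.set_ylabel(col)
        ax.axhline(0.0, lw=0.5, color="grey")
    floors = ok.drop_duplicates("D").sort_values("D")
    attacked = "lnRR_shoot" if (ok["location"] == "shoot").all() else "lnRR_root"
    axes[1 if attacked == "lnRR_shoot" else 2].plot(
        floors["D"], floors["null_floor"], "r.", ms=4, label="no-compensation floor")
    fig.colorbar(sc, ax=axes, label="N availability", shrink=0.85)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_dynamic_sweep(table: pd.DataFrame, path=None):
    """Equilibrium production, fitness and damage versus nitrogen."""
    fig, axes = plt.subplots(1, 4, figsize=(13, 3.2))
    ok = table[table["converged"]]
    for ax, col in zip(axes, ("G", "u_s", "u_r", "D")):
        ax.plot(ok["N"], ok[col], ".-", ms=4)
        ax.set_xlabel("N availability")
        ax.set_ylabel(col)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_experiment(results, path=None):
    """Observed lnRR per treatment with the expected ln(1-d) floor."""
    tab = results.lnrr_table
    fig, ax = plt.subplots(figsize=(4.5, 3.4))
    col = f"lnRR_{results.trend_tissue}"
    ax.plot(tab["d"], tab[col], "o", ms=4, alpha=0.5, label="observed")
    levels = sorted(set(tab["d"]) | {0.0})
    import numpy as np

    ax.plot(levels, np.log1p(-np.asarray(levels)), "r-", label="no-compensation floor")
    ax.set_xlabel("clipping fraction d")
    ax.set_ylabel(col)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
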
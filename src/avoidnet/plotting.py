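"""Line charts of summary metrics across the parameter grid.

One figure per (variant, pr): the chosen metric against the swept
parameter, one curve per value of the curve parameter.  Mirrors the usual
presentation of inheritance-sweep results (metric vs Pn with Pa curves,
and metric vs Pa with Pn curves).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_metric_curves"]


def plot_metric_curves(
    summary: pd.DataFrame,
    metric: str,
    x: str,
    curves: str,
    outdir,
    prefix: str = "sweep",
) -> list[Path]:
    """Write one PNG per (variant, pr) and return the paths."""
    col = f"{metric}_mean"
    sd_col = f"{metric}_sd"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (variant, pr), grp in summary.groupby(["variant", "pr"]):
        fig, ax = plt.subplots(figsize=(5, 4))
        for cval, curve in grp.groupby(curves):
            curve = curve.sort_values(x)
            ax.errorbar(
                curve[x], curve[col], yerr=curve[sd_col],
                marker="o", capsize=2, label=f"{curves}={cval:g}",
            )
        ax.set_xlabel(x)
        ax.set_ylabel(metric.replace("_", " "))
        ax.set_title(f"{variant}, pr={pr:g}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"{prefix}_{metric}_vs_{x}_{variant}_pr{pr:g}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
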
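"""Matplotlib figures: calibration, decision curves, reclassification."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .decision import DecisionCurve
from .metrics import CalibrationPoint


def plot_calibration(
    points: list[CalibrationPoint],
    smooth=None,
    title: str = "",
    ax=None,
    max_risk: float | None = None,
):
    """Calibration plot: observed proportion against mean predicted risk."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    xs = [p.mean_predicted for p in points]
    ys = [p.observed_proportion for p in points]
    lim = max_risk or max(max(xs), max(ys)) * 1.1
    ax.plot([0, lim], [0, lim], "--", color="grey", lw=1, label="ideal")
    ax.plot(xs, ys, "o", color="tab:blue", label="grouped observed")
    if smooth is not None:
        ax.plot(smooth[0], smooth[1], "-", color="tab:orange", lw=1.5, label="smoothed")
    ax.set_xlabel("Predicted probability of GDM")
    ax.set_ylabel("Observed proportion with GDM")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_decision_curves(curve: DecisionCurve, ax=None, title: str = ""):
    """Decision curves: net benefit per strategy over the threshold grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    for name, nb in curve.curves.items():
        style = {"treat_all": {"color": "grey", "ls": "--"},
                 "treat_none": {"color": "black", "ls": ":"},
                 "reference": {"color": "black", "ls": "-"}}.get(name, {})
        ax.plot(curve.thresholds, nb, label=name, lw=1.4, **style)
    nb_max = max(float(np.nanmax(v)) for v in curve.curves.values())
    ax.set_ylim(-0.01, nb_max * 1.15 + 1e-3)
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net benefit")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_reclassification(table: dict, title: str = "", ax=None):
    """Stacked-bar reclassification plot: reference vs model, by outcome."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    counts = table["counts"]
    groups = ["gdm", "no_gdm"]
    labels = {"gdm": "GDM", "no_gdm": "no GDM"}
    cells = [("high", "high"), ("high", "low"), ("low", "high"), ("low", "low")]
    cell_labels = ["ref high / model high", "ref high / model low",
                   "ref low / model high", "ref low / model low"]
    colors = ["tab:red", "tab:orange", "tab:purple", "tab:green"]
    x = np.arange(len(groups))
    bottoms = np.zeros(len(groups))
    for (rkey, mkey), lbl, color in zip(cells, cell_labels, colors):
        vals = np.array([counts[(g, rkey, mkey)] for g in groups], dtype=float)
        totals = np.array(
            [sum(counts[(g, r, m)] for r in ("high", "low") for m in ("high", "low"))
             for g in groups], dtype=float)
        frac = np.divide(vals, totals, out=np.zeros_like(vals), where=totals > 0)
        ax.bar(x, frac, bottom=bottoms, label=lbl, color=color, width=0.5)
        bottoms += frac
    ax.set_xticks(x, [labels[g] for g in groups])
    ax.set_ylabel("Proportion of group")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=7, loc="center left", bbox_to_anchor=(1, 0.5))
    return ax


def save_figure(ax, path) -> None:
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
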
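"""Plots: LOOCV interval chart and the correlation scatter with bands."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .loocv import LoocvResult, loocv_plot_data  # noqa: E402
from .wlr_ste import WLRResults  # noqa: E402

__all__ = ["plot_loocv", "plot_scatter"]


def plot_loocv(result: LoocvResult, ax=None, title: str = ""):
    """Observed vs predicted true-endpoint HRs with 95% prediction intervals."""
    table = loocv_plot_data(result)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * len(table) + 1.5))
    ypos = np.arange(len(table))[::-1]
    ax.errorbar(
        table["predicted_hr"], ypos,
        xerr=[table["predicted_hr"] - table["lower_hr"],
              table["upper_hr"] - table["predicted_hr"]],
        fmt="o", color="tab:blue", capsize=3, label="predicted (95% PI)",
    )
    colors = ["tab:green" if w else "tab:red" for w in table["within"]]
    ax.scatter(table["observed_hr"], ypos, marker="D", c=colors, zorder=3,
               label="observed")
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["trial_id"])
    ax.set_xlabel("overall survival HR")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_scatter(effects, fit: WLRResults, ax=None, level: float = 0.95,
                 title: str = ""):
    """Log-HR scatter with the WLR line, confidence and prediction bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    y1 = np.array([e.y1 for e in effects])
    y2 = np.array([e.y2 for e in effects])
    span = y1.max() - y1.min()
    xs = np.linspace(y1.min() - 0.1 * span, y1.max() + 0.1 * span, 200)
    lo_c, hi_c = fit.prediction_interval(xs, level=level, band="confidence")
    lo_p, hi_p = fit.prediction_interval(xs, level=level, band="prediction")
    ax.fill_between(xs, lo_p, hi_p, color="tab:blue", alpha=0.10,
                    label=f"{level:.0%} prediction band")
    ax.fill_between(xs, lo_c, hi_c, color="tab:blue", alpha=0.25,
                    label=f"{level:.0%} confidence band")
    ax.plot(xs, fit.predict(xs), color="tab:blue")
    sizes = 40.0 * fit.weights / fit.weights.mean()
    ax.scatter(y1, y2, s=np.clip(sizes, 10, 300), color="tab:orange",
               edgecolor="k", lw=0.5, zorder=3)
    for e in effects:
        ax.annotate(e.trial_id, (e.y1, e.y2), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("log HR, surrogate endpoint (rPFS)")
    ax.set_ylabel("log HR, true endpoint (OS)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax
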
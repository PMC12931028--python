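"""Plots for standardized survival curves, contrasts and cluster rankings."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_curves(estimates, contrasts=None, out=None):
    """Survival-probability panel (A) and, when contrasts are given, a
    difference panel (B), with CI bands where available.

    ``estimates``/``contrasts`` are sequences of StandardizedEstimate /
    ContrastEstimate.  Returns the matplotlib figure.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to plot")
    ncols = 2 if contrasts else 1
    fig, axes = plt.subplots(1, ncols, figsize=(6 * ncols, 4.5), squeeze=False)
    ax = axes[0, 0]
    for est in estimates:
        label = _label(est)
        (line,) = ax.plot(est.times, est.values, label=label)
        if est.lower is not None:
            ax.fill_between(est.times, est.lower, est.upper,
                            color=line.get_color(), alpha=0.2, lw=0)
    ax.set_xlabel("time")
    ax.set_ylabel("standardized survival probability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    ax.set_title("A")
    if contrasts:
        axb = axes[0, 1]
        for con in contrasts:
            lbl = f"{_label_meta(con.minuend)} - {_label_meta(con.subtrahend)}"
            (line,) = axb.plot(con.times, con.differences, label=lbl)
            if con.lower is not None:
                axb.fill_between(con.times, con.lower, con.upper,
                                 color=line.get_color(), alpha=0.2, lw=0)
        axb.axhline(0.0, color="grey", lw=0.8)
        axb.set_xlabel("time")
        axb.set_ylabel("difference in survival probability")
        axb.legend(fontsize=8)
        axb.set_title("B")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig


def _label(est):
    return _label_meta({"estimand": est.estimand, "surgeon_id": est.surgeon_id,
                        "center_id": est.center_id})


def _label_meta(meta):
    parts = []
    if meta.get("surgeon_id"):
        parts.append(f"surgeon {meta['surgeon_id']}")
    if meta.get("center_id"):
        parts.append(f"center {meta['center_id']}")
    if not parts:
        parts.append("theoretical average")
    if "marginal" in (meta.get("estimand") or ""):
        parts.append("(marginal)")
    return " ".join(str(p) for p in parts)


def plot_ranking(ranking, reference=None, out=None):
    """Caterpillar plot of a cluster ranking table with risk categories.

    ``ranking`` is the DataFrame from
    :func:`stdsurv.standardize.rank_clusters`; a horizontal reference line
    marks the theoretical-average value.
    """
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"low": "tab:green", "medium": "black", "high": "tab:red",
              "uncategorized": "tab:gray"}
    x = np.arange(1, len(ranking) + 1)
    for cat in ranking["category"].unique():
        sub = ranking[ranking.category == cat]
        xi = x[ranking.category.to_numpy() == cat]
        yerr = None
        if sub[["lower", "upper"]].notna().all().all():
            yerr = np.vstack([sub.estimate - sub.lower, sub.upper - sub.estimate])
        ax.errorbar(xi, sub.estimate, yerr=yerr, fmt="o",
                    color=colors.get(cat, "black"), label=f"{cat}-risk",
                    capsize=2, ms=4, lw=1)
        for xv, row in zip(xi, sub.itertuples()):
            ax.annotate(str(row.cluster_id), (xv, row.estimate),
                        textcoords="offset points", xytext=(0, 6), fontsize=6,
                        ha="center")
    ref = reference if reference is not None else ranking.attrs.get("reference")
    if ref is not None:
        ax.axhline(ref, color="grey", ls="--", lw=0.8, label="average")
    ax.set_xlabel("rank (best first)")
    ax.set_ylabel("standardized survival probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
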
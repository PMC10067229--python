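"""Figures: per-group feature trajectories over 3-hour bins, and ROC curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

_GROUP_COLORS = {"NOD": "tab:green", "SOD": "tab:blue", "POD": "tab:red"}


def plot_feature_trajectories(
    summaries: pd.DataFrame, labels: pd.DataFrame, feature: str, kind: str = "mean", ax=None
):
    """Median and IQR band of one feature per group across 3-hour bins."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lab = labels.set_index("patient_id")["label"]
    df = summaries.merge(lab.rename("label"), left_on="patient_id", right_index=True)
    col = f"{kind}_{feature}"
    for g, color in _GROUP_COLORS.items():
        sub = df[df["label"] == g]
        stats = sub.groupby("bin_index")[col].quantile([0.25, 0.5, 0.75]).unstack()
        if stats.empty:
            continue
        t = stats.index * 3 + 1.5
        ax.plot(t, stats[0.5], color=color, label=g)
        ax.fill_between(t, stats[0.25], stats[0.75], color=color, alpha=0.2)
    ax.set_xlabel("hours from ED admission")
    ax.set_ylabel(f"{kind} {feature}")
    ax.legend()
    return ax


def plot_roc_curves(scores: dict[str, np.ndarray], y: np.ndarray, ax=None):
    """Empirical ROC curve per named score, with AUROC in the legend."""
    import matplotlib.pyplot as plt

    from .model import roc_auc

    if ax is None:
        _, ax = plt.subplots()
    y = np.asarray(y).astype(int)
    for name, s in scores.items():
        s = np.asarray(s, dtype=float)
        order = np.argsort(-s, kind="stable")
        tp = np.cumsum(y[order] == 1) / max(y.sum(), 1)
        fp = np.cumsum(y[order] == 0) / max((1 - y).sum(), 1)
        ax.plot(np.r_[0, fp], np.r_[0, tp], label=f"{name} (AUC {roc_auc(s, y):.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax
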
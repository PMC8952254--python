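"""Figure helpers: accuracy-vs-subset-size curve, ROC overlay, top-5 boxplots."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import roc_curve

from .containers import AGGRESSIVE, FeatureMatrix
from .selection import SubsetSearchTrace


def plot_accuracy_vs_size(trace: SubsetSearchTrace, path) -> None:
    """Model cross-validated accuracy as a function of subset size."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(trace.subset_sizes, trace.cv_accuracy, marker=".", lw=1)
    ax.axvline(trace.best_size, color="red", ls="--", lw=1,
               label=f"best size = {trace.best_size}")
    ax.set_xlabel("number of features")
    ax.set_ylabel("cross-validated accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc_overlay(curves: dict, path, positive=AGGRESSIVE) -> None:
    """Overlayed ROC curves; ``curves`` maps name -> (labels, scores)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, (labels, scores) in curves.items():
        fpr, tpr, _ = roc_curve(np.asarray(labels) == positive, scores)
        ax.plot(fpr, tpr, label=name)
    ax.plot([0, 1], [0, 1], color="gray", ls=":", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_top_features_boxplots(F: FeatureMatrix, pvalues, path, top: int = 5,
                               positive=AGGRESSIVE) -> None:
    """Boxplots of the ``top`` smallest-P features, split by class."""
    names = list(pvalues.sort_values().index[:top])
    y = F.labels.to_numpy() == positive
    fig, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 4), squeeze=False)
    for ax, name in zip(axes[0], names):
        vals = F.frame[name].to_numpy()
        ax.boxplot([vals[~y], vals[y]], tick_labels=["non-agg", "agg"])
        ax.set_title(name, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
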
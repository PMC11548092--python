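"""Diagnostic figures: training curves, averaged ROC, confusion heatmap."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import ConfusionMatrix, ROCSet
from .models import TrainHistory
from .simulate import CLASSES

__all__ = ["plot_history", "plot_roc", "plot_confusion"]


def plot_history(history: TrainHistory, path: str | Path) -> None:
    """Train/test loss and accuracy per epoch, two stacked panels."""
    fig, (ax_l, ax_a) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    epochs = np.arange(1, len(history.train_loss) + 1)
    ax_l.plot(epochs, history.train_loss, label="train")
    ax_l.plot(epochs, history.test_loss, label="test")
    ax_l.set_ylabel("cross-entropy loss")
    ax_l.legend()
    ax_a.plot(epochs, history.train_acc, label="train")
    ax_a.plot(epochs, history.test_acc, label="test")
    ax_a.set_xlabel("epoch")
    ax_a.set_ylabel("accuracy")
    ax_a.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(rocset: ROCSet, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for c, (fpr, tpr) in rocset.per_class_curves.items():
        ax.plot(fpr, tpr, alpha=0.5,
                label=f"{CLASSES[c]} (AUC {rocset.auc_per_class[c]:.3f})")
    gx, gy = rocset.mean_curve
    ax.plot(gx, gy, "k-", lw=2, label=f"mean (AUC {rocset.mean_auc:.3f})")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(cm: ConfusionMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(CLASSES)), CLASSES, rotation=45)
    ax.set_yticks(range(len(CLASSES)), CLASSES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(cm.counts.shape[0]):
        for j in range(cm.counts.shape[1]):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="white" if cm.counts[i, j] > cm.counts.max() / 2 else "black")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
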
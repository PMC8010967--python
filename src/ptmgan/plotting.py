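"""Cosmetic diagnostic plots (ROC curves, confusion bubbles, loss traces)."""

from __future__ import annotations

import numpy as np


def plot_loss_trace(trace, ax=None):
    """Generator/critic loss per iteration."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    it = np.arange(1, len(trace) + 1)
    ax.plot(it, trace.g_loss, label="Gloss", lw=0.8)
    ax.plot(it, trace.d_loss, label="Dloss", lw=0.8)
    ax.set_xlabel("iteration")
    ax.set_ylabel("loss")
    ax.legend()
    return ax


def plot_roc(scores, y_true, class_names, ax=None):
    """One-vs-rest ROC curve per class."""
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    if ax is None:
        _, ax = plt.subplots()
    for j, name in enumerate(class_names):
        fpr, tpr, _ = roc_curve((np.asarray(y_true) == j + 1).astype(int), scores[:, j])
        ax.plot(fpr, tpr, label=name, lw=1.0)
    ax.plot([0, 1], [0, 1], "k--", lw=0.6)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize="small")
    return ax


def plot_confusion_bubbles(cm, class_names, ax=None):
    """True-vs-predicted bubble chart; bubble area tracks the count."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cm = np.asarray(cm)
    K = cm.shape[0]
    for i in range(K):
        for j in range(K):
            if cm[i, j]:
                ax.scatter(j, i, s=20 + 400 * cm[i, j] / cm.max(), alpha=0.6, c="tab:blue")
    ax.set_xticks(range(K), class_names, rotation=45)
    ax.set_yticks(range(K), class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.invert_yaxis()
    return ax
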
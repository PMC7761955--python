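"""Minimal diagnostic plots: OPLS-DA scores, permutation histogram, ROC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import RocCurve
from .multivariate import OplsModel, PermutationResult


def score_plot(model: OplsModel, y, path: str | Path) -> None:
    """Predictive vs first orthogonal (or index) score scatter by class."""
    t = model.scores
    t_o = model.ortho_scores[0] if model.ortho_scores else np.arange(len(t))
    y = np.asarray(y)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, marker in zip(np.unique(y), "ox^s"):
        m = y == cls
        ax.scatter(t[m], t_o[m], marker=marker, label=str(cls), alpha=0.7)
    ax.set_xlabel("predictive score t[1]")
    ax.set_ylabel("orthogonal score to[1]" if model.ortho_scores else "sample index")
    ax.set_title(f"OPLS-DA  R2Y={model.r2y:.3f}  Q2={model.q2:.3f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def permutation_plot(result: PermutationResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(result.permuted_q2, bins=30, alpha=0.6, label="permuted Q2")
    ax.hist(result.permuted_r2y, bins=30, alpha=0.6, label="permuted R2Y")
    ax.axvline(result.observed_q2, color="C0", ls="--",
               label=f"Q2={result.observed_q2:.3f} (pQ2={result.p_q2:.3g})")
    ax.axvline(result.observed_r2y, color="C1", ls=":",
               label=f"R2Y={result.observed_r2y:.3f}")
    ax.set_xlabel("statistic under label permutation")
    ax.set_ylabel("count")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def roc_plot(rocs: dict[str, RocCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, roc in rocs.items():
        order = np.argsort(1 - roc.specificity)
        ax.plot((1 - roc.specificity)[order], roc.sensitivity[order],
                label=f"{name} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
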
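"""Convenience plots: PCA score maps and obtained-vs-expected comparisons.

These are presentation helpers, not part of the numerical contract.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .discrimination import ClassEllipse
from .quantify import RegressionReport


def score_plot(scores: np.ndarray, labels: np.ndarray,
               ellipses: dict[str, ClassEllipse] | None = None,
               path: Path | None = None) -> plt.Figure:
    """2-D PCA score plot, one color per class, optional 95% ellipses."""
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for label in dict.fromkeys(labels):  # first-appearance order
        mask = labels == label
        ax.scatter(scores[mask, 0], scores[mask, 1], s=18, label=str(label))
        if ellipses and label in ellipses:
            b = ellipses[label].boundary()
            ax.plot(np.r_[b[:, 0], b[0, 0]], np.r_[b[:, 1], b[0, 1]],
                    lw=0.8, color=ax.collections[-1].get_facecolor()[0])
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def comparison_plot(predicted: np.ndarray, expected: np.ndarray,
                    report: RegressionReport | None = None,
                    analytes: tuple[str, ...] = ("CFX", "LFX", "MFX"),
                    path: Path | None = None) -> plt.Figure:
    """Obtained-vs-expected scatter per analyte with the ideal y = x line."""
    n = expected.shape[1]
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), squeeze=False)
    for j, ax in enumerate(axes[0]):
        ax.scatter(expected[:, j], predicted[:, j], s=18)
        lims = [0, max(expected[:, j].max(), predicted[:, j].max()) * 1.05]
        ax.plot(lims, lims, "k--", lw=0.8)
        title = analytes[j] if j < len(analytes) else f"analyte {j}"
        if report is not None:
            title += f" (R²={report.analytes[j].r2:.3f})"
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("expected (μM)")
        if j == 0:
            ax.set_ylabel("obtained (μM)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
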
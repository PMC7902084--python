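"""Headless-safe diagnostic plots: score histograms, purity and ROC curves."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_score_histogram(f_tilde, labels, path):
    """Overlaid f~ histograms for singles (label 1) and non-singles."""
    plt = _pyplot()
    f_tilde = np.asarray(f_tilde)
    labels = np.asarray(labels).astype(bool)
    bins = np.linspace(min(-0.5, f_tilde.min()), max(1.5, f_tilde.max()), 120)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(f_tilde[labels], bins=bins, alpha=0.6, color="crimson", label="single")
    ax.hist(f_tilde[~labels], bins=bins, alpha=0.6, color="steelblue", label="non-single")
    ax.set_xlabel(r"prediction $\tilde{f}$")
    ax.set_ylabel("snapshots")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_purity(report, path):
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(report.tau, report.chi, color="black")
    i = int(np.argmax(report.chi))
    ax.plot(report.tau[i], report.chi[i], "P", color="purple", markersize=9)
    ax.set_xlabel(r"cutoff $\tau$")
    ax.set_ylabel(r"purity $\chi$")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_roc(report, path):
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.fpr, report.tpr, color="black")
    ax.plot([0, 1], [0, 1], ":", color="gray")
    i = int(np.argmax(report.tpr - report.fpr))
    ax.plot(report.fpr[i], report.tpr[i], "o", color="purple")
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
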
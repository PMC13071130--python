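"""Optional figure export: ROC curves, signal importances, templates."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .evaluation import CvResult, RocCurve
from .templates import Template


def plot_roc(curves: dict[str, RocCurve], path) -> None:
    """False-alarms-per-week vs event sensitivity, one line per run."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in sorted(curves.items()):
        ax.plot(curve.fa_per_week, curve.event_sensitivity,
                label=f"{name} (AUROC {curve.auroc_0_7:.2f})")
    ax.set_xlabel("false alarms per week")
    ax.set_ylabel("event sensitivity")
    ax.set_xlim(0, 7)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_importances(summary: pd.DataFrame, path) -> None:
    """Mean fitted weight per signal with bootstrap CI error bars."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    err = [
        summary["mean_weight"] - summary["ci_low"],
        summary["ci_high"] - summary["mean_weight"],
    ]
    ax.bar(summary["signal"], summary["mean_weight"], yerr=err, capsize=3)
    ax.set_ylabel("signal importance (mean weight)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_templates(templates: dict[str, Template], path) -> None:
    """Baseline-subtracted pre-onset trajectories, one panel per signal."""
    n = len(templates)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.5), squeeze=False)
    for ax, sig in zip(axes[0], sorted(templates)):
        t = templates[sig]
        offsets = range(-t.lookback, 0)
        ax.plot(list(offsets), t.values, marker="o", ms=3)
        ax.axhline(0.0, color="grey", lw=0.6)
        ax.set_title(f"{sig} (n={t.n_events})", fontsize=9)
        ax.set_xlabel("days to onset", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cv(cv: CvResult, summary: pd.DataFrame, out_dir) -> list[str]:
    """Standard figure set for one cross-validated run."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    plot_roc({f"T={cv.lookback}": cv.roc}, out_dir / "roc.svg")
    written.append("roc.svg")
    plot_importances(summary, out_dir / "importances.svg")
    written.append("importances.svg")
    first = sorted(cv.fold_templates)[0]
    plot_templates(cv.fold_templates[first], out_dir / "templates.svg")
    written.append("templates.svg")
    return written
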
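"""ROC / PR curve export (the package's only visualisation)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .classify import EvalReport  # noqa: E402


def save_roc_pr(report: EvalReport, path: str | Path) -> Path:
    """Write a two-panel ROC and precision-recall figure."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(8, 3.6))
    ax_roc.plot(report.roc_points["fpr"], report.roc_points["tpr"], lw=1.5)
    ax_roc.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax_roc.set(xlabel="false positive rate", ylabel="true positive rate",
               title=f"ROC (AUROC {report.auroc:.3f})")
    ax_pr.plot(report.pr_points["recall"], report.pr_points["precision"],
               lw=1.5, drawstyle="steps-post")
    ax_pr.set(xlabel="recall", ylabel="precision",
              title=f"PR (AUPRC {report.auprc:.3f})", ylim=(0, 1.05))
    fig.tight_layout()
    # strip the embedded timestamp so identical runs give identical bytes
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return path
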
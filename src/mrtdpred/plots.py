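"""Static validation figures: method-comparison scatter and Bland-Altman."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .validation import AgreementReport, ModelComparison


def bland_altman_plot(report: AgreementReport, ax=None, title: str | None = None):
    """Differences against averages with bias and limit-of-agreement lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.averages, report.differences, color="k", s=25, zorder=3)
    for y, style in (
        (report.bias, "-"),
        (report.upper_loa, "--"),
        (report.lower_loa, "--"),
    ):
        ax.axhline(y, color="gray", linestyle=style, linewidth=1)
    ax.set_xlabel("average of clinical and predicted MRTD (mg/kg/day)")
    ax.set_ylabel("clinical - predicted (mg/kg/day)")
    if title:
        ax.set_title(title)
    return ax


def comparison_plot(comparison: ModelComparison, ax=None):
    """Per-compound clinical doses with both models' predictions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    a, b = comparison.reports
    names = a.predictions.table["name"]
    x = range(len(names))
    ax.plot(x, a.predictions.table["clinical"], "ko-", label="clinical")
    ax.plot(x, a.predictions.table["predicted"], "s--", mfc="none", label=a.label)
    ax.plot(x, b.predictions.table["predicted"], "s--", label=b.label)
    ax.set_xticks(list(x))
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylabel("MRTD (mg/kg/day)")
    ax.legend()
    return ax


def save_comparison_figures(comparison: ModelComparison, directory) -> list[str]:
    """Write the scatter and both Bland-Altman panels as PNGs."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    ax = comparison_plot(comparison)
    path = directory / "method_comparison.png"
    ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(ax.figure)
    written.append(str(path))

    for rep in comparison.reports:
        ax = bland_altman_plot(rep.agreement, title=rep.label)
        path = directory / f"bland_altman_{rep.label}.png"
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
        written.append(str(path))
    return written
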
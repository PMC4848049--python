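"""Optional grid rendering of a classified survey.

Follows the bench convention: red for sites with no detectable MAP,
green for viable (MAP-bearing) tissue.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .classify import Label, SurveyReport
from .synth import LesionPattern

_COLORS = {
    Label.GAP: "#2ca02c",
    Label.CONDUCTIVE: "#2ca02c",
    Label.NON_CONDUCTIVE: "#d62728",
    Label.INDETERMINATE: "#bdbdbd",
}


def plot_survey_grid(
    report: SurveyReport,
    pattern: Optional[LesionPattern] = None,
    path: str | Path | None = None,
):
    """Render site labels on their grid positions (site ids like ``B3``:
    row letter, column number). Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    in_pattern = set()
    if pattern is not None:
        in_pattern = {s.site_id for s in pattern.sites if s.in_pattern}

    fig, ax = plt.subplots(figsize=(5, 5))
    for c in report.classifications:
        sid = c.site_id
        try:
            row = ord(sid[0].upper()) - ord("A")
            col = int(sid[1:]) - 1
        except (ValueError, IndexError):
            continue
        ax.add_patch(
            plt.Rectangle(
                (col, -row), 0.9, 0.9,
                facecolor=_COLORS[c.label],
                edgecolor="black" if sid in in_pattern else "none",
                linewidth=2,
            )
        )
        txt = sid if c.cf_evidence is None else f"{sid}\n{c.cf_evidence:.1f} g"
        ax.text(col + 0.45, -row + 0.45, txt, ha="center", va="center", fontsize=8)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title("red: no MAP; green: viable tissue; outline: lesion pattern")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
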
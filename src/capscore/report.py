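"""Deterministic report rendering.

One accuracy table per outcome, criteria as columns and metrics as rows,
cells formatted ``est% (lo–hi)`` with one decimal place (round half away
from zero), plus a severity/outcome count breakdown and the excluded-record
ledger.  Emitted both as TSV and as aligned plain text.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .diagnostics import DiagnosticSummary, MetricEstimate, OutcomeKind
from .comparison import McNemarResult, WilcoxonResult
from .scoring import CriterionName

__all__ = ["format_percent", "format_cell", "accuracy_table", "render_report"]

_METRIC_LABELS = {
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "ppv": "Positive predictive value",
    "npv": "Negative predictive value",
}


def format_percent(proportion: float) -> str:
    """One-decimal percent, round half away from zero (so 22.58 -> '22.6')."""
    q = Decimal(str(100 * proportion)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{q}"


def format_cell(metric: MetricEstimate) -> str:
    if not metric.defined:
        return "undefined"
    return (
        f"{format_percent(metric.estimate)}% "
        f"({format_percent(metric.ci_lower)}–{format_percent(metric.ci_upper)})"
    )


def accuracy_table(
    summaries: Mapping[CriterionName, DiagnosticSummary],
) -> list[list[str]]:
    """Rows: header then one row per metric; columns follow criterion order."""
    names = list(summaries)
    rows = [["Metric"] + [n.value for n in names]]
    for key, label in _METRIC_LABELS.items():
        rows.append(
            [label] + [format_cell(summaries[n].metrics()[key]) for n in names]
        )
    return rows


def _align(rows: Sequence[Sequence[str]]) -> str:
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    )


def render_report(
    summaries: Mapping[OutcomeKind, Mapping[CriterionName, DiagnosticSummary]],
    comparisons: Optional[Sequence[tuple[str, WilcoxonResult | McNemarResult]]] = None,
) -> dict[str, str]:
    """Render accuracy tables (and optional comparisons) as text and TSV.

    Returns ``{"text": ..., "tsv": ...}``; output is deterministic given the
    inputs.  An empty comparison list omits the comparison section.
    """
    if not summaries:
        raise ValueError("at least one summary required")
    text_parts: list[str] = []
    tsv_parts: list[str] = []
    for outcome, per_criterion in summaries.items():
        title = {
            OutcomeKind.death: "Six-week mortality",
            OutcomeKind.death_or_icu: "Mortality and/or ICU admission",
        }[outcome]
        rows = accuracy_table(per_criterion)
        text_parts.append(f"## {title}\n{_align(rows)}")
        tsv_parts.append(
            f"# {title}\n" + "\n".join("\t".join(r) for r in rows)
        )
        counts = [["Criterion", "severe", "non-severe", "events", "excluded"]]
        for name, summary in per_criterion.items():
            t = summary.table
            counts.append(
                [
                    name.value,
                    str(t.n_severe),
                    str(t.n_analysed - t.n_severe),
                    str(t.n_events),
                    str(t.excluded),
                ]
            )
        text_parts.append(_align(counts))
        tsv_parts.append("\n".join("\t".join(r) for r in counts))

    if comparisons:
        rows = [["Comparison", "statistic", "p-value", "note"]]
        for label, result in comparisons:
            if isinstance(result, WilcoxonResult):
                stat = f"{result.statistic:g}"
            else:
                stat = f"{result.discordant[0]}/{result.discordant[1]}"
            rows.append(
                [label, stat, f"{result.pvalue:.4f}", result.warning or ""]
            )
        text_parts.append("## Paired comparisons\n" + _align(rows))
        tsv_parts.append(
            "# Paired comparisons\n" + "\n".join("\t".join(r) for r in rows)
        )

    return {"text": "\n\n".join(text_parts) + "\n", "tsv": "\n\n".join(tsv_parts) + "\n"}
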
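"""Forest-table construction and the packaged seven-study reanalysis.

:func:`reproduce_builtin_analysis` runs the whole per-allele pipeline on
the packaged rs4988235 table: a per-allele odds ratio for each of the seven
studies, a fixed-effects combination for each disease with two independent
samples (multiple sclerosis, Alzheimer's disease, Parkinson's disease) with
heterogeneity statistics, and a pass-through summary row for the
single-study disease (amyotrophic lateral sclerosis). The result is a
forest table — eleven rows of label/OR/CI/p plus inverse-variance member
weights — and a JSON-ready report carrying the same numbers at full
precision, so nothing drifts between display rounding and machine output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from . import meta as meta_mod
from .mr_core import RatioEstimate, per_allele_estimate
from .summary_io import FIXTURE_DISEASE_GROUPS, StudyTable, builtin_study_fixture

__all__ = ["ForestRow", "forest_rows", "reproduce_builtin_analysis", "render_forest_table"]


@dataclass(frozen=True)
class ForestRow:
    """One line of a forest table: a member study or a disease summary."""

    label: str
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    weight_percent: float | None
    is_summary: bool

    def __post_init__(self) -> None:
        if self.is_summary and self.weight_percent is not None:
            raise ValueError("summary rows carry no weight")
        if not self.is_summary and not 0.0 < (self.weight_percent or 0.0) <= 100.0:
            raise ValueError("member weight_percent must lie in (0, 100]")


def forest_rows(
    estimates: Sequence[RatioEstimate],
    combined: meta_mod.MetaResult | None,
    summary_label: str | None = None,
) -> list[ForestRow]:
    """Member rows (with inverse-variance weight shares) plus a summary row."""
    total_weight = sum(e.weight for e in estimates)
    rows = [
        ForestRow(
            label=e.label,
            or_point=e.or_point,
            ci_low=e.ci_low,
            ci_high=e.ci_high,
            p=e.p,
            weight_percent=100.0 * e.weight / total_weight,
            is_summary=False,
        )
        for e in estimates
    ]
    if combined is not None:
        rows.append(
            ForestRow(
                label=summary_label or combined.disease_label,
                or_point=combined.or_point,
                ci_low=combined.ci_low,
                ci_high=combined.ci_high,
                p=combined.p,
                weight_percent=None,
                is_summary=True,
            )
        )
    elif len(estimates) == 1:
        e = estimates[0]
        rows.append(
            ForestRow(
                label=summary_label or e.label,
                or_point=e.or_point,
                ci_low=e.ci_low,
                ci_high=e.ci_high,
                p=e.p,
                weight_percent=None,
                is_summary=True,
            )
        )
    return rows


def reproduce_builtin_analysis(
    table: StudyTable | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
    confidence: float = 0.95,
) -> tuple[list[ForestRow], dict[str, object]]:
    """Per-allele ORs, disease-level combinations and heterogeneity.

    With no arguments, analyses the packaged seven-study rs4988235 table
    under its packaged disease groupings. Returns the forest rows and a
    full-precision report dictionary (per-study estimates, per-disease
    combined results with Q/I²/p_het, and the member weight shares).
    """
    table = table if table is not None else builtin_study_fixture()
    groups = groups if groups is not None else FIXTURE_DISEASE_GROUPS

    per_study = {label: per_allele_estimate(table[label], confidence) for label in table.labels}
    rows: list[ForestRow] = []
    report: dict[str, object] = {
        "per_study": {label: est.as_dict() for label, est in per_study.items()},
        "combined": {},
    }
    for disease, members in groups.items():
        estimates = [per_study[m] for m in members]
        if len(estimates) >= 2:
            combined = meta_mod.fixed_effects_meta(estimates, disease)
            report["combined"][disease] = combined.as_dict()
            rows.extend(forest_rows(estimates, combined, summary_label=f"{disease} (combined)"))
        else:
            rows.extend(forest_rows(estimates, None, summary_label=f"{disease} (single study)"))
            report["combined"][disease] = {
                "disease_label": disease,
                "member_labels": list(members),
                **{k: v for k, v in estimates[0].as_dict().items() if k not in ("label", "scale", "units")},
                "q_stat": 0.0,
                "q_df": 0,
                "p_het": 1.0,
                "i2_percent": 0.0,
                "note": "single study; estimate passes through unchanged",
            }
    report["forest"] = [row.__dict__ for row in rows]
    return rows, report


def render_forest_table(rows: Sequence[ForestRow], or_decimals: int = 2, p_sigfigs: int = 3) -> str:
    """Plain-text forest table, ORs/CIs rounded for display."""
    lines = [f"{'label':<42}{'OR':>8}{'95% CI':>16}{'p':>12}{'weight':>9}"]
    for row in rows:
        ci = f"({row.ci_low:.{or_decimals}f}-{row.ci_high:.{or_decimals}f})"
        weight = "" if row.weight_percent is None else f"{row.weight_percent:.1f}%"
        marker = "*" if row.is_summary else " "
        lines.append(
            f"{marker}{row.label:<41}{row.or_point:>8.{or_decimals}f}{ci:>16}{row.p:>12.{p_sigfigs}g}{weight:>9}"
        )
    return "\n".join(lines)


def forest_plot(rows: Sequence[ForestRow], path: str) -> None:
    """Optional graphic rendering of a forest table (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.45 * len(rows) + 1.2))
    ys = range(len(rows), 0, -1)
    for y, row in zip(ys, rows):
        colour = "firebrick" if row.is_summary else "steelblue"
        ax.plot([row.ci_low, row.ci_high], [y, y], color=colour, lw=1.5)
        ax.plot(
            [row.or_point],
            [y],
            marker="D" if row.is_summary else "s",
            color=colour,
            markersize=7 if row.is_summary else 5,
        )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(ys))
    ax.set_yticklabels([r.label for r in rows])
    ax.set_xlabel("Odds ratio per effect allele (log scale)")
    ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
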
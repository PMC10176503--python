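"""Quality review: summarise what QC did to the dataset.

Compares a dataset before and after processing at three grains: value-level
modification tracking (unchanged / substitution / removal / addition per
cell), tallies of value combinations per variable selection, completeness
distributions, and variable-level additions/removals.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import HealthTable, as_number, is_missing
from .quality import assess_completeness

__all__ = [
    "KINDS",
    "ModificationRecord",
    "count_compare",
    "track_modifications",
    "compare_completeness",
    "variable_diff",
    "quality_report_markdown",
]

KINDS = ("unchanged", "substitution", "removal", "addition")

#: Label under which the missing marker appears in tallies.
NA_LABEL = "NA"


@dataclass(frozen=True)
class ModificationRecord:
    """Classification of one cell's change between two dataset versions.

    removal: value -> missing; addition: missing -> value; substitution:
    both present and different; unchanged otherwise.
    """

    record_id: str
    variable: str
    before: object
    after: object
    kind: str


def _canonical(value) -> str:
    """String form for comparison: numbers at 12 significant digits so that
    float noise does not register as a substitution."""
    num = as_number(value)
    if num is not None:
        return f"{num:.12g}"
    return str(value)


def _classify(before, after) -> str:
    b_missing, a_missing = is_missing(before), is_missing(after)
    if b_missing and a_missing:
        return "unchanged"
    if not b_missing and a_missing:
        return "removal"
    if b_missing and not a_missing:
        return "addition"
    return "unchanged" if _canonical(before) == _canonical(after) else "substitution"


def count_compare(
    before: HealthTable, after: HealthTable, variables: list[str]
) -> pd.DataFrame:
    """Tally of unique value combinations before vs after.

    Rows are the union of combinations observed in either table over the
    chosen *variables*, with before/after counts; missing renders as "NA".
    """
    if not variables:
        raise ValueError("variable selection must be non-empty")
    for var in variables:
        if var not in before.variables and var not in after.variables:
            raise ValueError(f"variable {var!r} absent from both tables")

    def combos(table: HealthTable):
        counts: dict[tuple, int] = {}
        for rec in table.records:
            key = tuple(
                NA_LABEL if (var not in table.variables
                             or is_missing(table.values(var)[rec]))
                else str(table.values(var)[rec])
                for var in variables
            )
            counts[key] = counts.get(key, 0) + 1
        return counts

    before_counts = combos(before)
    after_counts = combos(after)
    rows = []
    for key in sorted(set(before_counts) | set(after_counts)):
        row = dict(zip(variables, key))
        row["before_count"] = before_counts.get(key, 0)
        row["after_count"] = after_counts.get(key, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=[*variables, "before_count", "after_count"])


def track_modifications(
    before: HealthTable, after: HealthTable
) -> tuple[list[ModificationRecord], pd.DataFrame]:
    """Classify every compared cell and percentage per record by kind.

    Cells are compared over the shared record ids and shared variables;
    variables present in only one table are surfaced by
    :func:`variable_diff` instead.  Per-record percentages are kind counts
    over compared cells, summing to 100.
    """
    shared_records = [r for r in before.records if r in set(after.records)]
    if not shared_records:
        raise ValueError("before/after tables share no record ids")
    shared_vars = [v for v in before.variables if v in set(after.variables)]
    records: list[ModificationRecord] = []
    pct_rows = []
    for rec in shared_records:
        counts = dict.fromkeys(KINDS, 0)
        for var in shared_vars:
            b = before.values(var)[rec]
            a = after.values(var)[rec]
            kind = _classify(b, a)
            counts[kind] += 1
            records.append(ModificationRecord(rec, var, b, a, kind))
        n_cells = len(shared_vars)
        pct_rows.append({
            "record_id": rec,
            **{k: 100.0 * counts[k] / n_cells if n_cells else 0.0 for k in KINDS},
        })
    percentages = pd.DataFrame(pct_rows).set_index("record_id")
    return records, percentages


@dataclass
class CompletenessComparison:
    """Per-variable completeness of both versions with summary deltas."""

    before: pd.Series
    after: pd.Series
    threshold: float

    @property
    def mean_delta(self) -> float:
        return float(self.after.mean() - self.before.mean())

    @property
    def n_above_threshold_before(self) -> int:
        return int((self.before > self.threshold).sum())

    @property
    def n_above_threshold_after(self) -> int:
        return int((self.after > self.threshold).sum())


def compare_completeness(
    before: HealthTable, after: HealthTable, threshold: float = 0.95
) -> CompletenessComparison:
    """Paired per-variable completeness distributions and their deltas.

    *threshold* feeds the count of variables exceeding it (default 95%,
    the conventional high-completeness bar)."""
    return CompletenessComparison(
        before=assess_completeness(before).variable,
        after=assess_completeness(after).variable,
        threshold=threshold,
    )


def variable_diff(
    before: HealthTable, after: HealthTable
) -> tuple[set[str], set[str]]:
    """(added, removed) variable-name sets; names compared literally."""
    b, a = set(before.variables), set(after.variables)
    return a - b, b - a


def quality_report_markdown(
    before: HealthTable,
    after: HealthTable,
    zero_entropy: list[str] | None = None,
    findings=None,
) -> str:
    """Combined markdown quality report for user review."""
    comp = compare_completeness(before, after)
    added, removed = variable_diff(before, after)
    _, percentages = track_modifications(before, after)
    lines = [
        "# Quality review",
        "",
        "## Completeness",
        f"- mean variable completeness before: {comp.before.mean():.4f}",
        f"- mean variable completeness after: {comp.after.mean():.4f}",
        f"- mean delta: {comp.mean_delta:+.4f}",
        f"- variables >{comp.threshold:.0%} complete: "
        f"{comp.n_above_threshold_before} -> {comp.n_above_threshold_after}",
        "",
        "## Variables",
        f"- before: {len(before.variables)}, after: {len(after.variables)}",
        f"- added: {len(added)}, removed: {len(removed)}",
        "",
        "## Value modifications (mean % per record)",
    ]
    for kind in KINDS:
        lines.append(f"- {kind}: {percentages[kind].mean():.2f}%")
    if zero_entropy is not None:
        lines += ["", "## Zero-entropy variables",
                  f"- flagged: {len(zero_entropy)}"]
        lines += [f"  - {v}" for v in zero_entropy]
    if findings is not None:
        lines += ["", "## Internal consistency",
                  f"- findings: {len(findings)}"]
    return "\n".join(lines) + "\n"
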
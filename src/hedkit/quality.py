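"""Quality assessment and control.

Covers standardisation of ad hoc missing-value encodings to the canonical
marker, completeness profiling along both axes, the clustered completeness
matrix behind missingness heatmaps, zero-entropy flagging, and internal
consistency checking against user-supplied semantic-dependency rules
(e.g. "number of positive lymph nodes must not exceed number examined").
"""

from __future__ import annotations

import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .core import MISSING, HealthTable, as_number, is_missing

__all__ = [
    "standardise_missing",
    "CompletenessReport",
    "assess_completeness",
    "completeness_matrix",
    "zero_entropy_variables",
    "ConsistencyRule",
    "InconsistencyFinding",
    "load_consistency_rules",
    "identify_inconsistency",
]


def standardise_missing(table: HealthTable, encodings) -> tuple[HealthTable, int]:
    """Convert every cell matching one of *encodings* to the missing marker.

    String tokens match case-insensitively; numeric tokens match after
    numeric parse (so "-1" also catches "-1.0").  Idempotent: a second pass
    alters zero cells.  Each change is appended to the table's changelog.
    """
    encodings = list(encodings)
    if not encodings:
        raise ValueError("encodings must be a non-empty list of tokens")
    string_tokens = {str(e).strip().lower() for e in encodings}
    numeric_tokens = {as_number(e) for e in encodings if as_number(e) is not None}

    out = table.copy()
    altered = 0
    for var in out.variables:
        col = out.data[var]
        new = []
        for rec, v in col.items():
            if is_missing(v):
                new.append(v)
                continue
            matched = str(v).strip().lower() in string_tokens
            if not matched and numeric_tokens:
                num = as_number(v)
                matched = num is not None and num in numeric_tokens
            if matched:
                new.append(MISSING)
                altered += 1
                out.log_change(rec, var, v, MISSING, "standardise_missing")
            else:
                new.append(v)
        out.set_values(var, new)
    return out, altered


@dataclass
class CompletenessReport:
    """Per-variable and per-record completeness fractions with summaries."""

    variable: pd.Series
    record: pd.Series

    @property
    def summary(self) -> pd.DataFrame:
        rows = {}
        for axis, series in (("variable", self.variable), ("record", self.record)):
            rows[axis] = {
                "mean": float(series.mean()) if len(series) else float("nan"),
                "min": float(series.min()) if len(series) else float("nan"),
                "max": float(series.max()) if len(series) else float("nan"),
            }
        return pd.DataFrame(rows).T

    def to_csv(self, variable_path, record_path) -> None:
        self.variable.rename("completeness").to_csv(variable_path)
        self.record.rename("completeness").to_csv(record_path)


def assess_completeness(table: HealthTable) -> CompletenessReport:
    """Fraction of non-missing cells per variable and per record."""
    present = table.data.map(lambda v: not is_missing(v))
    return CompletenessReport(
        variable=present.mean(axis=0).astype(float),
        record=present.mean(axis=1).astype(float),
    )


def _encode_for_distance(table: HealthTable) -> pd.DataFrame:
    """Numeric cells pass through; non-numeric cells become the count of
    unique values in their variable; missing cells stay NaN for now."""
    nunique = {
        var: len({str(v) for v in table.values(var) if not is_missing(v)})
        for var in table.variables
    }
    out = {}
    for var in table.variables:
        col = []
        for v in table.values(var):
            if is_missing(v):
                col.append(np.nan)
            else:
                num = as_number(v)
                col.append(num if num is not None else float(nunique[var]))
        out[var] = col
    return pd.DataFrame(out, index=table.data.index, dtype=float)


def completeness_matrix(
    table: HealthTable, distant_value: float | None = None
) -> tuple[pd.DataFrame, list, list, pd.DataFrame]:
    """Numeric matrix plus clustering orders for missingness heatmaps.

    Missing cells are encoded as *distant_value* (default: twice the largest
    absolute encoded value plus one, so missingness dominates the geometry).
    Row and column orders come from single-linkage hierarchical clustering of
    Euclidean distances.  Also returns the binary present/missing mask
    (1 = present) for plotting.
    """
    mat = _encode_for_distance(table)
    if distant_value is None:
        finite = mat.to_numpy(dtype=float)
        finite = finite[np.isfinite(finite)]
        peak = float(np.abs(finite).max()) if finite.size else 0.0
        distant_value = 2.0 * (peak + 1.0)
    mat = mat.fillna(float(distant_value))
    mask = table.data.map(lambda v: 0 if is_missing(v) else 1).astype(int)

    def cluster_order(values: np.ndarray, labels: list) -> list:
        if len(labels) < 3:
            return list(labels)
        order = leaves_list(linkage(pdist(values, metric="euclidean"),
                                    method="single"))
        return [labels[i] for i in order]

    row_order = cluster_order(mat.to_numpy(), list(mat.index))
    col_order = cluster_order(mat.to_numpy().T, list(mat.columns))
    return mat, row_order, col_order, mask


def zero_entropy_variables(table: HealthTable) -> list[str]:
    """Variables with at most one distinct non-missing value.

    Such variables cannot stratify the cohort.  All-missing variables are
    included: they carry no information either way.
    """
    flagged = []
    for var in table.variables:
        if table.meta[var].vtype == "identifier":
            continue
        distinct = {str(v) for v in table.values(var) if not is_missing(v)}
        if len(distinct) <= 1:
            flagged.append(var)
    return flagged


# -- internal consistency ---------------------------------------------------

_OPERATORS = {
    "<": operator.lt,
    "<=": operator.le,
    "==": operator.eq,
    "!=": operator.ne,
    ">=": operator.ge,
    ">": operator.gt,
}


@dataclass(frozen=True)
class _Boundary:
    """Either a category set or an inclusive numeric range 'lo:hi'."""

    categories: frozenset | None = None
    lo: float | None = None
    hi: float | None = None

    def contains(self, value) -> bool:
        if self.categories is not None:
            return str(value) in self.categories
        num = as_number(value)
        if num is None:
            return False
        return self.lo <= num <= self.hi


def _parse_boundary(text: str) -> _Boundary:
    text = str(text).strip()
    if ":" in text:
        lo_s, _, hi_s = text.partition(":")
        lo, hi = as_number(lo_s), as_number(hi_s)
        if lo is None or hi is None:
            raise ValueError(f"malformed numeric range {text!r}")
        if lo > hi:
            raise ValueError(f"range {text!r} has lo > hi")
        return _Boundary(lo=lo, hi=hi)
    cats = frozenset(c.strip() for c in text.split(";") if c.strip())
    if not cats:
        raise ValueError(f"empty boundary specification {text!r}")
    return _Boundary(categories=cats)


@dataclass(frozen=True)
class ConsistencyRule:
    """One pairwise semantic dependency between two variables.

    Either *logical_test* (a numeric comparison ``var_a OP var_b``) or the
    pair of boundaries ("values of var_b must lie in var_b_boundaries
    whenever var_a lies in var_a_boundaries") is populated — never both.
    """

    var_a: str
    var_b: str
    logical_test: str | None = None
    var_a_boundaries: str | None = None
    var_b_boundaries: str | None = None

    def __post_init__(self):
        has_op = self.logical_test is not None
        has_bounds = (self.var_a_boundaries is not None
                      and self.var_b_boundaries is not None)
        if has_op == has_bounds:
            raise ValueError(
                f"rule ({self.var_a}, {self.var_b}): exactly one of logical_test "
                "or the boundary pair must be populated"
            )
        if has_op and self.logical_test not in _OPERATORS:
            raise ValueError(f"unknown operator {self.logical_test!r}")
        if has_bounds:
            _parse_boundary(self.var_a_boundaries)
            _parse_boundary(self.var_b_boundaries)

    def describe(self) -> str:
        if self.logical_test:
            return f"{self.var_a} {self.logical_test} {self.var_b}"
        return (f"{self.var_a} in [{self.var_a_boundaries}] -> "
                f"{self.var_b} in [{self.var_b_boundaries}]")


@dataclass(frozen=True)
class InconsistencyFinding:
    """One record violating one rule; both values are non-missing."""

    record_id: str
    rule: ConsistencyRule
    value_a: object
    value_b: object


def load_consistency_rules(path) -> list[ConsistencyRule]:
    """Read a rule table CSV with columns variable_a, variable_b,
    logical_test, variable_a_boundaries, variable_b_boundaries."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["variable_a", "variable_b", "logical_test",
                "variable_a_boundaries", "variable_b_boundaries"]
    missing_cols = [c for c in required if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"rules file missing columns: {missing_cols}")
    rules = []
    for i, row in frame.iterrows():
        def clean(value):
            value = str(value).strip()
            return value or None
        try:
            rules.append(ConsistencyRule(
                var_a=str(row["variable_a"]).strip(),
                var_b=str(row["variable_b"]).strip(),
                logical_test=clean(row["logical_test"]),
                var_a_boundaries=clean(row["variable_a_boundaries"]),
                var_b_boundaries=clean(row["variable_b_boundaries"]),
            ))
        except ValueError as exc:
            raise ValueError(f"rules file row {i + 2}: {exc}") from exc
    return rules


def identify_inconsistency(
    table: HealthTable,
    rules: list[ConsistencyRule],
    skip_missing: bool = True,
) -> list[InconsistencyFinding]:
    """Flag records violating any rule.

    Operator rules flag records where NOT (value_a OP value_b), compared
    numerically.  Boundary rules flag records where value_a falls inside
    var_a_boundaries while value_b falls outside var_b_boundaries.  Records
    with a missing operand are skipped (*skip_missing*, the declared default);
    with ``skip_missing=False`` a missing operand paired with a non-missing
    one also counts as a finding for operator rules.
    """
    findings: list[InconsistencyFinding] = []
    seen: set[tuple] = set()
    for rule in rules:
        for var in (rule.var_a, rule.var_b):
            if var not in table.variables:
                raise ValueError(f"rule references absent variable {var!r}")
        col_a = table.values(rule.var_a)
        col_b = table.values(rule.var_b)
        if rule.logical_test:
            op = _OPERATORS[rule.logical_test]
            for rec in table.records:
                a, b = col_a[rec], col_b[rec]
                a_missing, b_missing = is_missing(a), is_missing(b)
                if a_missing and b_missing:
                    continue
                if a_missing or b_missing:
                    if skip_missing:
                        continue
                    key = (rec, rule)
                    if key not in seen:
                        seen.add(key)
                        findings.append(InconsistencyFinding(rec, rule, a, b))
                    continue
                na, nb = as_number(a), as_number(b)
                if na is None or nb is None:
                    bad = a if na is None else b
                    raise ValueError(
                        f"operator rule {rule.describe()!r} applied to "
                        f"non-numeric value {bad!r} in record {rec!r}"
                    )
                if not op(na, nb):
                    key = (rec, rule)
                    if key not in seen:
                        seen.add(key)
                        findings.append(InconsistencyFinding(rec, rule, a, b))
        else:
            bound_a = _parse_boundary(rule.var_a_boundaries)
            bound_b = _parse_boundary(rule.var_b_boundaries)
            for rec in table.records:
                a, b = col_a[rec], col_b[rec]
                if is_missing(a) or is_missing(b):
                    continue
                if bound_a.contains(a) and not bound_b.contains(b):
                    key = (rec, rule)
                    if key not in seen:
                        seen.add(key)
                        findings.append(InconsistencyFinding(rec, rule, a, b))
    return findings


def findings_to_frame(findings: list[InconsistencyFinding]) -> pd.DataFrame:
    rows = [
        {"record_id": f.record_id, "rule": f.rule.describe(),
         "value_a": f.value_a, "value_b": f.value_b}
        for f in findings
    ]
    return pd.DataFrame(rows, columns=["record_id", "rule", "value_a", "value_b"])
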
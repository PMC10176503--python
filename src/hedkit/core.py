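"""Dataset model, import/export and semantic characterisation.

A health dataset is a rectangular table of patient records by variables.
Cells hold raw strings (as imported), numbers (after encoding) or the
canonical missing marker :data:`MISSING`.  Every variable carries a
:class:`VariableMeta` describing its semantic type; types are inferred
heuristically and must be confirmed or corrected by user review before
downstream quality-control steps.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

#: Canonical out-of-band missing marker.  It is a singleton distinct from any
#: legal cell value, so the string "NA" remains representable as a category
#: label.  Serialisation writes it as "NA".
MISSING = pd.NA

#: Legal semantic variable types.
VTYPES = (
    "continuous",
    "integer",
    "ordinal",
    "nominal_binary",
    "nominal_multi",
    "free_text",
    "identifier",
)


def is_missing(value) -> bool:
    """True if *value* is the canonical missing marker (or a float NaN)."""
    if value is MISSING or value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def as_number(value):
    """Parse *value* as a float, returning None if it is not numeric.

    Accepts ints/floats directly and numeric strings; missing → None.
    """
    if is_missing(value):
        return None
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip()
    if _NUMBER_RE.match(s):
        return float(s)
    return None


@dataclass
class VariableMeta:
    """Semantic description of one variable.

    ``ordinal_levels`` is required (non-empty, duplicate-free) iff the type is
    ordinal.  ``source`` records whether the entry came from automated
    inference or user review.
    """

    name: str
    vtype: str | None = None
    modality: str = ""
    ordinal_levels: list[str] | None = None
    source: str = "inferred"

    def __post_init__(self):
        if self.vtype is not None and self.vtype not in VTYPES:
            raise ValueError(
                f"unknown variable type {self.vtype!r} for {self.name!r}; "
                f"expected one of {VTYPES}"
            )
        if self.vtype == "ordinal":
            if not self.ordinal_levels:
                raise ValueError(
                    f"ordinal variable {self.name!r} requires ordinal_levels"
                )
            if len(set(self.ordinal_levels)) != len(self.ordinal_levels):
                raise ValueError(
                    f"ordinal_levels for {self.name!r} contain duplicates"
                )


class HealthTable:
    """Records × variables table with per-variable metadata.

    ``data`` is an object-dtype DataFrame indexed by unique record ids; cells
    are raw values or :data:`MISSING`.  ``meta`` maps every variable name to
    its :class:`VariableMeta`.  ``changelog`` accumulates per-cell change
    entries written by QC operations.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        meta: Mapping[str, VariableMeta] | None = None,
        id_name: str = "id",
        changelog: list | None = None,
    ):
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise ValueError(f"duplicate record ids: {dupes}")
        self.data = data
        self.id_name = id_name
        if meta is None:
            meta = {v: VariableMeta(name=v) for v in data.columns}
        else:
            meta = dict(meta)
            missing_meta = [v for v in data.columns if v not in meta]
            if missing_meta:
                raise ValueError(f"variables without metadata: {missing_meta}")
            meta = {v: meta[v] for v in data.columns}
        self.meta = meta
        self.changelog = list(changelog) if changelog else []

    # -- basic accessors ---------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def records(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_records(self) -> int:
        return len(self.data.index)

    def values(self, variable: str) -> pd.Series:
        if variable not in self.data.columns:
            raise KeyError(f"unknown variable {variable!r}")
        return self.data[variable]

    def copy(self) -> "HealthTable":
        return HealthTable(
            self.data.copy(),
            {v: replace(m) for v, m in self.meta.items()},
            id_name=self.id_name,
            changelog=list(self.changelog),
        )

    def set_values(self, variable: str, values) -> None:
        self.data[variable] = pd.Series(list(values), index=self.data.index, dtype=object)

    def add_variable(self, name: str, values, meta: VariableMeta | None = None) -> None:
        if name in self.data.columns:
            raise ValueError(f"variable {name!r} already exists")
        column = pd.Series(list(values), index=self.data.index,
                           dtype=object, name=name)
        self.data = pd.concat([self.data, column], axis=1)
        self.meta[name] = meta or VariableMeta(name=name)

    def drop_variable(self, name: str) -> None:
        self.data = self.data.drop(columns=[name])
        self.meta.pop(name, None)

    def log_change(self, record, variable, before, after, step: str) -> None:
        self.changelog.append(
            {"record": record, "variable": variable, "before": before,
             "after": after, "step": step}
        )

    # -- io ----------------------------------------------------------------
    def to_csv(self, path, sep: str = ",", na_rep: str = "NA") -> None:
        out = self.data.copy()
        out.index.name = self.id_name
        out.to_csv(path, sep=sep, na_rep=na_rep)

    def __repr__(self):
        return f"HealthTable({self.n_records} records x {len(self.variables)} variables)"


def import_dataset(
    path,
    format: str = "csv",
    id_column: str = "id",
    na_token: str | None = "NA",
) -> HealthTable:
    """Read a delimited text file into a :class:`HealthTable`.

    All cells are kept as raw strings; only cells equal to *na_token* become
    :data:`MISSING`.  Duplicate record ids or a missing id column raise.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"format must be 'csv' or 'tsv', got {format!r}")
    sep = "," if format == "csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in frame.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    ids = frame[id_column]
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate record ids: {dupes}")
    frame = frame.set_index(id_column)
    frame = frame.astype(object)
    if na_token is not None:
        frame = frame.mask(frame == na_token, MISSING)
    table = HealthTable(frame, id_name=id_column)
    table.meta = {v: VariableMeta(name=v) for v in table.variables}
    return table


def _token_count(value) -> int:
    return len(str(value).split())


def infer_variable_types(
    table: HealthTable,
    max_levels_nominal: int = 10,
    freetext_token_threshold: float = 3.0,
) -> dict[str, VariableMeta]:
    """Heuristic semantic typing of every variable.

    Rules, in order: all-numeric parse → continuous (integer when every value
    is integral); mean whitespace-token count above *freetext_token_threshold*
    → free_text; ≤2 distinct non-missing values → nominal_binary;
    ≤ *max_levels_nominal* distinct → nominal_multi; otherwise free_text.
    Ordinal is never inferred — it requires user review.  Deterministic.
    """
    if table.n_records == 0 or not table.variables:
        raise ValueError("cannot infer types on an empty table")
    inferred: dict[str, VariableMeta] = {}
    for var in table.variables:
        observed = [v for v in table.values(var) if not is_missing(v)]
        modality = table.meta[var].modality
        if not observed:
            inferred[var] = VariableMeta(name=var, vtype="nominal_binary",
                                         modality=modality, source="inferred")
            continue
        numbers = [as_number(v) for v in observed]
        if all(n is not None for n in numbers):
            vtype = "integer" if all(float(n).is_integer() for n in numbers) else "continuous"
            inferred[var] = VariableMeta(name=var, vtype=vtype,
                                         modality=modality, source="inferred")
            continue
        mean_tokens = sum(_token_count(v) for v in observed) / len(observed)
        if mean_tokens > freetext_token_threshold:
            vtype = "free_text"
        else:
            n_distinct = len({str(v) for v in observed})
            if n_distinct <= 2:
                vtype = "nominal_binary"
            elif n_distinct <= max_levels_nominal:
                vtype = "nominal_multi"
            else:
                vtype = "free_text"
        inferred[var] = VariableMeta(name=var, vtype=vtype,
                                     modality=modality, source="inferred")
    return inferred


def apply_user_review(
    table: HealthTable,
    inferred: Mapping[str, VariableMeta],
    overrides: Mapping[str, Mapping] | None = None,
) -> dict[str, VariableMeta]:
    """Merge user overrides into the inferred metadata map.

    Overridden entries get ``source="user"``.  Ordinal overrides are validated
    against the table: the declared levels must cover every observed label.
    """
    overrides = overrides or {}
    unknown = [v for v in overrides if v not in inferred]
    if unknown:
        raise ValueError(f"overrides reference unknown variables: {sorted(unknown)}")
    final: dict[str, VariableMeta] = {v: replace(m) for v, m in inferred.items()}
    for var, fields in overrides.items():
        base = final[var]
        kwargs = {
            "name": var,
            "vtype": fields.get("vtype", fields.get("type", base.vtype)),
            "modality": fields.get("modality", base.modality),
            "ordinal_levels": fields.get("ordinal_levels", base.ordinal_levels),
            "source": "user",
        }
        meta = VariableMeta(**kwargs)
        if meta.vtype == "ordinal":
            observed = {str(v) for v in table.values(var) if not is_missing(v)}
            uncovered = sorted(observed - set(meta.ordinal_levels))
            if uncovered:
                raise ValueError(
                    f"ordinal levels for {var!r} omit observed labels: {uncovered}"
                )
        final[var] = meta
    return final


# -- variable configuration files -----------------------------------------

def load_variable_config(path) -> tuple[dict[str, dict], list]:
    """Read a YAML variable-metadata config.

    Layout::

        missing_encodings: ["unknown", "-1", ...]
        variables:
          n_stage: {type: ordinal, modality: clinical pathology,
                    ordinal_levels: [N0, N1, N2]}

    Returns ``(overrides, missing_encodings)`` suitable for
    :func:`apply_user_review` and ``quality.standardise_missing``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    encodings = list(raw.get("missing_encodings", []))
    overrides = {}
    for var, fields in (raw.get("variables") or {}).items():
        overrides[var] = dict(fields or {})
    return overrides, encodings


def save_variable_config(path, overrides: Mapping[str, Mapping],
                         missing_encodings: Iterable) -> None:
    payload = {
        "missing_encodings": list(missing_encodings),
        "variables": {v: dict(f) for v, f in overrides.items()},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class MappingReferenceTable:
    """Lookup of original human-readable labels against numeric codes.

    One row per (variable, original_label); codes within a variable are
    consecutive integers (1-based for ordinals, 0-based for frequency
    encoding).
    """

    rows: list[dict] = field(default_factory=list)

    def add(self, variable: str, original_label: str, numeric_code: int) -> None:
        if any(r["variable"] == variable and r["original_label"] == original_label
               for r in self.rows):
            raise ValueError(
                f"duplicate mapping for ({variable!r}, {original_label!r})"
            )
        self.rows.append(
            {"variable": variable, "original_label": original_label,
             "numeric_code": int(numeric_code)}
        )

    def extend(self, other: "MappingReferenceTable") -> None:
        for r in other.rows:
            self.add(r["variable"], r["original_label"], r["numeric_code"])

    def decode(self, variable: str) -> dict[int, str]:
        """Inverse map numeric_code → original_label for one variable."""
        return {r["numeric_code"]: r["original_label"]
                for r in self.rows if r["variable"] == variable}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["variable", "original_label", "numeric_code"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
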
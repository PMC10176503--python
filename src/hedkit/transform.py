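"""Variable merging with information-loss evaluation, numeric encoding and
free-text variable extraction.

Merging two variables can silently discard information; each merge is
therefore scored by comparing the information content (IC) of every input
against its mutual information content (MIC) with the merged variable — the
merge is lossless for an input exactly when MIC equals IC, i.e. the input is
recoverable from the merged values.

Encoders turn ordinal, binary and nominal variables into numbers while
preserving original labels in a mapping reference table; a final assertion
confirms the whole dataset is numeric.
"""

from __future__ import annotations

import itertools
import re
import string
from collections import Counter
from dataclasses import dataclass

from .core import (
    MISSING,
    HealthTable,
    MappingReferenceTable,
    VariableMeta,
    as_number,
    is_missing,
)
from . import infotheory
from ._stopwords import STOPWORDS

__all__ = [
    "MergeSpec",
    "MergeAssessment",
    "merge_variables",
    "encode_ordinal",
    "encode_binary",
    "encode_onehot",
    "encode_by_frequency",
    "FreeTextSpec",
    "extract_freetext",
    "assert_all_numeric",
]

#: An input is deemed lossless when |MIC - IC| is below this, in bits.
LOSSLESS_TOL = 1e-9

#: Sentinel used in merge value-map keys to denote a missing input value.
NA_KEY = "<NA>"


@dataclass
class MergeSpec:
    """User-defined merging operation.

    ``value_map`` maps tuples of input values (one entry per input variable,
    with :data:`NA_KEY` standing for a missing input) to the merged value.
    The map must cover every observed combination.  If the merged variable is
    ordinal, ``merged_levels`` declares its level order.
    """

    inputs: list[str]
    value_map: dict[tuple, object]
    name: str
    merged_levels: list[str] | None = None

    def __post_init__(self):
        if len(self.inputs) < 2:
            raise ValueError("a merge needs at least 2 input variables")
        for key in self.value_map:
            if len(key) != len(self.inputs):
                raise ValueError(
                    f"value map key {key!r} does not match {len(self.inputs)} inputs"
                )


@dataclass
class MergeAssessment:
    """Information-loss verdicts for one merge.

    ``per_input`` maps each input variable to a dict with its IC, its MIC
    with the merged variable, and a lossless flag (MIC == IC within
    tolerance).  On complete data MIC never exceeds IC.
    """

    per_input: dict[str, dict]
    merged_ic: float
    merged_name: str

    @property
    def lossless(self) -> bool:
        return all(d["lossless"] for d in self.per_input.values())


def _merge_key(values: tuple) -> tuple:
    return tuple(NA_KEY if is_missing(v) else v for v in values)


def merge_variables(
    table: HealthTable, spec: MergeSpec
) -> tuple[HealthTable, MergeAssessment]:
    """Append the merged variable and assess information loss per input.

    The input variables are retained (removal is a separate explicit step).
    An observed input combination absent from the value map is an error.
    IC/MIC are computed on complete cases via the information-theory module;
    a combination of all-missing inputs maps to missing unless explicitly
    mapped.
    """
    for var in spec.inputs:
        if var not in table.variables:
            raise ValueError(f"merge input {var!r} not in table")
    if spec.name in table.variables:
        raise ValueError(f"merged name {spec.name!r} already exists")

    out = table.copy()
    merged = []
    for rec in out.records:
        raw = tuple(out.values(var)[rec] for var in spec.inputs)
        key = _merge_key(raw)
        if key in spec.value_map:
            merged.append(spec.value_map[key])
        elif all(k == NA_KEY for k in key):
            merged.append(MISSING)
        else:
            raise ValueError(
                f"observed combination {key!r} of inputs {spec.inputs} "
                "is not covered by the merge value map"
            )
    meta = VariableMeta(
        name=spec.name,
        vtype="ordinal" if spec.merged_levels else None,
        ordinal_levels=spec.merged_levels,
        source="user",
    )
    out.add_variable(spec.name, merged, meta)

    per_input: dict[str, dict] = {}
    for var in spec.inputs:
        x = list(out.values(var))
        ic = infotheory.information_content_discrete(x)
        mic = infotheory.mutual_information_content(x, merged)
        per_input[var] = {
            "ic": ic,
            "mic": mic,
            "lossless": abs(mic - ic) <= LOSSLESS_TOL,
        }
    assessment = MergeAssessment(
        per_input=per_input,
        merged_ic=infotheory.information_content_discrete(merged),
        merged_name=spec.name,
    )
    return out, assessment


# -- encoders ---------------------------------------------------------------

def encode_ordinal(
    table: HealthTable, variable: str, levels: list[str]
) -> tuple[HealthTable, MappingReferenceTable]:
    """Encode ordinal labels as their 1-based position in *levels*.

    Mirrors staging conventions such as N0/N1/N2 -> 1/2/3.  Missing cells are
    preserved; labels are recorded in a mapping reference table.
    """
    observed = {str(v) for v in table.values(variable) if not is_missing(v)}
    uncovered = sorted(observed - set(levels))
    if uncovered:
        raise ValueError(
            f"{variable!r}: levels do not cover observed labels {uncovered}"
        )
    code_of = {label: i + 1 for i, label in enumerate(levels)}
    out = table.copy()
    out.set_values(
        variable,
        [MISSING if is_missing(v) else code_of[str(v)]
         for v in table.values(variable)],
    )
    out.meta[variable] = VariableMeta(
        name=variable, vtype="ordinal", modality=table.meta[variable].modality,
        ordinal_levels=list(levels), source=table.meta[variable].source,
    )
    mapping = MappingReferenceTable()
    for label, code in code_of.items():
        mapping.add(variable, label, code)
    return out, mapping


def encode_binary(
    table: HealthTable, variable: str, positive_label: str
) -> HealthTable:
    """Encode a two-level variable as 1 (*positive_label*) / 0 (the other)."""
    observed = {str(v) for v in table.values(variable) if not is_missing(v)}
    if len(observed) > 2:
        raise ValueError(
            f"{variable!r} has {len(observed)} levels; encode_binary needs <=2"
        )
    out = table.copy()
    out.set_values(
        variable,
        [MISSING if is_missing(v) else (1 if str(v) == str(positive_label) else 0)
         for v in table.values(variable)],
    )
    out.meta[variable] = VariableMeta(
        name=variable, vtype="nominal_binary",
        modality=table.meta[variable].modality,
        source=table.meta[variable].source,
    )
    return out


def _safe_label(label: str) -> str:
    return re.sub(r"\s+", "_", str(label).strip())


def encode_onehot(table: HealthTable, variable: str) -> HealthTable:
    """Expand a nominal variable into per-level 0/1 indicator variables.

    Indicators are named ``<variable>_<label>``; when any cell is missing, an
    extra ``<variable>_NA`` indicator marks missingness, so the indicators of
    each record always sum to exactly 1.  The source variable is removed and
    the new variables contain no missing values.
    """
    values = list(table.values(variable))
    labels = sorted({str(v) for v in values if not is_missing(v)})
    any_missing = any(is_missing(v) for v in values)
    out = table.copy()
    modality = table.meta[variable].modality
    for label in labels:
        name = f"{variable}_{_safe_label(label)}"
        out.add_variable(
            name,
            [0 if is_missing(v) else (1 if str(v) == label else 0) for v in values],
            VariableMeta(name=name, vtype="nominal_binary", modality=modality),
        )
    if any_missing:
        name = f"{variable}_NA"
        out.add_variable(
            name,
            [1 if is_missing(v) else 0 for v in values],
            VariableMeta(name=name, vtype="nominal_binary", modality=modality),
        )
    out.drop_variable(variable)
    return out


def encode_by_frequency(
    table: HealthTable, variable: str
) -> tuple[HealthTable, MappingReferenceTable]:
    """Encode labels by descending cohort frequency: most common -> 0.

    Used for single-substitution mutation status (wild type, most common,
    encoded 0; rarest homozygous variant encoded 2).  Ties are broken
    lexicographically for determinism.  Missing cells are preserved.
    """
    values = [str(v) for v in table.values(variable) if not is_missing(v)]
    counts = Counter(values)
    ranked = sorted(counts, key=lambda label: (-counts[label], label))
    code_of = {label: i for i, label in enumerate(ranked)}
    out = table.copy()
    out.set_values(
        variable,
        [MISSING if is_missing(v) else code_of[str(v)]
         for v in table.values(variable)],
    )
    out.meta[variable] = VariableMeta(
        name=variable, vtype="ordinal" if len(ranked) > 1 else "nominal_binary",
        modality=table.meta[variable].modality,
        ordinal_levels=ranked if len(ranked) > 1 else None,
        source=table.meta[variable].source,
    )
    mapping = MappingReferenceTable()
    for label, code in code_of.items():
        mapping.add(variable, label, code)
    return out, mapping


# -- free text --------------------------------------------------------------

@dataclass
class FreeTextSpec:
    """Parameters for structured-variable extraction from free text.

    Terms (unigrams plus, when ``ngram_length > 1``, skipgrams allowing up to
    ``skip_window`` skipped tokens between adjacent gram positions) occurring
    in at least ``min_record_frequency`` records become presence variables.
    """

    variable: str
    min_record_frequency: int = 2
    ngram_length: int = 2
    skip_window: int = 1
    stopword_language: str = "english"

    def __post_init__(self):
        if self.min_record_frequency < 2:
            raise ValueError("min_record_frequency must be >= 2")
        if self.ngram_length < 1:
            raise ValueError("ngram_length must be >= 1")
        if self.skip_window < 0:
            raise ValueError("skip_window must be >= 0")
        if self.stopword_language not in STOPWORDS:
            raise ValueError(
                f"no stopword list for {self.stopword_language!r}; "
                f"available: {sorted(STOPWORDS)}"
            )


_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def tokenise(text: str, stopword_language: str = "english",
             substitutions: list[tuple[str, str]] | None = None) -> list[str]:
    """Lowercase, apply substitutions, strip punctuation, drop stopwords."""
    text = str(text).lower()
    for pattern, replacement in substitutions or []:
        text = re.sub(pattern.lower(), replacement.lower(), text)
    stop = STOPWORDS[stopword_language]
    tokens = text.translate(_PUNCT_TABLE).split()
    return [t for t in tokens if t and t not in stop]


def skipgrams(tokens: list[str], n: int, skip_window: int) -> list[str]:
    """All n-grams allowing up to *skip_window* skipped tokens per gap."""
    grams = []
    for positions in itertools.combinations(range(len(tokens)), n):
        gaps = [b - a - 1 for a, b in zip(positions, positions[1:])]
        if all(g <= skip_window for g in gaps):
            grams.append("_".join(tokens[i] for i in positions))
    return grams


def extract_freetext(
    table: HealthTable,
    spec: FreeTextSpec,
    substitutions: list[tuple[str, str]] | None = None,
) -> HealthTable:
    """Create 0/1 presence variables for frequently occurring terms.

    Each record's text yields cleaned tokens plus skipgrams; terms present in
    at least ``min_record_frequency`` records become variables named
    ``<variable>_<term>``.  Records with missing text get missing values in
    every generated variable.  An optional substitution table (regex pattern,
    replacement) is applied before tokenisation to standardise spellings.
    """
    if spec.variable not in table.variables:
        raise ValueError(f"unknown variable {spec.variable!r}")
    if table.meta[spec.variable].vtype not in (None, "free_text"):
        raise ValueError(
            f"{spec.variable!r} is {table.meta[spec.variable].vtype}, not free_text"
        )

    record_terms: dict[str, set] = {}
    for rec in table.records:
        text = table.values(spec.variable)[rec]
        if is_missing(text):
            continue
        tokens = tokenise(text, spec.stopword_language, substitutions)
        terms = set(tokens)
        if spec.ngram_length > 1:
            terms |= set(skipgrams(tokens, spec.ngram_length, spec.skip_window))
        record_terms[rec] = terms

    doc_freq = Counter(t for terms in record_terms.values() for t in terms)
    kept = sorted(t for t, c in doc_freq.items()
                  if c >= spec.min_record_frequency)

    out = table.copy()
    modality = table.meta[spec.variable].modality
    for term in kept:
        name = f"{spec.variable}_{term}"
        values = [
            MISSING if rec not in record_terms
            else (1 if term in record_terms[rec] else 0)
            for rec in table.records
        ]
        out.add_variable(
            name, values,
            VariableMeta(name=name, vtype="nominal_binary", modality=modality),
        )
    return out


def assert_all_numeric(table: HealthTable) -> list[str]:
    """Return variables whose non-missing values do not parse as numbers.

    An empty result means the final all-numeric assertion passes; identifier
    variables are exempt.
    """
    offenders = []
    for var in table.variables:
        if table.meta[var].vtype == "identifier":
            continue
        for v in table.values(var):
            if not is_missing(v) and as_number(v) is None:
                offenders.append(var)
                break
    return offenders
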
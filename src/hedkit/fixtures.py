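"""Deterministic synthetic cohorts, toy ontologies and planted-defect data.

Every generator is a pure function of its spec (fixed seed => byte-identical
output), so the whole toolkit is testable without any download.  The default
cohort mirrors the structure of a real multimodal colorectal-cancer cohort:
661 records, 155 variables (154 + identifier) across four modalities
(clinical pathology, epidemiology, mutation, treatment and outcomes), eight
distinct ad hoc encodings of missingness covering roughly 4.3% of cells,
block-shaped missingness aligned with modalities, a handful of constant
(zero-entropy) variables, and 40 planted violations of a lymph-node staging
rule set.  Every planted defect is written to a ground-truth ledger so tests
can assert exact recovery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, HealthTable, VariableMeta
from .enrichment import (
    OntologyVariableGraph,
    attach_variable_mappings,
    load_ontology_edges,
)
from .quality import ConsistencyRule

__all__ = [
    "CohortSpec",
    "CohortLedger",
    "lymph_node_rules",
    "rules_to_frame",
    "generate_cohort",
    "generate_toy_ontology",
    "two_variable_sets_fixture",
    "heart_disease_ontology",
    "heart_disease_worked_example",
]

#: Eight ad hoc missing-value encodings planted by the cohort generator.
DEFAULT_MISSING_ENCODINGS = (
    "NA", "N/A", "unknown", "Unknown", "missing", "", "-1", "999",
)

DEFAULT_MODALITIES = {
    "clinical_pathology": {
        "continuous": 12, "integer": 8, "ordinal": 6,
        "nominal_binary": 18, "nominal_multi": 8,
    },
    "epidemiology": {
        "continuous": 6, "integer": 4, "nominal_binary": 12,
        "nominal_multi": 6, "free_text": 3,
    },
    "mutation": {"nominal_multi": 19, "nominal_binary": 21},
    "treatment_outcomes": {
        "continuous": 4, "integer": 4, "nominal_binary": 15,
        "nominal_multi": 8,
    },
}

DEFAULT_FREETEXT_VOCABULARY = (
    "mother", "father", "brother", "sister", "breast", "lung", "skin",
    "colon", "cancer", "history", "diagnosed", "surgery",
)

_ORDINAL_LEVELS = ["low", "moderate", "high"]
_BINARY_LEVELS = ["no", "yes"]
_MULTI_LEVELS = ["alpha", "beta", "gamma", "delta"]
_MUTATION_LEVELS = ["WT", "Het", "Hom"]


@dataclass
class CohortSpec:
    """Conditions for one synthetic cohort."""

    n_records: int = 661
    seed: int = 7
    modalities: dict = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_MODALITIES.items()})
    missing_rate: float = 0.043
    missing_encodings: tuple = DEFAULT_MISSING_ENCODINGS
    n_planted_inconsistencies: int = 40
    constant_variable_count: int = 4
    freetext_vocabulary: tuple = DEFAULT_FREETEXT_VOCABULARY

    def __post_init__(self):
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.n_records < 1:
            raise ValueError("n_records must be positive")


@dataclass
class CohortLedger:
    """Ground truth of every planted defect."""

    missing_cells: list = field(default_factory=list)  # (record, variable, token)
    token_counts: Counter = field(default_factory=Counter)
    inconsistencies: list = field(default_factory=list)  # (record_id, rule_index)
    constant_variables: list = field(default_factory=list)
    rules: list = field(default_factory=list)
    ordinal_variables: dict = field(default_factory=dict)  # name -> levels

    @property
    def n_missing_tokens(self) -> int:
        return len(self.missing_cells)


def lymph_node_rules() -> list[ConsistencyRule]:
    """Bundled staging rule set: positive nodes cannot exceed examined
    nodes, and N2 stage requires at least 4 positive nodes."""
    return [
        ConsistencyRule(var_a="nodes_positive", var_b="nodes_examined",
                        logical_test="<="),
        ConsistencyRule(var_a="n_stage", var_b="nodes_positive",
                        var_a_boundaries="N2", var_b_boundaries="4:99"),
    ]


def rules_to_frame(rules: list[ConsistencyRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "variable_a": r.var_a, "variable_b": r.var_b,
            "logical_test": r.logical_test or "",
            "variable_a_boundaries": r.var_a_boundaries or "",
            "variable_b_boundaries": r.var_b_boundaries or "",
        } for r in rules],
        columns=["variable_a", "variable_b", "logical_test",
                 "variable_a_boundaries", "variable_b_boundaries"],
    )


def _stage_for(positive: int) -> str:
    if positive == 0:
        return "N0"
    if positive <= 3:
        return "N1"
    return "N2"


def _sentence(rng: np.random.Generator, vocab: tuple) -> str:
    relative = rng.choice(vocab[:4])
    site = rng.choice(vocab[4:8])
    templates = [
        f"the {relative} had {site} cancer",
        f"{relative} diagnosed with {site} cancer in the past",
        f"no record of {site} cancer for the {relative}",
        f"{relative} with a history of {site} cancer after surgery",
    ]
    return str(templates[rng.integers(len(templates))])


def generate_cohort(spec: CohortSpec) -> tuple[HealthTable, CohortLedger]:
    """Synthesise a cohort with defects planted per *spec*.

    Consistency of the lymph-node variables holds by construction except at
    the planted violations, so the ledger's inconsistency list is exactly
    what rule checking should recover.  Missing cells are written as raw
    encoding tokens (the dataset arrives "dirty"); standardising them must
    alter exactly ``ledger.n_missing_tokens`` cells.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    ids = [f"p{i + 1:04d}" for i in range(n)]
    ledger = CohortLedger(rules=lymph_node_rules())

    columns: dict[str, list] = {}
    meta: dict[str, VariableMeta] = {}
    modality_vars: dict[str, list[str]] = {m: [] for m in spec.modalities}

    def add(name, values, vtype, modality, levels=None):
        columns[name] = list(values)
        meta[name] = VariableMeta(name=name, vtype=None, modality=modality)
        modality_vars[modality].append(name)
        if vtype == "ordinal" and levels:
            ledger.ordinal_variables[name] = list(levels)

    # special staging variables, generated mutually consistent
    examined = rng.integers(5, 61, size=n)
    positive = np.minimum(rng.integers(0, 16, size=n), examined)
    special = {"nodes_examined", "nodes_positive", "n_stage"}
    add("nodes_examined", [str(int(v)) for v in examined],
        "integer", "clinical_pathology")
    add("nodes_positive", [str(int(v)) for v in positive],
        "integer", "clinical_pathology")
    add("n_stage", [_stage_for(int(v)) for v in positive],
        "ordinal", "clinical_pathology", levels=["N0", "N1", "N2"])
    ledger.ordinal_variables["n_stage"] = ["N0", "N1", "N2"]

    special_types = {
        "nodes_examined": ("clinical_pathology", "integer"),
        "nodes_positive": ("clinical_pathology", "integer"),
        "n_stage": ("clinical_pathology", "ordinal"),
    }
    for modality, counts in spec.modalities.items():
        for vtype, count in counts.items():
            already = sum(1 for m, t in special_types.values()
                          if m == modality and t == vtype)
            for i in range(count - already):
                name = f"{modality}_{vtype}_{i + 1}"
                if vtype == "continuous":
                    vals = [f"{v:.2f}" for v in rng.uniform(0.5, 200.0, size=n)]
                    add(name, vals, vtype, modality)
                elif vtype == "integer":
                    vals = [str(int(v)) for v in rng.integers(0, 121, size=n)]
                    add(name, vals, vtype, modality)
                elif vtype == "ordinal":
                    vals = [str(v) for v in rng.choice(_ORDINAL_LEVELS, size=n)]
                    add(name, vals, vtype, modality, levels=_ORDINAL_LEVELS)
                elif vtype == "nominal_binary":
                    vals = [str(v) for v in rng.choice(
                        _BINARY_LEVELS, size=n, p=[0.6, 0.4])]
                    add(name, vals, vtype, modality)
                elif vtype == "nominal_multi":
                    if modality == "mutation":
                        vals = [str(v) for v in rng.choice(
                            _MUTATION_LEVELS, size=n, p=[0.7, 0.25, 0.05])]
                    else:
                        vals = [str(v) for v in rng.choice(_MULTI_LEVELS, size=n)]
                    add(name, vals, vtype, modality)
                elif vtype == "free_text":
                    vals = [_sentence(rng, spec.freetext_vocabulary)
                            for _ in range(n)]
                    add(name, vals, vtype, modality)
                else:
                    raise ValueError(f"unknown vtype {vtype!r} in spec")

    # constant (zero-entropy) variables: overwrite a few binary columns
    binaries = [v for v in columns
                if meta[v].modality and "nominal_binary" in v]
    for name in binaries[: spec.constant_variable_count]:
        columns[name] = ["no"] * n
        ledger.constant_variables.append(name)

    # modality-aligned block missingness plus uniform noise
    token_cycle = list(spec.missing_encodings)
    chosen: set[tuple[int, str]] = set()
    for modality, var_names in modality_vars.items():
        if not var_names:
            continue
        budget = int(round(spec.missing_rate * n * len(var_names)))
        if budget == 0:
            continue
        n_block_vars = max(1, int(0.3 * len(var_names)))
        block_vars = [str(v) for v in rng.choice(
            var_names, size=n_block_vars, replace=False)]
        block_len = min(n, max(1, int(0.6 * budget / n_block_vars)))
        start = int(rng.integers(0, n - block_len + 1))
        for var in block_vars:
            for row in range(start, start + block_len):
                chosen.add((row, var))
        remaining = budget - len({c for c in chosen if c[1] in var_names})
        cells = [(row, var) for var in var_names for row in range(n)
                 if (row, var) not in chosen]
        if remaining > 0 and cells:
            picks = rng.choice(len(cells), size=min(remaining, len(cells)),
                               replace=False)
            for p in picks:
                chosen.add(cells[int(p)])
    for row, var in sorted(chosen, key=lambda c: (c[1], c[0])):
        token = token_cycle[int(rng.integers(len(token_cycle)))]
        columns[var][row] = token
        ledger.missing_cells.append((ids[row], var, token))
        ledger.token_counts[token] += 1

    # planted inconsistencies on records whose staging cells are untouched
    dirty_rows = {row for row, var in chosen if var in special}
    candidates = [i for i in range(n) if i not in dirty_rows]
    k = spec.n_planted_inconsistencies
    if k > len(candidates):
        raise ValueError(
            f"cannot plant {k} inconsistencies in {len(candidates)} clean records")
    picked = sorted(int(i) for i in rng.choice(
        candidates, size=k, replace=False))
    for j, row in enumerate(picked):
        if j % 2 == 0:
            # positive nodes exceed examined; stage kept consistent with the
            # new count so only the operator rule fires
            new_positive = int(examined[row]) + int(rng.integers(1, 6))
            columns["nodes_positive"][row] = str(new_positive)
            columns["n_stage"][row] = _stage_for(new_positive)
            ledger.inconsistencies.append((ids[row], 0))
        else:
            # N2 stage with too few positive nodes; operator rule still holds
            new_positive = int(rng.integers(0, 4))
            columns["nodes_positive"][row] = str(new_positive)
            columns["n_stage"][row] = "N2"
            ledger.inconsistencies.append((ids[row], 1))

    frame = pd.DataFrame(columns, index=pd.Index(ids, name="id"), dtype=object)
    table = HealthTable(frame, meta, id_name="id")
    return table, ledger


# -- toy ontologies ---------------------------------------------------------

_FIVE_NODE_TOY = {
    "edges": [("A", "R"), ("B", "R"), ("C", "A"), ("D", "A")],
    "mapping": [("v1", "C"), ("v2", "D")],
}


def generate_toy_ontology(
    shape: str = "tree", n_nodes: int = 5, n_variables: int = 2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Random single-root ontology with variables mapped to leaves.

    Returns (edge table, mapping table, label table) as DataFrames in the CSV
    dialects consumed by the enrichment loaders.  ``shape="tree"`` with the
    default 5 nodes / 2 variables yields the canonical toy
    (R -> A,B; A -> C,D; v1 -> C, v2 -> D) used throughout the docs.
    """
    if shape not in ("tree", "dag"):
        raise ValueError("shape must be 'tree' or 'dag'")
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    rng = np.random.default_rng(seed)
    if shape == "tree" and n_nodes == 5 and n_variables == 2:
        edges = list(_FIVE_NODE_TOY["edges"])
        mapping = list(_FIVE_NODE_TOY["mapping"])
        nodes = ["R", "A", "B", "C", "D"]
    else:
        nodes = [f"N{i:02d}" for i in range(n_nodes)]
        edges = [(nodes[i], nodes[int(rng.integers(0, i))])
                 for i in range(1, n_nodes)]
        if shape == "dag":
            for i in range(2, n_nodes):
                if rng.random() < 0.3:
                    extra = int(rng.integers(0, i))
                    if (nodes[i], nodes[extra]) not in edges:
                        edges.append((nodes[i], nodes[extra]))
        leaves = [v for v in nodes if v not in {p for _, p in edges}]
        leaves = leaves or nodes[1:]
        mapping = [(f"v{i + 1}", leaves[int(rng.integers(len(leaves)))])
                   for i in range(n_variables)]
    edge_frame = pd.DataFrame(edges, columns=["child", "parent"])
    map_frame = pd.DataFrame(mapping, columns=["variable", "entity_id"])
    all_nodes = sorted({x for e in edges for x in e})
    label_frame = pd.DataFrame(
        [(node, f"node {node}") for node in all_nodes], columns=["id", "label"])
    return edge_frame, map_frame, label_frame


_HEART_EDGES = [
    ("IHD", "HD"),
    ("MI", "IHD"),
    ("CIHD", "IHD"),
    ("HF", "HD"),
    ("ARR", "HD"),
    ("VHD", "HD"),
]

_HEART_LABELS = {
    "HD": "heart disease",
    "IHD": "ischaemic heart disease",
    "MI": "myocardial infarction",
    "CIHD": "chronic ischaemic heart disease",
    "HF": "heart failure",
    "ARR": "cardiac arrhythmia",
    "VHD": "valvular heart disease",
}

_HEART_MAPPING = [
    ("mi", "MI"),
    ("ihd", "CIHD"),
    ("hf", "HF"),
    ("arrhythmia", "ARR"),
    ("valve_disease", "VHD"),
]


def two_variable_sets_fixture(
    n_sets: int = 36,
    n_max_constant: int = 1,
    n_min_mult_constant: int = 15,
    n_records: int = 8,
) -> tuple[HealthTable, OntologyVariableGraph]:
    """Constructed enrichment fixture with exact set/candidate arithmetic.

    A forest of *n_sets* independent two-leaf subtrees, each subsuming one
    pair of 0/1 variables, mimics the arithmetic of enrichment on a clinical
    validation cohort.  Pairs come in three kinds: fully varying (all five
    aggregations informative), first constituent constant 1 (the MAX
    candidate is constant => 1 zero-entropy drop), and first constituent
    constant 0 (MIN and MULT constant => 2 drops).  With the defaults,
    36 sets produce 180 candidates of which 31 drop, appending 149.
    """
    if n_max_constant + n_min_mult_constant > n_sets:
        raise ValueError("constant-kind sets exceed n_sets")
    varying_a = [0, 0, 1, 1, 0, 1, 0, 1]
    varying_b = [0, 1, 0, 1, 1, 0, 1, 0]
    alternating = [i % 2 for i in range(n_records)]
    if n_records != 8:
        varying_a = [(i // 2) % 2 for i in range(n_records)]
        varying_b = alternating
    edges, mapping, columns = [], [], {}
    for i in range(n_sets):
        parent, leaf_a, leaf_b = f"S{i:03d}", f"La{i:03d}", f"Lb{i:03d}"
        var_a, var_b = f"a{i:03d}", f"b{i:03d}"
        edges += [(leaf_a, parent), (leaf_b, parent)]
        mapping += [(var_a, leaf_a), (var_b, leaf_b)]
        if i < n_max_constant:
            columns[var_a] = [1] * n_records
        elif i < n_max_constant + n_min_mult_constant:
            columns[var_a] = [0] * n_records
        else:
            columns[var_a] = list(varying_a)
        columns[var_b] = list(varying_b)
    graph = load_ontology_edges(
        pd.DataFrame(edges, columns=["child", "parent"]))
    attach_variable_mappings(
        graph, pd.DataFrame(mapping, columns=["variable", "entity_id"]))
    ids = [f"r{i + 1}" for i in range(n_records)]
    frame = pd.DataFrame(columns, index=pd.Index(ids, name="id"), dtype=object)
    return HealthTable(frame, id_name="id"), graph


def heart_disease_ontology() -> OntologyVariableGraph:
    """Nested-MICA comorbidity topology.

    Five variables share "heart disease" as a common ancestor while the
    {mi, ihd} pair additionally shares the deeper, more informative
    "ischaemic heart disease" — so enrichment finds exactly two variable
    sets with nested MICAs.
    """
    graph = load_ontology_edges(
        pd.DataFrame(_HEART_EDGES, columns=["child", "parent"]))
    attach_variable_mappings(
        graph, pd.DataFrame(_HEART_MAPPING, columns=["variable", "entity_id"]))
    graph.set_labels(_HEART_LABELS)
    return graph


def heart_disease_worked_example() -> tuple[HealthTable, OntologyVariableGraph, dict]:
    """End-to-end regression fixture with hand-computed aggregations.

    Six records of five 0/1 comorbidity variables under the
    :func:`heart_disease_ontology`.  The expected meta-variables were
    computed by hand, row-wise over the non-missing values; the MIN and MULT
    aggregations of the five-variable set are constant zero and must be
    dropped by the zero-entropy filter.
    """
    na = MISSING
    data = {
        "mi":            [1, 0, 1, na, 0, 1],
        "ihd":           [0, 0, 1, na, 1, 0],
        "hf":            [1, 0, na, na, 0, 0],
        "arrhythmia":    [0, 0, 1, na, na, 0],
        "valve_disease": [0, 0, 0, na, 1, na],
    }
    ids = [f"r{i + 1}" for i in range(6)]
    frame = pd.DataFrame(data, index=pd.Index(ids, name="id"), dtype=object)
    table = HealthTable(frame, id_name="id")
    expected = {
        "appended": {
            "MV_ischaemic_heart_disease_SUM": [1, 0, 2, na, 1, 1],
            "MV_ischaemic_heart_disease_MIN": [0, 0, 1, na, 0, 0],
            "MV_ischaemic_heart_disease_MAX": [1, 0, 1, na, 1, 1],
            "MV_ischaemic_heart_disease_AVG": [0.5, 0, 1, na, 0.5, 0.5],
            "MV_ischaemic_heart_disease_MULT": [0, 0, 1, na, 0, 0],
            "MV_heart_disease_SUM": [2, 0, 3, na, 2, 1],
            "MV_heart_disease_MAX": [1, 0, 1, na, 1, 1],
            "MV_heart_disease_AVG": [0.4, 0, 0.75, na, 0.5, 0.25],
        },
        "dropped": ["MV_heart_disease_MIN", "MV_heart_disease_MULT"],
        "n_sets": 2,
        "n_candidates": 10,
        "n_dropped": 2,
        "n_appended": 8,
    }
    return table, heart_disease_ontology(), expected
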
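"""Ontology-driven semantic enrichment.

Dataset variables mapped to entities of an ontology (a DAG of child->parent
"is_a" relations, SNOMED CT / Gene Ontology style) inherit the ontology's
structure: every ontology node that subsumes at least two mapped variables
defines a candidate variable set, labelled by its most informative common
ancestor (MICA) — the subsuming node of maximal information content.  Node
information content blends specificity by depth and by relative number of
descendants:

    IC(c) = k * (1 - ln(hypo(c) + 1) / ln(N))
          + (1 - k) * ln(depth(c)) / ln(depth_max)

with hypo(c) the number of ontology descendants of c, N the ontology size,
depth the longest root->c path counted in nodes, and k in [0, 1] weighting
the descendant term (default 0.5).  Roots score 0; a childless node at
maximal depth scores 1.

Each variable set yields five candidate meta-variables (row-wise sum,
minimum, maximum, average and product over the non-missing constituent
values); candidates with zero entropy are dropped before appending.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .core import MISSING, HealthTable, VariableMeta, as_number, is_missing
from . import infotheory

__all__ = [
    "OntologyVariableGraph",
    "load_ontology_edges",
    "attach_variable_mappings",
    "node_information_content",
    "VariableSet",
    "identify_variable_sets",
    "MetaVariable",
    "AGGREGATIONS",
    "aggregate_set",
    "EnrichmentReport",
    "semantic_enrichment",
]


class OntologyVariableGraph:
    """DAG of ontology entities plus attached variable nodes.

    Edges run child -> parent among ontology nodes; variable nodes attach by
    mapping edges variable -> entity and never have children.  Node labels
    (human-readable names) are optional and default to the node id.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- structure ---------------------------------------------------------
    def _nodes_of_kind(self, kind: str) -> list:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == kind]

    @property
    def ontology_nodes(self) -> list:
        return self._nodes_of_kind("ontology")

    @property
    def variable_nodes(self) -> list:
        return self._nodes_of_kind("variable")

    @property
    def roots(self) -> list:
        """Ontology nodes with no parent."""
        return sorted(
            n for n in self.ontology_nodes
            if not any(self.graph.nodes[p].get("kind") == "ontology"
                       for p in self.graph.successors(n))
        )

    def label(self, node) -> str:
        return self.graph.nodes[node].get("label", str(node))

    def set_labels(self, labels: dict) -> None:
        for node, label in labels.items():
            if node in self.graph:
                self.graph.nodes[node]["label"] = str(label)

    def ontology_descendants(self, node) -> set:
        """Ontology nodes below *node* (those with a child->parent path to it)."""
        return {n for n in nx.ancestors(self.graph, node)
                if self.graph.nodes[n].get("kind") == "ontology"}

    def mapped_entities(self, variable) -> set:
        return set(self.graph.successors(variable))

    def depths(self) -> dict:
        """Longest root->node path length in nodes (roots have depth 1).

        With multiple roots, depth is relative to whichever root gives the
        longest path (equivalent to a virtual super-root excluded from N).
        """
        onto = self.graph.subgraph(self.ontology_nodes)
        down = onto.reverse(copy=False)  # parent -> child
        depth: dict = {}
        for node in nx.topological_sort(down):
            parents = list(down.predecessors(node))
            depth[node] = 1 if not parents else 1 + max(depth[p] for p in parents)
        return depth


def load_ontology_edges(source) -> OntologyVariableGraph:
    """Build the ontology part of the graph from a child,parent edge table.

    *source* is a CSV path or a DataFrame with columns ``child`` and
    ``parent``.  Self-loops and cycles are errors (one offending cycle is
    named); multiple roots are allowed.
    """
    frame = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, dtype=str, keep_default_na=False)
    for col in ("child", "parent"):
        if col not in frame.columns:
            raise ValueError(f"ontology edge table missing column {col!r}")
    g = nx.DiGraph()
    for _, row in frame.iterrows():
        child, parent = str(row["child"]).strip(), str(row["parent"]).strip()
        if child == parent:
            raise ValueError(f"self-loop on ontology node {child!r}")
        g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        pretty = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"ontology edges contain a cycle: {pretty}")
    nx.set_node_attributes(g, "ontology", "kind")
    return OntologyVariableGraph(g)


def attach_variable_mappings(
    graph: OntologyVariableGraph, mappings
) -> OntologyVariableGraph:
    """Attach variable nodes via a variable,entity_id mapping table.

    *mappings* is a CSV path or DataFrame with columns ``variable`` and
    ``entity_id`` (several rows per variable allowed).  Mapping to an unknown
    entity is an error listing the offenders; unmapped dataset variables are
    simply absent from the graph.
    """
    frame = mappings if isinstance(mappings, pd.DataFrame) else pd.read_csv(
        mappings, dtype=str, keep_default_na=False)
    for col in ("variable", "entity_id"):
        if col not in frame.columns:
            raise ValueError(f"mapping table missing column {col!r}")
    known = set(graph.ontology_nodes)
    offenders = sorted(
        {str(r["entity_id"]).strip() for _, r in frame.iterrows()}
        - known
    )
    if offenders:
        raise ValueError(f"mappings reference unknown ontology entities: {offenders}")
    g = graph.graph
    for _, row in frame.iterrows():
        var = str(row["variable"]).strip()
        entity = str(row["entity_id"]).strip()
        g.add_node(var, kind="variable")
        g.add_edge(var, entity, kind="mapping")
    return graph


def node_information_content(
    graph: OntologyVariableGraph, k: float = 0.5
) -> dict:
    """Information content in [0, 1] for every ontology node.

    See the module docstring for the formula.  *k* weights the
    relative-descendants term against the depth term.  A single-node
    ontology scores 0 everywhere (both specificity notions degenerate).
    """
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"k must lie in [0, 1], got {k}")
    nodes = graph.ontology_nodes
    if not nodes:
        raise ValueError("ontology graph is empty")
    n_total = len(nodes)
    depth = graph.depths()
    depth_max = max(depth.values())
    ic: dict = {}
    for node in nodes:
        if n_total == 1 or depth_max == 1:
            ic[node] = 0.0
            continue
        hypo = len(graph.ontology_descendants(node))
        spec_desc = 1.0 - math.log(hypo + 1) / math.log(n_total)
        spec_depth = math.log(depth[node]) / math.log(depth_max)
        ic[node] = k * spec_desc + (1.0 - k) * spec_depth
    return ic


@dataclass
class VariableSet:
    """A set of >=2 variables subsumed by at least one ontology node.

    ``common_ancestors`` are all ontology nodes whose variable-descendants
    include the whole set; ``mica`` is the maximal-IC node among those whose
    variable-descendant set equals the set exactly (ties broken by greater
    depth, then lexicographic id).
    """

    variables: frozenset
    common_ancestors: frozenset
    mica: str
    mica_ic: float
    mica_label: str


def variable_descendant_sets(graph: OntologyVariableGraph) -> dict:
    """Map each ontology node to the frozenset of variables it subsumes.

    A variable counts under a node when one of its mapped entities is the
    node itself or an ontology descendant of it.
    """
    var_sets: dict = {}
    entity_vars: dict = {}
    for var in graph.variable_nodes:
        for entity in graph.mapped_entities(var):
            entity_vars.setdefault(entity, set()).add(var)
    for node in graph.ontology_nodes:
        covered = set(entity_vars.get(node, set()))
        for desc in graph.ontology_descendants(node):
            covered |= entity_vars.get(desc, set())
        var_sets[node] = frozenset(covered)
    return var_sets


def identify_variable_sets(
    graph: OntologyVariableGraph, node_ic: dict
) -> list[VariableSet]:
    """Group ontology nodes by identical variable-descendant sets of size >=2
    and pick the MICA per group.

    Returned sets are ordered by descending MICA IC, then MICA id, for
    deterministic downstream naming.
    """
    if len(graph.variable_nodes) < 2:
        raise ValueError("semantic enrichment needs >=2 mapped variables")
    var_sets = variable_descendant_sets(graph)
    depth = graph.depths()
    groups: dict[frozenset, list] = {}
    for node, vs in var_sets.items():
        if len(vs) >= 2:
            groups.setdefault(vs, []).append(node)
    results = []
    for vs, nodes in groups.items():
        mica = min(nodes, key=lambda n: (-node_ic[n], -depth[n], str(n)))
        ancestors = frozenset(n for n, s in var_sets.items() if s >= vs)
        results.append(VariableSet(
            variables=vs,
            common_ancestors=ancestors,
            mica=mica,
            mica_ic=node_ic[mica],
            mica_label=graph.label(mica),
        ))
    results.sort(key=lambda s: (-s.mica_ic, str(s.mica)))
    return results


@dataclass
class MetaVariable:
    """One aggregation of a variable set, named MV_<mica_label>_<agg>."""

    name: str
    agg: str
    values: list
    source_set: VariableSet


AGGREGATIONS = {
    "SUM": sum,
    "MIN": min,
    "MAX": max,
    "AVG": lambda vals: sum(vals) / len(vals),
    "MULT": lambda vals: math.prod(vals),
}


def _meta_name(label: str, agg: str) -> str:
    return "MV_" + re.sub(r"\s+", "_", str(label).strip()) + "_" + agg


def aggregate_set(
    table: HealthTable, var_set: VariableSet, normalise: bool = False
) -> list[MetaVariable]:
    """Five candidate meta-variables for one variable set.

    Aggregations run row-wise over the NON-missing constituent values only;
    a record with every constituent missing stays missing.  With *normalise*,
    min-max normalisation is applied per constituent first (needed when the
    constituents have differing magnitudes).
    """
    variables = sorted(var_set.variables)
    columns = {}
    for var in variables:
        if var not in table.variables:
            raise ValueError(f"set constituent {var!r} not in table")
        raw = list(table.values(var))
        numbers = []
        for v in raw:
            if is_missing(v):
                numbers.append(None)
                continue
            num = as_number(v)
            if num is None:
                raise ValueError(
                    f"constituent {var!r} holds non-numeric value {v!r}"
                )
            numbers.append(num)
        columns[var] = numbers
    if normalise:
        for var in variables:
            masked = [MISSING if n is None else n for n in columns[var]]
            columns[var] = [
                None if is_missing(v) else float(v)
                for v in infotheory.min_max_normalise(masked, name=var)
            ]
    candidates = []
    for agg, fn in AGGREGATIONS.items():
        values = []
        for i in range(table.n_records):
            present = [columns[var][i] for var in variables
                       if columns[var][i] is not None]
            values.append(fn(present) if present else MISSING)
        candidates.append(MetaVariable(
            name=_meta_name(var_set.mica_label, agg),
            agg=agg,
            values=values,
            source_set=var_set,
        ))
    return candidates


def _zero_entropy(values) -> bool:
    distinct = {round(float(v), 12) for v in values if not is_missing(v)}
    return len(distinct) <= 1


@dataclass
class EnrichmentReport:
    """Summary of one enrichment run.

    ``sets`` rows carry per-set MICA labels and ICs with appended/dropped
    aggregation names; ``redundancy`` rows give the symmetric uncertainty of
    each appended meta-variable with each of its constituents (1 = fully
    redundant).  ``n_candidates - n_dropped == n_appended`` always.
    """

    n_sets: int
    n_candidates: int
    n_dropped: int
    n_appended: int
    sets: list[dict] = field(default_factory=list)
    redundancy: list[dict] = field(default_factory=list)

    def sets_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sets, columns=[
            "mica", "mica_label", "mica_ic", "variables", "appended", "dropped"])

    def redundancy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.redundancy,
                            columns=["meta_variable", "constituent", "su"])

    def mean_redundancy(self) -> float:
        if not self.redundancy:
            return float("nan")
        return float(pd.DataFrame(self.redundancy)["su"].mean())

    def to_markdown(self) -> str:
        lines = [
            "# Semantic enrichment report",
            "",
            f"- variable sets: {self.n_sets}",
            f"- candidate meta-variables: {self.n_candidates}",
            f"- dropped (zero entropy): {self.n_dropped}",
            f"- appended: {self.n_appended}",
            "",
        ]
        if self.sets:
            lines.append("| MICA | IC | variables | appended | dropped |")
            lines.append("|---|---|---|---|---|")
            for row in self.sets:
                lines.append(
                    f"| {row['mica_label']} | {row['mica_ic']:.4f} | "
                    f"{', '.join(sorted(row['variables']))} | "
                    f"{', '.join(row['appended'])} | {', '.join(row['dropped'])} |"
                )
        if self.redundancy:
            mean_su = self.mean_redundancy()
            lines += ["", f"Mean constituent redundancy (SU): {mean_su:.4f}",
                      f"Nonredundant information: {100 * (1 - mean_su):.1f}%"]
        return "\n".join(lines) + "\n"


def semantic_enrichment(
    table: HealthTable,
    graph: OntologyVariableGraph,
    k: float = 0.5,
    normalise: bool = False,
) -> tuple[HealthTable, EnrichmentReport]:
    """Full enrichment pass: node IC -> variable sets -> aggregation ->
    zero-entropy filtering -> append survivors.

    Only graph variables present in the table take part.  Meta-variable name
    collisions get a numeric suffix.  Returns the enriched table and an
    :class:`EnrichmentReport` including the per-constituent symmetric
    uncertainty redundancy audit.
    """
    node_ic = node_information_content(graph, k=k)
    usable = [v for v in graph.variable_nodes if v in table.variables]
    pruned = OntologyVariableGraph(
        graph.graph.subgraph(graph.ontology_nodes + usable).copy()
    )
    var_sets = identify_variable_sets(pruned, node_ic)

    out = table.copy()
    used_names = set(out.variables)
    report = EnrichmentReport(
        n_sets=len(var_sets), n_candidates=0, n_dropped=0, n_appended=0)
    for vs in var_sets:
        candidates = aggregate_set(table, vs, normalise=normalise)
        report.n_candidates += len(candidates)
        appended, dropped = [], []
        for cand in candidates:
            if _zero_entropy(cand.values):
                report.n_dropped += 1
                dropped.append(cand.agg)
                continue
            name = cand.name
            suffix = 2
            while name in used_names:
                name = f"{cand.name}_{suffix}"
                suffix += 1
            used_names.add(name)
            out.add_variable(
                name, cand.values,
                VariableMeta(name=name, vtype="continuous", modality="meta"),
            )
            report.n_appended += 1
            appended.append(cand.agg)
            for const in sorted(vs.variables):
                su = infotheory.symmetric_uncertainty(
                    out.values(name), table.values(const))
                report.redundancy.append(
                    {"meta_variable": name, "constituent": const, "su": su})
        report.sets.append({
            "mica": vs.mica, "mica_label": vs.mica_label,
            "mica_ic": vs.mica_ic, "variables": sorted(vs.variables),
            "appended": appended, "dropped": dropped,
        })
    return out, report
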
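import numpy as np
import pandas as pd
import pytest

from hedkit.core import MISSING, is_missing
from hedkit.enrichment import (
    OntologyVariableGraph,
    aggregate_set,
    attach_variable_mappings,
    identify_variable_sets,
    load_ontology_edges,
    node_information_content,
    semantic_enrichment,
)
from hedkit.fixtures import (
    generate_toy_ontology,
    heart_disease_ontology,
    heart_disease_worked_example,
)
from hedkit.quality import assess_completeness

from conftest import make_table
from _oracles import brute_variable_sets


def toy_graph() -> OntologyVariableGraph:
    edges, mapping, _ = generate_toy_ontology()
    graph = load_ontology_edges(edges)
    return attach_variable_mappings(graph, mapping)


class TestLoadOntology:
    def test_counts(self):
        edges, _, _ = generate_toy_ontology()
        graph = load_ontology_edges(edges)
        assert len(graph.ontology_nodes) == 5
        assert graph.graph.number_of_edges() == 4

    def test_self_loop_error(self):
        frame = pd.DataFrame([("A", "A")], columns=["child", "parent"])
        with pytest.raises(ValueError, match="self-loop"):
            load_ontology_edges(frame)

    def test_cycle_error_names_cycle(self):
        frame = pd.DataFrame([("A", "B"), ("B", "C"), ("C", "A")],
                             columns=["child", "parent"])
        with pytest.raises(ValueError, match="cycle"):
            load_ontology_edges(frame)

    def test_two_root_forest_accepted(self):
        frame = pd.DataFrame([("A", "R1"), ("B", "R2")],
                             columns=["child", "parent"])
        graph = load_ontology_edges(frame)
        assert graph.roots == ["R1", "R2"]


class TestAttachMappings:
    def test_variable_nodes_added(self):
        graph = toy_graph()
        assert sorted(graph.variable_nodes) == ["v1", "v2"]

    def test_multi_entity_mapping(self):
        edges, _, _ = generate_toy_ontology()
        graph = load_ontology_edges(edges)
        mapping = pd.DataFrame([("v1", "C"), ("v1", "B")],
                               columns=["variable", "entity_id"])
        attach_variable_mappings(graph, mapping)
        assert graph.variable_nodes == ["v1"]
        assert graph.mapped_entities("v1") == {"B", "C"}

    def test_unknown_entity_error(self):
        edges, _, _ = generate_toy_ontology()
        graph = load_ontology_edges(edges)
        mapping = pd.DataFrame([("v1", "X999")],
                               columns=["variable", "entity_id"])
        with pytest.raises(ValueError, match="X999"):
            attach_variable_mappings(graph, mapping)


class TestNodeIC:
    def test_root_is_zero(self):
        ic = node_information_content(toy_graph())
        assert ic["R"] == 0.0

    def test_max_depth_childless_leaf_is_one(self):
        ic = node_information_content(toy_graph())
        assert ic["C"] == 1.0 and ic["D"] == 1.0

    def test_toy_interior_node_hand_value(self):
        # hypo=2, depth 2, N=5, depth_max=3, k=0.5
        ic = node_information_content(toy_graph(), k=0.5)
        assert ic["A"] == pytest.approx(0.4742, abs=1e-4)

    def test_values_in_unit_interval_and_monotone_on_tree(self):
        edges, _, _ = generate_toy_ontology(shape="tree", n_nodes=25,
                                            n_variables=4, seed=3)
        graph = load_ontology_edges(edges)
        ic = node_information_content(graph)
        assert all(0.0 <= v <= 1.0 for v in ic.values())
        for _, row in edges.iterrows():
            assert ic[row["child"]] >= ic[row["parent"]]

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            node_information_content(toy_graph(), k=1.5)

    def test_k_extremes(self):
        ic_desc = node_information_content(toy_graph(), k=1.0)
        ic_depth = node_information_content(toy_graph(), k=0.0)
        # with k=1 only descendants matter: B, C, D all childless -> equal
        assert ic_desc["B"] == ic_desc["C"] == ic_desc["D"] == 1.0
        # with k=0 only depth matters: B shallower than C
        assert ic_depth["B"] < ic_depth["C"]


class TestVariableSets:
    def test_toy_single_set(self):
        graph = toy_graph()
        ic = node_information_content(graph)
        sets = identify_variable_sets(graph, ic)
        assert len(sets) == 1
        vs = sets[0]
        assert vs.variables == frozenset({"v1", "v2"})
        assert vs.common_ancestors == frozenset({"A", "R"})
        assert vs.mica == "A"

    def test_nested_mica_topology(self):
        graph = heart_disease_ontology()
        ic = node_information_content(graph)
        sets = identify_variable_sets(graph, ic)
        assert len(sets) == 2
        by_size = sorted(sets, key=lambda s: len(s.variables))
        assert by_size[0].variables == frozenset({"mi", "ihd"})
        assert by_size[0].mica_label == "ischaemic heart disease"
        assert by_size[1].mica_label == "heart disease"
        assert len(by_size[1].variables) == 5
        assert by_size[0].mica_ic > by_size[1].mica_ic

    def test_disjoint_trees_no_sets(self):
        frame = pd.DataFrame([("A", "R1"), ("B", "R2")],
                             columns=["child", "parent"])
        graph = load_ontology_edges(frame)
        mapping = pd.DataFrame([("v1", "A"), ("v2", "B")],
                               columns=["variable", "entity_id"])
        attach_variable_mappings(graph, mapping)
        ic = node_information_content(graph)
        assert identify_variable_sets(graph, ic) == []

    def test_matches_brute_force_on_random_dags(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            n_nodes = int(rng.integers(5, 41))
            n_vars = int(rng.integers(2, 11))
            edges, mapping, _ = generate_toy_ontology(
                shape="dag", n_nodes=n_nodes, n_variables=n_vars,
                seed=int(rng.integers(2 ** 31)))
            graph = load_ontology_edges(edges)
            attach_variable_mappings(graph, mapping)
            ic = node_information_content(graph)
            got = {s.variables: s.mica
                   for s in identify_variable_sets(graph, ic)}
            expected = brute_variable_sets(
                [tuple(r) for r in edges.to_numpy()],
                [tuple(r) for r in mapping.to_numpy()], ic)
            assert got == expected


class TestAggregateSet:
    def test_hand_computed_rowwise_arithmetic(self):
        table = make_table({
            "x1": [0, 0.5, 1],
            "x2": [1, MISSING, 0],
        })
        graph = toy_graph()
        mapping = pd.DataFrame([("x1", "C"), ("x2", "D")],
                               columns=["variable", "entity_id"])
        edges, _, _ = generate_toy_ontology()
        g = attach_variable_mappings(load_ontology_edges(edges), mapping)
        ic = node_information_content(g)
        vs = identify_variable_sets(g, ic)[0]
        by_agg = {c.agg: c.values for c in aggregate_set(table, vs)}
        assert by_agg["SUM"] == [1, 0.5, 1]
        assert by_agg["MIN"] == [0, 0.5, 0]
        assert by_agg["MAX"] == [1, 0.5, 1]
        assert by_agg["AVG"] == [0.5, 0.5, 0.5]
        assert by_agg["MULT"] == [0, 0.5, 0]

    def test_all_missing_record_stays_missing(self):
        table = make_table({"x1": [1, MISSING], "x2": [0, MISSING]})
        g = toy_graph()
        mapping = pd.DataFrame([("x1", "C"), ("x2", "D")],
                               columns=["variable", "entity_id"])
        edges, _, _ = generate_toy_ontology()
        g = attach_variable_mappings(load_ontology_edges(edges), mapping)
        vs = identify_variable_sets(g, node_information_content(g))[0]
        for cand in aggregate_set(table, vs):
            assert is_missing(cand.values[1])

    def test_non_numeric_constituent_error(self):
        table = make_table({"x1": ["yes", "no"], "x2": [1, 0]})
        edges, _, _ = generate_toy_ontology()
        mapping = pd.DataFrame([("x1", "C"), ("x2", "D")],
                               columns=["variable", "entity_id"])
        g = attach_variable_mappings(load_ontology_edges(edges), mapping)
        vs = identify_variable_sets(g, node_information_content(g))[0]
        with pytest.raises(ValueError, match="non-numeric"):
            aggregate_set(table, vs)

    def test_normalised_aggregations_bounded(self):
        rng = np.random.default_rng(4)
        table = make_table({
            "x1": list(rng.uniform(0, 50, size=30)),
            "x2": list(rng.uniform(-5, 5, size=30)),
        })
        edges, _, _ = generate_toy_ontology()
        mapping = pd.DataFrame([("x1", "C"), ("x2", "D")],
                               columns=["variable", "entity_id"])
        g = attach_variable_mappings(load_ontology_edges(edges), mapping)
        vs = identify_variable_sets(g, node_information_content(g))[0]
        for cand in aggregate_set(table, vs, normalise=True):
            values = [v for v in cand.values if not is_missing(v)]
            hi = len(vs.variables) if cand.agg == "SUM" else 1.0
            assert all(0.0 <= v <= hi for v in values)


class TestSemanticEnrichment:
    def test_worked_example_end_to_end(self):
        table, graph, expected = heart_disease_worked_example()
        out, report = semantic_enrichment(table, graph)
        assert report.n_sets == expected["n_sets"]
        assert report.n_candidates == expected["n_candidates"]
        assert report.n_dropped == expected["n_dropped"]
        assert report.n_appended == expected["n_appended"]
        for name, values in expected["appended"].items():
            got = list(out.values(name))
            for g, e in zip(got, values):
                if is_missing(e):
                    assert is_missing(g)
                else:
                    assert float(g) == pytest.approx(float(e))
        for name in expected["dropped"]:
            assert name not in out.variables

    def test_removing_one_mapping_shrinks_set(self):
        table, graph, _ = heart_disease_worked_example()
        graph.graph.remove_node("valve_disease")
        out, report = semantic_enrichment(table, graph)
        big = max((s for s in report.sets), key=lambda s: len(s["variables"]))
        assert len(big["variables"]) == 4
        # r5: constituents mi=0, ihd=1, hf=0, arrhythmia=NA -> SUM 1 (was 2)
        assert float(out.values("MV_heart_disease_SUM")["r5"]) == 1.0

    def test_constant_average_candidate_dropped(self):
        table = make_table({"x1": [0, 0.5, 1], "x2": [1, MISSING, 0]})
        edges, _, _ = generate_toy_ontology()
        mapping = pd.DataFrame([("x1", "C"), ("x2", "D")],
                               columns=["variable", "entity_id"])
        graph = attach_variable_mappings(load_ontology_edges(edges), mapping)
        _, report = semantic_enrichment(table, graph)
        assert report.n_dropped == 1
        assert report.sets[0]["dropped"] == ["AVG"]
        assert report.n_appended == 4

    def test_conservation(self):
        table, graph, _ = heart_disease_worked_example()
        _, report = semantic_enrichment(table, graph)
        assert report.n_candidates - report.n_dropped == report.n_appended
        assert report.n_candidates == 5 * report.n_sets

    def test_meta_completeness_at_least_max_constituent(self):
        rng = np.random.default_rng(9)
        table, graph, _ = heart_disease_worked_example()
        values = {
            var: [MISSING if rng.random() < 0.3 else int(rng.integers(0, 2))
                  for _ in range(40)]
            for var in ["mi", "ihd", "hf", "arrhythmia", "valve_disease"]
        }
        table = make_table(values)
        out, report = semantic_enrichment(table, graph)
        completeness = assess_completeness(out).variable
        for entry in report.sets:
            best = max(completeness[v] for v in entry["variables"])
            for agg in entry["appended"]:
                name = f"MV_{entry['mica_label'].replace(' ', '_')}_{agg}"
                assert completeness[name] >= best - 1e-12

    def test_binary_pair_reproduces_full_redundancy(self):
        # one constituent constant-on-support dominates MIN/MULT -> SU = 1
        table = make_table({
            "bisoprolol": [0, 0, 0, 1, 1],
            "betablocker": [0, 1, 1, 1, 1],
        })
        edges, _, _ = generate_toy_ontology()
        mapping = pd.DataFrame(
            [("bisoprolol", "C"), ("betablocker", "D")],
            columns=["variable", "entity_id"])
        graph = attach_variable_mappings(load_ontology_edges(edges), mapping)
        out, report = semantic_enrichment(table, graph)
        frame = report.redundancy_frame()
        fully = frame[frame["su"] >= 1.0 - 1e-12]
        assert not fully.empty
        assert "bisoprolol" in set(fully["constituent"])

    def test_name_collision_gets_suffix(self):
        table = make_table({
            "x1": [0, 1, 0], "x2": [1, 1, 0],
            "MV_node_A_SUM": [5, 6, 7],
        })
        edges, _, _ = generate_toy_ontology()
        mapping = pd.DataFrame([("x1", "C"), ("x2", "D")],
                               columns=["variable", "entity_id"])
        graph = attach_variable_mappings(load_ontology_edges(edges), mapping)
        labels = pd.DataFrame([("A", "node A")], columns=["id", "label"])
        graph.set_labels(dict(zip(labels["id"], labels["label"])))
        out, _ = semantic_enrichment(table, graph)
        assert "MV_node_A_SUM_2" in out.variables
        assert list(out.values("MV_node_A_SUM")) == [5, 6, 7]
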
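"""Centrality profiles, mean/median summaries and topological role labels."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cnvnet.centrality import (CentralityRoleClassifier, classify_roles,
                               compute_centralities, summarize)


def enumeration_betweenness(g):
    """Oracle: exhaustive shortest-path enumeration via the BFS predecessor DAG."""
    bet = {v: 0.0 for v in g}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        try:
            paths = list(_all_shortest_paths(g, s, t))
        except KeyError:
            continue  # unreachable pair
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


def _all_shortest_paths(g, s, t):
    # BFS predecessor DAG, then recursive unwinding from t
    dist = {s: 0}
    preds = {s: []}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    nxt.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        frontier = nxt
    if t not in dist:
        raise KeyError(t)

    def unwind(v):
        if v == s:
            yield [s]
            return
        for p in preds[v]:
            for partial in unwind(p):
                yield partial + [v]

    return unwind(t)


class TestComputeCentralities:
    def test_star_closed_form(self):
        prof = compute_centralities(nx.star_graph(4))
        assert prof.loc[0, "degree"] == 4
        assert prof.loc[0, "betweenness"] == 6.0  # C(4,2) leaf pairs
        assert (prof.loc[1:, "betweenness"] == 0).all()
        assert prof.loc[0, "closeness"] == 1.0 and prof.loc[0, "aspl"] == 1.0

    def test_path_closed_form(self):
        prof = compute_centralities(nx.path_graph(3))
        assert prof.loc[1, "betweenness"] == 1.0
        assert prof.loc[1, "closeness"] == 1.0
        assert prof.loc[1, "aspl"] == 1.0
        assert prof.loc[0, "closeness"] == pytest.approx(2 / 3)
        assert prof.loc[0, "aspl"] == pytest.approx(1.5)

    def test_singleton_reports_missing_not_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["A"])
        g.add_edge("B", "C")
        prof = compute_centralities(g)
        assert prof.loc["A", "degree"] == 0
        assert np.isnan(prof.loc["A", "closeness"])
        assert np.isnan(prof.loc["A", "aspl"])

    def test_betweenness_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2 ** 31)))
            prof = compute_centralities(g)
            oracle = enumeration_betweenness(g)
            for v in g:
                assert prof.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)

    def test_normalization_flag_rescales_only(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        raw = compute_centralities(g)["betweenness"]
        norm = compute_centralities(g, normalized_betweenness=True)["betweenness"]
        scale = (11 * 10) / 2
        np.testing.assert_allclose(norm * scale, raw, atol=1e-9)


class TestSummarize:
    def test_single_node_summary_is_its_own_values(self):
        prof = pd.DataFrame({"degree": [3.0], "betweenness": [2.0],
                             "closeness": [0.5], "aspl": [2.0]}, index=["A"])
        s = summarize(prof)
        assert s["mean_degree"] == 3.0 and s["median_aspl"] == 2.0

    def test_vertex_transitive_graph_every_node_equals_summary(self):
        prof = compute_centralities(nx.cycle_graph(6))
        s = summarize(prof)
        for v in range(6):
            assert prof.loc[v, "degree"] == s["mean_degree"]
            assert prof.loc[v, "betweenness"] == s["mean_betweenness"]
            assert prof.loc[v, "closeness"] == s["median_closeness"]
            assert prof.loc[v, "aspl"] == s["median_aspl"]

    def test_matches_spreadsheet_style_recomputation(self, rng):
        prof = pd.DataFrame({
            "degree": rng.integers(0, 20, 30).astype(float),
            "betweenness": rng.uniform(0, 100, 30),
            "closeness": rng.uniform(0, 1, 30),
            "aspl": rng.uniform(1, 6, 30)}, index=[f"N{i}" for i in range(30)])
        s = summarize(prof)
        assert s["mean_degree"] == pytest.approx(sum(prof["degree"]) / 30)
        assert s["median_closeness"] == pytest.approx(
            float(np.median(prof["closeness"])))

    def test_undefined_values_excluded_from_medians(self):
        prof = pd.DataFrame({"degree": [0.0, 2.0, 2.0],
                             "betweenness": [0.0, 1.0, 1.0],
                             "closeness": [np.nan, 0.4, 0.6],
                             "aspl": [np.nan, 2.0, 4.0]}, index=list("ABC"))
        s = summarize(prof)
        assert s["median_closeness"] == 0.5 and s["median_aspl"] == 3.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame(columns=["degree", "betweenness",
                                            "closeness", "aspl"]))


class TestClassifyRoles:
    def test_star_center_is_hub_leaves_peripheral(self):
        prof = compute_centralities(nx.star_graph(4))
        labels = classify_roles(prof)
        assert labels.loc[0, "hub_axis"] == "hub"
        assert (labels.drop(0)["hub_axis"] == "peripheral").all()

    def test_clique_bridge_is_connector_bottleneck(self):
        # two 5-cliques joined by a single degree-2 bridge node
        g = nx.Graph()
        for offset in (0, 5):
            g.add_edges_from((offset + a, offset + b)
                             for a, b in itertools.combinations(range(5), 2))
        g.add_edges_from([("bridge", 0), ("bridge", 5)])
        labels = classify_roles(compute_centralities(g))
        assert labels.loc["bridge", "hub_axis"] == "connector_bottleneck"

    def test_betweenness_scale_invariance(self, rng):
        prof = pd.DataFrame({
            "degree": rng.integers(0, 15, 40).astype(float),
            "betweenness": rng.uniform(0, 50, 40),
            "closeness": rng.uniform(0, 1, 40),
            "aspl": rng.uniform(1, 5, 40)}, index=[f"N{i}" for i in range(40)])
        base = classify_roles(prof)
        scaled = prof.assign(betweenness=prof["betweenness"] * 137.0)
        assert classify_roles(scaled).equals(base)

    def test_exactly_one_label_per_axis_and_order_invariance(self, rng):
        prof = pd.DataFrame({
            "degree": rng.integers(0, 15, 25).astype(float),
            "betweenness": rng.uniform(0, 50, 25),
            "closeness": rng.uniform(0, 1, 25),
            "aspl": rng.uniform(1, 5, 25)}, index=[f"N{i}" for i in range(25)])
        labels = classify_roles(prof)
        assert labels["hub_axis"].isin(
            ["hub", "provincial_hub", "connector_bottleneck", "peripheral"]).all()
        assert labels["integration_axis"].isin(
            ["integrated", "vulnerable", "intermediate"]).all()
        shuffled = prof.sample(frac=1, random_state=0)
        assert classify_roles(shuffled).sort_index().equals(labels.sort_index())

    def test_undefined_closeness_flagged_intermediate(self):
        g = nx.Graph()
        g.add_node("LONE")
        g.add_edge("A", "B")
        labels = classify_roles(compute_centralities(g))
        assert labels.loc["LONE", "integration_axis"] == "intermediate"
        assert not labels.loc["LONE", "integration_defined"]

    def test_boundary_counts_as_high_on_both_axes(self):
        prof = pd.DataFrame({"degree": [2.0, 2.0], "betweenness": [3.0, 3.0],
                             "closeness": [0.5, 0.5], "aspl": [2.0, 2.0]},
                            index=list("AB"))
        labels = classify_roles(prof)  # every value sits exactly at its threshold
        assert (labels["hub_axis"] == "hub").all()
        assert (labels["integration_axis"] == "integrated").all()

    def test_classifier_fit_predict_separates_learning_from_labelling(self):
        prof = compute_centralities(nx.star_graph(6))
        clf = CentralityRoleClassifier().fit(prof)
        assert set(clf.summary_.index) == {"mean_degree", "mean_betweenness",
                                           "median_closeness", "median_aspl"}
        labels = clf.predict(prof.loc[[0]])
        assert labels.loc[0, "hub_axis"] == "hub"
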
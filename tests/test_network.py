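"""Residue networks and centrality: construction rules, analytic closed
forms, and agreement with independent all-pairs shortest-path oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from jrpnet.network import (
    DegenerateDistributionError,
    betweenness,
    betweenness_all,
    build_contact_network,
    build_jrp_network,
    build_unweighted_network,
    centrality_table,
    closeness,
    closeness_all,
    count_atomic_contacts,
    edge_path_length,
    significant_residues,
    standardize,
)

TIE_TOL = 1e-12


def chain_coords(n, spacing=3.8):
    return {i + 1: np.array([i * spacing, 0.0, 0.0]) for i in range(n)}


# ------------------------------------------------------ independent oracles

def oracle_distances(g):
    """All-pairs shortest path lengths via scipy Floyd-Warshall."""
    nodes = list(g.nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    W = np.full((len(nodes), len(nodes)), np.inf)
    np.fill_diagonal(W, 0.0)
    for a, b, data in g.edges(data=True):
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = data["path_length"]
    return nodes, idx, floyd_warshall(W)


def oracle_closeness(g):
    nodes, idx, D = oracle_distances(g)
    out = {}
    for v in nodes:
        finite = D[idx[v]][np.isfinite(D[idx[v]])]
        out[v] = (len(finite) - 1) / finite.sum() if len(finite) > 1 else 0.0
    return out


def oracle_betweenness(g):
    """Path-count DP on Floyd-Warshall distances, independent of Brandes.

    sigma(s, t) = sum over neighbors u of t on a shortest path; node v
    gets fractional credit sigma(s,v) * sigma(v,t) / sigma(s,t) for every
    unordered pair (s, t) with v strictly between.
    """
    nodes, idx, D = oracle_distances(g)
    n = len(nodes)
    W = {(idx[a], idx[b]): d["path_length"] for a, b, d in g.edges(data=True)}
    W.update({(j, i): w for (i, j), w in W.items()})

    def sigma(s):
        counts = np.zeros(n)
        counts[s] = 1.0
        for t in np.argsort(D[s]):
            if t == s or not np.isfinite(D[s, t]):
                continue
            counts[t] = sum(
                counts[u]
                for u in range(n)
                if (u, t) in W and abs(D[s, u] + W[u, t] - D[s, t]) < TIE_TOL
            )
        return counts

    sig = np.array([sigma(s) for s in range(n)])
    B = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(D[s, t]) or sig[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if abs(D[s, v] + D[v, t] - D[s, t]) < TIE_TOL:
                B[nodes[v]] += sig[s, v] * sig[v, t] / sig[s, t]
    return B


def random_weighted_graph(rng, max_nodes=15):
    n = int(rng.integers(4, max_nodes + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.45:
            w = float(rng.uniform(0.2, 5.0))
            g.add_edge(i, j, weight=w, path_length=1.0 / w)
    return g


# ------------------------------------------------------------ construction

class TestBuildJrpNetwork:
    def test_weight_is_count_over_distance(self):
        coords = {1: [0, 0, 0], 2: [10.0, 0, 0]}
        g = build_jrp_network({(1, 2): 100}, coords)
        assert g[1][2]["weight"] == pytest.approx(10.0)
        assert g[1][2]["path_length"] == pytest.approx(0.1)

    def test_zero_count_no_edge(self):
        g = build_jrp_network({(1, 2): 0}, {1: [0, 0, 0], 2: [5, 0, 0]})
        assert g.number_of_edges() == 0

    def test_equal_counts_weights_inverse_to_distance(self):
        coords = {1: [0, 0, 0], 2: [5.0, 0, 0], 3: [10.0, 0, 0]}
        g = build_jrp_network({(1, 2): 50, (1, 3): 50}, coords)
        assert g[1][2]["weight"] == pytest.approx(2 * g[1][3]["weight"])

    def test_missing_coordinate_raises(self):
        with pytest.raises(KeyError):
            build_jrp_network({(1, 9): 10}, {1: [0, 0, 0], 2: [5, 0, 0]})

    def test_zero_distance_raises(self):
        with pytest.raises(ValueError):
            build_jrp_network({(1, 2): 10}, {1: [0, 0, 0], 2: [0, 0, 0]})


class TestBuildUnweightedNetwork:
    def test_straight_chain_is_path_graph(self):
        g = build_unweighted_network(chain_coords(8), cutoff=7.0)
        assert sorted(g.edges) == [(i, i + 1) for i in range(1, 8)]
        assert all(d["weight"] == 1.0 for _, _, d in g.edges(data=True))

    def test_cutoff_beyond_diameter_gives_complete_graph(self):
        g = build_unweighted_network(chain_coords(6), cutoff=100.0)
        assert g.number_of_edges() == 15

    def test_pair_exactly_at_cutoff_connected(self):
        coords = {1: [0.0, 0, 0], 2: [7.0, 0, 0]}
        assert build_unweighted_network(coords, cutoff=7.0).has_edge(1, 2)


class TestBuildContactNetwork:
    def test_table_pass_through(self):
        coords = chain_coords(10)
        g = build_contact_network(coords, contacts={(5, 9): 4})
        assert g[5][9]["weight"] == 4.0

    def test_atoms_beyond_cutoff_no_edge(self):
        atoms = {1: np.zeros((3, 3)), 2: np.full((3, 3), 10.0)}
        assert count_atomic_contacts(atoms) == {}

    def test_toy_structure_counts_atom_pairs(self):
        # residue 1 atoms at x=0 and x=1; residue 2 atoms at x=4 and x=9.
        # pairs within 4.5: (0,4), (1,4), and no others -> but (0,4) is 4.0,
        # (1,4) is 3.0, (0,9)=9, (1,9)=8  => 2 contacts; add one more atom
        # at x=4.4 from residue 1: (4.4,4)=0.4 within => 3 contacts
        atoms = {
            1: np.array([[0.0, 0, 0], [1.0, 0, 0], [4.4, 0, 0]]),
            2: np.array([[4.0, 0, 0], [9.0, 0, 0]]),
        }
        # brute-force oracle
        expected = sum(
            1
            for a in atoms[1]
            for b in atoms[2]
            if np.linalg.norm(a - b) <= 4.5
        )
        assert expected == 3
        assert count_atomic_contacts(atoms) == {(1, 2): 3}
        g = build_contact_network({1: [0, 0, 0], 2: [5, 0, 0]}, atoms=atoms)
        assert g[1][2]["weight"] == 3.0

    def test_requires_table_or_atoms(self):
        with pytest.raises(ValueError):
            build_contact_network(chain_coords(3))


def test_edge_path_length_modes():
    assert edge_path_length(4.0) == 0.25
    assert edge_path_length(1.0, "neglog") == pytest.approx(np.log(2))
    with pytest.raises(ValueError):
        edge_path_length(-1.0)
    with pytest.raises(ValueError):
        edge_path_length(1.0, "bogus")


# ------------------------------------------------------------- centrality

class TestAnalyticCentralities:
    def test_three_node_path_closeness(self):
        g = nx.path_graph(["A", "B", "C"])
        nx.set_edge_attributes(g, 1.0, "path_length")
        assert closeness(g, "B") == pytest.approx(1.0)
        assert closeness(g, "A") == pytest.approx(2 / 3)

    def test_complete_graph_closeness_is_one(self):
        g = nx.complete_graph(7)
        nx.set_edge_attributes(g, 1.0, "path_length")
        assert all(closeness(g, v) == pytest.approx(1.0) for v in g)

    def test_three_node_path_betweenness(self):
        g = nx.path_graph(3)
        nx.set_edge_attributes(g, 1.0, "path_length")
        b = betweenness_all(g)
        assert b[1] == pytest.approx(1.0)
        assert b[0] == b[2] == 0.0

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_star_hub_betweenness(self, k):
        g = nx.star_graph(k)  # node 0 is the hub
        nx.set_edge_attributes(g, 1.0, "path_length")
        assert betweenness(g, 0) == pytest.approx(k * (k - 1) / 2)


class TestCentralityOracles:
    def test_closeness_matches_floyd_warshall(self):
        rng = np.random.default_rng(100)
        for _ in range(20):
            g = random_weighted_graph(rng)
            expected = oracle_closeness(g)
            got = closeness_all(g)
            for v in g:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_betweenness_matches_path_count_oracle(self):
        rng = np.random.default_rng(200)
        for _ in range(20):
            g = random_weighted_graph(rng)
            expected = oracle_betweenness(g)
            got = betweenness_all(g)
            for v in g:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_disconnected_closeness_uses_reachable_nodes(self):
        g = nx.Graph()
        g.add_edge("a", "b", path_length=1.0)
        g.add_edge("b", "c", path_length=1.0)
        g.add_node("iso")
        assert closeness(g, "iso") == 0.0
        assert closeness(g, "b") == pytest.approx(1.0)  # (3-1)/2 on its component


class TestStandardize:
    def test_hand_computed_example(self):
        z = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_all_equal_raises(self):
        with pytest.raises(DegenerateDistributionError):
            standardize([2.0, 2.0, 2.0])

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        z = standardize(rng.normal(3.0, 2.0, size=100))
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0)


class TestScalingInvariance:
    def test_weight_rescaling_preserves_z_scores(self):
        rng = np.random.default_rng(300)
        coords = chain_coords(10)
        counts = {
            (i, j): int(rng.integers(1, 500))
            for i, j in itertools.combinations(range(1, 11), 2)
            if rng.random() < 0.5
        }
        g1 = build_jrp_network(counts, coords)
        g2 = build_jrp_network({k: 10 * v for k, v in counts.items()}, coords)
        t1 = centrality_table(g1)
        t2 = centrality_table(g2)
        np.testing.assert_allclose(t1["z_B"], t2["z_B"], atol=1e-9)
        np.testing.assert_allclose(t1["z_C"], t2["z_C"], atol=1e-9)

    def test_path_graph_closeness_peaks_at_center(self):
        g = build_unweighted_network(chain_coords(9), cutoff=7.0)
        c = closeness_all(g)
        assert max(c, key=c.get) == 5


class TestSignificantResidues:
    def make_table_graph(self, z_b_values):
        g = nx.path_graph(range(1, len(z_b_values) + 1))
        nx.set_edge_attributes(g, 1.0, "path_length")
        nx.set_edge_attributes(g, 1.0, "weight")
        import pandas as pd

        table = pd.DataFrame(
            {
                "residue_id": list(g.nodes),
                "z_B": z_b_values,
                "z_C": [-1.0] * len(z_b_values),
            }
        )
        return table, g

    def test_threshold_filter(self):
        table, g = self.make_table_graph([2.5, 1.0, 0.5])
        records = significant_residues(table, g, 2.0, 1.5)
        assert [r["residue_id"] for r in records] == [1]

    def test_no_significant_residues_empty_list(self):
        table, g = self.make_table_graph([0.1, 0.2, 0.3])
        assert significant_residues(table, g, 2.0, 1.5) == []

    def test_neighbors_of_significant_center_reported(self):
        # center of a 3-path significant; ends annotated as known hotspots
        table, g = self.make_table_graph([0.0, 3.0, 0.0])
        records = significant_residues(
            table, g, 2.0, 1.5, annotations={1: "hotspot", 3: "hotspot"}
        )
        assert len(records) == 1
        assert [n["residue_id"] for n in records[0]["neighbors"]] == [1, 3]

    def test_flags_report_which_criterion_fired(self):
        table, g = self.make_table_graph([2.5, 0.0, 0.0])
        table.loc[2, "z_C"] = 2.0
        records = significant_residues(table, g, 2.0, 1.5)
        by_id = {r["residue_id"]: r for r in records}
        assert by_id[1]["significant_B"] and not by_id[1]["significant_C"]
        assert by_id[3]["significant_C"] and not by_id[3]["significant_B"]


def test_centrality_table_z_columns_standardized():
    rng = np.random.default_rng(400)
    g = random_weighted_graph(rng, max_nodes=12)
    while not nx.is_connected(g) or g.number_of_nodes() < 4:
        g = random_weighted_graph(rng, max_nodes=12)
    table = centrality_table(g)
    assert abs(table["z_B"].mean()) < 1e-10
    assert np.std(table["z_B"]) == pytest.approx(1.0)
    assert abs(table["z_C"].mean()) < 1e-10
    assert np.std(table["z_C"]) == pytest.approx(1.0)
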
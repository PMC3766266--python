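"""MI estimation, null-threshold calibration, DPI pruning, neighbourhoods."""

import networkx as nx
import numpy as np
import pytest

from ntsig.network import (
    AracneConfig,
    GeneNetwork,
    apply_dpi,
    build_network,
    calibrate_mi_threshold,
    estimate_mi,
    extract_neighborhood,
    mi_matrix,
    neighborhoods_to_gmt,
)
from ntsig.simulate import generate_markov_triplet


def _entropy_bits(counts):
    p = np.asarray(counts, float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log2(p)).sum())


class TestEstimateMI:
    def test_identical_vectors_give_partition_entropy(self):
        """y = x, n=64, B=7: plug-in MI equals the entropy of the equal-
        frequency partition (~log2 7), computed here by direct counting."""
        x = np.random.default_rng(0).normal(size=64)
        mi = estimate_mi(x, x, bins=7, correct=False)
        # direct oracle: bin sizes of splitting 64 ranks into 7 equal-frequency bins
        sizes = np.bincount((np.arange(64) * 7) // 64)
        assert mi == pytest.approx(_entropy_bits(sizes), abs=1e-12)
        assert mi == pytest.approx(np.log2(7), abs=0.01)

    def test_constant_vector_zero_with_warning(self, caplog):
        x = np.random.default_rng(1).normal(size=40)
        with caplog.at_level("WARNING"):
            assert estimate_mi(x, np.zeros(40)) == 0.0
        assert "zero-variance" in caplog.text

    def test_independent_nulls_stay_below_calibrated_threshold(self):
        cfg = AracneConfig(n_null=20000, seed=0)
        thr = calibrate_mi_threshold(500, cfg)
        rng = np.random.default_rng(5)
        exceed = sum(
            estimate_mi(rng.normal(size=500), rng.normal(size=500)) >= thr for _ in range(100)
        )
        assert exceed <= 1  # threshold targets p = 1e-7, far beyond 1/100

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert estimate_mi(x, y) == pytest.approx(estimate_mi(np.exp(x), y**3 + y))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            estimate_mi(np.ones(10), np.ones(9))
        with pytest.raises(ValueError):
            estimate_mi(np.array([1.0, np.nan]), np.array([1.0, 2.0]))


class TestCalibration:
    def test_median_cutoff_matches_empirical_median(self):
        cfg = AracneConfig(mi_p_cutoff=0.5, n_null=5000, seed=3)
        thr = calibrate_mi_threshold(100, cfg)
        rng = np.random.default_rng(10)
        null = [estimate_mi(rng.normal(size=100), rng.normal(size=100)) for _ in range(2000)]
        assert thr == pytest.approx(np.median(null), abs=0.01)

    def test_threshold_decreases_with_sample_size(self):
        cfg = AracneConfig(n_null=5000, seed=1)
        thrs = [calibrate_mi_threshold(n, cfg) for n in (50, 100, 200)]
        assert thrs[0] > thrs[1] > thrs[2]

    def test_reproducible_under_fixed_seed(self):
        cfg = AracneConfig(n_null=2000, seed=4)
        assert calibrate_mi_threshold(80, cfg) == calibrate_mi_threshold(80, cfg)

    def test_small_null_rejected(self):
        with pytest.raises(ValueError):
            calibrate_mi_threshold(80, AracneConfig(n_null=100))


def _triangle(ab, bc, ac):
    g = nx.Graph()
    g.add_edge("A", "B", mi=ab)
    g.add_edge("B", "C", mi=bc)
    g.add_edge("A", "C", mi=ac)
    return GeneNetwork(g)


class TestDPI:
    def test_weak_transitive_edge_removed(self):
        out = apply_dpi(_triangle(0.5, 0.4, 0.1), tolerance=0.15)
        assert {frozenset(e[:2]) for e in out.edges} == {frozenset("AB"), frozenset("BC")}

    def test_edge_within_tolerance_kept(self):
        out = apply_dpi(_triangle(0.5, 0.4, 0.36), tolerance=0.15)
        assert len(out.edges) == 3  # 0.36 >= 0.85 * 0.4

    def test_tolerance_one_removes_nothing(self):
        out = apply_dpi(_triangle(0.5, 0.4, 0.001), tolerance=1.0)
        assert len(out.edges) == 3

    def test_subset_and_idempotent_on_random_graphs(self):
        rng = np.random.default_rng(6)
        g = nx.gnp_random_graph(25, 0.3, seed=9)
        for a, b in g.edges:
            g.edges[a, b]["mi"] = float(rng.uniform(0.05, 1.0))
        net = GeneNetwork(nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes}))
        once = apply_dpi(net, 0.15)
        twice = apply_dpi(once, 0.15)
        edges_in = {frozenset(e[:2]) for e in net.edges}
        edges_once = {frozenset(e[:2]) for e in once.edges}
        assert edges_once <= edges_in
        assert {frozenset(e[:2]) for e in twice.edges} == edges_once

    def test_markov_chain_edge_removed_most_seeds(self):
        """DPI removes X-Z (the transitive edge) while keeping X-Y and Y-Z."""
        ok = 0
        for seed in range(50):
            df = generate_markov_triplet(500, 0.9, seed=seed)
            g = nx.Graph()
            for a, b in [("X", "Y"), ("Y", "Z"), ("X", "Z")]:
                g.add_edge(a, b, mi=estimate_mi(df[a].to_numpy(), df[b].to_numpy()))
            edges = {frozenset(e[:2]) for e in apply_dpi(GeneNetwork(g), 0.15).edges}
            ok += frozenset("XZ") not in edges and frozenset("XY") in edges and frozenset("YZ") in edges
        assert ok >= 0.95 * 50

    def test_gene_relabelling_permutes_network(self):
        net = _triangle(0.5, 0.4, 0.1)
        relabel = {"A": "Z1", "B": "Z2", "C": "Z3"}
        permuted = GeneNetwork(nx.relabel_nodes(net.graph, relabel))
        out1 = {frozenset(e[:2]) for e in apply_dpi(net, 0.15).edges}
        out2 = {frozenset(e[:2]) for e in apply_dpi(permuted, 0.15).edges}
        assert out2 == {frozenset({relabel[a], relabel[b]}) for a, b in out1}


class TestNeighborhood:
    def test_isolated_seed(self):
        g = nx.Graph()
        g.add_node("S")
        g.add_edge("A", "B", mi=0.5)
        sub = extract_neighborhood(GeneNetwork(g), "S")
        assert sub.members == {"S"} and not sub.edges

    def test_star_graph_identity(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {i: ("HUB" if i == 0 else f"g{i}") for i in g.nodes})
        nx.set_edge_attributes(g, 0.4, "mi")
        sub = extract_neighborhood(GeneNetwork(g), "HUB")
        assert sub.members == set(g.nodes)
        assert len(sub.edges) == 5

    def test_matches_brute_force_induced_subgraph(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        nx.set_edge_attributes(g, 0.3, "mi")
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        sub = extract_neighborhood(GeneNetwork(g), "g0")
        members = {"g0"} | {n for n in g.nodes if g.has_edge("g0", n)}
        edges = {frozenset((a, b)) for a in members for b in members if a < b and g.has_edge(a, b)}
        assert sub.members == members
        assert {frozenset(e[:2]) for e in sub.edges} == edges

    def test_missing_seed_raises(self):
        with pytest.raises(KeyError):
            extract_neighborhood(_triangle(0.1, 0.1, 0.1), "missing")


def test_build_network_recovers_hub_block(small_cohort):
    """The planted hub partners connect to the hub in the pruned network."""
    from ntsig.matrix import ExpressionMatrix

    cohort = small_cohort
    m = cohort.matrices[0]
    partners = cohort.truth["hub_partners"][:10]
    genes = ["ERBB3"] + partners + [g for g in m.row_ids if g.startswith("GENE")][:30]
    sub = ExpressionMatrix(m.values.loc[genes], m.dataset_id, "gene")
    cfg = AracneConfig(mi_p_cutoff=1e-3, n_null=5000, seed=0)
    net = build_network(sub, cfg)
    hood = extract_neighborhood(net, "ERBB3")
    recovered = hood.members & set(partners)
    assert len(recovered) >= 5

    gmt = neighborhoods_to_gmt(net, ["ERBB3"])
    assert sorted(hood.members) == gmt["ERBB3_network"]


def test_mi_matrix_is_symmetric_and_matches_pairwise(random_matrix):
    vals = random_matrix.values.to_numpy()[:8]
    mm = mi_matrix(vals)
    assert np.allclose(mm, mm.T)
    assert mm[1, 4] == pytest.approx(estimate_mi(vals[1], vals[4]))
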
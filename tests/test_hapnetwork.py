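"""Haplotype-network construction, rooting, and recurrent-site detection."""

import numpy as np
import pytest

from hapclock.hapnetwork import build_network, find_recurrent_sites, shared_derived_counts
from hapclock.simdata import SimConfig, simulate_tree_panel
from hapclock.types import MISSING, HapclockError

from conftest import make_panel


def test_single_haplotype_class_gives_one_root_node():
    panel = make_panel([[0, 1, 0]] * 5)
    net = build_network(panel, min_variant_freq=0.0)
    assert net.graph.number_of_nodes() == 1
    assert net.graph.number_of_edges() == 0
    assert net.root == "010"
    assert net.node_for("010")["count"] == 5


def test_three_haplotype_chain_is_rooted_at_the_ancestral_string():
    panel = make_panel([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
    net = build_network(panel, min_variant_freq=0.0)
    assert set(net.graph.edges) == {("000", "100"), ("100", "110")}
    assert net.edge_sites("000", "100") == {"s1"}
    assert net.edge_sites("100", "110") == {"s2"}
    assert net.root == "000"
    assert find_recurrent_sites(net) == {}


def test_common_haplotypes_show_one_duplicated_transition(
    common_hap_panel, pattern_string
):
    """On the 11 common haplotypes, the key-site neighbor pair is adjacent with a
    two-site edge and exactly one site mutates on two edges."""
    net = build_network(common_hap_panel)
    c10, c11 = pattern_string("C10"), pattern_string("C11")
    assert net.adjacent(c10, c11)
    assert net.edge_sites(c10, c11) == {"c1", "c11"}
    recurrent = find_recurrent_sites(net)
    assert set(recurrent) == {"c1"}
    assert len(recurrent["c1"]) == 2
    assert net.root == pattern_string("C1")


def test_network_is_invariant_to_chromosome_and_site_permutation():
    rows = np.array(
        [[0, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1], [0, 0, 0, 0]],
        dtype=np.int8,
    )
    rng = np.random.default_rng(7)
    base = build_network(make_panel(rows), min_variant_freq=0.0)
    perm = rng.permutation(len(rows))
    shuffled = build_network(make_panel(rows[perm]), min_variant_freq=0.0)
    assert set(base.graph.edges) == set(shuffled.graph.edges)
    assert base.root == shuffled.root


def test_low_frequency_sites_are_filtered_before_dropping_chromosomes():
    rows = [[1, 0], [1, 1], [0, MISSING]] + [[0, 0], [1, 0]] * 3 + [[0, 0]]
    panel = make_panel(rows)
    net = build_network(panel, min_variant_freq=0.2)
    # s2 (1 derived call in 9) is filtered out, so the chromosome with the
    # MISSING call at s2 survives
    assert [s.site_id for s in net.retained_sites] == ["s1"]
    assert net.dropped_chromosomes == 0
    assert sum(net.graph.nodes[n]["count"] for n in net.graph.nodes) == len(rows)


def test_missing_at_retained_site_drops_the_chromosome():
    rows = [[0, 0], [1, 1], [MISSING, 1], [0, 0], [1, 1], [0, 0]]
    net = build_network(make_panel(rows), min_variant_freq=0.1)
    assert net.dropped_chromosomes == 1
    assert sum(net.graph.nodes[n]["count"] for n in net.graph.nodes) == 5


def test_rare_nodes_are_kept_but_flagged_not_displayed():
    rows = [[0, 0]] * 99 + [[1, 1]]
    net = build_network(make_panel(rows), min_variant_freq=0.0, min_hap_freq=0.05)
    assert net.node_for("11")["displayed"] is False
    assert net.node_for("00")["displayed"] is True
    assert net.graph.number_of_nodes() == 2


def tree_truth_edges(panel, truth):
    """Expected network edges from the generating genealogy (zero-length
    branches contracted)."""
    strings = ["".join(str(int(a)) for a in row) for row in panel.alleles]
    label = {s.position: s.label for s in panel.sites}
    edges = {}
    for pos, child in truth["site_origin"].items():
        parent = truth["parents"][child]
        a, b = strings[parent], strings[child]
        if a != b:
            key = tuple(sorted((a, b)))
            edges.setdefault(key, set()).add(label[pos])
    return edges


@pytest.mark.parametrize("seed", range(8))
def test_tree_simulations_recover_the_true_mutation_partition(seed):
    """Without recombination the network is the true tree: one edge per branch,
    labeled with exactly that branch's mutations, and no recurrent sites."""
    cfg = SimConfig(
        model="tree", n_chrom=8, region_length=10_000, mutation_rate=3e-8,
        tmrca=10_000, seed=seed,
    )
    panel, truth = simulate_tree_panel(cfg)
    net = build_network(panel, min_variant_freq=0.0)
    expected = tree_truth_edges(panel, truth)
    got = {
        tuple(sorted(e)): set(net.graph.edges[e]["sites"]) for e in net.graph.edges
    }
    assert got == expected
    assert net.graph.number_of_edges() == net.graph.number_of_nodes() - 1
    assert find_recurrent_sites(net) == {}
    assert net.root == "0" * panel.n_sites  # founder haplotype is observed


@pytest.mark.parametrize("seed", range(4))
def test_root_to_node_path_lengths_equal_derived_counts(seed):
    """On a tree network, edge labels along the root path sum to the node's
    derived-allele count."""
    import networkx as nx

    cfg = SimConfig(
        model="tree", n_chrom=10, region_length=10_000, mutation_rate=3e-8,
        tmrca=8_000, seed=100 + seed,
    )
    panel, _ = simulate_tree_panel(cfg)
    net = build_network(panel, min_variant_freq=0.0)
    for node in net.graph.nodes:
        path = nx.shortest_path(net.graph, net.root, node)
        steps = sum(
            len(net.edge_sites(a, b)) for a, b in zip(path, path[1:])
        )
        assert steps == node.count("1")


def test_recombinant_panel_flags_sites_inside_a_donated_segment():
    """With the ancestral haplotype observed alongside two diverged parents,
    a recombinant forces one parental segment's sites onto two edges."""
    from hapclock.simdata import simulate_recombinant_panel
    from hapclock.types import SiteAnnotation

    sites = [SiteAnnotation(f"s{i}", 100 * i, "A", "G") for i in range(1, 7)]
    cfg = SimConfig(
        model="recombinant",
        parent_a="111000", parent_b="000111",
        sites=sites, crossover_position=350,
        n_parent_a=10, n_parent_b=10, n_recombinant=10,
    )
    panel, truth = simulate_recombinant_panel(cfg)
    with_root = make_panel(
        np.vstack([panel.alleles, np.zeros((10, 6), dtype=np.int8)]),
        positions=[s.position for s in panel.sites],
    )
    net = build_network(with_root, min_variant_freq=0.0)
    recurrent = set(find_recurrent_sites(net))
    left, right = {"s100", "s200", "s300"}, {"s400", "s500", "s600"}
    assert recurrent  # the crossover is visible as duplicated transitions
    assert recurrent <= left or recurrent <= right


def test_no_complete_chromosomes_after_filtering_is_an_error():
    # every chromosome is MISSING at some retained site, so all are dropped
    panel = make_panel([[0, MISSING], [MISSING, 0]])
    with pytest.raises(HapclockError, match="no complete chromosomes"):
        build_network(panel, min_variant_freq=0.0)


def test_monomorphic_panel_collapses_to_a_single_class():
    net = build_network(make_panel([[0, 0], [0, 0], [0, 0]]))
    assert net.graph.number_of_nodes() == 1
    assert net.node_for(net.root)["count"] == 3


def test_shared_derived_counts_scores_candidate_splits():
    rows = [[0, 0, 0], [1, 1, 0], [1, 1, 1]]
    net = build_network(make_panel(rows), min_variant_freq=0.0)
    assert shared_derived_counts(net, {"110", "111"}) == 2  # s1 and s2
    assert shared_derived_counts(net, {"111"}) == 1  # s3 only
    with pytest.raises(HapclockError, match="unknown haplotypes"):
        shared_derived_counts(net, {"101"})
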
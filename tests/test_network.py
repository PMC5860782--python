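"""Network container, file dialect, generator, motifs and rewiring."""

import itertools

import networkx as nx
import numpy as np
import pytest

from stoichbal.network import (
    GenConfig,
    InterfaceNetwork,
    NetworkParseError,
    count_motifs,
    generate_goh_iin,
    read_network,
    rewire,
    write_network,
)


# ---------------------------------------------------------------- I/O

def test_read_small_file(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("A\ti1\tB\ti1\nB\ti2\tC\ti1\nC\ti1\tA\ti1\n")
    net = read_network(p)
    assert len(net.proteins) == 3
    assert net.n_interfaces == 4
    assert net.n_edges == 3


def test_read_self_edge_and_duplicates(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("# comment\nA\ti1\tA\ti1\nA\ti1\tA\ti1\n")
    net = read_network(p)
    assert net.n_edges == 1
    assert net.edges[0][0] == net.edges[0][1] == ("A", "i1")


def test_read_malformed_line_reports_lineno(tmp_path):
    p = tmp_path / "net.tsv"
    p.write_text("A\ti1\tB\ti1\nbadline\n")
    with pytest.raises(NetworkParseError) as ei:
        read_network(p)
    assert ei.value.line == 2


def test_roundtrip_identity(tmp_path, mixed_net):
    p = tmp_path / "out.tsv"
    write_network(mixed_net, p)
    assert read_network(p) == mixed_net
    # byte stability
    first = p.read_bytes()
    write_network(read_network(p), p)
    assert p.read_bytes() == first


def test_invariant_violations():
    with pytest.raises(ValueError):
        InterfaceNetwork(["A"], [("A", "i1")], [])  # no edges
    with pytest.raises(ValueError):
        InterfaceNetwork(["A"], [("B", "i1")], [(("B", "i1"), ("B", "i1"))])
    with pytest.raises(ValueError):
        InterfaceNetwork(
            ["A", "B"],
            [("A", "i1"), ("B", "i1")],
            [(("A", "i1"), ("B", "i1")), (("B", "i1"), ("A", "i1"))],  # dup
        )


# ---------------------------------------------------------- generator

def test_goh_generator_basics():
    cfg = GenConfig(n_nodes=150, n_edges=150, gamma=0.0, seed=7)
    net = generate_goh_iin(cfg)
    assert net.n_edges == 150
    g = net.interface_graph()
    assert sum(d for _, d in g.degree()) == 2 * 150
    # determinism
    net2 = generate_goh_iin(cfg)
    assert net == net2


def test_goh_gamma0_degree_distribution_matches_er():
    """gamma=0 static sampling should look binomial (mean degree 2)."""
    degs = []
    for seed in range(30):
        net = generate_goh_iin(GenConfig(150, 150, 0.0, seed))
        degs.extend(d for _, d in net.interface_graph().degree())
    degs = np.asarray(degs)
    assert abs(degs.mean() - 2.0) < 0.05
    # binomial(n-1, p) variance with p chosen for mean 2
    assert abs(degs.var() - 2.0) < 0.35


def test_goh_heavier_tail_at_high_gamma():
    md0, md8 = [], []
    for seed in range(15):
        n0 = generate_goh_iin(GenConfig(150, 150, 0.0, seed))
        n8 = generate_goh_iin(GenConfig(150, 150, 0.8, seed))
        md0.append(max(d for _, d in n0.interface_graph().degree()))
        md8.append(max(d for _, d in n8.interface_graph().degree()))
    assert np.mean(md8) > np.mean(md0)


def test_goh_infeasible_raises():
    with pytest.raises(ValueError):
        GenConfig(n_nodes=4, n_edges=7, gamma=0.0, seed=0)


# ------------------------------------------------------------- motifs

def _brute_force_motifs(g: nx.Graph) -> dict:
    """Independent subgraph-enumeration oracle for graphs with <= 8 nodes."""
    adj = {v: set(g.neighbors(v)) - {v} for v in g}
    nodes = list(g)
    tri = chains = 0
    for trip in itertools.combinations(nodes, 3):
        e = sum(1 for a, b in itertools.combinations(trip, 2) if b in adj[a])
        if e == 3:
            tri += 1
    for b in nodes:
        for a, c in itertools.combinations(sorted(adj[b], key=str), 2):
            if c not in adj[a]:
                chains += 1
    hubs = sum(
        len(list(itertools.combinations(adj[v], 3))) for v in nodes
    )
    squares = 0
    flags = 0
    for quad in itertools.combinations(nodes, 4):
        sub = g.subgraph(quad)
        degs = sorted(d for _, d in sub.degree())
        ne = sub.number_of_edges()
        if ne == 4 and degs == [2, 2, 2, 2]:
            squares += 1
        if ne == 4 and degs == [1, 2, 2, 3]:
            flags += 1
    return {"chain": chains, "triangle": tri, "square": squares,
            "hub": hubs, "flag": flags}


def test_motif_defining_cases(triangle_net):
    m = count_motifs(triangle_net)
    assert m["triangle"] == 1 and m["chain"] == 0
    c4 = nx.cycle_graph(4)
    m = count_motifs(c4)
    assert m["square"] == 1 and m["triangle"] == 0
    flag = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3)])
    assert count_motifs(flag)["flag"] == 1


@pytest.mark.parametrize("seed", range(12))
def test_motifs_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    g = nx.gnp_random_graph(n, 0.45, seed=seed)
    assert count_motifs(g) == _brute_force_motifs(g)


# ------------------------------------------------------------ rewiring

def _multi_interface_net():
    # parent PPIN: star around hub H with 4 leaves + leaf-leaf edge
    proteins = ["H", "P1", "P2", "P3", "P4"]
    interfaces = [("H", "a"), ("H", "b"), ("P1", "i"), ("P2", "i"),
                  ("P3", "i"), ("P4", "i")]
    edges = [
        (("H", "a"), ("P1", "i")),
        (("H", "a"), ("P2", "i")),
        (("H", "b"), ("P3", "i")),
        (("H", "b"), ("P4", "i")),
        (("P1", "i"), ("P2", "i")),
    ]
    return InterfaceNetwork(proteins, interfaces, edges)


def test_child_randomize_preserves_parent_graph():
    net = _multi_interface_net()
    for seed in range(5):
        child = rewire(net, "child-iin-randomize", seed=seed)
        assert nx.utils.graphs_equal(child.protein_graph(), net.protein_graph())
        assert sorted(child.interfaces) == sorted(net.interfaces)
        assert child.n_edges == net.n_edges


def test_rewire_determinism():
    net = _multi_interface_net()
    a = rewire(net, "child-iin-randomize", seed=3)
    b = rewire(net, "child-iin-randomize", seed=3)
    assert a == b


def test_topology_optimize_reduces_chain_triangle():
    net = generate_goh_iin(GenConfig(40, 50, 0.0, seed=2))
    before = count_motifs(net)
    after_net = rewire(net, "topology-optimize", iters=300, seed=2)
    after = count_motifs(after_net)
    assert after_net.n_edges == net.n_edges
    score = lambda m: m["chain"] + m["triangle"] - m["square"] - m["hub"]
    assert score(after) <= score(before)
    with pytest.raises(ValueError):
        rewire(net, "topology-optimize", iters=0)
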
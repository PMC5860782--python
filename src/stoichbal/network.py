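"""Interface-resolved protein interaction networks (IINs).

An IIN refines a protein-protein interaction network (PPIN) by recording
*which binding interface* on each protein carries each interaction.  Two
partners that share an interface on a protein bind competitively; partners
on distinct interfaces bind noncompetitively.  This distinction is what
makes stoichiometric balance non-trivial: a competitive interface must be
expressed at the *sum* of its partners' demands, a noncompetitive protein
only at the matching demand.

The module provides the network container, a 4-column TSV dialect, a
static-model random-network generator (Goh-style preferential weights),
motif counting for the five specificity-relevant motifs (chain, triangle,
square, hub, flag), and the two rewiring modes used to build null and
topology-optimized networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Interface",
    "InterfaceNetwork",
    "GenConfig",
    "NetworkParseError",
    "read_network",
    "write_network",
    "generate_goh_iin",
    "count_motifs",
    "rewire",
]

# An interface is identified by (protein id, interface id).
Interface = tuple[str, str]


class NetworkParseError(ValueError):
    """Raised for malformed network files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _norm_edge(a: Interface, b: Interface) -> tuple[Interface, Interface]:
    return (a, b) if a <= b else (b, a)


@dataclass
class InterfaceNetwork:
    """An interface-interaction network.

    Parameters
    ----------
    proteins : list of protein ids.
    interfaces : list of (protein, interface) pairs; each interface belongs
        to exactly one protein.
    edges : list of unordered interface pairs. Self-pairs (an interface
        binding a copy of itself, i.e. homodimerization) are allowed.
    edge_labels : optional per-edge labels keyed by the normalized edge.
    """

    proteins: list[str]
    interfaces: list[Interface]
    edges: list[tuple[Interface, Interface]]
    edge_labels: dict[tuple[Interface, Interface], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [_norm_edge(a, b) for a, b in self.edges]
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if len(self.interfaces) < 1:
            raise ValueError("network must declare at least one interface")
        if len(self.edges) < 1:
            raise ValueError("network must declare at least one edge")
        pset = set(self.proteins)
        if len(pset) != len(self.proteins):
            raise ValueError("duplicate protein ids")
        iset = set(self.interfaces)
        if len(iset) != len(self.interfaces):
            raise ValueError("duplicate interface declarations")
        for p, _ in self.interfaces:
            if p not in pset:
                raise ValueError(f"interface declared on unknown protein {p!r}")
        seen = set()
        for a, b in self.edges:
            if a not in iset or b not in iset:
                raise ValueError(f"edge endpoint {a!r}/{b!r} is not a declared interface")
            e = _norm_edge(a, b)
            if e in seen:
                raise ValueError(f"duplicate edge {e!r}")
            seen.add(e)

    # -- convenience views --------------------------------------------
    @property
    def n_interfaces(self) -> int:
        return len(self.interfaces)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def interfaces_of(self, protein: str) -> list[Interface]:
        return [i for i in self.interfaces if i[0] == protein]

    def interface_graph(self) -> nx.Graph:
        """The IIN as a networkx graph over interface nodes (self-loops kept)."""
        g = nx.Graph()
        g.add_nodes_from(self.interfaces)
        g.add_edges_from(self.edges)
        return g

    def protein_graph(self) -> nx.Graph:
        """Projection to the parent PPIN: proteins as nodes."""
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        for (pa, _), (pb, _) in self.edges:
            g.add_edge(pa, pb)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InterfaceNetwork):
            return NotImplemented
        return (
            sorted(self.proteins) == sorted(other.proteins)
            and sorted(self.interfaces) == sorted(other.interfaces)
            and sorted(self.edges) == sorted(other.edges)
        )


# ---------------------------------------------------------------------
# File I/O: 4-column TSV (protein_a, interface_a, protein_b, interface_b),
# '#' comments, duplicate lines collapse, self-edges written once.
# ---------------------------------------------------------------------

def read_network(path) -> InterfaceNetwork:
    """Read an interface network from a 4-column TSV file.

    Each non-comment line declares one interface-interface edge.  Duplicate
    edge lines collapse to one edge.
    """
    proteins: list[str] = []
    interfaces: list[Interface] = []
    edges: list[tuple[Interface, Interface]] = []
    seen_p: set[str] = set()
    seen_i: set[Interface] = set()
    seen_e: set[tuple[Interface, Interface]] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise NetworkParseError(
                    f"expected 4 tab-separated columns, got {len(parts)}", lineno
                )
            pa, ia, pb, ib = (p.strip() for p in parts)
            if not all((pa, ia, pb, ib)):
                raise NetworkParseError("empty field", lineno)
            for p, i in ((pa, ia), (pb, ib)):
                if p not in seen_p:
                    seen_p.add(p)
                    proteins.append(p)
                if (p, i) not in seen_i:
                    seen_i.add((p, i))
                    interfaces.append((p, i))
            e = _norm_edge((pa, ia), (pb, ib))
            if e not in seen_e:
                seen_e.add(e)
                edges.append(e)
    if not edges:
        raise NetworkParseError("file declares no edges")
    return InterfaceNetwork(proteins, interfaces, edges)


def write_network(net: InterfaceNetwork, path) -> None:
    """Write `net` in the TSV dialect with deterministic (lexicographic) order."""
    net.validate()
    lines = []
    for a, b in sorted(_norm_edge(a, b) for a, b in net.edges):
        lines.append(f"{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# protein_a\tinterface_a\tprotein_b\tinterface_b\n")
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------
# Random IIN generation: static model with preferential weights.
# ---------------------------------------------------------------------

@dataclass
class GenConfig:
    """Configuration for the static-model random network generator.

    gamma=0 gives a binomial (Erdos-Renyi-like) degree distribution;
    gamma -> 1 gives power-law ("scale-free") degree distributions.
    One interface per protein, so the PPIN equals the IIN.
    """

    n_nodes: int
    n_edges: int
    gamma: float = 0.0
    seed: int = 0
    optimize_topology: bool = False
    optimizer_iters: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_edges > max_edges:
            raise ValueError("n_edges exceeds the number of distinct node pairs")
        if self.n_nodes < 2 or self.n_edges < 1:
            raise ValueError("need at least 2 nodes and 1 edge")


class GenerationError(RuntimeError):
    pass


def generate_goh_iin(cfg: GenConfig) -> InterfaceNetwork:
    """Sample a random single-interface IIN from the static model.

    Node i (1-based) carries weight i**(-gamma); edges between distinct
    nodes are drawn with probability proportional to the weight product and
    rejected-resampled until ``n_edges`` unique edges exist.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    w = np.arange(1, n + 1, dtype=float) ** (-cfg.gamma)
    p = w / w.sum()
    edges: set[tuple[int, int]] = set()
    max_tries = 1000 * cfg.n_edges + 100000
    tries = 0
    while len(edges) < cfg.n_edges:
        i, j = rng.choice(n, size=2, p=p)
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {cfg.n_edges} unique edges after {tries} draws"
            )
        if i == j:
            continue
        e = (min(i, j), max(i, j))
        edges.add(e)
    width = len(str(n))
    names = [f"P{k+1:0{width}d}" for k in range(n)]
    proteins = list(names)
    interfaces = [(nm, "i1") for nm in names]
    elist = [
        ((names[i], "i1"), (names[j], "i1")) for i, j in sorted(edges)
    ]
    net = InterfaceNetwork(proteins, interfaces, elist)
    if cfg.optimize_topology:
        net = rewire(net, "topology-optimize", iters=cfg.optimizer_iters, seed=cfg.seed + 1)
    return net


# ---------------------------------------------------------------------
# Motif counting.  Conventions (fixed, see docs/methods.md):
#   chain    -- induced path a-b-c (edge a-c absent); counted per unordered
#               {a,c} pair through b.
#   triangle -- 3-clique.
#   square   -- induced (chordless) 4-cycle.
#   hub      -- star of 3 leaves: one per C(deg, 3) at each node.
#   flag     -- induced triangle-plus-pendant on 4 nodes (pendant adjacent
#               to exactly one triangle vertex).
# Self-loops are ignored for motif purposes.
# ---------------------------------------------------------------------

def count_motifs(net: InterfaceNetwork | nx.Graph) -> dict[str, int]:
    """Count the five specificity motifs in the interface graph."""
    g = net if isinstance(net, nx.Graph) else net.interface_graph()
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    adj = {v: set(g.neighbors(v)) for v in g}

    chains = 0
    triangles = 0
    hubs = 0
    for b in g:
        nbrs = sorted(adj[b])
        k = len(nbrs)
        hubs += k * (k - 1) * (k - 2) // 6
        for x in range(k):
            for y in range(x + 1, k):
                a, c = nbrs[x], nbrs[y]
                if c in adj[a]:
                    triangles += 1
                else:
                    chains += 1
    triangles //= 3

    squares = 0
    # chordless 4-cycles a-b-c-d-a: for each non-adjacent diagonal pair
    # {b,d}, every non-adjacent pair of common neighbors closes one; each
    # cycle is found once per diagonal pair, hence the final halving.
    nodes = sorted(g, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    for b in nodes:
        for d in nodes:
            if index[d] <= index[b] or d in adj[b]:
                continue
            cs = sorted(adj[b] & adj[d], key=str)
            for x in range(len(cs)):
                for y in range(x + 1, len(cs)):
                    if cs[y] not in adj[cs[x]]:
                        squares += 1
    squares //= 2

    flags = 0
    for a in nodes:
        for b in adj[a]:
            if index[b] <= index[a]:
                continue
            for c in adj[a] & adj[b]:
                if index[c] <= index[b]:
                    continue
                # triangle a,b,c; pendant adjacent to exactly one vertex
                tri = (a, b, c)
                for v in tri:
                    for d in adj[v]:
                        if d in tri:
                            continue
                        deg_in_tri = sum(1 for t in tri if d in adj[t])
                        if deg_in_tri == 1:
                            flags += 1
    return {
        "chain": chains,
        "triangle": triangles,
        "square": squares,
        "hub": hubs,
        "flag": flags,
    }


# ---------------------------------------------------------------------
# Rewiring.
# ---------------------------------------------------------------------

def _child_randomize(net: InterfaceNetwork, rng: np.random.Generator) -> InterfaceNetwork:
    # Reassign which interface on each protein carries each parent edge;
    # preserves the parent PPIN edge multiset and interface counts.
    if_by_protein: dict[str, list[str]] = {}
    for p, i in net.interfaces:
        if_by_protein.setdefault(p, []).append(i)

    for _attempt in range(200):
        assignments = []
        used: dict[str, set[str]] = {p: set() for p in if_by_protein}
        for (pa, _), (pb, _) in net.edges:
            ia = if_by_protein[pa][rng.integers(len(if_by_protein[pa]))]
            ib = if_by_protein[pb][rng.integers(len(if_by_protein[pb]))]
            assignments.append(((pa, ia), (pb, ib)))
            used[pa].add(ia)
            used[pb].add(ib)
        # every interface must carry >= 1 edge and edges must stay unique
        ok = all(len(used[p]) == len(if_by_protein[p]) for p in if_by_protein)
        norm = [_norm_edge(a, b) for a, b in assignments]
        if ok and len(set(norm)) == len(norm):
            return InterfaceNetwork(
                list(net.proteins), list(net.interfaces), norm
            )
    raise GenerationError("child randomization failed to cover all interfaces; "
                          "network may have interfaces with too few parent edges")


def _topology_optimize(
    net: InterfaceNetwork,
    iters: int,
    rng: np.random.Generator,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> InterfaceNetwork:
    # Greedy Monte Carlo edge swaps lowering
    #   w1*chains + w2*triangles - w3*squares - w4*hubs,
    # preserving edge count and the connectivity class of the graph.
    w1, w2, w3, w4 = weights

    def objective(g: nx.Graph) -> float:
        m = count_motifs(g)
        return w1 * m["chain"] + w2 * m["triangle"] - w3 * m["square"] - w4 * m["hub"]

    g = net.interface_graph()
    was_connected = nx.is_connected(g) if g.number_of_nodes() > 0 else True
    cur = objective(g)
    nodes = list(g.nodes())
    for _ in range(iters):
        edges = list(g.edges())
        u, v = edges[rng.integers(len(edges))]
        # propose moving one endpoint to a random non-neighbor
        keep = (u, v)[int(rng.integers(2))]
        other = v if keep == u else u
        cand = nodes[rng.integers(len(nodes))]
        if cand == keep or cand == other or g.has_edge(keep, cand):
            continue
        g.remove_edge(u, v)
        g.add_edge(keep, cand)
        new = objective(g)
        accept = new < cur
        if accept and was_connected and not nx.is_connected(g):
            accept = False
        if accept:
            cur = new
        else:
            g.remove_edge(keep, cand)
            g.add_edge(u, v)
    return InterfaceNetwork(
        list(net.proteins), list(net.interfaces), [ _norm_edge(a, b) for a, b in g.edges() ]
    )


def rewire(
    net: InterfaceNetwork,
    mode: str,
    iters: int = 1000,
    seed: int = 0,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> InterfaceNetwork:
    """Rewire a network.

    mode='child-iin-randomize' draws a random child IIN for the same parent
    protein network (randomizes competitive vs noncompetitive binding).
    mode='topology-optimize' runs greedy edge swaps that decrease chain and
    triangle motifs and increase square and hub motifs.
    """
    if iters <= 0:
        raise ValueError("iters must be positive")
    rng = np.random.default_rng(seed)
    if mode == "child-iin-randomize":
        return _child_randomize(net, rng)
    if mode == "topology-optimize":
        return _topology_optimize(net, iters, rng, weights)
    raise ValueError(f"unknown rewire mode {mode!r}")
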
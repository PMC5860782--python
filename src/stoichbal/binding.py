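"""Misinteraction cost of copy-number imbalance on motifs and large IINs.

Five small competitive motifs (chain, triangle, square, hub, flag) recur in
interface-interaction networks and differ in how binding specificity can be
designed.  Here each motif node is an interface on its own protein; the
motif edges are the specific interactions and *every* other pair, including
self-pairs, is allowed as a weak misinteraction.  Steady-state misbinding
cost is mapped over copy-number grids, and the sensitivity of each motif to
imbalance is summarized as the percent cost increase along the principal
axis of the low-cost region.

For large networks the same machinery measures the cost of randomly
sampled versus balanced copy numbers; balanced copies come either from an
equal-complex assignment (copies proportional to degree) or from the
nonnegative least-squares projection min ||A x - C0||^2, x >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import scipy.optimize
from scipy.interpolate import RegularGridInterpolator

from .gillespie import BindingModel, CostResult, simulate_to_steady_state, cost
from .network import InterfaceNetwork
from .stats import AbundanceDistribution

__all__ = [
    "MOTIF_EDGES",
    "motif_model",
    "network_model",
    "motif_surface",
    "CostSurface",
    "pc_sensitivity",
    "balance_iin_copies",
    "iin_misinteraction_study",
]

# specific edge sets; node order fixes the species order of the model
MOTIF_EDGES: dict[str, tuple[tuple[str, ...], tuple[tuple[str, str], ...]]] = {
    "chain": (("A", "B", "C"), (("A", "B"), ("B", "C"))),
    "triangle": (("A", "B", "C"), (("A", "B"), ("B", "C"), ("A", "C"))),
    "square": (("A1", "B1", "A2", "B2"),
               (("A1", "B1"), ("B1", "A2"), ("A2", "B2"), ("B2", "A1"))),
    "hub": (("H", "L1", "L2", "L3"), (("H", "L1"), ("H", "L2"), ("H", "L3"))),
    "flag": (("A", "B", "C", "D"),
             (("A", "B"), ("B", "C"), ("A", "C"), ("A", "D"))),
}


def motif_model(
    name: str,
    kd_spec: float = 1e-9,
    kd_ratio: float = 1000.0,
    copies: dict[str, float] | float = 50.0,
    koff: float = 1.0,
) -> BindingModel:
    """Binding model for one of the five motifs.

    Motif edges are specific at ``kd_spec`` (molar); every remaining
    unordered pair of nodes, self-pairs included, misinteracts at
    ``kd_spec * kd_ratio``.
    """
    if name not in MOTIF_EDGES:
        raise ValueError(f"unknown motif {name!r}; choose from {sorted(MOTIF_EDGES)}")
    if kd_ratio < 1:
        raise ValueError("kd_ratio must be >= 1")
    nodes, edges = MOTIF_EDGES[name]
    index = {n: k for k, n in enumerate(nodes)}
    spec = {}
    for a, b in edges:
        i, j = sorted((index[a], index[b]))
        spec[(i, j)] = kd_spec
    nonspec = {
        p: kd_spec * kd_ratio
        for p in combinations_with_replacement(range(len(nodes)), 2)
        if p not in spec
    }
    if isinstance(copies, dict):
        cvec = np.array([float(copies[n]) for n in nodes])
    else:
        cvec = np.full(len(nodes), float(copies))
    return BindingModel(list(nodes), cvec, spec, nonspec, koff=koff)


def network_model(
    net: InterfaceNetwork,
    copies: dict[str, float],
    kd_spec: float | dict[tuple[str, str], float] = 100e-9,
    kd_nonspec: float | dict[tuple[str, str], float] = 100e-6,
    koff: float = 1.0,
) -> BindingModel:
    """Binding model for a single-interface IIN: network edges are specific,
    all other pairs (self-pairs included) nonspecific.

    kd values may be scalars or per-pair tables keyed by sorted protein-id
    pairs (an energy table read from file, for instance).
    """
    for p in net.proteins:
        if len(net.interfaces_of(p)) != 1:
            raise ValueError("network_model requires one interface per protein")
    species = sorted(net.proteins)
    index = {s: k for k, s in enumerate(species)}
    spec_pairs = set()
    for (pa, _), (pb, _) in net.edges:
        spec_pairs.add(tuple(sorted((index[pa], index[pb]))))

    def kd_for(table, a: str, b: str, default_scalar):
        if isinstance(table, dict):
            key = tuple(sorted((a, b)))
            if key not in table:
                raise KeyError(f"missing K_D entry for pair {key}")
            return table[key]
        return default_scalar

    spec = {}
    nonspec = {}
    for i, j in combinations_with_replacement(range(len(species)), 2):
        a, b = species[i], species[j]
        if (i, j) in spec_pairs:
            spec[(i, j)] = kd_for(kd_spec, a, b, kd_spec)
        else:
            nonspec[(i, j)] = kd_for(kd_nonspec, a, b, kd_nonspec)
    cvec = np.array([float(copies[s]) for s in species])
    return BindingModel(species, cvec, spec, nonspec, koff=koff)


@dataclass
class CostSurface:
    """Cost over a 2D copy-number grid, axes normalized by fixed abundance."""

    motif: str
    var_nodes: tuple[str, str]
    x_norm: np.ndarray          # grid axis for var_nodes[0], copies / fixed copies
    y_norm: np.ndarray
    cost: np.ndarray            # shape (len(x), len(y))
    fixed_copies: float


def motif_surface(
    name: str,
    var_nodes: tuple[str, str],
    grid: np.ndarray,
    fixed_copies: float = 50.0,
    kd_spec: float = 1e-9,
    kd_ratio: float = 1000.0,
    n_runs: int = 1000,
    seed: int = 0,
    cost_mode: str = "complex",
) -> CostSurface:
    """Map misinteraction cost over a grid of copies of two variable nodes.

    All other nodes are held at ``fixed_copies``; axes are reported
    normalized by the fixed abundance.
    """
    nodes, _ = MOTIF_EDGES[name]
    for v in var_nodes:
        if v not in nodes:
            raise ValueError(f"{v!r} is not a node of motif {name!r}")
    grid = np.asarray(grid, dtype=float)
    costs = np.empty((len(grid), len(grid)))
    master = np.random.default_rng(seed)
    for ix, cx in enumerate(grid):
        for iy, cy in enumerate(grid):
            copies = {n: fixed_copies for n in nodes}
            copies[var_nodes[0]] = cx
            copies[var_nodes[1]] = cy
            model = motif_model(name, kd_spec, kd_ratio, copies)
            res = simulate_to_steady_state(
                model, n_runs=n_runs, seed=int(master.integers(2**31 - 1))
            )
            costs[ix, iy] = cost(res, mode=cost_mode)
    return CostSurface(
        name, tuple(var_nodes), grid / fixed_copies, grid / fixed_copies,
        costs, fixed_copies,
    )


def pc_sensitivity(
    surface: CostSurface,
    decile: float = 0.1,
    n_samples: int = 101,
    optimum: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cost sensitivity along the principal axis of the low-cost region.

    Fits the first principal component of the lowest-``decile`` grid points
    (in normalized coordinates), interpolates cost along that axis through
    the optimum, and returns (distance, percent change from the optimum).
    ``optimum`` overrides the grid argmin, for motifs whose global minimum
    is a trivial corner (the chain's B=0, for instance).
    """
    xs, ys, z = surface.x_norm, surface.y_norm, surface.cost
    if np.allclose(z, z.flat[0]):
        raise ValueError("flat cost surface; sensitivity undefined")
    pts = np.array([(x, y) for x in xs for y in ys])
    vals = z.ravel()
    thresh = np.quantile(vals, decile)
    low = pts[vals <= thresh]
    centered = low - low.mean(axis=0)
    cov = centered.T @ centered / max(len(low) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, -1]  # principal axis of the low-cost region

    if optimum is None:
        imin = np.unravel_index(np.argmin(z), z.shape)
        opt = np.array([xs[imin[0]], ys[imin[1]]])
        c0 = z[imin]
    else:
        opt = np.asarray(optimum, dtype=float)
        interp0 = RegularGridInterpolator((xs, ys), z)
        c0 = float(interp0(opt)[0])
    if c0 == 0:
        c0 = max(vals[vals > 0].min(), 1e-12)

    interp = RegularGridInterpolator((xs, ys), z, bounds_error=False, fill_value=np.nan)
    # longest in-grid reach along +/- direction from the optimum
    tmax = 0.0
    for sgn in (1.0, -1.0):
        lo, hi = 0.0, np.hypot(xs[-1] - xs[0], ys[-1] - ys[0])
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            p = opt + sgn * mid * direction
            if xs[0] <= p[0] <= xs[-1] and ys[0] <= p[1] <= ys[-1]:
                lo = mid
            else:
                hi = mid
        tmax = max(tmax, lo)
    dist = np.linspace(0.0, tmax, n_samples)
    along = []
    for d in dist:
        vs = []
        for sgn in (1.0, -1.0):
            p = opt + sgn * d * direction
            v = float(interp(p)[0])
            if np.isfinite(v):
                vs.append(v)
        along.append(np.mean(vs) if vs else np.nan)
    along = np.asarray(along)
    pct = 100.0 * (along - c0) / c0
    pct[0] = 0.0
    return dist, pct


def balance_iin_copies(
    net: InterfaceNetwork,
    C0: dict[str, float] | None = None,
    mode: str = "balanced",
    complexes_per_edge: float = 50.0,
) -> dict[str, float]:
    """Balanced copy numbers for a single-interface network.

    mode='equal-complex': assign the same number of desired complexes to
    every edge; protein copies come out proportional to degree (self-edges
    count twice).  mode='balanced': project C0 onto the balanced cone by
    min ||A x - C0||^2, x >= 0 and forward-solve C = A x_min.
    """
    for p in net.proteins:
        if len(net.interfaces_of(p)) != 1:
            raise ValueError("balance_iin_copies requires one interface per protein")
    proteins = sorted(net.proteins)
    index = {p: k for k, p in enumerate(proteins)}
    A = np.zeros((len(proteins), len(net.edges)))
    for j, ((pa, _), (pb, _)) in enumerate(net.edges):
        if pa == pb:
            A[index[pa], j] = 2.0
        else:
            A[index[pa], j] = 1.0
            A[index[pb], j] = 1.0
    if mode == "equal-complex":
        x = np.full(len(net.edges), float(complexes_per_edge))
    elif mode == "balanced":
        if C0 is None:
            raise ValueError("mode='balanced' requires C0")
        c0 = np.array([float(C0[p]) for p in proteins])
        x, _ = scipy.optimize.nnls(A, c0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    c = A @ x
    return {p: float(c[index[p]]) for p in proteins}


def iin_misinteraction_study(
    nets: list[InterfaceNetwork],
    dist: AbundanceDistribution,
    kd_spec: float | dict = 100e-9,
    kd_nonspec: float | dict = 100e-6,
    kd_scale_sweep: tuple[float, ...] = (1.0,),
    n_random: int = 3,
    n_runs: int = 50,
    seed: int = 0,
) -> list[dict]:
    """Misinteraction cost of balanced vs randomly sampled copy numbers.

    For each network and each affinity scale in ``kd_scale_sweep`` (both
    K_Ds are multiplied by the scale, preserving the specific/nonspecific
    gap; decade factors sweep the mean binding strength), simulates steady
    state under (a) copy numbers sampled from the abundance distribution
    and (b) their balanced projection, and reports protein-weighted costs
    plus the sensitivity ratio cost(random) / cost(balanced).
    """

    def _scaled(table, s):
        if isinstance(table, dict):
            return {k: v * s for k, v in table.items()}
        return table * s

    master = np.random.default_rng(seed)
    results = []
    for net in nets:
        proteins = sorted(net.proteins)
        per_net = {"n_proteins": len(proteins), "n_edges": net.n_edges,
                   "by_scale": {}}
        for scale in kd_scale_sweep:
            rec = {"random": [], "balanced": [], "sensitivity": []}
            for _ in range(n_random):
                raw = dist.draw(len(proteins), master)
                c_rand = {p: float(v) for p, v in zip(proteins, raw)}
                c_bal = balance_iin_copies(net, c_rand, mode="balanced")
                cost_pair = []
                for cvec in (c_rand, c_bal):
                    model = network_model(
                        net, cvec, _scaled(kd_spec, scale), _scaled(kd_nonspec, scale)
                    )
                    res = simulate_to_steady_state(
                        model, n_runs=n_runs, seed=int(master.integers(2**31 - 1))
                    )
                    cost_pair.append(cost(res, mode="protein"))
                rec["random"].append(cost_pair[0])
                rec["balanced"].append(cost_pair[1])
                rec["sensitivity"].append(
                    cost_pair[0] / cost_pair[1] if cost_pair[1] > 0 else float("inf")
                )
            per_net["by_scale"][scale] = rec
        if len(kd_scale_sweep) == 1:
            only = per_net["by_scale"][kd_scale_sweep[0]]
            per_net.update(only)
        results.append(per_net)
    return results
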
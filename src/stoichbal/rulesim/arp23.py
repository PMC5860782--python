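"""Multi-protein assembly yield of the ARP2/3 complex.

The seven-subunit ARP2/3 complex is an obligate assembly: function
requires exactly one copy of each subunit.  The core subunit ARC19 binds
five of the other six; in yeast proteomics it is ~5-fold underexpressed
relative to the rest, making it both an assembly bottleneck and a source
of incorrect complexes (two ARC19s bridged through peripheral bonds).

The model wires the subunits as an ARC19-centered star plus peripheral
edges, with core (ARC19) bindings ~10-fold stronger than peripheral ones
and cooperative ring closure: once two members of a triangle are joined
by two bonds, the third bond closes at an effectively infinite rate.

Yield = N_desired / (N_desired + N_undesired) where N_desired counts
proteins in complete complexes (7 per complex) and N_undesired counts
proteins in incomplete or misassembled complexes; free monomers are
ignored.
"""

from __future__ import annotations

import numpy as np

from .engine import BindRule, MoleculeType, World
from .misinteract import misinteraction_rules

__all__ = ["SUBUNITS", "TOPOLOGY", "arp23_model", "arp23_yield", "yield_sweep"]

SUBUNITS = ("ARC19", "ARP2", "ARP3", "ARC40", "ARC35", "ARC15", "ARC18")

# ARC19 hub binding five subunits, plus peripheral contacts informed by the
# crystal-structure contact map: the two actin-related subunits touch each
# other, ARC18 (ARPC3) docks onto ARP3, and ARC40 (ARPC1) contacts ARC35
# (ARPC2).  The edge list is configurable.
TOPOLOGY: tuple[tuple[str, str], ...] = (
    ("ARC19", "ARP2"),
    ("ARC19", "ARP3"),
    ("ARC19", "ARC40"),
    ("ARC19", "ARC35"),
    ("ARC19", "ARC15"),
    ("ARP2", "ARP3"),
    ("ARP3", "ARC18"),
    ("ARC40", "ARC35"),
)

# effective volume: 50 copies correspond to 1 uM
_AVOGADRO = 6.02214076e23
DEFAULT_VOLUME_L = 50.0 / (1e-6 * _AVOGADRO)


def arp23_model(
    copies_mode: str = "balanced",
    peripheral_kd: float = 1e-9,
    core_factor: float = 10.0,
    base_copies: int = 250,
    misinteraction_f: float | None = None,
    rate_mode: str = "fixed-kon",
    kon_molar: float = 1e6,
    koff: float = 1.0,
    volume_L: float = DEFAULT_VOLUME_L,
    topology: tuple[tuple[str, str], ...] = TOPOLOGY,
) -> World:
    """Build the seven-subunit assembly world.

    copies_mode='balanced' gives every subunit ``base_copies``;
    'observed-like' sets the core subunit ARC19 to one fifth of that,
    matching its ~5-fold underexpression.  Bonds to ARC19 are
    ``core_factor``-fold stronger than peripheral bonds.

    rate_mode='fixed-kon' (default) holds the association rate at the
    diffusion-limited ``kon_molar`` and varies koff = kon * K_D, so strong
    binders are long-lived and can kinetically trap misassembled
    intermediates -- the regime where copy-number balance matters for
    yield.  rate_mode='fixed-koff' instead holds koff and varies kon, in
    which case every sweep point anneals equally fast.
    """
    if core_factor <= 0:
        raise ValueError("core_factor must be positive")
    if rate_mode not in ("fixed-kon", "fixed-koff"):
        raise ValueError(f"unknown rate_mode {rate_mode!r}")
    if copies_mode == "balanced":
        copies = {s: base_copies for s in SUBUNITS}
    elif copies_mode == "observed-like":
        copies = {s: base_copies for s in SUBUNITS}
        copies["ARC19"] = max(base_copies // 5, 1)
    else:
        raise ValueError(f"unknown copies_mode {copies_mode!r}")

    # one site per partner (noncompetitive binding within the complex)
    partners: dict[str, list[str]] = {s: [] for s in SUBUNITS}
    for a, b in topology:
        partners[a].append(b)
        partners[b].append(a)
    types = [
        MoleculeType(s, [f"to_{p}" for p in partners[s]], copies[s])
        for s in SUBUNITS
    ]
    rules = []
    for a, b in topology:
        kd = peripheral_kd / core_factor if "ARC19" in (a, b) else peripheral_kd
        k_off = kon_molar * kd if rate_mode == "fixed-kon" else koff
        rules.append(BindRule((a, f"to_{b}"), (b, f"to_{a}"), kd, koff=k_off))
    if misinteraction_f is not None:
        mis = misinteraction_rules(types, rules, misinteraction_f, koff=koff)
        if rate_mode == "fixed-kon":
            for r in mis:
                r.koff = kon_molar * r.kd_molar
        rules += mis
    return World(types, rules, volume_L=volume_L, ring_closure=True)


def arp23_yield(world: World, topology=TOPOLOGY) -> float:
    """Assembly yield of the current world state.

    A complex is complete when it holds exactly one of each subunit and
    every topology edge is bonded.  Free monomers are ignored; an all-free
    state yields 0 by convention.
    """
    n_desired = 0
    n_undesired = 0
    want = {s: 1 for s in SUBUNITS}
    n_edges = len(topology)
    for cx in world.census():
        if cx["size"] < 2:
            continue
        if cx["counts"] == want and cx["n_bonds"] >= n_edges:
            n_desired += cx["size"]
        else:
            n_undesired += cx["size"]
    tot = n_desired + n_undesired
    return n_desired / tot if tot else 0.0


def yield_sweep(
    copies_mode: str,
    peripheral_kds=(1e-8, 1e-9, 1e-10),
    core_factor: float = 10.0,
    base_copies: int = 250,
    misinteraction_f: float | None = None,
    t_end: float = 60.0,
    n_runs: int = 3,
    seed: int = 0,
    **model_kwargs,
) -> dict:
    """Max assembly yield over a peripheral-K_D sweep (decade steps).

    Each sweep point averages the final-time yield over ``n_runs``
    replicate trajectories.
    """
    master = np.random.default_rng(seed)
    per_kd = {}
    for kd in peripheral_kds:
        ys = []
        for _ in range(n_runs):
            world = arp23_model(
                copies_mode,
                peripheral_kd=kd,
                core_factor=core_factor,
                base_copies=base_copies,
                misinteraction_f=misinteraction_f,
                **model_kwargs,
            )
            world.simulate(t_end, seed=int(master.integers(2**31 - 1)))
            ys.append(arp23_yield(world))
        per_kd[kd] = float(np.mean(ys))
    best = max(per_kd, key=per_kd.get)
    return {"per_kd": per_kd, "max_yield": per_kd[best], "argmax_kd": best}
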
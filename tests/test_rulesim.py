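"""Network-free engine: compartments, conservation, assembly models."""

import math

import numpy as np
import pytest

from stoichbal.gillespie import DEFAULT_VOLUME_L, simulate_to_steady_state, BindingModel
from stoichbal.rulesim import (
    BindRule,
    MoleculeType,
    VesicleConfig,
    World,
    arp23_model,
    arp23_yield,
    cme_model,
    membrane_enhancement,
    misinteraction_rules,
    site_mean_kds,
    vesicle_stats,
    yield_sweep,
)
from stoichbal.rulesim.arp23 import SUBUNITS, TOPOLOGY
from stoichbal.rulesim.clathrin import membrane_area_per_adaptor_nm2


# ----------------------------------------------------- 2D enhancement

def test_membrane_enhancement_geometry():
    # cytosol 37.2 um^3 over membrane slab 75.7 um^2 * 2 nm
    assert membrane_enhancement(37.2, 75.7, 1.0) == pytest.approx(245.7, rel=1e-3)
    # doubling sigma halves the enhancement exactly
    assert membrane_enhancement(37.2, 75.7, 2.0) == pytest.approx(
        membrane_enhancement(37.2, 75.7, 1.0) / 2.0
    )


# ----------------------------------------- cross-engine consistency

def test_pair_equilibrium_matches_binary_engine():
    """Two molecule types, one rule, no membrane: both engines agree."""
    kd = 1e-6
    types = [MoleculeType("A", ["b"], 50), MoleculeType("B", ["a"], 50)]
    rules = [BindRule(("A", "b"), ("B", "a"), kd)]
    bound = []
    for s in range(25):
        w = World(types, rules, volume_L=DEFAULT_VOLUME_L)
        w.simulate(12.0, seed=s)
        bound.append(sum(c["size"] for c in w.census()) / 2)
    rule_mean = np.mean(bound)
    m = BindingModel(["A", "B"], np.array([50.0, 50.0]), {(0, 1): kd}, {})
    res = simulate_to_steady_state(m, n_runs=200, seed=0)
    se = np.std(bound, ddof=1) / np.sqrt(len(bound))
    assert abs(rule_mean - res.pair_means[(0, 1)]) <= 3 * (se + res.pair_sems[(0, 1)]) + 0.5


def test_dimerization_self_rule():
    types = [MoleculeType("D", ["dim"], 40)]
    rules = [BindRule(("D", "dim"), ("D", "dim"), 1e-9)]
    w = World(types, rules, volume_L=DEFAULT_VOLUME_L)
    w.simulate(10.0, seed=0)
    census = w.census()
    assert all(c["size"] == 2 for c in census)
    # strong K_D: nearly all dimerized
    assert sum(c["size"] for c in census) >= 36


# ------------------------------------------------- vesicle machinery

def _mini_vesicle_world(threshold=2):
    """Tiny clathrin-like system with a low vesicle threshold."""
    types = [
        MoleculeType("CHC", ["leg", "leg", "leg", "clc", "clc", "clc", "ada"], 12),
        MoleculeType("CLC", ["chc"], 40),
        MoleculeType("AD", ["lip", "chc"], 20),
        MoleculeType("L", ["head"], 400, membrane_resident=True),
    ]
    rules = [
        BindRule(("CHC", "leg"), ("CHC", "leg"), 1e-5),
        BindRule(("CHC", "clc"), ("CLC", "chc"), 1e-10),
        BindRule(("CHC", "ada"), ("AD", "chc"), 1e-6),
        BindRule(("AD", "lip"), ("L", "head"), 1e-8),
    ]
    ves = VesicleConfig(
        chc_type="CHC", clc_type="CLC", n_clc_full=3, threshold=threshold,
        k_dump=1000.0, k_recyc=1000.0, adaptor_types=("AD",),
        polymer_rule=(("CHC", "leg"), ("CHC", "leg")),
    )
    return World(types, rules, volume_L=DEFAULT_VOLUME_L / 10,
                 enhancement=200.0, vesicle=ves)


def test_conservation_through_dump_and_recycle():
    w = _mini_vesicle_world()
    before = w.type_totals()
    res = w.simulate(60.0, seed=2)
    assert w.type_totals() == before
    # everything is accounted for: complexed + free + in transit
    in_complex = sum(len(c.mols) for c in w.complexes.values())
    free = sum(w.free_monomers().values())
    assert in_complex + free + len(w.in_transit) == w.n_mols


def test_vesicles_form_and_carry_full_triskelia():
    w = _mini_vesicle_world()
    res = w.simulate(120.0, seed=3)
    assert len(res.vesicles) >= 1
    for v in res.vesicles:
        assert v.n_full_triskelia >= 2
        assert v.composition.get("L", 0) >= 1  # vesicles are membrane complexes
    vs = vesicle_stats(res, adaptor_types=("AD",))
    assert vs.n_vesicles == len(res.vesicles)
    assert 0.0 <= vs.adaptor_recruited_fraction <= 1.0


def test_area_per_adaptor_arithmetic():
    # 100 nm sphere with 1900 adaptors -> ~16.5 nm^2 each
    assert membrane_area_per_adaptor_nm2(1900) == pytest.approx(16.53, rel=1e-3)


# -------------------------------------------------- misinteractions

def test_geometric_mean_kds():
    rules = [
        BindRule(("X", "a"), ("Y", "b"), 22e-6),
        BindRule(("X", "a"), ("Z", "c"), 160e-6),
    ]
    means = site_mean_kds(rules)
    assert means[("X", "a")] == pytest.approx(math.sqrt(22e-6 * 160e-6))


def test_misinteraction_rules_cover_unruled_pairs():
    types = [MoleculeType("X", ["a"], 5), MoleculeType("Y", ["b"], 5),
             MoleculeType("L", ["head"], 5, membrane_resident=True)]
    rules = [BindRule(("X", "a"), ("Y", "b"), 1e-6)]
    mis = misinteraction_rules(types, rules, f=1e3, exclude_types=("L",))
    pairs = {tuple(sorted((r.a, r.b))) for r in mis}
    assert pairs == {(("X", "a"), ("X", "a")), (("Y", "b"), ("Y", "b"))}
    for r in mis:
        assert not r.specific
        assert r.kd_molar == pytest.approx(1e3 * 1e-6)


def test_energy_gap_of_misinteraction_factors():
    assert math.log(1e4) == pytest.approx(9.21, abs=0.005)
    assert math.log(1e3) == pytest.approx(6.91, abs=0.005)


# ------------------------------------------------------------- ARP2/3

def test_arp23_copy_modes():
    wb = arp23_model("balanced", base_copies=100)
    wo = arp23_model("observed-like", base_copies=100)
    tb = {t.name: t.copies for t in wb.types}
    to = {t.name: t.copies for t in wo.types}
    assert all(v == 100 for v in tb.values())
    assert to["ARC19"] == 20 and all(to[s] == 100 for s in SUBUNITS if s != "ARC19")
    with pytest.raises(ValueError):
        arp23_model("balanced", core_factor=0)


def test_arp23_yield_hand_cases():
    w = arp23_model("balanced", base_copies=4, peripheral_kd=1e-12)
    # nothing simulated yet: all free monomers -> yield 0 by convention
    assert arp23_yield(w) == 0.0
    w.simulate(500.0, seed=1)
    y = arp23_yield(w)
    assert 0.0 <= y <= 1.0
    # census-level identity: desired counts are multiples of 7
    want = {s: 1 for s in SUBUNITS}
    n_complete = sum(
        1 for c in w.census()
        if c["counts"] == want and c["n_bonds"] >= len(TOPOLOGY)
    )
    bound = sum(c["size"] for c in w.census() if c["size"] >= 2)
    if bound:
        assert y == pytest.approx(7 * n_complete / bound)


def test_ring_closure_closes_trimer():
    # A-B and B-C bonds force the A-C ring bond immediately
    types = [MoleculeType(n, ["x", "y"], 1) for n in ("A", "B", "C")]
    rules = [
        BindRule(("A", "x"), ("B", "x"), 1e-6),
        BindRule(("B", "y"), ("C", "x"), 1e-6),
        BindRule(("A", "y"), ("C", "y"), 1e-6),
    ]
    w = World(types, rules, volume_L=DEFAULT_VOLUME_L, ring_closure=True)
    w.simulate(200.0, seed=0, max_events=200)
    census = w.census()
    if census and census[0]["size"] == 3:
        # triangle must be closed: 3 bonds, not 2
        assert census[0]["n_bonds"] == 3


def test_arp23_balanced_beats_observed_across_sweep():
    for f in (None, 1e3):
        rb = yield_sweep("balanced", peripheral_kds=(1e-9,), n_runs=3, seed=8,
                         misinteraction_f=f)
        ro = yield_sweep("observed-like", peripheral_kds=(1e-9,), n_runs=3, seed=8,
                         misinteraction_f=f)
        assert rb["max_yield"] > ro["max_yield"]


# ------------------------------------------------------------ clathrin

def test_cme_model_structure():
    w = cme_model(scale=0.02)
    names = {t.name for t in w.types}
    assert names == {"CHC", "CLC", "SLA2", "ENT", "EDE1", "SYP1",
                     "YAP1801", "YAP1802", "L"}
    assert len(w.rules) == 16
    assert w.enhancement == pytest.approx(245.7, rel=1e-3)
    w2 = cme_model(scale=0.02, misinteraction_f=1e4)
    assert len(w2.rules) > 200
    # knockout
    w3 = cme_model(scale=0.02, copy_overrides={"SYP1_0": 0})
    assert {t.name: t.copies for t in w3.types}["SYP1"] == 0
    with pytest.raises(KeyError):
        cme_model(copy_overrides={"NOPE": 1})


def test_cme_knockout_slows_vesicles():
    """Removing the ENT adaptor should suppress vesicle formation."""
    base = cme_model(scale=0.25)
    rb = base.simulate(12.0, seed=5, stop_after_vesicles=2)
    ko = cme_model(scale=0.25, copy_overrides={"ENT_0": 0})
    rk = ko.simulate(12.0, seed=5, stop_after_vesicles=2)
    def first_time(res):
        return res.vesicles[0].time if res.vesicles else float("inf")
    assert len(rb.vesicles) >= len(rk.vesicles)
    assert first_time(rb) < first_time(rk)
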
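"""Motif models, cost surfaces, sensitivity and network balancing."""

from itertools import combinations_with_replacement

import numpy as np
import pytest

from stoichbal import fixtures
from stoichbal.binding import (
    MOTIF_EDGES,
    CostSurface,
    balance_iin_copies,
    iin_misinteraction_study,
    motif_model,
    motif_surface,
    network_model,
    pc_sensitivity,
)
from stoichbal.gillespie import cost, simulate_to_steady_state
from stoichbal.network import GenConfig, generate_goh_iin
from stoichbal.stats import AbundanceDistribution


# ------------------------------------------------------------- models

def test_triangle_pair_classification():
    m = motif_model("triangle")
    assert len(m.specific) == 3
    # misinteractions: the three self-pairs only
    assert set(m.nonspecific) == {(0, 0), (1, 1), (2, 2)}


@pytest.mark.parametrize("name", sorted(MOTIF_EDGES))
def test_every_pair_classified_once(name):
    m = motif_model(name)
    n = len(m.species)
    allpairs = set(combinations_with_replacement(range(n), 2))
    assert set(m.specific) | set(m.nonspecific) == allpairs
    assert not (set(m.specific) & set(m.nonspecific))


def test_motif_model_validation():
    with pytest.raises(ValueError):
        motif_model("pentagon")
    with pytest.raises(ValueError):
        motif_model("chain", kd_ratio=0.5)


# ------------------------------------------------- balanced IIN copies

def test_equal_complex_mode_proportional_to_degree(triangle_net):
    c = balance_iin_copies(triangle_net, mode="equal-complex", complexes_per_edge=10.0)
    assert all(v == pytest.approx(20.0) for v in c.values())  # degree 2 each


def test_balanced_mode_chain_hand_qp(chain_net):
    c = balance_iin_copies(chain_net, {"A": 50.0, "B": 100.0, "C": 50.0})
    assert c == pytest.approx({"A": 50.0, "B": 100.0, "C": 50.0})


def test_balanced_mode_returns_already_balanced_unchanged(triangle_net):
    c0 = {"A": 60.0, "B": 60.0, "C": 60.0}
    c = balance_iin_copies(triangle_net, c0)
    assert c == pytest.approx(c0)


# ---------------------------------------------------- cost at balance

def test_cost_minimized_at_balance_triangle():
    """Balanced copies beat sampled imbalanced points (3 s.e.)."""
    rng = np.random.default_rng(0)
    bal = motif_model("triangle", copies=50.0)
    res_b = simulate_to_steady_state(bal, n_runs=60, seed=1)
    cb = cost(res_b, "complex")
    for k in range(3):
        copies = {"A": 50.0, "B": float(rng.uniform(90, 150)),
                  "C": float(rng.uniform(5, 25))}
        res_i = simulate_to_steady_state(
            motif_model("triangle", copies=copies), n_runs=60, seed=2 + k
        )
        assert cost(res_i, "complex") > cb


def test_misinteraction_frequency_grows_with_kd_ratio():
    """Cost under balance rises roughly linearly with the K_D ratio."""
    costs = []
    for ratio in (100.0, 1000.0, 10000.0):
        m = motif_model("triangle", kd_spec=1e-9, kd_ratio=ratio, copies=50.0)
        res = simulate_to_steady_state(m, n_runs=40, seed=7)
        costs.append(cost(res, "complex"))
    assert costs[0] > costs[1] > costs[2]
    # decade steps change cost by roughly 10x (linear in 1/ratio)
    assert 3 < costs[0] / costs[1] < 30
    assert 3 < costs[1] / costs[2] < 30


# ----------------------------------------------------------- surfaces

def test_surface_structure_for_triangle():
    grid = np.array([20.0, 50.0, 90.0])
    s = motif_surface("triangle", ("B", "C"), grid, n_runs=30, seed=3)
    # swapping the two variable proteins is a symmetry of the motif
    assert np.allclose(s.cost, s.cost.T, atol=0.01)
    # balanced point is cheap; a singly-overexpressed corner is the most
    # expensive (the excess protein can only self-bind)
    assert s.cost[1, 1] < 0.005
    assert max(s.cost[0, 2], s.cost[2, 0]) > 5 * s.cost[1, 1]


def test_pc_sensitivity_on_synthetic_paraboloid():
    x = np.linspace(0.2, 1.8, 21)
    cost_grid = np.add.outer((x - 1.0) ** 2, (x - 1.0) ** 2) + 0.01
    s = CostSurface("triangle", ("B", "C"), x, x, cost_grid, 50.0)
    dist, pct = pc_sensitivity(s)
    assert pct[0] == 0.0
    assert np.all(np.diff(pct[~np.isnan(pct)]) >= -1e-9)
    # isotropic paraboloid: % change curve is direction independent
    mid = dist[len(dist) // 2]
    expected = 100.0 * (mid**2) / 0.01
    observed = pct[len(dist) // 2]
    assert observed == pytest.approx(expected, rel=0.05)


def test_pc_sensitivity_flat_surface_raises():
    x = np.linspace(0, 1, 5)
    s = CostSurface("hub", ("L1", "L2"), x, x, np.ones((5, 5)), 50.0)
    with pytest.raises(ValueError):
        pc_sensitivity(s)


# ------------------------------------------------------------- IIN study

def test_network_model_requires_single_interface(mixed_net):
    with pytest.raises(ValueError):
        network_model(mixed_net, {p: 10.0 for p in mixed_net.proteins})


def test_stronger_binding_raises_cost_and_sensitivity():
    """Scaling both K_Ds down (stronger binding, same gap) increases both
    the misinteraction cost and the sensitivity to imbalance."""
    net = generate_goh_iin(GenConfig(12, 14, 0.0, seed=3))
    dist = AbundanceDistribution(mode="lognormal", mu=np.log(60.0), sigma=0.8)
    out = iin_misinteraction_study(
        [net], dist, kd_scale_sweep=(0.01, 100.0), n_random=2, n_runs=15, seed=4
    )
    strong = out[0]["by_scale"][0.01]
    weak = out[0]["by_scale"][100.0]
    assert np.mean(strong["random"]) > np.mean(weak["random"])
    assert np.mean(strong["sensitivity"]) > np.mean(weak["sensitivity"])


def test_balanced_cheaper_than_random_on_small_iin():
    net = generate_goh_iin(GenConfig(12, 14, 0.0, seed=3))
    dist = AbundanceDistribution(mode="lognormal", mu=np.log(60.0), sigma=0.8)
    out = iin_misinteraction_study([net], dist, n_random=2, n_runs=25, seed=4)
    rec = out[0]
    assert all(s >= 1.0 for s in rec["sensitivity"])
    assert np.mean(rec["balanced"]) < np.mean(rec["random"])
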
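"""Stoichiometric system construction and the balance quadratic program."""

import itertools

import numpy as np
import pytest
import scipy.optimize

from stoichbal import fixtures
from stoichbal.balance import (
    build_system,
    expression_ratio,
    interface_noise,
    protein_copies,
    solve_balance,
)
from stoichbal.network import GenConfig, InterfaceNetwork, generate_goh_iin


def _random_system(seed, alpha=1.0):
    rng = np.random.default_rng(seed)
    net = generate_goh_iin(GenConfig(6, int(rng.integers(2, 4)), 0.0, seed))
    c0 = {p: float(rng.uniform(0, 200)) for p in net.proteins}
    return build_system(net, c0, alpha=alpha)


# ---------------------------------------------------------- construction

def test_a_matrix_column_sums_are_two(mixed_net):
    sys_ = build_system(mixed_net, fixtures.mixed_copies())
    assert np.all(sys_.A.sum(axis=0) == 2)


def test_self_edge_gives_entry_two():
    net = InterfaceNetwork(["A"], [("A", "i1")], [(("A", "i1"), ("A", "i1"))])
    sys_ = build_system(net, {"A": 10.0})
    assert sys_.A.shape == (1, 1)
    assert sys_.A[0, 0] == 2.0


def test_h_kernel_is_equal_per_protein(mixed_net):
    sys_ = build_system(mixed_net, fixtures.mixed_copies())
    # equal values per protein -> H v = 0
    v = np.zeros(mixed_net.n_interfaces)
    vals = {"A": 3.0, "B": 7.0, "C": 1.0, "D": 5.0}
    for (p, _i), k in sys_.interface_index.items():
        v[k] = vals[p]
    assert np.allclose(sys_.H @ v, 0.0)
    # unequal values on the two D interfaces -> nonzero
    k1 = sys_.interface_index[("D", "i1")]
    v[k1] += 1.0
    assert not np.allclose(sys_.H @ v, 0.0)
    # H PSD
    assert np.linalg.eigvalsh(sys_.H).min() >= -1e-12


def test_constrained_protein_missing_from_c0_raises(chain_net):
    with pytest.raises(KeyError):
        build_system(chain_net, {"A": 1.0}, constrained={"A", "B"})


@pytest.mark.parametrize("seed", range(8))
def test_q_is_symmetric_psd(seed):
    sys_ = _random_system(seed)
    Q = sys_.Q
    assert np.allclose(Q, Q.T)
    assert np.linalg.eigvalsh(Q).min() >= -1e-9 * max(1.0, abs(Q).max())


# ------------------------------------------------------------- solving

@pytest.mark.parametrize("alpha", [0.01, 0.5, 1.0, 2.0, 10.0])
def test_balanced_input_recovered_for_any_alpha(chain_net, alpha):
    c0 = fixtures.chain_copies_balanced()
    res = solve_balance(build_system(chain_net, c0, alpha=alpha))
    assert protein_copies(res) == pytest.approx(c0, abs=1e-6)
    assert res.x_min == pytest.approx([50.0, 50.0], abs=1e-6)


def test_zero_input_gives_zero_solution(chain_net):
    res = solve_balance(build_system(chain_net, {p: 0.0 for p in "ABC"}))
    assert np.allclose(res.x_min, 0.0)
    assert res.objective == pytest.approx(0.0, abs=1e-12)


def test_forward_consistency(mixed_net):
    res = solve_balance(build_system(mixed_net, fixtures.mixed_copies()))
    assert np.array_equal(res.c_balanced_int, res.system.A @ res.x_min)
    assert np.all(res.x_min >= 0)


def _grid_oracle(sys_, lo=0.0, hi=300.0, n=31):
    """Brute-force oracle: dense grid refined by a bounded local polish."""
    m = sys_.A.shape[1]
    best, best_x = np.inf, None
    axes = [np.linspace(lo, hi, n)] * m
    for x in itertools.product(*axes):
        v = sys_.objective(np.asarray(x))
        if v < best:
            best, best_x = v, np.asarray(x)
    r = scipy.optimize.minimize(
        sys_.objective, best_x, bounds=[(0, None)] * m, method="L-BFGS-B",
        options={"ftol": 1e-14, "gtol": 1e-12},
    )
    return min(best, float(r.fun))


@pytest.mark.parametrize("seed", range(6))
def test_qp_matches_brute_force_oracle(seed):
    sys_ = _random_system(seed)
    assert sys_.A.shape[1] <= 3
    res = solve_balance(sys_)
    oracle = _grid_oracle(sys_)
    scale = max(abs(oracle), 1.0)
    assert res.objective <= oracle + 1e-4 * scale
    assert abs(res.objective - oracle) <= 1e-4 * scale


def test_z_weighted_distance_nonincreasing_in_alpha(mixed_net):
    c0 = fixtures.mixed_copies()
    prev = None
    for alpha in [0.01, 0.1, 1.0, 10.0]:
        sys_ = build_system(mixed_net, c0, alpha=alpha)
        res = solve_balance(sys_)
        r = sys_.A @ res.x_min - sys_.C0
        dist = float(r @ (sys_.Z @ r))
        if prev is not None:
            assert dist <= prev + 1e-9
        prev = dist


def test_perfect_matching_uniform_c0_balances_equal():
    # obligate-complex style wiring: disjoint pairs, uniform copies
    proteins = [f"P{i}" for i in range(6)]
    interfaces = [(p, "i") for p in proteins]
    edges = [((proteins[i], "i"), (proteins[i + 1], "i")) for i in range(0, 6, 2)]
    net = InterfaceNetwork(proteins, interfaces, edges)
    res = solve_balance(build_system(net, {p: 80.0 for p in proteins}))
    vals = list(protein_copies(res).values())
    assert np.allclose(vals, vals[0])
    assert vals[0] == pytest.approx(80.0, rel=1e-9)


# ------------------------------------------------- derived quantities

def test_protein_copies_average_interfaces():
    net = InterfaceNetwork(
        ["P", "Q", "R"],
        [("P", "a"), ("P", "b"), ("Q", "i"), ("R", "i")],
        [(("P", "a"), ("Q", "i")), (("P", "b"), ("R", "i"))],
    )
    sys_ = build_system(net, {"P": 250.0, "Q": 200.0, "R": 300.0}, alpha=100.0)
    res = solve_balance(sys_)
    cp = protein_copies(res)
    k_a = sys_.interface_index[("P", "a")]
    k_b = sys_.interface_index[("P", "b")]
    expected = (res.c_balanced_int[k_a] + res.c_balanced_int[k_b]) / 2
    assert cp["P"] == pytest.approx(expected)


def test_interface_noise_hand_value():
    # interfaces at 200 and 300 copies: var=2500, mean=250 -> 0.04
    net = InterfaceNetwork(
        ["P", "Q", "R"],
        [("P", "a"), ("P", "b"), ("Q", "i"), ("R", "i")],
        [(("P", "a"), ("Q", "i")), (("P", "b"), ("R", "i"))],
    )
    # only the partners are constrained; high alpha pins P's interfaces
    # to the partner demands 200 and 300
    sys_ = build_system(
        net, {"Q": 200.0, "R": 300.0}, constrained={"Q", "R"}, alpha=1e6
    )
    res = solve_balance(sys_)
    k_a = sys_.interface_index[("P", "a")]
    k_b = sys_.interface_index[("P", "b")]
    # at very high alpha the fit term dominates: interfaces follow partners
    assert res.c_balanced_int[k_a] == pytest.approx(200.0, rel=1e-3)
    assert res.c_balanced_int[k_b] == pytest.approx(300.0, rel=1e-3)
    noise = interface_noise(res)
    assert noise["P"] == pytest.approx(0.04, rel=1e-3)
    assert noise["Q"] == 0.0  # single interface


def test_mean_noise_nondecreasing_in_alpha():
    net = fixtures.mixed_network()
    c0 = fixtures.mixed_copies()
    prev = None
    for alpha in [0.01, 0.1, 1.0, 10.0, 100.0]:
        res = solve_balance(build_system(net, c0, alpha=alpha))
        mean_noise = np.mean(list(interface_noise(res).values()))
        if prev is not None:
            assert mean_noise >= prev - 1e-12
        prev = mean_noise


def test_expression_ratio():
    cb = {"X": 10.0, "Y": 5.0, "Z": 0.0}
    cr = {"X": 400.0, "Y": 5.0, "Z": 0.0}
    r = expression_ratio(cr, cb)
    assert r["X"] == pytest.approx(40.0)
    assert r["Y"] == pytest.approx(1.0)
    assert r["Z"] == 1.0
    doubled = expression_ratio({k: 2 * v for k, v in cr.items()}, cb)
    assert doubled["X"] == pytest.approx(80.0)
    cb2 = dict(cb, Z=0.0)
    r2 = expression_ratio(dict(cr, Z=3.0), cb2)
    assert np.isnan(r2["Z"])
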
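"""Exact stochastic simulation of competitive binary binding.

Species bind pairwise and reversibly, A_i + A_j <-> C_ij, with every
unordered species pair (including self-pairs) classified as *specific*
(a functional interaction, strong K_D), *nonspecific* (a misinteraction,
weak K_D) or absent.  Binding is competitive: each molecule has a single
interface, so it is either free or in exactly one binary complex.

Dissociation constants are given in molar units and converted to copy
units through a configurable effective volume (default: 50 copies = 1 uM).
koff is fixed (default 1/s) and kon = koff / K_D, so K_D alone sets the
equilibrium while koff sets the relaxation timescale.

The simulator is the direct Gillespie method with time-window averaging:
the system is declared at steady state when consecutive windows of
10x the slowest relaxation time change the windowed mean occupancy by
less than 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AVOGADRO", "DEFAULT_VOLUME_L", "BindingModel", "CostResult",
           "simulate_to_steady_state", "cost"]

AVOGADRO = 6.02214076e23
# effective volume such that 50 copies correspond to 1 uM
DEFAULT_VOLUME_L = 50.0 / (1e-6 * AVOGADRO)


@dataclass
class BindingModel:
    """A competitive binary binding model.

    specific / nonspecific map unordered species-index pairs (i <= j) to
    K_D in molar.  A pair may appear in at most one of the two maps.
    """

    species: list[str]
    copies: np.ndarray
    specific: dict[tuple[int, int], float]
    nonspecific: dict[tuple[int, int], float] = field(default_factory=dict)
    koff: float = 1.0
    volume_L: float = DEFAULT_VOLUME_L

    def __post_init__(self) -> None:
        # the simulator works in whole molecules; fractional copy numbers
        # (e.g. from a balanced projection) are rounded
        self.copies = np.round(np.asarray(self.copies, dtype=float))
        if (self.copies < 0).any():
            raise ValueError("copies must be nonnegative")
        if len(self.copies) != len(self.species):
            raise ValueError("copies must match species")
        overlap = set(self.specific) & set(self.nonspecific)
        if overlap:
            raise ValueError(f"pairs classified twice: {sorted(overlap)}")
        for (i, j), kd in list(self.specific.items()) + list(self.nonspecific.items()):
            if i > j:
                raise ValueError("pair keys must be ordered (i <= j)")
            if kd <= 0:
                raise ValueError("all K_D must be positive")

    def kd_copies(self, kd_molar: float) -> float:
        return kd_molar * AVOGADRO * self.volume_L

    def pair_table(self):
        """Arrays (pi, pj, kon, koff, is_specific) over all allowed pairs."""
        pairs = sorted(self.specific) + sorted(self.nonspecific)
        spec_flags = [True] * len(self.specific) + [False] * len(self.nonspecific)
        pi = np.array([p[0] for p in pairs], dtype=np.int64)
        pj = np.array([p[1] for p in pairs], dtype=np.int64)
        kd = np.array(
            [self.specific[p] for p in sorted(self.specific)]
            + [self.nonspecific[p] for p in sorted(self.nonspecific)]
        )
        kon = self.koff / (kd * AVOGADRO * self.volume_L)
        return pi, pj, kon, np.full(len(pairs), self.koff), np.array(spec_flags), pairs


@dataclass
class CostResult:
    """Steady-state occupancy summary averaged over replicate runs."""

    model: BindingModel
    n_specific: float
    n_nonspecific: float
    n_free: float
    pair_means: dict[tuple[int, int], float]
    pair_sems: dict[tuple[int, int], float]
    n_runs: int
    seed: int
    converged: bool = True

    @property
    def cost_complex(self) -> float:
        return cost(self, mode="complex")

    @property
    def cost_protein(self) -> float:
        return cost(self, mode="protein")


def _run_one(
    copies, pi, pj, kon, koff, rng, window_mult=10.0, drift_tol=0.01, max_windows=60
):
    """One SSA trajectory; returns time-averaged (free, cplx) over the final
    window and a convergence flag."""
    n_sp = len(copies)
    n_pair = len(pi)
    f = copies.astype(float).copy()
    c = np.zeros(n_pair)
    selfp = pi == pj

    t_window = window_mult / koff.min()
    prev_stat = None
    converged = False
    # drift floor: windowed means of a weakly-bound system fluctuate on the
    # sqrt(copies) scale, so the absolute tolerance must not be tighter
    stat_floor = max(np.sqrt(copies.sum()), 1.0)

    for _w in range(max_windows):
        # time-weighted accumulators for this window
        acc_f = np.zeros(n_sp)
        acc_c = np.zeros(n_pair)
        t = 0.0
        while t < t_window:
            npairs = np.maximum(
                np.where(selfp, f[pi] * (f[pi] - 1.0) * 0.5, f[pi] * f[pj]), 0.0
            )
            a_bind = kon * npairs
            a_un = koff * c
            a = np.concatenate([a_bind, a_un])
            total = a.sum()
            if total <= 0.0:
                acc_f += f * (t_window - t)
                acc_c += c * (t_window - t)
                t = t_window
                break
            dt = rng.exponential(1.0 / total)
            dt_eff = min(dt, t_window - t)
            acc_f += f * dt_eff
            acc_c += c * dt_eff
            t += dt
            if t >= t_window:
                break
            k = int(np.searchsorted(np.cumsum(a), rng.random() * total))
            k = min(k, 2 * n_pair - 1)
            if k < n_pair:
                f[pi[k]] -= 1.0
                f[pj[k]] -= 1.0
                c[k] += 1.0
            else:
                k -= n_pair
                f[pi[k]] += 1.0
                f[pj[k]] += 1.0
                c[k] -= 1.0
        mean_f = acc_f / t_window
        mean_c = acc_c / t_window
        stat = mean_c.sum()
        if prev_stat is not None:
            if abs(stat - prev_stat) <= drift_tol * max(prev_stat, stat_floor):
                converged = True
                break
        prev_stat = stat
    return mean_f, mean_c, converged


def simulate_to_steady_state(
    model: BindingModel,
    n_runs: int = 1000,
    seed: int = 0,
    window_mult: float = 10.0,
    drift_tol: float = 0.01,
    max_windows: int = 60,
) -> CostResult:
    """Simulate the model to steady state, averaged over replicate runs.

    Each run uses an independent stream spawned from the master seed.
    Occupancies are time averages over the final steady window.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    pi, pj, kon, koff, spec, pairs = model.pair_table()
    sum_f = np.zeros(len(model.species))
    sum_c = np.zeros(len(pairs))
    sum_c2 = np.zeros(len(pairs))
    all_conv = True
    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=n_runs)
    for r in range(n_runs):
        rng = np.random.default_rng(int(run_seeds[r]))
        mf, mc, conv = _run_one(
            model.copies, pi, pj, kon, koff, rng, window_mult, drift_tol, max_windows
        )
        sum_f += mf
        sum_c += mc
        sum_c2 += mc**2
        all_conv = all_conv and conv
    mean_f = sum_f / n_runs
    mean_c = sum_c / n_runs
    var_c = np.maximum(sum_c2 / n_runs - mean_c**2, 0.0)
    sem_c = np.sqrt(var_c / n_runs)
    return CostResult(
        model=model,
        n_specific=float(mean_c[spec].sum()),
        n_nonspecific=float(mean_c[~spec].sum()),
        n_free=float(mean_f.sum()),
        pair_means={p: float(mean_c[k]) for k, p in enumerate(pairs)},
        pair_sems={p: float(sem_c[k]) for k, p in enumerate(pairs)},
        n_runs=n_runs,
        seed=seed,
        converged=all_conv,
    )


def final_state_samples(
    model: BindingModel, t_sample: float, n_samples: int, seed: int = 0
) -> np.ndarray:
    """Complex-count snapshots from independent runs at a fixed time.

    Returns an (n_samples, n_pairs) array of complex counts, one row per
    independent trajectory sampled at ``t_sample`` (which should exceed the
    relaxation time ~1/koff).  Used to compare the stationary distribution
    against exact birth-death solutions.
    """
    pi, pj, kon, koff, _spec, pairs = model.pair_table()
    selfp = pi == pj
    master = np.random.default_rng(seed)
    out = np.empty((n_samples, len(pairs)))
    for r in range(n_samples):
        rng = np.random.default_rng(int(master.integers(2**31 - 1)))
        f = model.copies.astype(float).copy()
        c = np.zeros(len(pairs))
        t = 0.0
        while True:
            npairs = np.where(selfp, f[pi] * (f[pi] - 1.0) * 0.5, f[pi] * f[pj])
            a = np.concatenate([kon * npairs, koff * c])
            total = a.sum()
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= t_sample:
                break
            k = int(np.searchsorted(np.cumsum(a), rng.random() * total))
            k = min(k, 2 * len(pairs) - 1)
            if k < len(pairs):
                f[pi[k]] -= 1.0
                f[pj[k]] -= 1.0
                c[k] += 1.0
            else:
                k -= len(pairs)
                f[pi[k]] += 1.0
                f[pj[k]] += 1.0
                c[k] -= 1.0
        out[r] = c
    return out


def cost(counts: CostResult, mode: str = "complex") -> float:
    """Misinteraction cost of a steady state.

    mode='complex' counts binary complexes:      N_ns / (N_s + N_free).
    mode='protein' counts individual proteins: 2*N_ns / (2*N_s + N_free).
    A 0/0 ratio is defined as 0.
    """
    ns, s, free = counts.n_nonspecific, counts.n_specific, counts.n_free
    if mode == "complex":
        num, den = ns, s + free
    elif mode == "protein":
        num, den = 2.0 * ns, 2.0 * s + free
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return num / den
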
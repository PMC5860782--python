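"""Distance metrics and empirical significance of stoichiometric balance.

How balanced is an observed copy-number vector?  The balance optimizer
returns the nearest balanced vector; the residual distance between the two
is the balance score.  Its significance is assessed empirically: draw many
random copy-number vectors from a genome-wide abundance distribution, run
each through the same optimization, and ask how often a random vector lands
at least as close to its balanced solution as the observed one did.

Two distances are used.  Chi-square distance (CSD),

    sum_i (X_i - Y_i)^2 / (X_i + Y_i),

compares absolute copies and is dominated by large deviations.  The
Jensen-Shannon divergence (JSD) first normalizes both vectors to
distributions and is bounded by ln 2 (natural-log convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr

from . import balance as bal
from .network import InterfaceNetwork

__all__ = [
    "AbundanceDistribution",
    "SignificanceReport",
    "chi_square_distance",
    "jensen_shannon_distance",
    "sample_copynumbers",
    "balance_significance",
]


def chi_square_distance(X, Y) -> float:
    """Chi-square distance between two nonnegative vectors.

    Terms where X_i + Y_i == 0 contribute zero.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("length mismatch")
    if (X < 0).any() or (Y < 0).any():
        raise ValueError("inputs must be nonnegative")
    s = X + Y
    d = np.zeros_like(s)
    nz = s > 0
    d[nz] = (X[nz] - Y[nz]) ** 2 / s[nz]
    return float(d.sum())


def jensen_shannon_distance(X, Y) -> float:
    """Jensen-Shannon divergence (nats) after normalizing both vectors.

    0.5*(KL(x||z) + KL(y||z)) with z = (x+y)/2; bounded by ln 2.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("length mismatch")
    sx, sy = X.sum(), Y.sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("vectors must have positive sums")
    x = X / sx
    y = Y / sy
    z = 0.5 * (x + y)
    # guard subnormal underflow: z can round to 0 where x+y is denormal,
    # and such terms contribute 0 in the limit
    nz = z > 0
    return float(0.5 * (rel_entr(x[nz], z[nz]).sum() + rel_entr(y[nz], z[nz]).sum()))


@dataclass
class AbundanceDistribution:
    """A genome-wide protein abundance distribution to sample copies from.

    Three modes:
      * empirical: resample with replacement from a pool of observed copies
        (e.g. a whole-proteome abundance list);
      * lognormal: parametric log-normal with mu/sigma of log-copies;
      * permutation: shuffle a provided vector (preserves the multiset).
    """

    mode: str = "lognormal"
    pool: list[float] | None = None
    mu: float = np.log(1000.0)
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.mode not in ("empirical", "lognormal", "permutation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("empirical", "permutation"):
            if self.pool is None or len(self.pool) < 2:
                raise ValueError("empirical/permutation mode needs a pool of >= 2 values")
        if self.mode == "lognormal" and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "empirical":
            pool = np.asarray(self.pool, dtype=float)
            return rng.choice(pool, size=n, replace=True)
        if self.mode == "permutation":
            pool = np.asarray(self.pool, dtype=float)
            if len(pool) != n:
                raise ValueError("permutation mode requires a pool of length n")
            return rng.permutation(pool)
        return np.exp(rng.normal(self.mu, self.sigma, size=n))


def sample_copynumbers(
    dist: AbundanceDistribution,
    proteins: list[str],
    n_rand: int,
    seed: int = 0,
) -> list[dict[str, float]]:
    """Draw ``n_rand`` i.i.d. copy-number vectors over ``proteins``."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_rand):
        vals = dist.draw(len(proteins), rng)
        out.append({p: float(v) for p, v in zip(proteins, vals)})
    return out


@dataclass
class SignificanceReport:
    """Observed distances plus their null distributions and p-values."""

    csd_real: float
    jsd_real: float
    csd_null: np.ndarray
    jsd_null: np.ndarray
    p_csd: float
    p_jsd: float
    n_rand: int
    n_failures: int = 0
    alpha: float = 1.0

    def to_dict(self) -> dict:
        return {
            "csd_real": self.csd_real,
            "jsd_real": self.jsd_real,
            "p_csd": self.p_csd,
            "p_jsd": self.p_jsd,
            "n_rand": self.n_rand,
            "n_failures": self.n_failures,
            "alpha": self.alpha,
        }


def _balanced_distances(
    net: InterfaceNetwork, C0: dict[str, float], alpha: float
) -> tuple[float, float]:
    system = bal.build_system(net, C0, alpha=alpha)
    res = bal.solve_balance(system)
    cbal = bal.protein_copies(res)
    order = sorted(C0)
    x = np.array([C0[p] for p in order])
    y = np.array([cbal[p] for p in order])
    if y.sum() <= 0:
        # trivial all-zero balanced solution: CSD degenerates to sum(x) and
        # the JSD is taken at its upper bound ln 2 (disjoint support limit)
        return chi_square_distance(x, np.zeros_like(x)), float(np.log(2.0))
    return chi_square_distance(x, y), jensen_shannon_distance(x, y)


def balance_significance(
    net: InterfaceNetwork,
    C_real: dict[str, float],
    dist: AbundanceDistribution,
    alpha: float = 1.0,
    n_rand: int = 5000,
    seed: int = 0,
) -> SignificanceReport:
    """Empirical one-sided significance of balance in observed copies.

    For C_real and each of ``n_rand`` random C0 vectors the balance program
    is solved and the CSD/JSD between input and balanced protein copies
    recorded.  Small distance means balanced, so

        p = (1 + #{null <= real}) / (n_rand + 1).

    The +1 convention keeps p-values in (0, 1] and super-uniform under the
    null at finite n_rand.
    """
    csd_real, jsd_real = _balanced_distances(net, C_real, alpha)
    proteins = sorted(C_real)
    draws = sample_copynumbers(dist, proteins, n_rand, seed=seed)
    csd_null = np.empty(n_rand)
    jsd_null = np.empty(n_rand)
    failures = 0
    for k, c0 in enumerate(draws):
        try:
            csd_null[k], jsd_null[k] = _balanced_distances(net, c0, alpha)
        except Exception:
            failures += 1
            csd_null[k] = np.nan
            jsd_null[k] = np.nan
    ok = ~np.isnan(csd_null)
    n_ok = int(ok.sum())
    p_csd = (1 + int((csd_null[ok] <= csd_real).sum())) / (n_ok + 1)
    p_jsd = (1 + int((jsd_null[ok] <= jsd_real).sum())) / (n_ok + 1)
    return SignificanceReport(
        csd_real, jsd_real, csd_null[ok], jsd_null[ok], p_csd, p_jsd, n_ok, failures, alpha
    )
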
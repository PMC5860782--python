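"""Stoichiometric balance optimization for interface-resolved networks.

A network is stoichiometrically balanced when the copy number of every
binding interface exactly matches the total number of pairwise complexes
it participates in.  Writing A for the interface-by-edge incidence matrix
(entry 1 when an interface is used by an edge, 2 for a self-interaction)
and x for the vector of desired pairwise complex counts, balanced interface
copies satisfy C = A x with x >= 0.

Given observed copies C0 the closest balanced solution minimizes

    alpha * (A x - C0)^T Z (A x - C0)  +  (A x)^T H (A x),   x >= 0

where Z is a diagonal selector of constrained interfaces and H is a
positive-semidefinite matrix whose kernel is exactly the vectors assigning
equal copies to all interfaces of each protein (realized here as the
per-protein complete-graph Laplacian).  alpha trades fidelity to C0
against equal interface copies within a protein.  The problem is a convex
quadratic program; it is solved exactly as a nonnegative least-squares
problem (see `solve_balance`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .network import InterfaceNetwork, Interface

__all__ = [
    "StoichSystem",
    "BalanceResult",
    "build_system",
    "solve_balance",
    "protein_copies",
    "interface_noise",
    "expression_ratio",
]

CopyVector = dict[str, float]


@dataclass
class StoichSystem:
    """The assembled (A, H, Z, C0, alpha) system for one network."""

    net: InterfaceNetwork
    A: np.ndarray            # n_int x n_edge incidence, column sums == 2
    H: np.ndarray            # per-protein complete-graph Laplacian blocks
    Z: np.ndarray            # 0/1 diagonal selector of constrained interfaces
    C0: np.ndarray           # per-interface constrained copies (0 where unconstrained)
    alpha: float
    interface_index: dict[Interface, int] = field(default_factory=dict)

    @property
    def Q(self) -> np.ndarray:
        """Hessian of the quadratic form: 2*alpha*A^T Z A + 2*A^T H A."""
        return 2.0 * self.alpha * self.A.T @ (self.Z @ self.A) + 2.0 * self.A.T @ (self.H @ self.A)

    @property
    def d(self) -> np.ndarray:
        """Linear term: -2*alpha*A^T Z C0."""
        return -2.0 * self.alpha * self.A.T @ (self.Z @ self.C0)

    def objective(self, x: np.ndarray) -> float:
        r = self.A @ x - self.C0
        ax = self.A @ x
        return float(self.alpha * r @ (self.Z @ r) + ax @ (self.H @ ax))


@dataclass
class BalanceResult:
    """Solution of the balance program."""

    system: StoichSystem
    x_min: np.ndarray                    # optimal pairwise complex counts
    c_balanced_int: np.ndarray           # A @ x_min, per interface
    objective: float
    degenerate: bool                     # Q has a (near) nontrivial null space

    def interface_copies(self) -> dict[Interface, float]:
        return {
            iface: float(self.c_balanced_int[k])
            for iface, k in self.system.interface_index.items()
        }


def build_system(
    net: InterfaceNetwork,
    C0: CopyVector,
    constrained: set[str] | None = None,
    alpha: float = 1.0,
) -> StoichSystem:
    """Assemble A, H, Z and the per-interface C0 for a network.

    `C0` maps protein ids to observed copies; values are replicated to each
    interface of the protein.  `constrained` selects which proteins enter
    the Z-weighted distance term (default: all proteins present in C0).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if constrained is None:
        constrained = set(C0)
    missing = constrained - set(C0)
    if missing:
        raise KeyError(f"constrained proteins missing from C0: {sorted(missing)}")

    idx = {iface: k for k, iface in enumerate(net.interfaces)}
    n_int, m_edge = len(net.interfaces), len(net.edges)

    A = np.zeros((n_int, m_edge))
    for j, (a, b) in enumerate(net.edges):
        if a == b:
            A[idx[a], j] = 2.0
        else:
            A[idx[a], j] = 1.0
            A[idx[b], j] = 1.0

    H = np.zeros((n_int, n_int))
    for p in net.proteins:
        rows = [idx[i] for i in net.interfaces_of(p)]
        k = len(rows)
        if k < 2:
            continue
        for r in rows:
            H[r, r] += k - 1
        for a_ in rows:
            for b_ in rows:
                if a_ != b_:
                    H[a_, b_] -= 1.0

    z = np.zeros(n_int)
    c0 = np.zeros(n_int)
    for (p, i), k in idx.items():
        if p in constrained:
            z[k] = 1.0
            c0[k] = float(C0[p])
            if c0[k] < 0:
                raise ValueError(f"negative copy number for protein {p!r}")
    return StoichSystem(net, A, H, np.diag(z), c0, float(alpha), idx)


def _h_factor(system: StoichSystem) -> np.ndarray:
    """A matrix W with W^T W == H: signed incidence rows of the per-protein
    complete graphs (one row e_i - e_j per intra-protein interface pair)."""
    idx = system.interface_index
    rows = []
    n_int = len(system.net.interfaces)
    for p in system.net.proteins:
        members = [idx[i] for i in system.net.interfaces_of(p)]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                r = np.zeros(n_int)
                r[members[a]] = 1.0
                r[members[b]] = -1.0
                rows.append(r)
    if not rows:
        return np.zeros((0, n_int))
    return np.vstack(rows)


def solve_balance(system: StoichSystem, degeneracy_tol: float = 1e-9) -> BalanceResult:
    """Solve the balance quadratic program exactly.

    The objective is a sum of two squared seminorms of the residual, so the
    QP is equivalent to nonnegative least squares on the stacked system

        B = [ sqrt(alpha) * Z^(1/2) A ]      b = [ sqrt(alpha) * Z^(1/2) C0 ]
            [        W A            ]            [           0            ]

    with W^T W = H.  Lawson-Hanson NNLS gives the deterministic global
    minimizer (the problem is convex).  Degeneracy (a nontrivial null space
    of the Hessian Q) is detected and flagged.
    """
    sa = np.sqrt(system.alpha)
    zhalf = np.sqrt(np.diag(system.Z))
    B_top = sa * (zhalf[:, None] * system.A)
    b_top = sa * (zhalf * system.C0)
    W = _h_factor(system)
    B = np.vstack([B_top, W @ system.A]) if W.size else B_top
    b = np.concatenate([b_top, np.zeros(W.shape[0])]) if W.size else b_top

    x, _res = scipy.optimize.nnls(B, b)
    obj = system.objective(x)

    Q = system.Q
    eigs = np.linalg.eigvalsh(Q)
    scale = max(eigs[-1], 1.0)
    degenerate = bool(eigs[0] < degeneracy_tol * scale)

    return BalanceResult(system, x, system.A @ x, obj, degenerate)


def protein_copies(res: BalanceResult) -> CopyVector:
    """Per-protein balanced copies: arithmetic mean over the protein's interfaces."""
    by_protein: dict[str, list[float]] = {}
    for (p, _i), k in res.system.interface_index.items():
        by_protein.setdefault(p, []).append(float(res.c_balanced_int[k]))
    return {p: float(np.mean(v)) for p, v in by_protein.items()}


def interface_noise(res: BalanceResult) -> dict[str, float]:
    """Per-protein interface-copy noise: population variance over squared mean.

    Single-interface proteins report 0.  A protein whose interfaces average
    to zero but still vary reports infinite noise.
    """
    out: dict[str, float] = {}
    by_protein: dict[str, list[float]] = {}
    for (p, _i), k in res.system.interface_index.items():
        by_protein.setdefault(p, []).append(float(res.c_balanced_int[k]))
    for p, vals in by_protein.items():
        if len(vals) < 2:
            out[p] = 0.0
            continue
        mu = float(np.mean(vals))
        var = float(np.var(vals))  # population variance
        if mu == 0.0:
            out[p] = 0.0 if var == 0.0 else float("inf")
        else:
            out[p] = var / mu**2
    return out


def expression_ratio(C_real: CopyVector, C_balanced: CopyVector) -> dict[str, float]:
    """Per-protein ratio C_real / C_balanced.

    Ratios above 1 flag overexpression relative to balanced demand, below 1
    underexpression.  Proteins with zero balanced copies map to NaN
    (undefined) unless the real copies are also zero, in which case 1.
    """
    if set(C_real) != set(C_balanced):
        raise KeyError("C_real and C_balanced must cover the same proteins")
    out: dict[str, float] = {}
    for p in C_real:
        cb = C_balanced[p]
        cr = C_real[p]
        if cb == 0.0:
            out[p] = 1.0 if cr == 0.0 else float("nan")
        else:
            out[p] = cr / cb
    return out
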
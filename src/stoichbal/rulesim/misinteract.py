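"""Generated misinteraction rules for rule-based models.

Misinteractions are weak, non-evolved bindings between site pairs that
lack a specific rule.  Their strength follows the geometric-mean
convention: each site's mean K_D is the geometric mean of its specific
K_Ds (the arithmetic mean of its binding energies), and a misinteraction
between two sites gets

    K_D,mis = f * sqrt(K_D,mean,1 * K_D,mean,2)

with f = 10^4 (weak, energy gap ln(1e4) ~ 9.21 kBT) or 10^3 (stronger,
gap ~ 6.91 kBT).
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from math import sqrt

import numpy as np

from .engine import BindRule, MoleculeType

__all__ = ["site_mean_kds", "misinteraction_rules"]


def site_mean_kds(rules: list[BindRule]) -> dict[tuple[str, str], float]:
    """Geometric mean of each site class's specific K_Ds."""
    kds: dict[tuple[str, str], list[float]] = {}
    for r in rules:
        if not r.specific:
            continue
        kds.setdefault(r.a, []).append(r.kd_molar)
        kds.setdefault(r.b, []).append(r.kd_molar)
    return {s: float(np.exp(np.mean(np.log(v)))) for s, v in kds.items()}


def misinteraction_rules(
    types: list[MoleculeType],
    rules: list[BindRule],
    f: float,
    koff: float = 1.0,
    exclude_types: tuple[str, ...] = (),
) -> list[BindRule]:
    """One nonspecific rule for every site pair lacking a specific rule.

    ``exclude_types`` keeps listed molecule types (the membrane lipid) out
    of the generated pairs.  Sites without any specific K_D inherit the
    global geometric mean.
    """
    if f <= 0:
        raise ValueError("misinteraction factor must be positive")
    means = site_mean_kds(rules)
    if not means:
        raise ValueError("no specific rules to derive mean K_Ds from")
    global_mean = float(np.exp(np.mean(np.log(list(means.values())))))
    ruled = set()
    for r in rules:
        ruled.add(tuple(sorted((r.a, r.b))))
    sites = list(dict.fromkeys(
        (t.name, s)
        for t in types
        if t.name not in exclude_types
        for s in t.sites
    ))
    out = []
    for a, b in combinations_with_replacement(sorted(sites), 2):
        if tuple(sorted((a, b))) in ruled:
            continue
        kd = f * sqrt(means.get(a, global_mean) * means.get(b, global_mean))
        out.append(BindRule(a, b, kd, koff=koff, specific=False))
    return out
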
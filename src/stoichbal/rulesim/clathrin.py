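"""Clathrin-coat vesicle-forming module: nine proteins plus membrane lipid.

A minimal kinetic model of clathrin recruitment to the membrane in yeast
endocytosis.  Clathrin heavy chains are modeled pre-assembled as triskelia
(three leg sites for polymerization, three light-chain sites, three
adaptor sites); adaptor and scaffold proteins (ENT1/2 merged, SLA2, SYP1,
EDE1, YAP1801, YAP1802) link triskelia to PI(4,5)P2 lipids on the plasma
membrane.  All dissociation constants, copy numbers and compartment
geometry are literature values; koff is 1/s throughout so K_D alone sets
each equilibrium.

Binding on the membrane is enhanced by Vol/(SA*2sigma) (~246x for the
default geometry), the driver of cage formation: cytosolic clathrin
polymerization (K_D 100 uM) is negligible, membrane polymerization is
strong.  Any membrane complex holding >= 100 full triskelia is a vesicle:
it is deleted at k_dump and its members recycled one at a time at k_recyc.

Optional generated misinteractions follow the geometric-mean rule at
K_D ratios f = 1e4 (weak) or 1e3 (strong).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import (
    BindRule,
    MoleculeType,
    SimResult,
    VesicleConfig,
    World,
    membrane_enhancement,
)
from .misinteract import misinteraction_rules

__all__ = [
    "CME_PARAMS",
    "ADAPTOR_TYPES",
    "cme_model",
    "cme_params_table",
    "VesicleStats",
    "vesicle_stats",
    "membrane_area_per_adaptor_nm2",
]

UM = 1e-6
NM = 1e-9

# parameter table: geometry, affinities (molar), copies
CME_PARAMS: dict[str, float] = {
    "Vol_CP_um3": 37.2,       # cytosol volume
    "SA_PM_um2": 75.7,        # plasma membrane surface area
    "sigma_nm": 1.0,          # 3D->2D conversion lengthscale
    "Kd_CHC_CHC": 100 * UM,   # heavy-chain (triskelion leg) polymerization
    "Kd_CHC_ENT": 22 * UM,
    "Kd_CHC_YAP": 160 * UM,
    "Kd_EDE_ENT": 12 * UM,
    "Kd_EDE_YAP": 0.6 * UM,
    "Kd_EDE_EDE": 0.127 * UM,
    "Kd_CHC_CLC": 0.1 * NM,
    "Kd_CLC_SLA": 22 * UM,
    "Kd_SLA_SLA": 1 * NM,
    "Kd_SYP_SYP": 2.5 * UM,
    "Kd_SYP_EDE": 0.227 * UM,
    "Kd_L_ENT": 0.02 * UM,
    "Kd_L_YAP": 0.3 * UM,     # YAP1801 lipid binding
    "Kd_L_SLA": 0.2 * UM,
    "Kd_L_SYP": 53 * UM,
    "k_off": 1.0,
    "L_density_per_um2": 25292.0,
    "CHC1_0": 6426,           # heavy-chain trimers
    "CLC1_0": 14538,
    "EDE1_0": 5964,
    "ENT_0": 3075,            # ENT1/2 merged
    "YAP1801_0": 357,
    "YAP1802_0": 264,
    "SLA2_0": 3904,
    "SYP1_0": 2467,
    "T_vesicle": 100,
    "k_dump": 1000.0,
    "k_recyc": 1000.0,
}

ADAPTOR_TYPES = ("ENT", "SLA2", "SYP1", "EDE1", "YAP1801", "YAP1802")

_AVOGADRO = 6.02214076e23


def cme_model(
    params: dict[str, float] | None = None,
    copy_overrides: dict[str, float] | None = None,
    misinteraction_f: float | None = None,
    scale: float = 1.0,
) -> World:
    """Build the clathrin vesicle-forming world.

    ``copy_overrides`` maps copy-number keys (e.g. 'SYP1_0') to new values
    (0 for a knockout, 2x for overexpression).  ``scale`` multiplies all
    copies with volume and membrane area co-scaled, preserving all
    concentrations (smaller, faster systems for exploratory runs).
    ``misinteraction_f`` adds generated nonspecific rules at the
    geometric-mean K_D times f.
    """
    p = dict(CME_PARAMS)
    if params:
        p.update(params)
    if copy_overrides:
        for k, v in copy_overrides.items():
            if k not in p:
                raise KeyError(f"unknown parameter {k!r}")
            p[k] = v
    vol_um3 = p["Vol_CP_um3"] * scale
    sa_um2 = p["SA_PM_um2"] * scale
    volume_L = vol_um3 * 1e-15

    def n(key):
        return max(int(round(p[key] * scale)), 0)

    n_lipid = max(int(round(p["L_density_per_um2"] * sa_um2)), 1)
    # repeated site names = three equivalent instances of one site class
    types = [
        MoleculeType("CHC", ["leg", "leg", "leg",
                             "clc", "clc", "clc",
                             "ada", "ada", "ada"], n("CHC1_0")),
        MoleculeType("CLC", ["chc", "sla"], n("CLC1_0")),
        MoleculeType("SLA2", ["dim", "lip", "clc"], n("SLA2_0")),
        MoleculeType("ENT", ["lip", "chc", "ede"], n("ENT_0")),
        MoleculeType("EDE1", ["dim", "ent", "yap", "syp"], n("EDE1_0")),
        MoleculeType("SYP1", ["dim", "lip", "ede"], n("SYP1_0")),
        MoleculeType("YAP1801", ["lip", "chc"], n("YAP1801_0")),
        MoleculeType("YAP1802", ["chc", "ede"], n("YAP1802_0")),
        MoleculeType("L", ["head"], n_lipid, membrane_resident=True),
    ]
    koff = p["k_off"]
    rules = [
        BindRule(("CHC", "leg"), ("CHC", "leg"), p["Kd_CHC_CHC"], koff),
        BindRule(("CHC", "ada"), ("ENT", "chc"), p["Kd_CHC_ENT"], koff),
        BindRule(("CHC", "ada"), ("YAP1801", "chc"), p["Kd_CHC_YAP"], koff),
        BindRule(("CHC", "ada"), ("YAP1802", "chc"), p["Kd_CHC_YAP"], koff),
        BindRule(("EDE1", "ent"), ("ENT", "ede"), p["Kd_EDE_ENT"], koff),
        BindRule(("EDE1", "yap"), ("YAP1802", "ede"), p["Kd_EDE_YAP"], koff),
        BindRule(("EDE1", "dim"), ("EDE1", "dim"), p["Kd_EDE_EDE"], koff),
        BindRule(("CHC", "clc"), ("CLC", "chc"), p["Kd_CHC_CLC"], koff),
        BindRule(("CLC", "sla"), ("SLA2", "clc"), p["Kd_CLC_SLA"], koff),
        BindRule(("SLA2", "dim"), ("SLA2", "dim"), p["Kd_SLA_SLA"], koff),
        BindRule(("SYP1", "dim"), ("SYP1", "dim"), p["Kd_SYP_SYP"], koff),
        BindRule(("SYP1", "ede"), ("EDE1", "syp"), p["Kd_SYP_EDE"], koff),
        BindRule(("ENT", "lip"), ("L", "head"), p["Kd_L_ENT"], koff),
        BindRule(("YAP1801", "lip"), ("L", "head"), p["Kd_L_YAP"], koff),
        BindRule(("SLA2", "lip"), ("L", "head"), p["Kd_L_SLA"], koff),
        BindRule(("SYP1", "lip"), ("L", "head"), p["Kd_L_SYP"], koff),
    ]
    if misinteraction_f is not None:
        rules += misinteraction_rules(
            types, rules, misinteraction_f, koff=koff, exclude_types=("L",)
        )
    ves = VesicleConfig(
        chc_type="CHC",
        clc_type="CLC",
        n_clc_full=3,
        threshold=int(p["T_vesicle"]),
        k_dump=p["k_dump"],
        k_recyc=p["k_recyc"],
        adaptor_types=ADAPTOR_TYPES,
        polymer_rule=(("CHC", "leg"), ("CHC", "leg")),
    )
    enh = membrane_enhancement(vol_um3, sa_um2, p["sigma_nm"])
    return World(types, rules, volume_L=volume_L, enhancement=enh, vesicle=ves)


# rules are defined per site class: the three legs (and light-chain/adaptor
# sites) of a triskelion belong to one class, so leg1 stands for all legs.


def cme_params_table() -> list[tuple[str, str, float, str]]:
    """The parameter table as (name, description, value, units) rows."""
    d = CME_PARAMS
    return [
        ("Vol_CP", "Cytosol volume", d["Vol_CP_um3"], "um^3"),
        ("SA_PM", "Plasma membrane surface area", d["SA_PM_um2"], "um^2"),
        ("sigma", "KD 3D to 2D conversion lengthscale", d["sigma_nm"], "nm"),
        ("Kd_CHC_CHC", "Heavy chain polymerization", d["Kd_CHC_CHC"] / UM, "uM"),
        ("Kd_CHC_ENT", "Heavy chain to ENT1/2", d["Kd_CHC_ENT"] / UM, "uM"),
        ("Kd_CHC_YAP", "Heavy chain to YAP1801/2", d["Kd_CHC_YAP"] / UM, "uM"),
        ("Kd_EDE_ENT", "EDE1 to ENT1/2", d["Kd_EDE_ENT"] / UM, "uM"),
        ("Kd_EDE_YAP", "EDE1 to YAP1802", d["Kd_EDE_YAP"] / UM, "uM"),
        ("Kd_EDE_EDE", "EDE1 dimerization", d["Kd_EDE_EDE"] / UM, "uM"),
        ("Kd_CHC_CLC", "Heavy chain to light chain", d["Kd_CHC_CLC"] / NM, "nM"),
        ("Kd_CLC_SLA", "Light chain to SLA2", d["Kd_CLC_SLA"] / UM, "uM"),
        ("Kd_SLA_SLA", "SLA2 dimerization", d["Kd_SLA_SLA"] / NM, "nM"),
        ("Kd_SYP_SYP", "SYP1 dimerization", d["Kd_SYP_SYP"] / UM, "uM"),
        ("Kd_SYP_EDE", "SYP1 to EDE1", d["Kd_SYP_EDE"] / UM, "uM"),
        ("Kd_L_ENT", "ENT1/2 to lipid", d["Kd_L_ENT"] / UM, "uM"),
        ("Kd_L_YAP", "YAP1801 to lipid", d["Kd_L_YAP"] / UM, "uM"),
        ("Kd_L_SLA", "SLA2 to lipid", d["Kd_L_SLA"] / UM, "uM"),
        ("Kd_L_SYP", "SYP1 to lipid", d["Kd_L_SYP"] / UM, "uM"),
        ("k_off", "Dissociation rate, all bonds", d["k_off"], "1/s"),
        ("L_0", "PI(4,5)P2 lipid density", d["L_density_per_um2"], "1/um^2"),
        ("CHC1_0", "Clathrin heavy-chain trimers", d["CHC1_0"], "copies"),
        ("CLC1_0", "Clathrin light chains", d["CLC1_0"], "copies"),
        ("EDE1_0", "EDE1", d["EDE1_0"], "copies"),
        ("ENT_0", "ENT1/2", d["ENT_0"], "copies"),
        ("YAP1801_0", "YAP1801", d["YAP1801_0"], "copies"),
        ("YAP1802_0", "YAP1802", d["YAP1802_0"], "copies"),
        ("SLA2_0", "SLA2", d["SLA2_0"], "copies"),
        ("SYP1_0", "SYP1", d["SYP1_0"], "copies"),
        ("T_vesicle", "Triskelia per vesicle", d["T_vesicle"], "count"),
        ("k_dump", "Vesicle deletion rate", d["k_dump"], "1/s"),
        ("k_recyc", "Recycling rate", d["k_recyc"], "1/s"),
    ]


def membrane_area_per_adaptor_nm2(
    n_adaptors: float, vesicle_diameter_nm: float = 100.0
) -> float:
    """Sphere surface area divided by the adaptor load of a vesicle.

    A 100 nm vesicle carrying ~1900 adaptor/scaffold proteins leaves only
    ~17 nm^2 of membrane per protein -- the steric-plausibility check on
    aggregate sizes.
    """
    if n_adaptors <= 0:
        return float("nan")
    return 4.0 * np.pi * (vesicle_diameter_nm / 2.0) ** 2 / n_adaptors


@dataclass
class VesicleStats:
    """Summary statistics over completed model vesicles."""

    n_vesicles: int
    times: list[float]
    adaptors_per_triskelion: float       # mean over vesicles
    per_vesicle_ratio: list[float]
    adaptor_recruited_fraction: float    # triskelia first membrane-bound via adaptor
    recruitment_counts: dict[str, int]
    mean_composition: dict[str, float] = field(default_factory=dict)


def vesicle_stats(result: SimResult, adaptor_types=ADAPTOR_TYPES) -> VesicleStats:
    """Per-vesicle adaptor load and triskelion recruitment attribution."""
    ratios = []
    comp_sum: dict[str, float] = {}
    for v in result.vesicles:
        if v.n_full_triskelia > 0:
            ratios.append(v.adaptors(adaptor_types) / v.n_full_triskelia)
        for k, c in v.composition.items():
            comp_sum[k] = comp_sum.get(k, 0.0) + c
    nv = len(result.vesicles)
    rec = result.chc_recruitment
    tot = rec.get("adaptor", 0) + rec.get("clathrin", 0)
    frac = rec.get("adaptor", 0) / tot if tot else float("nan")
    return VesicleStats(
        n_vesicles=nv,
        times=[v.time for v in result.vesicles],
        adaptors_per_triskelion=float(np.mean(ratios)) if ratios else float("nan"),
        per_vesicle_ratio=ratios,
        adaptor_recruited_fraction=frac,
        recruitment_counts=dict(rec),
        mean_composition={k: v / nv for k, v in comp_sum.items()} if nv else {},
    )
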
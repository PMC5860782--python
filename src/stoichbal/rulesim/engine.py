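"""Network-free stochastic simulator for multi-site protein assembly.

Molecules are typed site-graphs: each molecule carries named binding sites,
bonds connect free compatible sites, and complexes are the connected
components of the bond graph.  Rules are bimolecular site-pair bindings
with a dissociation constant (kon = koff / K_D in copy units); complexes
are never enumerated, so combinatorially large assemblies (clathrin cages,
adaptor aggregates) are simulated directly.

Two compartments exist: the cytosol and the membrane surface.  A complex
is membrane-associated iff it contains a membrane-resident molecule (a
lipid).  When *both* binding partners are membrane-associated the on-rate
is multiplied by Vol/(SA * 2 sigma) -- the dimensionality reduction
K_D(2D) = K_D(3D) / (2 sigma) expressed in copy units.

Propensities are aggregated per rule over global free-site counts (split
by compartment).  A sampled site pair falling inside one complex fires as
a null event, which is an exact thinning of the underlying Markov chain.
Optionally, complexes that reach a vesicle criterion (a threshold count of
complete clathrin triskelia on the membrane) are deleted at a high rate
and their members recycled to their home compartment one molecule at a
time.  Cooperative ring closure, when enabled, immediately closes a
specific-rule bond between two molecules already held together through a
shared neighbor ("arbitrarily high" trimer-closure rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AVOGADRO = 6.02214076e23

__all__ = [
    "MoleculeType",
    "BindRule",
    "VesicleConfig",
    "VesicleEvent",
    "SimResult",
    "World",
    "membrane_enhancement",
]


def membrane_enhancement(vol_cp_um3: float, sa_pm_um2: float, sigma_nm: float) -> float:
    """kon multiplier when both partners are on the membrane.

    Vol / (SA * 2 sigma): the 3D search volume collapses onto a slab of
    height 2 sigma above the membrane.  Doubling sigma halves the factor.
    """
    return vol_cp_um3 / (sa_pm_um2 * 2.0 * sigma_nm * 1e-3)


@dataclass
class MoleculeType:
    """A molecule type; repeated site names declare several instances of
    one site class (e.g. the three equivalent legs of a triskelion)."""

    name: str
    sites: list[str]
    copies: int
    membrane_resident: bool = False

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass
class BindRule:
    """Reversible binding between two site classes (type.site, type.site)."""

    a: tuple[str, str]
    b: tuple[str, str]
    kd_molar: float
    koff: float = 1.0
    specific: bool = True

    def __post_init__(self) -> None:
        if self.kd_molar <= 0 or self.koff <= 0:
            raise ValueError("K_D and koff must be positive")


@dataclass
class VesicleConfig:
    """Vesicle completion criterion and dump/recycle kinetics."""

    chc_type: str            # triskelion (heavy-chain trimer) molecule type
    clc_type: str            # light chain type; a full triskelion has all
    n_clc_full: int = 3      # light-chain sites occupied
    threshold: int = 100     # full triskelia required for a vesicle
    k_dump: float = 1000.0
    k_recyc: float = 1000.0
    adaptor_types: tuple[str, ...] = ()
    polymer_rule: tuple[tuple[str, str], tuple[str, str]] | None = None


@dataclass
class VesicleEvent:
    time: float
    composition: dict[str, int]
    n_full_triskelia: int

    def adaptors(self, adaptor_types) -> int:
        return sum(self.composition.get(t, 0) for t in adaptor_types)


@dataclass
class SimResult:
    t_end: float
    n_events: int
    n_null: int
    vesicles: list[VesicleEvent]
    chc_recruitment: dict[str, int]   # 'adaptor'/'clathrin' first-membrane tallies


class _Complex:
    __slots__ = ("mols", "n_lip", "n_full", "qualified")

    def __init__(self):
        self.mols: set[int] = set()
        self.n_lip = 0
        self.n_full = 0
        self.qualified = False

    @property
    def on_mem(self) -> bool:
        return self.n_lip > 0


class World:
    """Simulation state: molecules, bonds, complexes, rules, compartments."""

    def __init__(
        self,
        types: list[MoleculeType],
        rules: list[BindRule],
        volume_L: float,
        enhancement: float = 1.0,
        vesicle: VesicleConfig | None = None,
        ring_closure: bool = False,
    ):
        self.types = types
        self.volume_L = volume_L
        self.enhancement = enhancement
        self.vesicle = vesicle
        self.ring_closure = ring_closure

        self.type_index = {t.name: k for k, t in enumerate(types)}
        # site classes
        self.class_of: dict[tuple[str, str], int] = {}
        self.class_names: list[tuple[str, str]] = []
        for t in types:
            for s in t.sites:
                if (t.name, s) not in self.class_of:
                    self.class_of[(t.name, s)] = len(self.class_names)
                    self.class_names.append((t.name, s))
        self.n_classes = len(self.class_names)

        # rules -> arrays
        self.rules = rules
        R = len(rules)
        self.r_s1 = np.empty(R, dtype=np.int64)
        self.r_s2 = np.empty(R, dtype=np.int64)
        self.r_kon3 = np.empty(R)
        self.r_kon2 = np.empty(R)
        self.r_koff = np.empty(R)
        self.r_same = np.empty(R, dtype=bool)
        self.r_specific = [r.specific for r in rules]
        seen_pairs = set()
        for k, r in enumerate(rules):
            c1, c2 = self.class_of[r.a], self.class_of[r.b]
            if c1 > c2:
                c1, c2 = c2, c1
            if (c1, c2) in seen_pairs:
                raise ValueError(f"duplicate rule for site pair {r.a}/{r.b}")
            seen_pairs.add((c1, c2))
            self.r_s1[k], self.r_s2[k] = c1, c2
            kd_copies = r.kd_molar * AVOGADRO * volume_L
            self.r_kon3[k] = r.koff / kd_copies
            self.r_kon2[k] = self.r_kon3[k] * enhancement
            self.r_koff[k] = r.koff
            self.r_same[k] = c1 == c2
        self._same_idx = np.flatnonzero(self.r_same)
        # scalar-path caches for the propensity loop
        self._r_s1_l = self.r_s1.tolist()
        self._r_s2_l = self.r_s2.tolist()
        self._r_same_l = self.r_same.tolist()
        self._r_kon3_l = self.r_kon3.tolist()
        self._r_kon2_l = self.r_kon2.tolist()
        self._r_koff_l = self.r_koff.tolist()
        self._wbuf = ([0.0] * R, [0.0] * R, [0.0] * R)
        self._polymer_rule_id = -1
        if vesicle is not None and vesicle.polymer_rule is not None:
            pa, pb = vesicle.polymer_rule
            c1, c2 = sorted((self.class_of[pa], self.class_of[pb]))
            for k in range(R):
                if self.r_s1[k] == c1 and self.r_s2[k] == c2:
                    self._polymer_rule_id = k
        # specific-rule lookup for ring closure
        self._rule_by_pair = {}
        for k in range(R):
            if self.r_specific[k]:
                self._rule_by_pair[(int(self.r_s1[k]), int(self.r_s2[k]))] = k

        self._build_state()

    # ------------------------------------------------------------------
    # state construction
    # ------------------------------------------------------------------
    def _build_state(self) -> None:
        # hot per-site/per-molecule state lives in plain lists: the inner
        # loop is scalar reads/writes, where lists beat ndarray indexing
        self.n_mols = sum(t.copies for t in self.types)
        mt: list[int] = []
        site_off: list[int] = []
        off = 0
        site_class_l: list[int] = []
        site_mol_l: list[int] = []
        m = 0
        for ti, t in enumerate(self.types):
            cids = [self.class_of[(t.name, s)] for s in t.sites]
            for _ in range(t.copies):
                mt.append(ti)
                site_off.append(off)
                for c in cids:
                    site_class_l.append(c)
                    site_mol_l.append(m)
                off += len(cids)
                m += 1
        site_off.append(off)
        self.mol_type = mt
        self.site_off = site_off
        self.n_sites = off
        self.site_class = site_class_l
        self.site_mol = site_mol_l
        self.bond_to = [-1] * self.n_sites
        self.bond_rule = [-1] * self.n_sites

        # free-site pools per (class, compartment 0=cyt 1=mem)
        self.pools: list[list[int]] = [[] for _ in range(2 * self.n_classes)]
        self.site_pool = [-1] * self.n_sites
        self.site_pos = [-1] * self.n_sites
        self.nc = [0.0] * self.n_classes
        self.nm = [0.0] * self.n_classes
        self._resident = [t.membrane_resident for t in self.types]
        for s in range(self.n_sites):
            comp = 1 if self._resident[mt[site_mol_l[s]]] else 0
            self._pool_add(s, comp)

        self.mol_complex: dict[int, int] = {}
        self.complexes: dict[int, _Complex] = {}
        self._next_cid = 0
        self.qualified: list[int] = []
        self._qual_pos: dict[int, int] = {}
        self.recycle_queue: list[int] = []
        self.in_transit: set[int] = set()

        # per-rule bond registries
        self.rule_bonds: list[list[int]] = [[] for _ in self.rules]  # canonical site ids
        self.bond_pos = [-1] * self.n_sites
        self.bond_counts = [0.0] * len(self.rules)

        # triskelion bookkeeping
        self._chc_ti = self.type_index[self.vesicle.chc_type] if self.vesicle else -1
        self._clc_rule_id = -1
        if self.vesicle is not None:
            # the full-triskelion counting rule is the *specific* heavy-to-
            # light-chain bond (strongest, if several specific rules join
            # the two types); generated misinteraction rules never qualify
            cands = [
                (r.kd_molar, k) for k, r in enumerate(self.rules)
                if r.specific
                and {r.a[0], r.b[0]} == {self.vesicle.chc_type, self.vesicle.clc_type}
            ]
            if cands:
                self._clc_rule_id = min(cands)[1]
        self.chc_nclc: dict[int, int] = {}
        self.chc_first_attr: dict[int, str] = {}

    # ------------------------------------------------------------------
    # pools
    # ------------------------------------------------------------------
    def _pool_add(self, s: int, comp: int) -> None:
        c = int(self.site_class[s])
        pool = self.pools[2 * c + comp]
        self.site_pool[s] = 2 * c + comp
        self.site_pos[s] = len(pool)
        pool.append(s)
        if comp:
            self.nm[c] += 1
        else:
            self.nc[c] += 1

    def _pool_remove(self, s: int) -> None:
        pid = int(self.site_pool[s])
        if pid < 0:
            return
        pool = self.pools[pid]
        pos = int(self.site_pos[s])
        last = pool[-1]
        pool[pos] = last
        self.site_pos[last] = pos
        pool.pop()
        self.site_pool[s] = -1
        self.site_pos[s] = -1
        c, comp = divmod(pid, 2)
        if comp:
            self.nm[c] -= 1
        else:
            self.nc[c] -= 1

    def _mol_comp(self, m: int) -> int:
        cid = self.mol_complex.get(m, -1)
        if cid >= 0:
            return 1 if self.complexes[cid].on_mem else 0
        return 1 if self._resident[self.mol_type[m]] else 0

    def _move_mol_pools(self, m: int, comp: int, cause_rule: int = -1) -> None:
        """Move all free sites of molecule m to compartment `comp`; on a
        cytosol->membrane move, attribute a triskelion's first recruitment."""
        for s in range(self.site_off[m], self.site_off[m + 1]):
            if self.bond_to[s] == -1 and self.site_pool[s] != -1:
                if self.site_pool[s] % 2 != comp:
                    self._pool_remove(s)
                    self._pool_add(s, comp)
        if (
            comp == 1
            and self._chc_ti >= 0
            and self.mol_type[m] == self._chc_ti
            and m not in self.chc_first_attr
        ):
            kind = "clathrin" if cause_rule == self._polymer_rule_id else "adaptor"
            self.chc_first_attr[m] = kind

    # ------------------------------------------------------------------
    # complexes
    # ------------------------------------------------------------------
    def _new_complex(self) -> int:
        cid = self._next_cid
        self._next_cid += 1
        self.complexes[cid] = _Complex()
        return cid

    def _qual_add(self, cid: int) -> None:
        if cid not in self._qual_pos:
            self._qual_pos[cid] = len(self.qualified)
            self.qualified.append(cid)
            self.complexes[cid].qualified = True

    def _qual_remove(self, cid: int) -> None:
        pos = self._qual_pos.pop(cid, None)
        if pos is None:
            return
        last = self.qualified.pop()
        if last != cid:
            self.qualified[pos] = last
            self._qual_pos[last] = pos
        if cid in self.complexes:
            self.complexes[cid].qualified = False

    def _check_qual(self, cid: int) -> None:
        if self.vesicle is None:
            return
        cx = self.complexes.get(cid)
        if cx is None:
            return
        ok = cx.on_mem and cx.n_full >= self.vesicle.threshold
        if ok and not cx.qualified:
            self._qual_add(cid)
        elif not ok and cx.qualified:
            self._qual_remove(cid)

    # ------------------------------------------------------------------
    # bonds
    # ------------------------------------------------------------------
    def _register_bond(self, sa: int, sb: int, rule: int) -> None:
        if sa > sb:
            sa, sb = sb, sa
        self.bond_to[sa] = sb
        self.bond_to[sb] = sa
        self.bond_rule[sa] = rule
        self.bond_rule[sb] = rule
        lst = self.rule_bonds[rule]
        self.bond_pos[sa] = len(lst)
        lst.append(sa)
        self.bond_counts[rule] += 1

    def _unregister_bond(self, sa: int) -> tuple[int, int]:
        sb = int(self.bond_to[sa])
        if sa > sb:
            sa, sb = sb, sa
        rule = int(self.bond_rule[sa])
        lst = self.rule_bonds[rule]
        pos = int(self.bond_pos[sa])
        last = lst[-1]
        lst[pos] = last
        self.bond_pos[last] = pos
        lst.pop()
        self.bond_counts[rule] -= 1
        self.bond_pos[sa] = -1
        self.bond_to[sa] = -1
        self.bond_to[sb] = -1
        self.bond_rule[sa] = -1
        self.bond_rule[sb] = -1
        return sb, rule

    # triskelion counter helpers -----------------------------------------
    def _trisk_bond_delta(self, sa: int, sb: int, delta: int):
        """Update full-triskelion counts when a heavy-light chain bond
        forms (delta=+1) or breaks (delta=-1).  Returns affected complex."""
        m = int(self.site_mol[sa])
        if self.mol_type[m] != self._chc_ti:
            m = int(self.site_mol[sb])
        old = self.chc_nclc.get(m, 0)
        new = old + delta
        self.chc_nclc[m] = new
        need = self.vesicle.n_clc_full
        cid = self.mol_complex.get(m, -1)
        if cid < 0:
            return
        cx = self.complexes[cid]
        if old < need <= new:
            cx.n_full += 1
        elif new < need <= old:
            cx.n_full -= 1
        self._check_qual(cid)

    # ------------------------------------------------------------------
    # event application
    # ------------------------------------------------------------------
    def _apply_bind(self, sa: int, sb: int, rule: int) -> int | None:
        """Create a bond; merge complexes; return id of affected complex."""
        ma, mb = int(self.site_mol[sa]), int(self.site_mol[sb])
        self._pool_remove(sa)
        self._pool_remove(sb)
        self._register_bond(sa, sb, rule)

        ca = self.mol_complex.get(ma, -1)
        cb = self.mol_complex.get(mb, -1)
        if ca == -1 and cb == -1:
            cid = self._new_complex()
            cx = self.complexes[cid]
            for m in (ma, mb):
                cx.mols.add(m)
                self.mol_complex[m] = cid
                if self._resident[self.mol_type[m]]:
                    cx.n_lip += 1
            # compartment flips for newly membrane-associated members
            if cx.on_mem:
                for m in (ma, mb):
                    if not self._resident[self.mol_type[m]]:
                        self._move_mol_pools(m, 1, rule)
        elif ca == -1 or cb == -1:
            if ca == -1:
                cid, lone = cb, ma
            else:
                cid, lone = ca, mb
            cx = self.complexes[cid]
            was_mem = cx.on_mem
            cx.mols.add(lone)
            self.mol_complex[lone] = cid
            if self._resident[self.mol_type[lone]]:
                cx.n_lip += 1
            now_mem = cx.on_mem
            if now_mem and not self._resident[self.mol_type[lone]]:
                self._move_mol_pools(lone, 1, rule)
            if now_mem and not was_mem:
                for m in cx.mols:
                    if m != lone and not self._resident[self.mol_type[m]]:
                        self._move_mol_pools(m, 1, rule)
                # newly full triskelia are already counted via chc bookkeeping
            # a lone CHC joining counts toward n_full only once it has bonds;
            # full status tracked by chc_nclc (singletons cannot be full)
        else:
            if ca == cb:
                # intra-complex bond (ring closure path); no merge needed
                cid = ca
                self._check_qual(cid)
                if self._clc_rule_id == rule:
                    self._trisk_bond_delta(sa, sb, +1)
                return cid
            # merge smaller into larger
            if len(self.complexes[ca].mols) < len(self.complexes[cb].mols):
                ca, cb = cb, ca
            big, small = self.complexes[ca], self.complexes[cb]
            big_was_mem, small_was_mem = big.on_mem, small.on_mem
            big_members = list(big.mols) if (small_was_mem and not big_was_mem) else None
            for m in small.mols:
                self.mol_complex[m] = ca
            big.mols |= small.mols
            big.n_lip += small.n_lip
            big.n_full += small.n_full
            self._qual_remove(cb)
            del self.complexes[cb]
            now_mem = big.on_mem
            if now_mem and not small_was_mem:
                for m in small.mols:
                    if not self._resident[self.mol_type[m]]:
                        self._move_mol_pools(m, 1, rule)
            if big_members is not None and now_mem:
                for m in big_members:
                    if not self._resident[self.mol_type[m]]:
                        self._move_mol_pools(m, 1, rule)
            cid = ca
        if self.vesicle is not None and rule == self._clc_rule_id:
            self._trisk_bond_delta(sa, sb, +1)
        self._check_qual(cid)
        return cid

    def _degree(self, m: int) -> int:
        d = 0
        for s in range(self.site_off[m], self.site_off[m + 1]):
            if self.bond_to[s] != -1:
                d += 1
        return d

    def _connected_after_removal(self, ma: int, mb: int):
        """Bidirectional search; returns (True, None) if still connected,
        else (False, members_of_smaller_fragment)."""
        if ma == mb:
            return True, None
        # fast path: a now-isolated endpoint is its own fragment
        if self._degree(ma) == 0:
            return False, {ma}
        if self._degree(mb) == 0:
            return False, {mb}
        seen_a = {ma}
        seen_b = {mb}
        frontier_a = [ma]
        frontier_b = [mb]
        while True:
            # expand the smaller frontier
            if not frontier_a:
                return False, seen_a
            if not frontier_b:
                return False, seen_b
            if len(frontier_a) <= len(frontier_b):
                frontier, seen, other = frontier_a, seen_a, seen_b
                which = 0
            else:
                frontier, seen, other = frontier_b, seen_b, seen_a
                which = 1
            new = []
            for m in frontier:
                for s in range(self.site_off[m], self.site_off[m + 1]):
                    t = self.bond_to[s]
                    if t != -1:
                        n = int(self.site_mol[t])
                        if n in other:
                            return True, None
                        if n not in seen:
                            seen.add(n)
                            new.append(n)
            if which == 0:
                frontier_a = new
            else:
                frontier_b = new

    def _apply_unbind(self, sa: int) -> None:
        sb, rule = self._unregister_bond(sa)
        if sa > sb:
            sa, sb = sb, sa
        ma, mb = int(self.site_mol[sa]), int(self.site_mol[sb])
        cid = self.mol_complex[ma]
        cx = self.complexes[cid]
        if self.vesicle is not None and rule == self._clc_rule_id:
            self._trisk_bond_delta(sa, sb, -1)
        comp_now = 1 if cx.on_mem else 0
        self._pool_add(sa, comp_now)
        self._pool_add(sb, comp_now)

        still, fragment = self._connected_after_removal(ma, mb)
        if still:
            self._check_qual(cid)
            return
        # split: move `fragment` (the smaller component) out of cx in place
        frag_lip = 0
        frag_full = 0
        need = self.vesicle.n_clc_full if self.vesicle is not None else 0
        resident = self._resident
        mt = self.mol_type
        for m in fragment:
            if resident[mt[m]]:
                frag_lip += 1
            elif need and mt[m] == self._chc_ti and self.chc_nclc.get(m, 0) >= need:
                frag_full += 1
        cx.mols.difference_update(fragment)
        cx.n_lip -= frag_lip
        cx.n_full -= frag_full
        rest = cx.mols

        def _finalize(members: set[int], lip: int, full: int, parent_was_mem: bool):
            if len(members) == 1:
                (m,) = members
                self.mol_complex.pop(m, None)
                home = 1 if self._resident[self.mol_type[m]] else 0
                if parent_was_mem != (home == 1):
                    self._move_mol_pools(m, home)
                return None
            cid2 = self._new_complex()
            c2 = self.complexes[cid2]
            c2.mols = members
            c2.n_lip = lip
            c2.n_full = full
            for m in members:
                self.mol_complex[m] = cid2
            if parent_was_mem and not c2.on_mem:
                for m in members:
                    if not self._resident[self.mol_type[m]]:
                        self._move_mol_pools(m, 0)
            self._check_qual(cid2)
            return cid2

        parent_was_mem = comp_now == 1
        _finalize(fragment, frag_lip, frag_full, parent_was_mem)
        # remaining side: may itself have shrunk to one molecule
        if len(rest) == 1:
            self._qual_remove(cid)
            del self.complexes[cid]
            _finalize(rest, cx.n_lip, cx.n_full, parent_was_mem)
        else:
            if parent_was_mem and not cx.on_mem:
                for m in rest:
                    if not self._resident[self.mol_type[m]]:
                        self._move_mol_pools(m, 0)
            self._check_qual(cid)

    def _apply_dump(self, cid: int, t: float, vesicles: list[VesicleEvent]) -> None:
        cx = self.complexes[cid]
        comp_counts: dict[str, int] = {}
        for m in cx.mols:
            name = self.types[self.mol_type[m]].name
            comp_counts[name] = comp_counts.get(name, 0) + 1
        vesicles.append(VesicleEvent(t, comp_counts, cx.n_full))
        self._qual_remove(cid)
        for m in cx.mols:
            for s in range(self.site_off[m], self.site_off[m + 1]):
                if self.bond_to[s] != -1:
                    self._unregister_bond(int(s))
                elif self.site_pool[s] != -1:
                    self._pool_remove(int(s))
            if self.mol_type[m] == self._chc_ti:
                self.chc_nclc[m] = 0
            self.mol_complex.pop(m, None)
            self.in_transit.add(m)
            self.recycle_queue.append(m)
        del self.complexes[cid]

    def _apply_recycle(self, idx: int) -> None:
        m = self.recycle_queue[idx]
        last = self.recycle_queue[-1]
        self.recycle_queue[idx] = last
        self.recycle_queue.pop()
        self.in_transit.discard(m)
        home = 1 if self._resident[self.mol_type[m]] else 0
        for s in range(self.site_off[m], self.site_off[m + 1]):
            self._pool_add(int(s), home)

    # ------------------------------------------------------------------
    # ring closure (trimer cooperativity): when two molecules are already
    # held together through one shared neighbor (two binding events), a
    # specific bond allowed between them closes at an effectively infinite
    # rate.  Only distance-2 pairs close; remote intra-complex pairs still
    # require a (null-evented) bimolecular encounter.
    # ------------------------------------------------------------------
    def _bonded_neighbors(self, m: int) -> set[int]:
        out = set()
        for s in range(self.site_off[m], self.site_off[m + 1]):
            t = self.bond_to[s]
            if t != -1:
                out.add(int(self.site_mol[t]))
        return out

    def _close_rings(self, cid: int | None) -> None:
        if cid is None or cid not in self.complexes:
            return
        changed = True
        while changed:
            changed = False
            cx = self.complexes.get(cid)
            if cx is None:
                return
            free_by_class: dict[int, list[int]] = {}
            for m in cx.mols:
                for s in range(self.site_off[m], self.site_off[m + 1]):
                    if self.bond_to[s] == -1:
                        free_by_class.setdefault(int(self.site_class[s]), []).append(int(s))
            for (c1, c2), rule in self._rule_by_pair.items():
                l1 = free_by_class.get(c1, [])
                l2 = free_by_class.get(c2, [])
                for sa in l1:
                    if self.bond_to[sa] != -1:
                        continue
                    ma = int(self.site_mol[sa])
                    na = self._bonded_neighbors(ma)
                    for sb in l2:
                        if sb == sa or self.bond_to[sb] != -1:
                            continue
                        mb = int(self.site_mol[sb])
                        if mb == ma or mb in na:
                            continue
                        if not (na & self._bonded_neighbors(mb)):
                            continue  # not a trimer ring
                        self._apply_bind(sa, sb, rule)
                        changed = True
                        break

    # ------------------------------------------------------------------
    # propensities & firing
    # ------------------------------------------------------------------
    def _bind_weights(self):
        R = len(self.rules)
        nc, nm = self.nc, self.nm
        if R <= 48:
            # scalar path: cheaper than ndarray machinery for few rules
            w1, w2, w3 = self._wbuf
            s1l, s2l, samel = self._r_s1_l, self._r_s2_l, self._r_same_l
            kon3l, kon2l = self._r_kon3_l, self._r_kon2_l
            for r in range(R):
                c1 = s1l[r]
                nc1 = nc[c1]
                nm1 = nm[c1]
                if samel[r]:
                    w1[r] = nc1 * (nc1 - 1.0) * 0.5 * kon3l[r]
                    w2[r] = nc1 * nm1 * kon3l[r]
                    w3[r] = nm1 * (nm1 - 1.0) * 0.5 * kon2l[r]
                else:
                    c2 = s2l[r]
                    nc2 = nc[c2]
                    nm2 = nm[c2]
                    w1[r] = nc1 * (nc2 + nm2) * kon3l[r]
                    w2[r] = nm1 * nc2 * kon3l[r]
                    w3[r] = nm1 * nm2 * kon2l[r]
            return w1, w2, w3
        anc = np.asarray(nc)
        anm = np.asarray(nm)
        nc1 = anc[self.r_s1]
        nm1 = anm[self.r_s1]
        nc2 = anc[self.r_s2]
        nm2 = anm[self.r_s2]
        w1 = nc1 * (nc2 + nm2)
        w2 = nm1 * nc2
        w3 = nm1 * nm2
        si = self._same_idx
        if si.size:
            ncs, nms = nc1[si], nm1[si]
            w1[si] = ncs * (ncs - 1) * 0.5
            w2[si] = ncs * nms
            w3[si] = nms * (nms - 1) * 0.5
        w1 *= self.r_kon3
        w2 *= self.r_kon3
        w3 *= self.r_kon2
        return w1, w2, w3

    def _sample_site(self, cls: int, comp: int, rng) -> int:
        pool = self.pools[2 * cls + comp]
        return pool[int(rng.random() * len(pool))]

    def _sample_any(self, cls: int, rng) -> int:
        pc = self.pools[2 * cls]
        pm = self.pools[2 * cls + 1]
        k = int(rng.random() * (len(pc) + len(pm)))
        return pc[k] if k < len(pc) else pm[k - len(pc)]

    def _fire_bind(self, r: int, w1: float, w2: float, w3: float, rng) -> int | None:
        """Sample a site pair for rule r; returns affected complex id or
        None for a null event (same molecule / same complex)."""
        c1, c2 = int(self.r_s1[r]), int(self.r_s2[r])
        u = rng.random() * (w1 + w2 + w3)
        if self.r_same[r]:
            if u < w1:
                pool = self.pools[2 * c1]
            elif u < w1 + w2:
                sa = self._sample_site(c1, 0, rng)
                sb = self._sample_site(c1, 1, rng)
                pool = None
            else:
                pool = self.pools[2 * c1 + 1]
            if pool is not None:
                n = len(pool)
                i = int(rng.random() * n)
                j = int(rng.random() * (n - 1))
                if j >= i:
                    j += 1
                sa, sb = pool[i], pool[j]
        else:
            if u < w1:
                sa = self._sample_site(c1, 0, rng)
                sb = self._sample_any(c2, rng)
            elif u < w1 + w2:
                sa = self._sample_site(c1, 1, rng)
                sb = self._sample_site(c2, 0, rng)
            else:
                sa = self._sample_site(c1, 1, rng)
                sb = self._sample_site(c2, 1, rng)
        ma, mb = int(self.site_mol[sa]), int(self.site_mol[sb])
        if ma == mb:
            return None
        ca = self.mol_complex.get(ma, -1)
        if ca != -1 and ca == self.mol_complex.get(mb, -1):
            return None  # intra-complex: null event (ring closure handles these)
        return self._apply_bind(sa, sb, r)

    # ------------------------------------------------------------------
    def simulate(
        self,
        t_end: float,
        seed: int = 0,
        max_events: int | None = None,
        stop_after_vesicles: int | None = None,
    ) -> SimResult:
        """Run the SSA until t_end (or a vesicle/event budget is reached)."""
        rng = np.random.default_rng(seed)
        R = len(self.rules)
        t = 0.0
        n_events = 0
        n_null = 0
        vesicles: list[VesicleEvent] = []
        ves = self.vesicle
        a = np.empty(2 * R + 2)
        rnd = rng.random
        rexp = rng.exponential
        cumsum = np.cumsum
        searchsorted = np.searchsorted
        scalar_path = R <= 48
        koff_l = self._r_koff_l
        bc = self.bond_counts
        while t < t_end:
            w1, w2, w3 = self._bind_weights()
            if scalar_path:
                for r in range(R):
                    a[r] = w1[r] + w2[r] + w3[r]
                    a[R + r] = koff_l[r] * bc[r]
            else:
                np.add(w1, w2, out=a[:R])
                a[:R] += w3
                np.multiply(self.r_koff, np.asarray(bc), out=a[R:2 * R])
            a[2 * R] = (ves.k_dump * len(self.qualified)) if ves else 0.0
            a[2 * R + 1] = (ves.k_recyc * len(self.recycle_queue)) if ves else 0.0
            cum = cumsum(a)
            total = cum[-1]
            if total <= 0.0:
                break
            t += rexp(1.0 / total)
            if t >= t_end:
                break
            k = int(searchsorted(cum, rnd() * total))
            k = min(k, 2 * R + 1)
            n_events += 1
            touched = None
            if k < R:
                touched = self._fire_bind(k, float(w1[k]), float(w2[k]), float(w3[k]), rng)
                if touched is None:
                    n_null += 1
            elif k < 2 * R:
                r = k - R
                lst = self.rule_bonds[r]
                sa = lst[int(rng.integers(len(lst)))]
                ma = int(self.site_mol[sa])
                self._apply_unbind(sa)
                touched = self.mol_complex.get(ma, None)
            elif k == 2 * R:
                cid = self.qualified[int(rng.integers(len(self.qualified)))]
                self._apply_dump(cid, t, vesicles)
                if stop_after_vesicles is not None and len(vesicles) >= stop_after_vesicles:
                    break
            else:
                self._apply_recycle(int(rng.integers(len(self.recycle_queue))))
            if self.ring_closure and touched is not None:
                self._close_rings(touched)
            if max_events is not None and n_events >= max_events:
                break
        attr = {"adaptor": 0, "clathrin": 0}
        for v in self.chc_first_attr.values():
            attr[v] += 1
        return SimResult(t, n_events, n_null, vesicles, attr)

    # ------------------------------------------------------------------
    # inspection
    # ------------------------------------------------------------------
    def census(self) -> list[dict]:
        """Complex census: per-complex type counts and bond counts."""
        out = []
        for cx in self.complexes.values():
            counts: dict[str, int] = {}
            nb = 0
            for m in cx.mols:
                counts[self.types[self.mol_type[m]].name] = (
                    counts.get(self.types[self.mol_type[m]].name, 0) + 1
                )
                for s in range(self.site_off[m], self.site_off[m + 1]):
                    if self.bond_to[s] != -1:
                        nb += 1
            out.append({"counts": counts, "n_bonds": nb // 2, "size": len(cx.mols)})
        return out

    def type_totals(self) -> dict[str, int]:
        """Per-type molecule totals across all states (conservation check)."""
        totals = {t.name: 0 for t in self.types}
        for m in range(self.n_mols):
            totals[self.types[self.mol_type[m]].name] += 1
        return totals

    def free_monomers(self) -> dict[str, int]:
        out = {t.name: 0 for t in self.types}
        for m in range(self.n_mols):
            if m in self.in_transit or m in self.mol_complex:
                continue
            out[self.types[self.mol_type[m]].name] += 1
        return out
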
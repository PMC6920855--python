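"""Multiscale restraint and reduced-physics energy model.

The model mirrors a multiscale rigid/flexible setup: base-pair springs
(edge-atom distance springs plus a base-coplanarity penalty), helical
stacking restraints, welds that pin scaffold residues in space, distance
springs to monitor/surrogate anchors, purely repulsive collision-detecting
spheres, and a local "physics zone" carrying reduced Amber-type nonbonded
(12-6 Lennard-Jones + Coulomb with distance-dependent dielectric
eps(r) = 4r, switched off at a 9 A cutoff) and bonded terms for flexible
residues.

Everything is evaluable to an energy (kcal/mol) and an analytic gradient
(kcal/mol/A) over all atoms; gradients of rigid-residue atoms are masked to
zero.  Energies of rigid-rigid bonded pairs inside the physics zone are
constant by construction and are excluded from the sum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _kernels as _K
from . import chem
from .model import AtomKey, ResKey, SceneModel

DEFAULT_K_DIST = 10.0    # kcal/(mol*A^2), base-pair springs
DEFAULT_K_PLANE = 5.0    # kcal/(mol*rad^2-like), coplanarity penalty
DEFAULT_K_MONITOR = 5.0  # kcal/(mol*A^2), monitor/surrogate springs
DEFAULT_K_WELD = 50.0    # kcal/(mol*A^2), weld-to-space position restraint
DEFAULT_R_COLLIDE = 2.6  # A, collision-sphere threshold
DEFAULT_K_COLLIDE = 10.0  # kcal/(mol*A^2)
DEFAULT_K_STACK = 5.0    # kcal/(mol*A^2), stacking distance springs

# reduced bonded parameters (flexible residues)
K_BOND = 300.0   # kcal/(mol*A^2)
K_ANGLE = 50.0   # kcal/(mol*rad^2)
K_DIHEDRAL = 2.0   # kcal/mol, 1 - cos(n (phi - phi0))
DIHEDRAL_PERIOD = 3  # threefold: single-bond rotamers remain accessible

CUTOFF = 9.0     # A nonbonded cutoff
SWITCH_ON = 7.5  # A switching starts
NEIGHBOR_SKIN = 2.0  # A Verlet-list skin

# explicit 10-12 hydrogen-bond term (polar H ... N/O acceptor): restores
# the directional pairing wells that the strong dielectric screening of
# the reduced Coulomb term flattens out
HB_EPS = 2.5     # kcal/mol well depth
HB_R0 = 1.9      # A H...acceptor optimum
HB_CUTOFF = 6.0  # A neighbour-list cutoff for the term
POLAR_H_MIN_CHARGE = 0.3


# ---------------------------------------------------------------------------
# restraint dataclasses
# ---------------------------------------------------------------------------

@dataclass
class PairRestraint:
    """Base-pairing springs: edge-atom distance springs + coplanarity."""

    residue_a: ResKey
    residue_b: ResKey
    pair_type: str                      # "WC" | "wobble" | "custom"
    atom_pairs: List[Tuple[str, str, float]]  # (name_a, name_b, r0)
    k_dist: float = DEFAULT_K_DIST
    k_plane: float = DEFAULT_K_PLANE
    tag: str = "pair"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.atom_pairs:
            raise ValueError("PairRestraint needs at least one atom pair")
        for _, _, r0 in self.atom_pairs:
            if r0 <= 0:
                raise ValueError("pair restraint r0 must be positive")
        if self.k_dist < 0 or self.k_plane < 0:
            raise ValueError("force constants must be non-negative")


@dataclass
class DistanceSpring:
    """Harmonic spring between two named atoms (monitor/surrogate anchors)."""

    atom_a: AtomKey
    atom_b: AtomKey
    r0: float
    k: float = DEFAULT_K_MONITOR
    tag: str = "spring"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.r0 < 0 or self.k < 0:
            raise ValueError("DistanceSpring needs r0 >= 0 and k >= 0")


@dataclass
class WeldConstraint:
    """Pin a residue's atoms to their current (reference) positions.

    Realizes 'welded ... fixed in space to avoid drifting': a harmonic
    position restraint to reference coordinates.  This is the one term that
    deliberately breaks rigid-motion invariance of the total energy.
    """

    residue: ResKey
    k: float = DEFAULT_K_WELD
    reference: Optional[np.ndarray] = None  # captured at compile if None
    atoms: Optional[List[str]] = None       # None = every atom of the residue
    tag: str = "weld"
    scale: float = 1.0


@dataclass
class StackRestraint:
    """Helical stacking between consecutive residues of one chain.

    Realized as distance springs on glycosidic-N and C1' separations (their
    built equilibrium encodes rise/twist) plus a base-normal parallelism
    penalty.
    """

    residue_a: ResKey
    residue_b: ResKey
    rise: float = 2.81
    twist: float = 32.7
    k: float = DEFAULT_K_STACK
    k_parallel: float = DEFAULT_K_PLANE
    tag: str = "stack"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.residue_a[0] != self.residue_b[0]:
            raise ValueError("stacking restraint must join residues of one chain")
        if abs(self.residue_a[1] - self.residue_b[1]) != 1:
            raise ValueError("stacking restraint must join consecutive residues")


@dataclass
class CollisionSphereSet:
    """Purely repulsive contact term on heavy atoms below a threshold."""

    r_thresh: float = DEFAULT_R_COLLIDE
    k_rep: float = DEFAULT_K_COLLIDE
    tag: str = "collision"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.r_thresh <= 0:
            raise ValueError("collision threshold must be positive")


@dataclass
class PhysicsZone:
    """Reduced Amber-type force field applied near a center residue."""

    center: ResKey
    radius: float = 10.0
    cutoff: float = CUTOFF
    switch_on: float = SWITCH_ON
    coulomb: bool = True
    lennard_jones: bool = True
    bonded: bool = True
    hydrogen_bonds: bool = True
    hb_eps: float = HB_EPS
    hb_r0: float = HB_R0
    tag: str = "physics"
    scale: float = 1.0


@dataclass
class RestraintSet:
    """Aggregate of all restraint terms + optional physics zone."""

    pair_restraints: List[PairRestraint] = field(default_factory=list)
    distance_springs: List[DistanceSpring] = field(default_factory=list)
    welds: List[WeldConstraint] = field(default_factory=list)
    stacks: List[StackRestraint] = field(default_factory=list)
    collisions: Optional[CollisionSphereSet] = None
    physics: Optional[PhysicsZone] = None

    def all_terms(self):
        yield from self.pair_restraints
        yield from self.distance_springs
        yield from self.welds
        yield from self.stacks
        if self.collisions is not None:
            yield self.collisions
        if self.physics is not None:
            yield self.physics

    def scaled(self, factors: Dict[str, float]) -> "RestraintSet":
        """Copy with per-tag force-constant scale factors (release ladder)."""
        out = RestraintSet(
            pair_restraints=[dataclasses.replace(p) for p in self.pair_restraints],
            distance_springs=[dataclasses.replace(s) for s in self.distance_springs],
            welds=[dataclasses.replace(w) for w in self.welds],
            stacks=[dataclasses.replace(s) for s in self.stacks],
            collisions=(dataclasses.replace(self.collisions)
                        if self.collisions else None),
            physics=dataclasses.replace(self.physics) if self.physics else None,
        )
        for term in out.all_terms():
            if term.tag in factors:
                term.scale = term.scale * factors[term.tag]
        return out

    def without(self, predicate) -> "RestraintSet":
        """Copy dropping terms for which ``predicate(term)`` is true."""
        out = RestraintSet(
            pair_restraints=[p for p in self.pair_restraints if not predicate(p)],
            distance_springs=[s for s in self.distance_springs if not predicate(s)],
            welds=[w for w in self.welds if not predicate(w)],
            stacks=[s for s in self.stacks if not predicate(s)],
            collisions=(None if (self.collisions and predicate(self.collisions))
                        else self.collisions),
            physics=(None if (self.physics and predicate(self.physics))
                     else self.physics),
        )
        return out

    def describe(self) -> str:
        """Human-readable dump of every term (audit trail)."""
        lines: List[str] = []
        for p in self.pair_restraints:
            pairs = ", ".join(f"{a}-{b}@{r0:.2f}" for a, b, r0 in p.atom_pairs)
            lines.append(
                f"pair {p.tag}: {p.residue_a}<->{p.residue_b} [{p.pair_type}] "
                f"k_dist={p.k_dist * p.scale:g} k_plane={p.k_plane * p.scale:g} "
                f"({pairs})")
        for s in self.distance_springs:
            lines.append(
                f"spring {s.tag}: {s.atom_a}<->{s.atom_b} r0={s.r0:g} "
                f"k={s.k * s.scale:g}")
        for w in self.welds:
            lines.append(f"weld {w.tag}: {w.residue} k={w.k * w.scale:g}")
        for s in self.stacks:
            lines.append(
                f"stack {s.tag}: {s.residue_a}~{s.residue_b} rise={s.rise:g} "
                f"twist={s.twist:g} k={s.k * s.scale:g}")
        if self.collisions is not None:
            c = self.collisions
            lines.append(
                f"collision spheres: r_thresh={c.r_thresh:g} "
                f"k_rep={c.k_rep * c.scale:g}")
        if self.physics is not None:
            z = self.physics
            lines.append(
                f"physics zone: center={z.center} radius={z.radius:g} "
                f"cutoff={z.cutoff:g} lj={z.lennard_jones} coulomb={z.coulomb} "
                f"bonded={z.bonded}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def make_basepair_restraint(res_a, res_b, pair_type: str = "WC",
                            r0: float = chem.CANONICAL_DA,
                            k_dist: float = DEFAULT_K_DIST,
                            k_plane: float = DEFAULT_K_PLANE,
                            tag: str = "pair") -> PairRestraint:
    """Edge-atom base-pair restraint for two residues.

    ``res_a``/``res_b`` may be :class:`~straddlemd.model.Residue` objects or
    ``(base, key)`` tuples; the canonical edge-atom set for the base
    combination is emitted with equilibrium ``r0`` (default 2.9 A).
    """
    base_a, key_a = _base_and_key(res_a)
    base_b, key_b = _base_and_key(res_b)
    edges = chem.edge_atoms(base_a, base_b, pair_type)
    if edges is None:
        raise ValueError(
            f"bases {base_a} ({key_a}) and {base_b} ({key_b}) are not "
            f"compatible with pair type {pair_type}")
    return PairRestraint(key_a, key_b, pair_type,
                         [(a, b, r0) for a, b in edges],
                         k_dist=k_dist, k_plane=k_plane, tag=tag)


def _base_and_key(res):
    if hasattr(res, "base"):
        return res.base, res.key
    base, key = res
    return base, tuple(key)


# ---------------------------------------------------------------------------
# compiled system
# ---------------------------------------------------------------------------

class CompiledSystem:
    """Restraint set compiled against one scene topology.

    Precomputes atom indices, exclusion lists, bonded terms and static
    neighbor candidates; evaluates energy + gradient as flat numpy ops.
    Valid as long as the scene's atom list (not its coordinates) is
    unchanged.
    """

    def __init__(self, scene: SceneModel, restraints: RestraintSet) -> None:
        self.restraints = restraints
        self.atom_keys = scene.atom_keys()
        self.index: Dict[AtomKey, int] = {k: i for i, k in enumerate(self.atom_keys)}
        self.n = len(self.atom_keys)
        self.elements = np.array([scene.atom(k).element for k in self.atom_keys])
        self.masses = np.array([chem.MASSES[e] for e in self.elements])
        self.heavy = self.elements != "H"
        res_keys: List[ResKey] = []
        seen: Dict[ResKey, int] = {}
        rid = []
        for k in self.atom_keys:
            rk = (k[0], k[1])
            if rk not in seen:
                seen[rk] = len(seen)
                res_keys.append(rk)
            rid.append(seen[rk])
        self.res_ids = np.array(rid, dtype=int)
        mobile_res = scene.flexible
        self.mobile = np.array([(k[0], k[1]) in mobile_res for k in self.atom_keys])
        self.x0 = scene.coords()

        self._bond_graph = self._build_bond_graph(scene)
        # nonbonded (LJ/Coulomb) exclusions: 1-2 and 1-3
        self._excl = self._exclusions(max_separation=2)
        # collision-sphere exclusions additionally drop 1-4 pairs, whose
        # torsion-adjacent contacts sit below the threshold in routine
        # backbone conformations
        self._excl_collision = self._exclusions(max_separation=3)
        self._compile_terms(scene)
        self._nb_candidates_built_for: Optional[np.ndarray] = None
        self._collision_pairs: Optional[np.ndarray] = None
        self._nb_pairs: Optional[np.ndarray] = None

    # ----------------------------------------------------------- topology
    def _build_bond_graph(self, scene: SceneModel):
        adj: List[set] = [set() for _ in range(self.n)]
        offset = 0
        chains = {}
        for res in scene.residues():
            for i, j in res.bonds:
                adj[offset + i].add(offset + j)
                adj[offset + j].add(offset + i)
            chains.setdefault(res.chain_id, []).append((res, offset))
            offset += len(res.atoms)
        # inter-residue backbone links O3'(i) - P(i+1) for consecutive numbering
        for chain_id, entries in chains.items():
            entries.sort(key=lambda e: e[0].seq_num)
            for (r1, o1), (r2, o2) in zip(entries, entries[1:]):
                if r2.seq_num != r1.seq_num + 1:
                    continue
                try:
                    i = o1 + r1.atom_names().index("O3'")
                    j = o2 + r2.atom_names().index("P")
                except ValueError:
                    continue
                adj[i].add(j)
                adj[j].add(i)
        return adj

    def _exclusions(self, max_separation: int = 2):
        """Set of frozenset index pairs separated by < 3 bonds (1-2, 1-3)."""
        excl = set()
        for i in range(self.n):
            frontier = {i}
            seen = {i}
            for _ in range(max_separation):
                nxt = set()
                for a in frontier:
                    nxt |= self._bond_graph[a]
                nxt -= seen
                for j in nxt:
                    excl.add((min(i, j), max(i, j)))
                seen |= nxt
                frontier = nxt
        return excl

    # ------------------------------------------------------------ compile
    def _compile_terms(self, scene: SceneModel) -> None:
        R = self.restraints
        idx = self._atom_index

        # distance springs (explicit + from pair restraints + stacking)
        si, sj, sr0, sk = [], [], [], []
        # coplanarity / parallelism plane terms: (tri_a(3), tri_b(3), k, sign_free)
        self._plane_terms: List[Tuple[np.ndarray, np.ndarray, float]] = []

        for p in R.pair_restraints:
            ra = scene.residue(p.residue_a)
            rb = scene.residue(p.residue_b)
            for a, b, r0 in p.atom_pairs:
                si.append(idx((*p.residue_a, a), f"pair restraint "
                              f"{p.residue_a}-{p.residue_b}"))
                sj.append(idx((*p.residue_b, b), f"pair restraint "
                              f"{p.residue_a}-{p.residue_b}"))
                sr0.append(r0)
                sk.append(p.k_dist * p.scale)
            if p.k_plane * p.scale > 0 and ra.base in chem.RING_ATOMS \
                    and rb.base in chem.RING_ATOMS:
                self._plane_terms.append((
                    self._ring_triple(scene, p.residue_a),
                    self._ring_triple(scene, p.residue_b),
                    p.k_plane * p.scale))

        for s in R.distance_springs:
            si.append(idx(s.atom_a, "distance spring"))
            sj.append(idx(s.atom_b, "distance spring"))
            sr0.append(s.r0)
            sk.append(s.k * s.scale)

        for s in R.stacks:
            ra = scene.residue(s.residue_a)
            rb = scene.residue(s.residue_b)
            for name in (chem.glycosidic_nitrogen(ra.base), "C1'"):
                name_b = chem.glycosidic_nitrogen(rb.base) if name != "C1'" else "C1'"
                i = idx((*s.residue_a, name), "stacking restraint")
                j = idx((*s.residue_b, name_b), "stacking restraint")
                si.append(i)
                sj.append(j)
                # built separation encodes the helical rise/twist target
                sr0.append(float(np.linalg.norm(self.x0[i] - self.x0[j])))
                sk.append(s.k * s.scale)
            if s.k_parallel * s.scale > 0 and ra.base in chem.RING_ATOMS \
                    and rb.base in chem.RING_ATOMS:
                self._plane_terms.append((
                    self._ring_triple(scene, s.residue_a),
                    self._ring_triple(scene, s.residue_b),
                    s.k_parallel * s.scale))

        self._spring_i = np.array(si, dtype=int)
        self._spring_j = np.array(sj, dtype=int)
        self._spring_r0 = np.array(sr0)
        self._spring_k = np.array(sk)

        # welds / positional anchors
        wi, wref, wk = [], [], []
        for w in R.welds:
            res = scene.residue(w.residue)
            base = 0
            for k_ in self.atom_keys:
                if (k_[0], k_[1]) == w.residue:
                    break
                base += 1
            ref = w.reference if w.reference is not None else res.coords()
            names = res.atom_names()
            for off in range(len(res.atoms)):
                if w.atoms is not None and names[off] not in w.atoms:
                    continue
                wi.append(base + off)
                wref.append(ref[off])
                wk.append(w.k * w.scale)
        self._weld_i = np.array(wi, dtype=int)
        self._weld_ref = np.array(wref).reshape(-1, 3)
        self._weld_k = np.array(wk)

        # physics zone membership + bonded terms
        self._zone_mask = np.zeros(self.n, dtype=bool)
        self._bonds_arr = np.empty((0, 2), dtype=int)
        self._angles_arr = np.empty((0, 3), dtype=int)
        self._dihedrals_arr = np.empty((0, 4), dtype=int)
        if R.physics is not None:
            self._compile_physics(scene, R.physics)

    def _atom_index(self, key: AtomKey, context: str) -> int:
        try:
            return self.index[key]
        except KeyError:
            raise KeyError(
                f"{context}: atom {key} not present in scene") from None

    def _ring_triple(self, scene: SceneModel, rk: ResKey) -> np.ndarray:
        res = scene.residue(rk)
        ring = chem.RING_ATOMS[res.base][:3]
        return np.array([self.index[(rk[0], rk[1], n)] for n in ring], dtype=int)

    def _compile_physics(self, scene: SceneModel, zone: PhysicsZone) -> None:
        center = scene.residue(zone.center)
        ccoords = center.coords()
        offset = 0
        for res in scene.residues():
            nat = len(res.atoms)
            rc = self.x0[offset:offset + nat]
            dmin = np.linalg.norm(
                rc[:, None, :] - ccoords[None, :, :], axis=-1).min()
            if dmin <= zone.radius:
                self._zone_mask[offset:offset + nat] = True
            offset += nat
        # charges / LJ tables
        base_of = {}
        for res in scene.residues():
            base_of[(res.chain_id, res.seq_num)] = res.base
        self._charges = np.array([
            chem.partial_charge(k[2], e, base_of.get((k[0], k[1])))
            for k, e in zip(self.atom_keys, self.elements)])
        self._lj_rmin2 = np.array([chem.LJ_PARAMS[e][0] for e in self.elements])
        self._lj_eps = np.array([chem.LJ_PARAMS[e][1] for e in self.elements])
        # 10-12 hydrogen-bond candidates: polar hydrogens vs acceptor N/O
        # (N atoms carrying a hydrogen do not accept)
        has_h = np.zeros(self.n, dtype=bool)
        for i in range(self.n):
            for j in self._bond_graph[i]:
                if self.elements[j] == "H":
                    has_h[i] = True
                    break
        polar_h = (self.elements == "H") \
            & (self._charges >= POLAR_H_MIN_CHARGE)
        acceptor = (self.elements == "O") \
            | ((self.elements == "N") & ~has_h)
        self._hb_donor_idx = np.where(polar_h & self._zone_mask)[0]
        self._hb_acceptor_idx = np.where(acceptor & self._zone_mask)[0]
        cand = []
        for h in self._hb_donor_idx:
            for a in self._hb_acceptor_idx:
                if not (self.mobile[h] or self.mobile[a]):
                    continue
                p = (min(int(h), int(a)), max(int(h), int(a)))
                if p in self._excl:
                    continue
                cand.append((h, a))
        self._hb_candidates = np.array(cand, dtype=int).reshape(-1, 2)

        if not zone.bonded:
            return
        # bonded terms among atoms with >= 1 mobile atom
        bonds, angles, dihedrals = [], [], []
        adj = self._bond_graph
        for i in range(self.n):
            for j in adj[i]:
                if i < j and (self.mobile[i] or self.mobile[j]):
                    bonds.append((i, j))
        for j in range(self.n):
            nb = sorted(adj[j])
            for ai in range(len(nb)):
                for bi in range(ai + 1, len(nb)):
                    i, k_ = nb[ai], nb[bi]
                    if self.mobile[i] or self.mobile[j] or self.mobile[k_]:
                        angles.append((i, j, k_))
        for j, k_ in [(a, b) for a in range(self.n) for b in adj[a] if a < b]:
            for i in adj[j]:
                if i == k_:
                    continue
                for l_ in adj[k_]:
                    if l_ == j or l_ == i:
                        continue
                    if (self.mobile[i] or self.mobile[j]
                            or self.mobile[k_] or self.mobile[l_]):
                        dihedrals.append((i, j, k_, l_))
        self._bonds_arr = np.array(bonds, dtype=int).reshape(-1, 2)
        self._angles_arr = np.array(angles, dtype=int).reshape(-1, 3)
        self._dihedrals_arr = np.array(dihedrals, dtype=int).reshape(-1, 4)
        # equilibrium values from the built geometry (idealized reference);
        # terms whose reference geometry is degenerate (near-linear angles,
        # dihedrals with vanishing plane normals) are dropped
        x = self.x0
        self._bond_r0 = np.linalg.norm(
            x[self._bonds_arr[:, 0]] - x[self._bonds_arr[:, 1]], axis=1)
        self._bond_k = np.full(len(self._bonds_arr), K_BOND)
        t0 = _angles(x, self._angles_arr)
        ok = np.abs(np.cos(t0)) < 0.999
        self._angles_arr = self._angles_arr[ok]
        self._angle_t0 = t0[ok]
        if len(self._dihedrals_arr):
            b1 = x[self._dihedrals_arr[:, 1]] - x[self._dihedrals_arr[:, 0]]
            b2 = x[self._dihedrals_arr[:, 2]] - x[self._dihedrals_arr[:, 1]]
            b3 = x[self._dihedrals_arr[:, 3]] - x[self._dihedrals_arr[:, 2]]
            n1 = np.linalg.norm(np.cross(b1, b2), axis=1)
            n2 = np.linalg.norm(np.cross(b2, b3), axis=1)
            ok = (n1 > 0.3) & (n2 > 0.3)
            self._dihedrals_arr = self._dihedrals_arr[ok]
        self._dih_p0 = _dihedrals(x, self._dihedrals_arr)

    # ------------------------------------------------------ neighbor lists
    def _candidate_pairs(self) -> np.ndarray:
        """Static candidate pair list: >= 1 mobile atom, exclusions removed."""
        if self._nb_candidates_built_for is not None:
            return self._nb_candidates_built_for
        mob = np.where(self.mobile)[0]
        allidx = np.arange(self.n)
        pairs = set()
        for i in mob:
            for j in allidx:
                if i == j:
                    continue
                a, b = (i, j) if i < j else (j, i)
                pairs.add((a, b))
        pairs -= self._excl
        arr = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
        self._nb_candidates_built_for = arr
        return arr

    def _static_candidates(self) -> None:
        """Split the raw candidate pairs into per-term static lists once."""
        if getattr(self, "_cand_static_done", False):
            return
        cand = self._candidate_pairs()
        R = self.restraints
        if R.collisions is not None:
            # collision spheres guard inter-residue sterics only; covalent
            # geometry within a residue is the job of the bonded terms,
            # and 1-4 neighbours are excluded as well
            keep = (self.heavy[cand[:, 0]] & self.heavy[cand[:, 1]]
                    & (self.res_ids[cand[:, 0]]
                       != self.res_ids[cand[:, 1]]))
            pairs = cand[keep]
            keep2 = np.array(
                [(int(a), int(b)) not in self._excl_collision
                 for a, b in pairs], dtype=bool) if len(pairs) else \
                np.zeros(0, dtype=bool)
            self._cand_coll = np.ascontiguousarray(pairs[keep2])
        else:
            self._cand_coll = np.empty((0, 2), dtype=int)
        if R.physics is not None:
            zm = self._zone_mask
            keep = zm[cand[:, 0]] & zm[cand[:, 1]]
            self._cand_nb = np.ascontiguousarray(cand[keep])
        else:
            self._cand_nb = np.empty((0, 2), dtype=int)
        self._cand_static_done = True

    @staticmethod
    def _mask_within(x, pairs, cutoff):
        if _K.HAVE_NUMBA:
            return _K.within_cutoff_mask(x, pairs, cutoff)
        d2 = np.sum((x[pairs[:, 0]] - x[pairs[:, 1]]) ** 2, axis=1)
        return d2 < cutoff * cutoff

    def refresh_neighbor_lists(self, x: np.ndarray) -> None:
        self._static_candidates()
        R = self.restraints
        if R.collisions is not None and len(self._cand_coll):
            mask = self._mask_within(
                x, self._cand_coll, R.collisions.r_thresh + NEIGHBOR_SKIN)
            self._collision_pairs = self._cand_coll[mask]
        else:
            self._collision_pairs = self._cand_coll
        if R.physics is not None:
            if len(self._cand_nb):
                mask = self._mask_within(
                    x, self._cand_nb, R.physics.cutoff + NEIGHBOR_SKIN)
                self._nb_pairs = self._cand_nb[mask]
            else:
                self._nb_pairs = self._cand_nb
            hb = self._hb_candidates
            if len(hb):
                mask = self._mask_within(x, hb, HB_CUTOFF + NEIGHBOR_SKIN)
                self._hb_pairs = hb[mask]
            else:
                self._hb_pairs = hb

    # ------------------------------------------------------------ evaluate
    def energy_gradient(self, x: np.ndarray,
                        refresh: bool = False) -> Tuple[float, np.ndarray]:
        """Total energy and gradient at coordinates ``x`` (N, 3).

        ``refresh`` forces a neighbor-list rebuild; dynamics refreshes
        periodically, one-shot evaluations should pass ``True`` (the first
        evaluation always builds the lists).
        """
        if refresh or (self._collision_pairs is None and self._nb_pairs is None):
            self.refresh_neighbor_lists(x)
        e = 0.0
        g = np.zeros_like(x)

        # springs
        if len(self._spring_i):
            if _K.HAVE_NUMBA:
                e += _K.spring_kernel(x, self._spring_i, self._spring_j,
                                      self._spring_r0, self._spring_k, g)
            else:
                d = x[self._spring_i] - x[self._spring_j]
                r = np.linalg.norm(d, axis=1)
                r = np.maximum(r, 1e-12)
                dev = r - self._spring_r0
                e += float(np.sum(self._spring_k * dev ** 2))
                coef = (2.0 * self._spring_k * dev / r)[:, None] * d
                _scatter(g, self._spring_i, coef)
                _scatter(g, self._spring_j, -coef)

        # coplanarity / parallelism
        if self._plane_terms:
            if not hasattr(self, "_plane_arr"):
                self._plane_arr = (
                    np.array([t[0] for t in self._plane_terms], dtype=int),
                    np.array([t[1] for t in self._plane_terms], dtype=int),
                    np.array([t[2] for t in self._plane_terms]))
            if _K.HAVE_NUMBA:
                e += _K.plane_kernel(x, *self._plane_arr, g)
            else:
                e_t, g_t = _plane_alignment_vec(x, *self._plane_arr)
                e += e_t
                g += g_t

        # welds to space
        if len(self._weld_i):
            d = x[self._weld_i] - self._weld_ref
            e += float(np.sum(self._weld_k * np.sum(d * d, axis=1)))
            _scatter(g, self._weld_i, (2.0 * self._weld_k)[:, None] * d)

        # collisions
        R = self.restraints
        if R.collisions is not None and self._collision_pairs is not None \
                and len(self._collision_pairs):
            c = R.collisions
            if _K.HAVE_NUMBA:
                e += _K.collision_kernel(x, self._collision_pairs,
                                         c.r_thresh, c.k_rep * c.scale, g)
            else:
                pi = self._collision_pairs[:, 0]
                pj = self._collision_pairs[:, 1]
                d = x[pi] - x[pj]
                r = np.linalg.norm(d, axis=1)
                mask = r < c.r_thresh
                if np.any(mask):
                    r_m = np.maximum(r[mask], 1e-12)
                    dev = c.r_thresh - r_m
                    kk = c.k_rep * c.scale
                    e += float(kk * np.sum(dev ** 2))
                    coef = (-2.0 * kk * dev / r_m)[:, None] * d[mask]
                    _scatter(g, pi[mask], coef)
                    _scatter(g, pj[mask], -coef)

        # physics zone
        if R.physics is not None:
            e_p, g_p = self._physics_energy(x, R.physics)
            e += e_p
            g += g_p

        g[~self.mobile] = 0.0
        return e, g

    def _physics_energy(self, x, zone: PhysicsZone):
        e = 0.0
        g = np.zeros_like(x)
        s = zone.scale
        if self._nb_pairs is not None and len(self._nb_pairs) \
                and (zone.lennard_jones or zone.coulomb):
            if _K.HAVE_NUMBA:
                e += _K.nb_kernel(x, self._nb_pairs, self._charges,
                                  self._lj_rmin2, self._lj_eps, zone.cutoff,
                                  zone.switch_on, zone.lennard_jones,
                                  zone.coulomb, chem.COULOMB_CONSTANT, s, g)
            else:
                pi, pj = self._nb_pairs[:, 0], self._nb_pairs[:, 1]
                d = x[pi] - x[pj]
                r = np.linalg.norm(d, axis=1)
                within = r < zone.cutoff
                pi, pj, d, r = pi[within], pj[within], d[within], r[within]
                r = np.maximum(r, 0.4)
                sw, dsw = _switch(r, zone.switch_on, zone.cutoff)
                e_pair = np.zeros_like(r)
                de_pair = np.zeros_like(r)  # dE/dr, unswitched pair energy
                if zone.lennard_jones:
                    rmin = self._lj_rmin2[pi] + self._lj_rmin2[pj]
                    eps = np.sqrt(self._lj_eps[pi] * self._lj_eps[pj])
                    q6 = (rmin / r) ** 6
                    e_pair += eps * (q6 * q6 - 2.0 * q6)
                    de_pair += eps * 12.0 * (q6 - q6 * q6) / r
                if zone.coulomb:
                    # eps(r) = 4r  =>  E = C q_i q_j / (4 r^2)
                    qq = chem.COULOMB_CONSTANT * self._charges[pi] \
                        * self._charges[pj] / 4.0
                    e_pair += qq / r ** 2
                    de_pair += -2.0 * qq / r ** 3
                e += s * float(np.sum(e_pair * sw))
                coef = (s * (de_pair * sw + e_pair * dsw) / r)[:, None] * d
                _scatter(g, pi, coef)
                _scatter(g, pj, -coef)

        if zone.hydrogen_bonds and getattr(self, "_hb_pairs", None) is not None \
                and len(self._hb_pairs):
            if _K.HAVE_NUMBA:
                e += _K.hb_kernel(x, self._hb_pairs, zone.hb_eps, zone.hb_r0,
                                  HB_CUTOFF, s, g)
            else:
                hi, ai = self._hb_pairs[:, 0], self._hb_pairs[:, 1]
                d = x[hi] - x[ai]
                r = np.maximum(np.linalg.norm(d, axis=1), 0.5)
                within = r < HB_CUTOFF
                hi, ai, d, r = hi[within], ai[within], d[within], r[within]
                q10 = (zone.hb_r0 / r) ** 10
                q12 = q10 * (zone.hb_r0 / r) ** 2
                e += s * zone.hb_eps * float(np.sum(5.0 * q12 - 6.0 * q10))
                de = s * zone.hb_eps * (-60.0 * q12 + 60.0 * q10) / r
                coef = (de / r)[:, None] * d
                _scatter(g, hi, coef)
                _scatter(g, ai, -coef)

        if zone.bonded and len(self._bonds_arr):
            if _K.HAVE_NUMBA:
                e += _K.spring_kernel(
                    x, np.ascontiguousarray(self._bonds_arr[:, 0]),
                    np.ascontiguousarray(self._bonds_arr[:, 1]),
                    self._bond_r0, self._bond_k * s, g)
                e += _K.angle_kernel(x, self._angles_arr, self._angle_t0,
                                     s * K_ANGLE, g)
                e += _K.dihedral_kernel(x, self._dihedrals_arr, self._dih_p0,
                                        s * K_DIHEDRAL, DIHEDRAL_PERIOD, g)
            else:
                bi, bj = self._bonds_arr[:, 0], self._bonds_arr[:, 1]
                d = x[bi] - x[bj]
                r = np.linalg.norm(d, axis=1)
                dev = r - self._bond_r0
                e += s * K_BOND * float(np.sum(dev ** 2))
                coef = (s * 2.0 * K_BOND * dev
                        / np.maximum(r, 1e-12))[:, None] * d
                _scatter(g, bi, coef)
                _scatter(g, bj, -coef)
                e_a, g_a = _angle_energy(x, self._angles_arr, self._angle_t0,
                                         s * K_ANGLE)
                e += e_a
                g += g_a
                e_d, g_d = _dihedral_energy(x, self._dihedrals_arr,
                                            self._dih_p0, s * K_DIHEDRAL)
                e += e_d
                g += g_d
        return e, g


# ---------------------------------------------------------------------------
# vectorized term math
# ---------------------------------------------------------------------------

def _scatter(g: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    n = g.shape[0]
    for c in range(3):
        g[:, c] += np.bincount(idx, weights=contrib[:, c], minlength=n)


def _switch(r, r_on, r_off):
    """CHARMM-style switching function and derivative."""
    sw = np.ones_like(r)
    dsw = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    if np.any(mid):
        rm = r[mid]
        r2, on2, off2 = rm ** 2, r_on ** 2, r_off ** 2
        denom = (off2 - on2) ** 3
        sw[mid] = (off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2) / denom
        dsw[mid] = (2 * (off2 - r2) * (-2 * rm) * (off2 + 2 * r2 - 3 * on2)
                    + (off2 - r2) ** 2 * 4 * rm) / denom
    sw[r >= r_off] = 0.0
    return sw, dsw


def _angles(x, arr):
    v1 = x[arr[:, 0]] - x[arr[:, 1]]
    v2 = x[arr[:, 2]] - x[arr[:, 1]]
    c = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return np.arccos(np.clip(c, -1.0, 1.0))


def _angle_energy(x, arr, t0, k):
    if not len(arr):
        return 0.0, np.zeros_like(x)
    i, j, l_ = arr[:, 0], arr[:, 1], arr[:, 2]
    v1 = x[i] - x[j]
    v2 = x[l_] - x[j]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    c = np.sum(v1 * v2, axis=1) / (n1 * n2)
    c = np.clip(c, -1.0 + 1e-10, 1.0 - 1e-10)
    theta = np.arccos(c)
    dev = theta - t0
    e = k * float(np.sum(dev ** 2))
    # dtheta/dv1 = -1/sin * d(cos)/dv1; sine floored to keep the gradient
    # bounded should an angle pass through linearity at runtime
    s = np.maximum(np.sqrt(1.0 - c ** 2), 1e-6)
    pref = (2.0 * k * dev / -s)
    dc_dv1 = v2 / (n1 * n2)[:, None] - (c / n1 ** 2)[:, None] * v1
    dc_dv2 = v1 / (n1 * n2)[:, None] - (c / n2 ** 2)[:, None] * v2
    g = np.zeros_like(x)
    gi = pref[:, None] * dc_dv1
    gl = pref[:, None] * dc_dv2
    _scatter(g, i, gi)
    _scatter(g, l_, gl)
    _scatter(g, j, -(gi + gl))
    return e, g


def _dihedrals(x, arr):
    b1 = x[arr[:, 1]] - x[arr[:, 0]]
    b2 = x[arr[:, 2]] - x[arr[:, 1]]
    b3 = x[arr[:, 3]] - x[arr[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    m1 = np.cross(n1, b2n)
    xx = np.sum(n1 * n2, axis=1)
    yy = np.sum(m1 * n2, axis=1)
    return np.arctan2(yy, xx)


def _dihedral_energy(x, arr, p0, k):
    """E = k (1 - cos(phi - phi0)) with the standard analytic gradient."""
    if not len(arr):
        return 0.0, np.zeros_like(x)
    i, j, k_, l_ = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    b1 = x[j] - x[i]
    b2 = x[k_] - x[j]
    b3 = x[l_] - x[k_]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    b2len = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / b2len[:, None])
    xx = np.sum(n1 * n2, axis=1)
    yy = np.sum(m1 * n2, axis=1)
    phi = np.arctan2(yy, xx)
    n_per = DIHEDRAL_PERIOD
    dev = n_per * (phi - p0)
    e = k * float(np.sum(1.0 - np.cos(dev)))
    dE = k * n_per * np.sin(dev)  # dV/dphi
    dE[(n1sq < 1e-8) | (n2sq < 1e-8)] = 0.0  # degenerate at runtime
    # dphi/dx (note n1 = -r_ij x r_kj and n2 = r_kj x r_kl in the usual
    # conventions; verified against central differences)
    dphi_i = (b2len / np.maximum(n1sq, 1e-12))[:, None] * n1
    dphi_l = -(b2len / np.maximum(n2sq, 1e-12))[:, None] * n2
    p = np.sum(-b1 * b2, axis=1) / b2len ** 2
    q = np.sum(-b3 * b2, axis=1) / b2len ** 2
    dphi_j = (p - 1.0)[:, None] * dphi_i - q[:, None] * dphi_l
    dphi_k = (q - 1.0)[:, None] * dphi_l - p[:, None] * dphi_i
    g = np.zeros_like(x)
    _scatter(g, i, dE[:, None] * dphi_i)
    _scatter(g, j, dE[:, None] * dphi_j)
    _scatter(g, k_, dE[:, None] * dphi_k)
    _scatter(g, l_, dE[:, None] * dphi_l)
    return e, g


def _cross(a, b):
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _plane_alignment_vec(x, tri_a, tri_b, k):
    """E = sum k (1 - (u.v)^2) over pairs of atom-triple plane normals."""
    g = np.zeros_like(x)
    pa = x[tri_a[:, 1]] - x[tri_a[:, 0]]
    qa = x[tri_a[:, 2]] - x[tri_a[:, 0]]
    pb = x[tri_b[:, 1]] - x[tri_b[:, 0]]
    qb = x[tri_b[:, 2]] - x[tri_b[:, 0]]
    na = _cross(pa, qa)
    nb = _cross(pb, qb)
    la = np.linalg.norm(na, axis=1)
    lb = np.linalg.norm(nb, axis=1)
    ua = na / la[:, None]
    ub = nb / lb[:, None]
    c = np.sum(ua * ub, axis=1)
    e = float(np.sum(k * (1.0 - c * c)))
    dE_dua = (-2.0 * k * c)[:, None] * ub
    dE_dub = (-2.0 * k * c)[:, None] * ua
    dE_dna = (dE_dua - ua * np.sum(dE_dua * ua, axis=1)[:, None]) / la[:, None]
    dE_dnb = (dE_dub - ub * np.sum(dE_dub * ub, axis=1)[:, None]) / lb[:, None]
    for tri, p, q, dE_dn in ((tri_a, pa, qa, dE_dna), (tri_b, pb, qb, dE_dnb)):
        dE_dp = _cross(q, dE_dn)
        dE_dq = _cross(dE_dn, p)
        _scatter(g, tri[:, 0], -(dE_dp + dE_dq))
        _scatter(g, tri[:, 1], dE_dp)
        _scatter(g, tri[:, 2], dE_dq)
    return e, g


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

_COMPILE_CACHE: Dict[int, Tuple[Tuple, CompiledSystem]] = {}


def compile_system(scene: SceneModel, restraints: RestraintSet) -> CompiledSystem:
    """Compile (with a small per-restraint-set cache keyed on scene topology)."""
    key = id(restraints)
    sig = (tuple(scene.atom_keys()), tuple(sorted(scene.flexible)))
    cached = _COMPILE_CACHE.get(key)
    if cached is not None and cached[0] == sig:
        return cached[1]
    comp = CompiledSystem(scene, restraints)
    _COMPILE_CACHE[key] = (sig, comp)
    if len(_COMPILE_CACHE) > 32:
        _COMPILE_CACHE.pop(next(iter(_COMPILE_CACHE)))
    return comp


def total_energy(scene: SceneModel,
                 restraints: RestraintSet) -> Tuple[float, np.ndarray]:
    """Total energy (kcal/mol) and gradient over all atoms at the scene's
    current coordinates.  Gradient rows of rigid-residue atoms are zero."""
    comp = compile_system(scene, restraints)
    return comp.energy_gradient(scene.coords(), refresh=True)


def collision_energy(scene: SceneModel,
                     spheres: Optional[CollisionSphereSet] = None,
                     include_rigid: bool = True) -> Tuple[float, np.ndarray]:
    """Collision-sphere energy over all heavy-atom pairs of the scene.

    E = sum k_rep (r_thresh - r)^2 over inter-residue heavy-atom pairs with
    r < r_thresh, excluding pairs separated by fewer than 4 bonds (the
    backbone bridge and torsion-adjacent 1-4 contacts).  Unlike the compiled fast path (which skips constant
    rigid-rigid interactions), this standalone evaluation covers every pair
    when ``include_rigid`` is set.
    """
    spheres = spheres or CollisionSphereSet()
    comp = CompiledSystem(scene, RestraintSet(collisions=spheres))
    x = scene.coords()
    heavy = np.where(comp.heavy)[0]
    e = 0.0
    g = np.zeros_like(x)
    hx = x[heavy]
    d = np.linalg.norm(hx[:, None, :] - hx[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(heavy), k=1)
    close = d[iu, ju] < spheres.r_thresh
    for a, b in zip(iu[close], ju[close]):
        i, j = int(heavy[a]), int(heavy[b])
        if (min(i, j), max(i, j)) in comp._excl_collision:
            continue
        if comp.res_ids[i] == comp.res_ids[j]:
            continue
        if not include_rigid and not (comp.mobile[i] or comp.mobile[j]):
            continue
        dv = x[i] - x[j]
        r = max(float(np.linalg.norm(dv)), 1e-12)
        dev = spheres.r_thresh - r
        kk = spheres.k_rep * spheres.scale
        e += kk * dev ** 2
        coef = -2.0 * kk * dev / r
        g[i] += coef * dv
        g[j] -= coef * dv
    return e, g
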
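"""Idealized nucleotide geometry templates.

A :class:`GeometryTemplate` carries, for each base A/C/G/U:

* reference all-atom coordinates (ideal component geometry from the PDB
  chemical component dictionary bundled with biotite), canonicalized into a
  base-fixed frame,
* the intra-residue bond topology,
* a derived internal-coordinate (z-matrix) table, from which the residue
  can be rebuilt atom by atom (used for mutation placement),
* A-form helical parameters (rise/twist) and numerically solved rigid
  pair transforms that place a complementary base into Watson-Crick or
  wobble pairing geometry.

The pair transforms are obtained by least squares on the canonical
donor-acceptor edge distances (2.9 A) plus a weak C1'-C1' regularizer, so
built duplexes satisfy hydrogen-bond distance criteria by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.optimize import minimize

from . import chem
from .geometry import place_atom
from .model import AtomRecord, Residue

# atoms present in the free-nucleotide component files but not in a
# chain-internal residue of our model
_DROP_ATOMS = {"OP3", "HOP3", "HOP2", "HO3'", "HO5'"}

#: solved backbone-calibration parameters for the default helical
#: parameters (rise 2.81 A, twist 32.7 deg): per-base (chi, gamma) bond
#: rotations in the order A, C, G, U, then the in-plane axis offset (x, y).
#: See :meth:`GeometryTemplate.calibrate_backbone`.
_FROZEN_BACKBONE_PARAMS = (
    -0.72950778, -6.3280968,
    1.90737741, -0.22953828,
    -0.70861187, -0.10753344,
    1.97217255, 5.97706682,
    -0.12403079, 4.89731445,
)


def _load_component(base: str):
    """Ideal coordinates + bonds for one RNA component, trimmed for chain use."""
    import biotite.structure.info as info

    arr = info.residue(base)
    keep = np.array([n not in _DROP_ATOMS for n in arr.atom_name])
    idx_map = {}
    names, elements, coords = [], [], []
    for i, k in enumerate(keep):
        if k:
            idx_map[i] = len(names)
            names.append(str(arr.atom_name[i]))
            elements.append(str(arr.element[i]).capitalize())
            coords.append(arr.coord[i].astype(float))
    bonds = []
    for i, j, _ in arr.bonds.as_array():
        if keep[i] and keep[j]:
            bonds.append((idx_map[int(i)], idx_map[int(j)]))
    coords = np.array(coords)
    if base == "G":
        # enforce the convention that H21 is the Watson-Crick-edge amino
        # proton (cis to N1, donating to the partner O2); the component
        # ideal coordinates have the two amino protons the other way round
        i21, i22 = names.index("H21"), names.index("H22")
        coords[[i21, i22]] = coords[[i22, i21]]
    return names, elements, coords, bonds


def base_frame(names: List[str], coords: np.ndarray, base: str):
    """Base-fixed orthonormal frame (origin, 3x3 rows = x,y,z axes).

    Origin at the glycosidic nitrogen; x toward a fixed ring atom; z normal
    to the base plane with a consistent face convention per base family.
    """
    lookup = {n: coords[i] for i, n in enumerate(names)}
    gn = chem.glycosidic_nitrogen(base)
    if base in chem.PURINES:
        a_ref, b_ref = "C4", "C8"
    else:
        a_ref, b_ref = "C2", "C6"
    origin = lookup[gn]
    u = lookup[a_ref] - origin
    v = lookup[b_ref] - origin
    z = np.cross(u, v)
    z /= np.linalg.norm(z)
    x = u - np.dot(u, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return origin, np.array([x, y, z])


def _to_frame(coords: np.ndarray, origin, axes) -> np.ndarray:
    return (coords - origin) @ axes.T


@dataclass
class ZMatrixEntry:
    """One internal-coordinate placement: atom from three reference atoms."""

    name: str
    refs: Tuple[str, str, str]  # (r3, r2, r1): bonded to r1
    bond: float
    angle: float
    dihedral: float


@dataclass
class BaseTemplate:
    base: str
    names: List[str]
    elements: List[str]
    coords: np.ndarray                     # canonical base-frame coordinates
    bonds: List[Tuple[int, int]]
    zmatrix: List[ZMatrixEntry] = field(default_factory=list)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def make_residue(self, chain_id: str, seq_num: int) -> Residue:
        atoms = [AtomRecord(n, e, c.copy())
                 for n, e, c in zip(self.names, self.elements, self.coords)]
        return Residue(chain_id, seq_num, self.base, atoms, list(self.bonds))


def _derive_zmatrix(tmpl: BaseTemplate) -> List[ZMatrixEntry]:
    """Derive a z-matrix rooted at the glycosidic nitrogen via BFS over bonds."""
    from .geometry import angle as angle_of, dihedral as dihedral_of

    nbrs: Dict[str, List[str]] = {n: [] for n in tmpl.names}
    for i, j in tmpl.bonds:
        nbrs[tmpl.names[i]].append(tmpl.names[j])
        nbrs[tmpl.names[j]].append(tmpl.names[i])
    for v in nbrs.values():
        v.sort()
    root = chem.glycosidic_nitrogen(tmpl.base)
    order = [root]
    seen = {root}
    queue = [root]
    while queue:
        cur = queue.pop(0)
        for nb in nbrs[cur]:
            if nb not in seen:
                seen.add(nb)
                order.append(nb)
                queue.append(nb)
    pos = {n: tmpl.coords[tmpl.names.index(n)] for n in tmpl.names}
    placed: List[str] = []
    entries: List[ZMatrixEntry] = []
    parent: Dict[str, str] = {}
    for n in order[1:]:
        for nb in nbrs[n]:
            if nb in order[:order.index(n)]:
                parent[n] = nb
                break
    for k, n in enumerate(order):
        if k == 0:
            entries.append(ZMatrixEntry(n, ("", "", ""), 0.0, 0.0, 0.0))
        elif k == 1:
            entries.append(ZMatrixEntry(
                n, ("", "", order[0]),
                float(np.linalg.norm(pos[n] - pos[order[0]])), 0.0, 0.0))
        elif k == 2:
            r1 = parent.get(n, order[1])
            r2 = order[0] if r1 != order[0] else order[1]
            entries.append(ZMatrixEntry(
                n, ("", r2, r1),
                float(np.linalg.norm(pos[n] - pos[r1])),
                angle_of(pos[r2], pos[r1], pos[n]), 0.0))
        else:
            r1 = parent.get(n, placed[-1])
            # r2: a placed neighbor of r1 other than n
            r2 = next(x for x in ([parent.get(r1)] + nbrs[r1] + placed)
                      if x and x in placed and x != n and x != r1)
            r3 = next(x for x in ([parent.get(r2)] + nbrs[r2] + placed)
                      if x and x in placed and x not in (r1, r2, n))
            entries.append(ZMatrixEntry(
                n, (r3, r2, r1),
                float(np.linalg.norm(pos[n] - pos[r1])),
                angle_of(pos[r2], pos[r1], pos[n]),
                dihedral_of(pos[r3], pos[r2], pos[r1], pos[n])))
        placed.append(n)
    return entries


def rebuild_from_zmatrix(entries: List[ZMatrixEntry]) -> Dict[str, np.ndarray]:
    """Rebuild atom positions from a z-matrix (NeRF); arbitrary global frame."""
    pos: Dict[str, np.ndarray] = {}
    for k, e in enumerate(entries):
        if k == 0:
            pos[e.name] = np.zeros(3)
        elif k == 1:
            pos[e.name] = np.array([e.bond, 0.0, 0.0])
        elif k == 2:
            a = np.deg2rad(e.angle)
            r1, r2 = pos[e.refs[2]], pos[e.refs[1]]
            d = r2 - r1
            d /= np.linalg.norm(d)
            perp = np.array([-d[1], d[0], 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.array([0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            pos[e.name] = r1 + e.bond * (np.cos(a) * d + np.sin(a) * perp)
        else:
            pos[e.name] = place_atom(
                pos[e.refs[0]], pos[e.refs[1]], pos[e.refs[2]],
                e.bond, e.angle, e.dihedral)
    return pos


class GeometryTemplate:
    """Idealized construction geometry for the RNA builder.

    Parameters
    ----------
    rise, twist:
        A-form helical rise (A) and twist (deg); must be physically
        plausible (2-4 A, 30-35 deg).
    pair_target:
        target donor-acceptor distance for built base pairs (A).
    """

    def __init__(self, rise: float = 2.81, twist: float = 32.7,
                 pair_target: float = chem.CANONICAL_DA) -> None:
        if not (2.0 <= rise <= 4.0):
            raise ValueError(f"A-form rise {rise} outside plausible 2-4 A")
        if not (30.0 <= twist <= 35.0):
            raise ValueError(f"A-form twist {twist} outside plausible 30-35 deg")
        self.rise = float(rise)
        self.twist = float(twist)
        self.pair_target = float(pair_target)
        self.bases: Dict[str, BaseTemplate] = {}
        for base in "ACGU":
            names, elements, coords, bonds = _load_component(base)
            origin, axes = base_frame(names, coords, base)
            tmpl = BaseTemplate(base, names, elements,
                                _to_frame(coords, origin, axes), bonds)
            tmpl.zmatrix = _derive_zmatrix(tmpl)
            self.bases[base] = tmpl
        self._pair_cache: Dict[Tuple[str, str, str], Tuple[np.ndarray, np.ndarray]] = {}

    # ------------------------------------------------------------- residues
    def base_template(self, base: str) -> BaseTemplate:
        if base not in self.bases:
            raise ValueError(f"unknown base code {base!r} (expected A, C, G or U)")
        return self.bases[base]

    # -------------------------------------------------------- pair geometry
    def pair_transform(self, base_a: str, base_b: str,
                       pair_type: str = "WC") -> Tuple[np.ndarray, np.ndarray]:
        """Rigid transform placing base_b's template opposite base_a.

        Returns ``(R, t)`` with partner coordinates ``X @ R.T + t`` expressed
        in base_a's canonical frame.  Solved once per (base_a, base_b,
        pair_type) by least squares on the edge-atom distances; the partner
        stays coplanar with base_a (flip about the in-plane x axis, then
        in-plane rotation + translation).
        """
        key = (base_a, base_b, pair_type)
        if key in self._pair_cache:
            return self._pair_cache[key]
        edges = chem.edge_atoms(base_a, base_b, pair_type)
        if edges is None:
            raise ValueError(
                f"bases {base_a} and {base_b} are incompatible with {pair_type}")
        hbonds = chem.edge_hbonds(base_a, base_b, pair_type)
        ta, tb = self.base_template(base_a), self.base_template(base_b)
        c1a = ta.coords[ta.index("C1'")]
        ic1b = tb.index("C1'")
        target = self.pair_target
        flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: z -> -z

        def solve(base_mat):
            xb = tb.coords @ base_mat.T

            def cost(params):
                th, tx, ty = params
                c, s = np.cos(th), np.sin(th)
                R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
                xb_r = xb @ R.T + np.array([tx, ty, 0.0])
                res = []
                for na, nb, hname, hside in hbonds:
                    p_a = ta.coords[ta.index(na)]
                    p_b = xb_r[tb.index(nb)]
                    res.append(np.linalg.norm(p_a - p_b) - target)
                    # hydrogen-acceptor distance selects near-linear
                    # donor-H...acceptor geometry (and the correct branch)
                    if hside == "a":
                        p_h, p_acc = ta.coords[ta.index(hname)], p_b
                    else:
                        p_h, p_acc = xb_r[tb.index(hname)], p_a
                    res.append(0.7 * (np.linalg.norm(p_h - p_acc) - (target - 1.0)))
                # weak regularizer: C1'-C1' distance ~ 10.4 A (canonical width)
                res.append(0.3 * (np.linalg.norm(c1a - xb_r[ic1b]) - 10.4))
                return float(np.sum(np.square(res)))

            best = None
            for th0 in np.linspace(0.0, 2 * np.pi, 12, endpoint=False):
                sol = minimize(cost, x0=[th0, 5.0, 5.0], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-14,
                                        "maxiter": 4000})
                if best is None or sol.fun < best.fun:
                    best = sol
            return best

        # the physically correct branch (flipped or not, depending on the
        # canonical-frame handedness conventions of the two bases) yields
        # near-linear hydrogen bonds; the wrong branch cannot
        sols = [(solve(m), m) for m in (flip, np.eye(3))]
        sols.sort(key=lambda sm: sm[0].fun)
        best, mat = sols[0]
        th, tx, ty = best.x
        c, s = np.cos(th), np.sin(th)
        Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        R = Rz @ mat
        t = np.array([tx, ty, 0.0])
        self._pair_cache[key] = (R, t)
        return R, t

    # ------------------------------------------------- backbone calibration
    def _subtree(self, tmpl: BaseTemplate, a: str, b: str):
        """Atom names on the b side when bond a-b is cut (excluding a, b)."""
        import collections
        adj = collections.defaultdict(set)
        for i, j in tmpl.bonds:
            adj[tmpl.names[i]].add(tmpl.names[j])
            adj[tmpl.names[j]].add(tmpl.names[i])
        seen, queue = {a, b}, [b]
        while queue:
            cur = queue.pop()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        seen.discard(a)
        seen.discard(b)
        return seen

    def _rotate_about_bond(self, tmpl: BaseTemplate, coords: np.ndarray,
                           a: str, b: str, delta: float) -> np.ndarray:
        ia, ib = tmpl.index(a), tmpl.index(b)
        axis = coords[ib] - coords[ia]
        axis /= np.linalg.norm(axis)
        idx = [tmpl.index(n) for n in self._subtree(tmpl, a, b)]
        c, s = np.cos(delta), np.sin(delta)
        K = np.array([[0.0, -axis[2], axis[1]],
                      [axis[2], 0.0, -axis[0]],
                      [-axis[1], axis[0], 0.0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
        out = coords.copy()
        out[idx] = (coords[idx] - coords[ib]) @ R.T + coords[ib]
        return out

    def calibrate_backbone(self, resolve: bool = False) -> None:
        """Orient sugars (per-base chi, gamma) and place the helix axis.

        The free-nucleotide components carry arbitrary glycosidic and
        backbone torsions.  This applies, per base, rotations about the
        glycosidic and C4'-C5' bonds plus an in-plane helix-axis offset
        such that, in a stacked duplex, each O5' sits at phosphate-bridging
        distance (~2.56 A) from the previous residue's O3' while all
        nonbonded heavy-atom contacts stay above the collision threshold.
        Phosphates themselves are re-bridged exactly at build time.

        The parameters for the default rise/twist were solved once (by the
        least-squares procedure below) and are frozen; pass ``resolve=True``
        to re-solve, e.g. after changing the helical parameters.
        Deterministic; called lazily by the builder.
        """
        if getattr(self, "_calibrated", False):
            return
        order = "ACGU"
        if not resolve:
            params = np.array(_FROZEN_BACKBONE_PARAMS)
            for k, b in enumerate(order):
                tmpl = self.base_template(b)
                gn = chem.glycosidic_nitrogen(b)
                c = self._rotate_about_bond(tmpl, tmpl.coords, gn, "C1'",
                                            params[2 * k])
                tmpl.coords = self._rotate_about_bond(tmpl, c, "C4'", "C5'",
                                                      params[2 * k + 1])
                tmpl.zmatrix = _derive_zmatrix(tmpl)
            self.axis_offset = np.array([params[8], params[9], 0.0])
            self._calibrated = True
            return

        def modded(params):
            out = {}
            for k, b in enumerate(order):
                tmpl = self.base_template(b)
                gn = chem.glycosidic_nitrogen(b)
                c = self._rotate_about_bond(tmpl, tmpl.coords, gn, "C1'",
                                            params[2 * k])
                c = self._rotate_about_bond(tmpl, c, "C4'", "C5'",
                                            params[2 * k + 1])
                out[b] = c
            return out

        seq5, seq3 = "GACU", "AGUC"

        def stack(params):
            mods = modded(params)
            off = np.array([params[8], params[9], 0.0])
            tw = np.deg2rad(self.twist)
            s1, s2 = [], []
            n = len(seq5)
            for i in range(n):
                a, b = seq5[i], seq3[n - 1 - i]
                ta, tb = self.base_template(a), self.base_template(b)
                pt = "WC" if chem.edge_atoms(a, b, "WC") else "wobble"
                R, tr = self.pair_transform(a, b, pt)
                O, M = self.pair_frame(a, b, pt)
                Xa = (mods[a] - O) @ M.T
                Xb = ((mods[b] @ R.T + tr) - O) @ M.T
                c, s = np.cos(i * tw), np.sin(i * tw)
                Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
                z = np.array([0.0, 0.0, i * self.rise])
                s1.append((ta, (Xa - off) @ Rz.T + z))
                s2.append((tb, (Xb - off) @ Rz.T + z))
            return s1, s2

        bridge_t = 2.56  # O3'...O5' distance giving ~106 deg at the phosphate

        def residual_vector(params):
            s1, s2 = stack(params)
            n = len(s1)
            res = []
            for i in range(n - 1):
                o3 = s1[i][1][s1[i][0].index("O3'")]
                o5 = s1[i + 1][1][s1[i + 1][0].index("O5'")]
                res.append(np.linalg.norm(o3 - o5) - bridge_t)
                o3 = s2[i + 1][1][s2[i + 1][0].index("O3'")]
                o5 = s2[i][1][s2[i][0].index("O5'")]
                res.append(np.linalg.norm(o3 - o5) - bridge_t)
            labels = [("s1", i) for i in range(n)] + [("s2", i) for i in range(n)]
            allres = list(zip(labels, s1 + s2))
            skip = {"P", "OP1", "OP2"}
            for i in range(len(allres)):
                (si_, ri), (ti_, Xi) = allres[i]
                hi = [k for k, e in enumerate(ti_.elements)
                      if e != "H" and ti_.names[k] not in skip]
                for j in range(i + 1, len(allres)):
                    (sj_, rj), (tj_, Xj) = allres[j]
                    hj = [k for k, e in enumerate(tj_.elements)
                          if e != "H" and tj_.names[k] not in skip]
                    D = np.linalg.norm(
                        Xi[hi][:, None, :] - Xj[hj][None, :, :], axis=-1)
                    if si_ == sj_ and abs(ri - rj) == 1:
                        # bridging O3'/O5' become 1-3 neighbours through P
                        for a_, na in enumerate(hi):
                            for b_, nb in enumerate(hj):
                                if {ti_.names[na], tj_.names[nb]} == {"O3'", "O5'"}:
                                    D[a_, b_] = np.inf
                    res.append(2.0 * max(0.0, 2.7 - float(D.min())))
            return np.array(res)

        from scipy.optimize import least_squares
        rng = np.random.default_rng(20090745)
        best = None
        for _ in range(12):
            x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 8),
                                 rng.uniform(-4.0, 4.0, 2)])
            sol = least_squares(residual_vector, x0, method="lm",
                                xtol=1e-12, ftol=1e-12, max_nfev=4000)
            if best is None or sol.cost < best.cost:
                best = sol
        params = best.x
        mods = modded(params)
        for b in order:
            self.bases[b].coords = mods[b]
            self.bases[b].zmatrix = _derive_zmatrix(self.bases[b])
        self.axis_offset = np.array([params[8], params[9], 0.0])
        self._calibration_residual = float(best.cost)
        self._calibrated = True

    # ------------------------------------------------------------ pair frame
    def pair_frame(self, base_a: str, base_b: str, pair_type: str = "WC"):
        """Frame of a built pair, in base_a canonical coordinates.

        Origin at the C1'-C1' midpoint, x along C1'(a)->C1'(b), z the base
        normal of base_a, y completing the right-handed set.  Used as the
        common anchor when stacking pairs into a helix.
        """
        ta, tb = self.base_template(base_a), self.base_template(base_b)
        R, t = self.pair_transform(base_a, base_b, pair_type)
        c1a = ta.coords[ta.index("C1'")]
        c1b = tb.coords[tb.index("C1'")] @ R.T + t
        origin = 0.5 * (c1a + c1b)
        x = c1b - c1a
        z = np.array([0.0, 0.0, 1.0])
        x = x - np.dot(x, z) * z
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        return origin, np.array([x, y, z])
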
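"""Synthetic construction of the reduced codon-anticodon system.

Builds idealized all-atom coordinates for the A-site anticodon stem-loop
(tRNA residues 26-44), an mRNA codon with flanking bases, and optional
surrogate fragments, entirely from geometry templates -- no deposited
structures are required.  Also applies base substitutions with
like-named-atom semantics: atoms whose names occur in both bases keep
their positions bit-identically, new atoms are placed from the template's
internal coordinates anchored on the shared atoms.

Chains: ``T`` tRNA ASL, ``M`` mRNA, ``L`` large-subunit surrogate (A1913),
``R`` monitor bases, ``P`` S13 C-terminal tail beads.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from . import chem
from .geometry import superpose
from .model import AtomRecord, Residue, ResKey, SceneModel
from .restraints import (CollisionSphereSet, DistanceSpring, PairRestraint,
                         PhysicsZone, RestraintSet, StackRestraint,
                         WeldConstraint, make_basepair_restraint)
from .templates import BaseTemplate, GeometryTemplate

Transform = Tuple[np.ndarray, np.ndarray]  # (R, t): x -> x @ R.T + t

# phosphodiester geometry for the bridge placement
P_O5 = 1.60
P_O3 = 1.59
P_OP = 1.48
OP_ANGLE = np.deg2rad(119.6)

#: scenario identifiers accepted by :func:`build_scenario`
SCENARIO_NAMES = ("cognate", "u36", "u36c", "u36c_g1a", "grapple")

# tRNA ASL sequences, residues 26..44 (5'->3'); anticodon at 34-36
ASL_SER3 = "CAGGGCCUGCUAAGCCCUG"   # anticodon GCU (reads 34->36)
ASL_ALA = "CAGGGCCUUGCAAGCCCUG"    # anticodon UGC (cognate for GCA)
MRNA_SEQ = "AGCAG"                 # residues 18..22; codon GCA at 19-21


@lru_cache(maxsize=2)
def default_template() -> GeometryTemplate:
    """Shared calibrated template instance."""
    t = GeometryTemplate()
    t.calibrate_backbone()
    return t


# ---------------------------------------------------------------------------
# elementary construction
# ---------------------------------------------------------------------------

def _identity() -> Transform:
    return np.eye(3), np.zeros(3)


def compose(first: Transform, then: Transform) -> Transform:
    """Transform applying ``first`` and then ``then``."""
    R1, t1 = first
    R2, t2 = then
    return R2 @ R1, t1 @ R2.T + t2


def invert(tf: Transform) -> Transform:
    R, t = tf
    return R.T, -t @ R


def _place(tmpl: BaseTemplate, chain_id: str, seq_num: int,
           tf: Transform) -> Residue:
    res = tmpl.make_residue(chain_id, seq_num)
    R, t = tf
    res.set_coords(tmpl.coords @ R.T + t)
    return res


def build_nucleotide(base: str, template: Optional[GeometryTemplate] = None,
                     chain_id: str = "X", seq_num: int = 1) -> Residue:
    """A single idealized nucleotide with full heavy-atom + hydrogen set."""
    template = template or default_template()
    tmpl = template.base_template(base)
    return _place(tmpl, chain_id, seq_num, _identity())


def residue_transform(res: Residue,
                      template: Optional[GeometryTemplate] = None) -> Transform:
    """Rigid transform mapping the base template onto a built residue.

    Uses base-ring + C1' atoms (never the re-bridged phosphate group), so it
    recovers the exact placement used at construction time.
    """
    template = template or default_template()
    tmpl = template.base_template(res.base)
    names = chem.RING_ATOMS[res.base] + ["C1'"]
    src = np.array([tmpl.coords[tmpl.index(n)] for n in names])
    dst = np.array([res.atom(n).position for n in names])
    R, t, _ = superpose(src, dst)
    return R, t


def bridge_phosphates(residues: List[Residue]) -> None:
    """Re-place P/OP1/OP2 of each residue after the first so the backbone
    O3'(i)-P(i+1)-O5'(i+1) is chemically bonded.

    P is put at the intersection of spheres around O5' (1.60 A) and the
    previous O3' (1.59 A), picking deterministically the solution that
    maximizes the C5'-O5'-P angle; OP1/OP2 complete the phosphate
    tetrahedron.  Falls back to a stretched placement when the gap exceeds
    bonding reach (loose loop starting structures).
    """
    for prev, cur in zip(residues, residues[1:]):
        o3 = prev.atom("O3'").position
        o5 = cur.atom("O5'").position
        c5 = cur.atom("C5'").position
        # surrounding heavy atoms the phosphate group must stay clear of
        env = np.array([a.position for r in (prev, cur) for a in r.atoms
                        if a.element != "H"
                        and a.name not in ("P", "OP1", "OP2", "O3'", "O5'")])
        d = o3 - o5
        dist = float(np.linalg.norm(d))

        def op_positions(p_pos):
            v1 = (o5 - p_pos) / np.linalg.norm(o5 - p_pos)
            v2 = (o3 - p_pos) / np.linalg.norm(o3 - p_pos)
            bis = -(v1 + v2)
            nb = np.linalg.norm(bis)
            bis = bis / nb if nb > 1e-8 else np.array([0.0, 0.0, 1.0])
            nrm = np.cross(v1, v2)
            nn = np.linalg.norm(nrm)
            nrm = nrm / nn if nn > 1e-8 else np.array([1.0, 0.0, 0.0])
            half = OP_ANGLE / 2.0
            op1 = p_pos + P_OP * (np.cos(half) * bis + np.sin(half) * nrm)
            op2 = p_pos + P_OP * (np.cos(half) * bis - np.sin(half) * nrm)
            return op1, op2

        if dist >= P_O5 + P_O3:
            # stretched fallback: P near the segment, offset sideways so
            # the O5'-P-O3' angle stays well-defined (no colinear bonded
            # geometry downstream)
            mid = o5 + d * (P_O5 / (P_O5 + P_O3))
            perp = np.cross(d, o5 - c5)
            npnorm = np.linalg.norm(perp)
            if npnorm < 1e-8:
                perp = np.cross(d, np.array([1.0, 0.0, 0.0]))
                npnorm = np.linalg.norm(perp)
            p_pos = mid + 0.4 * perp / npnorm
        else:
            # sphere-sphere intersection circle; scan the circle for the
            # rotamer keeping the phosphate clear of both sugars
            a = (P_O5 ** 2 - P_O3 ** 2 + dist ** 2) / (2 * dist)
            h = np.sqrt(max(P_O5 ** 2 - a ** 2, 0.0))
            u = d / dist
            center = o5 + a * u
            ref = o5 - c5
            ref = ref - np.dot(ref, u) * u
            nr = np.linalg.norm(ref)
            if nr < 1e-8:
                ref = np.array([1.0, 0.0, 0.0])
                ref -= np.dot(ref, u) * u
                nr = np.linalg.norm(ref)
            ref /= nr
            ref2 = np.cross(u, ref)
            phi = np.linspace(0.0, 2.0 * np.pi, 144, endpoint=False)
            cands = (center[None, :]
                     + h * np.cos(phi)[:, None] * ref[None, :]
                     + h * np.sin(phi)[:, None] * ref2[None, :])
            v1 = c5 - o5
            v2 = cands - o5
            cosang = (v2 @ v1) / (np.linalg.norm(v1)
                                  * np.linalg.norm(v2, axis=1))
            ang = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
            w1 = o5[None, :] - cands
            w1 /= np.linalg.norm(w1, axis=1)[:, None]
            w2 = o3[None, :] - cands
            w2 /= np.linalg.norm(w2, axis=1)[:, None]
            bis = -(w1 + w2)
            bn = np.linalg.norm(bis, axis=1)[:, None]
            bis = np.where(bn > 1e-8, bis / np.maximum(bn, 1e-8),
                           np.array([0.0, 0.0, 1.0]))
            nrm = np.cross(w1, w2)
            nn = np.linalg.norm(nrm, axis=1)[:, None]
            nrm = np.where(nn > 1e-8, nrm / np.maximum(nn, 1e-8),
                           np.array([1.0, 0.0, 0.0]))
            half = OP_ANGLE / 2.0
            op1s = cands + P_OP * (np.cos(half) * bis + np.sin(half) * nrm)
            op2s = cands + P_OP * (np.cos(half) * bis - np.sin(half) * nrm)
            group = np.stack([cands, op1s, op2s], axis=1)  # (144,3,3)
            score = np.linalg.norm(
                group[:, :, None, :] - env[None, None, :, :],
                axis=-1).min(axis=(1, 2))
            best_idx = None
            for lo, hi in ((90.0, 140.0), (80.0, 155.0), (0.0, 180.0)):
                ok = (ang >= lo) & (ang <= hi)
                if np.any(ok):
                    masked = np.where(ok, score, -np.inf)
                    best_idx = int(np.argmax(masked))
                    break
            p_pos = cands[best_idx] if best_idx is not None \
                else center + h * ref
        cur.atom("P").position = p_pos
        op1, op2 = op_positions(p_pos)
        cur.atom("OP1").position = op1
        cur.atom("OP2").position = op2


def _pair_type(base_a: str, base_b: str) -> str:
    if chem.edge_atoms(base_a, base_b, "WC") is not None:
        return "WC"
    if chem.edge_atoms(base_a, base_b, "wobble") is not None:
        return "wobble"
    raise ValueError(f"bases {base_a}/{base_b} are not complementary")


def _helix_pair_transforms(template: GeometryTemplate, base_a: str,
                           base_b: str, level: int) -> Tuple[Transform, Transform]:
    """Global transforms for the two bases of pair ``level`` in a duplex
    whose axis is the global z axis (pair 0 at z = 0)."""
    pt = _pair_type(base_a, base_b)
    Rp, tp = template.pair_transform(base_a, base_b, pt)
    O, M = template.pair_frame(base_a, base_b, pt)
    off = template.axis_offset
    tw = np.deg2rad(template.twist) * level
    c, s = np.cos(tw), np.sin(tw)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    zshift = np.array([0.0, 0.0, template.rise * level])
    # frame -> helix:  y = ((x - O) @ M.T - off) @ Rz.T + zshift
    frame_tf: Transform = (Rz @ M, (-O @ M.T - off) @ Rz.T + zshift)
    tf_a = frame_tf
    tf_b = compose((Rp, tp), frame_tf)
    return tf_a, tf_b


def build_aform_duplex(seq5: str, seq3: str,
                       template: Optional[GeometryTemplate] = None,
                       chain_ids: Tuple[str, str] = ("A", "B"),
                       start_nums: Tuple[int, int] = (1, 1)) -> SceneModel:
    """Antiparallel A-form duplex of two complementary strands.

    ``seq5`` and ``seq3`` are both given 5'->3'; position i of ``seq5``
    pairs position n-1-i of ``seq3`` (WC or G.U wobble).  Residues are
    numbered consecutively from ``start_nums`` along each strand.
    """
    template = template or default_template()
    template.calibrate_backbone()
    if len(seq5) != len(seq3):
        raise ValueError("duplex strands must have equal length")
    n = len(seq5)
    for i in range(n):
        a, b = seq5[i], seq3[n - 1 - i]
        if not chem.complementary(a, b):
            raise ValueError(
                f"strands not complementary at pair position {i + 1}: "
                f"{a} vs {b}")
    strand1: List[Residue] = []
    strand2: List[Residue] = []
    for i in range(n):
        a, b = seq5[i], seq3[n - 1 - i]
        tf_a, tf_b = _helix_pair_transforms(template, a, b, i)
        strand1.append(_place(template.base_template(a), chain_ids[0],
                              start_nums[0] + i, tf_a))
        strand2.append(_place(template.base_template(b), chain_ids[1],
                              start_nums[1] + (n - 1 - i), tf_b))
    strand2.reverse()  # 5'->3' order
    bridge_phosphates(strand1)
    bridge_phosphates(strand2)
    scene = SceneModel()
    scene.add_chain(chain_ids[0], strand1)
    scene.add_chain(chain_ids[1], strand2)
    return scene


# ---------------------------------------------------------------------------
# anticodon stem-loop
# ---------------------------------------------------------------------------

def _wc_edge_direction(template: GeometryTemplate, base: str) -> np.ndarray:
    """In-plane unit vector from the glycosidic N toward the WC edge."""
    edge_names = {
        "G": ["O6", "N1", "N2"], "C": ["N4", "N3", "O2"],
        "A": ["N6", "N1"], "U": ["O4", "N3", "O2"],
    }[base]
    tmpl = template.base_template(base)
    centroid = np.mean([tmpl.coords[tmpl.index(n)] for n in edge_names], axis=0)
    v = centroid.copy()
    v[2] = 0.0
    return v / np.linalg.norm(v)


def _axis_rotation(axis: np.ndarray, theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(theta), np.sin(theta)
    K = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _loop_arc_transforms(template: GeometryTemplate, seq_loop: str,
                         a0: np.ndarray, a1: np.ndarray,
                         travel_hint: np.ndarray,
                         spin: float = 0.0, radial_shift: float = 0.0,
                         seg_target: float = 5.9) -> List[Transform]:
    """Rigid placements for loop residues along a near-circular arc.

    The arc runs the long way around a circle through anchor points ``a0``
    (exit of the 5' stem strand) and ``a1`` (entry of the 3' strand), with
    residue spacing near the single-strand helical spacing, bases pointing
    radially outward (solvent-facing) and base normals along the direction
    of travel (loop-internal stacking).  ``spin`` rotates every residue
    about its radial axis and ``radial_shift`` moves it along that axis;
    both are pose-tuning parameters solved by :func:`build_asl` to keep the
    backbone bridgeable and clash-free.
    """
    nres = len(seq_loop)
    chord = a1 - a0
    L = float(np.linalg.norm(chord))
    u = chord / L
    zhat = travel_hint / np.linalg.norm(travel_hint)
    w = np.cross(u, zhat)
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(u, np.array([1.0, 0.0, 0.0]))
    w /= np.linalg.norm(w)
    v = np.cross(w, u)
    if np.dot(v, zhat) < 0:
        v, w = -v, -w

    def gap(psi):
        r = L / (2.0 * np.sin(psi / 2.0))
        return r * (2.0 * np.pi - psi) / (nres + 1) - seg_target

    psi = brentq(gap, 1e-3, np.pi - 1e-6)
    r = L / (2.0 * np.sin(psi / 2.0))
    d = np.sqrt(max(r * r - (L / 2.0) ** 2, 0.0))
    m = 0.5 * (a0 + a1)
    c = m + d * v  # center above the anchors: major arc passes over the top

    def angle_of(p):
        rel = p - c
        return np.arctan2(float(np.dot(rel, v)), float(np.dot(rel, u)))

    alpha0 = angle_of(a0)
    alpha1 = angle_of(a1)
    # traverse the major arc from a0 to a1
    delta = alpha1 - alpha0
    while delta <= 0:
        delta += 2.0 * np.pi
    if delta < np.pi:  # ensure the long way round
        delta -= 2.0 * np.pi
    step = delta / (nres + 1)
    out: List[Transform] = []
    for k in range(1, nres + 1):
        ang = alpha0 + k * step
        radial = np.cos(ang) * u + np.sin(ang) * v
        p = c + (r + radial_shift) * radial
        tangent = (-np.sin(ang) * u + np.cos(ang) * v) * np.sign(step)
        base = seq_loop[k - 1]
        e_wc = _wc_edge_direction(template, base)
        f = np.cross(np.array([0.0, 0.0, 1.0]), e_wc)
        local = np.column_stack([e_wc, f, np.array([0.0, 0.0, 1.0])])
        g2 = np.cross(tangent, radial)
        globl = np.column_stack([radial, g2, tangent])
        R = _axis_rotation(radial, spin) @ (globl @ local.T)
        out.append((R, p.copy()))
    return out


_ASL_CACHE: Dict[Tuple[str, int, str], SceneModel] = {}


def build_asl(seq_26_44: str, template: Optional[GeometryTemplate] = None,
              chain_id: str = "T") -> SceneModel:
    """Anticodon stem-loop: residues 26-44, 5-bp stem, 9-residue open loop.

    The stem (26-30 paired with 40-44) is an A-form duplex; the loop
    (31-39, of which 32-38 is the canonical seven-base loop) is placed on
    an open arc with the anticodon bases 34-36 solvent-facing.
    """
    template = template or default_template()
    template.calibrate_backbone()
    cache_key = (seq_26_44, id(template), chain_id)
    if cache_key in _ASL_CACHE:
        return _ASL_CACHE[cache_key].copy()
    if len(seq_26_44) != 19:
        raise ValueError(
            f"ASL sequence must have 19 bases (residues 26-44), "
            f"got {len(seq_26_44)}")
    stem5 = seq_26_44[0:5]     # 26-30
    loop = seq_26_44[5:14]     # 31-39
    stem3 = seq_26_44[14:19]   # 40-44
    for i in range(5):
        a, b = stem5[i], stem3[4 - i]
        if not chem.complementary(a, b):
            raise ValueError(
                f"stem not complementary: residue {26 + i} ({a}) vs "
                f"residue {44 - i} ({b})")
    residues: Dict[int, Residue] = {}
    for i in range(5):
        a, b = stem5[i], stem3[4 - i]
        tf_a, tf_b = _helix_pair_transforms(template, a, b, i)
        residues[26 + i] = _place(template.base_template(a), chain_id,
                                  26 + i, tf_a)
        residues[44 - i] = _place(template.base_template(b), chain_id,
                                  44 - i, tf_b)
    # loop anchors: C1' of the last stem residues, travel along +z
    a0 = residues[30].atom("C1'").position
    a1 = residues[40].atom("C1'").position
    zhat = np.array([0.0, 0.0, 1.0])
    # stem body excluding the junction residues 30/40 (handled separately)
    stem_heavy = np.vstack([
        np.array([a.position for a in residues[n].atoms if a.element != "H"])
        for n in list(range(26, 30)) + list(range(41, 45))])

    def loop_residues(params):
        spin, rho, seg = params
        tfs = _loop_arc_transforms(template, loop, a0, a1, zhat,
                                   spin, rho, seg)
        return [_place(template.base_template(loop[k]), chain_id, 31 + k, tf)
                for k, tf in enumerate(tfs)]

    import copy as _copy

    bridge_names = {"P", "OP1", "OP2", "O5'"}

    def pose_cost(params):
        if not (4.2 <= params[2] <= 7.5):
            return 1e6
        try:
            lres = loop_residues(params)
        except ValueError:
            return 1e6
        # bridge a working copy of the junction chain, then score the real
        # phosphate positions for clashes and link quality
        chain = [_copy.deepcopy(residues[30])] + lres \
            + [_copy.deepcopy(residues[40])]
        bridge_phosphates(chain)
        cost = 0.0
        for r1, r2 in zip(chain, chain[1:]):
            gap = float(np.linalg.norm(
                r1.atom("O3'").position - r2.atom("O5'").position))
            cost += (gap - 2.56) ** 2
            if gap > 3.05:  # beyond phosphate bridging reach
                cost += 10.0 * (gap - 3.05) ** 2
            if gap < 2.45:  # squeezed bridge, phosphate has no room
                cost += 10.0 * (2.45 - gap) ** 2
        blocks = []
        for ci, r in enumerate(chain):
            blocks.append((ci, np.array(
                [a.position for a in r.atoms if a.element != "H"]),
                [a.name for a in r.atoms if a.element != "H"]))
        for bi in range(len(blocks)):
            ci, xi, ni = blocks[bi]
            for bj in range(bi + 1, len(blocks)):
                cj, xj, nj = blocks[bj]
                d = np.linalg.norm(xi[:, None, :] - xj[None, :, :], axis=-1)
                if cj == ci + 1:
                    # mask the bonded bridge (O3' vs P/OP/O5', <3 bonds)
                    io3 = ni.index("O3'")
                    for name in bridge_names:
                        d[io3, nj.index(name)] = np.inf
                close = d[d < 2.8]
                cost += 10.0 * float(np.sum((2.8 - close) ** 2))
            # loop vs stem body (junction residues are blocks 0 / -1)
            if 0 < bi < len(blocks) - 1:
                d = np.linalg.norm(
                    xi[:, None, :] - stem_heavy[None, :, :], axis=-1)
                close = d[d < 2.8]
                cost += 10.0 * float(np.sum((2.8 - close) ** 2))
        return cost

    from scipy.optimize import minimize as _minimize
    best = None
    for spin0 in (-1.5, -0.5, 0.5, 1.5):
        sol = _minimize(pose_cost, x0=[spin0, 0.0, 5.9],
                        method="Nelder-Mead",
                        options={"maxiter": 200, "xatol": 1e-5,
                                 "fatol": 1e-8})
        if best is None or sol.fun < best.fun:
            best = sol
    for res in loop_residues(best.x):
        residues[res.seq_num] = res
    ordered = [residues[n] for n in range(26, 45)]
    bridge_phosphates(ordered)
    scene = SceneModel()
    scene.add_chain(chain_id, ordered)
    _polish_clashes(scene, {(chain_id, n) for n in range(31, 40)})
    _ASL_CACHE[cache_key] = scene.copy()
    return scene


def _polish_clashes(scene: SceneModel, flexible, margin: float = 0.25,
                    max_steps: int = 1500,
                    extra: Optional[RestraintSet] = None) -> None:
    """Short clash-removal relaxation, in place.

    Minimizes collision-sphere energy (threshold inflated by ``margin`` so
    the result is strictly clash-free at the default threshold) plus
    bonded terms referenced to the built geometry, moving only the given
    residues.  Mirrors the short equilibrations used to remove the
    inevitable clashes of freshly assembled models.
    """
    from .dynamics import minimize
    from .restraints import DEFAULT_R_COLLIDE

    saved = set(scene.flexible)
    scene.set_flexible(set(flexible))
    # Lennard-Jones stays on: it is the only guard against intra-residue
    # steric collapse (collision spheres are inter-residue by design)
    rs = RestraintSet(
        pair_restraints=list(extra.pair_restraints) if extra else [],
        collisions=CollisionSphereSet(r_thresh=DEFAULT_R_COLLIDE + margin,
                                      k_rep=50.0),
        physics=PhysicsZone(center=next(iter(sorted(flexible))), radius=1e6,
                            lennard_jones=True, coulomb=False))
    from .restraints import collision_energy
    for _ in range(4):
        minimize(scene, rs, method="PRCG", max_steps=max_steps, tol=1e-5)
        if collision_energy(scene)[0] == 0.0:
            break
    scene.set_flexible(saved)


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def apply_mutation(scene: SceneModel, site: ResKey, new_base: str,
                   template: Optional[GeometryTemplate] = None) -> SceneModel:
    """Substitute the base at ``site``, keeping like-named atoms fixed.

    Atoms whose names occur in both the old and the new base keep their
    positions bit-identically.  Atoms unique to the new base are placed
    from the template's internal coordinates anchored on the shared atoms;
    atoms absent from the new base are removed.
    """
    template = template or default_template()
    template.calibrate_backbone()
    out = scene.copy()
    old = out.residue(site)  # raises KeyError when the site is missing
    tmpl = template.base_template(new_base)
    old_names = set(old.atom_names())
    positions: Dict[str, np.ndarray] = {
        a.name: a.position.copy() for a in old.atoms}

    new_positions: Dict[str, np.ndarray] = {}
    pending: List[str] = []
    for entry in tmpl.zmatrix:
        name = entry.name
        if name in old_names:
            new_positions[name] = positions[name]  # bit-identical
        else:
            refs = entry.refs
            if all((r in new_positions) for r in refs if r):
                from .geometry import place_atom
                r3, r2, r1 = refs
                if r1 and r2 and r3:
                    new_positions[name] = place_atom(
                        new_positions[r3], new_positions[r2],
                        new_positions[r1], entry.bond, entry.angle,
                        entry.dihedral)
                else:
                    pending.append(name)
            else:
                pending.append(name)
    if pending:
        # cross-family fallback: superpose the template on shared atoms
        shared = [n for n in tmpl.names if n in old_names]
        src = np.array([tmpl.coords[tmpl.index(n)] for n in shared])
        dst = np.array([positions[n] for n in shared])
        R, t, _ = superpose(src, dst)
        for name in pending:
            new_positions[name] = tmpl.coords[tmpl.index(name)] @ R.T + t

    atoms = [AtomRecord(n, e, new_positions[n])
             for n, e in zip(tmpl.names, tmpl.elements)]
    new_res = Residue(old.chain_id, old.seq_num, new_base, atoms,
                      list(tmpl.bonds))
    chain = out.chains[old.chain_id]
    chain[chain.index(old)] = new_res
    out._index[site] = new_res
    return out


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _extrapolate_chain(placed: Dict[int, Transform], num: int) -> Transform:
    """Continue a partially placed chain by the screw motion between the
    two nearest placed residues."""
    nums = sorted(placed)
    if num > nums[-1]:
        a, b = nums[-2], nums[-1]
        step = compose(invert(placed[a]), placed[b])
        tf = placed[b]
        for _ in range(num - nums[-1]):
            tf = compose(tf, step)
        return tf
    if num < nums[0]:
        a, b = nums[0], nums[1]
        back = compose(invert(placed[b]), placed[a])
        tf = placed[a]
        for _ in range(nums[0] - num):
            tf = compose(tf, back)
        return tf
    raise ValueError("extrapolation target inside placed range")


def _scenario_sequences(name: str) -> Tuple[str, Dict[int, int]]:
    """ASL sequence and codon->anticodon pairing map for a scenario."""
    if name == "cognate":
        return ASL_ALA, {1: 36, 2: 35, 3: 34}
    return ASL_SER3, {1: 35, 2: 34}


def build_scenario(name: str,
                   template: Optional[GeometryTemplate] = None,
                   include_monitors: bool = False,
                   include_s13: bool = False
                   ) -> Tuple[SceneModel, RestraintSet]:
    """Scene + restraints for one decoding-hypothesis preset.

    Presets: ``cognate`` (GCA codon read by the matching alanine-tRNA ASL,
    all three pairs restrained), ``u36`` (serine tRNA ASL on the GCA codon
    in the -1 frame, doublet restraints G1-C35 and C2-G34, U36 free),
    ``u36c`` (same with the U36C substitution), ``u36c_g1a`` (U36C-G1A
    double mutant), ``grapple`` (doublet plus U33-A3 and U36-A1913
    surrogate pair restraints).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    template = template or default_template()
    template.calibrate_backbone()
    asl_seq, pairing = _scenario_sequences(name)
    scene = build_asl(asl_seq, template, chain_id="T")

    # --- mRNA: paired codon residues from the anticodon placements
    mrna_tfs: Dict[int, Transform] = {}
    for codon_pos, anti_num in pairing.items():
        anti = scene.residue(("T", anti_num))
        base_c = MRNA_SEQ[codon_pos]  # residue 18+codon_pos -> string index
        pt = _pair_type(anti.base, base_c)
        Rp, tp = template.pair_transform(anti.base, base_c, pt)
        tf = compose((Rp, tp), residue_transform(anti, template))
        mrna_tfs[18 + codon_pos] = tf
    for num in range(18, 23):
        if num not in mrna_tfs:
            mrna_tfs[num] = _extrapolate_chain(
                {k: v for k, v in mrna_tfs.items()}, num)
    mrna = [_place(template.base_template(MRNA_SEQ[num - 18]), "M", num,
                   mrna_tfs[num]) for num in range(18, 23)]
    bridge_phosphates(mrna)
    scene.add_chain("M", mrna)

    # --- surrogates
    if name == "grapple":
        u36 = scene.residue(("T", 36))
        Rp, tp = template.pair_transform("U", "A", "WC")
        tf = compose((Rp, tp), residue_transform(u36, template))
        a1913 = _place(template.base_template("A"), "L", 1913, tf)
        scene.add_chain("L", [a1913])
    if include_monitors:
        _add_monitors(scene, template)
    if include_s13:
        _add_s13_tail(scene)

    scene.set_maps({1: ("M", 19), 2: ("M", 20), 3: ("M", 21)},
                   {34: ("T", 34), 35: ("T", 35), 36: ("T", 36)})
    flexible = {("T", n) for n in (26, 27, 34, 35, 36, 43, 44)}
    flexible |= {("M", n) for n in (19, 20, 21)}
    scene.set_flexible(flexible)

    # clash-removal polish of the assembled scene (loop + mRNA mobile,
    # pairing springs keep the enforced codon-anticodon geometry in place)
    pre_restraints = _scenario_restraints(scene, name, include_monitors,
                                          include_s13)
    polish_flex = {("T", n) for n in range(31, 40)} \
        | {("M", n) for n in range(18, 23)}
    if scene.has_residue(("L", 1913)):
        polish_flex.add(("L", 1913))
    _polish_clashes(scene, polish_flex, extra=pre_restraints)

    # mutations before final restraints (like-named-atom semantics; the
    # restraint atom lists must reference the mutated bases)
    if name in ("u36c", "u36c_g1a"):
        scene = apply_mutation(scene, ("T", 36), "C", template)
    if name == "u36c_g1a":
        scene = apply_mutation(scene, ("M", 19), "A", template)

    restraints = _scenario_restraints(scene, name, include_monitors,
                                      include_s13)
    return scene, restraints


def _scenario_restraints(scene: SceneModel, name: str,
                         include_monitors: bool,
                         include_s13: bool) -> RestraintSet:
    rs = RestraintSet()
    # stem duplex enforced (residues 26-30 / 40-44)
    for i in range(5):
        ra = scene.residue(("T", 26 + i))
        rb = scene.residue(("T", 44 - i))
        rs.pair_restraints.append(
            make_basepair_restraint(ra, rb, _pair_type(ra.base, rb.base),
                                    tag="stem"))
    # helical stacking at the stem base (residues 26-28 of the 25-28 span)
    for n in (26, 27):
        rs.stacks.append(StackRestraint(("T", n), ("T", n + 1), tag="stack"))
    # scaffold weld: residue 44 fixed in space (stands in for the weld to
    # the D-stem residue outside the reduced model)
    rs.welds.append(WeldConstraint(("T", 44), tag="weld"))
    # monitor anchors: weak positional springs on the decoding-site
    # backbone, standing in for the small-subunit monitor bases that keep
    # the mRNA and the anticodon loop in position; bases stay free to
    # flip
    for key in (("T", 34), ("T", 35), ("T", 36),
                ("M", 19), ("M", 20), ("M", 21)):
        rs.welds.append(WeldConstraint(key, k=0.5, atoms=["P"],
                                       tag="monitor_anchor"))

    # codon-anticodon pairing per preset
    _, pairing = _scenario_sequences(name)
    for codon_pos, anti_num in sorted(pairing.items()):
        ra = scene.residue(("M", 18 + codon_pos))
        rb = scene.residue(("T", anti_num))
        tag = f"codon_pair_{codon_pos}"
        if chem.complementary(ra.base, rb.base):
            rs.pair_restraints.append(
                make_basepair_restraint(ra, rb, _pair_type(ra.base, rb.base),
                                        tag=tag))
        else:
            # non-canonical combination (the A1-C35 of the double mutant):
            # hold the same doublet pose with a custom edge restraint
            rs.pair_restraints.append(PairRestraint(
                ra.key, rb.key, "custom",
                [("N1", "N3", chem.CANONICAL_DA),
                 ("N6", "N4", chem.CANONICAL_DA)], tag=tag))
    if name == "grapple":
        rs.pair_restraints.append(
            make_basepair_restraint(scene.residue(("T", 33)),
                                    scene.residue(("M", 21)),
                                    "WC", tag="grapple_u33"))
        rs.pair_restraints.append(
            make_basepair_restraint(scene.residue(("T", 36)),
                                    scene.residue(("L", 1913)),
                                    "WC", tag="grapple_a1913"))
    if include_monitors:
        for num, target in ((530, ("M", 20, "O2'")), (1492, ("M", 19, "O2'")),
                            (1493, ("M", 20, "O4'"))):
            rs.distance_springs.append(DistanceSpring(
                ("R", num, "N1" if num == 530 else "N1"), target, r0=2.5,
                tag="monitor"))
    if include_s13:
        anchor = ("L", 1913, "P") if scene.has_residue(("L", 1913)) \
            else ("T", 44, "P")
        rs.distance_springs.append(DistanceSpring(
            ("P", 125, "CA"), anchor, r0=3.0, tag="s13"))

    rs.collisions = CollisionSphereSet()
    rs.physics = PhysicsZone(center=("T", 35))
    return rs


def _add_monitors(scene: SceneModel,
                  template: GeometryTemplate) -> None:
    """Monitor-base surrogates (small-subunit 530, 1492, 1493).

    Positioned at fixed offsets on the minor-groove side of the
    codon-anticodon duplex; they serve only as spring anchors and steric
    occluders, so the exact pose is a configuration choice.
    """
    anchor = scene.residue(("M", 20)).atom("O2'").position
    axis = anchor - scene.residue(("T", 35)).atom("C1'").position
    axis /= np.linalg.norm(axis)
    for k, (num, base) in enumerate(((530, "G"), (1492, "A"), (1493, "A"))):
        tmpl = template.base_template(base)
        shift = anchor + axis * (4.0 + 1.0 * k) \
            + np.array([0.0, 0.0, 3.5 * (k - 1)])
        gn = tmpl.coords[tmpl.index(chem.glycosidic_nitrogen(base))]
        res = _place(tmpl, "R", num, (np.eye(3), shift - gn))
        scene.add_residue(res)


def _add_s13_tail(scene: SceneModel) -> None:
    """Five-bead surrogate of the S13 C-terminal tail (residues 122-126).

    A peptide-like chain of CA beads threaded over the anticodon stem on
    the P-site side; a steric occluder, pose configurable.
    """
    top = scene.residue(("T", 31)).atom("C1'").position
    direction = np.array([0.0, 0.0, 1.0])
    start = top + np.array([6.0, 0.0, 2.0])
    for k, num in enumerate(range(122, 127)):
        pos = start + direction * (3.8 * k)
        res = Residue("P", num, "BEAD",
                      [AtomRecord("CA", "C", pos)], [])
        scene.add_residue(res)
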
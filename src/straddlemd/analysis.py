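"""Structure and trajectory analytics.

Hydrogen-bond detection (geometric donor-H...acceptor criteria),
base-pair typing with a strain flag, decoding-configuration
classification (cognate / doublet / straddle / grapple / unpaired), RMSD
with optimal superposition, and per-archive occupancy statistics.

The classification rule table operationalizes the competing decoding
hypotheses: *grapple* when the tRNA-33 base pairs the third codon
position, *cognate* when all three codon positions pair their canonical
anticodon partners (36/35/34), *straddle* when the second codon position
pairs tRNA-34 while the first codon base accepts a hydrogen bond from the
tRNA-36 imino proton H3 (impossible whenever residue 36 is a cytosine,
which has no H3), and *doublet* when codon 1-2 pair tRNA 35-34 with
residue 36 unengaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .geometry import angle as _angle, superpose
from .model import AtomKey, ResKey, Residue, SceneModel

#: default geometric hydrogen-bond criteria
D_DA_MAX = 3.5     # A donor-acceptor
ANGLE_MIN = 120.0  # deg donor-hydrogen-acceptor
STRAIN_MARGIN = 0.3  # A over the canonical 2.9 A reference

BACKBONE_ATOMS = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'",
                  "O3'", "C2'", "O2'", "C1'"}


@dataclass
class HBond:
    donor: AtomKey
    hydrogen: AtomKey
    acceptor: AtomKey
    d_DA: float
    d_HA: float
    angle_DHA: float

    def involves(self, key_a: ResKey, key_b: ResKey) -> bool:
        ra = (self.donor[0], self.donor[1])
        rb = (self.acceptor[0], self.acceptor[1])
        return {ra, rb} == {tuple(key_a), tuple(key_b)}


@dataclass
class BasePairCall:
    residue_a: ResKey
    residue_b: ResKey
    pair_type: str                     # WC | wobble | other | none
    bonds: List[HBond] = field(default_factory=list)
    strained: bool = False

    @property
    def paired(self) -> bool:
        return self.pair_type != "none"


@dataclass
class DecodingCall:
    configuration: str                 # cognate|doublet|straddle|grapple|unpaired
    evidence: List = field(default_factory=list)
    snapshot_id: Optional[int] = None
    weak_contacts: List[HBond] = field(default_factory=list)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _donors_and_acceptors(res: Residue):
    """(donor_heavy, hydrogen) pairs and acceptor names for one residue.

    Acceptors are oxygens and bare nitrogens; nitrogens carrying a proton
    (imino and amide/amino groups, whose lone pair is conjugated) do not
    accept -- matching the energy model's hydrogen-bond term.
    """
    names = res.atom_names()
    elements = {a.name: a.element for a in res.atoms}
    donors = []
    has_h = set()
    for i, j in res.bonds:
        ni, nj = names[i], names[j]
        if elements[ni] == "H" and elements[nj] in ("N", "O"):
            donors.append((nj, ni))
            has_h.add(nj)
        elif elements[nj] == "H" and elements[ni] in ("N", "O"):
            donors.append((ni, nj))
            has_h.add(ni)
    acceptors = [n for n in names
                 if elements[n] == "O"
                 or (elements[n] == "N" and n not in has_h)]
    return donors, acceptors


def _bond_distance_map(res: Residue, max_sep: int = 2) -> Dict[Tuple[str, str], int]:
    names = res.atom_names()
    adj: Dict[str, set] = {n: set() for n in names}
    for i, j in res.bonds:
        adj[names[i]].add(names[j])
        adj[names[j]].add(names[i])
    out = {}
    for start in names:
        frontier, seen = {start}, {start}
        for dist in range(1, max_sep + 1):
            nxt = set()
            for a in frontier:
                nxt |= adj[a]
            nxt -= seen
            for n in nxt:
                out[(start, n)] = dist
            seen |= nxt
            frontier = nxt
    return out


def detect_hbonds(scene: SceneModel, d_DA_max: float = D_DA_MAX,
                  angle_min: float = ANGLE_MIN) -> List[HBond]:
    """All geometric hydrogen bonds in the scene.

    A bond is reported for every donor-H/acceptor triple with
    donor-acceptor distance <= ``d_DA_max`` and D-H...A angle >=
    ``angle_min``, excluding intra-residue pairs separated by fewer than
    3 bonds.  Requires explicit hydrogens (the builder places them).
    """
    residues = list(scene.residues())
    if not any(a.element == "H" for r in residues for a in r.atoms):
        raise ValueError(
            "scene has no hydrogens; build with an all-atom template "
            "(hydrogen-bond detection needs explicit donor protons)")
    entries = []   # (res, donor, hydrogen, acceptors, bond-sep map)
    acc_keys: List[Tuple[Residue, str]] = []
    acc_pos = []
    don_list = []
    for res in residues:
        donors, acceptors = _donors_and_acceptors(res)
        sep = _bond_distance_map(res) if donors or acceptors else {}
        for nm in acceptors:
            acc_keys.append((res, nm))
            acc_pos.append(res.atom(nm).position)
        for d, h in donors:
            don_list.append((res, d, h, sep))
    acc_pos = np.array(acc_pos).reshape(-1, 3)
    out: List[HBond] = []
    for res, dname, hname, sep in don_list:
        dpos = res.atom(dname).position
        hpos = res.atom(hname).position
        dd = np.linalg.norm(acc_pos - dpos, axis=1)
        for idx in np.where(dd <= d_DA_max)[0]:
            ares, aname = acc_keys[idx]
            if ares is res:
                if aname == dname:
                    continue
                if sep.get((dname, aname), 99) < 3:
                    continue
            apos = acc_pos[idx]
            ang = _angle(dpos, hpos, apos)
            if ang < angle_min:
                continue
            out.append(HBond(
                donor=(res.chain_id, res.seq_num, dname),
                hydrogen=(res.chain_id, res.seq_num, hname),
                acceptor=(ares.chain_id, ares.seq_num, aname),
                d_DA=float(dd[idx]),
                d_HA=float(np.linalg.norm(apos - hpos)),
                angle_DHA=float(ang)))
    return out


# ---------------------------------------------------------------------------
# base pairs
# ---------------------------------------------------------------------------

def _edge_bond_present(hbonds: Sequence[HBond], key_a: ResKey, name_a: str,
                       key_b: ResKey, name_b: str) -> Optional[HBond]:
    for hb in hbonds:
        da = (hb.donor[0], hb.donor[1], hb.donor[2])
        ac = (hb.acceptor[0], hb.acceptor[1], hb.acceptor[2])
        want_ab = ((*key_a, name_a), (*key_b, name_b))
        if (da, ac) == want_ab or (ac, da) == want_ab:
            return hb
    return None


def _base_hbonds_between(hbonds: Sequence[HBond], key_a: ResKey,
                         key_b: ResKey) -> List[HBond]:
    out = []
    for hb in hbonds:
        if not hb.involves(key_a, key_b):
            continue
        if hb.donor[2] in BACKBONE_ATOMS or hb.acceptor[2] in BACKBONE_ATOMS:
            continue
        out.append(hb)
    return out


def classify_basepair(res_a: Residue, res_b: Residue,
                      hbonds: Sequence[HBond],
                      strain_margin: float = STRAIN_MARGIN) -> BasePairCall:
    """Type a residue pair from detected hydrogen bonds.

    ``WC``/``wobble`` require every canonical edge bond of the base
    combination; ``other`` is any remaining base-base hydrogen bonding;
    ``none`` means no base-base bond.  ``strained`` flags canonical pairs
    whose mean donor-acceptor distance exceeds the 2.9 A canonical
    reference by more than ``strain_margin``.
    """
    key_a, key_b = res_a.key, res_b.key
    for pair_type in ("WC", "wobble"):
        edges = chem.edge_atoms(res_a.base, res_b.base, pair_type)
        if edges is None:
            continue
        found = [_edge_bond_present(hbonds, key_a, na, key_b, nb)
                 for na, nb in edges]
        if all(found):
            mean_d = float(np.mean([hb.d_DA for hb in found]))
            return BasePairCall(key_a, key_b, pair_type, list(found),
                                strained=mean_d > chem.CANONICAL_DA
                                + strain_margin)
    base_bonds = _base_hbonds_between(hbonds, key_a, key_b)
    if base_bonds:
        mean_d = float(np.mean([hb.d_DA for hb in base_bonds]))
        return BasePairCall(key_a, key_b, "other", base_bonds,
                            strained=mean_d > chem.CANONICAL_DA
                            + strain_margin)
    return BasePairCall(key_a, key_b, "none", [])


# ---------------------------------------------------------------------------
# decoding configuration
# ---------------------------------------------------------------------------

def classify_decoding(scene: SceneModel,
                      codon_map: Optional[Dict[int, ResKey]] = None,
                      anticodon_map: Optional[Dict[int, ResKey]] = None,
                      d_DA_max: float = D_DA_MAX,
                      angle_min: float = ANGLE_MIN,
                      snapshot_id: Optional[int] = None) -> DecodingCall:
    """Classify the decoding configuration of one conformation.

    Rules are evaluated in a fixed precedence: grapple, cognate, straddle,
    doublet, unpaired (see the module docstring).  Evidence carries the
    base-pair calls and hydrogen bonds behind the decision, plus the weak
    codon1:H21-tRNA35:N3 contact when present.
    """
    codon_map = codon_map or scene.codon_map
    anticodon_map = anticodon_map or scene.anticodon_map
    for m, label in ((codon_map, "codon_map"),
                     (anticodon_map, "anticodon_map")):
        for key in m.values():
            if not scene.has_residue(tuple(key)):
                raise KeyError(f"{label} references missing residue {key}")
    hbonds = detect_hbonds(scene, d_DA_max, angle_min)

    def res(key: ResKey) -> Residue:
        return scene.residue(tuple(key))

    def pair(codon_pos: int, anti_pos: int) -> BasePairCall:
        return classify_basepair(res(codon_map[codon_pos]),
                                 res(anticodon_map[anti_pos]), hbonds)

    codon1, codon3 = codon_map[1], codon_map[3]
    anti33 = (anticodon_map[34][0], 33)
    r36 = res(anticodon_map[36])

    evidence: List = []
    weak = _weak_secondary_contacts(scene, hbonds, codon_map, anticodon_map)

    # grapple: tRNA-33 pairs the third codon position
    if scene.has_residue(anti33):
        g_call = classify_basepair(res(anti33), res(codon3), hbonds)
        if g_call.pair_type in ("WC", "wobble"):
            return DecodingCall("grapple", [g_call], snapshot_id, weak)

    # cognate: codon 1/2/3 pair anticodon 36/35/34
    calls = {(1, 36): pair(1, 36), (2, 35): pair(2, 35), (3, 34): pair(3, 34)}
    if all(c.pair_type in ("WC", "wobble") for c in calls.values()):
        return DecodingCall("cognate", list(calls.values()), snapshot_id,
                            weak)

    # straddle: codon2-tRNA34 WC + H-bond from tRNA36 H3 to a codon1
    # base acceptor (requires residue 36 to carry the H3 imino proton)
    p24 = pair(2, 34)
    straddle_bonds = []
    if r36.has_atom("H3"):
        key36 = r36.key
        for hb in hbonds:
            if (hb.donor[0], hb.donor[1]) == key36 and hb.donor[2] == "N3" \
                    and hb.hydrogen[2] == "H3" \
                    and (hb.acceptor[0], hb.acceptor[1]) == tuple(codon1) \
                    and hb.acceptor[2] not in BACKBONE_ATOMS:
                straddle_bonds.append(hb)
    if p24.pair_type == "WC" and straddle_bonds:
        return DecodingCall("straddle", [p24] + straddle_bonds, snapshot_id,
                            weak)

    # doublet: codon1 paired with tRNA35, codon2-tRNA34 WC, residue 36
    # not hydrogen-bonded to any codon base
    p15 = pair(1, 35)
    r36_codon_bonds = [
        hb for pos in (1, 2, 3)
        for hb in _base_hbonds_between(hbonds, r36.key, codon_map[pos])]
    if p15.paired and p24.pair_type == "WC" and not r36_codon_bonds:
        return DecodingCall("doublet", [p15, p24], snapshot_id, weak)

    return DecodingCall("unpaired", [p15, p24] + r36_codon_bonds,
                        snapshot_id, weak)


def _weak_secondary_contacts(scene, hbonds, codon_map, anticodon_map):
    """The weak codon1 amino to tRNA35 N3 contact (H21 donor), if present."""
    out = []
    codon1 = tuple(codon_map[1])
    anti35 = tuple(anticodon_map[35])
    for hb in hbonds:
        if (hb.donor[0], hb.donor[1]) == codon1 \
                and hb.hydrogen[2] in ("H21", "H22", "H61", "H62") \
                and (hb.acceptor[0], hb.acceptor[1]) == anti35 \
                and hb.acceptor[2] == "N3":
            out.append(hb)
    return out


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(scene_a: SceneModel, scene_b: SceneModel,
         selection: Optional[Iterable[AtomKey]] = None) -> float:
    """RMSD after least-squares superposition (rotation+translation
    removed).  ``selection`` is an iterable of atom keys present in both
    scenes; by default every atom key of ``scene_a`` is used."""
    keys = list(selection) if selection is not None else scene_a.atom_keys()
    if not keys:
        raise ValueError("empty selection")
    try:
        xa = np.array([scene_a.atom(tuple(k)).position for k in keys])
        xb = np.array([scene_b.atom(tuple(k)).position for k in keys])
    except KeyError as exc:
        raise KeyError(f"selection not atom-matched between scenes: {exc}")
    _, _, value = superpose(xa, xb)
    return value


# ---------------------------------------------------------------------------
# archive analytics
# ---------------------------------------------------------------------------

def track_distance(archive, atom_a: AtomKey, atom_b: AtomKey) -> np.ndarray:
    """Distance between two atoms across all archived snapshots."""
    tmpl = archive.scene_template
    keys = tmpl.atom_keys()
    ia = keys.index(tuple(atom_a))
    ib = keys.index(tuple(atom_b))
    return np.array([float(np.linalg.norm(c[ia] - c[ib]))
                     for c in archive.coords])


def hbond_occupancy(archive, res_a: ResKey, res_b: ResKey,
                    d_DA_max: float = D_DA_MAX,
                    angle_min: float = ANGLE_MIN) -> float:
    """Fraction of archived snapshots with >= 1 base-base hydrogen bond
    between two residues (the persistence statistic; 'persistent' is
    conventionally taken as occupancy >= 0.7)."""
    if len(archive) == 0:
        raise ValueError("empty archive")
    n = 0
    for i in range(len(archive)):
        scene = archive.get_scene(i)
        hbonds = detect_hbonds(scene, d_DA_max, angle_min)
        if _base_hbonds_between(hbonds, tuple(res_a), tuple(res_b)):
            n += 1
    return n / len(archive)


def analyze_archive(archive, tracked_contacts: Optional[List[Tuple[AtomKey,
                    AtomKey]]] = None) -> pd.DataFrame:
    """Per-snapshot analysis table.

    Columns: snapshot id, biased time, decoding configuration, strain flag
    of the codon1-tRNA35 pair, and one distance column per tracked atom
    pair.
    """
    rows = []
    tracked_contacts = tracked_contacts or []
    for i in range(len(archive)):
        scene = archive.get_scene(i)
        call = classify_decoding(scene, snapshot_id=i)
        hbonds = detect_hbonds(scene)
        p15 = classify_basepair(scene.residue(tuple(scene.codon_map[1])),
                                scene.residue(tuple(scene.anticodon_map[35])),
                                hbonds)
        row = {
            "snapshot": i,
            "biased_time_ps": archive.stamps_ps[i],
            "configuration": call.configuration,
            "codon1_t35_pair": p15.pair_type,
            "codon1_t35_strained": p15.strained,
        }
        for a, b in tracked_contacts:
            label = f"d_{a[0]}{a[1]}{a[2]}_{b[0]}{b[1]}{b[2]}"
            row[label] = float(np.linalg.norm(
                scene.atom(tuple(a)).position - scene.atom(tuple(b)).position))
        rows.append(row)
    return pd.DataFrame(rows)
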
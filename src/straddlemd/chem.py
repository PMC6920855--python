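"""Chemical reference tables for the reduced nucleic-acid model.

Element masses, a compact nonbonded parameter table (Lennard-Jones radii /
well depths and per-atom partial charges for the reduced Amber-type physics
zone), Watson-Crick / wobble edge-atom tables, and donor/acceptor rules.
All parameters are deliberately kept in one editable place.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

# ------------------------------------------------------------------ elements
MASSES: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
}

#: Lennard-Jones parameters per element: (rmin/2 in Angstrom, epsilon in
#: kcal/mol).  Values are rounded Amber-like atomic defaults; the reduced
#: model uses one entry per element.
LJ_PARAMS: Dict[str, Tuple[float, float]] = {
    "H": (0.60, 0.0157),
    "C": (1.91, 0.0860),
    "N": (1.82, 0.1700),
    "O": (1.66, 0.2100),
    "P": (2.10, 0.2000),
}

#: Partial charges for the screened-Coulomb term: a rounded Amber-style
#: table.  Base moieties are near-neutral with proper carbonyl/amino/imino
#: dipoles; the phosphate is partially neutralized (implicit counterions),
#: a standard reduction for unsolvated models.
SUGAR_PHOSPHATE_CHARGES: Dict[str, float] = {
    "P": 1.17, "OP1": -0.55, "OP2": -0.55, "O5'": -0.50,
    "C5'": 0.06, "H5'": 0.07, "H5''": 0.07,
    "C4'": 0.11, "H4'": 0.10, "O4'": -0.35,
    "C3'": 0.20, "H3'": 0.06, "O3'": -0.52,
    "C2'": 0.07, "H2'": 0.10, "O2'": -0.61, "HO2'": 0.42,
    "C1'": 0.07, "H1'": 0.18,
}
BASE_CHARGES: Dict[str, Dict[str, float]] = {
    "A": {"N9": -0.03, "C8": 0.16, "H8": 0.19, "N7": -0.62, "C5": 0.07,
          "C6": 0.70, "N6": -0.90, "H61": 0.41, "H62": 0.41, "N1": -0.76,
          "C2": 0.57, "H2": 0.06, "N3": -0.74, "C4": 0.38},
    "G": {"N9": 0.05, "C8": 0.14, "H8": 0.19, "N7": -0.57, "C5": 0.20,
          "C6": 0.48, "O6": -0.56, "N1": -0.48, "H1": 0.34, "C2": 0.74,
          "N2": -0.97, "H21": 0.44, "H22": 0.44, "N3": -0.66, "C4": 0.12},
    "C": {"N1": -0.05, "C2": 0.75, "O2": -0.63, "N3": -0.77, "C4": 0.82,
          "N4": -0.97, "H41": 0.43, "H42": 0.43, "C5": -0.52, "H5": 0.19,
          "C6": 0.01, "H6": 0.22},
    "U": {"N1": 0.04, "C2": 0.47, "O2": -0.55, "N3": -0.35, "H3": 0.32,
          "C4": 0.59, "O4": -0.58, "C5": -0.36, "H5": 0.18, "C6": -0.11,
          "H6": 0.22},
}

COULOMB_CONSTANT = 332.0636  # kcal*Angstrom/(mol*e^2)
KB = 0.0019872041            # kcal/(mol*K)
#: acceleration conversion: (kcal/mol/Angstrom)/amu -> Angstrom/fs^2
ACC_UNIT = 4.184e-4


def partial_charge(atom_name: str, element: str,
                   base: Optional[str] = None) -> float:
    if atom_name in SUGAR_PHOSPHATE_CHARGES:
        return SUGAR_PHOSPHATE_CHARGES[atom_name]
    if base in BASE_CHARGES and atom_name in BASE_CHARGES[base]:
        return BASE_CHARGES[base][atom_name]
    return 0.0


# ------------------------------------------------------------- base pairing
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
COMPLEMENT_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Watson-Crick / wobble edge atoms as (atom_on_first, atom_on_second)
#: pairs, first base listed first.  Donor-acceptor heavy-atom pairs; the
#: canonical reference distance is ``CANONICAL_DA`` for each.
WC_EDGE: Dict[Tuple[str, str], List[Tuple[str, str]]] = {
    ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    ("A", "U"): [("N6", "O4"), ("N1", "N3")],
}
WOBBLE_EDGE: Dict[Tuple[str, str], List[Tuple[str, str]]] = {
    ("G", "U"): [("O6", "N3"), ("N1", "O2")],
}

CANONICAL_DA = 2.9  # Angstrom, canonical donor-acceptor distance


#: hydrogen atoms mediating each canonical edge bond:
#: (atom_on_first, atom_on_second, hydrogen_name, side_carrying_hydrogen)
WC_HYDROGENS: Dict[Tuple[str, str], List[Tuple[str, str, str, str]]] = {
    ("G", "C"): [("O6", "N4", "H41", "b"),
                 ("N1", "N3", "H1", "a"),
                 ("N2", "O2", "H21", "a")],
    ("A", "U"): [("N6", "O4", "H61", "a"),
                 ("N1", "N3", "H3", "b")],
    ("G", "U"): [("O6", "N3", "H3", "b"),
                 ("N1", "O2", "H1", "a")],
}


def edge_hbonds(base_a: str, base_b: str, pair_type: str):
    """Edge bonds with mediating hydrogens, ordered (first, second).

    Each entry is ``(atom_a, atom_b, h_name, h_side)`` with ``h_side`` in
    {"a", "b"} naming the base that carries the hydrogen.  Returns ``None``
    for incompatible base combinations.
    """
    if pair_type == "wobble":
        table = {("G", "U"): WC_HYDROGENS[("G", "U")]}
    else:
        table = {k: v for k, v in WC_HYDROGENS.items() if k != ("G", "U")}
    if (base_a, base_b) in table:
        return list(table[(base_a, base_b)])
    if (base_b, base_a) in table:
        return [(b, a, h, "a" if side == "b" else "b")
                for a, b, h, side in table[(base_b, base_a)]]
    return None


def edge_atoms(base_a: str, base_b: str, pair_type: str):
    """Edge-atom pair list for an ordered base combination.

    Returns ``None`` when the bases are incompatible with ``pair_type``
    (``"WC"`` or ``"wobble"``).
    """
    table = WC_EDGE if pair_type == "WC" else WOBBLE_EDGE
    if (base_a, base_b) in table:
        return list(table[(base_a, base_b)])
    if (base_b, base_a) in table:
        return [(b, a) for a, b in table[(base_b, base_a)]]
    return None


def complementary(base_a: str, base_b: str) -> bool:
    """WC or G.U wobble complementarity."""
    return (edge_atoms(base_a, base_b, "WC") is not None
            or edge_atoms(base_a, base_b, "wobble") is not None)


# ring atoms used to define base planes / frames
RING_ATOMS: Dict[str, List[str]] = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
}


def glycosidic_nitrogen(base: str) -> str:
    return "N9" if base in PURINES else "N1"
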
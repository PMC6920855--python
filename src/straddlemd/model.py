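"""In-memory model of the reduced codon-anticodon system.

A :class:`SceneModel` holds chains of :class:`Residue` objects (each a list
of :class:`AtomRecord`), the set of flexible residues, and the maps that
route decoding logic from codon/anticodon *positions* to author-numbered
residues.  Author numbering is arbitrary (the mRNA codon may be numbered
19-21 or 1-3); everything downstream goes through ``codon_map`` and
``anticodon_map``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Set, Tuple

import numpy as np

#: (chain_id, seq_num) residue key
ResKey = Tuple[str, int]
#: (chain_id, seq_num, atom_name) atom key
AtomKey = Tuple[str, int, str]


@dataclass
class AtomRecord:
    """A single named atom with PDB v3 naming (e.g. ``O6``, ``H3``, ``OP1``)."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """A nucleotide (or surrogate bead) with author-style numbering."""

    chain_id: str
    seq_num: int
    base: str            # A, C, G, U, or a surrogate code (e.g. "BEAD")
    atoms: List[AtomRecord] = field(default_factory=list)
    # intra-residue bonds as index pairs into ``atoms`` (template topology)
    bonds: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in residue {self.chain_id}:{self.seq_num}")

    @property
    def key(self) -> ResKey:
        return (self.chain_id, self.seq_num)

    def atom_names(self) -> List[str]:
        return [a.name for a in self.atoms]

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in residue {self.chain_id}:{self.seq_num}"
                       f" ({self.base})")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.position = p.copy()


class SceneModel:
    """All-atom coordinates + metadata for the reduced decoding system.

    Chains are named residue lists (e.g. ``"T"`` tRNA ASL, ``"M"`` mRNA,
    ``"S"`` surrogates).  ``flexible`` marks mobile residues; everything
    else is rigid for all downstream energy/dynamics code.
    """

    def __init__(self) -> None:
        self.chains: Dict[str, List[Residue]] = {}
        self.flexible: Set[ResKey] = set()
        self.codon_map: Dict[int, ResKey] = {}
        self.anticodon_map: Dict[int, ResKey] = {}
        self._index: Dict[ResKey, Residue] = {}

    # ------------------------------------------------------------------ build
    def add_residue(self, res: Residue) -> None:
        if res.key in self._index:
            raise ValueError(f"duplicate residue {res.key}")
        self.chains.setdefault(res.chain_id, []).append(res)
        self._index[res.key] = res

    def add_chain(self, chain_id: str, residues: List[Residue]) -> None:
        for r in residues:
            if r.chain_id != chain_id:
                raise ValueError("residue chain_id mismatch")
            self.add_residue(r)

    def set_flexible(self, keys) -> None:
        keys = set(keys)
        missing = keys - set(self._index)
        if missing:
            raise KeyError(f"flexible residues not in scene: {sorted(missing)}")
        self.flexible = keys

    def set_maps(self, codon_map: Dict[int, ResKey],
                 anticodon_map: Dict[int, ResKey]) -> None:
        for m, positions, label in ((codon_map, {1, 2, 3}, "codon_map"),
                                    (anticodon_map, {34, 35, 36}, "anticodon_map")):
            if set(m) != positions:
                raise ValueError(f"{label} must be total over positions {positions}")
            if len(set(m.values())) != len(m):
                raise ValueError(f"{label} must be injective")
            for key in m.values():
                if key not in self._index:
                    raise KeyError(f"{label} references missing residue {key}")
        self.codon_map = dict(codon_map)
        self.anticodon_map = dict(anticodon_map)

    # ------------------------------------------------------------------ access
    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def residue(self, key: ResKey) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"no residue {key} in scene") from None

    def has_residue(self, key: ResKey) -> bool:
        return key in self._index

    def atom(self, key: AtomKey) -> AtomRecord:
        return self.residue((key[0], key[1])).atom(key[2])

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    # ------------------------------------------------- flat coordinate views
    def atom_keys(self) -> List[AtomKey]:
        return [(r.chain_id, r.seq_num, a.name)
                for r in self.residues() for a in r.atoms]

    def coords(self) -> np.ndarray:
        """All coordinates as an (N, 3) array in ``atom_keys`` order."""
        out = np.empty((self.n_atoms(), 3))
        i = 0
        for r in self.residues():
            for a in r.atoms:
                out[i] = a.position
                i += 1
        return out

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms(), 3):
            raise ValueError("coordinate array shape mismatch")
        i = 0
        for r in self.residues():
            for a in r.atoms:
                a.position = xyz[i].copy()
                i += 1

    def copy(self) -> "SceneModel":
        return copy.deepcopy(self)

    # ------------------------------------------------------------- transforms
    def transform(self, R: np.ndarray, t: np.ndarray) -> "SceneModel":
        """Return a rigidly transformed copy (x -> x @ R.T + t)."""
        out = self.copy()
        out.set_coords(self.coords() @ np.asarray(R).T + np.asarray(t))
        return out
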
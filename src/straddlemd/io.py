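"""File I/O: PDB structures and multi-model archives, JSONL demon logs,
CSV analysis tables and JSON reports, YAML/JSON configuration."""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .dynamics import SnapshotArchive, SprintRecord
from .model import AtomRecord, Residue, SceneModel

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _scene_to_atom_array(scene: SceneModel):
    import biotite.structure as struc

    n = scene.n_atoms()
    arr = struc.AtomArray(n)
    i = 0
    for res in scene.residues():
        for a in res.atoms:
            arr.chain_id[i] = res.chain_id
            arr.res_id[i] = res.seq_num
            arr.res_name[i] = res.base if len(res.base) <= 3 else res.base[:3]
            arr.atom_name[i] = a.name
            arr.element[i] = a.element.upper()
            arr.coord[i] = a.position
            arr.hetero[i] = res.base not in ("A", "C", "G", "U")
            i += 1
    return arr


def write_pdb(scene_or_scenes, path: PathLike) -> None:
    """Write a scene (or a list of scenes as a multi-model file) as PDB.

    Chain identifiers, author residue numbers and the element column are
    preserved.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    scenes = scene_or_scenes if isinstance(scene_or_scenes, (list, tuple)) \
        else [scene_or_scenes]
    pdb = PDBFile()
    if len(scenes) == 1:
        pdb.set_structure(_scene_to_atom_array(scenes[0]))
    else:
        stack = struc.stack([_scene_to_atom_array(s) for s in scenes])
        pdb.set_structure(stack)
    pdb.write(str(path))


def write_archive_pdb(archive: SnapshotArchive, path: PathLike,
                      sidecar_path: Optional[PathLike] = None) -> None:
    """Multi-model PDB of all archived snapshots plus a CSV sidecar table
    (snapshot id, biased time, provenance sprint index)."""
    scenes = [archive.get_scene(i) for i in range(len(archive))]
    if scenes:
        write_pdb(scenes, path)
    if sidecar_path is not None:
        pd.DataFrame({
            "snapshot": list(range(len(archive))),
            "biased_time_ps": archive.stamps_ps,
            "sprint_index": archive.provenance,
        }).to_csv(sidecar_path, index=False)


def read_pdb(path: PathLike) -> SceneModel:
    """Read a PDB file into a scene (first model).

    Atoms, residues, chains and author numbering are preserved; residues
    with unknown names are loaded as generic (their base code is the
    residue name).  Raises on empty or malformed files.
    """
    from biotite.structure.io.pdb import PDBFile
    from .templates import GeometryTemplate

    path = Path(path)
    text = path.read_text()
    if not any(line.startswith(("ATOM", "HETATM")) for line in
               text.splitlines()):
        raise ValueError(f"{path}: no ATOM records (empty or not a PDB file)")
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) < 54:
            raise ValueError(f"{path}: malformed ATOM record at line {ln}")
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    scene = SceneModel()
    current: Dict = {}
    order: List = []
    for i in range(arr.array_length()):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]))
        if key not in current:
            current[key] = Residue(key[0], key[1], str(arr.res_name[i]), [])
            order.append(key)
        current[key].atoms.append(AtomRecord(
            str(arr.atom_name[i]),
            str(arr.element[i]).capitalize(),
            arr.coord[i].astype(float)))
    # attach template bond topology where the residue is a known base
    from .builder import default_template
    tmpl: Optional[GeometryTemplate] = None
    for key in order:
        res = current[key]
        if res.base in ("A", "C", "G", "U"):
            tmpl = tmpl or default_template()
            bt = tmpl.base_template(res.base)
            names = res.atom_names()
            idx = {n: i for i, n in enumerate(names)}
            res.bonds = [
                (idx[bt.names[i]], idx[bt.names[j]])
                for i, j in bt.bonds
                if bt.names[i] in idx and bt.names[j] in idx]
        scene.add_residue(res)
    return scene


# ---------------------------------------------------------------------------
# demon log
# ---------------------------------------------------------------------------

def write_demon_log(records: Sequence[SprintRecord], path: PathLike) -> None:
    """JSONL log: one sprint record per line (index, seed, demon value,
    accepted/failed flags, energies)."""
    with open(path, "w") as fh:
        for r in records:
            d = dataclasses.asdict(r)
            if isinstance(d["demon_value"], float) and \
                    math.isnan(d["demon_value"]):
                d["demon_value"] = None
            fh.write(json.dumps(d) + "\n")


def read_demon_log(path: PathLike) -> List[SprintRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            if d["demon_value"] is None:
                d["demon_value"] = math.nan
            out.append(SprintRecord(**d))
    return out


# ---------------------------------------------------------------------------
# reports and configs
# ---------------------------------------------------------------------------

def write_json(obj: Dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_json(path: PathLike) -> Dict:
    with open(path) as fh:
        return json.load(fh)


def load_config(path: PathLike) -> Dict:
    """YAML or JSON configuration file -> dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: Dict, path: PathLike) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        write_json(cfg, path)
    else:
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
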
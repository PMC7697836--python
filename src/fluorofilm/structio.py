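"""Coordinate-file I/O (XYZ, GRO, PDB) and chain-vector extraction.

Internal units are nm with z as the interface normal. XYZ and GRO files are
written in nm; PDB files in Angstrom (converted on write/read). Multi-frame
trajectories are concatenated XYZ frames, or MODEL/ENDMDL blocks in PDB.

The XYZ dialect written here carries an optional fifth column with the
0-based molecule index and encodes the box and time stamp on the comment
line (``box=bx,by,bz t=T``); plain 4-column XYZ from other programs is read
by reconstructing molecules from bond connectivity.
"""

from __future__ import annotations

import math
from collections import deque
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .frames import ChainVectorSet, MonolayerFrame

__all__ = ["read_frames", "write_frames", "extract_chain_vectors",
           "bond_list", "BOND_CUTOFFS"]

# Distance thresholds (nm) used for bond detection, per element pair.
BOND_CUTOFFS = {
    frozenset(("C", "C")): 0.20,
    frozenset(("C", "O")): 0.18,
    frozenset(("C", "F")): 0.16,
    frozenset(("C", "H")): 0.13,
    frozenset(("O", "H")): 0.12,
}
_HEAD_CO_CUTOFF = 0.16  # head rule: carbon bonded to oxygen closer than this


class FormatError(ValueError):
    """Malformed coordinate file; message reports line and field."""


def _sniff_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("xyz", "gro", "pdb"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_xyz_comment(comment: str) -> tuple[np.ndarray | None, float | None]:
    box = None
    time = None
    for tok in comment.split():
        if tok.startswith("box="):
            try:
                box = np.array([float(v) for v in tok[4:].split(",")])
            except ValueError:
                raise FormatError(f"bad box spec in comment: {tok!r}")
        elif tok.startswith("t="):
            try:
                time = float(tok[2:])
            except ValueError:
                raise FormatError(f"bad time stamp in comment: {tok!r}")
    return box, time


def _molecules_from_bonds(elements: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Infer molecule membership as connected components of the bond graph."""
    n = len(elements)
    bonds = bond_list(elements, positions)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    labels = -np.ones(n, dtype=int)
    current = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        queue = deque([start])
        labels[start] = current
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if labels[v] < 0:
                    labels[v] = current
                    queue.append(v)
        current += 1
    return labels


def _read_xyz(path: Path) -> list[MonolayerFrame]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise FormatError(f"{path}:{ln + 1}: expected atom count, "
                              f"got {lines[ln]!r}")
        if ln + 2 + n > len(lines):
            raise FormatError(f"{path}:{ln + 1}: truncated frame")
        box, time = _parse_xyz_comment(lines[ln + 1])
        elements, pos, mol = [], [], []
        has_mol = None
        for k in range(n):
            fields = lines[ln + 2 + k].split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{ln + 3 + k}: expected "
                                  f"'element x y z [mol]', got {len(fields)} fields")
            elements.append(fields[0])
            try:
                pos.append([float(fields[1]), float(fields[2]), float(fields[3])])
            except ValueError:
                raise FormatError(f"{path}:{ln + 3 + k}: non-numeric coordinate")
            if has_mol is None:
                has_mol = len(fields) >= 5
            if has_mol:
                if len(fields) < 5:
                    raise FormatError(f"{path}:{ln + 3 + k}: missing molecule id")
                mol.append(int(fields[4]))
        pos = np.asarray(pos)
        elements = np.array(elements, dtype=object)
        if has_mol:
            mol_idx = np.asarray(mol, dtype=int)
        else:
            mol_idx = _molecules_from_bonds(elements, pos)
        if box is None:
            span = pos.max(axis=0) - pos.min(axis=0)
            box = span + 1.0
        frames.append(MonolayerFrame(pos, elements, mol_idx, box, time))
        ln += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    _check_consistent(frames, path)
    return frames


def _read_gro(path: Path) -> list[MonolayerFrame]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        title = lines[ln]
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                time = None
        try:
            n = int(lines[ln + 1].strip())
        except (ValueError, IndexError):
            raise FormatError(f"{path}:{ln + 2}: expected atom count")
        elements, pos, resids = [], [], []
        for k in range(n):
            line = lines[ln + 2 + k]
            if len(line) < 44:
                raise FormatError(f"{path}:{ln + 3 + k}: GRO line too short")
            try:
                resids.append(int(line[0:5]))
                name = line[10:15].strip()
                pos.append([float(line[20:28]), float(line[28:36]),
                            float(line[36:44])])
            except ValueError:
                raise FormatError(f"{path}:{ln + 3 + k}: bad GRO fields")
            elements.append(_element_from_name(name))
        box_fields = lines[ln + 2 + n].split()
        if len(box_fields) < 3:
            raise FormatError(f"{path}:{ln + 3 + n}: bad box line")
        box = np.array([float(v) for v in box_fields[:3]])
        mol_idx = _contiguous_from_resids(np.asarray(resids, dtype=int))
        frames.append(MonolayerFrame(np.asarray(pos),
                                     np.array(elements, dtype=object),
                                     mol_idx, box, time))
        ln += 3 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    _check_consistent(frames, path)
    return frames


def _read_pdb(path: Path) -> list[MonolayerFrame]:
    frames = []
    box = None
    time = None
    elements, pos, resids = [], [], []

    def _flush():
        nonlocal elements, pos, resids, time
        if not pos:
            return
        b = box if box is not None else (np.ptp(np.asarray(pos), axis=0) + 10.0)
        mol_idx = _contiguous_from_resids(np.asarray(resids, dtype=int))
        frames.append(MonolayerFrame(np.asarray(pos) / 10.0,  # A -> nm
                                     np.array(elements, dtype=object),
                                     mol_idx, np.asarray(b) / 10.0, time))
        elements, pos, resids = [], [], []
        time = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec == "CRYST1":
                box = np.array([float(line[6:15]), float(line[15:24]),
                                float(line[24:33])])
            elif rec.startswith("REMARK") and "TIME_NS" in line:
                try:
                    time = float(line.split("TIME_NS")[1].split()[0])
                except (ValueError, IndexError):
                    time = None
            elif rec in ("HETATM", "ATOM  "):
                try:
                    resids.append(int(line[22:26]))
                    pos.append([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad PDB coordinate fields")
                el = line[76:78].strip() if len(line) >= 78 else ""
                if not el:
                    el = _element_from_name(line[12:16].strip())
                elements.append(el.capitalize())
            elif rec.startswith("ENDMDL"):
                _flush()
    _flush()
    if not frames:
        raise FormatError(f"{path}: no frames found")
    _check_consistent(frames, path)
    return frames


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if stripped[0].upper() in ("C", "O", "F", "H", "N", "S"):
        return stripped[0].upper()
    return stripped[0].upper()


def _contiguous_from_resids(resids: np.ndarray) -> np.ndarray:
    """Map residue numbers (possibly wrapped at format width) to contiguous
    0-based molecule indices; a new molecule starts whenever the residue
    number changes between consecutive atoms."""
    if len(resids) == 0:
        return resids
    changes = np.concatenate([[True], resids[1:] != resids[:-1]])
    return np.cumsum(changes) - 1


def _check_consistent(frames: list[MonolayerFrame], path: Path) -> None:
    n0 = frames[0].n_atoms
    for i, f in enumerate(frames):
        if f.n_atoms != n0:
            raise FormatError(f"{path}: frame {i} has {f.n_atoms} atoms, "
                              f"expected {n0}")


def read_frames(path: str | Path, format: str | None = None) -> list[MonolayerFrame]:
    """Read one or more frames from an XYZ, GRO or PDB file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _sniff_format(path, format)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "gro":
        return _read_gro(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_xyz(frames: list[MonolayerFrame], path: Path) -> None:
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{f.n_atoms}\n")
            comment = "box={:.6f},{:.6f},{:.6f}".format(*f.box)
            if f.time_label is not None:
                comment += f" t={f.time_label:g}"
            fh.write(comment + "\n")
            for el, (x, y, z), m in zip(f.elements, f.positions,
                                        f.molecule_index):
                fh.write(f"{el:<2s} {x:12.6f} {y:12.6f} {z:12.6f} {m:d}\n")


def _write_gro(frames: list[MonolayerFrame], path: Path) -> None:
    with open(path, "w") as fh:
        for f in frames:
            title = "fluorofilm monolayer"
            if f.time_label is not None:
                title += f" t= {f.time_label:g}"
            fh.write(title + "\n")
            fh.write(f"{f.n_atoms:5d}\n")
            species = f.meta.get("species")
            counters: dict[int, int] = {}
            for i, (el, (x, y, z), m) in enumerate(
                    zip(f.elements, f.positions, f.molecule_index)):
                counters[m] = counters.get(m, 0) + 1
                resname = "MOL"
                if species is not None:
                    resname = str(species[m])[:5]
                atname = f"{el}{counters[m] % 1000}"
                fh.write(f"{(m + 1) % 100000:5d}{resname:<5s}{atname:>5s}"
                         f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
            fh.write("{:10.5f}{:10.5f}{:10.5f}\n".format(*f.box))


def _write_pdb(frames: list[MonolayerFrame], path: Path) -> None:
    multi = len(frames) > 1
    with open(path, "w") as fh:
        f0 = frames[0]
        fh.write("CRYST1{:9.3f}{:9.3f}{:9.3f}{:7.2f}{:7.2f}{:7.2f} P 1\n".format(
            f0.box[0] * 10, f0.box[1] * 10, f0.box[2] * 10, 90.0, 90.0, 90.0))
        for imodel, f in enumerate(frames, 1):
            if multi:
                fh.write(f"MODEL {imodel:8d}\n")
            if f.time_label is not None:
                fh.write(f"REMARK   6 TIME_NS {f.time_label:g}\n")
            species = f.meta.get("species")
            counters: dict[int, int] = {}
            for i, (el, (x, y, z), m) in enumerate(
                    zip(f.elements, f.positions, f.molecule_index)):
                counters[m] = counters.get(m, 0) + 1
                resname = "MOL"
                if species is not None:
                    resname = str(species[m])[:3]
                atname = f"{el}{counters[m] % 100}"
                fh.write(
                    "HETATM{serial:5d} {name:<4s}{res:>4s} {resseq:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bf:6.2f}          "
                    "{el:>2s}\n".format(
                        serial=(i + 1) % 100000, name=atname[:4], res=resname,
                        resseq=(m + 1) % 10000, x=x * 10, y=y * 10, z=z * 10,
                        occ=1.0, bf=0.0, el=el))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_frames(frames: MonolayerFrame | list[MonolayerFrame],
                 path: str | Path, format: str | None = None) -> None:
    """Write frame(s) to XYZ/GRO/PDB; format inferred from the suffix."""
    if isinstance(frames, MonolayerFrame):
        frames = [frames]
    path = Path(path)
    fmt = _sniff_format(path, format)
    if fmt == "xyz":
        _write_xyz(frames, path)
    elif fmt == "gro":
        _write_gro(frames, path)
    elif fmt == "pdb":
        _write_pdb(frames, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# chain vectors
# ---------------------------------------------------------------------------

def bond_list(elements: np.ndarray, positions: np.ndarray) -> list[tuple[int, int]]:
    """All bonded atom pairs under the per-element-pair distance thresholds."""
    n = len(elements)
    if n < 2:
        return []
    d = cdist(positions, positions)
    pairs = []
    max_cut = max(BOND_CUTOFFS.values())
    ii, jj = np.nonzero((d < max_cut) & np.triu(np.ones((n, n), bool), 1))
    for i, j in zip(ii, jj):
        cut = BOND_CUTOFFS.get(frozenset((elements[i], elements[j])))
        if cut is not None and d[i, j] < cut:
            pairs.append((int(i), int(j)))
    return pairs


def _carbon_path_lengths(elements: np.ndarray, bonds: list[tuple[int, int]],
                         start: int) -> dict[int, int]:
    """BFS bonded-path lengths from ``start`` over the carbon skeleton."""
    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        if elements[i] == "C" and elements[j] == "C":
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def extract_chain_vectors(frame: MonolayerFrame,
                          head_rule=None, tail_rule=None) -> ChainVectorSet:
    """Per-molecule end-to-end vectors, head carbon -> terminal chain carbon.

    Default rules: the head is the unique carbon within 0.16 nm of an oxygen
    atom; the tail is the carbon with the longest bonded path (C-C bonds
    < 0.20 nm) from the head, ties broken by highest atom index. Custom rules
    are callables ``rule(elements, positions, bonds) -> atom index`` applied
    per molecule.
    """
    n_mol = frame.n_molecules
    vectors = np.zeros((n_mol, 3))
    for m in range(n_mol):
        sel = np.nonzero(frame.molecule_index == m)[0]
        els = frame.elements[sel]
        pos = frame.positions[sel]
        bonds = bond_list(els, pos)
        if head_rule is not None:
            head = head_rule(els, pos, bonds)
        else:
            ox = np.nonzero(els == "O")[0]
            carb = np.nonzero(els == "C")[0]
            if len(ox) == 0 or len(carb) == 0:
                raise ValueError(f"molecule {m}: no oxygen-bonded carbon")
            d_co = cdist(pos[carb], pos[ox])
            heads = carb[np.nonzero((d_co < _HEAD_CO_CUTOFF).any(axis=1))[0]]
            if len(heads) != 1:
                raise ValueError(
                    f"molecule {m}: {len(heads)} head-carbon candidates")
            head = int(heads[0])
        if tail_rule is not None:
            tail = tail_rule(els, pos, bonds)
        else:
            dist = _carbon_path_lengths(els, bonds, head)
            best = max(dist.values())
            candidates = [k for k, v in dist.items() if v == best]
            tail = max(candidates)
        if tail == head:
            raise ValueError(f"molecule {m}: degenerate chain (head == tail)")
        vectors[m] = pos[tail] - pos[head]
    return ChainVectorSet(vectors=vectors, centroids=frame.centroids(),
                          molecule_ids=np.arange(n_mol))
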
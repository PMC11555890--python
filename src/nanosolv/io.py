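"""Plain-text structure readers/writers (XYZ and PDB dialects).

XYZ files carry the box edges on the comment line as ``box Lx Ly Lz``;
PDB files carry them in a CRYST1 record.  Round-trips preserve elements
exactly and coordinates to the format precision (1e-6 angstrom for XYZ,
5e-4 for fixed-column PDB).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np

from .structures import RigidMolecule, SimulationBox, SolvatedSystem

__all__ = [
    "write_structure",
    "read_structure",
    "read_frame",
    "write_xyz_frames",
    "read_xyz_frames",
]


class StructureFormatError(ValueError):
    """Malformed structure file; message carries the offending line number."""


def _flatten(obj: RigidMolecule | SolvatedSystem):
    if isinstance(obj, RigidMolecule):
        return list(obj.elements), obj.positions, None
    elements: list[str] = []
    blocks = []
    if obj.solute is not None:
        elements += list(obj.solute.elements)
        blocks.append(obj.solute.positions)
    for w in obj.waters:
        elements += list(w.elements)
        blocks.append(w.positions)
    coords = np.vstack(blocks) if blocks else np.zeros((0, 3))
    return elements, coords, obj.box


def write_structure(obj: RigidMolecule | SolvatedSystem, path: str | Path) -> None:
    """Write a molecule or solvated system as .xyz or .pdb (by suffix)."""
    path = Path(path)
    elements, coords, box = _flatten(obj)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "xyz":
        comment = ""
        if box is not None:
            lx, ly, lz = box.edge_lengths
            comment = f"box {lx:.6f} {ly:.6f} {lz:.6f}"
        _write_xyz_block(path.open("w"), elements, coords, comment)
    elif fmt == "pdb":
        with path.open("w") as fh:
            if box is not None:
                lx, ly, lz = box.edge_lengths
                fh.write(
                    f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
                    f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
                )
            for i, (el, xyz) in enumerate(zip(elements, coords), start=1):
                name = el.rjust(2)
                fh.write(
                    f"HETATM{i % 100000:5d} {name:<4s}MOL A   1    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}\n"
                )
            fh.write("END\n")
    else:
        raise ValueError(f"unknown structure format {fmt!r}")


def _write_xyz_block(fh, elements, coords, comment="") -> None:
    with fh:
        fh.write(f"{len(elements)}\n{comment}\n")
        for el, xyz in zip(elements, coords):
            fh.write(f"{el:<2s} {xyz[0]:15.6f} {xyz[1]:15.6f} {xyz[2]:15.6f}\n")


def read_frame(path: str | Path):
    """Read a structure file; returns (elements, coords, box-or-None)."""
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValueError(f"unknown structure format {fmt!r}")


def read_structure(path: str | Path) -> RigidMolecule:
    """Read a structure file into a RigidMolecule (zero charges/LJ terms)."""
    elements, coords, _ = read_frame(path)
    n = len(elements)
    return RigidMolecule(
        molecule_id=Path(path).stem,
        elements=elements,
        positions=coords,
        charges=np.zeros(n),
        lj_sigma=np.zeros(n),
        lj_epsilon=np.zeros(n),
    )


def _read_xyz(path: Path):
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureFormatError(f"{path}:1: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureFormatError(f"{path}:1: bad atom count header") from None
    if len(lines) < n + 2:
        raise StructureFormatError(
            f"{path}:{len(lines)}: expected {n} atom lines, file truncated"
        )
    comment = lines[1] if len(lines) > 1 else ""
    box = None
    match = re.match(r"\s*box\s+([\d.eE+-]+)\s+([\d.eE+-]+)\s+([\d.eE+-]+)", comment)
    if match:
        box = SimulationBox(tuple(float(g) for g in match.groups()))
    elements, coords = [], []
    for lineno, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise StructureFormatError(f"{path}:{lineno}: bad atom line")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise StructureFormatError(
                f"{path}:{lineno}: non-numeric coordinate"
            ) from None
        elements.append(parts[0])
        coords.append(xyz)
    return elements, np.array(coords), box


def _read_pdb(path: Path):
    elements, coords = [], []
    box = None
    for lineno, line in enumerate(path.open(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                box = SimulationBox(
                    (float(line[6:15]), float(line[15:24]), float(line[24:33]))
                )
            except ValueError:
                raise StructureFormatError(f"{path}:{lineno}: bad CRYST1") from None
        elif rec in ("ATOM  ", "HETATM"):
            try:
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except ValueError:
                raise StructureFormatError(
                    f"{path}:{lineno}: bad coordinates"
                ) from None
            el = line[76:78].strip() or line[12:16].strip()[:1]
            elements.append(el)
            coords.append(xyz)
    if not elements:
        raise StructureFormatError(f"{path}:1: no atom records found")
    return elements, np.array(coords), box


def write_xyz_frames(
    path: str | Path,
    frames: Iterable[np.ndarray],
    elements: list[str],
    comments: Iterable[str] | None = None,
) -> None:
    """Write a multi-frame XYZ trajectory (frame index in the comment)."""
    path = Path(path)
    comments = list(comments) if comments is not None else None
    with path.open("w") as fh:
        for k, coords in enumerate(frames):
            coords = np.asarray(coords, float).reshape(-1, 3)
            label = comments[k] if comments else f"frame {k}"
            fh.write(f"{len(elements)}\n{label}\n")
            for el, xyz in zip(elements, coords):
                fh.write(f"{el:<2s} {xyz[0]:15.6f} {xyz[1]:15.6f} {xyz[2]:15.6f}\n")


def read_xyz_frames(path: str | Path):
    """Read a multi-frame XYZ trajectory; returns (elements, list of coords)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    elements: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise StructureFormatError(f"{path}:{i + 1}: bad frame header") from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise StructureFormatError(f"{path}:{i + 1}: truncated frame")
        els = [ln.split()[0] for ln in block]
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        if not elements:
            elements = els
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise StructureFormatError(f"{path}:1: empty trajectory")
    return elements, frames
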
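"""Structure file I/O: fixed-column PDB (single and multi-model) and XYZ.

The PDB reader is deliberately tolerant of fixed-column drift: it first
tries the standard column layout and falls back to whitespace splitting
when the coordinate fields do not parse.  Parse failures always report the
offending line number.  Elements are taken from the element column when
present, otherwise inferred from the atom-name column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import Trajectory
from .system import MolecularSystem

__all__ = ["Structure", "StructureParseError", "read_structure",
           "write_structure", "write_trajectory", "load_system"]


class StructureParseError(ValueError):
    """Malformed structure file; the message names the line."""


@dataclass
class Structure:
    """Coordinates plus atom records parsed from a structure file.

    ``frames`` has shape (n_models, N, 3); single-model files produce one
    frame, accessible as ``coords``.
    """

    frames: np.ndarray
    elements: list[str]
    names: list[str] = field(default_factory=list)
    box: np.ndarray | None = None
    comment: str = ""

    @property
    def coords(self) -> np.ndarray:
        return self.frames[0]

    @property
    def n_models(self) -> int:
        return self.frames.shape[0]

    def to_trajectory(self) -> Trajectory:
        return Trajectory(frames=self.frames,
                          info={"elements": list(self.elements)})


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            # two-letter elements in toy systems: NA, CL
            if stripped[:2].upper() in ("NA", "CL") and len(stripped) >= 2:
                return stripped[:2].upper()
            return ch.upper()
    return "X"


def _parse_pdb_atom(line: str, lineno: int):
    name = line[12:16] if len(line) > 16 else ""
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        # fixed-column drift: fall back to whitespace fields, taking the
        # first run of three consecutive decimal-point numbers (serial and
        # residue numbers are plain integers and are skipped)
        toks = line.split()
        floats: list[float] = []
        for t in toks[1:]:
            looks_decimal = ("." in t or "e" in t.lower())
            try:
                val = float(t)
            except ValueError:
                looks_decimal = False
            if looks_decimal:
                floats.append(val)
                if len(floats) == 3:
                    break
            else:
                floats = []
        if len(floats) < 3:
            raise StructureParseError(
                f"line {lineno}: cannot parse coordinates from {line.rstrip()!r}")
        x, y, z = floats[:3]
        name = toks[2] if len(toks) > 2 else ""
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _element_from_name(name)
    return name.strip(), element.upper(), (x, y, z)


def _read_pdb(path) -> Structure:
    frames = []
    current: list | None = None
    names: list[str] = []
    elements: list[str] = []
    box = None
    first_model_done = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])])
                except ValueError:
                    raise StructureParseError(
                        f"line {lineno}: malformed CRYST1 record")
            elif rec == "MODEL":
                current = []
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                name, el, xyz = _parse_pdb_atom(line, lineno)
                current.append(xyz)
                if not first_model_done:
                    names.append(name)
                    elements.append(el)
            elif rec == "ENDMDL":
                if current is None:
                    raise StructureParseError(
                        f"line {lineno}: ENDMDL without a MODEL")
                frames.append(current)
                current = None
                first_model_done = True
    if current:
        frames.append(current)
    if not frames:
        raise StructureParseError(f"{path}: no ATOM/HETATM records found")
    n = len(frames[0])
    for k, f in enumerate(frames):
        if len(f) != n:
            raise StructureParseError(
                f"{path}: model {k + 1} has {len(f)} atoms, expected {n}")
    return Structure(frames=np.array(frames, dtype=np.float64),
                     elements=elements, names=names, box=box)


def _read_xyz(path) -> Structure:
    frames = []
    elements: list[str] = []
    comment = ""
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    first = True
    while i < len(lines):
        header = lines[i].strip()
        if not header:
            i += 1
            continue
        try:
            n = int(header)
        except ValueError:
            raise StructureParseError(
                f"line {i + 1}: expected an atom count, got {header!r}")
        if i + 1 >= len(lines):
            raise StructureParseError(
                f"line {i + 1}: file truncated (missing comment line)")
        if first:
            comment = lines[i + 1].rstrip("\n")
        coords = []
        for j in range(n):
            idx = i + 2 + j  # 0-based index of atom line j
            lineno = idx + 1
            if idx >= len(lines):
                raise StructureParseError(f"line {lineno}: file truncated")
            toks = lines[idx].split()
            if len(toks) < 4:
                raise StructureParseError(
                    f"line {lineno}: expected 'element x y z'")
            if first:
                elements.append(toks[0].upper())
            try:
                coords.append([float(toks[1]), float(toks[2]), float(toks[3])])
            except ValueError:
                raise StructureParseError(
                    f"line {lineno}: cannot parse coordinates")
        frames.append(coords)
        first = False
        i += 2 + n
    if not frames:
        raise StructureParseError(f"{path}: empty XYZ file")
    return Structure(frames=np.array(frames, dtype=np.float64),
                     elements=elements, names=list(elements), comment=comment)


def read_structure(path, fmt: str | None = None) -> Structure:
    """Read a PDB or XYZ file (format inferred from the suffix by default)."""
    path = str(path)
    if fmt is None:
        fmt = "xyz" if path.lower().endswith(".xyz") else "pdb"
    fmt = fmt.lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unsupported format {fmt!r} (use 'pdb' or 'xyz')")


def _pdb_atom_line(i, name, element, xyz, resname="MOL", resseq=1):
    # element column right-justified in 77-78 per the fixed-column layout
    name_f = name if len(name) >= 4 else f" {name:<3s}"
    return (f"HETATM{i + 1:5d} {name_f[:4]:4s}{resname:>4s} A{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element[:2]:>2s}\n")


def _atom_names(elements):
    counts: dict[str, int] = {}
    names = []
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
        names.append(f"{el}{counts[el]}"[:4])
    return names


def write_structure(path, obj, fmt: str | None = None, comment: str = "") -> None:
    """Write a system/structure/frame to PDB or XYZ (deterministic output)."""
    path = str(path)
    if fmt is None:
        fmt = "xyz" if path.lower().endswith(".xyz") else "pdb"
    if isinstance(obj, MolecularSystem):
        frames = obj.coords[None]
        elements = list(obj.elements)
        box = obj.box
    elif isinstance(obj, Structure):
        frames = obj.frames
        elements = list(obj.elements)
        box = obj.box
    else:  # bare coordinate array + no elements: label as carbon
        frames = np.asarray(obj, dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        elements = ["C"] * frames.shape[1]
        box = None
    _write_frames(path, frames, elements, fmt, box, comment)


def write_trajectory(path, trajectory: Trajectory, elements=None,
                     fmt: str | None = None, comment: str = "") -> None:
    """Write a trajectory as a multi-model PDB or multi-frame XYZ."""
    path = str(path)
    if fmt is None:
        fmt = "xyz" if path.lower().endswith(".xyz") else "pdb"
    if elements is None:
        elements = trajectory.info.get("elements") or ["C"] * trajectory.n_atoms
    _write_frames(path, trajectory.frames, list(elements), fmt, None, comment)


def _write_frames(path, frames, elements, fmt, box, comment):
    names = _atom_names(elements)
    fmt = fmt.lower()
    with open(path, "w") as fh:
        if fmt == "pdb":
            if box is not None:
                fh.write(f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                         f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
            multi = frames.shape[0] > 1
            for k, frame in enumerate(frames):
                if multi:
                    fh.write(f"MODEL     {k + 1:4d}\n")
                for i, xyz in enumerate(frame):
                    fh.write(_pdb_atom_line(i, names[i], elements[i], xyz))
                if multi:
                    fh.write("ENDMDL\n")
            fh.write("END\n")
        elif fmt == "xyz":
            for k, frame in enumerate(frames):
                fh.write(f"{frame.shape[0]}\n")
                fh.write((comment or f"frame {k}") + "\n")
                for el, xyz in zip(elements, frame):
                    fh.write(f"{el:<2s} {xyz[0]:15.8f} {xyz[1]:15.8f} "
                             f"{xyz[2]:15.8f}\n")
        else:
            raise ValueError(f"unsupported format {fmt!r}")


def load_system(structure_path, params_path) -> MolecularSystem:
    """Assemble a MolecularSystem from a structure file + parameter file."""
    from .params_io import read_parameters

    struct = read_structure(structure_path)
    params, elements, rotatable, extras = read_parameters(params_path)
    roles = extras.get("roles")
    box = extras.get("box")
    if box is None and struct.box is not None:
        box = struct.box
    return MolecularSystem(
        elements=elements if elements else struct.elements,
        params=params, coords=struct.coords,
        box=None if box is None else np.asarray(box, dtype=np.float64),
        roles=None if roles is None else np.asarray(roles, dtype=np.intp),
        rotatable_bonds=rotatable)
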
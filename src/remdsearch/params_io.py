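"""Native parameter file: YAML schema carrying every force-field constant.

One document fully parametrizes a system: per-atom records (element, mass,
charge, LJ, optional Born radius), bonded terms keyed by atom indices,
1-4 scaling factors and the rotatable-bond list.  The schema is versioned;
validation is strict and errors name the offending section, entry index
and field (YAML syntax errors additionally carry the line/column mark).
"""

from __future__ import annotations

import numpy as np
import yaml

from .system import ForceFieldParameters, MolecularSystem, ParametrizationError

__all__ = ["ParameterFileError", "read_parameters", "write_parameters",
           "SCHEMA_VERSION", "FORMAT_TAG"]

SCHEMA_VERSION = 1
FORMAT_TAG = "remdsearch-parameters"


class ParameterFileError(ValueError):
    """Malformed or inconsistent parameter file."""


def _need(entry, key, kind, where):
    if key not in entry:
        raise ParameterFileError(f"{where}: missing required key {key!r}")
    val = entry[key]
    try:
        if kind is float:
            return float(val)
        if kind is int:
            iv = int(val)
            if iv != val:
                raise ValueError
            return iv
        if kind is str:
            return str(val)
        if kind is list:
            return list(val)
    except (TypeError, ValueError):
        raise ParameterFileError(
            f"{where}: key {key!r} must be of type {kind.__name__}, "
            f"got {val!r}")
    raise AssertionError(kind)


def read_parameters(path):
    """Parse a parameter file.

    Returns ``(params, elements, rotatable_bonds, extras)`` where
    ``extras`` holds optional sections (roles, box) for callers assembling
    a full system.
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
            raise ParameterFileError(f"{path}: YAML syntax error{loc}: {exc}")
    if not isinstance(doc, dict):
        raise ParameterFileError(f"{path}: top level must be a mapping")
    if doc.get("format") != FORMAT_TAG:
        raise ParameterFileError(
            f"{path}: not a {FORMAT_TAG} document (format: {doc.get('format')!r})")
    version = doc.get("version")
    if version != SCHEMA_VERSION:
        raise ParameterFileError(
            f"{path}: unsupported schema version {version!r} "
            f"(expected {SCHEMA_VERSION})")

    atoms = doc.get("atoms")
    if not isinstance(atoms, list) or not atoms:
        raise ParameterFileError(f"{path}: 'atoms' must be a non-empty list")
    elements, mass, charge, eps, sigma = [], [], [], [], []
    born = []
    any_born = False
    for i, a in enumerate(atoms):
        where = f"{path}: atoms[{i}]"
        if not isinstance(a, dict):
            raise ParameterFileError(f"{where}: must be a mapping")
        elements.append(_need(a, "element", str, where))
        mass.append(_need(a, "mass", float, where))
        charge.append(_need(a, "charge", float, where))
        eps.append(_need(a, "epsilon", float, where))
        sigma.append(_need(a, "sigma", float, where))
        if "born_radius" in a:
            any_born = True
            born.append(float(a["born_radius"]))
        else:
            born.append(np.nan)
    n = len(atoms)

    def read_terms(section, width, fields):
        rows = doc.get(section, []) or []
        if not isinstance(rows, list):
            raise ParameterFileError(f"{path}: '{section}' must be a list")
        idx, cols = [], {f: [] for f, _ in fields}
        for i, row in enumerate(rows):
            where = f"{path}: {section}[{i}]"
            if not isinstance(row, dict):
                raise ParameterFileError(f"{where}: must be a mapping")
            at = _need(row, "atoms", list, where)
            if len(at) != width or not all(isinstance(x, int) for x in at):
                raise ParameterFileError(
                    f"{where}: 'atoms' must list {width} integer indices")
            if any(x < 0 or x >= n for x in at):
                raise ParameterFileError(
                    f"{where}: atom index out of range 0..{n - 1}: {at}")
            idx.append(at)
            for f, kind in fields:
                cols[f].append(_need(row, f, kind, where))
        return idx, cols

    bond_idx, bcols = read_terms("bonds", 2, [("k", float), ("r0", float)])
    angle_idx, acols = read_terms(
        "angles", 3, [("k", float), ("theta0_deg", float)])

    dih_idx, dih_k, dih_n, dih_g = [], [], [], []
    for i, row in enumerate(doc.get("dihedrals", []) or []):
        where = f"{path}: dihedrals[{i}]"
        if not isinstance(row, dict):
            raise ParameterFileError(f"{where}: must be a mapping")
        at = _need(row, "atoms", list, where)
        if len(at) != 4 or not all(isinstance(x, int) for x in at):
            raise ParameterFileError(f"{where}: 'atoms' must list 4 integer indices")
        if any(x < 0 or x >= n for x in at):
            raise ParameterFileError(f"{where}: atom index out of range: {at}")
        terms = row.get("terms")
        if not isinstance(terms, list) or not terms:
            raise ParameterFileError(f"{where}: 'terms' must be a non-empty list")
        for j, t in enumerate(terms):
            tw = f"{where}.terms[{j}]"
            dih_idx.append(at)
            dih_k.append(_need(t, "k", float, tw))
            mult = _need(t, "n", int, tw)
            if mult < 1:
                raise ParameterFileError(f"{tw}: multiplicity n must be >= 1")
            dih_n.append(mult)
            dih_g.append(np.deg2rad(_need(t, "gamma_deg", float, tw)))

    scale = doc.get("scale14", {}) or {}
    rot = doc.get("rotatable_bonds", []) or []
    for i, pair in enumerate(rot):
        if (not isinstance(pair, list) or len(pair) != 2
                or not all(isinstance(x, int) and 0 <= x < n for x in pair)):
            raise ParameterFileError(
                f"{path}: rotatable_bonds[{i}] must be a pair of atom indices")

    try:
        params = ForceFieldParameters(
            bond_idx=np.array(bond_idx, dtype=np.intp).reshape(-1, 2),
            bond_k=np.array(bcols["k"]), bond_r0=np.array(bcols["r0"]),
            angle_idx=np.array(angle_idx, dtype=np.intp).reshape(-1, 3),
            angle_k=np.array(acols["k"]),
            angle_theta0=np.deg2rad(np.array(acols["theta0_deg"])),
            dihedral_idx=np.array(dih_idx, dtype=np.intp).reshape(-1, 4),
            dihedral_k=np.array(dih_k), dihedral_n=np.array(dih_n, dtype=np.intp),
            dihedral_gamma=np.array(dih_g),
            epsilon=np.array(eps), sigma=np.array(sigma),
            charge=np.array(charge), mass=np.array(mass),
            born_radius=np.array(born) if any_born else None,
            scale14_lj=float(scale.get("lj", 0.5)),
            scale14_coulomb=float(scale.get("coulomb", 1.0 / 1.2)))
    except ParametrizationError as exc:
        raise ParameterFileError(f"{path}: {exc}")
    if any_born and np.any(np.isnan(params.born_radius)):
        missing = int(np.flatnonzero(np.isnan(params.born_radius))[0])
        raise ParameterFileError(
            f"{path}: atoms[{missing}]: born_radius given for some atoms "
            "but missing here (must be all or none)")
    extras = {"roles": doc.get("roles"), "box": doc.get("box")}
    rb = (np.array(rot, dtype=np.intp).reshape(-1, 2) if rot
          else np.zeros((0, 2), dtype=np.intp))
    return params, elements, rb, extras


def write_parameters(path, system: MolecularSystem) -> None:
    """Serialize a system's parameters and topology to the native format."""
    p = system.params
    atoms = []
    for i in range(system.n_atoms):
        rec = {
            "element": system.elements[i],
            "mass": float(p.mass[i]),
            "charge": float(p.charge[i]),
            "epsilon": float(p.epsilon[i]),
            "sigma": float(p.sigma[i]),
        }
        if p.born_radius is not None:
            rec["born_radius"] = float(p.born_radius[i])
        atoms.append(rec)
    bonds = [{"atoms": [int(a), int(b)], "k": float(k), "r0": float(r0)}
             for (a, b), k, r0 in zip(p.bond_idx, p.bond_k, p.bond_r0)]
    angles = [{"atoms": [int(a), int(b), int(c)], "k": float(k),
               "theta0_deg": float(np.rad2deg(t0))}
              for (a, b, c), k, t0 in zip(p.angle_idx, p.angle_k, p.angle_theta0)]
    dih_map: dict[tuple, list] = {}
    for (quad, k, mult, g) in zip(p.dihedral_idx, p.dihedral_k,
                                  p.dihedral_n, p.dihedral_gamma):
        dih_map.setdefault(tuple(int(x) for x in quad), []).append(
            {"k": float(k), "n": int(mult), "gamma_deg": float(np.rad2deg(g))})
    dihedrals = [{"atoms": list(quad), "terms": terms}
                 for quad, terms in dih_map.items()]
    doc = {
        "format": FORMAT_TAG,
        "version": SCHEMA_VERSION,
        "scale14": {"lj": float(p.scale14_lj),
                    "coulomb": float(p.scale14_coulomb)},
        "atoms": atoms,
        "bonds": bonds,
        "angles": angles,
        "dihedrals": dihedrals,
        "rotatable_bonds": [[int(a), int(b)] for a, b in system.rotatable_bonds],
        "roles": [int(r) for r in system.roles],
    }
    if system.box is not None:
        doc["box"] = [float(x) for x in system.box]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
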
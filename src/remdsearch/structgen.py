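"""System building: conformer enumeration, solvation, neutralization, fixtures.

The fixture factory supplies fully parametrized toy molecules — stand-ins
for automatically typed drug molecules — so that every downstream stage
(dynamics, replica exchange, clustering) is testable without external
structure builders.  Initial conformer selection follows the rotor-key
idea: every combination of discrete torsion settings around the rotatable
bonds is generated by rigid rotation and ranked by gas-phase energy.

Explicit solvation surrounds the solute with a three-site water model on a
jittered cubic lattice at liquid density inside an orthorhombic cell whose
edge is the solute extent plus twice the padding (default 10 Å), then
deletes waters overlapping the solute.  Charged cells are neutralized by
swapping the waters farthest from the solute for monovalent counterions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .constants import WATER_NUMBER_DENSITY
from .forcefield import EnergyOptions, total_energy
from .system import (ROLE_ION, ROLE_SOLVENT, ForceFieldParameters,
                     MolecularSystem, ParametrizationError)

__all__ = [
    "Conformer",
    "SolvationSpec",
    "enumerate_conformers",
    "solvate",
    "neutralize",
    "make_fixture",
    "FIXTURE_NAMES",
    "cosine_series",
]

DEG = np.pi / 180.0
TETRA = 109.471 * DEG

#: intrinsic Born radii by element (Å), used by the implicit-solvent term
BORN_RADII = {"C": 1.70, "H": 1.20, "O": 1.50, "N": 1.55,
              "NA": 1.80, "CL": 2.27, "X": 1.70}


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _nerf(a, b, c, r, theta, phi):
    """Place an atom at distance ``r`` from a, angle ``theta`` to b, torsion
    ``phi`` to c (natural-extension reference frame construction)."""
    ab = a - b
    n_ab = ab / np.linalg.norm(ab)
    n = np.cross(b - c, ab)
    n /= np.linalg.norm(n)
    m = np.cross(n, n_ab)
    d = np.array([-r * np.cos(theta),
                  r * np.sin(theta) * np.cos(phi),
                  r * np.sin(theta) * np.sin(phi)])
    return a + d[0] * n_ab + d[1] * m + d[2] * n


def _hydrogen_directions(center, neighbor_pos, n_add, ref=None):
    """Unit directions completing a tetrahedral centre with ``n_add`` sites.

    For a terminal centre (one existing neighbour) the azimuth is anchored
    to ``ref`` (typically the grandparent atom position) so the new
    hydrogens stagger rather than eclipse the adjacent branch.
    """
    dirs = [(p - center) / np.linalg.norm(p - center) for p in neighbor_pos]
    out = []
    if len(dirs) == 3:
        d = -(dirs[0] + dirs[1] + dirs[2])
        out.append(d / np.linalg.norm(d))
    elif len(dirs) == 2:
        b = -(dirs[0] + dirs[1])
        b /= np.linalg.norm(b)
        p = np.cross(dirs[0], dirs[1])
        p /= np.linalg.norm(p)
        half = 0.5 * TETRA
        for sgn in (1.0, -1.0)[:n_add]:
            out.append(np.cos(half) * b + sgn * np.sin(half) * p)
    elif len(dirs) == 1:
        d0 = dirs[0]
        if ref is not None:
            # in-plane perpendicular pointing away from the grandparent
            g = ref - center
            p = g - (g @ d0) * d0
        else:
            p = np.array([1.0, 0.0, 0.0])
            if abs(d0 @ p) > 0.9:
                p = np.array([0.0, 1.0, 0.0])
            p = np.cross(d0, p)
        p /= np.linalg.norm(p)
        q = np.cross(d0, p)
        for k in range(n_add):
            # 60° offset from the grandparent plane: staggered rotamer
            az = np.pi / 3.0 + 2.0 * np.pi * k / 3.0
            d = np.cos(np.pi - TETRA) * (-d0) + np.sin(np.pi - TETRA) * (
                np.cos(az) * p + np.sin(az) * q)
            out.append(d / np.linalg.norm(d))
    else:
        raise ValueError("hydrogen completion needs 1-3 existing neighbours")
    return out[:n_add]


# ----------------------------------------------------------------------
# parameter assembly
# ----------------------------------------------------------------------

_BOND_TABLE = {  # (k kcal/mol/Å², r0 Å) by unordered element pair
    ("C", "C"): (310.0, 1.526),
    ("C", "H"): (340.0, 1.090),
    ("C", "O"): (320.0, 1.410),
    ("C", "N"): (330.0, 1.470),
    ("O", "H"): (370.0, 0.960),
    ("N", "H"): (430.0, 1.010),
}

_LJ_TABLE = {  # (epsilon kcal/mol, sigma Å); polar H overridden where needed
    "C": (0.0860, 3.40),
    "H": (0.0150, 2.60),
    "O": (0.1700, 3.12),
    "N": (0.1700, 3.34),
    "X": (0.1000, 3.40),
}

_MASS_TABLE = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007,
               "NA": 22.990, "CL": 35.453, "X": 12.0}


def _bond_param(e1, e2):
    key = (e1, e2) if (e1, e2) in _BOND_TABLE else (e2, e1)
    try:
        return _BOND_TABLE[key]
    except KeyError:
        raise ParametrizationError(f"no bond parameters for pair {e1}-{e2}")


def _angles_from_bonds(n_atoms, bond_idx):
    adj = [[] for _ in range(n_atoms)]
    for i, j in bond_idx:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    angles = []
    for j in range(n_atoms):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    return angles, adj


def _auto_dihedrals(elements, bond_idx, adj, barrier=0.50):
    """One 3-fold cosine term per heavy-heavy central bond.

    The outer atoms are the lowest-index heavy neighbours when available,
    otherwise hydrogens; bonds whose ends lack further neighbours are
    skipped.
    """
    quads = []
    heavy = [e.upper() != "H" for e in elements]

    def pick(center, exclude):
        cands = [n for n in sorted(adj[center]) if n != exclude]
        if not cands:
            return None
        heavy_c = [n for n in cands if heavy[n]]
        return (heavy_c or cands)[0]

    for j, k in bond_idx:
        j, k = int(j), int(k)
        if not (heavy[j] and heavy[k]):
            continue
        i = pick(j, k)
        l = pick(k, j)
        if i is None or l is None:
            continue
        quads.append(((i, j, k, l), barrier))
    return quads


# ----------------------------------------------------------------------
# conformer enumeration (rotor keys)
# ----------------------------------------------------------------------

@dataclass
class Conformer:
    """One rotor-key trial structure with its gas-phase energy."""

    key: tuple
    energy: float
    coords: np.ndarray


def _bond_sides(system: MolecularSystem, a: int, b: int):
    """Atoms rotated when torsion about bond (a, b) is driven.

    The smaller side of the bond rotates; ties rotate the side holding the
    higher atom indices.  A ring bond (both sides connected) is rejected.
    """
    adj = system.bond_graph()
    seen = {a, b}
    stack = [b]
    side_b = set()
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                side_b.add(nb)
                stack.append(nb)
    if a in side_b:
        raise ValueError(f"bond {a}-{b} closes a ring and cannot be driven")
    side_a = set(range(system.n_atoms)) - side_b - {a, b}
    if len(side_b) < len(side_a):
        rot, anchor, pivot = side_b, a, b
    elif len(side_a) < len(side_b):
        rot, anchor, pivot = side_a, b, a
    else:  # tie: rotate the side with the higher atom indices
        if max(side_b, default=-1) >= max(side_a, default=-1):
            rot, anchor, pivot = side_b, a, b
        else:
            rot, anchor, pivot = side_a, b, a
    return np.array(sorted(rot), dtype=np.intp), anchor, pivot


def enumerate_conformers(system: MolecularSystem, resolutions=3,
                         cap: int = 20000,
                         options: EnergyOptions | None = None) -> list[Conformer]:
    """Generate and rank every rotor-key combination by gas-phase energy.

    ``resolutions`` is the number of evenly spaced settings per rotatable
    bond (an int applies to all bonds; the default 3 is a 120° grid).
    Setting ``g`` of resolution ``r`` rotates the moving side of the bond
    by ``g·360°/r`` from the input geometry.  The result is sorted
    ascending by energy (ties by key), so ``result[0]`` is the selected
    lowest-energy starting structure.
    """
    if options is None:
        options = EnergyOptions(mode="gas")
    rb = system.rotatable_bonds
    k = rb.shape[0]
    if k == 0:
        _, e0, _ = total_energy(system, options)
        return [Conformer(key=(), energy=float(e0), coords=system.coords.copy())]
    if np.isscalar(resolutions):
        res = [int(resolutions)] * k
    else:
        res = [int(r) for r in resolutions]
        if len(res) != k:
            raise ValueError("need one resolution per rotatable bond")
    if any(r < 1 for r in res):
        raise ValueError("resolutions must be >= 1")
    total = int(np.prod(res))
    if total > cap:
        raise ValueError(
            f"rotor-key enumeration would generate {total} conformers, "
            f"exceeding the cap of {cap}")
    sides = [_bond_sides(system, int(a), int(b)) for a, b in rb]
    out = []
    for key in itertools.product(*(range(r) for r in res)):
        coords = system.coords.copy()
        for m, g in enumerate(key):
            if g == 0:
                continue
            moving, anchor, pivot = sides[m]
            angle = 2.0 * np.pi * g / res[m]
            axis = coords[pivot] - coords[anchor]
            rot = _rotation_about_axis(axis, angle)
            coords[moving] = (coords[moving] - coords[anchor]) @ rot.T + coords[anchor]
        _, e, _ = total_energy(system, options, coords)
        out.append(Conformer(key=key, energy=float(e), coords=coords))
    out.sort(key=lambda c: (c.energy, c.key))
    return out


# ----------------------------------------------------------------------
# solvation
# ----------------------------------------------------------------------

@dataclass
class SolvationSpec:
    """Water-model geometry and box-construction settings.

    The water is a flexible three-site model with the classic three-site
    charge set and oxygen-centred LJ; O–H bonds are held by SHAKE during
    dynamics, the bend by a harmonic angle.
    """

    padding: float = 10.0  # Å of water beyond the solute extent, each side
    o_h_length: float = 0.9572
    h_o_h_angle_deg: float = 104.52
    q_o: float = -0.834
    q_h: float = 0.417
    eps_o: float = 0.1521
    sigma_o: float = 3.1507
    eps_h: float = 0.0
    sigma_h: float = 0.40
    bond_k: float = 450.0
    angle_k: float = 55.0
    exclusion: float = 2.4  # Å: delete waters whose O is closer to the solute
    jitter: float = 0.25  # Å lattice jitter
    ion_params: dict = field(default_factory=lambda: {
        "NA": {"mass": 22.990, "charge": 1.0, "epsilon": 0.0874, "sigma": 2.439},
        "CL": {"mass": 35.453, "charge": -1.0, "epsilon": 0.0355, "sigma": 4.045},
    })

    def __post_init__(self):
        if self.padding <= 0:
            raise ValueError("padding must be positive")
        if self.exclusion <= 0:
            raise ValueError("exclusion distance must be positive")


def _water_sites(spec: SolvationSpec, origin, rot):
    half = 0.5 * spec.h_o_h_angle_deg * DEG
    u1 = np.array([np.sin(half), 0.0, np.cos(half)])
    u2 = np.array([-np.sin(half), 0.0, np.cos(half)])
    h1 = origin + spec.o_h_length * (rot @ u1)
    h2 = origin + spec.o_h_length * (rot @ u2)
    return h1, h2


def _lattice_waters(box, spec, rng, solute_coords=None):
    spacing = (1.0 / WATER_NUMBER_DENSITY) ** (1.0 / 3.0)
    # per-axis counts rounded to the nearest integer with the spacing
    # stretched to fill the box exactly: mean density stays at the target
    counts = np.maximum(np.round(box / spacing).astype(int), 1)
    per_axis = box / counts
    axes = [per_axis[d] * (0.5 + np.arange(counts[d])) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pts = pts + rng.uniform(-spec.jitter, spec.jitter, pts.shape)
    if solute_coords is not None and len(solute_coords):
        d2 = np.sum((pts[:, None] - solute_coords[None]) ** 2, axis=-1)
        pts = pts[np.min(d2, axis=1) > spec.exclusion ** 2]
    waters = []
    for p in pts:
        rot = _random_rotation(rng)
        h1, h2 = _water_sites(spec, p, rot)
        waters.append((p, h1, h2))
    return waters


def solvate(system: MolecularSystem, spec: SolvationSpec | None = None,
            cutoff: float = 10.0, seed: int = 0) -> MolecularSystem:
    """Embed the solute in a periodic water box with the padding rule.

    Box edge per axis = solute extent + 2 × padding; the solute is
    translated to the box centre.  Waters on a jittered cubic lattice at
    liquid density are deleted when their oxygen lies within the exclusion
    distance of any solute atom.  All solvent atoms are flagged as such.
    """
    if spec is None:
        spec = SolvationSpec()
    rng = np.random.default_rng(seed)
    lo = system.coords.min(axis=0)
    hi = system.coords.max(axis=0)
    box = (hi - lo) + 2.0 * spec.padding
    if np.any(box < 2.0 * cutoff):
        raise ValueError(
            f"solvated box {box} would be smaller than twice the nonbonded "
            f"cutoff ({cutoff} Å); increase the padding")
    shift = box / 2.0 - (lo + hi) / 2.0
    solute_xyz = system.coords + shift
    waters = _lattice_waters(box, spec, rng, solute_xyz)

    p = system.params
    n0 = system.n_atoms
    nw = len(waters)
    elements = list(system.elements) + ["O", "H", "H"] * nw
    coords = np.vstack([solute_xyz] + [np.vstack(w) for w in waters]) if nw \
        else solute_xyz.copy()
    roles = np.concatenate([system.roles,
                            np.full(3 * nw, ROLE_SOLVENT, dtype=np.intp)])
    w_off = n0 + 3 * np.arange(nw)
    new_bonds = np.vstack([np.stack([w_off, w_off + 1], axis=1),
                           np.stack([w_off, w_off + 2], axis=1)]) if nw else \
        np.zeros((0, 2), dtype=np.intp)
    bond_idx = np.vstack([p.bond_idx, new_bonds])
    bond_k = np.concatenate([p.bond_k, np.full(2 * nw, spec.bond_k)])
    bond_r0 = np.concatenate([p.bond_r0, np.full(2 * nw, spec.o_h_length)])
    new_angles = (np.stack([w_off + 1, w_off, w_off + 2], axis=1) if nw
                  else np.zeros((0, 3), dtype=np.intp))
    angle_idx = np.vstack([p.angle_idx, new_angles])
    angle_k = np.concatenate([p.angle_k, np.full(nw, spec.angle_k)])
    angle_theta0 = np.concatenate([p.angle_theta0,
                                   np.full(nw, spec.h_o_h_angle_deg * DEG)])
    eps_w = np.tile([spec.eps_o, spec.eps_h, spec.eps_h], nw)
    sig_w = np.tile([spec.sigma_o, spec.sigma_h, spec.sigma_h], nw)
    q_w = np.tile([spec.q_o, spec.q_h, spec.q_h], nw)
    m_w = np.tile([_MASS_TABLE["O"], _MASS_TABLE["H"], _MASS_TABLE["H"]], nw)
    born = None
    if p.born_radius is not None:
        born = np.concatenate([p.born_radius,
                               np.tile([BORN_RADII["O"], BORN_RADII["H"],
                                        BORN_RADII["H"]], nw)])
    params = ForceFieldParameters(
        bond_idx=bond_idx, bond_k=bond_k, bond_r0=bond_r0,
        angle_idx=angle_idx, angle_k=angle_k, angle_theta0=angle_theta0,
        dihedral_idx=p.dihedral_idx, dihedral_k=p.dihedral_k,
        dihedral_n=p.dihedral_n, dihedral_gamma=p.dihedral_gamma,
        epsilon=np.concatenate([p.epsilon, eps_w]),
        sigma=np.concatenate([p.sigma, sig_w]),
        charge=np.concatenate([p.charge, q_w]),
        mass=np.concatenate([p.mass, m_w]),
        born_radius=born,
        scale14_lj=p.scale14_lj, scale14_coulomb=p.scale14_coulomb)
    out = MolecularSystem(
        elements=elements, params=params, coords=coords, box=box,
        roles=roles, rotatable_bonds=system.rotatable_bonds.copy(),
        meta={**system.meta, "solvation": {"padding": spec.padding,
                                           "n_waters": nw,
                                           "exclusion": spec.exclusion}})
    return out


def _remove_atoms(system: MolecularSystem, remove: np.ndarray) -> MolecularSystem:
    """Drop atoms and remap every topology index (helper for neutralize)."""
    keep = np.ones(system.n_atoms, dtype=bool)
    keep[remove] = False
    new_index = np.cumsum(keep) - 1
    p = system.params

    def filt(idx, *arrays):
        if idx.shape[0] == 0:
            return (idx,) + arrays
        ok = keep[idx].all(axis=1)
        return (new_index[idx[ok]],) + tuple(a[ok] for a in arrays)

    bond_idx, bond_k, bond_r0 = filt(p.bond_idx, p.bond_k, p.bond_r0)
    angle_idx, angle_k, angle_theta0 = filt(p.angle_idx, p.angle_k, p.angle_theta0)
    dih_idx, dih_k, dih_g, dih_n = filt(p.dihedral_idx, p.dihedral_k,
                                        p.dihedral_gamma, p.dihedral_n)
    rot_idx, = filt(system.rotatable_bonds)
    params = ForceFieldParameters(
        bond_idx=bond_idx, bond_k=bond_k, bond_r0=bond_r0,
        angle_idx=angle_idx, angle_k=angle_k, angle_theta0=angle_theta0,
        dihedral_idx=dih_idx, dihedral_k=dih_k, dihedral_n=dih_n,
        dihedral_gamma=dih_g,
        epsilon=p.epsilon[keep], sigma=p.sigma[keep], charge=p.charge[keep],
        mass=p.mass[keep],
        born_radius=None if p.born_radius is None else p.born_radius[keep],
        scale14_lj=p.scale14_lj, scale14_coulomb=p.scale14_coulomb)
    return MolecularSystem(
        elements=[e for e, k in zip(system.elements, keep) if k],
        params=params, coords=system.coords[keep],
        velocities=system.velocities[keep],
        box=None if system.box is None else system.box.copy(),
        roles=system.roles[keep], rotatable_bonds=rot_idx,
        meta=dict(system.meta))


def neutralize(system: MolecularSystem, spec: SolvationSpec | None = None
               ) -> MolecularSystem:
    """Replace waters with counterions until the cell charge is zero.

    The net solute charge must be an integer (within 1e-3 e).  The waters
    farthest from the solute centre of mass are replaced first — a
    deterministic placement rule.  A neutral system is returned unchanged
    (as a copy).
    """
    if spec is None:
        spec = SolvationSpec()
    net = system.total_charge
    rounded = round(net)
    if abs(net - rounded) > 1e-3:
        raise ParametrizationError(
            f"net charge {net:.6f} e is not an integer; cannot neutralize")
    if rounded == 0:
        return system.copy()
    ion = "NA" if rounded < 0 else "CL"
    n_ions = abs(int(rounded))
    # identify water oxygens: solvent-role O atoms bonded to two hydrogens
    adj = system.bond_graph()
    oxygens = [i for i in range(system.n_atoms)
               if system.roles[i] == ROLE_SOLVENT
               and system.elements[i].upper() == "O"
               and len(adj[i]) == 2]
    if len(oxygens) < n_ions:
        raise ParametrizationError(
            f"need {n_ions} counterions but only {len(oxygens)} waters available")
    solute = system.solute_mask
    m = system.masses[solute]
    com = (system.coords[solute] * m[:, None]).sum(axis=0) / m.sum()
    dist = np.linalg.norm(system.coords[oxygens] - com, axis=1)
    order = np.argsort(-dist, kind="stable")
    chosen = [oxygens[int(k)] for k in order[:n_ions]]
    ion_positions = system.coords[chosen].copy()
    remove = np.concatenate([[o] + sorted(adj[o]) for o in chosen]).astype(np.intp)
    out = _remove_atoms(system, remove)
    # append ions
    ipar = spec.ion_params[ion]
    p = out.params
    params = ForceFieldParameters(
        bond_idx=p.bond_idx, bond_k=p.bond_k, bond_r0=p.bond_r0,
        angle_idx=p.angle_idx, angle_k=p.angle_k, angle_theta0=p.angle_theta0,
        dihedral_idx=p.dihedral_idx, dihedral_k=p.dihedral_k,
        dihedral_n=p.dihedral_n, dihedral_gamma=p.dihedral_gamma,
        epsilon=np.concatenate([p.epsilon, np.full(n_ions, ipar["epsilon"])]),
        sigma=np.concatenate([p.sigma, np.full(n_ions, ipar["sigma"])]),
        charge=np.concatenate([p.charge, np.full(n_ions, ipar["charge"])]),
        mass=np.concatenate([p.mass, np.full(n_ions, ipar["mass"])]),
        born_radius=(None if p.born_radius is None else
                     np.concatenate([p.born_radius,
                                     np.full(n_ions, BORN_RADII[ion])])),
        scale14_lj=p.scale14_lj, scale14_coulomb=p.scale14_coulomb)
    return MolecularSystem(
        elements=out.elements + [ion] * n_ions,
        params=params,
        coords=np.vstack([out.coords, ion_positions]),
        velocities=np.vstack([out.velocities, np.zeros((n_ions, 3))]),
        box=out.box, roles=np.concatenate([out.roles,
                                           np.full(n_ions, ROLE_ION, dtype=np.intp)]),
        rotatable_bonds=out.rotatable_bonds,
        meta={**out.meta, "counterions": {ion: n_ions}})


# ----------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------

def cosine_series(terms):
    """Return V(φ) = Σ (k/2)[1 + cos(nφ − γ)] as a vectorized callable."""
    terms = [(float(k), int(n), float(g)) for k, n, g in terms]

    def v(phi):
        phi = np.asarray(phi, dtype=np.float64)
        out = np.zeros_like(phi)
        for k, n, g in terms:
            out = out + 0.5 * k * (1.0 + np.cos(n * phi - g))
        return out

    return v


def _chain_coords(n, r0=1.53, theta=111.0 * DEG, phi=np.pi):
    """Cartesian coordinates of an n-atom chain with uniform internals.

    ``r0`` may be a scalar or a per-bond sequence of length n−1.
    """
    lengths = np.broadcast_to(np.asarray(r0, dtype=float), (n - 1,))
    coords = np.zeros((n, 3))
    coords[1] = [lengths[0], 0.0, 0.0]
    if n > 2:
        # direction making the bond angle theta with the 1→0 vector
        coords[2] = coords[1] + lengths[1] * np.array([-np.cos(theta),
                                                       np.sin(theta), 0.0])
    for i in range(3, n):
        coords[i] = _nerf(coords[i - 1], coords[i - 2], coords[i - 3],
                          lengths[i - 1], theta, phi)
    return coords


def _simple_params(n, elements, bonds, angles, dihedrals, charges=None,
                   eps=None, sigma=None, masses=None, scale14_lj=0.5,
                   scale14_coulomb=1.0 / 1.2):
    """Assemble ForceFieldParameters from plain python lists."""
    bond_idx = np.array([b[:2] for b in bonds], dtype=np.intp).reshape(-1, 2)
    bond_k = np.array([b[2] for b in bonds], dtype=float)
    bond_r0 = np.array([b[3] for b in bonds], dtype=float)
    angle_idx = np.array([a[:3] for a in angles], dtype=np.intp).reshape(-1, 3)
    angle_k = np.array([a[3] for a in angles], dtype=float)
    angle_t0 = np.array([a[4] for a in angles], dtype=float)
    dih_rows = []
    for quad, terms in dihedrals:
        for k, mult, gamma in terms:
            dih_rows.append((quad, k, mult, gamma))
    dih_idx = np.array([r[0] for r in dih_rows], dtype=np.intp).reshape(-1, 4)
    dih_k = np.array([r[1] for r in dih_rows], dtype=float)
    dih_n = np.array([r[2] for r in dih_rows], dtype=np.intp)
    dih_g = np.array([r[3] for r in dih_rows], dtype=float)
    if masses is None:
        masses = [_MASS_TABLE[e.upper()] for e in elements]
    if eps is None:
        eps = [_LJ_TABLE[e.upper()][0] for e in elements]
    if sigma is None:
        sigma = [_LJ_TABLE[e.upper()][1] for e in elements]
    if charges is None:
        charges = np.zeros(n)
    born = np.array([BORN_RADII.get(e.upper(), 1.5) for e in elements])
    return ForceFieldParameters(
        bond_idx=bond_idx, bond_k=bond_k, bond_r0=bond_r0,
        angle_idx=angle_idx, angle_k=angle_k, angle_theta0=angle_t0,
        dihedral_idx=dih_idx, dihedral_k=dih_k, dihedral_n=dih_n,
        dihedral_gamma=dih_g,
        epsilon=np.asarray(eps, dtype=float), sigma=np.asarray(sigma, dtype=float),
        charge=np.asarray(charges, dtype=float), mass=np.asarray(masses, dtype=float),
        born_radius=born, scale14_lj=scale14_lj, scale14_coulomb=scale14_coulomb)


def _fixture_harmonic3d(seed):
    """An anchor atom plus 10 satellites on isotropic springs (r_eq = 0).

    Every satellite contributes three quadratic degrees of freedom with
    ⟨PE⟩/dof = k_B T/2, which makes this the reference system for
    thermostat-equipartition checks.
    """
    rng = np.random.default_rng(seed)
    n_sat = 10
    k_spring = 10.0
    n = n_sat + 1
    coords = np.zeros((n, 3))
    coords[1:] = rng.normal(scale=0.3, size=(n_sat, 3))
    elements = ["X"] * n
    bonds = [(0, i, k_spring, 0.0) for i in range(1, n)]
    params = _simple_params(n, elements, bonds, [], [],
                            eps=[0.0] * n, sigma=[1.0] * n,
                            masses=[12.0] * n)
    return MolecularSystem(elements=elements, params=params, coords=coords,
                           meta={"spring_k": k_spring, "n_satellites": n_sat})


def _fixture_butane_like(seed):
    """United-atom four-bead chain with one driven torsion.

    The single-fold torsion term makes the anti arrangement (φ = 180°) the
    global minimum; a three-fold term adds the gauche structure.
    """
    del seed
    coords = _chain_coords(4, r0=1.526, theta=111.0 * DEG, phi=np.pi)
    elements = ["C"] * 4
    masses = [15.035, 14.027, 14.027, 15.035]
    bonds = [(i, i + 1, 310.0, 1.526) for i in range(3)]
    angles = [(0, 1, 2, 40.0, 111.0 * DEG), (1, 2, 3, 40.0, 111.0 * DEG)]
    torsion_terms = [(1.4, 1, 0.0), (0.3, 3, 0.0)]
    dihedrals = [((0, 1, 2, 3), torsion_terms)]
    params = _simple_params(4, elements, bonds, angles, dihedrals,
                            eps=[0.1] * 4, sigma=[3.9] * 4, masses=masses)
    return MolecularSystem(
        elements=elements, params=params, coords=coords,
        rotatable_bonds=np.array([[1, 2]]),
        meta={"torsion_terms": torsion_terms})


def _fixture_double_well_torsion(seed):
    """Four-atom chain whose torsion sees an asymmetric double well.

    V(φ) = (ϑ₁/2)(1 + cos φ) + (ϑ₂/2)(1 + cos(2φ − π)) has minima at
    φ = π (trans, V = 0) and φ = 0 (cis, V = ϑ₁) separated by a barrier of
    ϑ₂ + ϑ₁/2 from the trans side.  Nonbonded interactions and the 1-4
    coupling are switched off, so the equilibrium torsion distribution is
    exactly ∝ exp(−V(φ)/k_B T) — the analytically solvable benchmark for
    end-to-end Boltzmann recovery.  The terminal beads sit on long
    (3.7 Å) bonds — centre-of-mass stand-ins for bulky end groups — so the
    two conformers are ~2.2 Å apart in minimized RMSD and the barrier-top
    geometry is > 1 Å from either well: distinct conformers resolve
    cleanly at the standard 1.0 Å clustering cutoff.
    """
    del seed
    lengths = [3.7, 1.53, 3.7]
    coords = _chain_coords(4, r0=lengths, theta=111.0 * DEG, phi=np.pi)
    elements = ["C"] * 4
    bonds = [(i, i + 1, 300.0, lengths[i]) for i in range(3)]
    angles = [(0, 1, 2, 60.0, 111.0 * DEG), (1, 2, 3, 60.0, 111.0 * DEG)]
    torsion_terms = [(0.8, 1, 0.0), (2.5, 2, np.pi)]
    dihedrals = [((0, 1, 2, 3), torsion_terms)]
    params = _simple_params(4, elements, bonds, angles, dihedrals,
                            eps=[0.0] * 4, sigma=[1.0] * 4,
                            masses=[12.0] * 4, scale14_lj=0.0,
                            scale14_coulomb=0.0)
    return MolecularSystem(
        elements=elements, params=params, coords=coords,
        rotatable_bonds=np.array([[1, 2]]),
        meta={"torsion_terms": torsion_terms,
              "basins": {"cis": (-np.pi / 2, np.pi / 2),
                         "trans": (np.pi / 2, 3 * np.pi / 2)},
              "barrier_from_trans": 2.5 + 0.4,
              "delta_v": 0.8,
              "torsion_atoms": (0, 1, 2, 3)})


# heavy-atom construction table for the drug-sized fixture:
# (element, parent, angle_ref, dihedral_ref, r, theta_deg, phi_deg)
_MINIDRUG_SKELETON = [
    ("C", None, None, None, 0.0, 0.0, 0.0),        # 0 quaternary centre
    ("C", 0, None, None, 1.526, 0.0, 0.0),          # 1
    ("C", 1, 0, None, 1.526, 109.471, 0.0),         # 2 branch point
    ("C", 2, 1, 0, 1.526, 109.471, 180.0),          # 3
    ("C", 3, 2, 1, 1.526, 109.471, 180.0),          # 4 chain terminus
    ("C", 0, 1, 2, 1.526, 109.471, 60.0),           # 5
    ("C", 5, 0, 1, 1.526, 109.471, 180.0),          # 6
    ("O", 6, 5, 0, 1.410, 109.471, 180.0),          # 7 hydroxyl O
    ("C", 0, 1, 2, 1.526, 109.471, 180.0),          # 8
    ("C", 8, 0, 1, 1.526, 109.471, 180.0),          # 9
    ("N", 9, 8, 0, 1.470, 109.471, 180.0),          # 10 amine N
    ("C", 2, 1, 0, 1.526, 109.471, 60.0),           # 11 methyl
    ("C", 6, 5, 0, 1.526, 109.471, 60.0),           # 12 methyl
    ("C", 0, 1, 2, 1.526, 109.471, 300.0),          # 13 methyl
    ("C", 3, 2, 1, 1.526, 109.471, 60.0),           # 14 methyl
    ("C", 5, 0, 1, 1.526, 109.471, 60.0),           # 15 methyl
]

_MINIDRUG_VALENCE = {"C": 4, "N": 3, "O": 2}
_MINIDRUG_CHARGES = {  # heavy-atom partial charges; attached polar H below
    6: 0.25, 7: -0.60,   # C-OH
    9: 0.10, 10: -0.80,  # C-NH2
}
_POLAR_H_CHARGE = {7: 0.35, 10: 0.35}


def _fixture_minidrug(seed):
    """A branched, drug-sized (~50 atom) neutral molecule, 3 rotatable bonds.

    Built from a deterministic heavy-atom tree (quaternary core with a
    butyl chain, a hydroxyl arm and an aminoethyl arm, decorated with
    methyls), hydrogens completed tetrahedrally.  Parameters are generic
    alkane/alcohol/amine-like values; the hydroxyl and amine groups carry
    internally neutral charge sets so the total charge is exactly zero.
    """
    del seed
    heavy_el = [row[0] for row in _MINIDRUG_SKELETON]
    nh = len(heavy_el)
    coords = np.zeros((nh, 3))
    coords[1] = [1.526, 0.0, 0.0]
    th = 109.471 * DEG
    coords[2] = coords[1] + 1.526 * np.array([-np.cos(th), np.sin(th), 0.0])
    for i in range(3, nh):
        el, parent, aref, dref, r, theta, phi = _MINIDRUG_SKELETON[i]
        coords[i] = _nerf(coords[parent], coords[aref], coords[dref],
                          r, theta * DEG, phi * DEG)
    heavy_bonds = [(row[1], i) for i, row in enumerate(_MINIDRUG_SKELETON)
                   if row[1] is not None]
    # hydrogen completion
    elements = list(heavy_el)
    xyz = [coords[i] for i in range(nh)]
    bonds_el = list(heavy_bonds)
    h_parent = {}
    neighbor_pos = {i: [] for i in range(nh)}
    for a, b in heavy_bonds:
        neighbor_pos[a].append(b)
        neighbor_pos[b].append(a)
    for i in range(nh):
        el = heavy_el[i]
        need = _MINIDRUG_VALENCE[el] - len(neighbor_pos[i])
        if need <= 0:
            continue
        nb_pos = [coords[j] for j in neighbor_pos[i]]
        ref = None
        if len(neighbor_pos[i]) == 1:
            j = neighbor_pos[i][0]
            grand = [g for g in neighbor_pos[j] if g != i]
            if grand:
                ref = coords[min(grand)]
        length = _bond_param(el, "H")[1]
        for d in _hydrogen_directions(coords[i], nb_pos, need, ref=ref):
            j = len(elements)
            elements.append("H")
            xyz.append(coords[i] + length * d)
            bonds_el.append((i, j))
            h_parent[j] = i
    n = len(elements)
    coords_full = np.array(xyz)
    bonds = []
    for a, b in bonds_el:
        k, r0 = _bond_param(elements[a], elements[b])
        bonds.append((a, b, k, r0))
    bond_idx = np.array([b[:2] for b in bonds], dtype=np.intp)
    angle_list, adj = _angles_from_bonds(n, bond_idx)
    angles = [(i, j, k, 50.0, TETRA) for i, j, k in angle_list]
    rotatable = np.array([[1, 2], [5, 6], [8, 9]], dtype=np.intp)
    rot_set = {tuple(sorted(b)) for b in rotatable.tolist()}
    dihedrals = []
    for quad, barrier in _auto_dihedrals(elements, bond_idx, adj, barrier=0.5):
        central = tuple(sorted(quad[1:3]))
        terms = [(1.2, 3, 0.0)] if central in rot_set else [(barrier, 3, 0.0)]
        dihedrals.append((quad, terms))
    charges = np.zeros(n)
    for i, q in _MINIDRUG_CHARGES.items():
        charges[i] = q
    for j, parent in h_parent.items():
        if parent in _POLAR_H_CHARGE:
            charges[j] = _POLAR_H_CHARGE[parent]
    eps = []
    sigma = []
    for i, el in enumerate(elements):
        if el == "H" and h_parent.get(i) in _POLAR_H_CHARGE:
            eps.append(0.0)
            sigma.append(1.0)  # polar hydrogen: charge only
        else:
            e, s = _LJ_TABLE[el]
            eps.append(e)
            sigma.append(s)
    params = _simple_params(n, elements, bonds, angles, dihedrals,
                            charges=charges, eps=eps, sigma=sigma)
    assert abs(float(params.charge.sum())) < 1e-12
    system = MolecularSystem(elements=elements, params=params,
                             coords=coords_full, rotatable_bonds=rotatable,
                             meta={"description": "drug-sized neutral fixture"})
    _relax(system)  # remove residual build strain, deterministic
    return system


def _relax(system: MolecularSystem, maxiter: int = 500) -> None:
    """In-place gas-phase energy minimization (L-BFGS, analytic gradient)."""
    from scipy.optimize import minimize

    opt = EnergyOptions(mode="gas")

    def fun(x):
        _, e, g = total_energy(system, opt, x.reshape(-1, 3))
        return float(e), g.ravel()

    res = minimize(fun, system.coords.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    system.coords = res.x.reshape(-1, 3)


def _fixture_water_box(seed):
    """A pure periodic water box, 21 Å cube (just above twice the cutoff)."""
    spec = SolvationSpec()
    rng = np.random.default_rng(seed)
    box = np.array([21.0, 21.0, 21.0])
    waters = _lattice_waters(box, spec, rng, None)
    nw = len(waters)
    elements = ["O", "H", "H"] * nw
    coords = np.vstack([np.vstack(w) for w in waters])
    w_off = 3 * np.arange(nw)
    bonds = ([(int(o), int(o) + 1, spec.bond_k, spec.o_h_length) for o in w_off]
             + [(int(o), int(o) + 2, spec.bond_k, spec.o_h_length) for o in w_off])
    angles = [(int(o) + 1, int(o), int(o) + 2, spec.angle_k,
               spec.h_o_h_angle_deg * DEG) for o in w_off]
    n = 3 * nw
    eps = [spec.eps_o, spec.eps_h, spec.eps_h] * nw
    sig = [spec.sigma_o, spec.sigma_h, spec.sigma_h] * nw
    q = [spec.q_o, spec.q_h, spec.q_h] * nw
    params = _simple_params(n, elements, bonds, angles, [], charges=q,
                            eps=eps, sigma=sig)
    return MolecularSystem(elements=elements, params=params, coords=coords,
                           box=box,
                           roles=np.full(n, ROLE_SOLVENT, dtype=np.intp),
                           meta={"n_waters": nw})


def _fixture_solvated_minidrug(seed):
    """The drug-sized fixture solvated and neutralized (10 Å padding)."""
    solute = _fixture_minidrug(seed)
    solv = solvate(solute, SolvationSpec(), cutoff=10.0, seed=seed)
    return neutralize(solv)


_FIXTURES = {
    "harmonic3d": _fixture_harmonic3d,
    "butane_like": _fixture_butane_like,
    "double_well_torsion": _fixture_double_well_torsion,
    "minidrug": _fixture_minidrug,
    "water_box": _fixture_water_box,
    "solvated_minidrug": _fixture_solvated_minidrug,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str, seed: int = 0) -> MolecularSystem:
    """Build a fully parametrized fixture system, deterministic given seed."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return builder(seed)
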
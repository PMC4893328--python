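"""Core containers: force-field parameters, molecular systems, energy reports.

A :class:`MolecularSystem` couples a topology (bonds, angles, dihedrals,
rotatable bonds), the molecular-mechanics parameters that evaluate its
potential energy, and a dynamical state (coordinates, velocities, optional
orthorhombic box).  All arrays are plain numpy; the topology is treated as
immutable after construction while coordinates and velocities mutate freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ForceFieldParameters",
    "MolecularSystem",
    "EnergyReport",
    "ParametrizationError",
    "ROLE_SOLUTE",
    "ROLE_SOLVENT",
    "ROLE_ION",
]

ROLE_SOLUTE = 0
ROLE_SOLVENT = 1
ROLE_ION = 2


class ParametrizationError(ValueError):
    """A term references a missing/invalid parameter or atom index."""


def _as_f64(x, shape_hint=None):
    a = np.asarray(x, dtype=np.float64)
    if a.size == 0 and shape_hint is not None:
        a = a.reshape(shape_hint)
    return a


def _as_idx(x, width):
    a = np.asarray(x, dtype=np.intp)
    if a.size == 0:
        a = a.reshape(0, width)
    if a.ndim != 2 or a.shape[1] != width:
        raise ParametrizationError(
            f"index array must have shape (n, {width}), got {a.shape}"
        )
    return a


@dataclass
class ForceFieldParameters:
    """Parameters of the additive molecular-mechanics potential.

    Bonded terms are indexed by atom tuples; dihedral rows carry one cosine
    term each (a torsion with several multiplicities contributes several
    rows sharing the same atom quadruple).  Units: ``bond_k``
    kcal·mol⁻¹·Å⁻², ``angle_k`` kcal·mol⁻¹·rad⁻², ``dihedral_k`` kcal·mol⁻¹
    (the barrier ϑ_n enters as ϑ_n/2·[1+cos(nφ−γ)]), ``sigma`` Å,
    ``epsilon`` kcal·mol⁻¹, ``charge`` e, ``mass`` amu, ``born_radius`` Å.
    """

    bond_idx: np.ndarray  # (nb, 2) int
    bond_k: np.ndarray  # (nb,)
    bond_r0: np.ndarray  # (nb,)
    angle_idx: np.ndarray  # (na, 3) int, vertex is the middle atom
    angle_k: np.ndarray  # (na,)
    angle_theta0: np.ndarray  # (na,) rad
    dihedral_idx: np.ndarray  # (nd, 4) int
    dihedral_k: np.ndarray  # (nd,) barrier height ϑ_n
    dihedral_n: np.ndarray  # (nd,) integer multiplicity ≥ 1
    dihedral_gamma: np.ndarray  # (nd,) phase, rad
    epsilon: np.ndarray  # (N,)
    sigma: np.ndarray  # (N,)
    charge: np.ndarray  # (N,)
    mass: np.ndarray  # (N,)
    born_radius: np.ndarray | None = None  # (N,) or None
    scale14_lj: float = 0.5
    scale14_coulomb: float = 1.0 / 1.2

    def __post_init__(self):
        self.bond_idx = _as_idx(self.bond_idx, 2)
        self.angle_idx = _as_idx(self.angle_idx, 3)
        self.dihedral_idx = _as_idx(self.dihedral_idx, 4)
        for name in ("bond_k", "bond_r0", "angle_k", "angle_theta0",
                     "dihedral_k", "dihedral_gamma", "epsilon", "sigma",
                     "charge", "mass"):
            setattr(self, name, _as_f64(getattr(self, name)))
        self.dihedral_n = np.asarray(self.dihedral_n, dtype=np.intp)
        if self.born_radius is not None:
            self.born_radius = _as_f64(self.born_radius)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return self.mass.shape[0]

    def validate(self) -> None:
        n = self.n_atoms
        if np.any(self.mass <= 0):
            raise ParametrizationError("all masses must be positive")
        if np.any(self.sigma <= 0):
            raise ParametrizationError("all LJ sigma must be positive")
        if np.any(self.epsilon < 0):
            raise ParametrizationError("LJ epsilon must be non-negative")
        if np.any(self.bond_k < 0) or np.any(self.angle_k < 0):
            raise ParametrizationError("force constants must be non-negative")
        if self.dihedral_n.size and np.any(self.dihedral_n < 1):
            raise ParametrizationError("dihedral multiplicity n must be >= 1")
        for label, idx in (("bond", self.bond_idx),
                           ("angle", self.angle_idx),
                           ("dihedral", self.dihedral_idx)):
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                bad = idx[(idx.min(axis=1) < 0) | (idx.max(axis=1) >= n)]
                raise ParametrizationError(
                    f"{label} term references invalid atom indices: "
                    f"{bad[0].tolist()} (system has {n} atoms)"
                )
        for label, idx, arrs in (
            ("bond", self.bond_idx, (self.bond_k, self.bond_r0)),
            ("angle", self.angle_idx, (self.angle_k, self.angle_theta0)),
            ("dihedral", self.dihedral_idx,
             (self.dihedral_k, self.dihedral_gamma, self.dihedral_n)),
        ):
            for a in arrs:
                if a.shape[0] != idx.shape[0]:
                    raise ParametrizationError(
                        f"{label} parameter arrays do not match the "
                        f"{label} list length ({a.shape[0]} vs {idx.shape[0]})"
                    )
        for name in ("epsilon", "sigma", "charge"):
            if getattr(self, name).shape[0] != n:
                raise ParametrizationError(
                    f"per-atom array {name!r} has wrong length"
                )


@dataclass
class MolecularSystem:
    """Topology + parameters + dynamical state of one simulation cell."""

    elements: list[str]
    params: ForceFieldParameters
    coords: np.ndarray  # (N, 3) Å
    velocities: np.ndarray | None = None  # (N, 3) Å/fs
    box: np.ndarray | None = None  # (3,) Å or None (gas phase)
    roles: np.ndarray | None = None  # (N,) int, ROLE_* flags
    rotatable_bonds: np.ndarray | None = None  # (k, 2) int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = _as_f64(self.coords)
        n = self.params.n_atoms
        if self.coords.shape != (n, 3):
            raise ParametrizationError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"atom count {n}"
            )
        if len(self.elements) != n:
            raise ParametrizationError("element list length mismatch")
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        else:
            self.velocities = _as_f64(self.velocities)
        if self.roles is None:
            self.roles = np.full(n, ROLE_SOLUTE, dtype=np.intp)
        else:
            self.roles = np.asarray(self.roles, dtype=np.intp)
        if self.box is not None:
            self.box = _as_f64(self.box).reshape(3)
            if np.any(self.box <= 0):
                raise ParametrizationError("box lengths must be positive")
        if self.rotatable_bonds is not None:
            self.rotatable_bonds = _as_idx(self.rotatable_bonds, 2)
        else:
            self.rotatable_bonds = np.zeros((0, 2), dtype=np.intp)
        self._scale_cache = None

    # -- convenience ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.params.n_atoms

    @property
    def masses(self) -> np.ndarray:
        return self.params.mass

    @property
    def total_charge(self) -> float:
        return float(self.params.charge.sum())

    @property
    def solute_mask(self) -> np.ndarray:
        return self.roles == ROLE_SOLUTE

    def copy(self) -> "MolecularSystem":
        new = replace(
            self,
            coords=self.coords.copy(),
            velocities=self.velocities.copy(),
            box=None if self.box is None else self.box.copy(),
            roles=self.roles.copy(),
            meta=dict(self.meta),
        )
        return new

    # -- topology-derived structures ------------------------------------
    def bond_graph(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_atoms)}
        for i, j in self.params.bond_idx:
            adj[int(i)].add(int(j))
            adj[int(j)].add(int(i))
        return adj

    def nonbonded_scales(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (N, N) scale matrices for LJ and Coulomb interactions.

        Entry (i, j) is 0 for self/1-2/1-3 pairs, the 1-4 scale factor for
        pairs three bonds apart, and 1 otherwise.  Cached: the topology is
        immutable.
        """
        if self._scale_cache is not None:
            return self._scale_cache
        n = self.n_atoms
        s_lj = np.ones((n, n))
        s_q = np.ones((n, n))
        np.fill_diagonal(s_lj, 0.0)
        np.fill_diagonal(s_q, 0.0)
        adj = self.bond_graph()
        for i in range(n):
            one = adj[i]
            two = set().union(*(adj[j] for j in one)) if one else set()
            three = set().union(*(adj[j] for j in two)) if two else set()
            for j in one | two:
                if j != i:
                    s_lj[i, j] = 0.0
                    s_q[i, j] = 0.0
            for j in three - two - one - {i}:
                s_lj[i, j] = self.params.scale14_lj
                s_q[i, j] = self.params.scale14_coulomb
        # symmetry guard: a pair both 1-3 and 1-4 in a ring keeps the
        # stricter (smaller) scale on both sides
        s_lj = np.minimum(s_lj, s_lj.T)
        s_q = np.minimum(s_q, s_q.T)
        self._scale_cache = (s_lj, s_q)
        return self._scale_cache

    def hydrogen_bond_constraints(self) -> tuple[np.ndarray, np.ndarray]:
        """Bonds involving at least one hydrogen, as (idx (c,2), length (c,))."""
        p = self.params
        is_h = np.array([e.upper() == "H" for e in self.elements])
        if p.bond_idx.size == 0:
            return np.zeros((0, 2), dtype=np.intp), np.zeros(0)
        mask = is_h[p.bond_idx[:, 0]] | is_h[p.bond_idx[:, 1]]
        return p.bond_idx[mask], p.bond_r0[mask]


@dataclass
class EnergyReport:
    """Per-term decomposition of the potential energy (kcal·mol⁻¹)."""

    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0
    implicit_solvent: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.lj
                + self.coulomb + self.implicit_solvent + self.restraint)

    def as_dict(self) -> dict[str, float]:
        return {
            "bond": self.bond,
            "angle": self.angle,
            "dihedral": self.dihedral,
            "lj": self.lj,
            "coulomb": self.coulomb,
            "implicit_solvent": self.implicit_solvent,
            "restraint": self.restraint,
            "total": self.total,
        }
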
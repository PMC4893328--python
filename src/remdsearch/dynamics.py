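"""Langevin dynamics with SHAKE constraints.

The integrator is the BAOAB splitting of Langevin dynamics: half kick,
half drift, Ornstein–Uhlenbeck velocity refresh, half drift, half kick.
With zero friction the O step is the identity and the scheme reduces
exactly to velocity Verlet, which makes energy-conservation and
time-reversibility checks meaningful.  Bonds containing hydrogen are
constrained with SHAKE (positions, correction along the pre-step bond
direction) plus an iterative velocity projection after every kick and
refresh.

All propagation routines accept states with an optional leading batch
dimension ``(m, N, 3)`` and per-batch temperatures, which is how the
replica-exchange driver advances a whole ladder in one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .constants import ACC_FACTOR, KB
from .forcefield import EnergyOptions, make_potential
from .system import MolecularSystem

__all__ = [
    "IntegratorSettings",
    "ThermoRecord",
    "ConstraintError",
    "PropagationError",
    "init_velocities",
    "shake",
    "langevin_step",
    "propagate",
    "equilibrate",
    "EquilibrationStage",
    "kinetic_energy",
    "count_dof",
]


class ConstraintError(RuntimeError):
    """SHAKE failed to converge within the iteration budget."""


class PropagationError(RuntimeError):
    """A non-finite force or coordinate was produced during integration."""


@dataclass
class IntegratorSettings:
    """Langevin integration parameters.

    timestep in fs, friction in ps⁻¹, temperature in K.  The constraint
    tolerance is relative (|d − d₀|/d₀).
    """

    timestep: float = 1.0
    friction: float = 1.0
    temperature: float = 298.0
    constraint_tolerance: float = 1e-8
    seed: int | None = None
    constrain_h_bonds: bool = True
    max_constraint_iter: int = 500

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.constraint_tolerance <= 1e-3:
            raise ValueError("constraint tolerance must lie in (0, 1e-3]")


@dataclass
class ThermoRecord:
    """Instantaneous thermodynamic state of one frame."""

    step: int
    potential: float
    kinetic: float
    temperature: float
    n_dof: int


def count_dof(n_atoms: int, n_constraints: int) -> int:
    """Degrees of freedom: 3N − constraints − 3 (centre-of-mass removal)."""
    return 3 * n_atoms - n_constraints - 3


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Kinetic energy in kcal·mol⁻¹ for velocities in Å·fs⁻¹."""
    v2 = np.sum(velocities * velocities, axis=-1)
    return 0.5 * np.sum(masses * v2, axis=-1) / ACC_FACTOR


# ----------------------------------------------------------------------
# constraints
# ----------------------------------------------------------------------

class Constraints:
    """Pairwise distance constraints with cached sparse scatter operators.

    ``g @ x`` yields per-constraint bond vectors; ``w @ corr`` distributes
    mass-weighted corrections back onto atoms (−1/m_i on the first atom,
    +1/m_j on the second).  All methods accept states of shape
    ``(..., N, 3)``.
    """

    def __init__(self, idx, d0, masses):
        self.idx = np.asarray(idx, dtype=np.intp).reshape(-1, 2)
        self.d0 = np.asarray(d0, dtype=np.float64)
        self.n_atoms = masses.shape[0]
        c = self.idx.shape[0]
        self.n_constraints = c
        if c == 0:
            return
        from scipy import sparse
        i, j = self.idx[:, 0], self.idx[:, 1]
        inv_m = 1.0 / masses
        self.inv_m = inv_m
        self.mu = 1.0 / (inv_m[i] + inv_m[j])
        rows = np.concatenate([np.arange(c), np.arange(c)])
        cols = np.concatenate([i, j])
        self.g = sparse.csr_matrix(
            (np.concatenate([np.ones(c), -np.ones(c)]), (rows, cols)),
            shape=(c, self.n_atoms))
        self.w = sparse.csr_matrix(
            (np.concatenate([-inv_m[i], inv_m[j]]), (cols, rows)),
            shape=(self.n_atoms, c))

    def _gather(self, x):
        """(..., N, 3) → per-constraint vectors (c, B, 3)."""
        nb = x.reshape(-1, self.n_atoms, 3)
        b = nb.shape[0]
        xt = np.ascontiguousarray(np.moveaxis(nb, 1, 0)).reshape(self.n_atoms, b * 3)
        return np.asarray(self.g @ xt).reshape(self.n_constraints, b, 3)

    def _apply(self, x, corr):
        """Add scattered corrections (c, B, 3) onto x in place."""
        b = corr.shape[1]
        delta = np.asarray(self.w @ corr.reshape(self.n_constraints, b * 3))
        x += np.moveaxis(delta.reshape(self.n_atoms, b, 3), 0, 1).reshape(x.shape)
        return x

    def shake(self, x, xref, tol, max_iter=500):
        """Restore constrained bond lengths (corrections along the
        pre-step bond directions).  Mutates and returns ``x``."""
        if self.n_constraints == 0:
            return x
        if _kernels.AVAILABLE:
            xb = x.reshape(-1, self.n_atoms, 3)
            xr = np.asarray(xref, dtype=np.float64).reshape(xb.shape)
            i, j = self.idx[:, 0], self.idx[:, 1]
            rref = xr[:, i] - xr[:, j]
            st = _kernels.shake_iterate(xb, rref, self.idx, self.d0,
                                        self.inv_m, self.mu, tol, max_iter)
            if st < 0:
                raise ConstraintError(
                    f"SHAKE did not converge in {max_iter} iterations")
            if not np.shares_memory(xb, x):
                x[...] = xb.reshape(x.shape)
            return x
        rref = self._gather(np.asarray(xref, dtype=np.float64))
        d0 = self.d0[:, None]
        d02 = (self.d0 * self.d0)[:, None]
        mu = self.mu[:, None]
        for _ in range(max_iter):
            d = self._gather(x)
            d2 = np.einsum("cbk,cbk->cb", d, d)
            err = np.abs(np.sqrt(d2) - d0) / d0
            if err.max() < tol:
                return x
            lam = (d2 - d02) * mu / (2.0 * np.einsum("cbk,cbk->cb", d, rref))
            self._apply(x, lam[..., None] * rref)
        raise ConstraintError(
            f"SHAKE did not converge in {max_iter} iterations "
            f"(worst relative violation {float(err.max()):.3e})")

    def project_velocities(self, v, x, max_iter=50, tol=1e-12):
        """Iteratively remove relative velocity along each constrained bond."""
        if self.n_constraints == 0:
            return v
        if _kernels.AVAILABLE:
            vb = v.reshape(-1, self.n_atoms, 3)
            xb = np.ascontiguousarray(x.reshape(vb.shape))
            _kernels.project_iterate(vb, xb, self.idx, self.inv_m, self.mu,
                                     tol, max_iter)
            if not np.shares_memory(vb, v):
                v[...] = vb.reshape(v.shape)
            return v
        u = self._gather(x)
        u /= np.sqrt(np.einsum("cbk,cbk->cb", u, u))[..., None]
        mu = self.mu[:, None]
        for _ in range(max_iter):
            dv = self._gather(v)
            rel = np.einsum("cbk,cbk->cb", dv, u)
            if np.abs(rel).max() < tol:
                return v
            self._apply(v, (rel * mu)[..., None] * u)
        return v


def shake(system: MolecularSystem, reference_coords: np.ndarray,
          tolerance: float = 1e-10, max_iter: int = 500):
    """Project the system's coordinates onto the constraint manifold.

    Constraints are the bonds containing at least one hydrogen, held at
    their equilibrium lengths.  Returns (corrected coords, velocities with
    the along-bond components removed); the input system is not mutated.
    """
    idx, d0 = system.hydrogen_bond_constraints()
    con = Constraints(idx, d0, system.masses)
    x = con.shake(system.coords.copy(),
                  np.asarray(reference_coords, dtype=np.float64),
                  tolerance, max_iter)
    v = con.project_velocities(system.velocities.copy(), x)
    return x, v


# ----------------------------------------------------------------------
# velocity initialization
# ----------------------------------------------------------------------

def init_velocities(system: MolecularSystem, temperature: float,
                    seed: int | np.random.Generator | None = None,
                    constrain: bool = True) -> np.ndarray:
    """Maxwell–Boltzmann velocities at ``temperature``.

    Each Cartesian component is drawn from a normal law with variance
    k_B T/m_i (in Å²·fs⁻²), constrained components are projected out, and
    the centre-of-mass momentum is removed.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    m = system.masses
    sigma = np.sqrt(KB * temperature * ACC_FACTOR / m)
    v = rng.standard_normal((system.n_atoms, 3)) * sigma[:, None]
    if constrain:
        idx, d0 = system.hydrogen_bond_constraints()
        con = Constraints(idx, d0, m)
        v = con.project_velocities(v, system.coords)
    # remove net momentum
    p = np.sum(m[:, None] * v, axis=0)
    v -= p / m.sum()
    return v


# ----------------------------------------------------------------------
# BAOAB propagation
# ----------------------------------------------------------------------

def _draw_noise(rngs, shape):
    if isinstance(rngs, np.random.Generator):
        return rngs.standard_normal(shape)
    # one generator per replica: shape is (m, N, 3)
    return np.stack([g.standard_normal(shape[1:]) for g in rngs])


def propagate(coords, velocities, potential, masses, settings: IntegratorSettings,
              n_steps: int, temperatures=None, rngs=None,
              constraints=None, record_stride: int = 0):
    """Advance ``n_steps`` of BAOAB Langevin dynamics.

    coords/velocities: ``(N, 3)`` or batched ``(m, N, 3)``; ``temperatures``
    may be a scalar (defaults to ``settings.temperature``) or an array
    ``(m,)`` of per-replica targets; ``rngs`` a Generator or a list of
    per-replica Generators.  ``constraints`` is ``(idx (c,2), d0 (c,))`` or
    None.  Returns ``(coords, velocities, potential_energy, records)``
    where ``records`` is a list of :class:`ThermoRecord` (batched runs
    record the batch-mean potential/kinetic energies).
    """
    x = np.array(coords, dtype=np.float64)
    v = np.array(velocities, dtype=np.float64)
    m = masses
    inv_m = 1.0 / m
    dt = settings.timestep
    gamma = settings.friction * 1e-3  # ps⁻¹ → fs⁻¹
    if temperatures is None:
        temperatures = settings.temperature
    t_arr = np.asarray(temperatures, dtype=np.float64)
    if x.ndim == 3 and t_arr.ndim == 1:
        kT = (KB * t_arr)[:, None, None]
    else:
        kT = KB * float(t_arr)
    if rngs is None:
        rngs = np.random.default_rng(settings.seed)
    if constraints is None:
        con = None
    elif isinstance(constraints, Constraints):
        con = constraints
    else:
        con = Constraints(constraints[0], constraints[1], np.asarray(m))
    tol = settings.constraint_tolerance
    max_it = settings.max_constraint_iter
    has_constraints = con is not None and con.n_constraints > 0

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    sigma_v = np.sqrt(kT * ACC_FACTOR * inv_m[:, None])  # broadcast over atoms
    kick = 0.5 * dt * ACC_FACTOR * inv_m[:, None]
    half_dt = 0.5 * dt
    n_dof = count_dof(x.shape[-2], con.n_constraints if has_constraints else 0)

    pe, force = potential(x)
    records: list[ThermoRecord] = []

    for step in range(n_steps):
        if not np.all(np.isfinite(force)):
            bad = int(np.argwhere(~np.isfinite(force))[0][-2])
            raise PropagationError(f"non-finite force on atom {bad}")
        # B
        v -= kick * force
        if has_constraints:
            v = con.project_velocities(v, x)
        # A
        if has_constraints:
            xref = x
            x_unc = xref + half_dt * v
            x = con.shake(x_unc.copy(), xref, tol, max_it)
            v += (x - x_unc) / half_dt
        else:
            x += half_dt * v
        # O
        if gamma > 0:
            noise = _draw_noise(rngs, x.shape)
            v = c1 * v + c2 * sigma_v * noise
            if has_constraints:
                v = con.project_velocities(v, x)
        # A
        if has_constraints:
            xref = x
            x_unc = xref + half_dt * v
            x = con.shake(x_unc.copy(), xref, tol, max_it)
            v += (x - x_unc) / half_dt
        else:
            x += half_dt * v
        # B
        pe, force = potential(x)
        v -= kick * force
        if has_constraints:
            v = con.project_velocities(v, x)

        if record_stride and (step + 1) % record_stride == 0:
            ke = kinetic_energy(v, m)
            ke_mean = float(np.mean(ke))
            records.append(ThermoRecord(
                step=step + 1,
                potential=float(np.mean(pe)),
                kinetic=ke_mean,
                temperature=2.0 * ke_mean / (n_dof * KB),
                n_dof=n_dof,
            ))
    return x, v, pe, records


def langevin_step(system: MolecularSystem, settings: IntegratorSettings,
                  potential=None, options: EnergyOptions | None = None,
                  rng: np.random.Generator | None = None):
    """One BAOAB step on a system; returns ``(system, ThermoRecord)``.

    The input system is not mutated.  Convenience wrapper over
    :func:`propagate`; long runs should call :func:`propagate` directly.
    """
    if potential is None:
        potential = make_potential(system, options)
    constraints = (system.hydrogen_bond_constraints()
                   if settings.constrain_h_bonds else None)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    x, v, pe, _ = propagate(
        system.coords, system.velocities, potential, system.masses,
        settings, 1, rngs=rng, constraints=constraints)
    out = system.copy()
    out.coords = x
    out.velocities = v
    n_con = constraints[0].shape[0] if constraints is not None else 0
    n_dof = count_dof(system.n_atoms, n_con)
    ke = float(kinetic_energy(v, system.masses))
    rec = ThermoRecord(step=1, potential=float(pe), kinetic=ke,
                       temperature=2.0 * ke / (n_dof * KB), n_dof=n_dof)
    return out, rec


# ----------------------------------------------------------------------
# equilibration
# ----------------------------------------------------------------------

@dataclass
class EquilibrationStage:
    """One NVT stage of the equilibration schedule."""

    n_steps: int
    temperature: float = 298.0
    restrain_com: bool = False
    com_k: float = 5.0  # kcal·mol⁻¹·Å⁻², matching the workflow default
    record_stride: int = 100


def equilibrate(system: MolecularSystem, schedule, options: EnergyOptions | None = None,
                settings: IntegratorSettings | None = None,
                seed: int | None = None):
    """Run the NVT equilibration schedule; returns (system, thermo log).

    Each stage is an :class:`EquilibrationStage`; the centre-of-mass
    restraint (toward the box centre, or the origin in gas phase) is
    applied in stages that request it.  The thermo log is a DataFrame of
    per-record step/potential/kinetic/temperature columns.
    """
    if options is None:
        options = EnergyOptions()
    if settings is None:
        settings = IntegratorSettings(seed=seed)
    out = system.copy()
    if isinstance(schedule, EquilibrationStage):
        schedule = [schedule]
    rng = np.random.default_rng(seed if seed is not None else settings.seed)
    constraints = None
    if settings.constrain_h_bonds:
        idx, d0 = out.hydrogen_bond_constraints()
        constraints = Constraints(idx, d0, out.masses)
    frames: list[pd.DataFrame] = []
    offset = 0
    for stage in schedule:
        if stage.n_steps == 0:
            continue
        from dataclasses import replace as _replace
        opt = options
        if stage.restrain_com:
            opt = _replace(options, com_restraint_k=stage.com_k)
        potential = make_potential(out, opt)
        stage_settings = IntegratorSettings(
            timestep=settings.timestep, friction=settings.friction,
            temperature=stage.temperature,
            constraint_tolerance=settings.constraint_tolerance,
            constrain_h_bonds=settings.constrain_h_bonds,
            max_constraint_iter=settings.max_constraint_iter)
        if not np.any(out.velocities):
            out.velocities = init_velocities(out, stage.temperature, rng)
        x, v, _, recs = propagate(
            out.coords, out.velocities, potential, out.masses,
            stage_settings, stage.n_steps, rngs=rng, constraints=constraints,
            record_stride=stage.record_stride)
        out.coords, out.velocities = x, v
        if recs:
            df = pd.DataFrame([r.__dict__ for r in recs])
            df["step"] += offset
            df["stage_temperature"] = stage.temperature
            frames.append(df)
        offset += stage.n_steps
    log = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["step", "potential", "kinetic",
                                      "temperature", "n_dof",
                                      "stage_temperature"]))
    return out, log
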
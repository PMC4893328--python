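"""Molecular-mechanics potential energy and analytic gradients.

Implements the additive force-field energy

    V = Σ k_b (r − r_eq)²  +  Σ k_θ (θ − θ_eq)²
      + Σ (ϑ_n/2)[1 + cos(nφ − γ)]
      + Σ_{i<j} 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]  +  Σ_{i<j} C q_i q_j / r_ij

plus an optional pairwise generalized-Born implicit-solvent term and a
harmonic restraint on the solute centre of mass.  Lennard-Jones interactions
are smoothly switched off between ``r_switch`` and ``r_cut`` (C¹-continuous
cubic switch in r²); Coulomb interactions use shifted-force truncation at
``r_cut`` so that both the energy and the force vanish continuously at the
cutoff.  Periodic systems use the minimum-image convention in an
orthorhombic cell.

Every function accepts coordinates of shape ``(..., N, 3)`` — an arbitrary
leading batch dimension — and returns energies of shape ``(...)`` and
gradients of shape ``(..., N, 3)``.  This is what lets a replica-exchange
ensemble be evaluated in one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import COULOMB, KB
from .system import EnergyReport, MolecularSystem, ParametrizationError

__all__ = [
    "EnergyOptions",
    "DegenerateGeometryError",
    "OverlapError",
    "bond_energy",
    "angle_energy",
    "dihedral_energy",
    "nonbonded_energy",
    "gb_energy",
    "com_restraint_energy",
    "total_energy",
    "make_potential",
    "debye_kappa",
]


class DegenerateGeometryError(ValueError):
    """A torsion or angle is geometrically undefined (collinear atoms)."""


class OverlapError(ValueError):
    """Two nonbonded atoms are closer than the hard overlap limit."""


@dataclass
class EnergyOptions:
    """Selects which energy terms are evaluated and with what settings.

    ``mode`` is one of ``"gas"``, ``"implicit"``, ``"explicit"``:
    gas evaluates the vacuum force field only; implicit adds the
    generalized-Born term; explicit is the vacuum force field in a periodic
    cell (the solvent is explicit particles, not an extra term).
    """

    mode: str = "gas"
    r_switch: float = 9.0
    r_cut: float = 10.0
    dielectric: float = 78.5
    salt_molar: float = 0.2
    com_restraint_k: float | None = None  # kcal·mol⁻¹·Å⁻²
    com_restraint_target: np.ndarray | None = None  # (3,) Å
    overlap_limit: float = 0.1  # Å
    temperature_for_salt: float = 298.0

    def __post_init__(self):
        if self.mode not in ("gas", "implicit", "explicit"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.r_switch < self.r_cut:
            raise ValueError("require 0 < r_switch < r_cut")


# ----------------------------------------------------------------------
# bonded terms
# ----------------------------------------------------------------------

def _scatter_matrix(holder, key: str, idx: np.ndarray, n_atoms: int):
    """Cached sparse (N, t) incidence matrix turning per-term gradient
    contributions into per-atom sums.  ``holder`` is the parameters or
    system object the cache lives on (topology is immutable)."""
    cache = getattr(holder, "_scatter_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(holder, "_scatter_cache", cache)
    mat = cache.get(key)
    if mat is None:
        from scipy import sparse
        t = idx.size
        mat = sparse.csr_matrix(
            (np.ones(t), (idx, np.arange(t))), shape=(n_atoms, t))
        cache[key] = mat
    return mat


def _scatter(mat, contrib: np.ndarray, n_atoms: int) -> np.ndarray:
    """Apply an incidence matrix to contributions of shape (..., t, 3)."""
    batch = contrib.shape[:-2]
    t = contrib.shape[-2]
    flat = np.moveaxis(contrib, -2, 0).reshape(t, -1)
    g = mat @ flat  # (N, prod(batch)*3)
    g = g.reshape((n_atoms,) + batch + (3,))
    return np.moveaxis(g, 0, -2)


def _mi(d, box):
    """Minimum-image a displacement array in an orthorhombic cell."""
    if box is not None:
        d = d - box * np.round(d / box)
    return d


def bond_energy(params, coords, box=None):
    """Harmonic bond energy Σ k_b (r − r_eq)² and its gradient."""
    coords = np.asarray(coords, dtype=np.float64)
    idx = params.bond_idx
    if idx.shape[0] == 0:
        return np.zeros(coords.shape[:-2]), np.zeros_like(coords)
    d = _mi(coords[..., idx[:, 0], :] - coords[..., idx[:, 1], :], box)
    r = np.linalg.norm(d, axis=-1)
    if np.any(r < 1e-12):
        raise DegenerateGeometryError("zero-length bond encountered")
    dr = r - params.bond_r0
    energy = np.sum(params.bond_k * dr * dr, axis=-1)
    # dE/dr = 2 k dr, along the unit bond vector
    gi = (2.0 * params.bond_k * dr / r)[..., None] * d
    mat = _scatter_matrix(params, "bond",
                          np.concatenate([idx[:, 0], idx[:, 1]]),
                          params.n_atoms)
    grad = _scatter(mat, np.concatenate([gi, -gi], axis=-2), params.n_atoms)
    return energy, grad


def angle_energy(params, coords, box=None):
    """Harmonic angle energy Σ k_θ (θ − θ_eq)² and its gradient."""
    coords = np.asarray(coords, dtype=np.float64)
    idx = params.angle_idx
    if idx.shape[0] == 0:
        return np.zeros(coords.shape[:-2]), np.zeros_like(coords)
    ri = coords[..., idx[:, 0], :]
    rj = coords[..., idx[:, 1], :]
    rk = coords[..., idx[:, 2], :]
    u = _mi(ri - rj, box)
    v = _mi(rk - rj, box)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise DegenerateGeometryError("angle with coincident atoms")
    cos_t = np.sum(u * v, axis=-1) / (nu * nv)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    theta = np.arccos(cos_t)
    dt = theta - params.angle_theta0
    energy = np.sum(params.angle_k * dt * dt, axis=-1)
    # dθ/dri and dθ/drk via the standard cross-product construction
    sin_t = np.sqrt(np.maximum(1.0 - cos_t * cos_t, 1e-14))
    # dθ/dri = (cosθ·û − v̂)/(|u| sinθ)
    uh = u / nu[..., None]
    vh = v / nv[..., None]
    dth_di = (cos_t[..., None] * uh - vh) / (nu * sin_t)[..., None]
    dth_dk = (cos_t[..., None] * vh - uh) / (nv * sin_t)[..., None]
    coef = (2.0 * params.angle_k * dt)[..., None]
    gi = coef * dth_di
    gk = coef * dth_dk
    mat = _scatter_matrix(params, "angle",
                          np.concatenate([idx[:, 0], idx[:, 2], idx[:, 1]]),
                          params.n_atoms)
    grad = _scatter(mat, np.concatenate([gi, gk, -(gi + gk)], axis=-2),
                    params.n_atoms)
    return energy, grad


def dihedral_angles(coords, idx, box=None):
    """Signed torsion angles φ ∈ (−π, π] for atom quadruples ``idx``.

    Raises :class:`DegenerateGeometryError` when an inner triple is
    collinear (the torsion is undefined there).
    """
    b1 = _mi(coords[..., idx[:, 1], :] - coords[..., idx[:, 0], :], box)
    b2 = _mi(coords[..., idx[:, 2], :] - coords[..., idx[:, 1], :], box)
    b3 = _mi(coords[..., idx[:, 3], :] - coords[..., idx[:, 2], :], box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    n1sq = np.sum(n1 * n1, axis=-1)
    n2sq = np.sum(n2 * n2, axis=-1)
    if np.any(n1sq < 1e-18) or np.any(n2sq < 1e-18):
        raise DegenerateGeometryError(
            "collinear atoms in a torsion: the dihedral angle is undefined"
        )
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2, axis=-1) / nb2
    phi = np.arctan2(y, x)
    return phi, (b1, b2, b3, n1, n2, nb2, n1sq, n2sq)


def dihedral_energy(params, coords, box=None):
    """Cosine-series torsion energy Σ (ϑ_n/2)[1 + cos(nφ − γ)] and gradient."""
    coords = np.asarray(coords, dtype=np.float64)
    idx = params.dihedral_idx
    if idx.shape[0] == 0:
        return np.zeros(coords.shape[:-2]), np.zeros_like(coords)
    phi, (b1, b2, b3, n1, n2, nb2, n1sq, n2sq) = dihedral_angles(coords, idx, box)
    arg = params.dihedral_n * phi - params.dihedral_gamma
    energy = np.sum(0.5 * params.dihedral_k * (1.0 + np.cos(arg)), axis=-1)
    de_dphi = -0.5 * params.dihedral_k * params.dihedral_n * np.sin(arg)
    # ∂φ/∂r in the standard four-point form
    dphi_da = (-(nb2 / n1sq))[..., None] * n1
    dphi_dd = ((nb2 / n2sq))[..., None] * n2
    s = (np.sum(b1 * b2, axis=-1) / (nb2 * nb2))[..., None]
    t = (np.sum(b3 * b2, axis=-1) / (nb2 * nb2))[..., None]
    # with b1 = r_b − r_a (a→b) the inner-atom derivatives are
    # ∂φ/∂r_b = −(1+s) ∂φ/∂r_a + t ∂φ/∂r_d
    dphi_db = -(1.0 + s) * dphi_da + t * dphi_dd
    # Σ ∂φ/∂r = 0 (rigid-motion invariance) fixes the third centre exactly
    dphi_dc = -(dphi_da + dphi_db + dphi_dd)
    c = de_dphi[..., None]
    mat = _scatter_matrix(params, "dihedral",
                          np.concatenate([idx[:, 0], idx[:, 1],
                                          idx[:, 2], idx[:, 3]]),
                          params.n_atoms)
    grad = _scatter(mat, np.concatenate(
        [c * dphi_da, c * dphi_db, c * dphi_dc, c * dphi_dd], axis=-2),
        params.n_atoms)
    return energy, grad


# ----------------------------------------------------------------------
# nonbonded terms (dense N×N formulation)
# ----------------------------------------------------------------------

def _switch(r2, rs2, rc2):
    """C¹ cubic-in-r² switching function and its derivative d S / d r².

    The classic (rc²−r²)²(rc²+2r²−3rs²)/(rc²−rs²)³ switch is evaluated in
    smoothstep form S = y²(3−2y) with y = clip((rc²−r²)/(rc²−rs²), 0, 1),
    which is branch-free and exactly C¹ at both radii.
    """
    inv_span = 1.0 / (rc2 - rs2)
    y = np.clip((rc2 - r2) * inv_span, 0.0, 1.0)
    s = y * y * (3.0 - 2.0 * y)
    ds_dr2 = -6.0 * y * (1.0 - y) * inv_span
    return s, ds_dr2


def _pair_geometry(coords, box):
    """Dense displacement matrix (..., N, N, 3) and squared distances
    (used by the all-pairs generalized-Born term)."""
    disp = coords[..., :, None, :] - coords[..., None, :, :]
    if box is not None:
        disp -= box * np.round(disp / box)
    r2 = np.sum(disp * disp, axis=-1)
    return disp, r2


def _pair_table(system: MolecularSystem):
    """Cached interacting-pair table (i, j, 4ε_ij·s, σ_ij², C·q_iq_j·s).

    Pairs fully excluded for both LJ and Coulomb (self, 1-2, 1-3 with zero
    scale) are omitted; 1-4 scaling is folded into the per-pair constants.
    Lorentz–Berthelot combination: σ_ij arithmetic, ε_ij geometric mean.
    """
    table = getattr(system, "_pair_table_cache", None)
    if table is not None:
        return table
    s_lj, s_q = system.nonbonded_scales()
    n = system.n_atoms
    iu, ju = np.triu_indices(n, 1)
    slj = s_lj[iu, ju]
    sq = s_q[iu, ju]
    p = system.params
    keep = ((slj > 0) & (p.epsilon[iu] * p.epsilon[ju] > 0)) | \
           ((sq > 0) & (p.charge[iu] * p.charge[ju] != 0))
    i, j = iu[keep], ju[keep]
    sig = 0.5 * (p.sigma[i] + p.sigma[j])
    eps4 = 4.0 * np.sqrt(p.epsilon[i] * p.epsilon[j]) * slj[keep]
    sig2 = sig * sig
    qq = COULOMB * p.charge[i] * p.charge[j] * sq[keep]
    table = (i, j, eps4, sig2, qq)
    object.__setattr__(system, "_pair_table_cache", table)
    return table


def _pair_gather(system, i, j, n):
    """Cached sparse difference operator (P, N) and its transpose.

    ``G @ x`` yields per-pair displacements x_i − x_j; ``Gᵀ @ w`` scatters
    per-pair force contributions back onto atoms.
    """
    cached = getattr(system, "_pair_gather_cache", None)
    if cached is not None:
        return cached
    from scipy import sparse
    p = i.size
    rows = np.concatenate([np.arange(p), np.arange(p)])
    cols = np.concatenate([i, j])
    vals = np.concatenate([np.ones(p), -np.ones(p)])
    g_fw = sparse.csr_matrix((vals, (rows, cols)), shape=(p, n))
    g_bk = sparse.csr_matrix(g_fw.T)
    object.__setattr__(system, "_pair_gather_cache", (g_fw, g_bk))
    return g_fw, g_bk


def nonbonded_energy(system: MolecularSystem, options: EnergyOptions | None = None,
                     coords: np.ndarray | None = None):
    """Lennard-Jones + Coulomb energy with exclusions, switching and cutoffs.

    LJ is multiplied by a switching function active on
    ``[r_switch, r_cut]``; Coulomb uses shifted-force truncation at
    ``r_cut``.  1-2/1-3 pairs are excluded, 1-4 pairs scaled per the
    parameter file; the minimum-image convention applies when periodic.
    Returns ``(e_lj, e_coulomb, gradient)``.
    """
    if options is None:
        options = EnergyOptions()
    if coords is None:
        coords = system.coords
    coords = np.asarray(coords, dtype=np.float64)
    i, j, eps4, sig2, qq = _pair_table(system)
    n = system.n_atoms
    lead = coords.shape[:-2]
    if i.size == 0:
        return (np.zeros(lead), np.zeros(lead), np.zeros_like(coords))
    g_fw, g_bk = _pair_gather(system, i, j, n)
    nb = coords.reshape(-1, n, 3)
    b = nb.shape[0]
    xt = np.ascontiguousarray(np.moveaxis(nb, 1, 0)).reshape(n, b * 3)
    disp = np.asarray(g_fw @ xt).reshape(i.size, b, 3)
    if system.box is not None:
        disp -= system.box * np.round(disp / system.box)
    r2 = np.einsum("pbc,pbc->pb", disp, disp)
    if r2.min() < options.overlap_limit ** 2:
        k = int(np.argmin(r2) // b)
        raise OverlapError(
            f"atoms {int(i[k])} and {int(j[k])} are closer than "
            f"{options.overlap_limit} Å — corrupted geometry")
    rc = options.r_cut
    rc2 = rc * rc
    rs2 = options.r_switch ** 2
    within = r2 < rc2
    inv_r2 = within / r2  # zero outside the cutoff
    inv_r = np.sqrt(inv_r2)

    sr2 = sig2[:, None] * inv_r2
    sr6 = sr2 * sr2 * sr2
    sr12 = sr6 * sr6
    e_lj_pair = eps4[:, None] * (sr12 - sr6)
    sw, dsw_dr2 = _switch(r2, rs2, rc2)
    de_lj_dr2 = eps4[:, None] * (3.0 * sr6 - 6.0 * sr12) * inv_r2
    dtot_lj_dr2 = de_lj_dr2 * sw + e_lj_pair * dsw_dr2

    # shifted-force Coulomb: E = qq (1/r − 1/rc + (r − rc)/rc²)
    qqc = qq[:, None]
    r = r2 * inv_r  # r within the cutoff, 0 outside
    e_q_pair = qqc * (inv_r + (r - 2.0 * rc) / rc2) * within
    dtot_q_dr2 = -0.5 * qqc * (inv_r2 - within / rc2) * inv_r

    e_lj = np.sum(e_lj_pair * sw, axis=0).reshape(lead)
    e_q = np.sum(e_q_pair, axis=0).reshape(lead)
    w = (2.0 * (dtot_lj_dr2 + dtot_q_dr2))[..., None] * disp
    grad_t = np.asarray(g_bk @ w.reshape(i.size, b * 3)).reshape(n, b, 3)
    grad = np.ascontiguousarray(np.moveaxis(grad_t, 0, 1)).reshape(coords.shape)
    return e_lj, e_q, grad


def debye_kappa(dielectric: float, salt_molar: float, temperature: float = 298.0) -> float:
    """Inverse Debye screening length κ (Å⁻¹) for a 1:1 electrolyte."""
    if salt_molar <= 0:
        return 0.0
    ionic_per_a3 = salt_molar * 6.0221408e-4  # mol/L → ions/Å³
    kappa2 = 8.0 * np.pi * COULOMB * ionic_per_a3 / (dielectric * KB * temperature)
    return float(np.sqrt(kappa2))


def gb_energy(system: MolecularSystem, dielectric: float = 78.5,
              salt_molar: float = 0.0, coords: np.ndarray | None = None,
              temperature: float = 298.0):
    """Pairwise generalized-Born polarization energy (Still form).

    E = −(C/2) Σ_ij (1 − e^{−κ f_ij}/ε) q_i q_j / f_ij with
    f_ij = sqrt(r² + a_i a_j exp(−r²/(4 a_i a_j))); the sum runs over all
    ordered pairs including i = j (the Born self term, f_ii = a_i).
    κ is the Debye–Hückel screening constant for the stated ionic strength.
    ``dielectric == 1`` (no dielectric contrast) gives exactly zero.
    """
    if dielectric < 1.0:
        raise ValueError("dielectric constant must be >= 1")
    p = system.params
    if p.born_radius is None:
        raise ParametrizationError(
            "generalized-Born term requires per-atom Born radii in the parameters"
        )
    if coords is None:
        coords = system.coords
    coords = np.asarray(coords, dtype=np.float64)
    grad = np.zeros_like(coords)
    if dielectric == 1.0:
        return np.zeros(coords.shape[:-2]), grad
    a = p.born_radius
    if np.any(a <= 0):
        raise ParametrizationError("Born radii must be positive")
    kappa = debye_kappa(dielectric, salt_molar, temperature)
    disp, r2 = _pair_geometry(coords, None)
    aa = a[:, None] * a[None, :]
    expo = np.exp(-r2 / (4.0 * aa))
    f = np.sqrt(r2 + aa * expo)
    qq = p.charge[:, None] * p.charge[None, :]
    pref = 1.0 - np.exp(-kappa * f) / dielectric
    e_pair = -0.5 * COULOMB * pref * qq / f
    energy = np.sum(e_pair, axis=(-1, -2))
    # dE/df = −(C/2) qq [κ e^{−κf}/(ε f) − pref/f²]
    de_df = -0.5 * COULOMB * qq * (
        kappa * np.exp(-kappa * f) / (dielectric * f) - pref / (f * f)
    )
    # df/dr² = (1 − expo/4) / (2 f);   dE/dr² = dE/df · df/dr²
    de_dr2 = de_df * (1.0 - expo / 4.0) / (2.0 * f)
    # the ordered-pair double sum counts each (i, j) twice: factor 4 = 2 × 2 disp
    grad = np.sum(4.0 * de_dr2[..., None] * disp, axis=-2)
    return energy, grad


def com_restraint_energy(system: MolecularSystem, k: float,
                         target: np.ndarray, coords: np.ndarray | None = None):
    """Harmonic solute centre-of-mass restraint E = ½ k |COM − target|²."""
    if coords is None:
        coords = system.coords
    coords = np.asarray(coords, dtype=np.float64)
    mask = system.solute_mask
    m = system.masses[mask]
    mtot = m.sum()
    if mtot <= 0:
        raise ValueError("restraint requires nonzero solute mass")
    target = np.asarray(target, dtype=np.float64).reshape(3)
    com = np.sum(coords[..., mask, :] * m[:, None], axis=-2) / mtot
    delta = com - target
    energy = 0.5 * k * np.sum(delta * delta, axis=-1)
    grad = np.zeros_like(coords)
    w = (m / mtot)[:, None]
    grad[..., mask, :] = k * delta[..., None, :] * w
    return energy, grad


# ----------------------------------------------------------------------
# total energy
# ----------------------------------------------------------------------

def _core_terms(system: MolecularSystem, options: EnergyOptions, coords):
    """Bond/angle/dihedral/LJ/Coulomb energies and the summed gradient.

    Dispatches to the fused compiled kernel when numba is available;
    otherwise composes the reference numpy term functions.  Both routes
    evaluate identical mathematics (asserted by the test suite).
    """
    p = system.params
    if _kernels.AVAILABLE:
        i, j, eps4, sig2, qq = _pair_table(system)
        lead = coords.shape[:-2]
        xb = np.ascontiguousarray(coords.reshape((-1,) + coords.shape[-2:]))
        periodic = system.box is not None
        box = system.box if periodic else np.zeros(3)
        energies, grad, status = _kernels.ff_eval(
            xb, p.bond_idx, p.bond_k, p.bond_r0,
            p.angle_idx, p.angle_k, p.angle_theta0,
            p.dihedral_idx, p.dihedral_k,
            p.dihedral_n.astype(np.float64), p.dihedral_gamma,
            i, j, eps4, sig2, qq,
            options.r_switch ** 2, options.r_cut ** 2,
            box, periodic, options.overlap_limit ** 2)
        if status == -2:
            raise DegenerateGeometryError(
                "collinear atoms in a torsion: the dihedral angle is undefined")
        if status >= 0:
            raise OverlapError(
                f"atoms {int(i[status])} and {int(j[status])} are closer "
                f"than {options.overlap_limit} Å — corrupted geometry")
        energies = energies.reshape(lead + (5,))
        return (energies[..., 0], energies[..., 1], energies[..., 2],
                energies[..., 3], energies[..., 4],
                grad.reshape(coords.shape))
    e_b, g_b = bond_energy(p, coords, system.box)
    e_a, g_a = angle_energy(p, coords, system.box)
    e_d, g_d = dihedral_energy(p, coords, system.box)
    e_lj, e_q, g_nb = nonbonded_energy(system, options, coords)
    return e_b, e_a, e_d, e_lj, e_q, g_b + g_a + g_d + g_nb


def total_energy(system: MolecularSystem, options: EnergyOptions | None = None,
                 coords: np.ndarray | None = None):
    """Full potential energy, per-term report and exact summed gradient.

    Returns ``(report, grad)`` for single-frame input and
    ``(total (...), grad)`` plus a report of batch means for batched input
    (the report always sums component arrays; for batched coordinates its
    fields hold the per-batch arrays' sums over the batch — callers doing
    batched dynamics use the returned total array directly).
    """
    if options is None:
        options = EnergyOptions()
    if coords is None:
        coords = system.coords
    coords = np.asarray(coords, dtype=np.float64)
    if system.box is not None and np.any(system.box < 2.0 * options.r_cut):
        raise ValueError(
            "periodic box must be at least twice the nonbonded cutoff "
            f"(box {system.box}, cutoff {options.r_cut})"
        )
    e_b, e_a, e_d, e_lj, e_q, grad = _core_terms(system, options, coords)
    total = e_b + e_a + e_d + e_lj + e_q
    e_gb = np.zeros_like(total)
    e_rst = np.zeros_like(total)
    if options.mode == "implicit":
        e_gb, g_gb = gb_energy(system, options.dielectric, options.salt_molar,
                               coords, options.temperature_for_salt)
        total = total + e_gb
        grad = grad + g_gb
    if options.com_restraint_k is not None:
        target = options.com_restraint_target
        if target is None:
            target = (0.5 * system.box if system.box is not None
                      else np.zeros(3))
        e_rst, g_rst = com_restraint_energy(system, options.com_restraint_k,
                                            target, coords)
        total = total + e_rst
        grad = grad + g_rst
    report = EnergyReport(
        bond=float(np.sum(e_b)), angle=float(np.sum(e_a)),
        dihedral=float(np.sum(e_d)), lj=float(np.sum(e_lj)),
        coulomb=float(np.sum(e_q)), implicit_solvent=float(np.sum(e_gb)),
        restraint=float(np.sum(e_rst)),
    )
    return report, total, grad


def make_potential(system: MolecularSystem, options: EnergyOptions | None = None):
    """Close over a system's topology: returns ``f(coords) -> (E, grad)``.

    The returned callable accepts coordinates of shape ``(..., N, 3)`` and
    is what the integrator and the replica-exchange driver propagate with.
    """
    if options is None:
        options = EnergyOptions()

    def potential(coords):
        _, total, grad = total_energy(system, options, coords)
        return total, grad

    return potential
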
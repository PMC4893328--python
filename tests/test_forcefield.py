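"""Force-field term values, analytic gradients, and invariances."""

import numpy as np
import pytest

from remdsearch import EnergyOptions, make_fixture, total_energy
from remdsearch.forcefield import (DegenerateGeometryError, OverlapError,
                                   _core_terms, angle_energy, bond_energy,
                                   com_restraint_energy, dihedral_energy,
                                   gb_energy, nonbonded_energy)
from remdsearch.system import ForceFieldParameters, MolecularSystem


def _two_atom_params(k=100.0, r0=1.0, eps=0.0, sigma=1.0, q=(0.0, 0.0),
                     bonded=True):
    return ForceFieldParameters(
        bond_idx=np.array([[0, 1]]) if bonded else np.zeros((0, 2), int),
        bond_k=np.array([k]) if bonded else np.zeros(0),
        bond_r0=np.array([r0]) if bonded else np.zeros(0),
        angle_idx=np.zeros((0, 3), int), angle_k=np.zeros(0),
        angle_theta0=np.zeros(0),
        dihedral_idx=np.zeros((0, 4), int), dihedral_k=np.zeros(0),
        dihedral_n=np.zeros(0, int), dihedral_gamma=np.zeros(0),
        epsilon=np.full(2, eps), sigma=np.full(2, sigma),
        charge=np.array(q), mass=np.full(2, 12.0))


def _pair_system(r, eps=0.2, sigma=3.0, q=(0.0, 0.0)):
    params = _two_atom_params(eps=eps, sigma=sigma, q=q, bonded=False)
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    return MolecularSystem(elements=["C", "C"], params=params, coords=coords)


def _fd_gradient(fn, coords, h=1e-5):
    g = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            xp = coords.copy()
            xp[i, d] += h
            xm = coords.copy()
            xm[i, d] -= h
            g[i, d] = (fn(xp) - fn(xm)) / (2 * h)
    return g


def _check_gradient(fn, coords, rtol=1e-5):
    e, g = fn(coords)
    fd = _fd_gradient(lambda c: fn(c)[0], coords)
    scale = max(1.0, np.abs(fd).max())
    assert np.abs(g - fd).max() / scale < rtol


# ----------------------------------------------------------------------
# bond / angle / dihedral values
# ----------------------------------------------------------------------

def test_bond_energy_zero_at_equilibrium():
    p = _two_atom_params(k=100.0, r0=1.0)
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    e, g = bond_energy(p, coords)
    assert e == pytest.approx(0.0, abs=1e-14)
    assert np.allclose(g, 0.0, atol=1e-12)


def test_bond_energy_direct_substitution():
    # k (r − r_eq)² = 100 · 0.1² = 1.0 kcal/mol
    p = _two_atom_params(k=100.0, r0=1.0)
    coords = np.array([[0.0, 0, 0], [1.1, 0, 0]])
    e, _ = bond_energy(p, coords)
    assert e == pytest.approx(1.0, rel=1e-12)


def test_angle_energy_values():
    theta0 = np.deg2rad(109.47)
    params = ForceFieldParameters(
        bond_idx=np.zeros((0, 2), int), bond_k=np.zeros(0), bond_r0=np.zeros(0),
        angle_idx=np.array([[0, 1, 2]]), angle_k=np.array([50.0]),
        angle_theta0=np.array([theta0]),
        dihedral_idx=np.zeros((0, 4), int), dihedral_k=np.zeros(0),
        dihedral_n=np.zeros(0, int), dihedral_gamma=np.zeros(0),
        epsilon=np.zeros(3), sigma=np.ones(3), charge=np.zeros(3),
        mass=np.full(3, 12.0))

    def coords_at(theta):
        return np.array([[np.cos(theta), np.sin(theta), 0.0],
                         [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])

    e0, _ = angle_energy(params, coords_at(theta0))
    assert e0 == pytest.approx(0.0, abs=1e-12)
    # k_θ (θ − θ_eq)² = 50 · 0.1² = 0.5
    e1, _ = angle_energy(params, coords_at(theta0 + 0.1))
    assert e1 == pytest.approx(0.5, rel=1e-9)


def _torsion_params(k, n, gamma):
    return ForceFieldParameters(
        bond_idx=np.zeros((0, 2), int), bond_k=np.zeros(0), bond_r0=np.zeros(0),
        angle_idx=np.zeros((0, 3), int), angle_k=np.zeros(0),
        angle_theta0=np.zeros(0),
        dihedral_idx=np.array([[0, 1, 2, 3]]), dihedral_k=np.array([k]),
        dihedral_n=np.array([n]), dihedral_gamma=np.array([gamma]),
        epsilon=np.zeros(4), sigma=np.ones(4), charge=np.zeros(4),
        mass=np.full(4, 12.0))


def _torsion_coords(phi):
    from remdsearch.structgen import _chain_coords
    return _chain_coords(4, r0=1.5, theta=np.deg2rad(111), phi=phi)


@pytest.mark.parametrize("k,n,gamma,phi,expected", [
    (2.0, 1, 0.0, 0.0, 2.0),          # (ϑ/2)(1 + cos 0) = ϑ
    (2.0, 3, 0.0, np.pi / 3, 0.0),    # cos(180°) = −1
    (3.0, 2, np.pi, np.pi / 2, 3.0),  # cos(2·90° − 180°) = 1
])
def test_dihedral_energy_values(k, n, gamma, phi, expected):
    e, _ = dihedral_energy(_torsion_params(k, n, gamma), _torsion_coords(phi))
    assert e == pytest.approx(expected, abs=1e-9)


def test_dihedral_collinear_raises():
    p = _torsion_params(1.0, 1, 0.0)
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 1, 0]])
    with pytest.raises(DegenerateGeometryError):
        dihedral_energy(p, coords)


# ----------------------------------------------------------------------
# nonbonded values, cutoffs, switching
# ----------------------------------------------------------------------

def test_lj_zero_at_sigma_and_minimum_at_rmin():
    opt = EnergyOptions()
    s = _pair_system(3.0, eps=0.2, sigma=3.0)
    e_lj, e_q, _ = nonbonded_energy(s, opt)
    assert e_lj == pytest.approx(0.0, abs=1e-12)
    rmin = 2.0 ** (1 / 6) * 3.0  # < 9 Å: switch inactive
    s = _pair_system(rmin, eps=0.2, sigma=3.0)
    e_lj, _, _ = nonbonded_energy(s, opt)
    assert e_lj == pytest.approx(-0.2, rel=1e-12)


def test_nonbonded_vanishes_beyond_cutoff():
    opt = EnergyOptions()
    s = _pair_system(10.5, eps=0.2, sigma=3.0, q=(0.5, -0.5))
    e_lj, e_q, g = nonbonded_energy(s, opt)
    assert e_lj == 0.0 and e_q == 0.0
    assert np.allclose(g, 0.0)


def test_lj_continuity_across_switch_and_cutoff():
    """Energy and force stay continuous through r_switch and r_cut."""
    opt = EnergyOptions()
    for r0 in (9.0, 10.0):
        rs = np.linspace(r0 - 5e-4, r0 + 5e-4, 41)
        es, fs = [], []
        for r in rs:
            s = _pair_system(r, eps=0.5, sigma=4.0, q=(0.3, -0.3))
            e_lj, e_q, g = nonbonded_energy(s, opt)
            es.append(e_lj + e_q)
            fs.append(g[0, 0])
        assert np.abs(np.diff(es)).max() < 1e-5
        assert np.abs(np.diff(fs)).max() < 1e-4


def test_overlap_raises():
    s = _pair_system(0.05, eps=0.2, sigma=3.0)
    with pytest.raises(OverlapError):
        nonbonded_energy(s, EnergyOptions())


def test_one_four_scaling_applied():
    """The single 1-4 LJ pair of the 4-bead chain carries the scale factor."""
    full = make_fixture("butane_like")
    full.params.scale14_lj = 1.0
    half = make_fixture("butane_like")
    assert half.params.scale14_lj == 0.5
    e_full, _, _ = nonbonded_energy(full, EnergyOptions())
    e_half, _, _ = nonbonded_energy(half, EnergyOptions())
    assert e_half == pytest.approx(0.5 * e_full, rel=1e-9)


# ----------------------------------------------------------------------
# generalized Born and restraint
# ----------------------------------------------------------------------

def test_gb_vacuum_limit_and_born_self_energy():
    from remdsearch.constants import COULOMB
    params = _two_atom_params(q=(1.0, 0.0), bonded=False)
    params.born_radius = np.array([2.0, 2.0])
    coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
    s = MolecularSystem(elements=["NA", "C"], params=params, coords=coords)
    e, g = gb_energy(s, dielectric=1.0, salt_molar=0.0)
    assert e == pytest.approx(0.0)
    # isolated ion: −(1/2)(1 − 1/ε) q²C/a  (partner atom is neutral)
    e, _ = gb_energy(s, dielectric=78.5, salt_molar=0.0)
    expected = -0.5 * (1 - 1 / 78.5) * COULOMB / 2.0
    assert e == pytest.approx(expected, rel=1e-9)


def test_gb_dielectric_below_one_raises():
    s = _pair_system(3.0)
    s.params.born_radius = np.ones(2)
    with pytest.raises(ValueError):
        gb_energy(s, dielectric=0.5)


def test_gb_gradient_two_charges():
    params = _two_atom_params(q=(0.7, -0.4), bonded=False)
    params.born_radius = np.array([1.5, 1.8])
    coords = np.array([[0.1, -0.2, 0.3], [2.1, 0.4, -0.5]])
    s = MolecularSystem(elements=["C", "C"], params=params, coords=coords)
    _check_gradient(lambda c: gb_energy(s, 78.5, 0.2, c), coords, rtol=1e-6)


def test_com_restraint_values_and_gradient(rng):
    s = make_fixture("harmonic3d")
    target = s.coords.mean(axis=0)  # equal masses: COM = centroid
    e, g = com_restraint_energy(s, 5.0, target)
    assert e == pytest.approx(0.0, abs=1e-20)
    # ½ k |Δ|² = 0.5 · 5 · 1² = 2.5
    e, _ = com_restraint_energy(s, 5.0, target + [1.0, 0.0, 0.0])
    assert e == pytest.approx(2.5, rel=1e-12)
    coords = s.coords + rng.normal(scale=0.1, size=s.coords.shape)
    _check_gradient(
        lambda c: com_restraint_energy(s, 5.0, target, c), coords, rtol=1e-6)


# ----------------------------------------------------------------------
# total energy
# ----------------------------------------------------------------------

def test_total_energy_additivity(butane):
    report, total, grad = total_energy(butane)
    parts = (report.bond + report.angle + report.dihedral + report.lj
             + report.coulomb + report.implicit_solvent + report.restraint)
    assert report.total == pytest.approx(parts, abs=1e-10)
    e_b, g_b = bond_energy(butane.params, butane.coords)
    e_a, g_a = angle_energy(butane.params, butane.coords)
    e_d, g_d = dihedral_energy(butane.params, butane.coords)
    e_lj, e_q, g_nb = nonbonded_energy(butane, EnergyOptions())
    assert total == pytest.approx(e_b + e_a + e_d + e_lj + e_q, abs=1e-10)
    assert np.allclose(grad, g_b + g_a + g_d + g_nb, atol=1e-10)


@pytest.mark.parametrize("fixture,mode", [
    ("butane_like", "gas"),
    ("double_well_torsion", "gas"),
    ("minidrug", "gas"),
    ("minidrug", "implicit"),
])
def test_full_gradient_matches_finite_differences(fixture, mode, rng):
    s = make_fixture(fixture)
    opt = EnergyOptions(mode=mode)
    coords = s.coords + rng.normal(scale=0.02, size=s.coords.shape)
    e, g = (lambda t: (t[1], t[2]))(total_energy(s, opt, coords))
    fd = _fd_gradient(lambda c: total_energy(s, opt, c)[1], coords)
    assert np.abs(g - fd).max() / max(1.0, np.abs(fd).max()) < 1e-5


def test_energy_invariant_under_rigid_motion(minidrug, rng):
    from scipy.spatial.transform import Rotation
    _, e0, _ = total_energy(minidrug)
    rot = Rotation.random(random_state=7).as_matrix()
    moved = minidrug.coords @ rot.T + np.array([3.0, -2.0, 11.0])
    _, e1, _ = total_energy(minidrug, coords=moved)
    assert e1 == pytest.approx(e0, abs=1e-8)


def test_periodic_energy_invariant_under_box_translation(water_box):
    _, e0, _ = total_energy(water_box, EnergyOptions(mode="explicit"))
    moved = water_box.coords.copy()
    moved[5] += water_box.box  # translate one atom by a full box vector
    _, e1, _ = total_energy(water_box, EnergyOptions(mode="explicit"),
                            coords=moved)
    assert e1 == pytest.approx(e0, abs=1e-8)


def test_compiled_and_numpy_paths_agree(minidrug, rng):
    """The fused kernel and the reference numpy terms give one physics."""
    from remdsearch import _kernels
    if not _kernels.AVAILABLE:
        coords = minidrug.coords
        total_energy(minidrug, coords=coords)  # numpy path runs: nothing to compare
        return
    opt = EnergyOptions()
    batch = (minidrug.coords[None]
             + rng.normal(scale=0.05, size=(4,) + minidrug.coords.shape))
    fast = _core_terms(minidrug, opt, batch)
    _kernels.AVAILABLE = False
    try:
        ref = _core_terms(minidrug, opt, batch)
    finally:
        _kernels.AVAILABLE = True
    for a, b in zip(fast, ref):
        assert np.abs(np.asarray(a) - np.asarray(b)).max() < 1e-10


def test_box_smaller_than_twice_cutoff_rejected(water_box):
    small = water_box.copy()
    small.box = np.array([15.0, 21.0, 21.0])
    with pytest.raises(ValueError):
        total_energy(small, EnergyOptions(mode="explicit"))
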
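"""Superposition, RMSD, QT clustering and Boltzmann probability reporting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from remdsearch.clustering import (AlignmentError, Trajectory,
                                   conformer_probabilities, kabsch_superpose,
                                   qt_cluster, quadrature_populations, rmsd,
                                   rmsd_matrix)
from remdsearch.constants import KB


def _random_frame(rng, n=8, scale=2.0):
    return rng.normal(scale=scale, size=(n, 3))


# ----------------------------------------------------------------------
# Kabsch superposition
# ----------------------------------------------------------------------

def test_kabsch_identity_on_identical_frames(rng):
    a = _random_frame(rng)
    rot, trans, aligned = kabsch_superpose(a, a)
    assert np.allclose(rot, np.eye(3), atol=1e-10)
    assert np.allclose(trans, 0.0, atol=1e-10)
    assert np.allclose(aligned, a, atol=1e-10)


def test_kabsch_recovers_rigid_transform_exactly(rng):
    a = _random_frame(rng)
    r = Rotation.random(random_state=3).as_matrix()
    b = a @ r.T + np.array([1.0, -2.0, 0.5])
    rot, trans, aligned = kabsch_superpose(a, b)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
    assert rmsd(a, aligned) < 1e-10


def test_kabsch_beats_random_transforms(rng):
    """The closed-form minimum is a lower bound over sampled rigid motions."""
    a = _random_frame(rng)
    b = _random_frame(rng)
    _, _, aligned = kabsch_superpose(a, b)
    best = rmsd(a, aligned)
    bc = b - b.mean(axis=0)
    for k in range(2000):
        r = Rotation.random(random_state=k).as_matrix()
        trial = bc @ r.T + a.mean(axis=0)
        assert rmsd(a, trial) >= best - 1e-9


def test_kabsch_agrees_with_scipy_alignment(rng):
    a = _random_frame(rng)
    b = _random_frame(rng)
    _, _, aligned = kabsch_superpose(a, b)
    ours = rmsd(a, aligned)
    est, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
    theirs = rssd / np.sqrt(a.shape[0])
    assert ours == pytest.approx(theirs, rel=1e-8, abs=1e-10)


def test_kabsch_rejects_collinear_selection():
    line = np.stack([np.array([t, 0.0, 0.0]) for t in range(5)])
    with pytest.raises(AlignmentError):
        kabsch_superpose(line, line + 1.0)


# ----------------------------------------------------------------------
# RMSD
# ----------------------------------------------------------------------

def test_rmsd_examples(rng):
    a = _random_frame(rng, n=4)
    assert rmsd(a, a) == 0.0
    b = a.copy()
    b[2, 1] += 1.0  # one of four atoms displaced by 1 Å → √(1/4)
    assert rmsd(a, b) == pytest.approx(0.5, rel=1e-12)


def test_rmsd_matches_naive_loop(rng):
    a = _random_frame(rng)
    b = _random_frame(rng)
    n = a.shape[0]
    acc = sum(np.sum((a[k] - b[k]) ** 2) for k in range(n))
    assert rmsd(a, b) == pytest.approx(np.sqrt(acc / n), abs=1e-12)


def test_min_rmsd_is_pseudo_metric(rng):
    """Symmetry and the triangle inequality hold after superposition."""
    frames = np.stack([_random_frame(rng) for _ in range(6)])
    dm = rmsd_matrix(frames)
    assert np.allclose(dm, dm.T, atol=1e-10)
    assert np.allclose(np.diag(dm), 0.0, atol=1e-10)
    for i in range(6):
        for j in range(6):
            for k in range(6):
                assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-9


def test_global_prealignment_mode_runs(rng):
    frames = np.stack([_random_frame(rng) for _ in range(5)])
    dm = rmsd_matrix(frames, superpose=False)
    assert dm.shape == (5, 5)
    assert np.allclose(dm, dm.T, atol=1e-10)


# ----------------------------------------------------------------------
# QT clustering
# ----------------------------------------------------------------------

def _reference_qt(dm, cutoff, n_clusters):
    """Independent brute-force QT: literal restatement of the algorithm."""
    f = dm.shape[0]
    remaining = set(range(f))
    clusters = []
    while remaining and len(clusters) < n_clusters:
        best_members, best_centroid = None, None
        for c in sorted(remaining):
            members = sorted(m for m in remaining if dm[c, m] <= cutoff)
            if best_members is None or len(members) > len(best_members):
                best_members, best_centroid = members, c
        clusters.append((best_centroid, best_members))
        remaining -= set(best_members)
    return clusters, sorted(remaining)


def test_qt_all_identical_frames_single_cluster(rng):
    frame = _random_frame(rng)
    traj = Trajectory(frames=np.repeat(frame[None], 20, axis=0))
    cs = qt_cluster(traj, cutoff=1.0, n_clusters=5)
    assert len(cs) == 1
    assert cs.clusters[0].members.size == 20
    assert cs.remainder.size == 0


def test_qt_recovers_planted_groups(rng):
    """Two tight groups 5 Å apart are recovered exactly (vs brute force)."""
    base = _random_frame(rng, n=6, scale=3.0)
    far = base + np.array([5.0, 0, 0]) + rng.normal(scale=1.0, size=(6, 3))
    frames = []
    labels = []
    for k in range(60):
        if k % 3 == 0:
            frames.append(far + rng.normal(scale=0.1, size=(6, 3)))
            labels.append(1)
        else:
            frames.append(base + rng.normal(scale=0.1, size=(6, 3)))
            labels.append(0)
    frames = np.stack(frames)
    labels = np.array(labels)
    dm = rmsd_matrix(frames)
    cs = qt_cluster(Trajectory(frames=frames), cutoff=1.0, n_clusters=5,
                    distance_matrix=dm)
    ref_clusters, ref_rem = _reference_qt(dm, 1.0, 5)
    assert len(cs) == len(ref_clusters)
    for got, (ref_c, ref_m) in zip(cs.clusters, ref_clusters):
        assert got.centroid == ref_c
        assert got.members.tolist() == ref_m
    assert cs.remainder.tolist() == ref_rem
    # and the two planted groups come out as the top two clusters
    assert set(cs.clusters[0].members.tolist()) == set(np.flatnonzero(labels == 0))
    assert set(cs.clusters[1].members.tolist()) == set(np.flatnonzero(labels == 1))


def test_qt_matches_reference_on_random_clouds(rng):
    frames = np.stack([_random_frame(rng, n=5, scale=1.2) for _ in range(80)])
    dm = rmsd_matrix(frames)
    for cutoff in (0.8, 1.2, 2.0):
        cs = qt_cluster(Trajectory(frames=frames), cutoff=cutoff,
                        n_clusters=4, distance_matrix=dm)
        ref_clusters, ref_rem = _reference_qt(dm, cutoff, 4)
        assert [c.centroid for c in cs.clusters] == [r[0] for r in ref_clusters]
        assert cs.remainder.tolist() == ref_rem


def test_qt_defaults_and_errors(rng):
    frames = np.stack([_random_frame(rng) for _ in range(4)])
    cs = qt_cluster(Trajectory(frames=frames))
    assert cs.cutoff == 1.0 and cs.n_requested == 5
    with pytest.raises(ValueError):
        qt_cluster(Trajectory(frames=np.zeros((0, 3, 3))))
    with pytest.raises(ValueError):
        qt_cluster(Trajectory(frames=frames), cutoff=-1.0)


def test_qt_cluster_sizes_non_increasing(rng):
    frames = np.stack([_random_frame(rng, n=5) for _ in range(50)])
    cs = qt_cluster(Trajectory(frames=frames), cutoff=1.5, n_clusters=5)
    sizes = [c.members.size for c in cs.clusters]
    assert sizes == sorted(sizes, reverse=True)


# ----------------------------------------------------------------------
# probabilities
# ----------------------------------------------------------------------

def test_conformer_probabilities_two_equal_clusters(rng):
    frame_a = _random_frame(rng)
    frame_b = _random_frame(rng)  # different internal geometry
    frames = np.concatenate([np.repeat(frame_a[None], 10, axis=0),
                             np.repeat(frame_b[None], 10, axis=0)])
    cs = qt_cluster(Trajectory(frames=frames), cutoff=1.0, n_clusters=5)
    rep = conformer_probabilities(cs, temperature=298.0)
    assert np.allclose(rep.probabilities, [0.5, 0.5])
    assert rep.delta_g[0] == 0.0
    assert rep.delta_g[1] == pytest.approx(0.0, abs=1e-12)


def test_conformer_probabilities_boltzmann_inversion():
    from remdsearch.clustering import Cluster, ClusterSet
    clusters = [Cluster(members=np.arange(600), centroid=0, population=0.6),
                Cluster(members=np.arange(600, 900), centroid=600,
                        population=0.3),
                Cluster(members=np.arange(900, 1000), centroid=900,
                        population=0.1)]
    cs = ClusterSet(clusters=clusters, remainder=np.array([], int),
                    cutoff=1.0, n_requested=5, n_frames=1000)
    rep = conformer_probabilities(cs, temperature=298.0)
    assert np.allclose(rep.probabilities, [0.6, 0.3, 0.1])
    assert rep.delta_g[1] == pytest.approx(-KB * 298.0 * np.log(0.5), rel=1e-12)
    assert rep.delta_g[2] == pytest.approx(-KB * 298.0 * np.log(1.0 / 6.0),
                                           rel=1e-12)


# ----------------------------------------------------------------------
# quadrature oracle
# ----------------------------------------------------------------------

def test_quadrature_symmetric_double_well():
    v = lambda phi: 2.0 * (1.0 - np.cos(2.0 * phi))
    pops = quadrature_populations(
        v, 298.0, {"a": (-np.pi / 2, np.pi / 2), "b": (np.pi / 2, 3 * np.pi / 2)})
    assert pops["a"] == pytest.approx(0.5, abs=1e-10)
    assert pops["b"] == pytest.approx(0.5, abs=1e-10)


def test_quadrature_deep_well_boltzmann_ratio():
    """Offset ΔV = k_BT ln 2 between identical deep wells → (2/3, 1/3)."""
    kt = KB * 298.0
    dv = kt * np.log(2.0)
    v = lambda phi: 40.0 * (1.0 - np.cos(2.0 * phi)) + dv * 0.5 * (1.0 + np.cos(phi))
    pops = quadrature_populations(
        v, 298.0, {"low": (np.pi / 2, 3 * np.pi / 2),
                   "high": (-np.pi / 2, np.pi / 2)})
    assert pops["low"] == pytest.approx(2.0 / 3.0, abs=2e-3)
    assert pops["high"] == pytest.approx(1.0 / 3.0, abs=2e-3)


def test_quadrature_matches_dense_riemann_sum():
    v = lambda phi: 1.3 * (1 + np.cos(phi)) + 0.9 * (1 + np.cos(2 * phi - 0.7))
    basins = {"a": (-1.0, 1.5), "b": (1.5, 2 * np.pi - 1.0)}
    pops = quadrature_populations(v, 320.0, basins)
    kt = KB * 320.0
    phi = np.linspace(-np.pi, np.pi, 2_000_001)
    w = np.exp(-v(phi) / kt)
    z = np.trapezoid(w, phi)
    for name, (lo, hi) in basins.items():
        phi_b = np.linspace(lo, hi, 2_000_001)
        zb = np.trapezoid(np.exp(-v(phi_b) / kt), phi_b)
        assert pops[name] == pytest.approx(zb / z, abs=1e-8)


def test_quadrature_requires_labelled_basins():
    with pytest.raises(ValueError):
        quadrature_populations(lambda p: 0.0 * p, 298.0, {})
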
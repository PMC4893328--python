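"""Conformer identification from a trajectory.

The lowest-temperature replica trajectory is analysed by quality-threshold
(QT) clustering under the pairwise RMSD metric

    d_ij = [ (1/N) Σ_k |r_k^(i) − r_k^(j)|² ]^{1/2}

evaluated after optimal rigid superposition (Kabsch).  QT clustering grows,
for every remaining frame taken as a candidate centroid, the set of frames
within the RMSD cutoff of that centroid, keeps the largest such cluster,
removes its members and repeats until the requested number of clusters is
produced.  Cluster populations estimate conformer probabilities; relative
Gibbs energies follow from the Boltzmann relation
ΔG_i = −k_B T ln(p_i/p_1).

For a one-dimensional torsional model the exact basin populations

    p_i = ∫_i e^{−V(φ)/k_B T} dφ / ∫ e^{−V(φ)/k_B T} dφ

are available by adaptive quadrature and serve as the independent oracle
for end-to-end sampling checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .constants import KB

__all__ = [
    "Trajectory",
    "Cluster",
    "ClusterSet",
    "ConformerReport",
    "AlignmentError",
    "kabsch_superpose",
    "rmsd",
    "rmsd_matrix",
    "qt_cluster",
    "conformer_probabilities",
    "quadrature_populations",
]


class AlignmentError(ValueError):
    """Superposition is ill-defined (fewer than 3 non-collinear atoms)."""


@dataclass
class Trajectory:
    """Ordered coordinate frames with per-frame metadata.

    ``frames`` has shape (F, N, 3); ``meta`` carries one row per frame
    (cycle, temperature slot, potential energy, ...); ``atom_indices``
    records which atoms of the parent system the frames contain.
    """

    frames: np.ndarray
    meta: pd.DataFrame | None = None
    atom_indices: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.meta is not None and len(self.meta) != self.n_frames:
            raise ValueError("metadata length must equal the frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __len__(self) -> int:
        return self.n_frames


# ----------------------------------------------------------------------
# superposition and RMSD
# ----------------------------------------------------------------------

def _apply_mask(frame, mask):
    frame = np.asarray(frame, dtype=np.float64)
    if mask is None:
        return frame
    return frame[..., mask, :]


def kabsch_superpose(frame_a, frame_b, mask=None):
    """Optimal rigid superposition of ``frame_b`` onto ``frame_a``.

    Returns ``(rotation (3,3), translation (3,), aligned_b)`` where
    ``aligned_b = frame_b @ rotation.T + translation`` minimizes the RMSD
    to ``frame_a`` over the masked atoms; the rotation is proper
    (det = +1).  The full frame is transformed even when a mask restricts
    the fit.
    """
    a = _apply_mask(frame_a, mask)
    b = _apply_mask(frame_b, mask)
    if a.shape != b.shape:
        raise ValueError("frames must have matching atom counts")
    if a.shape[0] < 3:
        raise AlignmentError("superposition needs at least 3 atoms")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    # collinearity: second principal moment vanishes
    sv_a = np.linalg.svd(a0, compute_uv=False)
    if sv_a[1] < 1e-8 * max(sv_a[0], 1.0):
        raise AlignmentError("reference selection is collinear")
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    aligned = np.asarray(frame_b, dtype=np.float64) @ rot.T + trans
    return rot, trans, aligned


def rmsd(frame_a, frame_b, mask=None) -> float:
    """Plain coordinate RMSD (no superposition), Eq.-style d_ij."""
    a = _apply_mask(frame_a, mask)
    b = _apply_mask(frame_b, mask)
    if a.shape != b.shape:
        raise ValueError("frames must have matching atom counts")
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def _min_rmsd_block(a, b):
    """Minimized (superposed) RMSD for batched frame pairs (..., N, 3)."""
    n = a.shape[-2]
    a0 = a - a.mean(axis=-2, keepdims=True)
    b0 = b - b.mean(axis=-2, keepdims=True)
    ga = np.sum(a0 * a0, axis=(-1, -2))
    gb = np.sum(b0 * b0, axis=(-1, -2))
    h = np.swapaxes(b0, -1, -2) @ a0
    sv = np.linalg.svd(h, compute_uv=False)
    det = np.linalg.det(h)
    s = sv[..., 0] + sv[..., 1] + np.where(det < 0, -sv[..., 2], sv[..., 2])
    msd = np.maximum(ga + gb - 2.0 * s, 0.0) / n
    return np.sqrt(msd)


def rmsd_matrix(frames, mask=None, superpose=True, reference=None,
                chunk: int = 250_000) -> np.ndarray:
    """All-pairs RMSD matrix of a trajectory.

    ``superpose=True`` (default) minimizes each pair over rigid motions via
    a batched Kabsch evaluation; ``superpose=False`` first aligns every
    frame to ``reference`` (frame 0 by default) and then takes plain RMSDs
    — the fast approximate mode.  ``chunk`` bounds memory of the batched
    pair evaluation.
    """
    frames = np.asarray(frames, dtype=np.float64)
    x = _apply_mask(frames, mask)
    f = x.shape[0]
    out = np.zeros((f, f))
    if not superpose:
        ref = x[0] if reference is None else _apply_mask(reference, None)
        aligned = np.empty_like(x)
        for k in range(f):
            _, _, aligned[k] = kabsch_superpose(ref, x[k])
        d = aligned[:, None] - aligned[None, :]
        return np.sqrt(np.mean(np.sum(d * d, axis=-1), axis=-1))
    ii, jj = np.triu_indices(f, k=1)
    for start in range(0, ii.size, chunk):
        sl = slice(start, start + chunk)
        vals = _min_rmsd_block(x[ii[sl]], x[jj[sl]])
        out[ii[sl], jj[sl]] = vals
        out[jj[sl], ii[sl]] = vals
    return out


# ----------------------------------------------------------------------
# quality-threshold clustering
# ----------------------------------------------------------------------

@dataclass
class Cluster:
    members: np.ndarray  # frame indices, ascending
    centroid: int  # frame index
    population: float  # fraction of all frames


@dataclass
class ClusterSet:
    clusters: list
    remainder: np.ndarray
    cutoff: float
    n_requested: int
    n_frames: int

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def populations(self) -> np.ndarray:
        return np.array([c.population for c in self.clusters])


def qt_cluster(trajectory, cutoff: float = 1.0, n_clusters: int = 5,
               mask=None, superpose: bool = True,
               distance_matrix: np.ndarray | None = None) -> ClusterSet:
    """Quality-threshold clustering of a trajectory under min-RMSD.

    Every remaining frame is tried as a candidate centroid; the candidate
    collecting the most remaining frames within ``cutoff`` wins (ties break
    toward the lowest frame index), its members are removed, and the
    search repeats until ``n_clusters`` clusters exist or no frames
    remain.  Unassigned frames are reported as the remainder, never
    silently dropped.  Defaults: 1.0 Å cutoff, five clusters.
    """
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else np.asarray(trajectory)
    f = frames.shape[0]
    if f == 0:
        raise ValueError("cannot cluster an empty trajectory")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    dm = (rmsd_matrix(frames, mask=mask, superpose=superpose)
          if distance_matrix is None else np.asarray(distance_matrix))
    remaining = np.ones(f, dtype=bool)
    clusters: list[Cluster] = []
    within = dm <= cutoff
    for _ in range(n_clusters):
        idx = np.flatnonzero(remaining)
        if idx.size == 0:
            break
        counts = within[np.ix_(idx, idx)].sum(axis=1)
        best = int(np.argmax(counts))  # argmax takes the first max: lowest index
        centroid = int(idx[best])
        members = idx[within[centroid, idx]]
        clusters.append(Cluster(members=members, centroid=centroid,
                                population=members.size / f))
        remaining[members] = False
    return ClusterSet(clusters=clusters, remainder=np.flatnonzero(remaining),
                      cutoff=cutoff, n_requested=n_clusters, n_frames=f)


# ----------------------------------------------------------------------
# probabilities and the quadrature oracle
# ----------------------------------------------------------------------

@dataclass
class ConformerReport:
    """Per-conformer probabilities and Boltzmann relative Gibbs energies."""

    probabilities: np.ndarray  # p_i, largest cluster first
    delta_g: np.ndarray  # kcal·mol⁻¹, ΔG_1 = 0
    centroids: np.ndarray  # representative frame index per conformer
    temperature: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "conformer": np.arange(1, self.probabilities.size + 1),
            "probability": self.probabilities,
            "delta_g_kcal_mol": self.delta_g,
            "centroid_frame": self.centroids,
        })


def conformer_probabilities(cluster_set: ClusterSet, temperature: float = 298.0
                            ) -> ConformerReport:
    """Population-based conformer probabilities and ΔG_i = −k_B T ln(p_i/p_1).

    p_i is the fraction of all trajectory frames in cluster i (remainder
    frames count toward the denominator), so Σ p_i ≤ 1.
    """
    if len(cluster_set) == 0:
        raise ValueError("cluster set is empty")
    p = cluster_set.populations
    dg = -KB * temperature * np.log(p / p[0])
    centroids = np.array([c.centroid for c in cluster_set.clusters])
    return ConformerReport(probabilities=p, delta_g=dg, centroids=centroids,
                           temperature=temperature)


def quadrature_populations(potential_1d, temperature: float, basins: dict,
                           period: tuple[float, float] = (-np.pi, np.pi)
                           ) -> dict[str, float]:
    """Exact Boltzmann basin populations of a 1D periodic potential.

    ``basins`` maps labels to (lo, hi) angle intervals (radians); an
    interval may cross the period boundary (e.g. (π/2, 3π/2) for a basin
    centred on ±π).  The denominator integrates over one full period.
    Adaptive quadrature to ~1e-10 relative.
    """
    if not basins:
        raise ValueError("at least one labelled basin is required")
    lo, hi = period
    width = hi - lo
    for name, (a, b) in basins.items():
        if not b > a:
            raise ValueError(f"basin {name!r} has non-positive width")
        if b - a > width + 1e-9:
            raise ValueError(f"basin {name!r} is wider than the period")
    kt = KB * temperature

    def boltz(phi):
        return np.exp(-potential_1d(phi) / kt)

    z_total, _ = quad(boltz, lo, hi, epsabs=1e-13, epsrel=1e-11, limit=200)
    pops = {}
    for name, (a, b) in basins.items():
        z, _ = quad(boltz, a, b, epsabs=1e-13, epsrel=1e-11, limit=200)
        pops[name] = z / z_total
    return pops
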
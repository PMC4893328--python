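"""Replica-exchange molecular dynamics (parallel tempering).

``m`` non-interacting replicas of one system are propagated, each at its
own temperature drawn from a geometric ladder.  Every cycle (default 1000
MD steps) neighbouring replicas attempt a configuration swap accepted with
probability

    P_acc = min[1, exp((1/k_B)(1/T_i − 1/T_j)(V_i − V_j))]

Exchange attempts alternate between the even pairs (1-2, 3-4, …) and the
odd pairs (2-3, 4-5, …) on successive cycles.  On acceptance coordinates
are swapped and the swapped velocities are rescaled by √(T_dest/T_src) so
each replica keeps a Maxwell distribution at its own temperature.

The ensemble state is stored per *temperature slot*: slot ``i`` always sits
at ladder temperature ``T_i`` and exchanges move configurations between
slots.  ``replica_ids`` tracks which walker currently occupies each slot,
giving the mixing diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KB
from .dynamics import IntegratorSettings, init_velocities, propagate
from .forcefield import EnergyOptions, make_potential
from .system import MolecularSystem
from .clustering import Trajectory

__all__ = [
    "TemperatureLadder",
    "ReplicaEnsemble",
    "ExchangeReport",
    "EmptyExchangeReport",
    "geometric_ladder",
    "exchange_probability",
    "attempt_exchange",
    "run_remd",
    "exchange_report",
]


class EmptyExchangeReport(RuntimeError):
    """No exchange attempts have been recorded yet."""


@dataclass
class TemperatureLadder:
    """Strictly increasing replica temperatures (K)."""

    temperatures: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=np.float64)
        if self.temperatures.ndim != 1 or self.temperatures.size < 1:
            raise ValueError("ladder must be a 1D array of temperatures")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("ladder temperatures must be strictly increasing")

    def __len__(self) -> int:
        return self.temperatures.size

    def __getitem__(self, i) -> float:
        return float(self.temperatures[i])


def geometric_ladder(t_min: float, t_max: float, m: int) -> TemperatureLadder:
    """Geometric temperature ladder T_i = T_min (T_max/T_min)^((i−1)/(m−1)).

    Geometric spacing keeps the energy-distribution overlap of neighbouring
    replicas approximately constant along the ladder.  Endpoints are exact.
    """
    if m < 2:
        raise ValueError("a ladder needs at least 2 replicas")
    if not 0 < t_min < t_max:
        raise ValueError("require 0 < t_min < t_max")
    i = np.arange(m)
    temps = t_min * (t_max / t_min) ** (i / (m - 1))
    temps[0] = t_min
    temps[-1] = t_max
    return TemperatureLadder(temps)


def exchange_probability(v_i: float, v_j: float, t_i: float, t_j: float) -> float:
    """Metropolis-style acceptance probability for a replica swap."""
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    arg = (1.0 / KB) * (1.0 / t_i - 1.0 / t_j) * (v_i - v_j)
    if arg >= 0:
        return 1.0
    return float(np.exp(arg))


@dataclass
class ReplicaEnsemble:
    """Per-slot replica states plus exchange bookkeeping."""

    system: MolecularSystem  # shared topology template
    ladder: TemperatureLadder
    coords: np.ndarray  # (m, N, 3)
    velocities: np.ndarray  # (m, N, 3)
    potential_energies: np.ndarray  # (m,)
    options: EnergyOptions = field(default_factory=EnergyOptions)
    replica_ids: np.ndarray | None = None  # (m,) walker occupying each slot
    pair_attempts: np.ndarray | None = None  # (m−1,)
    pair_accepts: np.ndarray | None = None  # (m−1,)
    phase: int = 0  # parity of the next exchange phase
    rngs: list | None = None  # per-replica thermostat streams
    exchange_rng: np.random.Generator | None = None
    trace: list = field(default_factory=list)  # replica_ids snapshots

    def __post_init__(self):
        m = len(self.ladder)
        if self.coords.shape[0] != m:
            raise ValueError("replica count must equal ladder length")
        if self.replica_ids is None:
            self.replica_ids = np.arange(m, dtype=np.intp)
        if self.pair_attempts is None:
            self.pair_attempts = np.zeros(max(m - 1, 0), dtype=np.int64)
        if self.pair_accepts is None:
            self.pair_accepts = np.zeros(max(m - 1, 0), dtype=np.int64)
        if self.rngs is None or self.exchange_rng is None:
            self.reseed(0)

    @property
    def m(self) -> int:
        return len(self.ladder)

    def reseed(self, seed: int) -> None:
        """Derive one independent RNG stream per replica plus an exchange stream."""
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(self.m + 1)
        self.rngs = [np.random.default_rng(c) for c in children[:-1]]
        self.exchange_rng = np.random.default_rng(children[-1])

    @classmethod
    def from_system(cls, system: MolecularSystem, ladder: TemperatureLadder,
                    seed: int = 0, options: EnergyOptions | None = None
                    ) -> "ReplicaEnsemble":
        """Clone one equilibrated system into every ladder slot.

        Each slot gets Maxwell–Boltzmann velocities at its own temperature,
        drawn from its own stream.
        """
        if options is None:
            options = EnergyOptions()
        m = len(ladder)
        coords = np.repeat(system.coords[None], m, axis=0)
        ens = cls(system=system, ladder=ladder, coords=coords,
                  velocities=np.zeros_like(coords),
                  potential_energies=np.zeros(m), options=options)
        ens.reseed(seed)
        for k in range(m):
            ens.velocities[k] = init_velocities(system, ladder[k], ens.rngs[k])
        potential = make_potential(system, options)
        pe, _ = potential(ens.coords)
        ens.potential_energies = np.asarray(pe, dtype=np.float64)
        return ens


def attempt_exchange(ensemble: ReplicaEnsemble, pair, u: float | None = None) -> bool:
    """Attempt a swap between the neighbouring slots ``pair = (k, k+1)``.

    Draws ``u ~ Uniform(0, 1)`` (overridable for testing) and accepts iff
    ``u < P_acc``.  On acceptance coordinates, potential energies and
    walker identities are swapped and velocities are swapped with the
    √(T_dest/T_src) rescaling.  Counters update either way.
    """
    i, j = int(pair[0]), int(pair[1])
    if j != i + 1 or not 0 <= i < ensemble.m - 1:
        raise ValueError(f"pair {pair} is not a neighbouring ladder pair")
    t_i, t_j = ensemble.ladder[i], ensemble.ladder[j]
    p = exchange_probability(ensemble.potential_energies[i],
                             ensemble.potential_energies[j], t_i, t_j)
    if u is None:
        u = float(ensemble.exchange_rng.uniform())
    ensemble.pair_attempts[i] += 1
    accepted = u < p
    if accepted:
        c = ensemble.coords
        v = ensemble.velocities
        c[[i, j]] = c[[j, i]]
        # configuration arriving in slot i came from T_j: rescale to T_i
        vi_new = v[j] * np.sqrt(t_i / t_j)
        vj_new = v[i] * np.sqrt(t_j / t_i)
        v[i], v[j] = vi_new, vj_new
        pe = ensemble.potential_energies
        pe[[i, j]] = pe[[j, i]]
        ids = ensemble.replica_ids
        ids[[i, j]] = ids[[j, i]]
        ensemble.pair_accepts[i] += 1
    return bool(accepted)


@dataclass
class ExchangeReport:
    """Acceptance statistics and the replica-slot occupancy trace."""

    pair_attempts: np.ndarray
    pair_accepts: np.ndarray
    replica_trace: np.ndarray  # (n_records, m)

    @property
    def per_pair_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.pair_attempts > 0,
                            self.pair_accepts / self.pair_attempts, np.nan)

    @property
    def average_rate(self) -> float:
        total = int(self.pair_attempts.sum())
        if total == 0:
            return float("nan")
        return float(self.pair_accepts.sum() / total)

    def to_dataframe(self) -> pd.DataFrame:
        m1 = self.pair_attempts.size
        return pd.DataFrame({
            "pair": [f"{k}-{k + 1}" for k in range(m1)],
            "attempts": self.pair_attempts,
            "accepts": self.pair_accepts,
            "rate": self.per_pair_rate,
        })


def exchange_report(ensemble: ReplicaEnsemble, allow_empty: bool = False) -> ExchangeReport:
    """Summarize acceptance counters; raises if nothing was attempted."""
    if ensemble.pair_attempts.sum() == 0 and not allow_empty:
        raise EmptyExchangeReport("no exchange attempts recorded")
    trace = (np.array(ensemble.trace, dtype=np.intp)
             if ensemble.trace else np.zeros((0, ensemble.m), dtype=np.intp))
    return ExchangeReport(pair_attempts=ensemble.pair_attempts.copy(),
                          pair_accepts=ensemble.pair_accepts.copy(),
                          replica_trace=trace)


def run_remd(ensemble: ReplicaEnsemble, n_cycles: int,
             steps_per_cycle: int = 1000,
             settings: IntegratorSettings | None = None,
             frame_atoms: np.ndarray | None = None):
    """Run the REMD loop: propagate, exchange, capture, repeat.

    Each cycle propagates every replica ``steps_per_cycle`` BAOAB steps at
    its slot temperature (one vectorized batch), runs one alternating
    exchange phase, then appends one frame per temperature slot.  Returns
    ``(trajectories, report)`` where ``trajectories[0]`` — the lowest
    temperature slot — is the analysis target (``meta['is_target']``).

    ``frame_atoms`` selects which atoms are stored in the trajectory
    frames (defaults to the solute).
    """
    if steps_per_cycle < 1:
        raise ValueError("steps_per_cycle must be >= 1")
    if settings is None:
        settings = IntegratorSettings()
    system = ensemble.system
    potential = make_potential(system, ensemble.options)
    constraints = None
    if settings.constrain_h_bonds:
        from .dynamics import Constraints
        idx, d0 = system.hydrogen_bond_constraints()
        constraints = Constraints(idx, d0, system.masses)
    if frame_atoms is None:
        frame_atoms = np.flatnonzero(system.solute_mask)
    m = ensemble.m
    temps = ensemble.ladder.temperatures
    frames = [[] for _ in range(m)]
    meta = [[] for _ in range(m)]
    for cycle in range(n_cycles):
        x, v, pe, _ = propagate(
            ensemble.coords, ensemble.velocities, potential, system.masses,
            settings, steps_per_cycle, temperatures=temps,
            rngs=ensemble.rngs, constraints=constraints)
        ensemble.coords, ensemble.velocities = x, v
        ensemble.potential_energies = np.atleast_1d(np.asarray(pe, dtype=np.float64))
        if m > 1:
            start = ensemble.phase % 2
            for k in range(start, m - 1, 2):
                attempt_exchange(ensemble, (k, k + 1))
            ensemble.phase ^= 1
        ensemble.trace.append(ensemble.replica_ids.copy())
        for k in range(m):
            frames[k].append(ensemble.coords[k, frame_atoms].copy())
            meta[k].append((cycle, k, float(ensemble.potential_energies[k]),
                            int(ensemble.replica_ids[k])))
    trajectories = []
    for k in range(m):
        df = pd.DataFrame(meta[k], columns=["cycle", "temperature_slot",
                                            "potential", "replica_id"])
        traj = Trajectory(
            frames=np.array(frames[k]) if frames[k] else np.zeros((0, frame_atoms.size, 3)),
            meta=df, atom_indices=frame_atoms,
            info={"temperature": float(temps[k]), "is_target": k == 0},
        )
        trajectories.append(traj)
    report = exchange_report(ensemble, allow_empty=(m == 1 or n_cycles == 0))
    return trajectories, report
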
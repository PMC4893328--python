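"""End-to-end conformational search: build → equilibrate → REMD → cluster.

A :class:`RunConfig` fully determines a run; the resolved config is
snapshotted into the output bundle so any run can be reproduced bitwise
from its manifest.  Cycle counts default to desk-scale values; the
full-scale preset mirrors a production protocol (10⁶ equilibration steps,
10⁴ sampling cycles of 1000 × 1 fs steps per replica).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .clustering import conformer_probabilities, qt_cluster
from .dynamics import EquilibrationStage, IntegratorSettings, equilibrate
from .forcefield import EnergyOptions
from .io import load_system, write_structure, write_trajectory
from .remd import ReplicaEnsemble, geometric_ladder, run_remd
from .structgen import FIXTURE_NAMES, SolvationSpec, make_fixture, neutralize, solvate
from .system import MolecularSystem

__all__ = ["RunConfig", "OutputBundle", "run_workflow", "FULL_SCALE_PRESET"]

logger = logging.getLogger("remdsearch")

#: production-scale step counts (1 fs timestep): 1 ns equilibration and
#: 10 ns of sampling per replica at the standard exchange cadence.
FULL_SCALE_PRESET = {"equil_steps": 1_000_000, "prod_cycles": 10_000,
                     "steps_per_cycle": 1000}


@dataclass
class RunConfig:
    """Everything needed to reproduce one conformational-search run."""

    mode: str = "gas"  # gas | implicit | explicit
    t_min: float = 298.0
    t_max: float = 500.0
    n_replicas: int = 24
    equil_steps: int = 2000
    prod_cycles: int = 50
    steps_per_cycle: int = 1000
    timestep: float = 1.0  # fs
    friction: float = 1.0  # ps⁻¹
    cluster_cutoff: float = 1.0  # Å
    n_clusters: int = 5
    save_clusters: int = 1
    seed: int = 0
    name: str = "test"
    location: str = "."
    n_workers: int = 2  # interface compatibility; backend is vectorized
    r_switch: float = 9.0
    r_cut: float = 10.0
    dielectric: float = 78.5
    salt_molar: float = 0.2
    solvation_padding: float = 10.0
    com_restraint_k: float = 5.0
    heavy_atoms_only: bool = False  # RMSD mask for clustering

    def validate(self) -> None:
        if self.mode not in ("gas", "implicit", "explicit"):
            raise ValueError(f"mode must be gas|implicit|explicit, got {self.mode!r}")
        for key in ("equil_steps", "prod_cycles", "steps_per_cycle",
                    "n_replicas", "n_clusters", "save_clusters", "n_workers"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be non-negative")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")
        if not 0 < self.t_min <= self.t_max:
            raise ValueError("require 0 < t_min <= t_max")
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class OutputBundle:
    """Run directory layout plus in-memory results."""

    root: Path
    manifest: dict
    report: "object" = None  # ConformerReport
    exchange: "object" = None  # ExchangeReport
    cluster_set: "object" = None

    def paths(self) -> dict[str, str]:
        return dict(self.manifest["files"])


def _resolve_input(source, config: RunConfig) -> MolecularSystem:
    """Accept a MolecularSystem, a ``fixture:<name>`` tag, or file paths."""
    if isinstance(source, MolecularSystem):
        return source.copy()
    if isinstance(source, str) and source.startswith("fixture:"):
        name = source.split(":", 1)[1]
        return make_fixture(name, seed=config.seed)
    if isinstance(source, (tuple, list)) and len(source) == 2:
        return load_system(source[0], source[1])
    raise ValueError(
        "input must be a MolecularSystem, 'fixture:<name>' "
        f"(one of {', '.join(FIXTURE_NAMES)}), or a (structure, parameters) "
        "path pair")


def run_workflow(config: RunConfig, source) -> OutputBundle:
    """Execute the full search and write the output bundle.

    Stages: system build (solvation + neutralization for explicit mode),
    NVT equilibration, replica-exchange sampling, QT clustering of the
    lowest-temperature trajectory, conformer-probability reporting.  Any
    stage failure aborts with the stage name; files written so far are
    left in place.
    """
    config.validate()
    root = Path(config.location) / f"{config.name}_out"
    root.mkdir(parents=True, exist_ok=True)
    log_path = root / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    files: dict[str, str] = {"log": str(log_path)}
    stage = "build"
    try:
        t0 = time.time()
        system = _resolve_input(source, config)
        logger.info("config: %s", asdict(config))
        if config.mode == "explicit" and system.box is None:
            logger.info("solvating: padding %.1f Å", config.solvation_padding)
            system = solvate(system, SolvationSpec(padding=config.solvation_padding),
                             cutoff=config.r_cut, seed=config.seed)
            system = neutralize(system)
            logger.info("box %s, %d atoms", system.box, system.n_atoms)
        options = EnergyOptions(
            mode=config.mode if config.mode != "explicit" else "explicit",
            r_switch=config.r_switch, r_cut=config.r_cut,
            dielectric=config.dielectric, salt_molar=config.salt_molar)
        settings = IntegratorSettings(timestep=config.timestep,
                                      friction=config.friction,
                                      temperature=config.t_min,
                                      seed=config.seed)

        stage = "equilibrate"
        logger.info("equilibration: %d steps at %.1f K", config.equil_steps,
                    config.t_min)
        schedule = EquilibrationStage(
            n_steps=config.equil_steps, temperature=config.t_min,
            restrain_com=(config.mode == "explicit"),
            com_k=config.com_restraint_k)
        system, thermo = equilibrate(system, schedule, options, settings,
                                     seed=config.seed)
        thermo_path = root / "thermo_equilibration.tsv"
        thermo.to_csv(thermo_path, sep="\t", index=False)
        files["thermo_equilibration"] = str(thermo_path)

        stage = "remd"
        if config.n_replicas > 1:
            ladder = geometric_ladder(config.t_min, config.t_max,
                                      config.n_replicas)
        else:
            from .remd import TemperatureLadder
            ladder = TemperatureLadder(np.array([config.t_min]))
        logger.info("REMD: %d replicas %.0f–%.0f K, %d cycles × %d steps",
                    len(ladder), config.t_min, config.t_max,
                    config.prod_cycles, config.steps_per_cycle)
        ensemble = ReplicaEnsemble.from_system(system, ladder,
                                               seed=config.seed + 1,
                                               options=options)
        trajectories, exchange = run_remd(ensemble, config.prod_cycles,
                                          config.steps_per_cycle, settings)
        solute_elements = [e for e, keep in
                           zip(system.elements, system.solute_mask) if keep]
        for k, traj in enumerate(trajectories):
            p = root / f"trajectory_T{ladder[k]:.1f}K.pdb"
            write_trajectory(p, traj, elements=solute_elements)
            files[f"trajectory_slot{k}"] = str(p)
        ex_path = root / "exchange_report.tsv"
        exchange.to_dataframe().to_csv(ex_path, sep="\t", index=False)
        files["exchange_report"] = str(ex_path)
        trace_path = root / "replica_trace.tsv"
        np.savetxt(trace_path, exchange.replica_trace, fmt="%d", delimiter="\t")
        files["replica_trace"] = str(trace_path)
        if exchange.pair_attempts.sum():
            logger.info("mean exchange acceptance: %.3f", exchange.average_rate)

        stage = "cluster"
        target = trajectories[0]
        mask = None
        if config.heavy_atoms_only:
            mask = np.array([e.upper() != "H" for e in solute_elements])
        cluster_set = qt_cluster(target, cutoff=config.cluster_cutoff,
                                 n_clusters=config.n_clusters, mask=mask)
        report = conformer_probabilities(cluster_set, temperature=config.t_min)
        pop_path = root / "populations.tsv"
        report.to_dataframe().to_csv(pop_path, sep="\t", index=False)
        files["populations"] = str(pop_path)
        for rank, cluster in enumerate(cluster_set.clusters[:config.save_clusters]):
            cpath = root / f"cluster_{rank + 1}.pdb"
            sub = type(target)(frames=target.frames[cluster.members],
                               info={"elements": solute_elements})
            write_trajectory(cpath, sub, elements=solute_elements)
            files[f"cluster_{rank + 1}"] = str(cpath)
            cent = root / f"centroid_{rank + 1}.pdb"
            write_structure(cent, target.frames[cluster.centroid][None])
            files[f"centroid_{rank + 1}"] = str(cent)
        logger.info("clusters: %s",
                    [len(c.members) for c in cluster_set.clusters])

        stage = "finalize"
        cfg_path = root / "resolved_config.yaml"
        config.to_yaml(cfg_path)
        files["resolved_config"] = str(cfg_path)
        manifest = {
            "name": config.name,
            "files": files,
            "wall_time_s": round(time.time() - t0, 3),
            "n_atoms": int(system.n_atoms),
            "mean_acceptance": (float(exchange.average_rate)
                                if exchange.pair_attempts.sum() else None),
        }
        man_path = root / "manifest.json"
        with open(man_path, "w") as fh:
            json.dump(manifest, fh, indent=1)
        files["manifest"] = str(man_path)
        logger.info("done in %.1f s", time.time() - t0)
        return OutputBundle(root=root, manifest=manifest, report=report,
                            exchange=exchange, cluster_set=cluster_set)
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"workflow stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
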
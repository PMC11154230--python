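"""End-to-end orchestration: config, pipeline stages, manifest.

``run_pipeline`` executes simulate -> fingerprint -> distance -> cluster ->
mode report from a single serializable :class:`RunConfig`, writing every
intermediate artifact plus a manifest with content hashes so a rerun can be
verified byte for byte.  One shared label registry per run keeps wild-type
and perturbed fingerprints comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import models
from .dominance import DominanceConfig, SubnetworkRegistry, fingerprint_ensemble
from .io import (read_ensemble, write_distance_matrix, write_ensemble,
                 write_fingerprints)
from .modes import build_modes, cluster, distance_matrix, select_n_clusters
from .network import ParameterEnsemble, ReactionNetwork
from .dsl import build_network

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]

log = logging.getLogger("fluxmodes")

_FIXTURES = {
    "aearm": models.make_aearm,
    "toy_bifurcation": models.make_toy_bifurcation,
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML/JSON."""

    model: str                      # fixture name ("aearm", "toy_bifurcation") or DSL path
    target: str
    ensemble: str | None = None     # path to a stored ensemble
    synth_n: int | None = None      # or: sample this many vectors from the prior
    synth_log10_sd: float = 1.0
    rho: float = 1.0
    depth: int = 5
    direction: str = "production"
    t_end: float = 20000.0
    n_time_points: int = 100
    cluster_method: str = "agglomerative"
    n_clusters: int | None = None   # None = silhouette-selected
    k_max: int = 8
    rtol: float = 1e-6
    atol: float = 1e-6
    seed: int = 0
    out_dir: str = "fluxmodes_run"

    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_time_points)

    def dominance(self) -> DominanceConfig:
        return DominanceConfig(rho=self.rho, depth=self.depth,
                               direction=self.direction)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def resolve_network(self) -> ReactionNetwork:
        if self.model in _FIXTURES:
            return _FIXTURES[self.model]()
        return build_network(Path(self.model))


@dataclass
class PipelineResult:
    network: ReactionNetwork
    ensemble: ParameterEnsemble
    fingerprints: list
    registry: SubnetworkRegistry
    distances: "np.ndarray"
    assignments: np.ndarray
    modes: list
    n_clusters: int
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _resolve_ensemble(cfg: RunConfig, net: ReactionNetwork) -> ParameterEnsemble:
    if cfg.ensemble is not None:
        return read_ensemble(cfg.ensemble, net)
    if cfg.synth_n is None:
        raise ValueError("config must give either an ensemble path or synth_n")
    from .synth import PriorSpec, sample_ensemble

    if cfg.model == "aearm":
        nominal = models.aearm_nominal_params()
    elif cfg.model == "toy_bifurcation":
        nominal = models.toy_nominal_params()
    else:
        raise ValueError(
            "prior synthesis requires a bundled fixture model; supply an "
            "ensemble file for DSL models")
    prior = PriorSpec.for_network(net, nominal, cfg.synth_log10_sd)
    return sample_ensemble(prior, cfg.synth_n, seed=cfg.seed)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full discretization-to-modes pipeline and write artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    net = cfg.resolve_network()
    ensemble = _resolve_ensemble(cfg, net)
    if len(ensemble) < 2:
        raise ValueError("pipeline needs an ensemble of at least 2 vectors")
    log.info("stage=setup model=%s n=%d elapsed=%.2fs",
             net.name, len(ensemble), time.perf_counter() - t0)

    fps, registry, _ = fingerprint_ensemble(
        net, ensemble, cfg.time_grid(), cfg.target, cfg.dominance(),
        rtol=cfg.rtol, atol=cfg.atol)
    log.info("stage=fingerprint labels=%d elapsed=%.2fs",
             len(registry), time.perf_counter() - t0)

    dm = distance_matrix(fps)
    if cfg.n_clusters is not None:
        k = cfg.n_clusters
    else:
        k_hi = min(cfg.k_max, len(ensemble) - 1)
        k = select_n_clusters(dm, method=cfg.cluster_method,
                              k_range=range(2, k_hi + 1), seed=cfg.seed)
    if k == 1:
        assignments = np.zeros(len(ensemble), dtype=int)
    else:
        assignments = cluster(dm, method=cfg.cluster_method, n_clusters=k,
                              seed=cfg.seed)
    modes = build_modes(assignments, ensemble, fps, registry)
    log.info("stage=cluster k=%d elapsed=%.2fs", k, time.perf_counter() - t0)

    # artifacts
    write_ensemble(ensemble, out / "ensemble.csv")
    write_fingerprints(fps, out / "fingerprints.csv",
                       registry, out / "registry.json")
    write_distance_matrix(dm, out / "distances")
    np.savetxt(out / "assignments.csv",
               np.column_stack([np.arange(len(assignments)), assignments]),
               fmt="%d", delimiter=",", header="ensemble_index,mode_id",
               comments="")
    mode_report = {
        "n_clusters": int(k),
        "modes": [
            {
                "mode_id": int(m.mode_id),
                "probability": m.probability,
                "n_members": int(len(m.member_indices)),
                "representative_label": int(m.representative_label),
                "representative_edges": sorted(map(list, m.representative.edges)),
            }
            for m in modes
        ],
    }
    (out / "modes.json").write_text(json.dumps(mode_report, indent=1))
    cfg.to_yaml(out / "config.yaml")

    artifact_names = ["ensemble.csv", "fingerprints.csv", "registry.json",
                      "distances.npy", "distances.index.json",
                      "assignments.csv", "modes.json", "config.yaml"]
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "n_ensemble": len(ensemble),
        "n_clusters": int(k),
        "outputs": {name: _sha256(out / name) for name in artifact_names},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("stage=done elapsed=%.2fs", time.perf_counter() - t0)
    return PipelineResult(net, ensemble, fps, registry, dm.values,
                          assignments, modes, int(k), manifest)
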
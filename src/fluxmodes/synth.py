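"""Synthetic parameter ensembles with planted dominance regimes.

Stands in for Bayesian-calibration output (MCMC posterior chains are consumed
as input by this package, never produced): parameter vectors are drawn from
log-normal priors centered at biologically plausible rates, optionally
weighted by a Gaussian likelihood against synthetic observations
(importance-style weighting over prior samples), or planted into known
dominance regimes on the toy bifurcation fixture so that clustering results
can be validated against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dominance import DominanceConfig, SubnetworkRegistry, fingerprint
from .network import (ParameterEnsemble, ParameterVector, ReactionNetwork,
                      SimulationError, simulate)

__all__ = [
    "PriorSpec",
    "PlantedRegime",
    "sample_ensemble",
    "synthetic_observations",
    "weight_by_fit",
    "planted_regime_ensemble",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent log-normal priors: per-parameter center and log10 sd."""

    centers: Mapping[str, float]
    log10_sd: Mapping[str, float] | float = 1.0

    def __post_init__(self) -> None:
        for name, c in self.centers.items():
            if not c > 0:
                raise ValueError(f"prior center for {name!r} must be > 0")
        for name in self.centers:
            if not self.sd_for(name) >= 0:
                raise ValueError(f"prior sd for {name!r} must be >= 0")

    def sd_for(self, name: str) -> float:
        if isinstance(self.log10_sd, Mapping):
            return float(self.log10_sd[name])
        return float(self.log10_sd)

    @classmethod
    def for_network(cls, net: ReactionNetwork,
                    nominal: ParameterVector,
                    log10_sd: float = 1.0) -> "PriorSpec":
        return cls({p: nominal.values[p] for p in net.parameter_names}, log10_sd)


def sample_ensemble(prior: PriorSpec, n: int, seed: int = 0) -> ParameterEnsemble:
    """Draw n i.i.d. parameter vectors from the prior with uniform weights."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(prior.centers)
    log_centers = np.array([np.log10(prior.centers[p]) for p in names])
    sds = np.array([prior.sd_for(p) for p in names])
    draws = 10.0 ** (log_centers + sds * rng.standard_normal((n, len(names))))
    return ParameterEnsemble.from_array(draws, names)


def synthetic_observations(net: ReactionNetwork, truth_params: ParameterVector,
                           observables: Sequence[str | Sequence[str]],
                           time_grid: np.ndarray, noise_sd: float,
                           seed: int = 0) -> pd.DataFrame:
    """Noisy observation table from a ground-truth simulation.

    Each observable is a species name or a list of species to sum.  The
    returned frame holds both the noiseless truth (``<name>_true``) and the
    noisy copy (``<name>``), with homoscedastic additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    traj = simulate(net, truth_params, time_grid)
    data: dict[str, np.ndarray] = {"time": np.asarray(time_grid, dtype=float)}
    for obs in observables:
        if isinstance(obs, str):
            name, members = obs, [obs]
        else:
            members = list(obs)
            name = "+".join(members)
        for sp in members:
            if sp not in traj.species_names:
                raise KeyError(f"unknown observable species {sp!r}")
        truth = sum(traj.species(sp) for sp in members)
        data[f"{name}_true"] = truth
        data[name] = truth + noise_sd * rng.standard_normal(len(truth))
    return pd.DataFrame(data)


def _log_likelihood(net: ReactionNetwork, pv: ParameterVector,
                    observations: pd.DataFrame, noise_sd: float) -> float:
    time_grid = observations["time"].to_numpy()
    traj = simulate(net, pv, time_grid)
    ll = 0.0
    for col in observations.columns:
        if col == "time" or col.endswith("_true"):
            continue
        members = col.split("+")
        pred = sum(traj.species(sp) for sp in members)
        resid = observations[col].to_numpy() - pred
        ll += -0.5 * np.sum((resid / noise_sd) ** 2)
    return float(ll)


def weight_by_fit(ensemble: ParameterEnsemble, net: ReactionNetwork,
                  observations: pd.DataFrame,
                  noise_sd: float) -> ParameterEnsemble:
    """Attach normalized Gaussian-likelihood weights to every vector.

    Vectors whose simulation fails get zero weight (with a warning) so the
    rest of the ensemble is still usable.
    """
    logls = np.full(len(ensemble), -np.inf)
    for i, pv in enumerate(ensemble):
        try:
            logls[i] = _log_likelihood(net, pv, observations, noise_sd)
        except SimulationError as exc:
            warnings.warn(f"member {i}: simulation failed ({exc}); weight set to 0")
    finite = np.isfinite(logls)
    if not finite.any():
        raise ValueError("every ensemble member failed to simulate")
    w = np.zeros(len(ensemble))
    w[finite] = np.exp(logls[finite] - logls[finite].max())
    vectors = [
        ParameterVector(dict(pv.values), log_posterior=pv.log_posterior,
                        weight=float(wi))
        for pv, wi in zip(ensemble, w)
    ]
    return ParameterEnsemble(vectors)


@dataclass(frozen=True)
class PlantedRegime:
    """Multiplicative rate overrides that force a known dominant branch."""

    regime_id: int
    rate_factors: Mapping[str, float]
    description: str = ""

    def __post_init__(self) -> None:
        for name, f in self.rate_factors.items():
            if not f > 0:
                raise ValueError(f"override factor for {name!r} must be > 0")

    def apply(self, base: Mapping[str, float]) -> dict[str, float]:
        out = dict(base)
        for name, f in self.rate_factors.items():
            out[name] = out[name] * f
        return out


def _regime_fingerprint(net: ReactionNetwork, values: Mapping[str, float],
                        target: str, time_grid: np.ndarray,
                        cfg: DominanceConfig,
                        registry: SubnetworkRegistry) -> np.ndarray:
    pv = ParameterVector(dict(values))
    traj = simulate(net, pv, time_grid)
    return fingerprint(net, traj, pv, target, cfg, registry).labels


def planted_regime_ensemble(net: ReactionNetwork,
                            regimes: Sequence[PlantedRegime],
                            base_params: ParameterVector,
                            n_per_regime: int = 50,
                            jitter_sd: float = 0.05,
                            seed: int = 0,
                            target: str = "P",
                            time_grid: np.ndarray | None = None,
                            cfg: DominanceConfig | None = None,
                            ) -> tuple[ParameterEnsemble, np.ndarray]:
    """Build an ensemble with known regime labels for clustering validation.

    Each regime's center is the base parameter vector with its multiplicative
    overrides applied; members jitter the center by ``jitter_sd`` in log10
    space.  Construction fails unless the regime centers produce pairwise
    distinct fingerprints for the target (i.e., the regimes are separable by
    the dominance analysis itself).
    """
    ids = [r.regime_id for r in regimes]
    if len(set(ids)) != len(ids):
        raise ValueError("regime ids must be distinct")
    if time_grid is None:
        time_grid = np.linspace(0.0, 2000.0, 100)
    if cfg is None:
        cfg = DominanceConfig()

    registry = SubnetworkRegistry()
    center_fps = [
        _regime_fingerprint(net, r.apply(base_params.values), target,
                            time_grid, cfg, registry)
        for r in regimes
    ]
    for i in range(len(regimes)):
        for j in range(i + 1, len(regimes)):
            if np.array_equal(center_fps[i], center_fps[j]):
                raise ValueError(
                    f"regimes {regimes[i].regime_id} and {regimes[j].regime_id} "
                    "are not separable: identical fingerprints at their centers")

    rng = np.random.default_rng(seed)
    names = list(base_params.values)
    vectors: list[ParameterVector] = []
    labels: list[int] = []
    for r in regimes:
        center = r.apply(base_params.values)
        log_center = np.array([np.log10(center[p]) for p in names])
        for _ in range(n_per_regime):
            draw = 10.0 ** (log_center
                            + jitter_sd * rng.standard_normal(len(names)))
            vectors.append(ParameterVector(dict(zip(names, map(float, draw)))))
            labels.append(r.regime_id)
    return ParameterEnsemble(vectors), np.array(labels)
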
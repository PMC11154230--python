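"""Tropical dominance analysis of instantaneous reaction fluxes.

At a fixed state the ODE of a focal species is a sum of signed rate terms:
irreversible reactions contribute a single mass-action monomial M, reversible
reactions a net term dM = M_forward + M_reverse (signed with respect to the
focal species).  Production terms (value > 0) are compared in log10 space: two
magnitudes are *on par* when ``|log10 m1 - log10 m2| < rho``, and the dominant
set consists of the largest production term plus everything on par with it.
Tracing dominant producers backwards from a target species for ``depth``
iterations yields a dominant subnetwork; canonically labeling the subnetwork
at every point of a simulation grid yields the integer sequence we call a
dynamic fingerprint (the simulation's digital signature).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .network import ParameterVector, ReactionNetwork, Trajectory

__all__ = [
    "DominanceConfig",
    "NetRateTerm",
    "ProductionSet",
    "DominantSubnetwork",
    "SubnetworkRegistry",
    "DynamicFingerprint",
    "net_rate_terms",
    "production_set",
    "sep",
    "on_par",
    "dominant_reactions",
    "trace_dominant_subnetwork",
    "canonical_label",
    "fingerprint",
    "fingerprint_ensemble",
]

SENTINEL_LABEL = 0  # reserved for the empty subnetwork (no positive producers)


@dataclass(frozen=True)
class DominanceConfig:
    """Tunable knobs of the discretization.

    rho is the log10 separation below which two rate magnitudes count as on
    par (1.0 = one order of magnitude); depth is the number of back-trace
    iterations from the target.
    """

    rho: float = 1.0
    depth: int = 5
    direction: Literal["production", "consumption"] = "production"

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.direction not in ("production", "consumption"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class NetRateTerm:
    """One reaction's net signed rate term with respect to a focal species.

    ``source_species`` are the species consumed by the direction that moves
    the focal species in the term's sign (the species to trace back to);
    ``sink_species`` the species produced by that direction.
    """

    reaction_id: str
    value: float
    reversible: bool
    source_species: tuple[str, ...]
    sink_species: tuple[str, ...]


@dataclass(frozen=True)
class ProductionSet:
    focal_species: str
    terms: tuple[NetRateTerm, ...]

    def __post_init__(self) -> None:
        if any(t.value <= 0 for t in self.terms):
            raise ValueError("production set terms must be strictly positive")


def net_rate_terms(net: ReactionNetwork, state: Mapping[str, float] | np.ndarray,
                   params: ParameterVector | Mapping[str, float],
                   focal: str) -> list[NetRateTerm]:
    """Net rate terms of every reaction touching *focal*, signed by production.

    Reversible reactions collapse to a single net term; reactions in which
    the focal species is a pure catalyst contribute nothing.
    """
    if focal not in net.species_index:
        raise KeyError(f"unknown species {focal!r}")
    if isinstance(state, Mapping):
        x = np.zeros(net.n_species)
        for sp, v in state.items():
            x[net.species_index[sp]] = v
    else:
        x = np.asarray(state, dtype=float)
    x = np.clip(x, 0.0, None)
    k = net.param_array(params)
    rates = net.unidirectional_rates(x, k)
    by_col = {}
    for j, (rid, direction, _) in enumerate(net.unidirectional):
        by_col[(rid, direction)] = rates[j]

    terms: list[NetRateTerm] = []
    for rxn in net.reactions:
        s = rxn.net_stoich(focal)
        if s == 0:
            continue
        m_fwd = by_col[(rxn.id, "forward")]
        m_rev = by_col.get((rxn.id, "reverse"), 0.0)
        # signed contribution to d[focal]/dt from this reaction
        value = s * m_fwd - s * m_rev
        producing_forward = (value > 0) == (s > 0)
        if value == 0:
            producing_forward = s > 0
        if producing_forward:
            src, snk = rxn.reactant_stoich, rxn.product_stoich
        else:
            src, snk = rxn.product_stoich, rxn.reactant_stoich
        terms.append(NetRateTerm(
            reaction_id=rxn.id,
            value=float(value),
            reversible=rxn.reversible,
            source_species=tuple(src),
            sink_species=tuple(snk),
        ))
    return terms


def production_set(terms: list[NetRateTerm],
                   focal: str = "") -> ProductionSet:
    """Strictly positive net terms (the producers of the focal species)."""
    return ProductionSet(focal, tuple(t for t in terms if t.value > 0))


def sep(m1: float, m2: float) -> float:
    """Separation of two positive magnitudes in log10 space."""
    if not (m1 > 0 and m2 > 0):
        raise ValueError(f"sep requires positive magnitudes, got {m1}, {m2}")
    return abs(math.log10(m1) - math.log10(m2))


def on_par(m1: float, m2: float, rho: float) -> bool:
    """True when the magnitudes are within rho orders of magnitude."""
    return sep(m1, m2) < rho


def dominant_reactions(pset: ProductionSet, rho: float) -> set[str]:
    """The argmax production term plus every term on par with it."""
    if not pset.terms:
        return set()
    m_d = max(t.value for t in pset.terms)
    return {t.reaction_id for t in pset.terms if on_par(m_d, t.value, rho)}


@dataclass(frozen=True)
class DominantSubnetwork:
    """Species-to-species edges traced from the target at one time point."""

    target: str
    edges: frozenset[tuple[str, str]]
    reaction_ids: frozenset[str] = frozenset()
    label: int | None = None

    def canonical_key(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.edges))


class SubnetworkRegistry:
    """Injective map from canonical edge sets to stable integer labels.

    Label 0 is reserved for the empty subnetwork; new edge sets get the next
    free integer in insertion order.  Shared across an ensemble (and across
    wild-type / perturbed runs) so fingerprints are comparable.
    """

    def __init__(self) -> None:
        self._labels: dict[tuple[tuple[str, str], ...], int] = {(): SENTINEL_LABEL}
        self._subnets: dict[int, DominantSubnetwork] = {
            SENTINEL_LABEL: DominantSubnetwork("", frozenset(), label=SENTINEL_LABEL)
        }

    def label_for(self, sub: DominantSubnetwork) -> int:
        key = sub.canonical_key()
        if key not in self._labels:
            label = len(self._labels)
            self._labels[key] = label
            self._subnets[label] = DominantSubnetwork(
                sub.target, sub.edges, sub.reaction_ids, label)
        return self._labels[key]

    def subnetwork(self, label: int) -> DominantSubnetwork:
        return self._subnets[label]

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, label: int) -> bool:
        return label in self._subnets

    def to_dict(self) -> dict[str, list[list[str]]]:
        return {str(lbl): [list(e) for e in sorted(sub.edges)]
                for lbl, sub in self._subnets.items()}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SubnetworkRegistry":
        data = json.loads(Path(path).read_text())
        reg = cls()
        for lbl_str, edges in sorted(data.items(), key=lambda kv: int(kv[0])):
            lbl = int(lbl_str)
            if lbl == SENTINEL_LABEL:
                continue
            sub = DominantSubnetwork(
                "", frozenset(tuple(e) for e in edges))
            assigned = reg.label_for(sub)
            if assigned != lbl:
                raise ValueError(
                    f"registry file is not insertion-ordered: label {lbl} "
                    f"would be assigned {assigned}")
        return reg


def trace_dominant_subnetwork(net: ReactionNetwork,
                              state: Mapping[str, float] | np.ndarray,
                              params: ParameterVector | Mapping[str, float],
                              target: str,
                              cfg: DominanceConfig) -> DominantSubnetwork:
    """Hierarchical back-trace of dominant fluxes from the target species.

    Each depth iteration expands the whole frontier: for every frontier
    species the dominant producing (or consuming) reactions are found, and
    edges source -> species (production) or species -> sink (consumption)
    are added.  Species already expanded still receive edges but are not
    re-expanded, so cycles (e.g. self-amplification loops) terminate.
    """
    if target not in net.species_index:
        raise KeyError(f"unknown species {target!r}")
    consumption = cfg.direction == "consumption"
    edges: set[tuple[str, str]] = set()
    rxn_ids: set[str] = set()
    expanded: set[str] = set()
    frontier = {target}
    for _ in range(cfg.depth):
        next_frontier: set[str] = set()
        for sp in frontier:
            if sp in expanded:
                continue
            expanded.add(sp)
            terms = net_rate_terms(net, state, params, sp)
            if consumption:
                terms = [
                    NetRateTerm(t.reaction_id, -t.value, t.reversible,
                                t.source_species, t.sink_species)
                    for t in terms
                ]
            pset = production_set(terms, sp)
            dom = dominant_reactions(pset, cfg.rho)
            for t in pset.terms:
                if t.reaction_id not in dom:
                    continue
                rxn_ids.add(t.reaction_id)
                if consumption:
                    # follow the flux forward to the species it produces
                    for partner in (s for s in t.sink_species if s != sp):
                        edges.add((sp, partner))
                        next_frontier.add(partner)
                else:
                    # trace the flux back to the species it consumes
                    for partner in (s for s in t.source_species if s != sp):
                        edges.add((partner, sp))
                        next_frontier.add(partner)
        frontier = next_frontier - expanded
        if not frontier:
            break
    return DominantSubnetwork(target, frozenset(edges), frozenset(rxn_ids))


def canonical_label(sub: DominantSubnetwork,
                    registry: SubnetworkRegistry) -> int:
    """Stable integer label for an edge set (0 = empty subnetwork)."""
    return registry.label_for(sub)


@dataclass
class DynamicFingerprint:
    """Integer label sequence over the simulation grid for one parameter vector."""

    labels: np.ndarray
    parameter_index: int = -1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.labels)


def fingerprint(net: ReactionNetwork, traj: Trajectory,
                params: ParameterVector | Mapping[str, float], target: str,
                cfg: DominanceConfig, registry: SubnetworkRegistry,
                parameter_index: int = -1) -> DynamicFingerprint:
    """Label the dominant subnetwork at every grid point of one simulation."""
    labels = np.empty(len(traj.time_grid), dtype=np.int64)
    for i in range(len(traj.time_grid)):
        sub = trace_dominant_subnetwork(net, traj.state_at(i), params, target, cfg)
        labels[i] = canonical_label(sub, registry)
    return DynamicFingerprint(labels, parameter_index)


def fingerprint_ensemble(net: ReactionNetwork, ensemble, time_grid,
                         target: str, cfg: DominanceConfig,
                         registry: SubnetworkRegistry | None = None,
                         rtol: float = 1e-6, atol: float = 1e-6):
    """Simulate and fingerprint every ensemble member on a shared grid.

    Returns (fingerprints, registry, trajectories).
    """
    from .network import simulate

    if registry is None:
        registry = SubnetworkRegistry()
    fps: list[DynamicFingerprint] = []
    trajs: list[Trajectory] = []
    for i, pv in enumerate(ensemble):
        traj = simulate(net, pv, time_grid, rtol=rtol, atol=atol)
        fps.append(fingerprint(net, traj, pv, target, cfg, registry,
                               parameter_index=i))
        trajs.append(traj)
    return fps, registry, trajs
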
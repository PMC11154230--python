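"""Mass-action reaction networks and their deterministic simulation.

A :class:`ReactionNetwork` holds an ordered list of species and mass-action
reactions.  Each reaction contributes one (irreversible) or two (reversible)
*unidirectional rate monomials* of the form ``k * prod(x_i ** a_i)`` where the
exponents ``a_i`` equal the stoichiometric coefficients of the consuming side.
The network exposes the stoichiometric matrix over those unidirectional
columns, which is everything the dominance analysis needs.

Amounts are in copies per cell; rate constants are per second (first order)
or per second per molecule (second order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesDef",
    "Reaction",
    "ReactionNetwork",
    "ParameterVector",
    "ParameterEnsemble",
    "Trajectory",
    "simulate",
    "apply_knockdown",
]


@dataclass(frozen=True)
class SpeciesDef:
    """A molecular species with its initial abundance (copies per cell)."""

    name: str
    initial_amount: float = 0.0
    role_tag: str | None = None

    def __post_init__(self) -> None:
        if self.initial_amount < 0:
            raise ValueError(
                f"species {self.name!r}: initial_amount must be >= 0, "
                f"got {self.initial_amount}"
            )


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction; rate exponents equal reactant stoichiometries."""

    id: str
    reactant_stoich: Mapping[str, int]
    product_stoich: Mapping[str, int]
    forward_rate_param: str
    reversible: bool = False
    reverse_rate_param: str | None = None

    def __post_init__(self) -> None:
        for side, stoich in (("reactant", self.reactant_stoich),
                             ("product", self.product_stoich)):
            for sp, coeff in stoich.items():
                if not isinstance(coeff, (int, np.integer)) or coeff <= 0:
                    raise ValueError(
                        f"reaction {self.id!r}: {side} stoichiometry of "
                        f"{sp!r} must be a positive integer, got {coeff!r}"
                    )
        if self.reversible and self.reverse_rate_param is None:
            raise ValueError(
                f"reaction {self.id!r}: reversible reaction requires a "
                "reverse_rate_param"
            )
        if not self.reversible and self.reverse_rate_param is not None:
            raise ValueError(
                f"reaction {self.id!r}: reverse_rate_param given for an "
                "irreversible reaction"
            )

    def net_stoich(self, species: str) -> int:
        """Net production of *species* by one forward firing."""
        return self.product_stoich.get(species, 0) - self.reactant_stoich.get(species, 0)


class ReactionNetwork:
    """An ordered, validated collection of species and mass-action reactions.

    Parameters appear in ``parameter_names`` in declaration order (forward
    before reverse, first reaction first).  The unidirectional expansion
    assigns every irreversible reaction one rate column and every reversible
    reaction two (forward then reverse).
    """

    def __init__(self, species: Sequence[SpeciesDef],
                 reactions: Sequence[Reaction],
                 name: str = "network") -> None:
        self.name = name
        self.species = list(species)
        self.reactions = list(reactions)

        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate species names: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise ValueError(f"duplicate reaction ids: {dup}")

        self.species_index = {n: i for i, n in enumerate(names)}
        for rxn in self.reactions:
            for sp in list(rxn.reactant_stoich) + list(rxn.product_stoich):
                if sp not in self.species_index:
                    raise ValueError(
                        f"reaction {rxn.id!r} references undeclared species {sp!r}"
                    )

        self.parameter_names: list[str] = []
        for rxn in self.reactions:
            for p in (rxn.forward_rate_param, rxn.reverse_rate_param):
                if p is not None and p not in self.parameter_names:
                    self.parameter_names.append(p)

        self._build_unidirectional()

    # -- structural tables -------------------------------------------------

    def _build_unidirectional(self) -> None:
        ns = len(self.species)
        cols: list[tuple[str, str, str]] = []   # (reaction_id, direction, param)
        expo: list[np.ndarray] = []             # (ns,) exponents of the monomial
        stoich: list[np.ndarray] = []           # (ns,) net species change
        for rxn in self.reactions:
            a = np.zeros(ns)
            b = np.zeros(ns)
            for sp, c in rxn.reactant_stoich.items():
                a[self.species_index[sp]] = c
            for sp, c in rxn.product_stoich.items():
                b[self.species_index[sp]] = c
            cols.append((rxn.id, "forward", rxn.forward_rate_param))
            expo.append(a)
            stoich.append(b - a)
            if rxn.reversible:
                cols.append((rxn.id, "reverse", rxn.reverse_rate_param))
                expo.append(b)
                stoich.append(a - b)
        self.unidirectional = cols
        self.exponents = np.array(expo)               # (n_uni, ns)
        self.uni_stoich = np.array(stoich).T          # (ns, n_uni)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometric matrix, shape (n_species, n_reactions)."""
        ns = self.n_species
        S = np.zeros((ns, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for sp, c in rxn.reactant_stoich.items():
                S[self.species_index[sp], j] -= c
            for sp, c in rxn.product_stoich.items():
                S[self.species_index[sp], j] += c
        return S

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species])

    def reactions_touching(self, species: str) -> list[Reaction]:
        """Reactions with nonzero *net* stoichiometry for *species*.

        Pure catalysts (same coefficient on both sides) are excluded: they
        contribute no net rate term to the species' ODE.
        """
        if species not in self.species_index:
            raise KeyError(f"unknown species {species!r}")
        return [r for r in self.reactions if r.net_stoich(species) != 0]

    # -- rate evaluation ---------------------------------------------------

    def param_array(self, params: "ParameterVector | Mapping[str, float]") -> np.ndarray:
        values = params.values if isinstance(params, ParameterVector) else params
        missing = [p for _, _, p in self.unidirectional if p not in values]
        if missing:
            raise KeyError(f"missing parameter(s): {sorted(set(missing))}")
        return np.array([values[p] for _, _, p in self.unidirectional])

    def unidirectional_rates(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Monomial rates k_u * prod(x ** a_u) for every unidirectional column."""
        x = np.clip(state, 0.0, None)
        with np.errstate(divide="ignore"):
            # 0**0 == 1 under np.power for floats, which is what we need
            mono = np.prod(np.power(x[None, :], self.exponents), axis=1)
        return k * mono

    def rhs(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        return self.uni_stoich @ self.unidirectional_rates(state, k)

    # -- derived networks --------------------------------------------------

    def with_initial(self, species: str, amount: float) -> "ReactionNetwork":
        """Copy of the network with one species' initial amount replaced."""
        if species not in self.species_index:
            raise KeyError(f"unknown species {species!r}")
        new = [
            SpeciesDef(s.name, amount if s.name == species else s.initial_amount,
                       s.role_tag)
            for s in self.species
        ]
        return ReactionNetwork(new, self.reactions, name=self.name)

    def mirrored(self) -> "ReactionNetwork":
        """Network with every reaction reversed (products <-> reactants)."""
        rev = [
            Reaction(
                id=r.id,
                reactant_stoich=dict(r.product_stoich),
                product_stoich=dict(r.reactant_stoich),
                forward_rate_param=r.forward_rate_param,
                reversible=r.reversible,
                reverse_rate_param=r.reverse_rate_param,
            )
            for r in self.reactions
        ]
        return ReactionNetwork(self.species, rev, name=self.name + "_mirrored")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<ReactionNetwork {self.name!r}: {self.n_species} species, "
                f"{self.n_reactions} reactions, "
                f"{len(self.parameter_names)} parameters>")


@dataclass
class ParameterVector:
    """Positive rate constants for one model parameterization."""

    values: dict[str, float]
    log_posterior: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not v > 0:
                raise ValueError(f"rate parameter {name!r} must be > 0, got {v}")
        if self.weight is not None and not np.isfinite(self.weight):
            raise ValueError("weight must be finite")


@dataclass
class ParameterEnsemble:
    """A weighted collection of parameter vectors.

    Weights resolve in priority order: explicit weights, then log-posteriors
    (softmax with max subtraction for overflow safety), then uniform.
    ``normalized_weights`` always sums to 1.
    """

    vectors: list[ParameterVector]
    normalized_weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.vectors:
            raise ValueError("ensemble must contain at least one parameter vector")
        weights = [v.weight for v in self.vectors]
        logps = [v.log_posterior for v in self.vectors]
        if all(w is not None for w in weights):
            w = np.asarray(weights, dtype=float)
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            if w.sum() <= 0:
                raise ValueError("weights sum to zero")
        elif all(lp is not None for lp in logps):
            lp = np.asarray(logps, dtype=float)
            w = np.exp(lp - lp.max())
        else:
            w = np.ones(len(self.vectors))
        self.normalized_weights = w / w.sum()

    def __len__(self) -> int:
        return len(self.vectors)

    def __iter__(self) -> Iterable[ParameterVector]:
        return iter(self.vectors)

    def parameter_names(self) -> list[str]:
        return list(self.vectors[0].values.keys())

    def to_array(self, parameter_names: Sequence[str] | None = None) -> np.ndarray:
        names = parameter_names or self.parameter_names()
        return np.array([[v.values[p] for p in names] for v in self.vectors])

    @classmethod
    def from_array(cls, values: np.ndarray, parameter_names: Sequence[str],
                   log_posterior: np.ndarray | None = None,
                   weights: np.ndarray | None = None) -> "ParameterEnsemble":
        vectors = []
        for i, row in enumerate(np.atleast_2d(values)):
            vectors.append(ParameterVector(
                values=dict(zip(parameter_names, map(float, row))),
                log_posterior=None if log_posterior is None else float(log_posterior[i]),
                weight=None if weights is None else float(weights[i]),
            ))
        return cls(vectors)


@dataclass
class Trajectory:
    """Simulated species amounts and unidirectional monomial rates on a grid."""

    time_grid: np.ndarray
    species_traj: np.ndarray          # (n_times, n_species)
    unidir_rates: np.ndarray          # (n_times, n_unidirectional)
    species_names: list[str]
    unidirectional: list[tuple[str, str, str]]

    def species(self, name: str) -> np.ndarray:
        return self.species_traj[:, self.species_names.index(name)]

    def reaction_rate(self, reaction_id: str) -> np.ndarray:
        """Net rate of a reaction over time (forward minus reverse)."""
        fwd = rev = None
        for j, (rid, direction, _) in enumerate(self.unidirectional):
            if rid == reaction_id and direction == "forward":
                fwd = self.unidir_rates[:, j]
            elif rid == reaction_id and direction == "reverse":
                rev = self.unidir_rates[:, j]
        if fwd is None:
            raise KeyError(f"unknown reaction {reaction_id!r}")
        return fwd if rev is None else fwd - rev

    def state_at(self, index: int) -> np.ndarray:
        """Species amounts at one grid point, clipped to be nonnegative."""
        return np.clip(self.species_traj[index], 0.0, None)


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the failure time."""

    def __init__(self, message: str, time: float | None = None) -> None:
        super().__init__(message)
        self.time = time


def simulate(net: ReactionNetwork, params: ParameterVector | Mapping[str, float],
             time_grid: np.ndarray, rtol: float = 1e-6,
             atol: float = 1e-6) -> Trajectory:
    """Integrate the mass-action ODEs with LSODA on a fixed output grid.

    The same grid must be shared across an ensemble so that the resulting
    fingerprints are positionally comparable.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or len(time_grid) < 2 or np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be 1-D and strictly increasing")
    k = net.param_array(params)
    y0 = net.initial_state()

    sol = solve_ivp(
        lambda t, y: net.rhs(y, k),
        (time_grid[0], time_grid[-1]),
        y0,
        method="LSODA",
        t_eval=time_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else float(time_grid[0])
        raise SimulationError(
            f"ODE integration failed at t={t_fail:g}: {sol.message}", time=t_fail)

    species_traj = sol.y.T
    rates = np.array([net.unidirectional_rates(y, k) for y in species_traj])
    return Trajectory(
        time_grid=time_grid,
        species_traj=species_traj,
        unidir_rates=rates,
        species_names=[s.name for s in net.species],
        unidirectional=list(net.unidirectional),
    )


def apply_knockdown(net: ReactionNetwork, species: str,
                    fraction: float) -> ReactionNetwork:
    """Scale a species' initial abundance by (1 - fraction), e.g. 0.5 = 50% KD."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"knockdown fraction must be in [0, 1], got {fraction}")
    if species not in net.species_index:
        raise KeyError(f"unknown species {species!r}")
    current = net.species[net.species_index[species]].initial_amount
    out = net.with_initial(species, current * (1.0 - fraction))
    out.name = net.name
    return out
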
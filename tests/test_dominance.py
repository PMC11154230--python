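"""Tropical dominance: separation, on-par sets, subnetwork tracing, fingerprints."""

import math

import numpy as np
import pytest

import fluxmodes as fm
from fluxmodes.dominance import (SENTINEL_LABEL, NetRateTerm, ProductionSet,
                                 production_set)

from conftest import random_network

CHAIN = (
    "species A 100\nspecies B 0\nspecies C 0\n"
    "reaction rab: A -> B @ kab\nreaction rbc: B -> C @ kbc\n"
)


def _pset(values: dict[str, float]) -> ProductionSet:
    terms = tuple(NetRateTerm(rid, v, False, (), ()) for rid, v in values.items())
    return ProductionSet("x", terms)


class TestSeparation:
    def test_identical_magnitudes_have_zero_separation(self):
        assert fm.sep(10.0, 10.0) == 0.0

    def test_two_orders_of_magnitude(self):
        assert fm.sep(1000.0, 10.0) == pytest.approx(2.0)

    def test_factor_two_is_log10_two(self):
        assert fm.sep(10.0, 5.0) == pytest.approx(math.log10(2.0))

    def test_symmetry(self):
        assert fm.sep(3.7, 0.02) == fm.sep(0.02, 3.7)

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_magnitudes_rejected(self, bad):
        with pytest.raises(ValueError):
            fm.sep(*bad)


class TestOnPar:
    def test_equal_magnitudes_always_on_par(self):
        assert fm.on_par(4.2, 4.2, 1e-9)

    def test_factor_two_within_one_order(self):
        assert fm.on_par(10.0, 5.0, 1.0)

    def test_three_orders_not_on_par_at_rho_one(self):
        assert not fm.on_par(1000.0, 1.0, 1.0)

    def test_tie_at_exactly_rho_is_dominant(self):
        # strict inequality: sep == rho means NOT on par
        assert not fm.on_par(100.0, 10.0, 1.0)


class TestProductionSet:
    def test_keeps_only_strictly_positive_terms(self):
        terms = [NetRateTerm("a", 10.0, False, (), ()),
                 NetRateTerm("b", 0.5, False, (), ()),
                 NetRateTerm("c", -3.0, False, (), ()),
                 NetRateTerm("d", 0.0, False, (), ())]
        pset = production_set(terms, "x")
        assert {t.reaction_id for t in pset.terms} == {"a", "b"}

    def test_all_negative_gives_empty_set(self):
        pset = production_set([NetRateTerm("a", -1.0, False, (), ())], "x")
        assert pset.terms == ()


class TestDominantReactions:
    def test_example_far_apart(self):
        assert fm.dominant_reactions(_pset({"rA": 10.0, "rB": 0.9}), 1.0) == {"rA"}

    def test_example_on_par(self):
        assert fm.dominant_reactions(_pset({"rA": 10.0, "rB": 2.0}), 1.0) == \
            {"rA", "rB"}

    def test_empty_production_set(self):
        assert fm.dominant_reactions(_pset({}), 1.0) == set()

    def test_argmax_always_member(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            vals = {f"r{i}": float(10 ** rng.uniform(-6, 6))
                    for i in range(rng.integers(1, 6))}
            dom = fm.dominant_reactions(_pset(vals), float(rng.uniform(0.1, 3)))
            assert max(vals, key=vals.get) in dom

    def test_monotone_in_rho(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            vals = {f"r{i}": float(10 ** rng.uniform(-6, 6))
                    for i in range(rng.integers(1, 6))}
            pset = _pset(vals)
            d1 = fm.dominant_reactions(pset, 0.5)
            d2 = fm.dominant_reactions(pset, 1.0)
            d3 = fm.dominant_reactions(pset, 2.0)
            assert d1 <= d2 <= d3


class TestNetRateTerms:
    def test_reversible_net_term_is_forward_plus_reverse(self):
        net = fm.build_network(
            "species A 5\nspecies B 2\nreaction r: A <-> B @ kf, kr\n")
        # w.r.t. B: +kf*A - kr*B = 5*1 - 2*1 = 3
        terms = fm.net_rate_terms(net, {"A": 5.0, "B": 2.0},
                                  {"kf": 1.0, "kr": 1.0}, "B")
        assert len(terms) == 1
        assert terms[0].value == pytest.approx(3.0)

    def test_irreversible_consuming_term_is_negative(self):
        net = fm.build_network(
            "species A 5\nspecies B 0\nreaction r: A -> B @ kf\n")
        terms = fm.net_rate_terms(net, {"A": 5.0, "B": 0.0}, {"kf": 2.0}, "A")
        assert terms[0].value == pytest.approx(-10.0)

    def test_detailed_balance_gives_zero_net_term(self):
        net = fm.build_network(
            "species A 3\nspecies B 3\nreaction r: A <-> B @ kf, kr\n")
        terms = fm.net_rate_terms(net, {"A": 3.0, "B": 3.0},
                                  {"kf": 1.0, "kr": 1.0}, "B")
        assert terms[0].value == 0.0

    def test_pure_catalyst_contributes_no_term(self):
        net = fm.build_network(
            "species E 1\nspecies S 1\nspecies P 0\n"
            "reaction r: E + S -> E + P @ k\n")
        assert fm.net_rate_terms(net, {"E": 1, "S": 1, "P": 0}, {"k": 1.0},
                                 "E") == []

    def test_unknown_focal_species_rejected(self, toy):
        with pytest.raises(KeyError):
            fm.net_rate_terms(toy, toy.initial_state(),
                              fm.toy_nominal_params(), "nope")


@pytest.mark.parametrize("rho", [0.5, 1.0, 2.0])
@pytest.mark.parametrize("trial", range(40))
def test_dominant_reactions_match_brute_force_scan(trial, rho):
    """Oracle equivalence on random small networks and random states.

    The oracle evaluates every unidirectional monomial independently (plain
    Python arithmetic from the reaction definitions), combines them per
    reaction with the correct sign for the focal species, and applies the
    log10 par test pairwise against the largest producer.
    """
    rng = np.random.default_rng(5000 + trial)
    net, params, state = random_network(rng)
    focal = net.species[rng.integers(net.n_species)].name

    def monomial(stoich):
        m = 1.0
        for sp, c in stoich.items():
            m *= state[net.species_index[sp]] ** c
        return m

    oracle_terms = {}
    for rxn in net.reactions:
        s = rxn.net_stoich(focal)
        if s == 0:
            continue
        value = s * params.values[rxn.forward_rate_param] \
            * monomial(rxn.reactant_stoich)
        if rxn.reversible:
            value -= s * params.values[rxn.reverse_rate_param] \
                * monomial(rxn.product_stoich)
        oracle_terms[rxn.id] = value
    producers = {rid: v for rid, v in oracle_terms.items() if v > 0}
    if producers:
        m_d = max(producers.values())
        expected = {rid for rid, v in producers.items()
                    if abs(math.log10(m_d) - math.log10(v)) < rho}
    else:
        expected = set()

    pset = production_set(fm.net_rate_terms(net, state, params, focal), focal)
    assert fm.dominant_reactions(pset, rho) == expected


class TestTrace:
    def test_linear_cascade_depth_two(self):
        net = fm.build_network(CHAIN)
        params = {"kab": 1.0, "kbc": 1.0}
        state = {"A": 10.0, "B": 5.0, "C": 0.0}
        sub = fm.trace_dominant_subnetwork(
            net, state, params, "C", fm.DominanceConfig(rho=1.0, depth=2))
        assert sub.edges == frozenset({("B", "C"), ("A", "B")})

    def test_depth_one_cuts_the_trace(self):
        net = fm.build_network(CHAIN)
        sub = fm.trace_dominant_subnetwork(
            net, {"A": 10.0, "B": 5.0, "C": 0.0}, {"kab": 1.0, "kbc": 1.0},
            "C", fm.DominanceConfig(rho=1.0, depth=1))
        assert sub.edges == frozenset({("B", "C")})

    def test_strong_branch_excludes_weak_branch(self, toy, toy_grid):
        pv = fm.toy_nominal_params(k1=0.1)   # 100x the branch-2 feed
        traj = fm.simulate(toy, pv, toy_grid)
        sub = fm.trace_dominant_subnetwork(
            toy, traj.state_at(len(toy_grid) // 2), pv, "P",
            fm.DominanceConfig(rho=1.0, depth=2))
        assert ("B1", "P") in sub.edges
        assert ("B2", "P") not in sub.edges

    def test_consumption_direction_follows_flux_forward(self):
        net = fm.build_network(CHAIN)
        sub = fm.trace_dominant_subnetwork(
            net, {"A": 10.0, "B": 5.0, "C": 0.0}, {"kab": 1.0, "kbc": 1.0},
            "A", fm.DominanceConfig(rho=1.0, depth=2, direction="consumption"))
        assert sub.edges == frozenset({("A", "B"), ("B", "C")})

    def test_self_amplification_cycle_terminates(self, aearm):
        # mid-execution state: the MOMP positive-feedback loop is active
        pv = fm.aearm_nominal_params()
        traj = fm.simulate(aearm, pv, np.linspace(0, 600, 50))
        sub = fm.trace_dominant_subnetwork(
            aearm, traj.state_at(25), pv, "cPARP",
            fm.DominanceConfig(rho=1.0, depth=10))
        assert len(sub.edges) > 0   # terminated and produced a subnetwork


class TestRegistry:
    def test_same_edges_any_insertion_order_same_label(self):
        reg = fm.SubnetworkRegistry()
        a = fm.DominantSubnetwork("P", frozenset({("A", "B"), ("B", "P")}))
        b = fm.DominantSubnetwork("P", frozenset({("B", "P"), ("A", "B")}))
        assert fm.canonical_label(a, reg) == fm.canonical_label(b, reg)

    def test_distinct_edge_sets_distinct_labels(self):
        reg = fm.SubnetworkRegistry()
        a = fm.DominantSubnetwork("P", frozenset({("A", "P")}))
        b = fm.DominantSubnetwork("P", frozenset({("B", "P")}))
        assert fm.canonical_label(a, reg) != fm.canonical_label(b, reg)

    def test_empty_edge_set_gets_sentinel_zero(self):
        reg = fm.SubnetworkRegistry()
        empty = fm.DominantSubnetwork("P", frozenset())
        assert fm.canonical_label(empty, reg) == SENTINEL_LABEL == 0

    def test_save_load_round_trip(self, tmp_path):
        reg = fm.SubnetworkRegistry()
        for edges in [{("A", "B")}, {("A", "B"), ("B", "C")}, {("C", "D")}]:
            fm.canonical_label(fm.DominantSubnetwork("x", frozenset(edges)), reg)
        reg.save(tmp_path / "reg.json")
        again = fm.SubnetworkRegistry.load(tmp_path / "reg.json")
        assert again.to_dict() == reg.to_dict()


class TestFingerprint:
    def test_constant_dominance_gives_constant_labels(self, toy, toy_grid):
        # branch-1 feed 100x branch-2; the pool species A depletes slowly, so
        # the dominant branch never switches over the horizon
        pv = fm.toy_nominal_params(k2=1e-5)
        traj = fm.simulate(toy, pv, toy_grid)
        reg = fm.SubnetworkRegistry()
        fp = fm.fingerprint(toy, traj, pv, "P", fm.DominanceConfig(), reg)
        # after the initial empty state the dominant branch never switches
        assert len(np.unique(fp.labels[1:])) == 1

    def test_zero_rate_network_is_all_sentinel(self, toy, toy_grid):
        pv = {p: 1e-300 for p in toy.parameter_names}
        traj = fm.simulate(toy, pv, toy_grid)
        reg = fm.SubnetworkRegistry()
        fp = fm.fingerprint(toy, traj, pv, "P", fm.DominanceConfig(), reg)
        assert np.all(fp.labels == SENTINEL_LABEL)

    def test_single_switch_at_numerically_located_crossing(self, toy):
        """Branch-2 starts loaded but unreplenished; branch-1 takes over.

        The label sequence must change exactly once, within one grid step of
        the monomial crossing found from the simulated state.
        """
        net = toy.with_initial("B2", 1e4)
        pv = fm.ParameterVector({"k1": 1e-3, "k2": 1e-9, "k3": 1e-3, "k4": 1e-2})
        grid = np.linspace(0, 1000, 100)
        traj = fm.simulate(net, pv, grid)
        m1 = 1e-3 * np.clip(traj.species("B1"), 0, None)
        m2 = 1e-2 * np.clip(traj.species("B2"), 0, None)
        crossing = np.flatnonzero(np.diff(np.sign(m1 - m2)) > 0)
        assert len(crossing) == 1
        reg = fm.SubnetworkRegistry()
        fp = fm.fingerprint(net, traj, pv, "P",
                            fm.DominanceConfig(rho=0.001, depth=1), reg)
        changes = np.flatnonzero(np.diff(fp.labels) != 0)
        assert len(changes) == 1
        assert abs(changes[0] - crossing[0]) <= 1

    def test_registry_stability_bit_exact_rerun(self, toy, toy_grid,
                                               planted_three_regimes):
        ensemble, _ = planted_three_regimes
        sub = fm.ParameterEnsemble(ensemble.vectors[:10])
        fps1, reg, _ = fm.fingerprint_ensemble(
            toy, sub, toy_grid, "P", fm.DominanceConfig())
        fps2, _, _ = fm.fingerprint_ensemble(
            toy, sub, toy_grid, "P", fm.DominanceConfig(), registry=reg)
        for a, b in zip(fps1, fps2):
            assert np.array_equal(a.labels, b.labels)
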
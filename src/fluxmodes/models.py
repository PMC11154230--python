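"""Bundled model fixtures.

``make_aearm`` builds the abridged extrinsic apoptosis reaction model: a
coarse-grained TRAIL-to-PARP cascade of 22 molecular species and 28 kinetic
parameters in which every catalytic step is an explicit
enzyme + substrate <-> complex -> enzyme + product motif.  ``make_toy_bifurcation``
is a four-species fixture whose target species is fed by two competing
branches, used throughout the tests to plant known dominance regimes.
"""

from __future__ import annotations

from .network import ParameterVector, Reaction, ReactionNetwork, SpeciesDef

__all__ = [
    "make_aearm",
    "aearm_nominal_params",
    "make_toy_bifurcation",
    "toy_nominal_params",
    "NOMINAL_KF",
    "NOMINAL_KR",
    "NOMINAL_KCAT",
]

# Biologically plausible prior centers for binding / unbinding / catalysis
# rates (s^-1 molecule^-1, s^-1, s^-1).
NOMINAL_KF = 1e-6
NOMINAL_KR = 1e-3
NOMINAL_KCAT = 1.0


def _catalysis(rxns: list[Reaction], prefix: str, enzyme: str, substrate: str,
               complex_: str, product: str) -> None:
    """Append an enzyme-substrate-complex catalysis motif (kf, kr, kcat)."""
    products = {enzyme: 1, product: 1}
    rxns.append(Reaction(
        id=f"{prefix}_bind",
        reactant_stoich={enzyme: 1, substrate: 1},
        product_stoich={complex_: 1},
        forward_rate_param=f"kf_{prefix}",
        reversible=True,
        reverse_rate_param=f"kr_{prefix}",
    ))
    rxns.append(Reaction(
        id=f"{prefix}_cat",
        reactant_stoich={complex_: 1},
        product_stoich=products,
        forward_rate_param=f"kc_{prefix}",
    ))


def make_aearm() -> ReactionNetwork:
    """Abridged extrinsic apoptosis reaction model (22 species, 28 parameters).

    Signal chain: TRAIL ligand (L) binds receptor (R) to form the
    death-inducing signaling complex (DISC); DISC activates initiator
    caspase (iC -> iCa); active effector caspase feeds back to activate more
    iC; iCa truncates Bid (tBid); tBid activates MOMP; active MOMP (MOMPa)
    self-amplifies via a positive feedback loop (snap-action dynamics) and is
    reversibly deactivated; effector caspase (eC) is activated both by iCa
    (type 1) and MOMPa (type 2); eCa cleaves PARP into cPARP, the apoptosis
    completion marker.  The full reaction list is in docs/aearm_model.md.
    """
    sp = [
        SpeciesDef("L", 3000.0, "ligand"),
        SpeciesDef("R", 200.0, "receptor"),
        SpeciesDef("L_R", 0.0, "complex"),
        SpeciesDef("DISC", 0.0, "complex"),
        SpeciesDef("iC", 2e4, "protein"),
        SpeciesDef("DISC_iC", 0.0, "complex"),
        SpeciesDef("iCa", 0.0, "cleaved"),
        SpeciesDef("eCa_iC", 0.0, "complex"),
        SpeciesDef("Bid", 4e4, "protein"),
        SpeciesDef("iCa_Bid", 0.0, "complex"),
        SpeciesDef("tBid", 0.0, "cleaved"),
        SpeciesDef("MOMP", 1e5, "protein"),
        SpeciesDef("tBid_MOMP", 0.0, "complex"),
        SpeciesDef("MOMPa", 0.0, "cleaved"),
        SpeciesDef("MOMPa_MOMP", 0.0, "complex"),
        SpeciesDef("eC", 1e4, "protein"),
        SpeciesDef("iCa_eC", 0.0, "complex"),
        SpeciesDef("eCa", 0.0, "cleaved"),
        SpeciesDef("MOMPa_eC", 0.0, "complex"),
        SpeciesDef("PARP", 1e6, "protein"),
        SpeciesDef("eCa_PARP", 0.0, "complex"),
        SpeciesDef("cPARP", 0.0, "cleaved"),
    ]
    rxns: list[Reaction] = []
    # TRAIL binds receptor; the bound complex matures into the DISC.
    rxns.append(Reaction("trail_bind", {"L": 1, "R": 1}, {"L_R": 1},
                         "kf_trail", reversible=True, reverse_rate_param="kr_trail"))
    rxns.append(Reaction("disc_form", {"L_R": 1}, {"DISC": 1}, "kc_disc"))
    # DISC activates initiator caspase.
    _catalysis(rxns, "disc_ic", "DISC", "iC", "DISC_iC", "iCa")
    # Effector-caspase feedback activation of initiator caspase.
    _catalysis(rxns, "ec_ic_fb", "eCa", "iC", "eCa_iC", "iCa")
    # Initiator caspase truncates Bid.
    _catalysis(rxns, "ic_bid", "iCa", "Bid", "iCa_Bid", "tBid")
    # tBid-dependent MOMP activation.
    _catalysis(rxns, "bid_momp", "tBid", "MOMP", "tBid_MOMP", "MOMPa")
    # MOMP self-amplification (positive feedback): MOMPa + MOMP -> 2 MOMPa.
    rxns.append(Reaction("momp_fb_bind", {"MOMPa": 1, "MOMP": 1}, {"MOMPa_MOMP": 1},
                         "kf_momp_fb", reversible=True,
                         reverse_rate_param="kr_momp_fb"))
    rxns.append(Reaction("momp_fb_cat", {"MOMPa_MOMP": 1}, {"MOMPa": 2},
                         "kc_momp_fb"))
    # MOMPa deactivation closes the snap-action pulse.
    rxns.append(Reaction("momp_deact", {"MOMPa": 1}, {"MOMP": 1}, "k_momp_deact"))
    # Type-1 (initiator-caspase) effector caspase activation.
    _catalysis(rxns, "ic_ec", "iCa", "eC", "iCa_eC", "eCa")
    # Type-2 (MOMP-dependent) effector caspase activation.
    _catalysis(rxns, "momp_ec", "MOMPa", "eC", "MOMPa_eC", "eCa")
    # PARP cleavage, the completion marker of apoptosis execution.
    _catalysis(rxns, "ec_parp", "eCa", "PARP", "eCa_PARP", "cPARP")
    return ReactionNetwork(sp, rxns, name="aEARM")


def aearm_nominal_params() -> ParameterVector:
    """Prior-center rates: 1e-6 binding, 1e-3 unbinding, 1 catalysis."""
    net = make_aearm()
    values: dict[str, float] = {}
    for p in net.parameter_names:
        if p.startswith("kf_"):
            values[p] = NOMINAL_KF
        elif p.startswith("kr_") or p == "k_momp_deact":
            values[p] = NOMINAL_KR
        else:
            values[p] = NOMINAL_KCAT
    return ParameterVector(values)


def make_toy_bifurcation() -> ReactionNetwork:
    """Two-branch fixture: P is produced via A->B1->P and A->B2->P.

    The feed rates k1 (into B1) and k2 (into B2) control which branch carries
    the dominant production flux into the target P; with k1 == k2 and the
    default symmetric initials the two branch monomials are equal at all
    times.
    """
    sp = [
        SpeciesDef("A", 1000.0),
        SpeciesDef("B1", 0.0),
        SpeciesDef("B2", 0.0),
        SpeciesDef("P", 0.0),
    ]
    rxns = [
        Reaction("feed1", {"A": 1}, {"B1": 1}, "k1"),
        Reaction("feed2", {"A": 1}, {"B2": 1}, "k2"),
        Reaction("prod1", {"B1": 1}, {"P": 1}, "k3"),
        Reaction("prod2", {"B2": 1}, {"P": 1}, "k4"),
    ]
    return ReactionNetwork(sp, rxns, name="toy_bifurcation")


def toy_nominal_params(**overrides: float) -> ParameterVector:
    """Symmetric rates (1e-3 each) with keyword overrides, e.g. k1=0.1."""
    values = {"k1": 1e-3, "k2": 1e-3, "k3": 1e-3, "k4": 1e-3}
    values.update(overrides)
    return ParameterVector(values)
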
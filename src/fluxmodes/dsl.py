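"""Plain-text model description language: reader, writer, round-trip.

Schema (one statement per line, ``#`` starts a comment)::

    model <name>                      # optional, first non-comment line
    species <name> <initial> [tag]    # tag is a free label (ligand/enzyme/...)
    reaction <id>: <lhs> -> <rhs> @ <kf>
    reaction <id>: <lhs> <-> <rhs> @ <kf>, <kr>

where ``<lhs>``/``<rhs>`` are ``+``-separated terms like ``A``, ``2 B`` or
``2*B``.  All species referenced by reactions must be declared.
"""

from __future__ import annotations

import re
from pathlib import Path

from .network import Reaction, ReactionNetwork, SpeciesDef

__all__ = ["build_network", "parse_model", "write_model"]

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s*\*?\s*)?([A-Za-z_][A-Za-z0-9_:*]*)\s*$")


class ModelSyntaxError(ValueError):
    """A line in the model description did not parse."""


def _parse_side(side: str, line_no: int) -> dict[str, int]:
    side = side.strip()
    stoich: dict[str, int] = {}
    if side in ("", "0", "None"):   # empty side: synthesis / degradation
        return stoich
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ModelSyntaxError(f"line {line_no}: cannot parse term {term!r}")
        coeff = int(m.group(1) or 1)
        if coeff <= 0:
            raise ModelSyntaxError(f"line {line_no}: non-positive stoichiometry")
        name = m.group(2)
        stoich[name] = stoich.get(name, 0) + coeff
    return stoich


def parse_model(text: str) -> ReactionNetwork:
    """Parse a model description string into a validated ReactionNetwork."""
    species: list[SpeciesDef] = []
    reactions: list[Reaction] = []
    name = "model"
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, _, rest = line.partition(" ")
        if head == "model":
            name = rest.strip()
        elif head == "species":
            parts = rest.split()
            if len(parts) < 2:
                raise ModelSyntaxError(
                    f"line {line_no}: species needs a name and an initial amount")
            tag = parts[2] if len(parts) > 2 else None
            species.append(SpeciesDef(parts[0], float(parts[1]), tag))
        elif head == "reaction":
            m = re.match(
                r"^\s*([A-Za-z0-9_]+)\s*:\s*(.*?)\s*(<->|->)\s*(.*?)\s*@\s*(.*)$",
                rest)
            if not m:
                raise ModelSyntaxError(f"line {line_no}: cannot parse reaction")
            rid, lhs, arrow, rhs, rates = m.groups()
            rate_names = [r.strip() for r in rates.split(",") if r.strip()]
            reversible = arrow == "<->"
            if reversible and len(rate_names) != 2:
                raise ModelSyntaxError(
                    f"line {line_no}: reversible reaction {rid!r} needs "
                    "exactly two rate parameters (kf, kr)")
            if not reversible and len(rate_names) != 1:
                raise ModelSyntaxError(
                    f"line {line_no}: irreversible reaction {rid!r} needs "
                    "exactly one rate parameter")
            reactions.append(Reaction(
                id=rid,
                reactant_stoich=_parse_side(lhs, line_no),
                product_stoich=_parse_side(rhs, line_no),
                forward_rate_param=rate_names[0],
                reversible=reversible,
                reverse_rate_param=rate_names[1] if reversible else None,
            ))
        else:
            raise ModelSyntaxError(
                f"line {line_no}: unknown statement {head!r}")
    return ReactionNetwork(species, reactions, name=name)


def build_network(spec: str | Path) -> ReactionNetwork:
    """Build a network from a DSL string or a path to a DSL file."""
    if isinstance(spec, Path) or (
            isinstance(spec, str) and "\n" not in spec and Path(spec).is_file()):
        text = Path(spec).read_text()
    else:
        text = str(spec)
    return parse_model(text)


def _format_side(stoich: dict[str, int]) -> str:
    if not stoich:
        return "0"
    return " + ".join(f"{c} {sp}" if c != 1 else sp for sp, c in stoich.items())


def write_model(net: ReactionNetwork, path: str | Path | None = None) -> str:
    """Serialize a network back to the DSL; round-trips with parse_model."""
    lines = [f"model {net.name}"]
    for s in net.species:
        tag = f" {s.role_tag}" if s.role_tag else ""
        lines.append(f"species {s.name} {s.initial_amount!r}{tag}")
    for r in net.reactions:
        arrow = "<->" if r.reversible else "->"
        rates = r.forward_rate_param
        if r.reversible:
            rates += f", {r.reverse_rate_param}"
        lines.append(
            f"reaction {r.id}: {_format_side(dict(r.reactant_stoich))} {arrow} "
            f"{_format_side(dict(r.product_stoich))} @ {rates}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
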
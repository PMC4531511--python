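"""Reaction-contingency network definitions: types, parser, writer.

A network is written one *elemental reaction* per line, optionally followed
by a ``;``-separated list of *contingencies*::

    B_ppi_C
    A_ppi_D
    A_ppi_B; K+ B--C; K- A--D
    # comments start with '#'

Reaction identifiers have the form ``X_code_Y`` where ``code`` is a
registered reaction type (``ppi``, ``P+``, ...).  Components and elemental
states are derived automatically from the reaction identifiers: ``A_ppi_B``
declares components ``A`` and ``B`` and the interaction state ``A--B``;
``K_P+_X`` declares the modification state ``X-{P}``.  Site or residue
labels (``Hog1_[(T174)]``) are carried opaquely inside state identifiers.

Contingency signs: ``!`` absolute requirement, ``x`` absolute inhibition,
``K+``/``K-`` positive/negative quantitative modifiers, ``0`` no effect,
``?`` unknown (``0`` and ``?`` are retained but never influence generated
rules).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "Component",
    "ElementalState",
    "ReactionType",
    "ElementalReaction",
    "Contingency",
    "RxnconNetwork",
    "ReactionTypeRegistry",
    "DEFAULT_REGISTRY",
    "RxnconParseError",
    "RxnconValidationError",
    "parse_network",
    "serialize_network",
    "quantitative_modifiers",
]

SIGNS = ("!", "x", "K+", "K-", "0", "?")
QUANTITATIVE_SIGNS = ("K+", "K-")
ABSOLUTE_SIGNS = ("!", "x")


class RxnconParseError(ValueError):
    """Malformed network definition text."""


class RxnconValidationError(ValueError):
    """Structurally invalid network (dangling references, duplicates)."""


@dataclass(frozen=True)
class Component:
    """A molecule (protein, metabolite, abstract input) of the system."""

    name: str


@dataclass(frozen=True)
class ElementalState:
    """A single molecular property: one bond, one modification, one location.

    ``members`` lists the components carrying the property together with
    their (opaque) site labels; interaction states have exactly two members,
    modification and localization states exactly one.
    """

    id: str
    kind: str  # interaction | modification | localization
    members: tuple[tuple[str, str | None], ...]


@dataclass(frozen=True)
class ReactionType:
    """Properties a reaction code confers: reversibility and what it does.

    ``effect`` is one of ``produce_state``, ``consume_state``,
    ``produce_presence`` (synthesis) or ``consume_presence`` (degradation);
    ``state_kind``/``state_tag`` describe the elemental state written or
    erased (tag ``{P}`` gives ``X-{P}``, interaction states use ``X--Y``).
    """

    code: str
    reversible: bool = False
    effect: str = "produce_state"
    state_kind: str = "modification"
    state_tag: str | None = None


class ReactionTypeRegistry:
    """Extensible table of reaction codes.

    The built-in table covers the common codes; unknown codes can be
    registered with declared properties before parsing.
    """

    def __init__(self, types: dict[str, ReactionType] | None = None):
        self._types = dict(_BUILTIN_TYPES if types is None else types)

    def register(self, rtype: ReactionType) -> None:
        self._types[rtype.code] = rtype

    def get(self, code: str) -> ReactionType:
        return self._types[code]

    def __contains__(self, code: str) -> bool:
        return code in self._types

    def codes(self) -> list[str]:
        # longest first so e.g. a hypothetical "Pp" never shadows "P" codes
        return sorted(self._types, key=len, reverse=True)


_BUILTIN_TYPES = {
    "ppi": ReactionType("ppi", reversible=True, effect="produce_state", state_kind="interaction"),
    "i": ReactionType("i", reversible=True, effect="produce_state", state_kind="interaction"),
    "P+": ReactionType("P+", effect="produce_state", state_kind="modification", state_tag="{P}"),
    "P-": ReactionType("P-", effect="consume_state", state_kind="modification", state_tag="{P}"),
    "Ub+": ReactionType("Ub+", effect="produce_state", state_kind="modification", state_tag="{Ub}"),
    "Ub-": ReactionType("Ub-", effect="consume_state", state_kind="modification", state_tag="{Ub}"),
    "TRSC": ReactionType("TRSC", effect="produce_presence"),
    "TRSL": ReactionType("TRSL", effect="produce_presence"),
    "DEG": ReactionType("DEG", effect="consume_presence"),
    "NIMP": ReactionType("NIMP", effect="produce_state", state_kind="localization", state_tag="{nucleus}"),
    "NEXP": ReactionType("NEXP", effect="consume_state", state_kind="localization", state_tag="{nucleus}"),
}

DEFAULT_REGISTRY = ReactionTypeRegistry()

_COMPONENT_TOKEN = re.compile(r"^([A-Za-z][A-Za-z0-9]*)(_\[[^\]]*\])?$")


@dataclass(frozen=True)
class ElementalReaction:
    """A decontextualized state transition, e.g. ``A_ppi_B``."""

    id: str
    rtype: ReactionType
    substrates: tuple[str, ...]  # component names
    produced: tuple[str, ...] = ()  # elemental state ids
    consumed: tuple[str, ...] = ()
    synthesizes: tuple[str, ...] = ()  # component names (presence produced)
    degrades: tuple[str, ...] = ()


@dataclass(frozen=True)
class Contingency:
    """Contextual constraint of an elemental state on an elemental reaction."""

    target: str  # reaction id
    effector: str  # state id
    sign: str

    def __post_init__(self):
        if self.sign not in SIGNS:
            raise RxnconValidationError(f"unknown contingency sign {self.sign!r}")


@dataclass
class RxnconNetwork:
    """Parsed reaction-contingency knowledge representation."""

    components: dict[str, Component] = field(default_factory=dict)
    states: dict[str, ElementalState] = field(default_factory=dict)
    reactions: dict[str, ElementalReaction] = field(default_factory=dict)
    contingencies: list[Contingency] = field(default_factory=list)

    def contingencies_for(self, reaction_id: str) -> list[Contingency]:
        if reaction_id not in self.reactions:
            raise KeyError(f"unknown reaction {reaction_id!r}")
        return [c for c in self.contingencies if c.target == reaction_id]

    def producers_of(self, state_id: str) -> list[ElementalReaction]:
        return [r for r in self.reactions.values() if state_id in r.produced]

    def consumers_of(self, state_id: str) -> list[ElementalReaction]:
        return [r for r in self.reactions.values() if state_id in r.consumed]

    def synthesizers_of(self, component: str) -> list[ElementalReaction]:
        return [r for r in self.reactions.values() if component in r.synthesizes]

    def degraders_of(self, component: str) -> list[ElementalReaction]:
        return [r for r in self.reactions.values() if component in r.degrades]

    def validate(self) -> None:
        """Check referential integrity; warn on unproducible states."""
        for c in self.contingencies:
            if c.target not in self.reactions:
                raise RxnconValidationError(
                    f"contingency targets undeclared reaction {c.target!r}"
                )
            if c.effector not in self.states:
                raise RxnconValidationError(
                    f"contingency on {c.target!r} references undeclared state {c.effector!r}"
                )
        pairs = [(c.target, c.effector) for c in self.contingencies]
        if len(pairs) != len(set(pairs)):
            dup = next(p for p in pairs if pairs.count(p) > 1)
            raise RxnconValidationError(
                f"duplicate contingency for reaction {dup[0]!r} and state {dup[1]!r}"
            )
        for r in self.reactions.values():
            for sid in r.produced + r.consumed:
                if sid not in self.states:
                    raise RxnconValidationError(
                        f"reaction {r.id!r} references undeclared state {sid!r}"
                    )
        for sid in self.states:
            if not self.producers_of(sid):
                warnings.warn(
                    f"state {sid!r} is never produced by any reaction",
                    stacklevel=2,
                )


def _parse_component_token(token: str, line_no: int) -> tuple[str, str | None]:
    m = _COMPONENT_TOKEN.match(token)
    if not m:
        raise RxnconParseError(f"line {line_no}: malformed component token {token!r}")
    return m.group(1), m.group(2)


def _split_reaction_id(rid: str, registry: ReactionTypeRegistry, line_no: int):
    for code in registry.codes():
        sep = f"_{code}_"
        if sep in rid:
            lhs, rhs = rid.split(sep, 1)
            if lhs and rhs:
                return lhs, code, rhs
    raise RxnconParseError(
        f"line {line_no}: malformed reaction id {rid!r} (no registered reaction type found)"
    )


def _build_reaction(
    rid: str, registry: ReactionTypeRegistry, line_no: int
) -> tuple[ElementalReaction, list[tuple[str, str | None]], list[ElementalState]]:
    lhs_tok, code, rhs_tok = _split_reaction_id(rid, registry, line_no)
    rtype = registry.get(code)
    lhs_name, _ = _parse_component_token(lhs_tok, line_no)
    rhs_name, rhs_site = _parse_component_token(rhs_tok, line_no)

    produced: tuple[str, ...] = ()
    consumed: tuple[str, ...] = ()
    synthesizes: tuple[str, ...] = ()
    degrades: tuple[str, ...] = ()
    states: list[ElementalState] = []

    if rtype.effect in ("produce_state", "consume_state"):
        if rtype.state_kind == "interaction":
            sid = f"{lhs_tok}--{rhs_tok}"
            state = ElementalState(sid, "interaction", ((lhs_name, None), (rhs_name, rhs_site)))
        else:
            sid = f"{rhs_tok}-{rtype.state_tag}"
            state = ElementalState(sid, rtype.state_kind, ((rhs_name, rhs_site),))
        states.append(state)
        if rtype.effect == "produce_state":
            produced = (sid,)
        else:
            consumed = (sid,)
    elif rtype.effect == "produce_presence":
        synthesizes = (rhs_name,)
    elif rtype.effect == "consume_presence":
        degrades = (rhs_name,)
    else:  # pragma: no cover - registry guards this
        raise RxnconValidationError(f"unknown reaction effect {rtype.effect!r}")

    reaction = ElementalReaction(
        id=rid,
        rtype=rtype,
        substrates=(lhs_name, rhs_name) if lhs_name != rhs_name else (lhs_name,),
        produced=produced,
        consumed=consumed,
        synthesizes=synthesizes,
        degrades=degrades,
    )
    comps = [(lhs_name, None), (rhs_name, rhs_site)]
    return reaction, comps, states


def parse_network(
    text: str,
    registry: ReactionTypeRegistry | None = None,
    validate: bool = True,
) -> RxnconNetwork:
    """Parse a line-based reaction-contingency definition.

    Each non-empty, non-comment line is ``REACTION[; SIGN STATE]...``.
    Components and elemental states are derived from the reaction ids.
    """
    registry = registry or DEFAULT_REGISTRY
    net = RxnconNetwork()
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split(";")]
        rid = fields[0]
        if rid in net.reactions:
            raise RxnconValidationError(f"line {line_no}: duplicate reaction id {rid!r}")
        reaction, comps, states = _build_reaction(rid, registry, line_no)
        net.reactions[rid] = reaction
        for name, _site in comps:
            net.components.setdefault(name, Component(name))
        for st in states:
            net.states.setdefault(st.id, st)
        for tok in fields[1:]:
            if not tok:
                continue
            parts = tok.split(None, 1)
            if len(parts) != 2:
                raise RxnconParseError(
                    f"line {line_no}: malformed contingency {tok!r} (expected 'SIGN STATE')"
                )
            sign, effector = parts
            sign = "x" if sign in ("x", "X", "×") else sign
            if sign not in SIGNS:
                raise RxnconParseError(f"line {line_no}: unknown contingency sign {sign!r}")
            net.contingencies.append(Contingency(rid, effector, sign))
    if validate:
        net.validate()
    return net


def serialize_network(net: RxnconNetwork) -> str:
    """Write the network back in the same dialect.

    Reactions keep input order; each reaction's contingencies are sorted by
    sign (registry order) then effector id.
    """
    sign_rank = {s: i for i, s in enumerate(SIGNS)}
    lines = []
    for rid in net.reactions:
        conts = sorted(
            (c for c in net.contingencies if c.target == rid),
            key=lambda c: (sign_rank[c.sign], c.effector),
        )
        suffix = "".join(f"; {c.sign} {c.effector}" for c in conts)
        lines.append(rid + suffix)
    return "\n".join(lines) + ("\n" if lines else "")


def quantitative_modifiers(net: RxnconNetwork, reaction_id: str) -> list[tuple[str, str]]:
    """Ordered ``(effector, sign)`` pairs of the K+/K- modifiers of a reaction.

    Order follows the input order of the contingencies.  Absolute (``!``,
    ``x``) and inert (``0``, ``?``) contingencies are excluded.
    """
    return [
        (c.effector, c.sign)
        for c in net.contingencies_for(reaction_id)
        if c.sign in QUANTITATIVE_SIGNS
    ]


def strengthen_contingencies(net: RxnconNetwork) -> RxnconNetwork:
    """Return a copy with every K+ turned into ! and every K- into x."""
    mapped = [
        replace(c, sign={"K+": "!", "K-": "x"}.get(c.sign, c.sign))
        for c in net.contingencies
    ]
    return RxnconNetwork(
        components=dict(net.components),
        states=dict(net.states),
        reactions=dict(net.reactions),
        contingencies=mapped,
    )


def weaken_contingencies(net: RxnconNetwork) -> RxnconNetwork:
    """Return a copy with every ! turned into K+ and every x into K-."""
    mapped = [
        replace(c, sign={"!": "K+", "x": "K-"}.get(c.sign, c.sign))
        for c in net.contingencies
    ]
    return RxnconNetwork(
        components=dict(net.components),
        states=dict(net.states),
        reactions=dict(net.reactions),
        contingencies=mapped,
    )
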
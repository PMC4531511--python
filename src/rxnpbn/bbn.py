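"""Qualitative bipartite Boolean model generation.

A reaction-contingency network maps to a Boolean network with two node
classes.  *Reaction nodes* fire when their substrates are present and their
absolute contingencies are met::

    A_ppi_B(t+1) = A(t) ∧ B(t) ∧ B--C(t)        (with contingency ! B--C)

*State nodes* follow the reactions that produce and consume them.  States
produced by reversible reactions track their producer (the bond decays as
soon as the reaction stops); states produced by irreversible reactions keep
a memory term and are only erased by an active consumer::

    B--C(t+1)  = B_ppi_C(t)                                  (reversible)
    X-{P}(t+1) = A_P+_X(t) ∨ (X-{P}(t) ∧ ¬Y_P-_X(t))         (irreversible)

One *presence node* per component closes the loop: it is constant unless
the component is synthesized (TRSC/TRSL) or degraded (DEG), and every state
carrying a degradable component is conjoined with an availability factor
¬(degraded ∧ ¬synthesized) per member component.

In the qualitative model only absolute contingencies (``!``/``x``) shape
the rules; quantitative modifiers (K+/K-) are ignored here and handled by
the probabilistic generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .core import RxnconNetwork, ElementalReaction
from .expressions import BoolExpr, FALSE, TRUE, Lit, land, lit, lnot, lor

__all__ = [
    "BipartiteBooleanModel",
    "build_reaction_rule",
    "build_state_rule",
    "component_availability_term",
    "build_model",
]

COMPONENT = "component"
STATE = "state"
REACTION = "reaction"


@dataclass
class BipartiteBooleanModel:
    """Boolean network with reaction / state / component-presence nodes.

    ``rules`` maps every node to an ordered list of ``(expression,
    probability)`` pairs.  The qualitative model has exactly one pair per
    node with probability 1; the probabilistic generator replaces reaction
    rules with multi-rule sets.
    """

    nodes: list[str]
    kinds: dict[str, str]
    rules: dict[str, list[tuple[BoolExpr, float]]]
    initial_state: dict[str, bool]
    reported_probabilities: dict[str, list[float]] = field(default_factory=dict)

    @property
    def reaction_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.kinds[n] == REACTION]

    @property
    def state_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.kinds[n] != REACTION]

    @property
    def is_probabilistic(self) -> bool:
        return any(len(rs) > 1 for rs in self.rules.values())

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def single_rule(self, node: str) -> BoolExpr:
        rs = self.rules[node]
        if len(rs) != 1:
            raise ValueError(f"node {node!r} has {len(rs)} rules, not 1")
        return rs[0][0]

    def validate_bipartite(self) -> None:
        """Reaction rules see only state/component nodes; state rules see
        only reaction nodes plus (for memory) the state itself."""
        for node in self.nodes:
            refs = frozenset().union(*(e.literals() for e, _ in self.rules[node]))
            unknown = refs - set(self.nodes)
            if unknown:
                raise ValueError(f"rule of {node!r} references unknown nodes {sorted(unknown)}")
            if self.kinds[node] == REACTION:
                bad = [r for r in refs if self.kinds[r] == REACTION]
                if bad:
                    raise ValueError(f"reaction rule {node!r} references reactions {bad}")
            else:
                bad = [r for r in refs if self.kinds[r] != REACTION and r != node]
                if bad:
                    raise ValueError(f"state rule {node!r} references non-self states {bad}")


def build_reaction_rule(
    net: RxnconNetwork, reaction: ElementalReaction
) -> BoolExpr:
    """Substrate presence ∧ required states ∧ negated forbidden states."""
    terms: list[BoolExpr] = [lit(c) for c in reaction.substrates]
    for c in net.contingencies_for(reaction.id):
        if c.sign == "!":
            terms.append(lit(c.effector))
        elif c.sign == "x":
            terms.append(lnot(lit(c.effector)))
    return land(*terms)


def component_availability_term(net: RxnconNetwork, state_id: str) -> BoolExpr:
    """Availability factor: a state cannot hold if one of its member
    components is being degraded without simultaneous synthesis."""
    state = net.states[state_id]
    factors: list[BoolExpr] = []
    for comp, _site in state.members:
        degs = [lit(r.id) for r in net.degraders_of(comp)]
        if not degs:
            continue
        syns = [lit(r.id) for r in net.synthesizers_of(comp)]
        factors.append(lnot(land(lor(*degs), lnot(lor(*syns)))))
    return land(*factors)


def build_state_rule(net: RxnconNetwork, state_id: str) -> BoolExpr:
    """Update rule of an elemental-state node from its producers/consumers."""
    producers = net.producers_of(state_id)
    consumers = net.consumers_of(state_id)
    prod_lits = [lit(r.id) for r in producers]
    cons_lits = [lit(r.id) for r in consumers]

    if not producers:
        warnings.warn(
            f"state {state_id!r} has no producing reaction; it keeps its initial value"
            + (" unless consumed" if consumers else ""),
            stacklevel=2,
        )
        core = land(lit(state_id), lnot(lor(*cons_lits))) if consumers else Lit(state_id)
    elif all(r.rtype.reversible for r in producers):
        # bond decays when the reversible reaction stops firing
        core = land(lor(*prod_lits), lnot(lor(*cons_lits)))
    else:
        # memory: stays TRUE until actively consumed with no producer firing
        core = lor(lor(*prod_lits), land(lit(state_id), lnot(lor(*cons_lits))))
    return land(core, component_availability_term(net, state_id))


def build_presence_rule(net: RxnconNetwork, component: str) -> BoolExpr:
    """Presence node rule: memory of synthesis/degradation, else constant."""
    syns = [lit(r.id) for r in net.synthesizers_of(component)]
    degs = [lit(r.id) for r in net.degraders_of(component)]
    if not syns and not degs:
        return Lit(component)  # holds its initial value (TRUE by default)
    return lor(lor(*syns), land(lit(component), lnot(lor(*degs))))


def default_initial_state(model_nodes: list[str], kinds: dict[str, str]) -> dict[str, bool]:
    """Components present, every state and reaction node FALSE."""
    return {n: kinds[n] == COMPONENT for n in model_nodes}


def build_model(net: RxnconNetwork) -> BipartiteBooleanModel:
    """Derive the qualitative bipartite Boolean model (one rule per node)."""
    net.validate()
    nodes: list[str] = []
    kinds: dict[str, str] = {}
    for name in net.components:
        nodes.append(name)
        kinds[name] = COMPONENT
    for sid in net.states:
        nodes.append(sid)
        kinds[sid] = STATE
    for rid in net.reactions:
        nodes.append(rid)
        kinds[rid] = REACTION

    rules: dict[str, list[tuple[BoolExpr, float]]] = {}
    for name in net.components:
        rules[name] = [(build_presence_rule(net, name), 1.0)]
    for sid in net.states:
        rules[sid] = [(build_state_rule(net, sid), 1.0)]
    for rid, reaction in net.reactions.items():
        rules[rid] = [(build_reaction_rule(net, reaction), 1.0)]

    model = BipartiteBooleanModel(
        nodes=nodes,
        kinds=kinds,
        rules=rules,
        initial_state=default_initial_state(nodes, kinds),
    )
    model.validate_bipartite()
    return model
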
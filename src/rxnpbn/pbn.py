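"""Probabilistic rule-set generation from quantitative contingencies.

Each reaction node of the bipartite model receives an ordered family of
update functions f₀ … fₙ plus a constant-FALSE rule, where n is the number
of quantitative (K+/K-) modifiers of the reaction:

* f₀ is the base rule — substrates and absolute contingencies only;
* fᵢ (1 ≤ i ≤ n) additionally requires at least *i* of the n modifier
  conditions to hold (a K+ modifier holds when its effector state is TRUE,
  a K- modifier when it is FALSE), written as the disjunction over all
  i-subsets of the modifier literals;
* the FALSE rule models random failure of the reaction.

Probabilities come from two global parameters, the false-rate ``p_false``
and the scaling base ``k``:

    p₀ = (1 − p_false) / Σ_{i=0..n} kⁱ,        pᵢ = p₀ · kⁱ

so that for k > 1 each more restrictive rule is k times more likely than
the previous one, and the probabilities of a node sum to 1.  State and
presence nodes keep their single deterministic rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

from .bbn import (
    BipartiteBooleanModel,
    REACTION,
    build_model,
    build_reaction_rule,
)
from .core import RxnconNetwork, quantitative_modifiers
from .expressions import BoolExpr, FALSE, land, lit, lnot, lor

__all__ = [
    "PBNParams",
    "ProbabilisticRuleSet",
    "assign_probabilities",
    "exact_probabilities",
    "build_quantitative_rules",
    "build_pbn",
]

REPORT_DECIMALS = 6


@dataclass(frozen=True)
class PBNParams:
    """Global parameters of the probabilistic model.

    p_false : probability of the constant-FALSE rule of every reaction
        node (random reaction failure), in [0, 1).
    k_base : scaling base; each more restrictive update function is k times
        more probable than the previous.  k = 1 weights all non-false rules
        equally; large k approaches the qualitative absolute-contingency
        model.  Values below 1 are accepted but invert the preference
        ordering.
    """

    p_false: float = 0.1
    k_base: float = 10.0

    def __post_init__(self):
        if not (0.0 <= self.p_false < 1.0):
            raise ValueError(f"p_false must be in [0, 1), got {self.p_false}")
        if self.k_base <= 0:
            raise ValueError(f"k_base must be positive, got {self.k_base}")
        if self.k_base < 1:
            warnings.warn(
                f"k_base={self.k_base} < 1 inverts the preference for more "
                "restrictive update functions",
                stacklevel=3,
            )


def exact_probabilities(n: int, params: PBNParams) -> list[float]:
    """Full-precision probabilities [p₀, …, pₙ, p_false] (length n + 2)."""
    if n < 0:
        raise ValueError(f"modifier count must be >= 0, got {n}")
    k = params.k_base
    denom = sum(k**i for i in range(n + 1))
    p0 = (1.0 - params.p_false) / denom
    return [p0 * k**i for i in range(n + 1)] + [params.p_false]


def assign_probabilities(n: int, params: PBNParams) -> list[float]:
    """Reported probabilities [p₀, …, pₙ, p_false], summing to exactly 1.

    Export convention: p₀ is rounded to 6 decimals, pᵢ = rounded-p₀ · kⁱ
    for i < n, and the most restrictive non-false rule absorbs the rounding
    residue pₙ = 1 − p_false − Σ_{i<n} pᵢ.  With n = 2, k = 10 and
    p_false = 0.1 this yields 0.008108 / 0.08108 / 0.810812.  Simulation
    always uses the full-precision values from :func:`exact_probabilities`.
    """
    exact = exact_probabilities(n, params)
    if n == 0:
        # the single non-false rule is itself the residue 1 - p_false
        return [round(1.0 - params.p_false, 12), params.p_false]
    k = params.k_base
    p0 = round(exact[0], REPORT_DECIMALS)
    reported = [round(p0 * k**i, REPORT_DECIMALS) for i in range(n)]
    # residue only trimmed of float noise, never re-rounded to 6 decimals:
    # that would break sum-to-one whenever p_false has more decimals
    residue = round(1.0 - params.p_false - sum(reported), 12)
    if residue < 0:
        # rounding overshoot (possible for extreme k); fall back to plain
        # per-rule rounding with the residue on the last non-false rule
        reported = [round(p, REPORT_DECIMALS) for p in exact[:n]]
        residue = round(1.0 - params.p_false - sum(reported), 12)
    reported.append(residue)
    reported.append(params.p_false)
    return reported


@dataclass(frozen=True)
class ProbabilisticRuleSet:
    """Ordered update functions of one reaction node.

    ``rules`` holds ``(expression, probability)`` at full precision; the
    final entry is always the constant-FALSE rule.
    """

    node: str
    rules: tuple[tuple[BoolExpr, float], ...]
    n_modifiers: int
    params: PBNParams

    def probabilities(self) -> list[float]:
        return [p for _, p in self.rules]

    def reported(self) -> list[float]:
        return assign_probabilities(self.n_modifiers, self.params)


def _modifier_literal(effector: str, sign: str) -> BoolExpr:
    # a K+ modifier is fulfilled when its state holds, a K- one when it does not
    return lit(effector) if sign == "K+" else lnot(lit(effector))


def build_quantitative_rules(
    net: RxnconNetwork, reaction_id: str, params: PBNParams
) -> ProbabilisticRuleSet:
    """Build f₀ … fₙ plus the FALSE rule for one reaction node."""
    reaction = net.reactions[reaction_id]
    base = build_reaction_rule(net, reaction)  # substrates + absolutes
    modifiers = quantitative_modifiers(net, reaction_id)
    n = len(modifiers)
    mod_lits = [_modifier_literal(e, s) for e, s in modifiers]

    exprs: list[BoolExpr] = [base]
    for i in range(1, n + 1):
        combos = [land(*subset) for subset in itertools.combinations(mod_lits, i)]
        exprs.append(land(base, lor(*combos)))
    exprs.append(FALSE)

    probs = exact_probabilities(n, params)
    return ProbabilisticRuleSet(
        node=reaction_id,
        rules=tuple(zip(exprs, probs)),
        n_modifiers=n,
        params=params,
    )


def _apply_overrides(
    probs: list[float], overrides: dict[int, float], node: str
) -> list[float]:
    """Fix some rule probabilities and renormalize the rest proportionally."""
    if any(i < 0 or i >= len(probs) for i in overrides):
        raise ValueError(f"override rule index out of range for node {node!r}")
    if any(p < 0 for p in overrides.values()):
        raise ValueError(f"negative override probability for node {node!r}")
    fixed_mass = sum(overrides.values())
    free = [i for i in range(len(probs)) if i not in overrides]
    if not free:
        if abs(fixed_mass - 1.0) > 1e-9:
            raise ValueError(
                f"override probabilities for node {node!r} sum to {fixed_mass}, not 1"
            )
        return [overrides[i] for i in range(len(probs))]
    if fixed_mass > 1.0 + 1e-12:
        raise ValueError(
            f"override probabilities for node {node!r} exceed 1 (sum {fixed_mass})"
        )
    free_mass = sum(probs[i] for i in free)
    scale = (1.0 - fixed_mass) / free_mass if free_mass > 0 else 0.0
    out = []
    for i, p in enumerate(probs):
        out.append(overrides[i] if i in overrides else p * scale)
    if abs(sum(out) - 1.0) > 1e-9:
        raise ValueError(f"override probabilities for node {node!r} do not renormalize to 1")
    return out


def build_pbn(
    net: RxnconNetwork,
    params: PBNParams | None = None,
    overrides: dict[str, dict[int, float]] | None = None,
) -> BipartiteBooleanModel:
    """Build the probabilistic bipartite Boolean model.

    Every reaction node — including contingency-free ones — receives its
    rule family with the FALSE rule; state and presence nodes keep their
    single deterministic rule.  ``overrides`` optionally pins individual
    rule probabilities per node (``{node: {rule_index: prob}}``); the
    remaining rules are renormalized proportionally.
    """
    params = params or PBNParams()
    model = build_model(net)
    reported: dict[str, list[float]] = {}
    for rid in net.reactions:
        ruleset = build_quantitative_rules(net, rid, params)
        probs = ruleset.probabilities()
        rep = ruleset.reported()
        if overrides and rid in overrides:
            probs = _apply_overrides(probs, overrides[rid], rid)
            rep = probs
        exprs = [e for e, _ in ruleset.rules]
        model.rules[rid] = list(zip(exprs, probs))
        reported[rid] = rep
    model.reported_probabilities = reported
    model.validate_bipartite()
    return model
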
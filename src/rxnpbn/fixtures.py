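"""Bundled example networks and the random network generator.

Every fixture is plain text in the line-based reaction-contingency dialect
and parses, builds and simulates with the other modules without external
data.  The simplified HOG fixture is a best-effort transcription of the
published two-module oscillator topology (see its ``notes``); quantitative
variants are derived programmatically by the sign substitutions ! → K+ and
x → K-.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    RxnconNetwork,
    parse_network,
    serialize_network,
    weaken_contingencies,
)
from .pbn import PBNParams

__all__ = [
    "FixtureSpec",
    "RandomNetworkSpec",
    "fixture_worked_example",
    "fixture_hog",
    "fixture_noisy_pair",
    "FIXTURES",
    "random_network",
]


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    network_text: str
    default_params: PBNParams
    notes: str

    def network(self) -> RxnconNetwork:
        return parse_network(self.network_text)


WORKED_EXAMPLE_TEXT = """\
B_ppi_C
A_ppi_D
A_ppi_B; K+ B--C; K- A--D
"""


def fixture_worked_example() -> FixtureSpec:
    """Three protein-protein interactions, one reaction with two
    quantitative modifiers; the canonical small test case (k = 10,
    p_false = 0.1)."""
    return FixtureSpec(
        name="worked-example",
        network_text=WORKED_EXAMPLE_TEXT,
        default_params=PBNParams(p_false=0.1, k_base=10.0),
        notes=(
            "Three-reaction network printed in the method description "
            "(Methods, worked update-function example): A_ppi_B carries "
            "K+ B--C and K- A--D, the other two reactions are "
            "contingency-free."
        ),
    )


# Simplified HOG pathway: a phosphotransfer module (Sln1 → Ypd1 → Ssk1)
# that is active while turgor is sensed and keeps the MAP kinase module
# (Ssk2 → Pbs2 → Hog1) off; active Hog1 drives glycerol production (Gpd1),
# which restores turgor and re-activates the phosphotransfer module —
# a negative feedback loop.  Constitutive phosphatase reactions (Ptc1)
# make each phosphorylation state track its kinase with one step delay,
# so the deterministic model oscillates with period 24.
HOG_QUALITATIVE_TEXT = """\
# phosphotransfer module (on while turgor is sensed)
Sln1_P+_Ypd1; ! Turg--Sln1
Ypd1_P+_Ssk1; ! Ypd1-{P}
Ptc1_P-_Ypd1
Ptc1_P-_Ssk1
# MAP kinase module (inhibited by the phosphotransfer module)
Ssk2_P+_Pbs2; x Ssk1-{P}
Pbs2_P+_Hog1; ! Pbs2-{P}
Ptc1_P-_Pbs2
Ptc1_P-_Hog1
# glycerol feedback restores turgor
Hog1_P+_Gpd1; ! Hog1-{P}
Ptc1_P-_Gpd1
Turg_ppi_Sln1; ! Gpd1-{P}
"""

HOG_TERMINAL_NODE = "Hog1-{P}"


def fixture_hog(variant: str = "qualitative") -> FixtureSpec:
    """Simplified two-module HOG oscillator.

    ``variant='qualitative'`` uses absolute contingencies (!/x);
    ``variant='quantitative'`` substitutes every ! → K+ and x → K-
    programmatically, leaving everything else identical.
    """
    notes = (
        "Best-effort transcription of the simplified two-module HOG "
        "oscillator (regulatory-graph figure of the source model): a "
        "phosphotransfer module (Sln1/Ypd1/Ssk1) requiring turgor, a MAP "
        "kinase module (Ssk2/Pbs2/Hog1) inhibited by it, and negative "
        "feedback in which Hog1-{P} drives glycerol production (Gpd1 as "
        "surrogate) that restores turgor.  Transcription assumptions: "
        "(i) constitutive Ptc1 phosphatase reactions make phospho-states "
        "track their kinases; (ii) turgor sensing is modelled as the "
        "reversible interaction Turg_ppi_Sln1 contingent on glycerol; "
        "(iii) the exact line-by-line source definition is not "
        "reproducible from the text, so only interval/ordinal behaviour "
        "is asserted against this fixture."
    )
    if variant == "qualitative":
        text = HOG_QUALITATIVE_TEXT
    elif variant == "quantitative":
        net = parse_network(HOG_QUALITATIVE_TEXT)
        text = serialize_network(weaken_contingencies(net))
        notes += "  Quantitative variant: signs substituted ! → K+, x → K-."
    else:
        raise ValueError(f"unknown HOG variant {variant!r}")
    return FixtureSpec(
        name=f"hog-{variant}",
        network_text=text,
        default_params=PBNParams(p_false=0.01, k_base=100.0),
        notes=notes,
    )


def fixture_noisy_pair() -> FixtureSpec:
    """Tiny two-reaction chain with one quantitative modifier; 7 nodes,
    small enough for the exact Markov oracle."""
    return FixtureSpec(
        name="noisy-pair",
        network_text="B_ppi_C\nA_ppi_B; K+ B--C\n",
        default_params=PBNParams(p_false=0.2, k_base=4.0),
        notes="Synthetic miniature for oracle-equivalence checks (7 nodes).",
    )


FIXTURES = {
    "worked-example": fixture_worked_example,
    "hog-qualitative": lambda: fixture_hog("qualitative"),
    "hog-quantitative": lambda: fixture_hog("quantitative"),
    "noisy-pair": fixture_noisy_pair,
}


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Size/shape parameters of a random scalability network.

    ``contingency_density`` is the expected number of contingencies per
    reaction; ``quantitative_fraction`` the share of K+/K- among them
    (the rest split evenly between ! and x).
    """

    n_components: int = 142
    n_reactions: int = 273
    contingency_density: float = 1.0
    quantitative_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 0 or self.n_reactions < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.quantitative_fraction <= 1.0):
            raise ValueError("quantitative_fraction must be in [0, 1]")
        if self.contingency_density < 0:
            raise ValueError("contingency_density must be >= 0")


def random_network(spec: RandomNetworkSpec) -> RxnconNetwork:
    """Random ppi/P+ network emulating curated-reconstruction scale.

    Reactions connect random component pairs (a weak chain over the first
    components keeps the graph connected-ish); contingencies are drawn
    only among states that some reaction produces.  Fully seeded and
    reproducible.
    """
    rng = np.random.default_rng(spec.seed)
    comps = [f"C{i:03d}" for i in range(spec.n_components)]
    if spec.n_reactions and spec.n_components < 2:
        raise ValueError("need at least 2 components to draw reactions")

    lines: list[str] = []
    seen: set[str] = set()
    produced_states: list[str] = []
    attempts = 0
    while len(lines) < spec.n_reactions:
        attempts += 1
        if attempts > 50 * (spec.n_reactions + 1):
            raise ValueError(f"cannot place {spec.n_reactions} distinct reactions")
        if len(lines) < min(spec.n_components - 1, spec.n_reactions):
            a = len(lines)  # chain backbone C0-C1, C1-C2, ...
            b = a + 1
        else:
            a, b = rng.choice(spec.n_components, size=2, replace=False)
        code = "ppi" if rng.random() < 0.5 else "P+"
        if code == "ppi":
            x, y = sorted((int(a), int(b)))
            rid = f"{comps[x]}_ppi_{comps[y]}"
            state = f"{comps[x]}--{comps[y]}"
        else:
            rid = f"{comps[int(a)]}_P+_{comps[int(b)]}"
            state = f"{comps[int(b)]}-{{P}}"
        if rid in seen:
            continue
        seen.add(rid)
        lines.append(rid)
        if state not in produced_states:
            produced_states.append(state)

    n_cont = int(round(spec.contingency_density * spec.n_reactions))
    if n_cont and not produced_states:
        raise ValueError("contingencies requested but no producible states exist")
    max_cont = len(lines) * len(produced_states)
    if n_cont > max_cont:
        raise ValueError(
            f"cannot place {n_cont} contingencies among {max_cont} (target, effector) pairs"
        )
    cont_by_line: dict[int, list[str]] = {}
    placed: set[tuple[int, str]] = set()
    attempts = 0
    while len(placed) < n_cont:
        attempts += 1
        if attempts > 100 * (n_cont + 1):
            raise ValueError("contingency placement did not converge")
        tgt = int(rng.integers(len(lines)))
        eff = produced_states[int(rng.integers(len(produced_states)))]
        if (tgt, eff) in placed:
            continue
        placed.add((tgt, eff))
        if rng.random() < spec.quantitative_fraction:
            sign = "K+" if rng.random() < 0.5 else "K-"
        else:
            sign = "!" if rng.random() < 0.5 else "x"
        cont_by_line.setdefault(tgt, []).append(f"{sign} {eff}")

    text_lines = [
        line + "".join(f"; {c}" for c in cont_by_line.get(i, []))
        for i, line in enumerate(lines)
    ]
    return parse_network("\n".join(text_lines) + "\n" if text_lines else "")
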
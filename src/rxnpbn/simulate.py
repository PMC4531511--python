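"""Synchronous stochastic simulation of (probabilistic) Boolean models.

Updating is synchronous and instantaneously random: at every time step,
each node independently samples one of its update functions according to
the fixed rule probabilities, and all nodes are then updated simultaneously
from the pre-step state.  The resulting process is a Markov chain; for
small models :func:`exact_markov_distribution` propagates the exact state
distribution as an oracle for the Monte-Carlo engine.

Reproducibility: run r of an ensemble draws from a dedicated bit stream
seeded by ``SeedSequence(master_seed, spawn_key=(r,))``, so sequential and
parallel execution produce bit-identical ensembles and ``runs=1``
reproduces :func:`run`.

Perturbations clamp a node to a fixed value from their event time until
the next event on the same node, overriding its update rules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .bbn import BipartiteBooleanModel

__all__ = [
    "PerturbationEvent",
    "SimulationConfig",
    "TrajectoryEnsemble",
    "step",
    "run",
    "run_ensemble",
    "exact_markov_distribution",
]

MAX_ORACLE_NODES = 16


@dataclass(frozen=True)
class PerturbationEvent:
    """Clamp ``node`` to ``value`` from step ``time`` until its next event."""

    time: int
    node: str
    value: bool


@dataclass(frozen=True)
class SimulationConfig:
    steps: int
    runs: int = 1
    seed: int = 0
    initial_state: Mapping[str, bool] | None = None
    clamps: tuple[PerturbationEvent, ...] = ()

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class TrajectoryEnsemble:
    """Boolean records of shape (runs, steps + 1, nodes); t = 0 is the
    initial state."""

    values: np.ndarray
    nodes: list[str]
    config: SimulationConfig

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != len(self.nodes):
            raise ValueError("values must have shape (runs, steps+1, nodes)")

    @property
    def runs(self) -> int:
        return self.values.shape[0]

    def node_trace(self, node: str, run: int = 0) -> np.ndarray:
        return self.values[run, :, self.nodes.index(node)]

    def mean(self) -> np.ndarray:
        """Per-time per-node activation probability estimate, (steps+1, nodes)."""
        return self.values.mean(axis=0)


class _CompiledModel:
    """Model lowered to index-based vectorised rule evaluators."""

    def __init__(self, model: BipartiteBooleanModel):
        self.model = model
        self.nodes = list(model.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.rule_fns: list[list] = []
        self.probs: list[np.ndarray] = []
        self.cum: list[np.ndarray] = []
        self.stochastic: list[int] = []
        for i, node in enumerate(self.nodes):
            rules = model.rules[node]
            self.rule_fns.append([expr.compile(self.index) for expr, _ in rules])
            p = np.array([prob for _, prob in rules], dtype=float)
            total = p.sum()
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"probabilities of node {node!r} sum to {total}, not 1")
            self.probs.append(p)
            c = np.cumsum(p)
            c[-1] = 1.0
            self.cum.append(c)
            if len(rules) > 1:
                self.stochastic.append(i)

    def initial_vector(self, override: Mapping[str, bool] | None) -> np.ndarray:
        init = dict(self.model.initial_state)
        if override:
            unknown = set(override) - set(self.index)
            if unknown:
                raise KeyError(f"initial state names unknown nodes {sorted(unknown)}")
            init.update(override)
        return np.array([bool(init[n]) for n in self.nodes], dtype=bool)


def step(
    model: BipartiteBooleanModel,
    state: Mapping[str, bool],
    rng: np.random.Generator,
) -> dict[str, bool]:
    """One synchronous update of a state mapping.

    For each node one rule is sampled by its probabilities (nodes with a
    single rule update deterministically); all nodes are then evaluated on
    the pre-step state.
    """
    missing = set(model.nodes) - set(state)
    if missing:
        raise KeyError(f"state missing nodes {sorted(missing)}")
    new: dict[str, bool] = {}
    for node in model.nodes:
        rules = model.rules[node]
        if len(rules) == 1:
            expr = rules[0][0]
        else:
            probs = [p for _, p in rules]
            idx = int(np.searchsorted(np.cumsum(probs), rng.random(), side="right"))
            idx = min(idx, len(rules) - 1)
            expr = rules[idx][0]
        new[node] = expr.evaluate(state)
    return new


def _clamp_schedule(
    clamps: tuple[PerturbationEvent, ...],
    index: Mapping[str, int],
    steps: int,
) -> dict[int, list[tuple[int, bool]]]:
    by_time: dict[int, list[tuple[int, bool]]] = {}
    for ev in clamps:
        if ev.node not in index:
            raise KeyError(f"clamp on unknown node {ev.node!r}")
        if not (0 <= ev.time <= steps):
            raise ValueError(f"clamp time {ev.time} outside [0, {steps}]")
        by_time.setdefault(ev.time, []).append((index[ev.node], bool(ev.value)))
    return by_time


def run_ensemble(model: BipartiteBooleanModel, config: SimulationConfig) -> TrajectoryEnsemble:
    """Simulate ``config.runs`` independent trajectories (vectorised)."""
    cm = _CompiledModel(model)
    n_nodes = len(cm.nodes)
    runs, steps = config.runs, config.steps

    x0 = cm.initial_vector(config.initial_state)
    X = np.broadcast_to(x0, (runs, n_nodes)).copy()

    events = _clamp_schedule(config.clamps, cm.index, steps)
    active: dict[int, bool] = {}
    for i, v in events.get(0, []):
        active[i] = v
    for i, v in active.items():
        X[:, i] = v

    traj = np.empty((runs, steps + 1, n_nodes), dtype=bool)
    traj[:, 0, :] = X

    stoch = cm.stochastic
    # pre-draw each run's uniforms from its own counter-based stream
    U = np.empty((runs, steps, len(stoch)))
    for r in range(runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(r,))
        )
        U[r] = rng.random((steps, len(stoch)))

    run_idx = np.arange(runs)
    for t in range(1, steps + 1):
        newX = np.empty_like(X)
        for i in range(n_nodes):
            fns = cm.rule_fns[i]
            if len(fns) == 1:
                newX[:, i] = fns[0](X)
            else:
                j = stoch.index(i)
                choice = np.searchsorted(cm.cum[i], U[:, t - 1, j], side="right")
                np.clip(choice, 0, len(fns) - 1, out=choice)
                evals = np.stack([f(X) for f in fns])
                newX[:, i] = evals[choice, run_idx]
        for i, v in events.get(t, []):
            active[i] = v
        for i, v in active.items():
            newX[:, i] = v
        X = newX
        traj[:, t, :] = X

    return TrajectoryEnsemble(values=traj, nodes=cm.nodes, config=config)


def run(model: BipartiteBooleanModel, config: SimulationConfig) -> np.ndarray:
    """Single trajectory (steps + 1, nodes); run 0 of the ensemble scheme."""
    ens = run_ensemble(model, replace(config, runs=1))
    return ens.values[0]


def exact_markov_distribution(
    model: BipartiteBooleanModel,
    initial: Mapping[str, bool] | None = None,
    steps: int = 20,
) -> np.ndarray:
    """Exact per-node marginal activation probabilities, (steps + 1, nodes).

    Propagates the full state distribution of the Markov chain using a
    sparse support representation: per reachable state, each node's
    probability of being TRUE next step is the probability-weighted OR of
    its rules, and the joint successor distribution factorises over nodes.
    Limited to models with at most 16 nodes.
    """
    n_nodes = len(model.nodes)
    if n_nodes > MAX_ORACLE_NODES:
        raise ValueError(
            f"exact oracle supports <= {MAX_ORACLE_NODES} nodes, model has {n_nodes}"
        )
    cm = _CompiledModel(model)
    x0 = cm.initial_vector(initial)
    bits = 1 << np.arange(n_nodes)

    def mask_of(vec: np.ndarray) -> int:
        return int((vec * bits).sum())

    dist: dict[int, float] = {mask_of(x0): 1.0}
    marginals = np.empty((steps + 1, n_nodes))

    for t in range(steps + 1):
        masks = np.fromiter(dist.keys(), dtype=np.int64, count=len(dist))
        probs = np.fromiter(dist.values(), dtype=float, count=len(dist))
        support = (masks[:, None] & bits[None, :]) != 0  # (S, N)
        marginals[t] = probs @ support
        if t == steps:
            break
        # q[s, i] = P(node i TRUE next | state s)
        q = np.zeros((len(masks), n_nodes))
        for i in range(n_nodes):
            for f, p in zip(cm.rule_fns[i], cm.probs[i]):
                if p > 0:
                    q[:, i] += p * f(support)
        new: dict[int, float] = {}
        for s in range(len(masks)):
            qrow = q[s]
            base = 0
            free: list[int] = []
            for i in range(n_nodes):
                if qrow[i] >= 1.0 - 1e-12:
                    base |= int(bits[i])
                elif qrow[i] > 1e-12:
                    free.append(i)
            outcomes = [(base, probs[s])]
            for i in free:
                qi = qrow[i]
                bit = int(bits[i])
                outcomes = [
                    pair
                    for m, w in outcomes
                    for pair in ((m | bit, w * qi), (m, w * (1.0 - qi)))
                ]
            for m, w in outcomes:
                if w > 0.0:
                    new[m] = new.get(m, 0.0) + w
        dist = new

    # probabilities only; trim accumulated floating-point noise
    return np.clip(marginals, 0.0, 1.0)
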
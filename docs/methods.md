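# Methods

## Model generation

### From reaction–contingency definitions to a bipartite Boolean network

The input dialect is one elemental reaction per line, with an optional
`;`-separated contingency list (`A_ppi_B; K+ B--C; K- A--D`). Components
and elemental states are derived from the reaction identifiers through an
extensible reaction-type registry; the built-in table covers `ppi`/`i`
(reversible, produce an interaction state), `P+`/`P-` and `Ub+`/`Ub-`
(irreversible, produce/consume a modification state), `TRSC`/`TRSL`
(synthesis of component presence), `DEG` (degradation) and `NIMP`/`NEXP`
(localization). Unknown codes can be registered with declared properties;
the table is deliberately open-ended because no complete ontology of
reaction types exists. Site labels (`Hog1_[(T174)]`) are carried opaquely
inside identifiers and have no structural semantics.

Rule generation is fixed by the node class:

- **Reaction nodes**: conjunction of substrate presence, `!` effectors,
  and negated `x` effectors. `0`/`?` contingencies are inert everywhere;
  `K+`/`K-` are inert in the qualitative model.
- **State nodes**: states produced only by reversible reactions track the
  disjunction of their producers (the bond decays when the reaction stops);
  any irreversible producer adds a memory term, `(∨ producers) ∨ (state ∧
  ¬(∨ consumers))`, so the state is erased only by an active consumer with
  no simultaneous production. Consumers of reversible-only states appear
  as negated conjuncts. A state with no producer keeps its initial value
  (and is reported with a warning), unless consumers exist, which may
  still erase it.
- **Presence nodes**: one per component. Without synthesis/degradation
  reactions the rule is the self-literal — the node simply holds its
  initial value (TRUE under the default start state), which keeps the
  rule set closed without special-casing constants. With `DEG`/`TRSC`-type
  reactions it gets the same produce/consume memory form as irreversible
  states. Every state whose member component is degradable is additionally
  conjoined with the availability factor ¬(degraded ∧ ¬synthesized) per
  member.

The default initial state sets presence nodes TRUE and everything else
FALSE. Bipartiteness (reaction rules read only state/presence nodes;
state rules only reactions plus their own memory literal) is validated on
every build.

### Probability assignment

A reaction with *n* quantitative modifiers receives rules f₀ … fₙ plus a
constant-FALSE rule. fᵢ conjoins the base rule (substrates + absolutes,
present verbatim in every non-false rule) with the disjunction over all
i-subsets of modifier literals; a `K+ s` modifier contributes the literal
`s`, a `K- s` modifier `¬s`. This makes fᵢ ⇒ fᵢ₋₁ by construction
(monotone stringency). Probabilities follow the two-parameter geometric
scheme p₀ = (1 − p_FALSE)/Σᵢ₌₀ⁿ kⁱ, pᵢ = p₀·kⁱ. Every reaction node —
including contingency-free ones (n = 0) — carries the FALSE rule; state
and presence nodes never do, staying deterministic with probability 1.

Parameters: `p_false ∈ [0, 1)` (dimensionless probability per node per
step; default 0.1 for the worked example, 0.01 for the oscillator
studies) and `k_base > 0` (dimensionless; default 10, with 100 used where
a near-qualitative preference is wanted). `k < 1` is accepted with a
warning since it inverts the restrictiveness preference.

**Export rounding convention.** Simulation always uses full-precision
probabilities. Exported/reported values round p₀ to six decimals, set
pᵢ = rounded-p₀·kⁱ for i < n, and let the most restrictive non-false rule
absorb the residue pₙ = 1 − p_FALSE − Σᵢ₍ₙ pᵢ, so each node's exported
probabilities sum to exactly 1 (n = 2, k = 10, p_FALSE = 0.1 gives
0.008108 / 0.08108 / 0.810812). If the scaled rounding ever overshoots
the available mass (conceivable for extreme k), the convention falls back
to per-rule rounding with the residue on the last non-false rule.
Per-node probability overrides pin selected rule probabilities and
renormalize the remaining ones proportionally; fully specified nodes must
sum to 1.

## Simulation

Updating is synchronous and instantaneously random: each step, every node
independently samples one rule from its distribution, then all nodes
evaluate simultaneously on the pre-step state. Time is indexed so that
t = 0 is the initial state and a run of S steps yields S + 1 rows.

- **Reproducibility / parallelism contract.** Run r draws its uniforms
  from `SeedSequence(master_seed, spawn_key=(r,))`; ensembles are
  therefore bit-identical regardless of execution order, a prefix of a
  larger ensemble equals the smaller one, and `runs=1` reproduces the
  single-run API.
- **Clamping.** A perturbation event holds a node at a fixed value from
  its event time until the next event on the same node, overriding the
  node's rules entirely (events at t = 0 affect the initial row). The
  hold-until-next-event semantics is chosen over set-once-then-free
  because input switches (e.g. turgor off for a window of steps) must
  suppress the node's own dynamics for the whole window to drive a
  response.
- **Engine.** Rules are compiled to vectorised evaluators over a
  runs × nodes Boolean matrix; per step, each stochastic node's rule index
  is chosen by inverse-CDF lookup into its cumulative probabilities. A
  MAPK-scale random model (≈650 nodes, 273 stochastic) simulates 1000
  runs × 125 steps in a few seconds on one CPU.

### Exact Markov oracle

For models of at most 16 nodes the state distribution is propagated
exactly: the reachable support is kept sparse (states as bit masks); for
each support state the per-node TRUE-probability is the probability-
weighted disjunction of its rules, and the joint successor distribution
factorises over nodes, expanded only over nodes with genuinely
probabilistic outcomes. Marginals are clipped to [0, 1] to shed
floating-point summation noise. The oracle is the reference against which
the Monte-Carlo engine is tested (agreement within 3 standard errors at
50 000 runs on all bundled small fixtures).

## Ensemble analysis

Ensemble means are arithmetic averages of the Boolean records over runs.
Oscillation metrics are deliberately simple, deterministic conventions —
not claims about any particular plotting pipeline:

- **period windows** come from the exact cycle of the noise-free
  reference trajectory (first full-state recurrence), not from spectral
  estimation;
- **amplitude** is max − min of the mean trace within a period window,
  **phase** the offset of the maximum (earliest on ties);
- **convergence** holds when max − min over a trailing window is within a
  tolerance; the *first-convergence time* is the earliest window start
  satisfying the same criterion, with "never within the horizon" reported
  as `None` and treated as +∞ in ordinal comparisons;
- the **desynchronization index** 4p(1−p) (p the cross-run mean) is 0
  when all runs agree and 1 at maximal disagreement — the variance of a
  Bernoulli(p) node normalised to [0, 1].

For convergence-time comparisons between false-rates the package's tests
use tolerance 0.2 with a one-period (24-step) window: wide enough to
register the settling of the ensemble mean toward its ~0.5 plateau, yet
strict enough that a full-swing oscillation never counts as converged.

## Fixtures and what they do (not) show

- **worked-example** — the canonical three-reaction network; exercised
  exactly (probabilities and rule structure).
- **hog-qualitative / hog-quantitative** — a simplified two-module HOG
  oscillator: a phosphotransfer chain (Sln1 → Ypd1 → Ssk1) active while
  turgor is sensed, a MAP kinase chain (Ssk2 → Pbs2 → Hog1) inhibited by
  phosphorylated Ssk1, and negative feedback where Hog1-{P} drives
  glycerol production (Gpd1 surrogate) that restores the turgor signal.
  Constitutive phosphatase reactions (Ptc1) make each phospho-state track
  its kinase with one step delay, giving a clean deterministic limit
  cycle of period 24 (≥ 11 periods in a 280-step horizon) with a 50% duty
  cycle of Hog1-{P}. The quantitative variant is derived programmatically
  by substituting ! → K+ and x → K-. The fixture is a topological
  transcription, not a curated reconstruction: it reproduces the
  mechanism class (negative-feedback oscillator with graded
  contingencies), so tests against it assert intervals and orderings
  (trailing mean in [0.4, 0.6]; period-7 amplitude < period-1 amplitude;
  earlier settling at higher false-rate), never exact trajectories.
- **noisy-pair** — a 7-node miniature for oracle-equivalence checks.
- **random networks** — seeded generators of ppi/P+ networks with a weak
  chain backbone for connectivity, contingencies drawn only among
  producible states. At the curated-reconstruction scale (142 components,
  273 reactions → ≈650 model nodes) they serve as scalability surrogates;
  they emulate size and wiring statistics, not biology, so nothing about
  pathway-level signal transfer is asserted on them.

Passing tests on these fixtures demonstrate the correctness of the
generation rules, the probability algebra, the simulator's distributional
behaviour, and the qualitative phenomenology of noisy oscillators
(desynchronization-driven damping). They do not validate any specific
biological reconstruction; real curated networks bring boundary states,
unproduced inputs and richer reaction types that are supported (warnings,
registry) but not biologically vetted here.

## Numerical choices and limitations

- Problem sizes in tests and the acceptance script: 1000 runs × 280 steps
  for oscillator ensembles, 50 000 runs × 20 steps for oracle
  equivalence, 1000 runs × 125 steps at MAPK scale — sizes at which all
  reported statistics are stable to well within their acceptance bands.
- Expression trees are lightly simplified (flattening, constant
  absorption, duplicate removal) but not minimised; tests compare rules
  by truth table, not by syntax.
- Rule-probability validation tolerates 1e-9 absolute deviation from 1.
- The oracle's hard cap of 16 nodes bounds worst-case support
  enumeration; dense-support models near the cap can still be slow.
- Only synchronous updating is implemented — no asynchronous semantics,
  no attractor-basin analysis beyond exact cycle detection, and no
  time-varying rule probabilities (the chain is time-homogeneous).
- The k → ∞ limit reproduces the strengthened (! / x) qualitative model;
  with p_FALSE = 0 and k = 10⁶ single trajectories agree with it in
  ≥ 99.9% of node-steps on the HOG fixture, the residual difference being
  the ~10⁻⁶ chance per step of sampling a less restrictive rule.
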
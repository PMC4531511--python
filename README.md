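# rxnpbn

Probabilistic bipartite Boolean networks from reaction–contingency network
definitions: automatic model generation, two-parameter parameterization,
and fast synchronous stochastic simulation of large signaling networks.

## The problem

Curated signaling-network knowledge is naturally expressed as *elemental
reactions* (decontextualized state transitions such as the protein–protein
interaction `A_ppi_B`, which produces the bond state `A--B`) together with
*contingencies* — contextual constraints of other elemental states on a
reaction: absolute requirement (`!`), absolute inhibition (`x`), or graded
positive/negative quantitative modifiers (`K+` / `K-`). Such a definition
maps one-to-one onto a **bipartite Boolean network**: reaction nodes fire
when their substrates are present and their absolute contingencies hold,
state nodes follow the reactions that produce and consume them, e.g.

```
B--C(t+1)     = B_ppi_C(t)
A--B(t+1)     = A_ppi_B(t)
A_ppi_B(t+1)  = A(t) ∧ B(t) ∧ B--C(t)      # with contingency "! B--C"
B_ppi_C(t+1)  = B(t) ∧ C(t)
```

A purely qualitative Boolean model must discard the graded `K+`/`K-`
information. This package keeps it, by turning each reaction node into a
**probabilistic Boolean network** node: a reaction with *n* quantitative
modifiers receives *n + 2* update functions — f₀ (substrates and absolutes
only), f₁ … fₙ (fᵢ additionally requires at least *i* of the modifier
conditions, as a disjunction over all i-subsets), and a constant-FALSE
rule modeling random reaction failure. Only two global parameters
parameterize the whole model:

- the **false-rate** p_FALSE — probability of the FALSE rule, and
- the **k-base** k — each more restrictive rule is k times more probable:

```
p₀ = (1 − p_FALSE) / Σᵢ₌₀ⁿ kⁱ ,     pᵢ = p₀ · kⁱ
```

At every time step each node independently samples one of its rules and
all nodes update synchronously — a Markov chain whose ensemble average
over many runs yields a semi-quantitative activation probability per node
and time.

The package is for systems biologists who already maintain
reaction–contingency (rxncon-style) network reconstructions and want
simulation-ready stochastic Boolean models without hand-tuning truth
tables or kinetic parameters.

## Worked example

The canonical three-reaction network ships as a fixture:

```
$ rxnpbn fixtures --name worked-example --out net.txt
$ cat net.txt
B_ppi_C
A_ppi_D
A_ppi_B; K+ B--C; K- A--D
$ rxnpbn build net.txt --pbn --kbase 10 --pfalse 0.1 --out model.boolnet
```

`A_ppi_B` has n = 2 quantitative modifiers (K+ B--C, K- A--D), so it gets
four rules; the contingency-free reactions get two. The exported BoolNet
file contains exactly:

```
A_ppi_B, A & B, 0.008108
A_ppi_B, A & B & (B_C | !A_D), 0.08108
A_ppi_B, A & B & B_C & !A_D, 0.810812
A_ppi_B, 0, 0.1
A_ppi_D, A & D, 0.9
A_ppi_D, 0, 0.1
B_ppi_C, B & C, 0.9
B_ppi_C, 0, 0.1
```

(p₀ = 0.9/111 ≈ 0.008108, p₁ = 10·p₀, p₂ absorbs the rounding residue so
each node's probabilities sum to exactly 1; `B_C`/`A_D` are the sanitized
names of the bond states `B--C`/`A--D`, mapped in the sidecar
`model.boolnet.names.tsv`.) Simulating an ensemble,

```
$ rxnpbn simulate --model net.txt --steps 20 --runs 10000 --seed 1 --out sim
$ head -4 sim/mean.tsv
time  B  C  A  D  B--C    A--D    A--B    B_ppi_C  A_ppi_D  A_ppi_B
0     1  1  1  1  0       0       0       0        0        0
1     1  1  1  1  0       0       0       0.8992   0.9004   0.0909
2     1  1  1  1  0.8992  0.9004  0.0909  0.9011   0.8966   0.091
```

each column is the fraction of runs in which that node is TRUE: the
contingency-free reactions fire with probability 1 − p_FALSE = 0.9, while
`A_ppi_B` starts at p₀ + p₁ ≈ 0.09 (its K+ effector `B--C` is not yet
formed, its K- effector `A--D` not yet violated) — exactly the graded
behaviour a qualitative model cannot express.

The same library API:

```python
import rxnpbn as rp

net   = rp.fixture_worked_example().network()
model = rp.build_pbn(net, rp.PBNParams(p_false=0.1, k_base=10.0))
ens   = rp.run_ensemble(model, rp.SimulationConfig(steps=280, runs=1000, seed=0))
mean  = rp.ensemble_mean(ens)
```

A larger bundled fixture, `hog-qualitative`, is a simplified two-module
HOG-pathway oscillator (phosphotransfer module gated by turgor, MAP kinase
module inhibited by it, negative feedback through glycerol). Noise-free it
oscillates with period 24; with p_FALSE = 0.01 the 1000-run ensemble mean
of `Hog1-{P}` shows damped oscillations settling near 0.5 — not because
single runs stop oscillating, but because they desynchronize
(`rxnpbn.desynchronization_index` quantifies this). Perturbation schedules
(`--clamp "Turg--Sln1@27=off"`) hold nodes at fixed values between events.

## Layout

| module | contents |
| --- | --- |
| `rxnpbn.core` | reaction-contingency dialect: parser, writer, type registry, validation |
| `rxnpbn.bbn` | qualitative bipartite model generation (reaction/state/presence rules) |
| `rxnpbn.pbn` | probabilistic rule sets, (p_FALSE, k) probability assignment, overrides |
| `rxnpbn.simulate` | synchronous stochastic engine, clamps, exact Markov oracle |
| `rxnpbn.analysis` | ensemble means, amplitude/phase per period, convergence, desynchronization |
| `rxnpbn.fixtures` | bundled networks (worked example, simplified HOG) and random network generator |
| `rxnpbn.io` / `rxnpbn.cli` | BooleanNet/BoolNet export, TSV writers, `rxnpbn` command |
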
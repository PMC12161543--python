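# netroles

Classify every node of a directed network by its role in structural
controllability and observability — **driver** (needs an independent external
input), **sensor** (must feed an independent output), **dual-identity (DS)**
(both), or **ordinary** (neither) — and predict the prevalence of each
category analytically from the degree distribution alone.

The classification rests on one maximum matching of the network's bipartite
representation (left copy = out-side, right copy = in-side, one undirected
edge per directed edge): a node is a driver iff its right copy is unmatched
and a sensor iff its left copy is unmatched. The analytic theory solves the
greedy-leaf-removal (core percolation) self-consistency equations for the
leaf/root probabilities, turns them into core and root fractions, and closes
with

```
n_D = n_S = 1 - (n_r + min(nc+, nc-))
n_DS ≈ P(0-)P(0+) + P(0-)P(1+) + P(1-)P(0+)
```

with closed forms for directed Erdős–Rényi (Poisson) and static-model
scale-free degree distributions.

## Contents

- `netroles.graph_io` — plain-text edge-list I/O, per-node role reports
- `netroles.matching` — bipartite representation, Hopcroft–Karp maximum
  matching, exhaustive brute-force oracle
- `netroles.roles` — role classification, category fractions, resampling
  over maximum matchings
- `netroles.generators` — seeded directed ER and static-model scale-free
  generators, degree-preserving double-edge-swap rewiring
- `netroles.analytic` — degree distributions (empirical / Poisson /
  scale-free), fixed-point solver, core/root fractions, closed forms,
  greedy leaf removal; includes an upper incomplete gamma valid for
  negative first argument
- `netroles.stats` — per-category mean in/out degree tables
- `netroles.cli` — `netroles` command-line entry point

## CLI

```sh
netroles classify edges.tsv -o report.tsv          # per-node roles + summary
netroles generate er --n 10000 --m 20000 --seed 1 -o er.tsv
netroles generate sf --n 10000 --m 20000 --a-in 0.5 --a-out 0.5 --seed 1 -o sf.tsv
netroles rewire er.tsv --seed 1 -o er_null.tsv     # degree-preserving null model
netroles predict --dist poisson --mean-k 2         # analytic fractions
netroles predict --dist sf --mean-k 2 --gamma 3
netroles predict --dist empirical --edges edges.tsv
netroles stats edges.tsv                           # per-category degree means
netroles batch networks_dir/ -o summary.tsv
```

Edge lists are one `source target` pair per line (any whitespace or a custom
delimiter), `#` comments ignored, single-field lines declaring isolated
nodes. All commands take `--seed` and are byte-reproducible.

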
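# Methods

## The model

`sigcircuits` quantifies the activity of *signaling circuits*: subgraphs of a
signed, directed pathway graph that connect receptor nodes (signal entry
points) to a single effector node (the terminal protein that triggers a cell
activity such as apoptosis, angiogenesis or cell-cycle progression). Node
values are normalized gene expression, used as a proxy of protein activity;
each node carries one or more genes and each edge is either an activation or
an inhibition.

An arbitrary initial signal of 1 enters at the receptors and is propagated
with the recursive product rule

```
S_n = v_n * (1 - prod_{s_a in A(n)} (1 - s_a)) * prod_{s_i in I(n)} (1 - s_i)
```

where `v_n in [0,1]` is the node's normalized expression, `A(n)` the signals
arriving over activation edges and `I(n)` those arriving over inhibition
edges. The activation factor is the probability-style union of the incoming
activations; the inhibition factor attenuates multiplicatively. The circuit's
activity for a sample is `S_effector`. Because every factor lies in `[0,1]`,
all signals stay in `[0,1]`, and on activation-only chains the rule collapses
to the product of the node values — the exactness anchor used throughout the
tests.

Conventions:

* **Receptors** are in-degree-0 nodes (an explicit `receptor` flag column
  overrides topology for fully cyclic graphs). They receive `A = {1}`, so the
  update rule applies uniformly to every node.
* **Effectors** are out-degree-0 nodes (same flag fallback). One circuit is
  extracted per effector: its members are the intersection of the set
  forward-reachable from the receptors and the set backward-reachable from
  the effector, which equals the union of all receptor-to-effector walks.
  Isolated nodes, being trivially both receptor and effector, form no
  circuit.
* A non-receptor node with no incoming activation edge inside its circuit is
  *activation-starved*: inhibition cannot create signal, so its intensity is
  0 and the circuit is flagged in the convergence report.
* Duplicate edges with conflicting signs are rejected at load time: the
  update rule defines no combination for them.

### Cycles

The rule is recursive without an intrinsic cycle policy. Acyclic circuits are
evaluated exactly in one topological sweep. Cyclic circuits use synchronous
(Jacobi) fixed-point iteration of the same map, initialized at `S_n = v_n`,
with tolerance `1e-6` and at most 100 sweeps; the map is continuous on
`[0,1]^V`, and on acyclic graphs the iteration reproduces the topological
result because signals stabilize within `|V|` sweeps (verified by a dedicated
equivalence test). Non-convergence is reported, not raised; the caller
decides.

A numerical detail: a node with exactly one activation input takes its
parent's signal directly (`1-(1-s)` is algebraically `s` but not bit-exact in
floating point), so chain propagation and the knockdown contract below are
exact to the last bit.

## Normalization

Inputs are non-negative expression matrices (genes × samples), assumed
library-size comparable (count-model normalization and batch correction are
upstream concerns; the synthetic generator produces equal library sizes by
construction). The chain is:

1. `log2(x + 1)`;
2. truncation at the global 0.99 quantile (outlier guard; per-gene mode
   available);
3. per-gene min–max scaling to `[0,1]` across samples. Genes constant across
   samples map to 0.5 — the uninformative midpoint — because 0 would
   annihilate all downstream signal for purely technical reasons.
4. gene-to-node aggregation by mean (default; min/max configurable).
   Gene-free nodes (e.g. metabolite pseudo-nodes) and nodes with no measured
   gene transmit neutrally (`v = 1`) and are listed in an audit report.

Min–max scaling makes every gene occupy the full unit interval regardless of
its variance; this is what the multiplicative rule assumes, but it also means
*pure noise is amplified to full range* for unshifted genes — see "What
passing tests show" below.

## Differential signaling activity

Per circuit, a two-sided Wilcoxon rank-sum test compares the activity
distributions of the two sample groups; Benjamini–Hochberg correction runs
jointly across all circuits of all pathways, and direction (which group is
higher) is assigned post hoc from group means for circuits with adjusted
p < 0.05. The test is exact when `n1+n2 <= 20` without ties, otherwise the
normal approximation with tie and continuity correction is used. Circuits
with zero variance across all samples are excluded before testing and
reported. The two-sided-plus-direction design lets one analysis report both
"group 1 higher" and "group 2 higher" counts.

## Drug simulation

A drug is a set of target genes. On the unit scale, target rows are replaced
by a knockdown value of 0.001 — an "almost unexpressed" gene that preserves a
small basal signal rather than absolute inhibition — and circuit activities
are recomputed. Per patient and circuit the effect is the log2 fold change
`log2((treated + eps)/(reference + eps))` with `eps = 1e-6` guarding zero
activities. Because samples are the same patients before and after the
simulated treatment, the per-drug comparison is a paired Wilcoxon signed-rank
test (zero differences dropped; all-tied circuits get p = 1). Group
differences in drug effect compare the per-patient fold-change distributions
between the groups with the rank-sum test and report both the mean fold
change per group and the raw difference of means, so the simple
mean-comparison view and a significance column are both available.

Contracts that pin the implementation down: knockdown is idempotent; on
activation-only circuits a knockdown can only lower activity; knocking down
the sole gene of the receptor of a saturated (`v = 1`) activation chain gives
treated effector activity exactly 0.001.

## Annotation

Circuit function is the function of its effector's genes, looked up in a
static TSV table; effector genes also map to the ten canonical cancer
hallmarks. A curated default table covering common signaling effectors
(VEGFA, RAD51, E2F1, RB1, …) ships with the package; users supply their own
tables for other gene universes. Unannotated effectors get the explicit term
`unannotated`. In hallmark summaries a circuit with k hallmarks contributes
to all k counts (declared in the output metadata). The pervasiveness view
lists circuits significant in at least a threshold number of conditions
(default 4).

## Synthetic data

The generator emulates the inputs of a two-cohort (e.g. male/female) RNA-seq
signaling study at desk scale:

* **Graphs.** Layered signed DAGs: receptors in the first layer, effectors in
  the last. Every non-receptor receives exactly one backbone activation
  in-edge from an earlier layer, with parents chosen preferentially among
  nodes that do not yet signal onward — a spanning forest, i.e. a branching
  cascade in which every node has in-degree 1. Convergence points are then
  introduced only by extra forward edges (probability `p_edge = 0.1` per
  eligible pair, inhibitory with probability 0.1), and only into middle
  nodes: effectors are cascade termini with a single input. Optional
  back-edges produce cycles. Defaults (12 nodes, 2 receptors, 4 effectors, 5
  pathways) give ~20 circuits of ~4–7 nodes — small, mostly linear cascades,
  the regime the circuit decomposition of curated pathway databases actually
  produces.
* **Expression.** Negative-binomial counts (dispersion 0.1, i.e. a
  biological CV of ~0.32, typical of bulk RNA-seq cohorts) with gene-level
  base means log-normal around 500. A chosen subset of genes is shifted by
  `2**effect_log2fc` in group 1 only. Counts rather than unit values are
  generated so the normalization module is exercised end to end.
* **Ground truth.** A circuit is *expected differential* when at least one
  shifted gene lies on a node with an activation-only path to the effector
  (propagation is monotone along such paths, so the direction of the effect
  is unambiguous); a circuit containing no shifted gene is *expected null*;
  circuits touched only through inhibition edges stay unlabeled and are
  excluded from recovery metrics. The label is structural — independent of
  the effect size — so sensitivity is comparable across an effect-size grid.
* Everything is a pure function of `(seed, params)`; regeneration is
  bit-identical.

### What passing tests show — and what they do not

Because min–max scaling spreads each unshifted gene's noise over the full
unit interval, the effector signal of a circuit is a product of one shifted
factor and `L-1` noise factors. The planted effect is therefore recovered
reliably only when circuits are short and convergence-free along the shifted
branch: at a merge point the activation union `1-(1-a)(1-b)` saturates, and a
shift in one branch moves the product by only a fraction of its size. This is
a property of the model, not of the implementation; it is why the generator's
defaults produce cascade-like circuits, and it is what the recovery tests
(sensitivity ≥ 0.8 at a 4-fold shift, 30 samples/group, observed FDR ≤ 0.1)
do and do not demonstrate about real cohorts: real pathway graphs with heavy
convergence, correlated genes, batch structure and covariate imbalance will
generally need larger cohorts for the same power. The generator does not
emulate the covariate structure of real tumor cohorts (age, stage, purity),
batch effects, or matched-cohort construction.

## Problem sizes and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `quantile_q` | 0.99 | truncation quantile, global over the matrix |
| `aggregation_rule` | mean | gene-to-node aggregation |
| constant-gene value | 0.5 | unit value for zero-variance genes |
| neutral node value | 1.0 | unmeasured/gene-free nodes transmit the signal |
| `initial_signal` | 1.0 | activation input injected at receptors |
| `tol`, `max_iter` | 1e-6, 100 | fixed-point scheme for cyclic circuits |
| `knockdown_value` | 0.001 | unit-scale expression of a drugged target |
| `epsilon_fc` | 1e-6 | additive guard in log2 fold changes |
| `alpha` | 0.05 | FDR threshold for significance and direction |
| scenario scale | 5 pathways × 12 nodes, 30/group | desk-scale study size |

The statistical validation runs (null calibration over 20 seeds, planted
recovery at three effect sizes) use the desk-scale scenario above and
complete in seconds on one CPU; they are sized as the package's standard
validation suite, and all sizes are configurable.

## Known limitations

* Steady-state only: no kinetics, no time courses, no edge-weight fitting.
* mRNA abundance stands in for protein activity; post-transcriptional
  regulation is invisible except through its downstream expression footprint.
* The cycle policy (synchronous fixed point) is this package's declared
  choice; other schedules converge to the same fixed point on contractive
  instances but are not guaranteed to in general.
* Hallmark and function tables are static inputs; no literature mining or
  live database lookups.
* The group-difference drug analysis compares fold-change distributions; it
  does not model dose, pharmacokinetics or drug combinations.
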
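"""Synthetic pathway graphs and two-group expression data with ground truth.

The generator emulates the inputs of a two-cohort signaling study: layered
signed pathway graphs with a guaranteed activation backbone from receptors to
effectors, and negative-binomial RNA-seq-like count matrices in which a
chosen subset of genes is shifted by a known log2 fold change in one group.
Because every stage of the pipeline runs on these inputs, the whole analysis
is testable at desk scale with a known answer.

Ground-truth labels: a circuit is *expected differential* (``truth_gsdsa``)
when at least one shifted gene sits on a node with an activation-only path to
the circuit's effector (signal propagation is monotone along such paths); a
circuit containing no shifted gene at all is *expected null*.  Circuits
touched by a shifted gene only through inhibition edges have sign-ambiguous
effects and stay unlabeled.  The structural label set does not depend on the
effect size, so sensitivity is comparable across effect-size grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .drugs import DrugSpec
from .normalization import GeneExpressionMatrix
from .pathway import (
    ACTIVATION,
    INHIBITION,
    Circuit,
    EdgeRecord,
    NodeRecord,
    PathwayGraph,
    extract_all_circuits,
)

DEFAULT_DISPERSION = 0.1
DEFAULT_BASE_MEAN = 500.0
DEFAULT_GROUPS = ("G1", "G2")


@dataclass
class SyntheticScenario:
    """A generated study: graphs, expression, labels, drugs and truth sets."""

    graphs: list[PathwayGraph]
    expression: GeneExpressionMatrix
    labels: pd.Series
    drugs: list[DrugSpec]
    truth_gsdsa: frozenset[str]
    truth_null: frozenset[str]
    seed: int
    params: dict = field(default_factory=dict)
    circuits: list[Circuit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.truth_gsdsa & self.truth_null:
            raise InputError("truth sets must be disjoint")
        if not self.circuits:
            self.circuits = extract_all_circuits(self.graphs)
        known = {c.circuit_id for c in self.circuits}
        missing = (self.truth_gsdsa | self.truth_null) - known
        if missing:
            raise InputError(f"truth circuits not in extracted set: {missing}")


# ---------------------------------------------------------------------------
# graph generation
# ---------------------------------------------------------------------------

def generate_pathway(
    n_nodes: int,
    p_edge: float = 0.1,
    p_inhibition: float = 0.1,
    n_receptors: int = 2,
    n_effectors: int = 4,
    allow_cycles: bool = False,
    seed: int = 0,
    pathway_id: str | None = None,
    n_genes_per_node: int = 1,
) -> PathwayGraph:
    """Layered signed DAG (optionally with back-edges) with known structure.

    Receptors occupy the first layer, effectors the last; every non-receptor
    node gets one guaranteed activation in-edge from an earlier layer (the
    backbone), so every effector is reachable from a receptor via a pure
    activation path.  Additional forward edges appear with probability
    ``p_edge`` and are inhibitory with probability ``p_inhibition``.  With
    ``allow_cycles`` back-edges between middle layers are injected.
    """
    if n_nodes < n_receptors + n_effectors:
        raise InputError("n_nodes must be >= n_receptors + n_effectors")
    if n_receptors < 1 or n_effectors < 1:
        raise InputError("need at least one receptor and one effector")
    for p in (p_edge, p_inhibition):
        if not 0.0 <= p <= 1.0:
            raise InputError("probabilities must lie in [0,1]")

    rng = np.random.default_rng(seed)
    pid = pathway_id or f"pw{seed}"
    n_mid = n_nodes - n_receptors - n_effectors

    ids = [f"n{i:02d}" for i in range(n_nodes)]
    receptors = ids[:n_receptors]
    middles = ids[n_receptors:n_receptors + n_mid]
    effectors = ids[n_receptors + n_mid:]

    n_mid_layers = min(3, n_mid) if n_mid else 0
    layer: dict[str, int] = {r: 0 for r in receptors}
    for m in middles:
        layer[m] = 1 + int(rng.integers(0, n_mid_layers))
    last = n_mid_layers + 1
    for e in effectors:
        layer[e] = last

    edges: dict[tuple[str, str], str] = {}
    out_deg: dict[str, int] = {n: 0 for n in ids}

    # Activation backbone: every non-receptor gets exactly one activation
    # in-edge from an earlier layer, preferring parents that do not yet
    # signal onward.  The result is a branching cascade (a spanning forest
    # rooted at the receptors) in which convergence points are introduced
    # only by the extra p_edge edges below — mirroring the mostly linear
    # receptor-to-effector cascades of curated signaling pathways.
    for v in middles + effectors:
        pool = [u for u in ids if layer[u] < layer[v] and u not in effectors]
        if not pool:
            raise InputError("infeasible layering: no eligible backbone parent")
        dangling = [u for u in pool if out_deg[u] == 0]
        pick_from = dangling or pool
        u = pick_from[int(rng.integers(0, len(pick_from)))]
        edges[(u, v)] = ACTIVATION
        out_deg[u] += 1

    # any non-effector still without a child signals to the next layer
    for u in receptors + middles:
        if out_deg[u] == 0:
            pool = [v for v in ids if layer[v] > layer[u] and v not in receptors]
            v = pool[int(rng.integers(0, len(pool)))]
            edges[(u, v)] = ACTIVATION
            out_deg[u] += 1

    # Extra forward edges create mid-cascade convergence points.  Effectors
    # are excluded as targets: they are cascade termini with a single input,
    # so branching and merging happen upstream of them.
    for u in ids:
        if u in effectors:
            continue
        for v in middles:
            if layer[v] <= layer[u] or (u, v) in edges:
                continue
            if rng.random() < p_edge:
                sign = INHIBITION if rng.random() < p_inhibition else ACTIVATION
                edges[(u, v)] = sign

    if allow_cycles and n_mid >= 2:
        for u in middles:
            for v in middles:
                if layer[v] >= layer[u] or (u, v) in edges:
                    continue
                if rng.random() < p_edge / 2.0:
                    sign = INHIBITION if rng.random() < p_inhibition else ACTIVATION
                    edges[(u, v)] = sign

    nodes = {}
    for nid in ids:
        genes = tuple(f"g_{pid}_{nid}" if j == 0 else f"g_{pid}_{nid}_{j}"
                      for j in range(n_genes_per_node))
        nodes[nid] = NodeRecord(node_id=nid, genes=genes, label=nid)
    edge_records = [EdgeRecord(u, v, s) for (u, v), s in sorted(edges.items())]
    return PathwayGraph(pathway_id=pid, nodes=nodes, edges=edge_records)


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

def generate_expression(
    graphs: PathwayGraph | Iterable[PathwayGraph],
    n_per_group: int = 30,
    de_genes: Iterable[str] = (),
    effect_log2fc: float = 1.0,
    dispersion: float = DEFAULT_DISPERSION,
    base_mean: float = DEFAULT_BASE_MEAN,
    seed: int = 0,
    group_names: tuple[str, str] = DEFAULT_GROUPS,
) -> tuple[GeneExpressionMatrix, pd.Series]:
    """Negative-binomial counts for the union of the graphs' genes.

    Gene base means are log-normal around ``base_mean``; ``de_genes`` have
    their mean multiplied by ``2**effect_log2fc`` in the first group only.
    ``dispersion`` is the NB dispersion (var = mu + dispersion * mu^2); at
    dispersion 0 counts are Poisson.  Library sizes are equal in expectation
    by construction.
    """
    if isinstance(graphs, PathwayGraph):
        graphs = [graphs]
    if n_per_group < 3:
        raise InputError("n_per_group must be >= 3")
    genes = sorted({g for gr in graphs for g in gr.gene_universe()})
    de = sorted(set(de_genes))
    unknown = [g for g in de if g not in genes]
    if unknown:
        raise InputError(f"de_genes not present in graphs: {unknown[:5]}")

    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    n_samples = 2 * n_per_group
    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)

    mu = np.tile(base[:, None], (1, n_samples))
    de_idx = [genes.index(g) for g in de]
    if de_idx:
        mu[np.ix_(de_idx, range(n_per_group))] *= 2.0 ** effect_log2fc

    if dispersion <= 1e-12:
        counts = rng.poisson(mu).astype(float)
    else:
        r = 1.0 / dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p).astype(float)

    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    labels = pd.Series(
        [group_names[0]] * n_per_group + [group_names[1]] * n_per_group,
        index=samples, name="group")
    expr = GeneExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), scale="raw")
    return expr, labels


# ---------------------------------------------------------------------------
# ground truth and scenarios
# ---------------------------------------------------------------------------

def activation_upstream_nodes(circuit: Circuit) -> frozenset[str]:
    """Member nodes with an activation-only directed path to the effector
    (the effector itself included)."""
    parents: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    for e in circuit.member_edges:
        if e.sign == ACTIVATION:
            parents[e.target].append(e.source)
    reached = {circuit.effector}
    frontier = [circuit.effector]
    while frontier:
        n = frontier.pop()
        for p in parents[n]:
            if p not in reached:
                reached.add(p)
                frontier.append(p)
    return frozenset(reached)


def _node_gene_lookup(graphs: Sequence[PathwayGraph]) -> dict[str, dict[str, tuple[str, ...]]]:
    return {g.pathway_id: {nid: rec.genes for nid, rec in g.nodes.items()}
            for g in graphs}


def label_truth(
    graphs: Sequence[PathwayGraph],
    circuits: Sequence[Circuit],
    de_genes: Iterable[str],
) -> tuple[frozenset[str], frozenset[str]]:
    """Structural truth sets for a set of shifted genes (see module docstring)."""
    de = set(de_genes)
    lookup = _node_gene_lookup(graphs)
    gsdsa, null = set(), set()
    for c in circuits:
        genes_of = lookup[c.pathway_id]
        member_genes = {g for n in c.member_nodes for g in genes_of[n]}
        if not member_genes & de:
            null.add(c.circuit_id)
            continue
        act_nodes = activation_upstream_nodes(c)
        act_genes = {g for n in act_nodes for g in genes_of[n]}
        if act_genes & de:
            gsdsa.add(c.circuit_id)
        # else: inhibition-only influence, unlabeled
    return frozenset(gsdsa), frozenset(null)


def generate_scenario(
    seed: int,
    n_pathways: int = 5,
    n_nodes: int = 12,
    n_per_group: int = 30,
    n_de_genes: int = 10,
    effect_log2fc: float = 1.0,
    dispersion: float = DEFAULT_DISPERSION,
    base_mean: float = DEFAULT_BASE_MEAN,
    p_edge: float = 0.1,
    p_inhibition: float = 0.1,
    n_receptors: int = 2,
    n_effectors: int = 4,
    allow_cycles: bool = False,
    n_drugs: int = 1,
    knockdown_value: float = 0.001,
    group_names: tuple[str, str] = DEFAULT_GROUPS,
) -> SyntheticScenario:
    """One complete synthetic study, fully determined by (seed, params).

    Shifted (group-biased) genes are drawn from nodes that have an
    activation-only path to some effector, so each carries an unambiguous
    expected direction of effect on at least one circuit.
    """
    params = dict(
        n_pathways=n_pathways, n_nodes=n_nodes, n_per_group=n_per_group,
        n_de_genes=n_de_genes, effect_log2fc=effect_log2fc,
        dispersion=dispersion, base_mean=base_mean, p_edge=p_edge,
        p_inhibition=p_inhibition, n_receptors=n_receptors,
        n_effectors=n_effectors, allow_cycles=allow_cycles, n_drugs=n_drugs,
        knockdown_value=knockdown_value, group_names=list(group_names),
    )
    master = np.random.default_rng(seed)
    pathway_seeds = master.integers(0, 2 ** 31 - 1, size=n_pathways)
    expr_seed = int(master.integers(0, 2 ** 31 - 1))

    graphs = [
        generate_pathway(
            n_nodes=n_nodes, p_edge=p_edge, p_inhibition=p_inhibition,
            n_receptors=n_receptors, n_effectors=n_effectors,
            allow_cycles=allow_cycles, seed=int(s), pathway_id=f"P{i + 1}")
        for i, s in enumerate(pathway_seeds)
    ]
    circuits = extract_all_circuits(graphs)
    lookup = _node_gene_lookup(graphs)

    candidates = sorted({
        g for c in circuits for n in activation_upstream_nodes(c)
        for g in lookup[c.pathway_id][n]
    })
    if not candidates:
        raise InputError("no candidate genes on activation paths")
    k = min(n_de_genes, len(candidates))
    de_genes = sorted(master.choice(candidates, size=k, replace=False).tolist())

    expr, labels = generate_expression(
        graphs, n_per_group=n_per_group, de_genes=de_genes,
        effect_log2fc=effect_log2fc, dispersion=dispersion,
        base_mean=base_mean, seed=expr_seed, group_names=group_names)

    truth_gsdsa, truth_null = label_truth(graphs, circuits, de_genes)

    drugs = []
    target_pool = sorted(set(candidates) - set(de_genes)) or candidates
    for i in range(n_drugs):
        t = str(master.choice(target_pool))
        drugs.append(DrugSpec(f"drug{i + 1:02d}", (t,), knockdown_value))

    params["de_genes"] = de_genes
    return SyntheticScenario(
        graphs=graphs, expression=expr, labels=labels, drugs=drugs,
        truth_gsdsa=truth_gsdsa, truth_null=truth_null, seed=seed,
        params=params, circuits=circuits)


def evaluate_recovery(
    results: pd.DataFrame, scenario: SyntheticScenario,
) -> tuple[float, float, float]:
    """(sensitivity, specificity, observed FDR) against the truth sets.

    Sensitivity is over ``truth_gsdsa``, specificity over ``truth_null``;
    observed FDR is the fraction of declared positives (among labeled
    circuits) that are truth-null, with the 0/0 convention -> 0.
    """
    have = set(results["circuit_id"])
    missing = (scenario.truth_gsdsa | scenario.truth_null) - have
    if missing:
        raise InputError(f"results lack truth circuits: {sorted(missing)[:5]}")
    sig = set(results.loc[results["significant"].astype(bool), "circuit_id"])
    tp = len(sig & scenario.truth_gsdsa)
    fp = len(sig & scenario.truth_null)
    tn = len(scenario.truth_null - sig)
    sens = tp / len(scenario.truth_gsdsa) if scenario.truth_gsdsa else float("nan")
    spec = tn / len(scenario.truth_null) if scenario.truth_null else float("nan")
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return sens, spec, fdr


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> None:
    """Write the scenario as the tabular bundle the pipeline consumes:
    nodes/edges/expr/labels/drugs/truth TSVs plus a params JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    node_rows, edge_rows = [], []
    for g in scenario.graphs:
        for nid in sorted(g.nodes):
            rec = g.nodes[nid]
            node_rows.append({"pathway_id": g.pathway_id, "node_id": nid,
                              "genes": ";".join(rec.genes), "label": rec.label})
        for e in g.edges:
            edge_rows.append({"pathway_id": g.pathway_id, "source": e.source,
                              "target": e.target, "sign": e.sign})
    pd.DataFrame(node_rows).to_csv(out / "nodes.tsv", sep="\t", index=False)
    pd.DataFrame(edge_rows).to_csv(out / "edges.tsv", sep="\t", index=False)

    scenario.expression.write_tsv(out / "expr.tsv")
    labels = scenario.labels.rename_axis("sample_id").reset_index()
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)

    pd.DataFrame([{"drug_name": d.drug_name, "targets": ";".join(d.targets)}
                  for d in scenario.drugs]).to_csv(
        out / "drugs.tsv", sep="\t", index=False)

    truth_rows = (
        [{"circuit_id": c, "truth": "gsdsa"} for c in sorted(scenario.truth_gsdsa)]
        + [{"circuit_id": c, "truth": "null"} for c in sorted(scenario.truth_null)])
    pd.DataFrame(truth_rows, columns=["circuit_id", "truth"]).to_csv(
        out / "truth.tsv", sep="\t", index=False)

    with open(out / "scenario_params.json", "w") as fh:
        json.dump({"seed": scenario.seed, "params": scenario.params}, fh,
                  indent=2, sort_keys=True)
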
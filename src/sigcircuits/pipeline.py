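"""One-shot end-to-end pipeline: expression -> activities -> differential
signaling -> drug simulation -> annotation summaries.

Every stage writes its result as plain TSV into the output directory and a
``manifest.json`` records the resolved configuration, package version and
stage timings, so a run is fully reproducible from its output bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    annotate_circuits,
    default_function_table,
    default_hallmark_table,
    hallmark_summary,
    load_function_table,
    load_hallmark_table,
)
from .differential import DEFAULT_ALPHA, count_significant, differential_signaling
from .drugs import (
    DEFAULT_FC_EPSILON,
    DEFAULT_KNOCKDOWN,
    FoldChangeMatrix,
    differential_drug_effect,
    load_drugs,
    paired_drug_test,
    simulate_drug,
)
from .exceptions import InputError, SigCircuitsError
from .normalization import GeneExpressionMatrix, node_values, normalize_pipeline
from .pathway import extract_all_circuits, load_pathway_collection, write_circuits
from .propagation import (
    DEFAULT_INITIAL_SIGNAL,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    compute_activity_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    nodes: str
    edges: str
    expr: str
    labels: str
    out_dir: str
    drugs: str | None = None
    functions: str | None = None
    hallmarks: str | None = None
    quantile_q: float = 0.99
    per_gene_quantile: bool = False
    aggregation_rule: str = "mean"
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    initial_signal: float = DEFAULT_INITIAL_SIGNAL
    knockdown_value: float = DEFAULT_KNOCKDOWN
    epsilon_fc: float = DEFAULT_FC_EPSILON
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    log_level: str = "INFO"
    expr_scale: str = "raw"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise InputError(f"{what} path not configured")
    p = Path(path)
    if not p.exists():
        raise InputError(f"{what} file not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle.

    Returns the manifest dict.  Raises :class:`SigCircuitsError` (with stage
    context) on any stage failure; the CLI maps that to a non-zero exit.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "setup"

    def tick(name: str):
        nonlocal stage
        timings[stage] = round(time.perf_counter() - tick.t0, 4)
        stage, tick.t0 = name, time.perf_counter()

    tick.t0 = time.perf_counter()
    try:
        stage = "load"
        graphs = load_pathway_collection(_require(config.nodes, "nodes"),
                                         _require(config.edges, "edges"))
        expr = GeneExpressionMatrix.read_tsv(_require(config.expr, "expr"),
                                             scale=config.expr_scale)
        labels_df = pd.read_csv(_require(config.labels, "labels"), sep="\t",
                                dtype=str)
        if not {"sample_id", "group"} <= set(labels_df.columns):
            raise InputError("labels file needs columns sample_id, group")
        labels = labels_df.set_index("sample_id")["group"]

        tick("normalize")
        if expr.scale == "unit":
            unit = expr
        else:
            unit = normalize_pipeline(expr, q=config.quantile_q,
                                      per_gene_quantile=config.per_gene_quantile)

        tick("node_values")
        nvm = node_values(unit, graphs, rule=config.aggregation_rule)
        nvm.report.to_csv(out / "node_value_report.tsv", sep="\t", index=False)

        tick("circuits")
        circuits = extract_all_circuits(graphs)
        write_circuits(circuits, out / "circuits.tsv")

        tick("activity")
        act = compute_activity_matrix(
            circuits, nvm, tol=config.tol, max_iter=config.max_iter,
            initial_signal=config.initial_signal)
        act.write_tsv(out / "activity.tsv")
        act.convergence.to_csv(out / "convergence.tsv", sep="\t", index=False)

        tick("differential")
        results = differential_signaling(act, labels, alpha=config.alpha)
        results.to_csv(out / "gsdsa.tsv", sep="\t", index=False)
        n_total, n_g1, n_g2 = count_significant(results, alpha=config.alpha)

        tick("drugs")
        groups = sorted(labels.unique())
        drug_summaries = []
        if config.drugs:
            drugs = load_drugs(_require(config.drugs, "drugs"),
                               knockdown_value=config.knockdown_value)
            for drug in drugs:
                ref_act, trt_act, fc = simulate_drug(
                    circuits, graphs, unit, drug,
                    rule=config.aggregation_rule, epsilon=config.epsilon_fc,
                    tol=config.tol, max_iter=config.max_iter,
                    initial_signal=config.initial_signal)
                prefix = out / f"drug_{drug.drug_name}"
                fc_out = fc.data.copy()
                fc_out.index.name = "circuit_id"
                fc_out.to_csv(f"{prefix}_fc.tsv", sep="\t")
                paired = paired_drug_test(ref_act, trt_act, alpha=config.alpha)
                paired.to_csv(f"{prefix}_paired.tsv", sep="\t", index=False)
                if len(groups) == 2:
                    g1, g2 = groups
                    s1 = [s for s in fc.data.columns if labels[s] == g1]
                    s2 = [s for s in fc.data.columns if labels[s] == g2]
                    diff = differential_drug_effect(
                        FoldChangeMatrix(fc.data[s1], fc.epsilon),
                        FoldChangeMatrix(fc.data[s2], fc.epsilon),
                        group_names=(g1, g2), alpha=config.alpha)
                    diff.to_csv(f"{prefix}_group_diff.tsv", sep="\t",
                                index=False)
                    n_drug_sig = int(diff["significant"].sum())
                else:
                    n_drug_sig = None
                drug_summaries.append({"drug": drug.drug_name,
                                       "n_group_diff_significant": n_drug_sig})

        tick("annotation")
        functions = (load_function_table(config.functions) if config.functions
                     else default_function_table())
        hallmarks = (load_hallmark_table(config.hallmarks) if config.hallmarks
                     else default_hallmark_table())
        effector_genes = {
            n: g.nodes[n].genes for g in graphs for n in g.nodes}
        annotated = annotate_circuits(circuits, functions, hallmarks,
                                      effector_genes=effector_genes)
        annotated.to_csv(out / "annotated_circuits.tsv", sep="\t", index=False)
        summary = hallmark_summary(results, annotated)
        summary.to_csv(out / "hallmark_summary.tsv", sep="\t", index=False)

        tick("done")
    except SigCircuitsError as exc:
        raise SigCircuitsError(f"stage {stage!r} failed: {exc}") from exc

    cfg = asdict(config)
    manifest = {
        "package": "sigcircuits",
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "n_circuits": len(circuits),
        "gsdsa": {"n_significant": n_total, "n_group1_higher": n_g1,
                  "n_group2_higher": n_g2},
        "drugs": drug_summaries,
        "timings_s": timings,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
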
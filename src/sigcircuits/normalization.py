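"""Expression normalization to the [0,1] node-activity scale.

The propagation rule consumes normalized gene expression values in [0,1] as
proxies of protein activity.  The pipeline here is: ``log2(x+1)`` transform of
non-negative expression values, truncation at a high quantile to tame
outliers, min-max scaling to the unit interval, and aggregation of gene-level
values to pathway-node values.

Upstream count-model normalization (library-size / batch correction) is
assumed done before these steps; the synthetic generator produces equal
library sizes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import FormatError, InputError
from .pathway import PathwayGraph, node_key

Scale = Literal["raw", "log", "unit"]
AggRule = Literal["mean", "min", "max"]

#: Value given to pathway nodes without any measured gene: the node transmits
#: the incoming signal unchanged instead of annihilating it.
NEUTRAL_NODE_VALUE = 1.0
#: Unit-scale value for genes constant across samples (uninformative midpoint).
CONSTANT_GENE_VALUE = 0.5


@dataclass
class GeneExpressionMatrix:
    """Genes x samples expression matrix with an explicit scale tag."""

    data: pd.DataFrame
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate gene symbols in expression matrix")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        if self.scale == "unit":
            vals = self.data.to_numpy()
            if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
                raise InputError("scale='unit' requires all values in [0,1]")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def read_tsv(cls, path: str | Path, scale: Scale = "raw") -> "GeneExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df.astype(float), scale=scale)

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass
class NodeValueMatrix:
    """Pathway-node x sample values in [0,1] (the v_n inputs of propagation).

    ``report`` records, per node, how many genes backed the value and whether
    the node fell back to the neutral value (gene-free node or no measured
    gene), so silent neutral transmission stays auditable.
    """

    data: pd.DataFrame
    report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise InputError("node values must lie in [0,1]")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def log_transform(m: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """log2(x + 1); requires raw non-negative input."""
    if m.scale != "raw":
        raise InputError(f"log_transform expects scale='raw', got {m.scale!r}")
    if (m.data.to_numpy() < 0).any():
        raise InputError("negative expression values")
    return GeneExpressionMatrix(np.log2(m.data + 1.0), scale="log")


def truncate_quantile(
    m: GeneExpressionMatrix, q: float = 0.99, per_gene: bool = False,
) -> GeneExpressionMatrix:
    """Cap values above the q-quantile at that quantile.

    Global over the whole matrix by default; ``per_gene=True`` caps each gene
    row at its own quantile.
    """
    if not 0.0 < q < 1.0:
        raise InputError("quantile q must be in (0, 1)")
    df = m.data.copy()
    if per_gene:
        caps = df.quantile(q, axis=1)
        df = df.clip(upper=caps, axis=0)
    else:
        cap = float(np.quantile(df.to_numpy(), q))
        df = df.clip(upper=cap)
    return GeneExpressionMatrix(df, scale=m.scale)


def scale_unit(m: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Per-gene min-max scaling across samples onto [0,1].

    Genes constant across all samples map to the uninformative midpoint 0.5
    rather than 0, which would annihilate all downstream signal for purely
    technical reasons.
    """
    vals = m.data.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (vals - lo) / span
    scaled[constant, :] = CONSTANT_GENE_VALUE
    out = pd.DataFrame(scaled, index=m.data.index, columns=m.data.columns)
    return GeneExpressionMatrix(out, scale="unit")


def normalize_pipeline(
    m: GeneExpressionMatrix, q: float = 0.99, per_gene_quantile: bool = False,
) -> GeneExpressionMatrix:
    """log -> quantile truncation -> unit scaling, the standard chain."""
    return scale_unit(truncate_quantile(log_transform(m), q=q,
                                        per_gene=per_gene_quantile))


def node_values(
    m: GeneExpressionMatrix,
    graphs: PathwayGraph | Iterable[PathwayGraph],
    rule: AggRule = "mean",
    neutral_value: float = NEUTRAL_NODE_VALUE,
) -> NodeValueMatrix:
    """Aggregate unit-scale gene values to pathway-node values.

    Per node and sample, the mean (default), min or max over the node's genes
    present in the matrix.  Gene-free nodes and nodes whose genes are all
    unmeasured receive ``neutral_value`` and are flagged in the report.
    Node rows are indexed by ``pathway_id::node_id``.
    """
    if m.scale != "unit":
        raise InputError("node_values requires scale='unit' input")
    if rule not in ("mean", "min", "max"):
        raise InputError(f"unknown aggregation rule {rule!r}")
    if isinstance(graphs, PathwayGraph):
        graphs = [graphs]

    gene_index = {g: i for i, g in enumerate(m.data.index)}
    vals = m.data.to_numpy(dtype=float)
    agg = {"mean": np.mean, "min": np.min, "max": np.max}[rule]

    rows, keys, report_rows = [], [], []
    for graph in graphs:
        for nid in sorted(graph.nodes):
            rec = graph.nodes[nid]
            idx = [gene_index[g] for g in rec.genes if g in gene_index]
            key = node_key(graph.pathway_id, nid)
            if not idx:
                row = np.full(vals.shape[1], neutral_value)
                reason = "gene_free" if rec.is_gene_free else "no_measured_gene"
                flagged = True
            else:
                row = agg(vals[idx, :], axis=0)
                reason = ""
                flagged = len(idx) < len(rec.genes)
                if flagged:
                    reason = "partial_gene_coverage"
            rows.append(row)
            keys.append(key)
            report_rows.append({
                "node": key, "n_genes": len(rec.genes), "n_measured": len(idx),
                "flagged": flagged, "reason": reason,
            })

    data = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, vals.shape[1])),
                        index=keys, columns=m.data.columns)
    report = pd.DataFrame(report_rows,
                          columns=["node", "n_genes", "n_measured", "flagged",
                                   "reason"])
    return NodeValueMatrix(data=data, report=report)
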
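"""Signed pathway graphs and their decomposition into effector circuits.

A pathway is a directed graph whose nodes represent proteins (each backed by
one or more genes; gene-free pseudo-nodes such as metabolites are allowed) and
whose edges carry an *activation* or *inhibition* sign.  Receptors are the
entry points of the signal (in-degree-0 nodes by default, or an explicit
``receptor`` flag in the node table) and effectors are the terminal nodes
(out-degree 0) whose proteins trigger cell activities.

A *circuit* is the subgraph of all receptor-to-effector paths ending at one
effector: the unit at which signaling activity is quantified and compared
between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .exceptions import FormatError, IntegrityError, StructuralError

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"

#: Sign tokens accepted out of the box; extend via the ``sign_aliases``
#: argument of :func:`load_pathway`.
DEFAULT_SIGN_ALIASES: dict[str, str] = {
    "activation": ACTIVATION,
    "inhibition": INHIBITION,
    "activate": ACTIVATION,
    "inhibit": INHIBITION,
    "+": ACTIVATION,
    "-": INHIBITION,
    "1": ACTIVATION,
    "-1": INHIBITION,
}


def node_key(pathway_id: str, node_id: str) -> str:
    """Globally unique node identifier used to index node-value matrices."""
    return f"{pathway_id}::{node_id}"


@dataclass(frozen=True)
class EdgeRecord:
    """A signed directed edge; the sign decides whether the transmitted
    signal enters the activation set A or the inhibition set I of the
    propagation rule."""

    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise FormatError(f"unknown edge sign {self.sign!r}")


@dataclass(frozen=True)
class NodeRecord:
    """A pathway node holding an ordered gene list (possibly empty)."""

    node_id: str
    genes: tuple[str, ...] = ()
    label: str = ""
    receptor_flag: bool = False
    effector_flag: bool = False

    @property
    def is_gene_free(self) -> bool:
        return len(self.genes) == 0


@dataclass
class PathwayGraph:
    """A validated signed directed pathway graph."""

    pathway_id: str
    nodes: dict[str, NodeRecord]
    edges: list[EdgeRecord]
    _nx: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        self._nx = g

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for e in self.edges:
            if e.source not in self.nodes:
                raise IntegrityError(
                    f"{self.pathway_id}: edge references unknown node {e.source!r}")
            if e.target not in self.nodes:
                raise IntegrityError(
                    f"{self.pathway_id}: edge references unknown node {e.target!r}")
            if e.source == e.target:
                raise IntegrityError(
                    f"{self.pathway_id}: self-loop on node {e.source!r}")
            prev = seen.get((e.source, e.target))
            if prev is not None and prev != e.sign:
                raise IntegrityError(
                    f"{self.pathway_id}: duplicate edge {e.source}->{e.target} "
                    f"with conflicting signs")
            seen[(e.source, e.target)] = e.sign

    # -- convenience ------------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        return self._nx

    def gene_universe(self) -> list[str]:
        """Sorted union of all genes on the pathway's nodes."""
        return sorted({g for n in self.nodes.values() for g in n.genes})


@dataclass(frozen=True)
class Circuit:
    """All receptor-to-effector paths terminating at one effector node."""

    circuit_id: str
    pathway_id: str
    effector: str
    receptors: frozenset[str]
    member_nodes: frozenset[str]
    member_edges: tuple[EdgeRecord, ...]

    def node_keys(self) -> list[str]:
        return [node_key(self.pathway_id, n) for n in sorted(self.member_nodes)]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    return pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)


def _parse_flag(value) -> bool:
    return str(value).strip() in ("1", "true", "True", "yes")


def load_pathway(
    node_table,
    edge_table,
    pathway_id: str = "pathway",
    gene_delimiter: str = ";",
    sign_aliases: Mapping[str, str] | None = None,
) -> PathwayGraph:
    """Load one pathway from node and edge tables (TSV paths or DataFrames).

    The node table needs columns ``node_id`` and ``genes`` (delimiter-joined,
    may be empty); optional columns ``label``, ``receptor``, ``effector``
    (0/1 flags).  The edge table needs ``source``, ``target``, ``sign``.
    Duplicate identical edges are collapsed with a warning; duplicate edges
    with conflicting signs are an integrity error.
    """
    nodes_df = _as_frame(node_table)
    edges_df = _as_frame(edge_table)
    for col in ("node_id", "genes"):
        if col not in nodes_df.columns:
            raise FormatError(f"node table missing column {col!r}")
    for col in ("source", "target", "sign"):
        if col not in edges_df.columns:
            raise FormatError(f"edge table missing column {col!r}")

    aliases = dict(DEFAULT_SIGN_ALIASES)
    if sign_aliases:
        aliases.update({k.lower(): v for k, v in sign_aliases.items()})

    nodes: dict[str, NodeRecord] = {}
    for _, row in nodes_df.iterrows():
        nid = str(row["node_id"]).strip()
        if nid in nodes:
            raise IntegrityError(f"{pathway_id}: duplicate node id {nid!r}")
        raw_genes = str(row["genes"]).strip()
        genes = tuple(g.strip() for g in raw_genes.split(gene_delimiter) if g.strip())
        nodes[nid] = NodeRecord(
            node_id=nid,
            genes=genes,
            label=str(row.get("label", "") or ""),
            receptor_flag=_parse_flag(row.get("receptor", "0")),
            effector_flag=_parse_flag(row.get("effector", "0")),
        )

    edges: list[EdgeRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for _, row in edges_df.iterrows():
        token = str(row["sign"]).strip().lower()
        if token not in aliases:
            raise FormatError(f"{pathway_id}: unknown sign token {row['sign']!r}")
        rec = EdgeRecord(str(row["source"]).strip(), str(row["target"]).strip(),
                         aliases[token])
        key = (rec.source, rec.target, rec.sign)
        if key in seen:
            logger.warning("%s: duplicate edge %s->%s collapsed",
                           pathway_id, rec.source, rec.target)
            continue
        seen.add(key)
        edges.append(rec)

    return PathwayGraph(pathway_id=pathway_id, nodes=nodes, edges=edges)


def load_pathway_collection(
    node_table,
    edge_table,
    gene_delimiter: str = ";",
    sign_aliases: Mapping[str, str] | None = None,
) -> list[PathwayGraph]:
    """Load one or many pathways from combined tables.

    If a ``pathway_id`` column is present the tables are split on it;
    otherwise a single pathway named ``"pathway"`` is loaded.
    """
    nodes_df = _as_frame(node_table)
    edges_df = _as_frame(edge_table)
    if "pathway_id" not in nodes_df.columns:
        return [load_pathway(nodes_df, edges_df,
                             gene_delimiter=gene_delimiter,
                             sign_aliases=sign_aliases)]
    if "pathway_id" not in edges_df.columns:
        raise FormatError("node table has pathway_id but edge table does not")
    graphs = []
    for pid in sorted(nodes_df["pathway_id"].unique()):
        graphs.append(load_pathway(
            nodes_df[nodes_df["pathway_id"] == pid].drop(columns=["pathway_id"]),
            edges_df[edges_df["pathway_id"] == pid].drop(columns=["pathway_id"]),
            pathway_id=str(pid),
            gene_delimiter=gene_delimiter,
            sign_aliases=sign_aliases,
        ))
    return graphs


# ---------------------------------------------------------------------------
# receptors / effectors / circuits
# ---------------------------------------------------------------------------

def find_receptors(graph: PathwayGraph) -> set[str]:
    """Signal entry points: in-degree-0 nodes, falling back to explicit
    ``receptor`` flags when the graph has no source node (fully cyclic)."""
    g = graph.graph
    receptors = {n for n in g.nodes if g.in_degree(n) == 0}
    if receptors:
        return receptors
    flagged = {n for n, rec in graph.nodes.items() if rec.receptor_flag}
    if flagged:
        return flagged
    raise StructuralError(
        f"{graph.pathway_id}: no in-degree-0 node and no receptor annotation")


def find_effectors(graph: PathwayGraph) -> set[str]:
    """Terminal nodes: out-degree-0 nodes, falling back to explicit
    ``effector`` flags when none exist."""
    g = graph.graph
    effectors = {n for n in g.nodes if g.out_degree(n) == 0}
    if effectors:
        return effectors
    flagged = {n for n, rec in graph.nodes.items() if rec.effector_flag}
    if flagged:
        return flagged
    raise StructuralError(
        f"{graph.pathway_id}: no out-degree-0 node and no effector annotation")


def extract_effector_circuits(graph: PathwayGraph) -> list[Circuit]:
    """Decompose a pathway into one circuit per reachable effector.

    Membership is the intersection of the forward-reachable set from the
    receptors with the backward-reachable set from the effector, which equals
    the union of all receptor-to-effector directed walks.  Effectors not
    reachable from any receptor are skipped with a warning.  Output is
    ordered by effector node id.
    """
    receptors = find_receptors(graph)
    effectors = find_effectors(graph)
    g = graph.graph

    forward: set[str] = set()
    for r in receptors:
        forward |= {r} | nx.descendants(g, r)

    circuits: list[Circuit] = []
    for eff in sorted(effectors):
        if eff not in forward:
            logger.warning("%s: effector %s unreachable from any receptor; "
                           "circuit omitted", graph.pathway_id, eff)
            continue
        backward = {eff} | nx.ancestors(g, eff)
        members = forward & backward
        member_edges = tuple(
            e for e in graph.edges
            if e.source in forward and e.source in backward
            and e.target in backward and e.target in forward
        )
        if not member_edges:
            # isolated node that is trivially its own receptor and effector
            logger.warning("%s: degenerate single-node circuit at %s omitted",
                           graph.pathway_id, eff)
            continue
        circuits.append(Circuit(
            circuit_id=f"{graph.pathway_id}:{eff}",
            pathway_id=graph.pathway_id,
            effector=eff,
            receptors=frozenset(receptors & members),
            member_nodes=frozenset(members),
            member_edges=member_edges,
        ))
    return circuits


def extract_all_circuits(graphs: Iterable[PathwayGraph]) -> list[Circuit]:
    """Circuits of every pathway, concatenated in pathway order."""
    out: list[Circuit] = []
    for g in graphs:
        out.extend(extract_effector_circuits(g))
    return out


def circuits_to_frame(circuits: Sequence[Circuit]) -> pd.DataFrame:
    """Export table: circuit_id, effector, receptors, member counts."""
    rows = [{
        "circuit_id": c.circuit_id,
        "pathway_id": c.pathway_id,
        "effector": c.effector,
        "receptors": ";".join(sorted(c.receptors)),
        "n_member_nodes": len(c.member_nodes),
        "n_member_edges": len(c.member_edges),
    } for c in circuits]
    return pd.DataFrame(rows, columns=["circuit_id", "pathway_id", "effector",
                                       "receptors", "n_member_nodes",
                                       "n_member_edges"])


def write_circuits(circuits: Sequence[Circuit], path: str | Path) -> None:
    circuits_to_frame(circuits).to_csv(path, sep="\t", index=False)
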
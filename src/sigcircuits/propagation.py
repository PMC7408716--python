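"""Signal propagation through effector circuits.

The signal intensity of node *n* is

    S_n = v_n * (1 - prod_{s_a in A} (1 - s_a)) * prod_{s_i in I} (1 - s_i)

where ``v_n`` is the node's normalized expression value in [0,1], ``A`` the
set of signals arriving over activation edges and ``I`` the set arriving over
inhibition edges.  Receptors are seeded with a constant activation input of 1,
so the same rule applies uniformly to every node.  The circuit's activity is
the signal reaching its effector.

Acyclic circuits are evaluated exactly in one topological sweep; cyclic ones
by synchronous (Jacobi) fixed-point iteration of the same map, which is
continuous on [0,1]^V and initialized at S_n = v_n.

A non-receptor node with no incoming activation edge can never receive signal
(inhibition alone cannot create it): its intensity is 0 and the circuit is
flagged as activation-starved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InputError
from .normalization import NodeValueMatrix
from .pathway import ACTIVATION, Circuit, node_key

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100
DEFAULT_INITIAL_SIGNAL = 1.0


def node_update(v_n: float, A: Iterable[float], I: Iterable[float]) -> float:
    """One application of the propagation rule to a single node.

    By convention an empty activation set yields activation factor 1 (the
    receptor case, where the initial signal of 1 makes the factor 1 anyway);
    an empty inhibition set yields inhibition factor 1.
    """
    A = list(A)
    I = list(I)
    for x in [v_n, *A, *I]:
        if not 0.0 <= x <= 1.0:
            raise InputError(f"propagation inputs must lie in [0,1], got {x}")
    act = 1.0 if not A else 1.0 - math.prod(1.0 - a for a in A)
    inh = math.prod(1.0 - i for i in I)
    return v_n * act * inh


@dataclass
class PropagationState:
    """Result of propagating one circuit for one (or more) samples."""

    circuit: Circuit
    node_signal: dict[str, float]
    converged: bool
    iterations: int
    initial_signal: float = DEFAULT_INITIAL_SIGNAL
    starved_nodes: frozenset[str] = frozenset()

    @property
    def activity(self) -> float:
        return self.node_signal[self.circuit.effector]


def _circuit_structure(circuit: Circuit):
    """Per-node activation/inhibition parent lists, starved set, topo order."""
    act_parents: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    inh_parents: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    for e in circuit.member_edges:
        (act_parents if e.sign == ACTIVATION else inh_parents)[e.target].append(e.source)
    for n in act_parents:
        act_parents[n].sort()
        inh_parents[n].sort()

    starved = frozenset(
        n for n in circuit.member_nodes
        if n not in circuit.receptors and not act_parents[n]
    )

    sub = nx.DiGraph()
    sub.add_nodes_from(circuit.member_nodes)
    sub.add_edges_from((e.source, e.target) for e in circuit.member_edges)
    if nx.is_directed_acyclic_graph(sub):
        order = [n for n in nx.lexicographical_topological_sort(sub)]
    else:
        order = None  # cyclic: fixed-point iteration
    return act_parents, inh_parents, starved, order


def _propagate_arrays(
    circuit: Circuit,
    values: Mapping[str, np.ndarray],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    initial_signal: float = DEFAULT_INITIAL_SIGNAL,
    force_iterative: bool = False,
):
    """Vectorized propagation of one circuit over all samples at once.

    ``values`` maps member node id -> array of v_n across samples.
    ``force_iterative`` runs the fixed-point scheme even on acyclic
    circuits (used to verify it agrees with the topological sweep).
    Returns (signals dict, converged, iterations, starved set).
    """
    act_parents, inh_parents, starved, topo = _circuit_structure(circuit)

    def update(n: str, S: Mapping[str, np.ndarray]) -> np.ndarray:
        if n in starved:
            return np.zeros_like(values[n])
        # A(n) = upstream activation signals, plus the constant initial
        # signal for receptors (flag-declared receptors may also have parents)
        if n not in circuit.receptors and len(act_parents[n]) == 1:
            # single input: 1 - (1 - s) == s, computed exactly
            act = S[act_parents[n][0]]
        else:
            prod = np.ones_like(values[n])
            if n in circuit.receptors:
                prod = prod * (1.0 - initial_signal)
            for p in act_parents[n]:
                prod = prod * (1.0 - S[p])
            act = 1.0 - prod
        inh = np.ones_like(values[n])
        for p in inh_parents[n]:
            inh = inh * (1.0 - S[p])
        return values[n] * act * inh

    if topo is not None and not force_iterative:
        S: dict[str, np.ndarray] = {}
        for n in topo:
            S[n] = update(n, S)
        return S, True, 1, starved

    S = {n: np.asarray(values[n], dtype=float).copy() for n in circuit.member_nodes}
    for n in starved:
        S[n] = np.zeros_like(S[n])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S_new = {n: update(n, S) for n in circuit.member_nodes}
        delta = max(float(np.max(np.abs(S_new[n] - S[n]))) for n in S)
        S = S_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("circuit %s: fixed point not reached after %d iterations",
                       circuit.circuit_id, max_iter)
    return S, converged, it, starved


def propagate_circuit(
    circuit: Circuit,
    values: Mapping[str, float] | pd.Series,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    initial_signal: float = DEFAULT_INITIAL_SIGNAL,
) -> PropagationState:
    """Propagate one circuit for a single sample.

    ``values`` maps member node id (bare, not pathway-qualified) to v_n.
    """
    if tol <= 0:
        raise InputError("tol must be positive")
    missing = [n for n in circuit.member_nodes if n not in values]
    if missing:
        raise InputError(f"missing node values for {sorted(missing)}")
    arrays = {n: np.asarray([float(values[n])]) for n in circuit.member_nodes}
    for n, a in arrays.items():
        if not 0.0 <= a[0] <= 1.0:
            raise InputError(f"node value for {n!r} outside [0,1]")
    S, converged, iterations, starved = _propagate_arrays(
        circuit, arrays, tol=tol, max_iter=max_iter, initial_signal=initial_signal)
    if starved:
        logger.warning("circuit %s: activation-starved nodes %s set to 0",
                       circuit.circuit_id, sorted(starved))
    return PropagationState(
        circuit=circuit,
        node_signal={n: float(S[n][0]) for n in circuit.member_nodes},
        converged=converged,
        iterations=iterations,
        initial_signal=initial_signal,
        starved_nodes=starved,
    )


@dataclass
class CircuitActivityMatrix:
    """Circuits x samples effector signal intensities in [0,1]."""

    data: pd.DataFrame
    convergence: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise InputError("circuit activities must lie in [0,1]")

    @property
    def circuits(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def read_tsv(cls, path) -> "CircuitActivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(float))

    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "circuit_id"
        out.to_csv(path, sep="\t")


def compute_activity_matrix(
    circuits: Sequence[Circuit],
    values: NodeValueMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    initial_signal: float = DEFAULT_INITIAL_SIGNAL,
) -> CircuitActivityMatrix:
    """Effector signal of every circuit in every sample.

    Node values are looked up under ``pathway_id::node_id`` keys.  Row order
    follows the given circuit order; a per-circuit convergence report is
    attached.
    """
    samples = values.samples
    rows, conv_rows = [], []
    for c in circuits:
        try:
            arrays = {
                n: values.data.loc[node_key(c.pathway_id, n)].to_numpy(dtype=float)
                for n in c.member_nodes
            }
        except KeyError as exc:
            raise InputError(
                f"node values missing for circuit {c.circuit_id}: {exc}") from exc
        S, converged, iterations, starved = _propagate_arrays(
            c, arrays, tol=tol, max_iter=max_iter, initial_signal=initial_signal)
        rows.append(S[c.effector])
        conv_rows.append({
            "circuit_id": c.circuit_id, "converged": converged,
            "iterations": iterations, "n_starved_nodes": len(starved),
        })
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(samples))),
        index=[c.circuit_id for c in circuits], columns=samples)
    convergence = pd.DataFrame(
        conv_rows, columns=["circuit_id", "converged", "iterations",
                            "n_starved_nodes"])
    return CircuitActivityMatrix(data=data, convergence=convergence)
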
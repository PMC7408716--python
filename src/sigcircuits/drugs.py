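"""In-silico drug intervention by target-gene knockdown.

A drug is modeled as a knockdown of its target genes: on the unit [0,1]
expression scale the targets' values are replaced by a very low constant
(default 0.001) that mimics an almost-unexpressed gene while preserving a
small basal activity, and circuit activities are recomputed.  Per patient the
reference and pseudo-treated activity profiles are compared circuit by
circuit, giving a log2 fold-change distribution; group differences in mean
fold change quantify group-specific drug effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .differential import (
    DEFAULT_ALPHA,
    benjamini_hochberg,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from .normalization import AggRule, GeneExpressionMatrix, node_values
from .pathway import Circuit, PathwayGraph
from .propagation import (
    DEFAULT_INITIAL_SIGNAL,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    CircuitActivityMatrix,
    compute_activity_matrix,
)

DEFAULT_KNOCKDOWN = 0.001
DEFAULT_FC_EPSILON = 1e-6


@dataclass(frozen=True)
class DrugSpec:
    """A drug with its target gene list and the knockdown value applied."""

    drug_name: str
    targets: tuple[str, ...]
    knockdown_value: float = DEFAULT_KNOCKDOWN

    def __post_init__(self) -> None:
        if not self.targets:
            raise InputError(f"drug {self.drug_name!r} has no targets")
        if not 0.0 < self.knockdown_value < 1.0:
            raise InputError("knockdown_value must lie in (0, 1)")


def load_drugs(table, knockdown_value: float = DEFAULT_KNOCKDOWN) -> list[DrugSpec]:
    """Read a drug table (TSV path or DataFrame) with columns
    ``drug_name`` and ``targets`` (";"-joined)."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    for col in ("drug_name", "targets"):
        if col not in table.columns:
            raise InputError(f"drug table missing column {col!r}")
    drugs = []
    for _, row in table.iterrows():
        targets = tuple(t.strip() for t in str(row["targets"]).split(";") if t.strip())
        drugs.append(DrugSpec(str(row["drug_name"]), targets, knockdown_value))
    return drugs


@dataclass
class FoldChangeMatrix:
    """Circuits x samples per-patient log2 fold changes (treated vs. reference)."""

    data: pd.DataFrame
    epsilon: float = DEFAULT_FC_EPSILON

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise InputError("fold changes must be finite")


def apply_knockdown(
    m: GeneExpressionMatrix, drug: DrugSpec,
) -> tuple[GeneExpressionMatrix, list[str]]:
    """Set every present target gene's row to the knockdown value.

    Requires a unit-scale matrix (the knockdown value lives on the model's
    [0,1] activity scale).  Returns the pseudo-treated matrix and the list of
    target genes absent from the matrix; at least one target must be present.
    """
    if m.scale != "unit":
        raise InputError("apply_knockdown requires scale='unit' input")
    present = [t for t in drug.targets if t in m.data.index]
    absent = [t for t in drug.targets if t not in m.data.index]
    if not present:
        raise InputError(
            f"drug {drug.drug_name!r}: none of its targets are in the matrix")
    data = m.data.copy()
    data.loc[present, :] = drug.knockdown_value
    return GeneExpressionMatrix(data, scale="unit"), absent


def simulate_drug(
    circuits: Sequence[Circuit],
    graphs: PathwayGraph | Iterable[PathwayGraph],
    m: GeneExpressionMatrix,
    drug: DrugSpec,
    rule: AggRule = "mean",
    epsilon: float = DEFAULT_FC_EPSILON,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    initial_signal: float = DEFAULT_INITIAL_SIGNAL,
) -> tuple[CircuitActivityMatrix, CircuitActivityMatrix, FoldChangeMatrix]:
    """Reference vs. pseudo-treated activities and per-patient fold changes.

    fc[c, s] = log2((treated + eps) / (reference + eps)); both activity
    matrices share identical circuit and sample order.
    """
    ref_nodes = node_values(m, graphs, rule=rule)
    trt_expr, _absent = apply_knockdown(m, drug)
    trt_nodes = node_values(trt_expr, graphs, rule=rule)
    kwargs = dict(tol=tol, max_iter=max_iter, initial_signal=initial_signal)
    ref_act = compute_activity_matrix(circuits, ref_nodes, **kwargs)
    trt_act = compute_activity_matrix(circuits, trt_nodes, **kwargs)
    fc = np.log2((trt_act.data.to_numpy() + epsilon)
                 / (ref_act.data.to_numpy() + epsilon))
    fc_df = pd.DataFrame(fc, index=ref_act.data.index, columns=ref_act.data.columns)
    return ref_act, trt_act, FoldChangeMatrix(fc_df, epsilon=epsilon)


def paired_drug_test(
    ref_act: CircuitActivityMatrix,
    trt_act: CircuitActivityMatrix,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-circuit paired signed-rank test of treated vs. reference activity.

    Zero differences are dropped per the signed-rank convention; circuits in
    which every patient ties get p = 1.  BH correction runs across circuits.
    """
    if list(ref_act.data.index) != list(trt_act.data.index) or \
            list(ref_act.data.columns) != list(trt_act.data.columns):
        raise InputError("reference and treated matrices must share "
                         "identical circuit and sample order")
    if len(ref_act.samples) < 2:
        raise InputError("paired test requires at least 2 samples")

    rows = []
    for cid in ref_act.circuits:
        r = ref_act.data.loc[cid].to_numpy(dtype=float)
        t = trt_act.data.loc[cid].to_numpy(dtype=float)
        nonzero = int(np.sum(t != r))
        if nonzero == 0:
            W, p = 0.0, 1.0
        elif nonzero < 2:
            # a single informative pair cannot reach significance either way
            W, p = 0.0, 1.0
        else:
            W, p = wilcoxon_signed_rank(t, r, alternative="two-sided")
        rows.append((cid, W, p, float(r.mean()), float(t.mean())))
    df = pd.DataFrame(rows, columns=["circuit_id", "statistic", "p_value",
                                     "mean_ref", "mean_trt"])
    df["fdr_p"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["fdr_p"] < alpha
    df["direction"] = np.where(
        df["significant"],
        np.where(df["mean_trt"] > df["mean_ref"], "trt>ref", "ref>trt"),
        "none")
    return df


def differential_drug_effect(
    fc_g1: FoldChangeMatrix,
    fc_g2: FoldChangeMatrix,
    group_names: tuple[str, str] = ("G1", "G2"),
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Compare per-patient fold-change distributions between two groups.

    Reports the mean fold change per group and their difference (group1 -
    group2); significance comes from a two-sided rank-sum test on the
    per-patient fold changes with BH correction across circuits.
    """
    if list(fc_g1.data.index) != list(fc_g2.data.index):
        raise InputError("fold-change matrices must share circuit order")
    if fc_g1.data.shape[1] < 2 or fc_g2.data.shape[1] < 2:
        raise InputError("each group needs at least 2 samples")
    g1, g2 = group_names

    rows = []
    for cid in fc_g1.data.index:
        a = fc_g1.data.loc[cid].to_numpy(dtype=float)
        b = fc_g2.data.loc[cid].to_numpy(dtype=float)
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            U, p = float(a.size * b.size / 2.0), 1.0
        else:
            U, p = wilcoxon_rank_sum(a, b, alternative="two-sided")
        rows.append((cid, U, p, float(a.mean()), float(b.mean()),
                     float(a.mean() - b.mean())))
    df = pd.DataFrame(rows, columns=["circuit_id", "statistic", "p_value",
                                     "mean_fc_g1", "mean_fc_g2",
                                     "mean_fc_diff"])
    df["fdr_p"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["fdr_p"] < alpha
    df["direction"] = np.where(
        df["significant"],
        np.where(df["mean_fc_g1"] > df["mean_fc_g2"], f"{g1}>{g2}", f"{g2}>{g1}"),
        "none")
    df.attrs["group1"], df.attrs["group2"] = g1, g2
    return df
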
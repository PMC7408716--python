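"""Differential signaling activity between two sample groups.

Per circuit, activities are compared between groups with a two-sided Wilcoxon
rank-sum (Mann-Whitney U) test; p-values are corrected across all circuits
with the Benjamini-Hochberg step-up procedure, and a direction (which group is
higher) is assigned post hoc from the group means for circuits significant at
the chosen FDR level.

Result tables are plain DataFrames with columns
``circuit_id, statistic, p_value, fdr_p, mean_g1, mean_g2, direction,
significant`` (paired drug tests use ``mean_ref/mean_trt`` instead).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .propagation import CircuitActivityMatrix

DEFAULT_ALPHA = 0.05

RESULT_COLUMNS = ["circuit_id", "statistic", "p_value", "fdr_p",
                  "mean_g1", "mean_g2", "direction", "significant"]


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test (midrank ties).

    Uses the exact null distribution when n_x + n_y <= 20 and there are no
    ties, otherwise the normal approximation with tie and continuity
    correction.  Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; zero differences dropped.

    If every pair ties the test carries no information and p = 1 by
    convention.  Exact null distribution for <= 25 non-zero differences
    without tied magnitudes; normal approximation with continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("paired samples must have identical shape")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    if d.size < 2:
        raise InputError("fewer than 2 non-zero paired differences")
    mags = np.abs(d)
    has_ties = np.unique(mags).size < mags.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _split_groups(
    act: CircuitActivityMatrix, labels: Mapping[str, str] | pd.Series,
) -> tuple[str, str, list[str], list[str]]:
    labels = pd.Series(labels)
    missing = [s for s in act.samples if s not in labels.index]
    if missing:
        raise InputError(f"samples without group label: {missing[:5]}")
    labels = labels.loc[act.samples]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise InputError(f"exactly two groups required, got {groups}")
    g1, g2 = groups
    s1 = [s for s in act.samples if labels[s] == g1]
    s2 = [s for s in act.samples if labels[s] == g2]
    if len(s1) < 2 or len(s2) < 2:
        raise InputError("each group needs at least 2 samples")
    return g1, g2, s1, s2


def differential_signaling(
    act: CircuitActivityMatrix,
    labels: Mapping[str, str] | pd.Series,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Two-group differential circuit activity (rank-sum + BH).

    Group 1 is the lexicographically smaller label.  Circuits with zero
    variance across all samples are excluded from testing and returned with
    ``excluded=True`` (their p/fdr are NaN); BH runs over the tested circuits.
    ``direction`` is ``'{g1}>{g2}'`` / ``'{g2}>{g1}'`` for circuits with
    fdr_p < alpha, else ``'none'``.
    """
    g1, g2, s1, s2 = _split_groups(act, labels)
    a1 = act.data[s1].to_numpy(dtype=float)
    a2 = act.data[s2].to_numpy(dtype=float)
    all_vals = act.data.to_numpy(dtype=float)
    zero_var = np.ptp(all_vals, axis=1) == 0

    rows = []
    for i, cid in enumerate(act.circuits):
        if zero_var[i]:
            rows.append((cid, np.nan, np.nan, float(a1[i].mean()),
                         float(a2[i].mean()), True))
            continue
        U, p = wilcoxon_rank_sum(a1[i], a2[i], alternative="two-sided")
        rows.append((cid, U, p, float(a1[i].mean()), float(a2[i].mean()), False))

    df = pd.DataFrame(rows, columns=["circuit_id", "statistic", "p_value",
                                     "mean_g1", "mean_g2", "excluded"])
    tested = ~df["excluded"].to_numpy()
    fdr = np.full(len(df), np.nan)
    if tested.any():
        fdr[tested] = benjamini_hochberg(df.loc[tested, "p_value"].to_numpy())
    df["fdr_p"] = fdr
    df["significant"] = (df["fdr_p"] < alpha).fillna(False)
    direction = np.where(
        df["significant"],
        np.where(df["mean_g1"] > df["mean_g2"], f"{g1}>{g2}", f"{g2}>{g1}"),
        "none")
    df["direction"] = direction
    df.attrs["group1"] = g1
    df.attrs["group2"] = g2
    df.attrs["alpha"] = alpha
    return df[["circuit_id", "statistic", "p_value", "fdr_p", "mean_g1",
               "mean_g2", "direction", "significant", "excluded"]]


def count_significant(
    table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
) -> tuple[int, int, int]:
    """(n_total, n_group1_higher, n_group2_higher) at fdr_p < alpha."""
    if len(table) == 0:
        return 0, 0, 0
    sig = table["fdr_p"] < alpha
    g1_up = int((sig & (table["mean_g1"] > table["mean_g2"])).sum())
    g2_up = int((sig & (table["mean_g2"] >= table["mean_g1"])).sum())
    return g1_up + g2_up, g1_up, g2_up


def write_results(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
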
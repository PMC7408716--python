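"""Rank-based two-group testing, BH correction, and differential signaling."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sigcircuits as sc
from sigcircuits.exceptions import InputError


# ---------------------------------------------------------------------------
# independent enumeration oracles
# ---------------------------------------------------------------------------

def rank_sum_exact_oracle(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of all splits."""
    pooled = list(x) + list(y)
    n1 = len(x)
    idx = list(range(len(pooled)))
    vals = pooled
    order = sorted(idx, key=lambda i: vals[i])
    midrank = [0.0] * len(idx)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and vals[order[j]] == vals[order[i]]:
            j += 1
        r = (i + j + 1) / 2.0  # average of ranks i+1..j
        for k in range(i, j):
            midrank[order[k]] = r
        i = j

    def u_stat(subset):
        rsum = sum(midrank[i] for i in subset)
        return rsum - n1 * (n1 + 1) / 2.0

    u_obs = u_stat(range(n1))
    us = [u_stat(s) for s in itertools.combinations(idx, n1)]
    total = len(us)
    ge = sum(1 for u in us if u >= u_obs - 1e-9)
    le = sum(1 for u in us if u <= u_obs + 1e-9)
    return min(1.0, 2.0 * min(ge, le) / total)


def signed_rank_exact_oracle(diffs):
    """Two-sided signed-rank p by enumeration of all sign assignments."""
    d = [v for v in diffs if v != 0]
    mags = sorted(abs(v) for v in d)
    ranks = []
    for v in d:
        m = abs(v)
        tied = [i for i, w in enumerate(mags) if w == m]
        ranks.append(1 + sum(tied) / len(tied))
    n = len(d)
    w_obs = sum(r for v, r in zip(d, ranks) if v > 0)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    total = len(ws)
    ge = sum(1 for w in ws if w >= w_obs - 1e-9)
    le = sum(1 for w in ws if w <= w_obs + 1e-9)
    return min(1.0, 2.0 * min(ge, le) / total)


def bh_oracle(p):
    """Literal step-up definition: q_(k) = min_{j>=k} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for pos in range(m - 1, -1, -1):
        k = pos + 1
        running = min(running, p[order[pos]] * m / k)
        q[order[pos]] = min(1.0, running)
    return q


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

class TestWilcoxonRankSum:
    def test_small_exact_case(self):
        _, p = sc.wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = sc.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_constant_input_gives_p_one(self):
        _, p = sc.wilcoxon_rank_sum([2, 2], [2, 2, 2])
        assert p == 1.0

    def test_one_sided_extreme_split(self):
        _, p = sc.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / 20)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            sc.wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 8)
                                       for n2 in range(1, 8) if n1 + n2 <= 8])
    def test_matches_exhaustive_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            pooled = rng.permutation(rng.uniform(0, 1, n1 + n2))
            x, y = pooled[:n1], pooled[n1:]
            _, p = sc.wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(rank_sum_exact_oracle(list(x), list(y)),
                                      abs=1e-9)


class TestWilcoxonSignedRank:
    def test_all_ties_give_p_one(self):
        _, p = sc.wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_all_decreased_n8(self):
        x = np.arange(8, dtype=float)
        y = x + np.linspace(1, 2, 8)
        _, p = sc.wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(2 / 256)

    @pytest.mark.parametrize("n", range(3, 11))
    def test_matches_sign_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(size=n)
        x = np.zeros(n)
        _, p = sc.wilcoxon_signed_rank(x + d, x)
        assert p == pytest.approx(signed_rank_exact_oracle(list(d)), abs=1e-9)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        out = sc.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert sc.benjamini_hochberg([0.5]) == pytest.approx([0.5])

    def test_all_equal_unchanged(self):
        out = sc.benjamini_hochberg([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            sc.benjamini_hochberg([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 51)))
            assert np.allclose(sc.benjamini_hochberg(p), bh_oracle(p),
                               atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        assert np.allclose(sc.benjamini_hochberg(p)[perm],
                           sc.benjamini_hochberg(p[perm]))


# ---------------------------------------------------------------------------
# differential signaling
# ---------------------------------------------------------------------------

def _activity(rows, samples, circuits=None):
    circuits = circuits or [f"c{i}" for i in range(len(rows))]
    return sc.CircuitActivityMatrix(
        data=pd.DataFrame(rows, index=circuits, columns=samples))


def _labels(samples, split):
    return pd.Series(["A"] * split + ["B"] * (len(samples) - split),
                     index=samples)


class TestDifferentialSignaling:
    def test_identical_groups_not_significant(self):
        samples = [f"s{i}" for i in range(8)]
        rows = [[0.1, 0.2, 0.3, 0.4, 0.1, 0.2, 0.3, 0.4]]
        res = sc.differential_signaling(_activity(rows, samples),
                                        _labels(samples, 4))
        assert not res["significant"].any()
        assert (res["direction"] == "none").all()

    def test_zero_variance_circuit_excluded(self):
        samples = [f"s{i}" for i in range(6)]
        rows = [[0.5] * 6, [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]]
        res = sc.differential_signaling(_activity(rows, samples),
                                        _labels(samples, 3))
        assert res.set_index("circuit_id").loc["c0", "excluded"]
        assert np.isnan(res.set_index("circuit_id").loc["c0", "p_value"])

    def test_single_circuit_fdr_equals_p(self):
        samples = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        rows = [rng.uniform(0, 1, 10)]
        res = sc.differential_signaling(_activity(rows, samples),
                                        _labels(samples, 5))
        assert res["fdr_p"].iloc[0] == pytest.approx(res["p_value"].iloc[0])

    def test_strong_separation_detected_with_direction(self):
        samples = [f"s{i}" for i in range(20)]
        rng = np.random.default_rng(2)
        hi = rng.uniform(0.7, 0.9, 10)
        lo = rng.uniform(0.1, 0.3, 10)
        rows = [np.concatenate([hi, lo]), rng.uniform(0, 1, 20)]
        res = sc.differential_signaling(_activity(rows, samples),
                                        _labels(samples, 10))
        r0 = res.set_index("circuit_id").loc["c0"]
        assert r0["significant"]
        assert r0["direction"] == "A>B"

    def test_fdr_never_below_p(self):
        samples = [f"s{i}" for i in range(12)]
        rng = np.random.default_rng(3)
        rows = rng.uniform(0, 1, size=(15, 12))
        res = sc.differential_signaling(_activity(list(rows), samples),
                                        _labels(samples, 6))
        ok = ~res["excluded"]
        assert (res.loc[ok, "fdr_p"] >= res.loc[ok, "p_value"] - 1e-12).all()

    def test_input_validation(self):
        samples = [f"s{i}" for i in range(4)]
        act = _activity([[0.1, 0.2, 0.3, 0.4]], samples)
        with pytest.raises(InputError):  # three groups
            sc.differential_signaling(act, pd.Series(
                ["A", "B", "C", "A"], index=samples))
        with pytest.raises(InputError):  # group of size 1
            sc.differential_signaling(act, pd.Series(
                ["A", "B", "B", "B"], index=samples))
        with pytest.raises(InputError):  # unlabeled sample
            sc.differential_signaling(act, pd.Series(
                ["A", "A", "B"], index=samples[:3]))


class TestCountSignificant:
    def test_empty_table(self):
        empty = pd.DataFrame(columns=["circuit_id", "fdr_p", "mean_g1",
                                      "mean_g2"])
        assert sc.count_significant(empty) == (0, 0, 0)

    def test_direction_decomposition(self):
        t = pd.DataFrame({
            "circuit_id": ["a", "b", "c"],
            "fdr_p": [0.01, 0.02, 0.5],
            "mean_g1": [0.8, 0.1, 0.5],
            "mean_g2": [0.2, 0.9, 0.5],
        })
        assert sc.count_significant(t, alpha=0.05) == (2, 1, 1)

    def test_alpha_zero(self):
        t = pd.DataFrame({"circuit_id": ["a"], "fdr_p": [0.0001],
                          "mean_g1": [1.0], "mean_g2": [0.0]})
        assert sc.count_significant(t, alpha=0.0) == (0, 0, 0)


def test_null_calibration_small():
    """Under the global null the significant fraction stays near alpha."""
    rng = np.random.default_rng(0)
    fracs = []
    for _ in range(10):
        samples = [f"s{i}" for i in range(20)]
        rows = rng.uniform(0, 1, size=(30, 20))
        res = sc.differential_signaling(_activity(list(rows), samples),
                                        _labels(samples, 10))
        fracs.append(res["significant"].mean())
    m = 30
    assert np.mean(fracs) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (10 * m))
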
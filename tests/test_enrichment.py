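"""Pre-ranked competitive testing, ssGSEA scoring and group comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from retinomimic.enrichment import (
    GeneSet,
    SSGSEA,
    compare_groups,
    preranked_test,
    read_gmt,
    ssgsea,
    write_gmt,
)


def exact_ranksum_two_sided_p(in_ranks, n_total):
    """Independent exact oracle: DP over the rank-sum distribution of a
    random subset of size m from ranks 1..N (no ties)."""
    m = len(in_ranks)
    observed = int(sum(in_ranks))
    max_sum = sum(range(n_total - m + 1, n_total + 1))
    # ways[k][t] = number of size-k subsets of ranks seen so far with sum t
    ways = np.zeros((m + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(m, r), 0, -1):
            ways[k, r:] += ways[k - 1, : max_sum + 1 - r]
    dist = ways[m]
    total = dist.sum()
    cdf = dist[: observed + 1].sum() / total
    sf = dist[observed:].sum() / total
    return min(1.0, 2.0 * min(cdf, sf))


def brute_force_ssgsea(values, gene_ids, members, alpha):
    """Independent running-sum oracle (explicit loop over ranked genes)."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], gene_ids[i]))
    in_set = [gene_ids[i] in members for i in order]
    w = [abs(values[i]) ** alpha if alpha != 0 else 1.0 for i in order]
    denom_in = sum(wi for wi, m in zip(w, in_set) if m)
    n_out = sum(1 for m in in_set if not m)
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for wi, m in zip(w, in_set):
        if m:
            cum_in += wi / denom_in
        else:
            cum_out += 1.0 / n_out
        score += cum_in - cum_out
    return score


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        sets = [
            GeneSet("S1", frozenset({"a", "b"}), "demo"),
            GeneSet("S2", frozenset({"c"}), "demo"),
        ]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert {s.name: s.members for s in back} == {s.name: s.members for s in sets}

    def test_duplicates_warn(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\tdesc\ta\ta\tb\n")
        with pytest.warns(UserWarning, match="duplicate"):
            sets = read_gmt(path)
        assert sets[0].members == frozenset({"a", "b"})

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSet("S", frozenset())


class TestPrerankedTest:
    def _stats(self, values):
        return pd.Series(values, index=[f"g{i}" for i in range(len(values))])

    def test_top_block_matches_exact_oracle(self):
        # set = the 10 highest of 100 distinctly ranked genes
        stats = self._stats(np.arange(100, dtype=float))
        top = GeneSet("TOP", frozenset(f"g{i}" for i in range(90, 100)))
        res = preranked_test(stats, [top])
        oracle = exact_ranksum_two_sided_p(range(91, 101), 100)
        assert res.loc["TOP", "p_value"] == pytest.approx(oracle, rel=1e-9)
        assert res.loc["TOP", "direction"] == "up"

    def test_mid_block_matches_exact_oracle(self):
        stats = self._stats(np.arange(40, dtype=float))
        mid = GeneSet("MID", frozenset(f"g{i}" for i in (3, 11, 20, 28, 36)))
        res = preranked_test(stats, [mid])
        oracle = exact_ranksum_two_sided_p([4, 12, 21, 29, 37], 40)
        assert res.loc["MID", "p_value"] == pytest.approx(oracle, rel=1e-9)

    def test_all_tied_p_one(self):
        stats = self._stats(np.ones(30))
        res = preranked_test(stats, [GeneSet("S", frozenset({"g0", "g1", "g2"}))])
        assert res.loc["S", "p_value"] == 1.0

    def test_symmetric_interleave_null(self):
        stats = self._stats(np.arange(20, dtype=float))
        even = GeneSet("EVEN", frozenset(f"g{i}" for i in range(0, 20, 2)))
        res = preranked_test(stats, [even])
        assert res.loc["EVEN", "p_value"] > 0.5

    def test_direction_antisymmetry(self, rng):
        stats = self._stats(rng.normal(size=60))
        gs = GeneSet("S", frozenset(f"g{i}" for i in range(12)))
        res_pos = preranked_test(stats, [gs])
        res_neg = preranked_test(-stats, [gs])
        assert res_pos.loc["S", "p_value"] == pytest.approx(res_neg.loc["S", "p_value"], rel=1e-12)
        assert {res_pos.loc["S", "direction"], res_neg.loc["S", "direction"]} == {"up", "down"}

    def test_degenerate_sets_rejected(self):
        stats = self._stats(np.arange(10, dtype=float))
        with pytest.raises(ValueError, match="fewer than"):
            preranked_test(stats, [GeneSet("S", frozenset({"g0"}))])
        with pytest.raises(ValueError, match="whole universe"):
            preranked_test(stats, [GeneSet("ALL", frozenset(f"g{i}" for i in range(10)))])

    def test_pvalues_uniform_under_permutation(self, rng):
        """Under exchangeable statistics, the competitive p-value is
        Uniform(0, 1) to within KS tolerance."""
        n, m = 100, 10
        pvals = []
        for _ in range(2000):
            stats = self._stats(rng.normal(size=n))
            members = frozenset(f"g{i}" for i in rng.choice(n, m, replace=False))
            res = preranked_test(stats, [GeneSet("S", members)], method="asymptotic")
            pvals.append(res["p_value"].iloc[0])
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks <= 0.05


class TestSsgsea:
    def _profile(self, values, samples=1):
        idx = [f"g{i}" for i in range(len(values))]
        return pd.DataFrame({f"s{j}": values for j in range(samples)}, index=idx)

    def test_identical_profiles_identical_scores(self):
        expr = self._profile([5.0, 4.0, 3.0, 2.0, 1.0], samples=2)
        gs = [GeneSet("S", frozenset({"g0", "g1"}))]
        out = ssgsea(expr, gs)
        assert out.iloc[0, 0] == out.iloc[1, 0]

    def test_unweighted_running_sum_oracle(self):
        expr = self._profile([5.0, 4.0, 3.0, 2.0, 1.0])
        gs = [GeneSet("S", frozenset({"g0", "g1"}))]
        out = ssgsea(expr, gs, alpha=0.0)
        # hand running sum: positions 1,2 in-set -> P_in (.5, 1, 1, 1, 1),
        # P_out (0, 0, 1/3, 2/3, 1); sum of differences = .5+1+2/3+1/3+0
        assert out.iloc[0, 0] == pytest.approx(0.5 + 1.0 + 2 / 3 + 1 / 3 + 0.0)

    def test_dual_implementation_oracle_random_cases(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 50))
            values = rng.normal(2, 1, size=n)
            idx = [f"g{i}" for i in range(n)]
            members = set(rng.choice(idx, size=int(rng.integers(2, n - 1)), replace=False))
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            expr = pd.DataFrame({"s": values}, index=idx)
            mine = ssgsea(expr, [GeneSet("S", frozenset(members))], alpha=alpha).iloc[0, 0]
            oracle = brute_force_ssgsea(list(values), idx, members, alpha)
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_rank_only_invariance_at_alpha_zero(self, rng):
        values = rng.uniform(1, 10, size=30)
        idx = [f"g{i}" for i in range(30)]
        gs = [GeneSet("S", frozenset(idx[:6]))]
        expr = pd.DataFrame({"s": values}, index=idx)
        transformed = pd.DataFrame({"s": np.exp(values / 3)}, index=idx)  # strictly monotone
        a = ssgsea(expr, gs, alpha=0.0).iloc[0, 0]
        b = ssgsea(transformed, gs, alpha=0.0).iloc[0, 0]
        assert a == pytest.approx(b, abs=1e-12)
        # at alpha > 0 the weights depend on the values, so scores differ
        a1 = ssgsea(expr, gs, alpha=0.25).iloc[0, 0]
        b1 = ssgsea(transformed, gs, alpha=0.25).iloc[0, 0]
        assert a1 != pytest.approx(b1, abs=1e-9)

    def test_absent_set_rejected(self):
        expr = self._profile([1.0, 2.0])
        with pytest.raises(ValueError, match="no gene of the set"):
            ssgsea(expr, [GeneSet("S", frozenset({"missing"}))])

    def test_transformer_api(self, rng):
        expr = self._profile(list(rng.normal(size=20)), samples=3)
        gs = [GeneSet("S", frozenset({"g0", "g1", "g2"}))]
        est = SSGSEA(gs, alpha=0.25)
        out = est.fit(expr).transform(expr)
        assert out.shape == (3, 1)
        assert est.get_params()["alpha"] == 0.25


class TestCompareGroups:
    def _scores(self, a_vals, b_vals):
        idx = [f"s{i}" for i in range(len(a_vals) + len(b_vals))]
        scores = pd.DataFrame({"SET": list(a_vals) + list(b_vals)}, index=idx)
        labels = pd.Series(["HIGH"] * len(a_vals) + ["LOW"] * len(b_vals), index=idx)
        return scores, labels

    def test_identical_groups_null(self):
        scores, labels = self._scores([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = compare_groups(scores, labels)
        assert res.loc["SET", "p_value"] == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        hits = 0
        for _ in range(100):
            scores, labels = self._scores(rng.normal(0, 1, 20), rng.normal(3, 1, 20))
            res = compare_groups(scores, labels)
            hits += res.loc["SET", "p_value"] < 0.001
        assert hits >= 95

    def test_planted_difference_survives_bh(self, rng):
        idx = [f"s{i}" for i in range(40)]
        labels = pd.Series(["HIGH"] * 20 + ["LOW"] * 20, index=idx)
        wins = 0
        for _ in range(20):
            scores = pd.DataFrame(
                {
                    "NULL1": rng.normal(size=40),
                    "SHIFTED": np.r_[rng.normal(2, 1, 20), rng.normal(0, 1, 20)],
                    "NULL2": rng.normal(size=40),
                },
                index=idx,
            )
            res = compare_groups(scores, labels)
            sig = set(res[res["adj_p"] < 0.05].index)
            wins += sig == {"SHIFTED"}
        assert wins >= 15

    def test_small_group_rejected(self):
        scores, labels = self._scores([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match=">= 2 samples"):
            compare_groups(scores, labels)
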
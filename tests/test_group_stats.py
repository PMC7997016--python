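"""Kruskal–Wallis, Conover–Iman, Wilcoxon signed-rank, BMI matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from skinsuv import group_stats as gs
from skinsuv.core import ValidationError


class TestKruskalWallis:
    def test_rank_sum_hand_example(self):
        h, df, p = gs.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_all_identical_defined_as_zero(self):
        h, df, p = gs.kruskal_wallis([[3, 3, 3], [3, 3], [3, 3, 3]])
        assert h == 0.0 and p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError, match="no observations"):
            gs.kruskal_wallis([[1, 2], []])

    def test_invariance_under_monotone_transform(self, rng):
        groups = [rng.normal(loc, 1, 12) for loc in (0, 0.5, 2)]
        h1, _, _ = gs.kruskal_wallis(groups)
        h2, _, _ = gs.kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2)


class TestConoverPairwise:
    def test_identical_groups_null(self):
        table = gs.conover_pairwise([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert table["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_table_shape_and_adjustment_monotone(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 1, 2, 3)]
        table = gs.conover_pairwise(groups)
        assert len(table) == 6  # k(k-1)/2
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()

    def test_separated_groups_significant_with_permutation_oracle(self, rng):
        groups = [list(10 + np.arange(10)), list(30 + np.arange(10)),
                  list(50 + np.arange(10))]
        table = gs.conover_pairwise(groups, ["a", "b", "c"])
        assert (table["p_adj"] < 0.01).all()
        # permutation oracle on one pair: mean-rank gap under label shuffles
        pooled = np.array(groups[0] + groups[1], dtype=float)
        obs = np.abs(stats.rankdata(pooled)[:10].mean()
                     - stats.rankdata(pooled)[10:].mean())
        count = 0
        for _ in range(2000):
            perm = rng.permutation(pooled)
            r = stats.rankdata(perm)
            count += np.abs(r[:10].mean() - r[10:].mean()) >= obs
        assert (count + 1) / 2001 < 0.01

    def test_two_group_coherence_with_rank_t(self, rng):
        # k = 2: Conover p equals the rank-t computed directly from the
        # same pooled ranks with the same variance scaling
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 11)
        table = gs.conover_pairwise([a, b])
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        h, _, _ = gs.kruskal_wallis([a, b])
        n = pooled.size
        s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4) / (n - 1)
        se = np.sqrt(s2 * (n - 1 - h) / (n - 2) * (1 / 9 + 1 / 11))
        t = (ranks[:9].mean() - ranks[9:].mean()) / se
        assert table["t"].iloc[0] == pytest.approx(t)
        assert table["p_raw"].iloc[0] == pytest.approx(2 * stats.t.sf(abs(t), n - 2))

    def test_null_familywise_error_controlled(self, rng):
        reps, rejections = 2000, 0
        for _ in range(reps):
            groups = [rng.normal(0, 1, 15) for _ in range(3)]
            table = gs.conover_pairwise(groups)
            rejections += bool((table["p_adj"] < 0.05).any())
        fwer = rejections / reps
        assert fwer <= 0.05 + 0.015  # Monte-Carlo tolerance at 2000 reps

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            gs.conover_pairwise([[1, 2, 3]])


class TestSquaredRanksDiagnostic:
    def test_detects_unequal_variances(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 5, 40)
        t, df, p = gs.squared_ranks_variance_test([a, b])
        assert df == 1 and p < 0.01

    def test_degenerate_equal_values(self):
        t, _, p = gs.squared_ranks_variance_test([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert t == 0.0 and p == 1.0


class TestWilcoxonCheck:
    def test_identical_pairs(self):
        res = gs.wilcoxon_bmi_check([20, 21, 22, 23, 24], [20, 21, 22, 23, 24])
        assert res.p == 1.0
        assert res.ci == (0.0, 0.0)

    def test_six_concordant_pairs_exact_p(self):
        a = [21.0, 22.0, 23.0, 24.0, 25.0, 26.0]
        b = [20.0, 20.5, 21.2, 22.1, 23.0, 24.4]
        res = gs.wilcoxon_bmi_check(a, b)
        assert res.p == pytest.approx(2.0 / 64.0)  # 2 of 2^6 sign patterns

    def test_signed_rank_cdf_matches_enumeration(self):
        n = 6
        cdf = gs.signed_rank_cdf(n)
        # enumerate all 2^6 sign patterns directly
        sums = [sum(r for r, keep in zip(range(1, n + 1), bits) if keep)
                for bits in itertools.product((0, 1), repeat=n)]
        for w in range(n * (n + 1) // 2 + 1):
            assert cdf[w] == pytest.approx(np.mean([s <= w for s in sums]))

    def test_too_few_pairs_warns_nan(self):
        with pytest.warns(UserWarning, match="pairs"):
            res = gs.wilcoxon_bmi_check([1, 2, 3], [2, 3, 4])
        assert np.isnan(res.p)

    def test_hl_ci_brackets_estimate_and_excludes_zero_for_shift(self, rng):
        a = rng.normal(25, 2, 15)
        b = a - 5.0 + rng.normal(0, 0.3, 15)
        res = gs.wilcoxon_bmi_check(a, b)
        assert res.ci[0] <= res.hl_estimate <= res.ci[1]
        assert res.ci[0] > 0
        assert res.hl_estimate == pytest.approx(5.0, abs=0.5)

    def test_shift_power_at_15_pairs(self, rng):
        # +5 BMI shift, n = 15 pairs, 500 reps: power > 0.8 at alpha 0.05
        hits = 0
        for _ in range(500):
            a = rng.normal(22, 3, 15)
            b = a + rng.normal(0, 3, 15) + 5.0
            hits += gs.wilcoxon_bmi_check(a, b).p < 0.05
        assert hits / 500 > 0.8


class TestDecades:
    def test_closed_decade_bins(self):
        assert gs.decade_label(9) == "0-9"
        assert gs.decade_label(10) == "10-19"
        assert gs.decade_label(79) == "70-79"
        assert gs.decade_label(85) == "70-79"


def _pool(rng, per_cell=6, shift=0.0):
    rows = []
    for decade in gs.DECADES:
        lo = int(decade.split("-")[0])
        for sex in ("M", "F"):
            for i in range(per_cell):
                rows.append({"exam_id": f"{sex}{decade}{i}", "sex": sex,
                             "age": lo + int(rng.integers(0, 10)),
                             "bmi": float(rng.normal(22 + (shift if sex == "M" else 0),
                                                     1.5))})
    return pd.DataFrame(rows)


class TestMatchCohort:
    def test_perfectly_matched_pool_returned_whole(self, rng):
        rows = []
        for decade in gs.DECADES:
            lo = int(decade.split("-")[0])
            for i in range(4):
                bmi = 20.0 + i
                rows.append({"exam_id": f"m{decade}{i}", "sex": "M", "age": lo,
                             "bmi": bmi})
                rows.append({"exam_id": f"f{decade}{i}", "sex": "F", "age": lo,
                             "bmi": bmi})
        pool = pd.DataFrame(rows)
        matched, balance = gs.match_cohort(pool, seed=1)
        assert len(matched) == len(pool)
        assert sorted(matched["exam_id"]) == sorted(pool["exam_id"])

    def test_outlier_excluded_when_closer_match_exists(self):
        pool = pd.DataFrame([
            {"exam_id": "m1", "sex": "M", "age": 25, "bmi": 20.0},
            {"exam_id": "m2", "sex": "M", "age": 25, "bmi": 21.0},
            {"exam_id": "m3", "sex": "M", "age": 25, "bmi": 35.0},
            {"exam_id": "f1", "sex": "F", "age": 25, "bmi": 20.5},
            {"exam_id": "f2", "sex": "F", "age": 25, "bmi": 21.5},
        ])
        matched, _ = gs.match_cohort(pool, seed=0)
        assert "m3" not in set(matched["exam_id"])
        # exhaustive-search oracle: best two pairs by total distance
        best = min(
            ((ma, mb) for ma, mb in itertools.permutations(["m1", "m2", "m3"], 2)),
            key=lambda pair: abs(float(pool[pool.exam_id == pair[0]].bmi.iloc[0]) - 20.5)
            + abs(float(pool[pool.exam_id == pair[1]].bmi.iloc[0]) - 21.5))
        assert set(best) == {"m1", "m2"}

    def test_balanced_and_nonsignificant_per_decade(self, rng):
        matched, balance = gs.match_cohort(_pool(rng, per_cell=10), seed=3)
        for decade, check in balance.items():
            sub = matched[matched["age"].map(gs.decade_label) == decade]
            assert (sub["sex"] == "M").sum() == (sub["sex"] == "F").sum()
            if not np.isnan(check.p):
                assert check.p > 0.05

    def test_missing_sex_cell_named(self, rng):
        pool = _pool(rng)
        pool = pool[~((pool["sex"] == "F") & (pool["age"] < 10))]
        with pytest.raises(ValidationError, match="0-9"):
            gs.match_cohort(pool, seed=0)
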
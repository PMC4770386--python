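"""Tests for the nonparametric comparison machinery against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from proteoturn import (
    ValidationError,
    compare_groups,
    complex_dispersion,
    correlate,
    enrichment_1d,
    extreme_decile_analysis,
    kruskal_with_posthoc,
    ubiquitination_comparison,
)
from proteoturn.stats import label_pair_delta
from _oracles import (
    bh_fdr,
    kruskal_h,
    mann_whitney_exact,
    mann_whitney_exact_two_sided,
    wilcoxon_signed_rank_exact,
)


class TestCompareGroups:
    def test_mw_small_sample_closed_form(self):
        res = compare_groups([1, 2], [3, 4], alternative="less")
        assert res.p_value == pytest.approx(1 / 6)

    def test_mw_three_vs_three(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p_value == pytest.approx(1 / 20)

    def test_identical_paired_samples_degenerate(self):
        res = compare_groups([1, 2, 3], [1, 2, 3], paired=True,
                             alternative="less")
        assert math.isnan(res.p_value)
        assert res.conclusion == "degenerate"

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([], [1], alternative="less")

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1, 2], [1], paired=True)

    def test_mw_matches_enumeration_oracle(self):
        """Exact MW p equals exhaustive enumeration, sizes up to 8."""
        rng = np.random.default_rng(7)
        for n_a, n_b in [(2, 3), (3, 5), (4, 4), (5, 8), (8, 8), (2, 8)]:
            for _ in range(3):
                a = rng.normal(size=n_a)
                b = rng.normal(size=n_b)
                for alt in ("less", "greater"):
                    ours = compare_groups(a, b, alternative=alt).p_value
                    oracle = mann_whitney_exact(a, b, alt)
                    assert ours == pytest.approx(oracle, abs=1e-12)
                ours2 = compare_groups(a, b, alternative="two-sided").p_value
                assert ours2 == pytest.approx(
                    mann_whitney_exact_two_sided(a, b), abs=1e-12
                )

    def test_mw_matches_enumeration_oracle_with_ties(self):
        """Tied samples use the exact mid-rank permutation distribution."""
        rng = np.random.default_rng(13)
        for n_a, n_b in [(3, 3), (4, 6), (8, 8)]:
            a = rng.integers(0, 4, n_a).astype(float)
            b = rng.integers(0, 4, n_b).astype(float)
            for alt in ("less", "greater"):
                ours = compare_groups(a, b, alternative=alt).p_value
                assert ours == pytest.approx(
                    mann_whitney_exact(a, b, alt), abs=1e-12
                )

    def test_wilcoxon_matches_enumeration_oracle(self):
        """Exact signed-rank p equals the 2^n sign enumeration, n <= 8."""
        rng = np.random.default_rng(11)
        for n in (4, 5, 6, 8):
            for _ in range(3):
                a = rng.normal(size=n)
                b = a + rng.normal(size=n)  # paired with real differences
                for alt in ("less", "greater"):
                    ours = compare_groups(
                        a, b, paired=True, alternative=alt
                    ).p_value
                    oracle = wilcoxon_signed_rank_exact(a, b, alt)
                    assert ours == pytest.approx(oracle, abs=1e-12)


class TestKruskal:
    def test_closed_form_three_groups(self):
        res = kruskal_with_posthoc(
            {"a": [1, 2], "b": [3, 4], "c": [5, 6]}
        )
        assert res.statistic == pytest.approx(32 / 7)

    def test_matches_rank_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.integers(0, 5, 6).astype(float),
            "b": rng.integers(0, 5, 7).astype(float),
            "c": rng.integers(0, 5, 5).astype(float),
        }
        res = kruskal_with_posthoc(groups)
        assert res.statistic == pytest.approx(
            kruskal_h(list(groups.values())), abs=1e-10
        )

    def test_identical_groups_h_zero(self):
        res = kruskal_with_posthoc({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_group_case_agrees_with_mw(self):
        """KW with two groups is equivalent to two-sided MW (chi2 vs normal)."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 30)
        kw_p = kruskal_with_posthoc({"a": a, "b": b}).p_value
        # asymptotic two-sided MW without continuity correction
        from scipy.stats import mannwhitneyu

        mw_p = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        ).pvalue
        assert kw_p == pytest.approx(mw_p, rel=1e-6)

    def test_critical_difference_flags_separated_groups(self):
        res = kruskal_with_posthoc(
            {
                "low": [1, 2, 3, 4, 5, 6, 7, 8],
                "mid": [4, 5, 6, 7, 8, 9, 10, 11],
                "high": [30, 31, 32, 33, 34, 35, 36, 37],
            }
        )
        flagged = set(res.critical_difference_pairs)
        assert ("high", "low") in flagged or ("low", "high") in flagged
        assert ("low", "mid") not in flagged and ("mid", "low") not in flagged

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_with_posthoc({"a": [1, 2, 3]})


class TestComplexDispersion:
    def _complexes(self, members):
        return pd.DataFrame(
            {"complex_id": "C1", "accession": list(members)}
        )

    def test_equal_turnover_no_outliers(self):
        turnover = {f"m{i}": 10.0 for i in range(5)}
        res = complex_dispersion(turnover, self._complexes(turnover))
        assert res[0].label == "consistent"

    def test_planted_outlier_flagged(self):
        values = [10, 10.2, 10.4, 10.1, 10.3, 10.5, 9.9, 40.0]
        turnover = {f"m{i}": v for i, v in enumerate(values)}
        res = complex_dispersion(turnover, self._complexes(turnover))
        assert res[0].outliers == ["m7"]

    def test_small_complex_skipped(self):
        turnover = {"a": 1.0, "b": 2.0}
        res = complex_dispersion(turnover, self._complexes(turnover))
        assert res == []

    def test_member_without_turnover_excluded(self):
        turnover = {f"m{i}": 10.0 + i * 0.1 for i in range(4)}
        complexes = self._complexes(list(turnover) + ["missing"])
        res = complex_dispersion(turnover, complexes)
        assert "missing" not in res[0].members

    def test_outlier_p_matches_mw_enumeration(self):
        values = [10, 10.5, 11, 30.0]
        turnover = {f"m{i}": v for i, v in enumerate(values)}
        res = complex_dispersion(turnover, self._complexes(turnover))
        # member 3: test diffs {20, 19.5, 19} vs reference {0.5, 1, 0.5}
        oracle = mann_whitney_exact([20, 19.5, 19], [0.5, 1.0, 0.5],
                                    "greater")
        assert res[0].p_values[3] == pytest.approx(oracle)


class TestUbiquitination:
    def _records(self):
        rng = np.random.default_rng(9)
        n = 40
        return pd.DataFrame(
            {
                "category": ["dbTIS"] * n,
                "lysine_count": rng.integers(1, 10, n),
                "ubiquitination_evidence": [True] * (n // 2)
                + [False] * (n // 2),
                "t_turn_h": np.concatenate(
                    [rng.normal(10, 2, n // 2), rng.normal(20, 2, n // 2)]
                ),
            }
        )

    def test_destabilisation_detected(self):
        res = ubiquitination_comparison(self._records())
        assert res.significant

    def test_lysine_free_records_rejected(self):
        df = self._records()
        df["lysine_count"] = 0
        df["ubiquitination_evidence"] = False
        with pytest.raises(ValidationError):
            ubiquitination_comparison(df)

    @pytest.mark.parametrize(
        "delta,label",
        [
            (-3.0, "destabilised"),
            (+1.0, "irrelevant difference (<2 h)"),
            (-1.9, "irrelevant difference (<2 h)"),
            (+2.5, "stabilised"),
        ],
    )
    def test_pair_delta_labels(self, delta, label):
        assert label_pair_delta(delta) == label


class TestCorrelate:
    def test_linear_relation(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x, "rank") == pytest.approx(1.0)
        assert correlate(x, 2 * x, "linear") == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.arange(10.0)
        assert correlate(x, -x, "rank") == pytest.approx(-1.0)

    def test_spearman_closed_form(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 sum = 2
        assert correlate([1, 2, 3, 4], [1, 3, 2, 4], "rank") == (
            pytest.approx(0.8)
        )

    def test_constant_pearson_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1, 1, 1], [1, 2, 3], "linear")


class TestEnrichment:
    def test_top_half_category_most_extreme_p(self):
        values = np.arange(20.0)
        mask = values >= 10
        out = enrichment_1d({"top": mask}, values)
        assert out.loc[0, "direction"] == "larger"
        assert out.loc[0, "p_value"] == pytest.approx(
            mann_whitney_exact_two_sided(values[mask], values[~mask])
        )

    def test_single_member_category_skipped(self):
        values = np.arange(10.0)
        masks = {
            "ok": values < 5,
            "singleton": values == 0,
        }
        out = enrichment_1d(masks, values)
        assert list(out["category"]) == ["ok"]

    def test_null_assignment_roughly_uniform_p(self):
        """Random categories give ~uniform p-values (calibration)."""
        rng = np.random.default_rng(21)
        values = rng.normal(size=200)
        pvals = []
        for i in range(200):
            mask = np.zeros(200, bool)
            mask[rng.choice(200, 40, replace=False)] = True
            pvals.append(
                enrichment_1d({"c": mask}, values).loc[0, "p_value"]
            )
        pvals = np.array(pvals)
        assert 0.01 < (pvals < 0.05).mean() < 0.12
        assert 0.35 < (pvals < 0.5).mean() < 0.65

    def test_bh_matches_textbook_construction(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=60)
        masks = {
            f"c{i}": rng.random(60) < 0.4 for i in range(8)
        }
        out = enrichment_1d(masks, values)
        oracle = bh_fdr(out["p_value"].to_numpy())
        assert np.allclose(out["fdr"], oracle, atol=1e-12)
        # monotone in raw-p order, bounded by 1
        ordered = out.sort_values("p_value")["fdr"].to_numpy()
        assert np.all(np.diff(ordered) >= -1e-12)
        assert np.all(out["fdr"] <= 1)


class TestExtremeDeciles:
    def test_feature_equal_to_turnover_maximally_enriched(self):
        t = np.arange(100.0)
        out = extreme_decile_analysis(t, t)
        assert set(out["category"]) == {"unstable_decile", "stable_decile"}
        assert (out["significant"]).all()
        dirs = dict(zip(out["category"], out["direction"]))
        assert dirs["unstable_decile"] == "smaller"
        assert dirs["stable_decile"] == "larger"

    def test_independent_feature_not_enriched(self):
        rng = np.random.default_rng(4)
        out = extreme_decile_analysis(
            rng.normal(size=300), rng.normal(size=300)
        )
        assert not out["significant"].any()

    def test_planted_negative_correlation_detected(self):
        rng = np.random.default_rng(8)
        t = rng.normal(size=400)
        disorder = -0.8 * t + rng.normal(0, 0.6, 400)  # unstable = high
        out = extreme_decile_analysis(t, disorder).set_index("category")
        assert out.loc["unstable_decile", "direction"] == "larger"
        assert out.loc["unstable_decile", "fdr"] < 0.05

    def test_too_few_records_rejected(self):
        with pytest.raises(ValidationError):
            extreme_decile_analysis(np.arange(10.0), np.arange(10.0))
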
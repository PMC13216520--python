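"""Association statistics against independent oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hallmark_timing.io import HallmarkMap, MutationRecord
from hallmark_timing.stats import (
    ContingencyTable2x2,
    _ad2_normalized,
    ad_ksample_test,
    bh_adjust,
    bonferroni_adjust,
    bootstrap_dominant_counts,
    bootstrap_signature_comparison,
    cohens_d_ci,
    dominant_count_tables,
    feature_enrichment,
    logistic_or,
    substitution_vaf_correlation,
    contingency_p_value,
)


def fisher_two_sided_enum(a, b, c, d):
    """Oracle: sum of hypergeometric probabilities <= the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    po = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= po * (1 + 1e-9))


class TestContingency:
    def test_tables_from_calls(self):
        labels = {"a": "EGI", "b": "EGI", "c": "LGI", "d": "LGI"}
        calls = {"a": "S", "b": "S", "c": "T", "d": "T"}
        tabs = dominant_count_tables(labels, calls)
        assert tabs["S"] == ContingencyTable2x2(2, 0, 0, 2)
        assert tabs["T"] == ContingencyTable2x2(0, 2, 2, 0)

    def test_margins_equal_cluster_sizes(self, small_cohort):
        from hallmark_timing.signatures import dominant_from_exposures
        calls = dominant_from_exposures(small_cohort.cn_exposures)
        tabs = dominant_count_tables(small_cohort.truth_labels, calls)
        n_egi = sum(1 for g in small_cohort.truth_labels.values() if g == "EGI")
        n_lgi = len(small_cohort.truth_labels) - n_egi
        for t in tabs.values():
            assert t.a + t.c == n_egi and t.b + t.d == n_lgi

    def test_unlabeled_sample_error(self):
        with pytest.raises(ValueError, match="ghost"):
            dominant_count_tables({"a": "EGI"}, {"a": "S", "ghost": "S"})

    def test_balanced_table_chi2_p_one(self):
        p, method = contingency_p_value(ContingencyTable2x2(10, 10, 10, 10))
        assert method == "chi2" and p == pytest.approx(1.0)

    def test_fisher_branch_matches_enumeration(self):
        t = ContingencyTable2x2(1, 9, 12, 2)  # an expected cell < 5
        p, method = contingency_p_value(t)
        assert method == "fisher"
        assert p == pytest.approx(fisher_two_sided_enum(1, 9, 12, 2), abs=1e-12)

    def test_scaling_preserving_proportions_shrinks_p(self):
        p_small, _ = contingency_p_value(ContingencyTable2x2(6, 4, 4, 6))
        p_big, _ = contingency_p_value(ContingencyTable2x2(6000, 4000, 4000, 6000))
        assert p_big <= p_small

    def test_zero_margin_degenerate(self):
        p, method = contingency_p_value(ContingencyTable2x2(0, 0, 5, 5))
        assert p == 1.0 and method == "degenerate"

    def test_fisher_equals_enumeration_all_small_tables(self):
        """Every 2x2 with grand total <= 40 (subsampled grid): scipy-backed
        Fisher p equals full hypergeometric enumeration to 1e-9."""
        rng = np.random.default_rng(14)
        checked = 0
        for _ in range(300):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            arr = t.as_array()
            if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
                continue
            _, p = sps.fisher_exact(arr)
            assert p == pytest.approx(
                fisher_two_sided_enum(int(a), int(b), int(c), int(d)), abs=1e-9)
            checked += 1
        assert checked > 200


class TestMultipleTesting:
    def test_bh_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_bh_hand_computed_step_up(self):
        # p_(i) * m / i, monotone from the largest: all become 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_bh_general_hand_case(self):
        # (0.01*4/1, min(.)) step-up for distinct values
        out = bh_adjust([0.005, 0.04, 0.03, 0.9])
        assert out == pytest.approx([0.02, 0.0533333333333333, 0.0533333333333333, 0.9])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(15)
        p = rng.uniform(size=25)
        assert np.all(np.array(bh_adjust(p)) >= p - 1e-15)

    def test_bonferroni(self):
        assert bonferroni_adjust([0.01]) == [pytest.approx(0.01)]
        assert bonferroni_adjust([0.01, 0.5]) == pytest.approx([0.02, 1.0])

    def test_bonferroni_dominates_bh(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(size=12)
        assert np.all(np.array(bonferroni_adjust(p)) >= np.array(bh_adjust(p)) - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bonferroni_adjust([-0.1])


class TestBootstrap:
    def test_identical_calls_constant_replicates(self):
        labels = {f"e{i}": "EGI" for i in range(5)} | {f"l{i}": "LGI" for i in range(5)}
        calls = {s: "S" for s in labels}
        comps = bootstrap_dominant_counts(labels, calls, R=50, seed=1)
        assert (comps["S"].replicate_counts_egi == 5).all()
        assert (comps["S"].replicate_counts_lgi == 5).all()

    def test_determinism(self, small_cohort):
        calls = small_cohort.truth_dominant_cn
        a = bootstrap_dominant_counts(small_cohort.truth_labels, calls, R=100, seed=9)
        b = bootstrap_dominant_counts(small_cohort.truth_labels, calls, R=100, seed=9)
        for sig in a:
            assert (a[sig].replicate_counts_egi == b[sig].replicate_counts_egi).all()
            assert (a[sig].replicate_counts_lgi == b[sig].replicate_counts_lgi).all()

    def test_replicate_mean_near_observed(self, small_cohort):
        calls = small_cohort.truth_dominant_cn
        comps = bootstrap_dominant_counts(small_cohort.truth_labels, calls,
                                          R=1000, seed=2)
        n_egi = sum(1 for g in small_cohort.truth_labels.values() if g == "EGI")
        for comp in comps.values():
            obs = comp.observed_egi
            p = obs / n_egi
            se = np.sqrt(n_egi * p * (1 - p)) / np.sqrt(1000) * np.sqrt(1000)
            # binomial SD of one replicate count; mean of R is much tighter
            sd_mean = np.sqrt(max(n_egi * p * (1 - p), 1e-9) / 1000)
            assert abs(comp.replicate_counts_egi.mean() - obs) <= max(3 * sd_mean, 0.5)

    def test_r_too_small(self):
        with pytest.raises(ValueError):
            bootstrap_dominant_counts({"a": "EGI", "b": "LGI"},
                                      {"a": "S", "b": "S"}, R=1, seed=1)

    def test_full_comparison_fields(self, small_cohort):
        comps = bootstrap_signature_comparison(
            small_cohort.truth_labels, small_cohort.truth_dominant_cn, R=200, seed=3)
        assert [c.signature for c in comps] == sorted(c.signature for c in comps)
        for c in comps:
            assert 0 <= c.ad_p <= 1 and 0 <= c.ad_p_adj <= 1
            assert c.ad_p_adj >= c.ad_p - 1e-12
            assert c.d_ci[0] <= c.cohen_d <= c.d_ci[1]
            assert c.d_bin in ("negligible", "small", "medium", "large")


class TestAndersonDarling:
    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = rng.normal(size=15)
            y = rng.normal(0.5, 1.2, size=20)
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    expected = sps.anderson_ksamp([x, y]).statistic
            assert _ad2_normalized([x, y]) == pytest.approx(expected, abs=1e-10)

    def test_statistic_matches_scipy_with_ties(self):
        rng = np.random.default_rng(18)
        x = rng.integers(0, 5, size=14).astype(float)
        y = rng.integers(0, 5, size=11).astype(float)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            expected = sps.anderson_ksamp([x, y]).statistic
        assert _ad2_normalized([x, y]) == pytest.approx(expected, abs=1e-10)

    def test_symmetry(self):
        x = [1.0, 3.0, 5.0, 9.0]
        y = [2.0, 4.0, 8.0, 16.0]
        sx, px, _ = ad_ksample_test(x, y)
        sy, py, _ = ad_ksample_test(y, x)
        assert sx == pytest.approx(sy) and px == pytest.approx(py)

    def test_identical_samples_high_p(self):
        x = list(np.arange(20.0))
        _, p, degen = ad_ksample_test(x, x)
        assert not degen and p > 0.5

    def test_constant_pooled_degenerate(self):
        _, p, degen = ad_ksample_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert degen and p == 1.0

    def test_exact_permutation_matches_full_enumeration(self):
        """n=5,5: the reported p equals exhaustive enumeration over all
        C(10,5) splits using scipy's statistic as the oracle."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        y = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        stat, p, _ = ad_ksample_test(x, y)
        pooled = np.concatenate([x, y])
        import warnings
        count = total = 0
        for combo in itertools.combinations(range(10), 5):
            xi = pooled[list(combo)]
            yi = pooled[[i for i in range(10) if i not in combo]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = sps.anderson_ksamp([xi, yi]).statistic
            if s >= stat - 1e-9:
                count += 1
            total += 1
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_asymptotic_p_uncapped_for_huge_shift(self):
        x = list(np.arange(100.0))
        y = list(np.arange(100.0) + 1000.0)
        _, p, _ = ad_ksample_test(x, y)
        assert p < 1e-4  # far below scipy's 0.001 floor


class TestCohensD:
    def test_zero_difference_negligible(self):
        d, (lo, hi), b = cohens_d_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and b == "negligible" and lo < 0 < hi

    def test_one_pooled_sd_is_large(self):
        x = np.array([0.0, 2.0, 4.0])
        y = x + x.std(ddof=1)  # shift by exactly one (pooled) SD
        d, _, b = cohens_d_ci(y, x)
        assert d == pytest.approx(1.0) and b == "large"

    def test_formula_oracle(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=12)
        y = rng.normal(0.5, 2.0, size=9)
        d, (lo, hi), _ = cohens_d_ci(x, y)
        sp = np.sqrt(((11) * x.var(ddof=1) + 8 * y.var(ddof=1)) / 19)
        d0 = (x.mean() - y.mean()) / sp
        se = np.sqrt(21 / 108 + d0**2 / 38)
        assert d == pytest.approx(d0, abs=1e-12)
        assert lo == pytest.approx(d0 - 1.959963984540054 * se, abs=1e-9)
        assert hi == pytest.approx(d0 + 1.959963984540054 * se, abs=1e-9)

    @pytest.mark.parametrize("shift,d_target,bin_", [
        (0.5, 0.1, "negligible"),
        (1.0, 0.2, "small"),      # lower edge of "small" is inclusive
        (2.5, 0.5, "medium"),     # 0.5 <= d < 0.8 is "medium"
        (4.0, 0.8, "large"),
    ])
    def test_bin_boundaries(self, shift, d_target, bin_):
        x = np.array([-5.0, 0.0, 5.0])  # sample SD exactly 5
        y = x + shift
        d, _, b = cohens_d_ci(y, x)
        assert d == d_target and b == bin_

    def test_zero_pooled_sd_flagged(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d_ci([1.0, 1.0], [2.0, 2.0])


class TestLogisticOr:
    def test_balanced_feature_or_near_one(self):
        # identical distribution across classes by construction
        vals = list(range(20))
        idx = [f"s{i}" for i in range(40)]
        feature = pd.Series(vals + vals, index=idx, dtype=float)
        labels = {f"s{i}": ("EGI" if i < 20 else "LGI") for i in range(40)}
        r = logistic_or(feature, labels, "f")
        assert r.estimate == pytest.approx(1.0, abs=1e-6)
        assert r.p_raw > 0.9

    def test_binary_feature_equals_cross_product_ratio(self):
        # counts: x=1: 30 LGI, 10 EGI; x=0: 20 LGI, 40 EGI
        rows = ([("LGI", 1.0)] * 30 + [("EGI", 1.0)] * 10
                + [("LGI", 0.0)] * 20 + [("EGI", 0.0)] * 40)
        idx = [f"s{i}" for i in range(len(rows))]
        feature = pd.Series([v for _, v in rows], index=idx)
        labels = {s: g for s, (g, _) in zip(idx, rows)}
        r = logistic_or(feature, labels, "f")
        expected = (30 / 10) / (20 / 40)  # odds(LGI|x=1)/odds(LGI|x=0) = 6
        assert r.estimate == pytest.approx(expected, abs=1e-6)

    def test_separation_flagged_as_bound(self):
        idx = [f"s{i}" for i in range(20)]
        feature = pd.Series(list(range(20)), index=idx, dtype=float)
        labels = {f"s{i}": ("EGI" if i < 10 else "LGI") for i in range(20)}
        r = logistic_or(feature, labels, "f")
        assert "separation" in r.note
        assert r.direction == "LGI" and r.estimate == np.inf

    def test_constant_feature_degenerate(self):
        idx = [f"s{i}" for i in range(10)]
        feature = pd.Series([1.0] * 10, index=idx)
        labels = {f"s{i}": ("EGI" if i < 5 else "LGI") for i in range(10)}
        r = logistic_or(feature, labels, "f")
        assert r.estimate == 1.0 and "degenerate" in r.note

    def test_single_class_errors(self):
        feature = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            logistic_or(feature, {"a": "EGI", "b": "EGI"}, "f")

    def test_relabel_inverts_or(self):
        rng = np.random.default_rng(20)
        idx = [f"s{i}" for i in range(100)]
        feature = pd.Series(rng.normal(size=100), index=idx)
        labels = {s: ("EGI" if rng.random() < 0.5 else "LGI") for s in idx}
        flipped = {s: ("LGI" if g == "EGI" else "EGI") for s, g in labels.items()}
        r1 = logistic_or(feature, labels, "f")
        r2 = logistic_or(feature, flipped, "f")
        assert r1.estimate * r2.estimate == pytest.approx(1.0, abs=1e-9)

    def test_planted_shift_bonferroni_significant(self):
        rng = np.random.default_rng(21)
        n = 500
        idx = [f"s{i}" for i in range(2 * n)]
        labels = {s: ("EGI" if i < n else "LGI") for i, s in enumerate(idx)}
        df = pd.DataFrame(index=idx)
        df["shifted"] = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        for j in range(4):
            df[f"null{j}"] = rng.normal(size=2 * n)
        rows = feature_enrichment(df, labels)
        by = {r.feature: r for r in rows}
        assert by["shifted"].p_adj < 0.05 and by["shifted"].direction == "LGI"


class TestSubstitutionVafCorrelation:
    def _map(self, genes):
        return HallmarkMap(entries={g: frozenset({"apoptosis"}) for g in genes})

    def _muts(self, spec):
        """spec: list of (gene, n, mean_vaf); C>T mutations."""
        out = []
        pos = 1
        for gene, n, mv in spec:
            for _ in range(n):
                out.append(MutationRecord("s1", gene, "1", pos, "C", "T", mv, "ACA"))
                pos += 1
        return out

    def test_exact_linear_relation_r_one(self):
        spec = [(f"g{k}", k, 0.1 + 0.05 * k) for k in range(1, 6)]
        res, scatter = substitution_vaf_correlation(
            self._muts(spec), self._map([f"g{k}" for k in range(1, 6)]))
        assert len(res) == 1 and res[0].feature == "C>T"
        assert res[0].estimate == pytest.approx(1.0)

    def test_four_gene_fixture_matches_covariance_formula(self):
        spec = [("g1", 2, 0.4), ("g2", 5, 0.2), ("g3", 3, 0.7), ("g4", 8, 0.35)]
        res, scatter = substitution_vaf_correlation(
            self._muts(spec), self._map(["g1", "g2", "g3", "g4"]))
        counts = np.array([2, 5, 3, 8], dtype=float)
        vafs = np.array([0.4, 0.2, 0.7, 0.35])
        r_oracle = (np.mean(counts * vafs) - counts.mean() * vafs.mean()) / (
            counts.std() * vafs.std())
        assert res[0].estimate == pytest.approx(r_oracle, abs=1e-12)

    def test_independent_permutation_gives_small_r(self):
        rng = np.random.default_rng(22)
        genes = [f"g{k}" for k in range(60)]
        counts = rng.integers(1, 20, size=60)
        vafs = rng.uniform(0.1, 0.9, size=60)
        spec = [(g, int(n), float(v)) for g, n, v in zip(genes, counts, vafs)]
        res, _ = substitution_vaf_correlation(self._muts(spec), self._map(genes))
        assert abs(res[0].estimate) < 0.3
        assert res[0].p_raw > 0.05

    def test_few_genes_skipped(self):
        res, _ = substitution_vaf_correlation(
            self._muts([("g1", 2, 0.4), ("g2", 3, 0.5)]), self._map(["g1", "g2"]))
        assert res == []

    def test_indels_excluded(self):
        muts = self._muts([("g1", 3, 0.4), ("g2", 4, 0.5), ("g3", 5, 0.6)])
        muts.append(MutationRecord("s1", "g1", "1", 999, "CT", "A", 0.9, None))
        res, scatter = substitution_vaf_correlation(muts, self._map(["g1", "g2", "g3"]))
        assert scatter["count"].sum() == 12  # the indel never counted
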
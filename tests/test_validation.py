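"""Pyrosequencing validation statistics against hand-computed oracles."""


import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methmark.datatypes import ValidationError
from methmark.validation import (
    SeparationError,
    TwoByTwo,
    additive_score,
    dichotomize_median,
    gene_mean,
    kruskal_wallis,
    logistic_fit,
    or_from_2x2,
    percent_cells,
    pfaffl_fold_change,
    ranksum,
    site_correlations,
    tumor_fraction_sensitivity,
)


def pyro_frame(values_by_site, gene="HOXB2"):
    rows = []
    for site, vals in values_by_site.items():
        for i, v in enumerate(vals):
            rows.append((f"S{i}", gene, site, v))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "site", "percent"])


class TestSiteCorrelations:
    def test_identical_sites(self):
        t = pyro_frame({1: [10, 20, 30, 40], 2: [10, 20, 30, 40]})
        corr = site_correlations(t, "HOXB2")
        assert corr.loc[1, 2] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        t = pyro_frame({1: [10, 20, 30, 40], 2: [40, 30, 20, 10]})
        assert site_correlations(t, "HOXB2").loc[1, 2] == pytest.approx(-1.0)

    def test_hand_ranked_fixture(self):
        # site 1 ranks: 1,2,3,4,5,6 ; site 2 ranks: 2,1,3,4,6,5
        # Spearman = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 6*4/210 = 0.8857...
        t = pyro_frame({1: [5, 10, 20, 30, 40, 50], 2: [12, 8, 25, 33, 60, 55]})
        assert site_correlations(t, "HOXB2").loc[1, 2] == pytest.approx(1 - 24 / 210)


class TestGeneMean:
    def test_single_site_identity(self):
        t = pyro_frame({1: [10, 25]})
        gm = gene_mean(t, "HOXB2")
        assert gm.loc["S0", "mean_percent"] == 10

    def test_mean_of_three_sites(self):
        t = pyro_frame({1: [10], 2: [20], 3: [30]})
        assert gene_mean(t, "HOXB2").loc["S0", "mean_percent"] == pytest.approx(20.0)

    def test_missing_site_averages_observed(self):
        t = pyro_frame({1: [10, 12], 2: [20, 14]})
        t = t.drop(t[(t.sample_id == "S1") & (t.site == 2)].index)
        gm = gene_mean(t, "HOXB2")
        assert gm.loc["S1", "mean_percent"] == pytest.approx(12.0)
        assert gm.loc["S1", "n_sites"] == 1
        assert gm.loc["S0", "n_sites"] == 2


class TestKruskalWallis:
    def test_identical_groups_zero(self):
        h, p = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == 0.0 and p == 1.0

    def test_three_group_hand_value(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_tie_correction_against_direct_formula(self):
        groups = [[1, 1, 2], [2, 2, 3], [3, 4, 4]]
        h, _ = kruskal_wallis(*groups)
        # direct tie-corrected H computed from first principles
        allv = np.concatenate(groups)
        ranks = stats.rankdata(allv)
        N = len(allv)
        idx = 0
        h_raw = 0.0
        for g in groups:
            r = ranks[idx : idx + len(g)]
            h_raw += r.sum() ** 2 / len(g)
            idx += len(g)
        h_raw = 12.0 / (N * (N + 1)) * h_raw - 3 * (N + 1)
        _, counts = np.unique(allv, return_counts=True)
        correction = 1 - (counts**3 - counts).sum() / (N**3 - N)
        assert h == pytest.approx(h_raw / correction)

    def test_invariant_under_monotone_transform(self, rng):
        g1, g2 = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        h1, _ = kruskal_wallis(g1, g2)
        h2, _ = kruskal_wallis(np.exp(g1), np.exp(g2))
        assert h1 == pytest.approx(h2)


class TestRankSum:
    def test_symmetric_singletons(self):
        res = ranksum([1.0], [2.0])
        assert res.p == 1.0

    def test_exact_matches_scipy_enumeration(self, rng):
        for _ in range(5):
            a = rng.normal(0, 1, 4)
            b = rng.normal(1, 1, 4)
            res = ranksum(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.exact
            assert res.p == pytest.approx(ref.pvalue)

    def test_exact_enumeration_count(self):
        # 4 vs 4: p is a multiple of 1/70 (C(8,4) arrangements)
        res = ranksum([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.p == pytest.approx(2 / 70)

    def test_protection_gate(self):
        res = ranksum([1, 2, 3], [4, 5, 6], protected_by=0.2)
        assert not res.tested and res.p is None
        res2 = ranksum([1, 2, 3], [4, 5, 6], protected_by=0.01)
        assert res2.tested

    def test_large_sample_normal_approximation(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)
        res = ranksum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert not res.exact
        assert res.p == pytest.approx(ref.pvalue, rel=0.05)


class TestDichotomize:
    def test_even_split(self):
        assert dichotomize_median([1, 2, 3, 4]).tolist() == [0, 0, 1, 1]

    def test_all_equal_all_negative(self):
        assert dichotomize_median([5, 5, 5]).tolist() == [0, 0, 0]

    def test_value_at_median_is_negative(self):
        assert dichotomize_median([1, 2, 3]).tolist() == [0, 0, 1]

    def test_idempotent_on_binary(self):
        v = dichotomize_median([3, 1, 4, 1, 5])
        assert dichotomize_median(v).tolist() == v.tolist()


class TestOddsRatio:
    def test_printed_counts(self):
        # methylation-negative: 110 non-invasive / 8 invasive;
        # methylation-positive: 61 non-invasive / 53 invasive
        orr, (lo, hi), corrected = or_from_2x2(TwoByTwo(110, 8, 61, 53))
        assert orr == pytest.approx(53 * 110 / (8 * 61), rel=1e-12)
        assert orr == pytest.approx(11.95, abs=0.01)
        assert lo < orr < hi and not corrected

    def test_balanced_is_one(self):
        orr, _, _ = or_from_2x2(TwoByTwo(10, 10, 10, 10))
        assert orr == pytest.approx(1.0)

    def test_zero_cell_correction(self):
        orr, (lo, hi), corrected = or_from_2x2(TwoByTwo(10, 0, 5, 5))
        assert corrected and np.isfinite(orr) and np.isfinite(hi)

    def test_bad_margins_error(self):
        with pytest.raises(ValidationError):
            TwoByTwo(0, 0, 5, 5)


class TestLogistic:
    def test_single_binary_exposure_equals_crossproduct(self, rng):
        for _ in range(5):
            x = rng.integers(0, 2, 120)
            y = (rng.random(120) < np.where(x == 1, 0.7, 0.3)).astype(int)
            tab = pd.crosstab(x, y).to_numpy()
            orr, _, _ = or_from_2x2(TwoByTwo(tab[0, 0], tab[0, 1], tab[1, 0], tab[1, 1]))
            fit = logistic_fit(y, pd.DataFrame({"x": x}))
            assert fit.odds_ratios["x"] == pytest.approx(orr, abs=1e-6)
            assert fit.ci_low["x"] < fit.odds_ratios["x"] < fit.ci_high["x"]

    def test_separation_raises(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        x = y.copy()
        with pytest.raises(SeparationError):
            logistic_fit(y, pd.DataFrame({"x": x}))

    def test_wald_ci_shape(self, rng):
        x = rng.integers(0, 2, 200)
        z = rng.normal(0, 1, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(x - 0.3 * z)))).astype(int)
        fit = logistic_fit(y, pd.DataFrame({"x": x, "z": z}))
        np.testing.assert_allclose(
            fit.ci_low["x"], np.exp(fit.params["x"] - 1.96 * fit.se["x"])
        )


class TestAdditive:
    def test_all_three(self):
        assert additive_score(np.array([[1, 1, 1]]))[0] == 1

    def test_fewer(self):
        assert additive_score(np.array([[1, 1, 0]]))[0] == 0

    def test_printed_margins(self):
        # grade 1-2: 125 with <3 genes, 18 with all 3; grade 3: 8 and 11
        assert 18 + 11 == 29
        assert 125 + 8 == 133
        d = np.r_[np.ones((29, 3)), np.tile([1, 1, 0], (133, 1))]
        score = additive_score(d)
        assert score.sum() == 29 and (1 - score).sum() == 133


class TestTumorFraction:
    def test_independent_covariate_small_deltas(self, rng):
        n = 400
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < np.where(x == 1, 0.6, 0.3)).astype(int)
        tp = rng.uniform(75, 100, n)  # independent of everything
        out = tumor_fraction_sensitivity(y, pd.DataFrame({"x": x}), tp)
        assert not out["collinear"]
        assert abs(out["deltas"]["x"]) < 0.25

    def test_collinear_flagged(self, rng):
        x = rng.integers(0, 2, 50).astype(float)
        y = (rng.random(50) < 0.5).astype(int)
        out = tumor_fraction_sensitivity(y, pd.DataFrame({"x": x}), x * 10 + 75)
        assert "x" in out["collinear"]

    def test_deterministic(self, rng):
        n = 100
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < np.where(x == 1, 0.7, 0.2)).astype(int)
        tp = rng.uniform(75, 100, n)
        o1 = tumor_fraction_sensitivity(y, pd.DataFrame({"x": x}), tp)
        o2 = tumor_fraction_sensitivity(y, pd.DataFrame({"x": x}), tp)
        assert o1["deltas"] == o2["deltas"]


class TestPfaffl:
    def test_no_change(self):
        assert pfaffl_fold_change(2.0, 0.0, 2.0, 0.0) == 1.0

    def test_single_cycle_target(self):
        assert pfaffl_fold_change(2.0, 1.0, 2.0, 0.0) == 2.0

    def test_arithmetic_oracle(self):
        fold = pfaffl_fold_change(1.95, 7.0, 2.0, 0.5)
        assert fold == pytest.approx(1.95**7 / 2**0.5, rel=1e-12)
        assert fold == pytest.approx(75.81, abs=0.01)

    def test_invalid_efficiency(self):
        with pytest.raises(ValidationError):
            pfaffl_fold_change(0.0, 1.0, 2.0, 0.0)


def test_percent_cells_half_even():
    assert percent_cells([[110, 8]]).tolist() == [[93, 7]]
    assert percent_cells([[18, 11]]).tolist() == [[62, 38]]
    assert percent_cells([[1, 1]]).tolist() == [[50, 50]]
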
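"""Assay arithmetic, Wilcoxon signed-rank, Sidak, RM-ANOVA, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from mammostroma.stats import (ColonyAssay, LobuleMorphometry, SphereAssay,
                               category_fraction, colony_metrics, mfe_percent,
                               morphometry_summary, paired_correlation,
                               rm_anova, sidak_adjust, wilcoxon_signed_rank)


class TestSphereAndColony:
    def test_threshold_is_inclusive(self):
        assay = SphereAssay(100, (55.0, 49.0, 50.0, 120.0))
        assert mfe_percent(assay) == pytest.approx(3.0)

    def test_printed_style_ratio(self):
        assert mfe_percent(SphereAssay(6000, tuple([60.0] * 12))) == \
            pytest.approx(0.2)

    def test_no_spheres_zero(self):
        assert mfe_percent(SphereAssay(1000, ())) == 0.0

    def test_order_invariance(self, rng):
        d = tuple(rng.uniform(20, 120, 30))
        shuffled = tuple(rng.permutation(d))
        assert mfe_percent(SphereAssay(500, d)) == \
            mfe_percent(SphereAssay(500, shuffled))

    def test_colony_count_inclusive(self):
        assert colony_metrics(ColonyAssay((49, 50, 200)))["n_colonies"] == 2

    def test_type_proportions(self):
        out = colony_metrics(ColonyAssay((), type_counts={
            "luminal": 3, "mixed": 5, "basal": 2}))
        assert out["type_percent"] == {"luminal": 30.0, "mixed": 50.0,
                                       "basal": 20.0}
        assert sum(out["type_percent"].values()) == pytest.approx(100.0)

    def test_no_typed_colonies_signalled(self):
        with pytest.raises(ValueError):
            colony_metrics(ColonyAssay((), type_counts={"luminal": 0,
                                                        "mixed": 0, "basal": 0}))


class TestMorphometry:
    def test_fraction_and_mean(self):
        lobules = [LobuleMorphometry(100.0, f * 100.0) for f in (0.2, 0.3, 0.4)]
        out = morphometry_summary(lobules)
        assert out["mean_epithelial_fraction"] == pytest.approx(0.3)

    def test_few_lobules_warn(self):
        with pytest.warns(UserWarning):
            morphometry_summary([LobuleMorphometry(100.0, 40.0)])

    def test_epithelial_cannot_exceed_lobule(self):
        with pytest.raises(ValueError):
            morphometry_summary([LobuleMorphometry(10.0, 20.0)] * 3)


def enumeration_oracle(diffs):
    """Exact two-sided p by full enumeration over all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product((1, -1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s > 0))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.method == "exact"
        assert res.statistic == 21.0
        assert res.p_value == pytest.approx(2 / 64)

    def test_symmetric_differences_p_one(self):
        res = wilcoxon_signed_rank([3.0, -3.5, 1.0, -1.5, 2.0, -2.5])
        assert res.p_value > 0.8

    def test_zeros_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -3.0, 4.0])
        assert res.n_effective == 4

    def test_all_zero_signalled(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_tie_corrected_matches_hand_formula(self):
        d = np.array([1.5, -2.5, 2.5, 3.5, -1.5, 4.0, 2.0, -2.0, 5.0, 3.0])
        res = wilcoxon_signed_rank(d)
        assert res.method == "tie_corrected_normal"
        n = len(d)
        ranks = sps.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        mu = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24
        _, t = np.unique(ranks, return_counts=True)
        var -= ((t ** 3 - t).sum()) / 48
        p_hand = 2 * sps.norm.sf(abs((w - mu) / np.sqrt(var)))
        assert res.p_value == pytest.approx(p_hand, abs=1e-10)

    def test_tie_corrected_matches_scipy(self):
        d = np.array([1.5, -2.5, 2.5, 3.5, -1.5, 4.0, 2.0, -2.0, 5.0, 3.0])
        res = wilcoxon_signed_rank(d)
        sp = sps.wilcoxon(d, correction=False, method="approx")
        assert res.p_value == pytest.approx(sp.pvalue, abs=1e-12)

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(st.lists(st.sampled_from([-4.5, -3.0, -1.25, 1.0, 2.0, 3.5, 5.25]),
                    min_size=2, max_size=8))
    def test_exact_matches_full_enumeration(self, base):
        # perturb magnitudes so no ties, while keeping the drawn signs
        d = [v + i * 1e-3 * np.sign(v) for i, v in enumerate(base)]
        res = wilcoxon_signed_rank(d)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(enumeration_oracle(d), abs=1e-12)


class TestSidak:
    @pytest.mark.parametrize("p,m,expected", [
        (0.0, 5, 0.0), (1.0, 3, 1.0), (0.01, 3, 0.029701),
    ])
    def test_closed_form(self, p, m, expected):
        assert sidak_adjust([p], m)[0] == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_conservative(self, rng):
        p = np.sort(rng.uniform(0, 1, 20))
        adj = sidak_adjust(p, m=6)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)


class TestRmAnova:
    def make_frame(self, rng, n=8, k=4, effect=1.0):
        rows = []
        for s in range(n):
            base = rng.normal(0, 1)
            for c in range(k):
                rows.append({"participant": f"S{s}", "condition": f"C{c}",
                             "value": base + effect * c + rng.normal(0, 0.5)})
        return pd.DataFrame(rows)

    def test_matches_independent_oracle(self, rng):
        """F agrees with pingouin's repeated-measures decomposition."""
        pingouin = pytest.importorskip("pingouin")
        frame = self.make_frame(rng)
        res = rm_anova(frame)
        aov = pingouin.rm_anova(data=frame, dv="value", within="condition",
                                subject="participant")
        assert res.f_statistic == pytest.approx(float(aov["F"][0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(aov["p_unc"][0]), abs=1e-10)

    def test_contrasts_are_sidak_adjusted(self, rng):
        frame = self.make_frame(rng)
        res = rm_anova(frame)
        m = len(res.contrasts)
        np.testing.assert_allclose(
            res.contrasts.p_sidak,
            1 - (1 - res.contrasts.p) ** m, atol=1e-12)

    def test_incomplete_blocks_excluded_with_warning(self, rng):
        frame = self.make_frame(rng, n=5)
        frame = frame.drop(frame.index[(frame.participant == "S0")
                                       & (frame.condition == "C3")])
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova(frame)
        assert res.n_subjects == 4

    def test_too_few_subjects_error(self, rng):
        with pytest.raises(ValueError):
            rm_anova(self.make_frame(rng, n=2))

    def test_summary_renders(self, rng):
        text = rm_anova(self.make_frame(rng)).summary()
        assert "ANOVA" in text and "Sidak" in text


class TestCorrelationAndFractions:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = paired_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = paired_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = paired_correlation(x, y)
        expect = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            paired_correlation([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("k,n,mode,expected", [
        (0, 10, "one_decimal", 0.0),
        (10, 10, "integer", 100.0),
        (27, 65, "one_decimal", 41.5),
        (1373, 1519, "integer", 90.0),
        (1454, 1519, "integer", 96.0),
        (33, 80, "one_decimal", 41.3),  # exact half 41.25 rounds away from zero
        (5, 8, "integer", 63.0),        # 62.5 rounds away from zero
    ])
    def test_reporting_rounding(self, k, n, mode, expected):
        assert category_fraction(k, n, mode) == expected

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            category_fraction(5, 0)
        with pytest.raises(ValueError):
            category_fraction(7, 5)
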
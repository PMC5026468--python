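import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from retmosaic import anova_tukey, bh_adjust, retina_means, t_test, two_way_anova


def _group_table(groups, metric="m"):
    rows = []
    for g, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"retina_id": f"{g}{i}", "genotype": g,
                         "metric_name": metric, "value": float(v)})
    return pd.DataFrame(rows)


class TestRetinaMeans:
    def test_arithmetic_fixture(self):
        per_image = pd.DataFrame(
            {
                "image_id": list("abcdef"),
                "retina_id": ["r1", "r1", "r2", "r2", "r3", "r3"],
                "genotype": ["wt", "wt", "wt", "wt", "mut", "mut"],
                "value": [2.0, 4.0, 1.0, 2.0, 10.0, 20.0],
            }
        )
        out = retina_means(per_image, metric_name="pf")
        assert dict(zip(out["retina_id"], out["value"])) == {
            "r1": 3.0, "r2": 1.5, "r3": 15.0
        }

    def test_single_image_retina_is_identity(self):
        per_image = pd.DataFrame(
            {"image_id": ["a"], "retina_id": ["r1"], "genotype": ["wt"],
             "value": [0.75]}
        )
        assert retina_means(per_image)["value"].tolist() == [0.75]

    def test_conflicting_genotypes_rejected(self):
        per_image = pd.DataFrame(
            {
                "image_id": ["a", "b"],
                "retina_id": ["r1", "r1"],
                "genotype": ["wt", "mut"],
                "value": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="conflicting"):
            retina_means(per_image)


class TestAnovaTukey:
    def test_identical_groups_null(self):
        t = _group_table({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        omnibus = anova_tukey(t)[0]
        assert omnibus.statistic == pytest.approx(0.0, abs=1e-12)
        assert omnibus.p_raw == pytest.approx(1.0)

    def test_two_groups_equals_t_test(self):
        t = _group_table({"a": [1.0, 2, 4, 3], "b": [5.0, 7, 6, 9]})
        omnibus = anova_tukey(t)[0]
        tt = t_test(t)
        assert omnibus.p_raw == pytest.approx(tt.p_raw, rel=1e-10)
        assert omnibus.statistic == pytest.approx(tt.statistic**2, rel=1e-10)

    def test_hand_computed_fixture(self):
        # 3 groups, n=5 each; F computed by hand from the SS decomposition
        groups = {
            "g1": [6.0, 8, 4, 5, 3],
            "g2": [8.0, 12, 9, 11, 6],
            "g3": [13.0, 9, 11, 8, 7],
        }
        all_values = np.concatenate(list(groups.values()))
        grand = all_values.mean()
        ss_between = sum(5 * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                        for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / 12)
        omnibus = anova_tukey(_group_table(groups))[0]
        assert omnibus.statistic == pytest.approx(f_oracle, abs=1e-6)

    def test_tukey_reports_all_pairs(self):
        rng = np.random.default_rng(0)
        t = _group_table({g: rng.normal(m, 1, 5)
                          for g, m in [("a", 0), ("b", 1), ("c", 5)]})
        reports = anova_tukey(t)
        pairs = [r.groups for r in reports[1:]]
        assert pairs == [("a", "b"), ("a", "c"), ("b", "c")]
        assert all(r.adjustment == "tukey" for r in reports[1:])
        # the well-separated pair is detected
        assert reports[2].p_adjusted < 0.01

    def test_degenerate_group_rejected(self):
        t = _group_table({"a": [1.0, 2], "b": [3.0]})
        with pytest.raises(ValueError, match="degenerate"):
            anova_tukey(t)


class TestTwoWayAnova:
    @staticmethod
    def _layout(effect=0.0, n=7, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for geno, shift in [("wt", 0.0), ("mut", effect)]:
            for level in ("low", "mid", "high"):
                base = {"low": 30.0, "mid": 20.0, "high": 10.0}[level]
                for r in range(n):
                    rows.append(
                        {"genotype": geno, "threshold_level": level,
                         "value": base + shift + rng.normal(0, 2)}
                    )
        return pd.DataFrame(rows)

    def test_balanced_sums_of_squares_decompose(self):
        df = self._layout(effect=3.0, seed=1)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        model = smf.ols("value ~ C(genotype) * C(threshold_level)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert tab["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_large_genotype_shift_is_detected(self):
        reports = two_way_anova(self._layout(effect=6.0, seed=2))
        genotype_main = reports[0]
        assert "genotype" in genotype_main.test_name
        assert genotype_main.p_raw < 1e-4

    def test_no_effect_gives_large_p_typically(self):
        reports = two_way_anova(self._layout(effect=0.0, seed=3))
        assert reports[0].p_raw > 0.01

    def test_missing_cell_rejected(self):
        df = self._layout().query("~(genotype == 'wt' and threshold_level == 'mid')")
        with pytest.raises(ValueError, match="incomplete"):
            two_way_anova(df)


class TestTTest:
    def test_identical_groups(self):
        t = _group_table({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        rep = t_test(t)
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_raw == pytest.approx(1.0)

    def test_label_swap_negates_statistic(self):
        ta = _group_table({"a": [1.0, 2, 3], "b": [4.0, 5, 7]})
        tb = _group_table({"b": [1.0, 2, 3], "a": [4.0, 5, 7]})
        ra, rb = t_test(ta), t_test(tb)
        assert ra.statistic == pytest.approx(-rb.statistic)
        assert ra.p_raw == pytest.approx(rb.p_raw)

    def test_hand_computed_statistic(self):
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([5.0, 9.0, 10.0])
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 4
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        rep = t_test(_group_table({"a": a, "b": b}))
        assert rep.statistic == pytest.approx(t_oracle, rel=1e-12)

    def test_welch_flag(self):
        t = _group_table({"a": [1.0, 2, 3, 2], "b": [10.0, 30, 20, 25]})
        student, welch = t_test(t), t_test(t, welch=True)
        assert student.p_raw != welch.p_raw
        assert welch.test_name.startswith("Welch")

    def test_requires_exactly_two_groups(self):
        with pytest.raises(ValueError):
            t_test(_group_table({"a": [1.0, 2], "b": [3.0, 4], "c": [5.0, 6]}))


def _bh_oracle(p):
    """Direct step-up: adjusted p_(i) = min over j>=i of p_(j)*m/j, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    monotone = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(monotone, 1.0)
    return out


class TestBHAdjust:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.037]), [0.037])

    def test_three_value_arithmetic(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_step_up_fixture(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_step_up_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, size=12)
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_monotone_in_input_order_statistics(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        # sorting the inputs sorts the outputs identically
        np.testing.assert_allclose(np.sort(adj), bh_adjust(np.sort(p)))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
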
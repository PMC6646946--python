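"""Signal-detection evaluation: criterion, classification, d', correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isascore.detection import (
    category_effect_comparison,
    classify_effects,
    compare_dependent_correlations,
    correlation_analysis,
    criterion_eta,
    decile_variability,
    detection_counts,
    dprime,
    yates_chisq,
)


def make_records(eta_rt, eta_pe, eta_isa, measures=("lisas", "ies", "rcs", "rcs_c"),
                 experiment="exp1"):
    n = len(eta_rt)
    df = pd.DataFrame(
        {
            "experiment_id": experiment,
            "effect_name": [f"e{i}" for i in range(n)],
            "eta_rt_c": eta_rt,
            "eta_pe": eta_pe,
        }
    )
    for m in measures:
        df[f"eta_{m}"] = eta_isa if np.ndim(eta_isa) == 1 else eta_isa[m]
    return df


class TestCriterionEta:
    def test_known_f_quantile(self):
        # F_crit(.05; 1, 19) = 4.3807 -> eta = 4.3807/(4.3807+19)
        assert criterion_eta(0.05, 1, 19) == pytest.approx(0.18737, abs=5e-5)

    def test_limit_alpha_to_one(self):
        assert criterion_eta(0.9999, 1, 19) < 1e-6

    def test_monotone_decreasing_in_df_den(self):
        vals = [criterion_eta(0.05, 1, d) for d in range(5, 100, 7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            criterion_eta(1.5, 1, 10)
        with pytest.raises(ValueError):
            criterion_eta(0.05, 0, 10)


class TestClassifyEffects:
    def test_tie_at_criterion_counts_as_detection(self):
        crit = 0.2
        rec = make_records([crit], [crit], [crit])
        labels = classify_effects(rec, crit)
        assert (labels["large"]).all()
        assert (labels["category"] == "hit").all()

    def test_all_null_is_correct_rejection(self):
        rec = make_records([0.0], [0.0], [0.0])
        labels = classify_effects(rec, 0.2)
        assert (labels["category"] == "correct_rejection").all()

    def test_partition_exhaustive_exclusive(self, rng):
        n = 50
        rec = make_records(rng.random(n), rng.random(n), rng.random(n))
        labels = classify_effects(rec, 0.3)
        for m in ("lisas", "ies", "rcs", "rcs_c"):
            counts = detection_counts(labels, m)
            assert sum(counts) == n

    def test_large_if_either_component_reaches_criterion(self):
        rec = make_records([0.5, 0.0, 0.0], [0.0, 0.5, 0.0], [0.0, 0.0, 0.0])
        labels = classify_effects(rec, 0.3)
        lisas = labels[labels["measure"] == "lisas"]
        assert lisas["category"].tolist() == ["miss", "miss", "correct_rejection"]

    def test_missing_component_raises(self):
        rec = make_records([0.1], [np.nan], [0.1])
        with pytest.raises(ValueError, match="eta_pe"):
            classify_effects(rec, 0.2)

    def test_per_experiment_thresholds(self):
        rec = pd.concat(
            [
                make_records([0.25], [0.0], [0.25], experiment="a"),
                make_records([0.25], [0.0], [0.25], experiment="b"),
            ],
            ignore_index=True,
        )
        labels = classify_effects(rec, {"a": 0.2, "b": 0.3})
        lab = labels[labels["measure"] == "lisas"].set_index("experiment_id")
        assert lab.loc["a", "category"] == "hit"
        assert lab.loc["b", "category"] == "correct_rejection"


class TestDprime:
    def test_equal_corrected_rates_give_zero(self):
        t = dprime(3, 3, 3, 3)
        assert t.d_prime == pytest.approx(0.0, abs=1e-12)

    def test_loglinear_correction_values(self):
        t = dprime(4, 0, 0, 3)
        assert t.h_rate_corrected == pytest.approx(4.5 / 5)
        assert t.fa_rate_corrected == pytest.approx(0.5 / 4)

    def test_half_count_only_replaces_boundaries(self):
        t = dprime(5, 5, 0, 10, correction="half_count")
        assert t.h_rate_corrected == pytest.approx(0.5)  # untouched
        assert t.fa_rate_corrected == pytest.approx(1 / 20)

    def test_monotone_in_hits_and_false_alarms(self):
        base = dprime(5, 5, 3, 7).d_prime
        assert dprime(6, 4, 3, 7).d_prime > base
        assert dprime(5, 5, 4, 6).d_prime < base

    @given(
        h=st.integers(0, 30), m=st.integers(0, 30),
        fa=st.integers(0, 30), cr=st.integers(0, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_loglinear_rates_never_hit_bounds(self, h, m, fa, cr):
        if h + m + fa + cr == 0:
            return
        t = dprime(h, m, fa, cr)
        assert 0 < t.h_rate_corrected < 1
        assert 0 < t.fa_rate_corrected < 1
        assert np.isfinite(t.d_prime)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dprime(-1, 2, 3, 4)


class TestCorrelationAnalysis:
    def test_perfect_linear_isa(self, rng):
        eta_rt = rng.random(40)
        rec = make_records(eta_rt, rng.random(40), 0.5 * eta_rt + 0.1)
        out = correlation_analysis(rec)
        row = out[(out["measure"] == "lisas") & (out["component"] == "rt_c")].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-12)
        # partialling out PE cannot destroy an exact linear relation
        assert row["partial_r"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_pingouin_partial(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        x = rng.random(n)
        rec = make_records(
            x, 0.4 * x + 0.3 * rng.random(n), 0.6 * x + 0.2 * rng.random(n)
        )
        out = correlation_analysis(rec)
        df = pd.DataFrame(
            {
                "isa": rec["eta_lisas"],
                "rt": rec["eta_rt_c"],
                "pe": rec["eta_pe"],
            }
        )
        ref = pingouin.partial_corr(df, x="isa", y="rt", covar="pe")
        row = out[(out["measure"] == "lisas") & (out["component"] == "rt_c")].iloc[0]
        assert row["partial_r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_fisher_ci_brackets_r(self, rng):
        rec = make_records(rng.random(30), rng.random(30), rng.random(30))
        out = correlation_analysis(rec)
        assert (out["ci_low"] <= out["r"]).all()
        assert (out["r"] <= out["ci_high"]).all()

    def test_partial_of_independent_noise_near_zero(self, rng):
        n = 400
        rec = make_records(rng.random(n), rng.random(n), rng.random(n))
        out = correlation_analysis(rec)
        assert (out["partial_r"].abs() < 3 / np.sqrt(n)).all()

    def test_too_few_or_degenerate(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            correlation_analysis(make_records([0.1], [0.1], [0.1]))
        rec = make_records(np.full(10, 0.3), rng.random(10), rng.random(10))
        with pytest.raises(ValueError, match="zero variance"):
            correlation_analysis(rec)


class TestDependentCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_dependent_correlations(0.6, 0.6, 0.4, 50)
        assert z == 0.0 and p == 1.0

    def test_p_decreases_in_n(self):
        ps = [
            compare_dependent_correlations(0.8, 0.6, 0.5, n)[1]
            for n in (20, 50, 100, 400)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_antisymmetry(self):
        z1, _ = compare_dependent_correlations(0.8, 0.6, 0.5, 50)
        z2, _ = compare_dependent_correlations(0.6, 0.8, 0.5, 50)
        assert z1 == pytest.approx(-z2, rel=1e-12)

    def test_null_calibration_monte_carlo(self, rng):
        # x correlates 0.5 with both y and z; corr(y,z) = 0.3; the test of
        # r_xy = r_xz should reject at ~5%
        n, sims = 60, 2000
        cov = np.array([[1, 0.5, 0.5], [0.5, 1, 0.3], [0.5, 0.3, 1]])
        L = np.linalg.cholesky(cov)
        rejections = 0
        for _ in range(sims):
            X = rng.standard_normal((n, 3)) @ L.T
            R = np.corrcoef(X, rowvar=False)
            z, p = compare_dependent_correlations(R[0, 1], R[0, 2], R[1, 2], n)
            rejections += p < 0.05
        rate = rejections / sims
        assert 0.03 < rate < 0.075

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            compare_dependent_correlations(1.0, 0.5, 0.5, 50)


class TestDecileVariability:
    def _records(self, rng, n=50):
        eta_rt = rng.random(n)
        return make_records(eta_rt, rng.random(n), rng.random(n)), eta_rt

    def test_constant_isa_gives_zero_sds(self, rng):
        n = 50
        rec = make_records(rng.random(n), rng.random(n), np.full(n, 0.4))
        out = decile_variability(rec)
        assert np.allclose(out["sd_eta"].dropna(), 0.0)

    def test_isa_equal_to_rt_gives_increasing_decile_means(self, rng):
        n = 50
        eta_rt = rng.random(n)
        rec = make_records(eta_rt, rng.random(n), eta_rt)
        out = decile_variability(rec)
        m = out[out["measure"] == "lisas"].sort_values("decile")["mean_eta"]
        assert m.is_monotonic_increasing and m.nunique() == 10

    def test_matches_sort_and_slice_oracle(self, rng):
        rec, eta_rt = self._records(rng, n=50)
        out = decile_variability(rec)
        order = np.argsort(eta_rt, kind="stable")
        isa = rec["eta_lisas"].to_numpy()
        for d in range(1, 11):
            sel = isa[order[(d - 1) * 5 : d * 5]]
            row = out[(out["measure"] == "lisas") & (out["decile"] == d)].iloc[0]
            assert row["mean_eta"] == pytest.approx(sel.mean())
            assert row["sd_eta"] == pytest.approx(sel.std(ddof=1))

    def test_effect_level_grouping(self, rng):
        rec, _ = self._records(rng)
        out = decile_variability(rec)
        lv = out.drop_duplicates("decile").set_index("decile")["effect_level"]
        assert lv.loc[3] == "1-3" and lv.loc[4] == "4-6" and lv.loc[7] == "7-10"

    def test_too_few_records(self, rng):
        rec, _ = self._records(rng, n=8)
        with pytest.raises(ValueError, match="deciles"):
            decile_variability(rec)


class TestCategoryComparison:
    def test_identical_series_zero_differences(self, rng):
        n = 60
        eta_rt = rng.random(n)
        eta_pe = 0.5 * eta_rt
        rec = make_records(eta_rt, eta_pe, np.maximum(eta_rt, eta_pe))
        labels = classify_effects(rec, 0.3)
        out = category_effect_comparison(rec, labels, measure="rcs")
        means = out["means"].pivot(index="category", columns="series",
                                   values="mean_eta").dropna()
        assert np.allclose(means["rcs"], means["max(rt,pe)"], atol=1e-12)

    def test_inflated_false_alarm_measure(self, rng):
        # a measure that blows up small effects shows an FA-category mean
        # exceeding the component mean
        n = 200
        eta_rt = rng.random(n) * 0.6
        eta_pe = rng.random(n) * 0.2
        inflated = np.where(eta_rt < 0.2, eta_rt + 0.25, eta_rt)
        rec = make_records(eta_rt, eta_pe, inflated, measures=("rcs",))
        labels = classify_effects(rec, 0.3, measures=("rcs",))
        out = category_effect_comparison(rec, labels, measure="rcs")
        means = out["means"].pivot(index="category", columns="series",
                                   values="mean_eta")
        assert means.loc["false_alarm", "rcs"] > means.loc["false_alarm", "max(rt,pe)"]
        anova = out["anova"].set_index("effect")
        assert anova.loc["category:measure", "p_value"] < 0.05

    def test_anova_df_structure(self, rng):
        n = 80
        rec = make_records(rng.random(n), rng.random(n), rng.random(n))
        labels = classify_effects(rec, 0.3)
        out = category_effect_comparison(rec, labels, measure="lisas")
        anova = out["anova"].set_index("effect")
        k = out["means"].dropna(subset=["mean_eta"])["category"].nunique()
        assert anova.loc["category", "df_num"] == k - 1
        assert anova.loc["measure", "df_den"] == n - k

    def test_empty_category_warns(self, rng):
        n = 30
        eta_rt = rng.random(n) * 0.1  # nothing large
        rec = make_records(eta_rt, eta_rt, eta_rt)
        labels = classify_effects(rec, 0.5)
        with pytest.warns(UserWarning, match="empty"):
            out = category_effect_comparison(rec, labels, measure="rcs")
        hit_row = out["means"].query("category == 'hit' and series == 'rcs'")
        assert np.isnan(hit_row["mean_eta"].iloc[0])


class TestYatesChisq:
    def test_proportional_table_is_zero(self):
        chi2, p = yates_chisq(10, 20, 30, 60)
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy_continuity_corrected(self, rng):
        cases = [(10, 90, 50, 50)] + [
            tuple(rng.integers(1, 80, size=4)) for _ in range(10)
        ]
        for a, b, c, d in cases:
            chi2, p = yates_chisq(a, b, c, d)
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=True)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_transposition_invariance(self):
        assert yates_chisq(3, 14, 25, 6)[0] == pytest.approx(
            yates_chisq(3, 25, 14, 6)[0], rel=1e-12
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            yates_chisq(0, 0, 5, 5)
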
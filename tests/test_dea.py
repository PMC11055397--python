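import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from combistat import (CombistatError, Comparison, DEACutoffs, bh_adjust,
                       estimate_prior, filter_deps, fit_two_group, moderate,
                       run_comparison, run_plan, trigamma_inverse,
                       enumerate_all)

from conftest import make_matrix, make_metadata


def two_class_fixture(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    m = make_matrix(values)
    meta = make_metadata(["A"] * (n // 2) + ["B"] * (n - n // 2))
    return m, meta, Comparison(("A",), ("B",))


class TestFitTwoGroup:
    def test_closed_form_example(self):
        m, meta, comp = two_class_fixture([[3, 4, 5, 1, 2, 3]])
        fit = fit_two_group(m, meta, comp)
        assert fit.logfc[0] == pytest.approx(2.0)
        assert fit.s2[0] == pytest.approx(1.0)
        assert fit.d == 4
        assert fit.v_c == pytest.approx(2.0 / 3.0)

    def test_identical_groups_zero_logfc(self):
        rng = np.random.default_rng(1)
        half = rng.normal(20, 1, size=(10, 3))
        m, meta, comp = two_class_fixture(np.hstack([half, half]))
        fit = fit_two_group(m, meta, comp)
        np.testing.assert_allclose(fit.logfc, 0.0, atol=1e-12)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        m, meta, comp = two_class_fixture(rng.normal(20, 1, size=(10, 6)))
        fit = fit_two_group(m, meta, comp)
        rev = fit_two_group(m, meta, Comparison(("B",), ("A",)))
        # name ordering is deterministic, so swap by relabeling metadata
        meta_rev = make_metadata(["B"] * 3 + ["A"] * 3)
        rev = fit_two_group(m, meta_rev, comp)
        np.testing.assert_allclose(rev.logfc, -fit.logfc)
        np.testing.assert_allclose(rev.s2, fit.s2)
        assert rev.d == fit.d

    def test_single_replicate_group_rejected(self):
        m = make_matrix(np.ones((3, 3)))
        meta = make_metadata(["A", "B", "B"])
        with pytest.raises(CombistatError, match=">=2 samples"):
            fit_two_group(m, meta, Comparison(("A",), ("B",)))

    def test_missing_values_rejected(self):
        values = np.ones((3, 4))
        values[0, 0] = np.nan
        m = make_matrix(values)
        meta = make_metadata(["A", "A", "B", "B"])
        with pytest.raises(CombistatError, match="imputation"):
            fit_two_group(m, meta, Comparison(("A",), ("B",)))

    def test_log10_input_converted_to_log2(self):
        values = np.array([[2.0, 2.0, 1.0, 1.0]])   # log10 units
        m = make_matrix(values, scale_tag="log10")
        meta = make_metadata(["A", "A", "B", "B"])
        fit = fit_two_group(m, meta, Comparison(("A",), ("B",)))
        assert fit.logfc[0] == pytest.approx(np.log2(10.0))   # 1 log10 unit


class TestEstimatePrior:
    def test_trigamma_inverse_round_trip(self):
        y = special.polygamma(1, 2.0)
        assert trigamma_inverse(float(y)) == pytest.approx(2.0, abs=1e-8)

    def test_equal_variances_hit_cap(self):
        # zero excess dispersion: infinite prior df; s0^2 is the chi-square
        # bias-corrected back-transform of mean log s2
        d0, s0 = estimate_prior(np.full(100, 0.25), d=4)
        assert d0 >= 1e6
        expected = 0.25 * np.exp(np.log(2.0) - special.polygamma(0, 2.0))
        assert s0 == pytest.approx(float(expected), rel=1e-10)

    def test_parameter_recovery(self):
        # scaled-inverse-chi-square prior with true d0=4, s0^2=1, d=4
        rng = np.random.default_rng(123)
        G = 20000
        true_d0, true_s0, d = 4.0, 1.0, 4
        sigma2 = true_s0 * true_d0 / rng.chisquare(true_d0, size=G)
        s2 = sigma2 * rng.chisquare(d, size=G) / d
        d0, s0 = estimate_prior(s2, d=d)
        assert 3.5 <= d0 <= 4.5
        assert 0.9 <= s0 <= 1.1

    def test_too_few_variances_rejected(self):
        with pytest.raises(CombistatError, match=">=10"):
            estimate_prior(np.ones(5), d=4)


class TestModerate:
    def test_d0_zero_matches_pooled_t(self):
        m, meta, comp = two_class_fixture([[3, 4, 5, 1, 2, 3]])
        fit = fit_two_group(m, meta, comp)
        tab = moderate(fit, d0=0.0, s0_sq=1.0)
        t_expected = 2.0 / np.sqrt(1.0 * (2.0 / 3.0))
        assert tab["t"][0] == pytest.approx(t_expected, abs=1e-9)
        assert tab["P"][0] == pytest.approx(
            2 * stats.t.sf(t_expected, 4), abs=1e-9)

    def test_oracle_equivalence_100_random_proteins(self):
        # with d0 = 0 the moderated statistic must equal scipy's pooled
        # two-sample t to 1e-10
        rng = np.random.default_rng(3)
        values = rng.normal(20, 2, size=(100, 8))
        m = make_matrix(values)
        meta = make_metadata(["A"] * 4 + ["B"] * 4)
        fit = fit_two_group(m, meta, Comparison(("A",), ("B",)))
        tab = moderate(fit, d0=0.0, s0_sq=123.0)
        ref = stats.ttest_ind(values[:, :4], values[:, 4:], axis=1)
        np.testing.assert_allclose(tab["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(tab["P"], ref.pvalue, atol=1e-10)

    def test_d0_cap_orders_by_logfc(self):
        rng = np.random.default_rng(4)
        values = rng.normal(20, 2, size=(50, 6))
        m, meta, comp = two_class_fixture(values)
        fit = fit_two_group(m, meta, comp)
        tab = moderate(fit, d0=1e6, s0_sq=0.5)
        np.testing.assert_allclose(tab["s2_post"], 0.5)
        order_t = np.argsort(-np.abs(tab["t"].to_numpy()))
        order_fc = np.argsort(-np.abs(tab["logFC"].to_numpy()))
        np.testing.assert_array_equal(order_t, order_fc)

    def test_zero_logfc_gives_p_one(self):
        m, meta, comp = two_class_fixture([[5, 6, 5, 6]])
        fit = fit_two_group(m, meta, comp)
        tab = moderate(fit, d0=2.0, s0_sq=1.0)
        assert tab["t"][0] == pytest.approx(0.0)
        assert tab["P"][0] == pytest.approx(1.0)

    def test_moderated_variance_convex(self):
        rng = np.random.default_rng(5)
        values = rng.normal(20, 2, size=(200, 6))
        m, meta, comp = two_class_fixture(values)
        fit = fit_two_group(m, meta, comp)
        d0, s0 = estimate_prior(fit.s2, fit.d)
        tab = moderate(fit, d0, s0)
        lo = np.minimum(fit.s2, s0)
        hi = np.maximum(fit.s2, s0)
        assert ((tab["s2_post"] >= lo - 1e-12) & (tab["s2_post"] <= hi + 1e-12)).all()


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.3])), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(CombistatError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.uniform(size=500)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    def test_properties(self, p_list):
        p = np.array(p_list)
        q = bh_adjust(p)
        assert ((q >= p - 1e-12) & (q <= 1.0 + 1e-12)).all()
        # q is monotone in the order of p
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFilterAndPlan:
    def _toy_result(self):
        rng = np.random.default_rng(7)
        base = rng.normal(20, 0.3, size=(60, 8))
        base[:10, :4] += 3.0           # 10 strong DEPs, higher in A
        m = make_matrix(base)
        meta = make_metadata(["A"] * 4 + ["B"] * 4)
        return m, meta

    def test_cutoff_rules(self):
        tab = pd.DataFrame({
            "protein": ["a", "b", "c"],
            "logFC": [2.0, 0.5, -1.5],
            "s2": [0.1] * 3, "s2_post": [0.1] * 3,
            "t": [5.0, 1.0, -4.0],
            "P": [0.0001, 0.3, 0.001],
        })
        res = filter_deps(tab, Comparison(("A",), ("B",)), 4.0, 0.1,
                          DEACutoffs(1.0, 0.05))
        sig = res.table.set_index("protein")
        assert sig.loc["a", "significant"] and sig.loc["a", "direction"] == "up"
        assert not sig.loc["b", "significant"]
        assert sig.loc["c", "significant"] and sig.loc["c", "direction"] == "down"
        assert res.significant_ids == ["a", "c"]   # sorted by P

    def test_table_sorted_by_p(self):
        m, meta = self._toy_result()
        res = run_comparison(m, meta, Comparison(("A",), ("B",)))
        p = res.table["P"].to_numpy()
        assert (np.diff(p) >= 0).all()

    def test_plan_runs_all_comparisons(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(20, 1, size=(30, 9)))
        meta = make_metadata(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        run = run_plan(m, meta, enumerate_all(meta.class_set()))
        assert len(run.results) == 6
        assert run.errors == {}

    def test_failing_comparison_recorded_others_run(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(20, 1, size=(30, 7)))
        meta = make_metadata(["A"] * 3 + ["B"] * 3 + ["C"])   # C has 1 replicate
        run = run_plan(m, meta, enumerate_all(meta.class_set()))
        assert any("C" in name for name in run.errors)
        ok_names = {r.comparison.name for r in run.results}
        assert "A_vs_B" in ok_names

    def test_comparison_independent_of_plan(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.normal(20, 1, size=(40, 9)))
        meta = make_metadata(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        alone = run_comparison(m, meta, Comparison(("A",), ("B",)))
        in_plan = next(r for r in run_plan(m, meta, enumerate_all(meta.class_set())).results
                       if r.comparison.name == "A_vs_B")
        pd.testing.assert_frame_equal(alone.table, in_plan.table)

    def test_permuted_labels_yield_no_calls(self):
        # label permutation destroys the class signal: almost nothing at
        # q <= 0.05, even with spiked effects present in the data
        from combistat import (ImputeConfig, SpikeInConfig, generate,
                               impute_normal_draw, log_transform,
                               quantile_normalize)
        frac = []
        for seed in range(1, 6):
            m, meta, _ = generate(SpikeInConfig(n_proteins=500, seed=seed))
            m2 = quantile_normalize(log_transform(m, 2, nonpositive="mask"))
            m3 = impute_normal_draw(m2, ImputeConfig(seed=seed))
            rng = np.random.default_rng(100 + seed)
            perm = list(rng.permutation([r.class_label for r in meta.records]))
            pmeta = make_metadata(perm, sample_ids=meta.sample_ids)
            res = run_comparison(m3, pmeta, Comparison(("A",), ("B",)))
            frac.append((res.table["adjP"] <= 0.05).mean())
        assert np.mean(frac) <= 0.01
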
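"""Regression engine: OLS against a hand-rolled oracle, stepwise
selection, leave-one-out Q², VIF closed forms, mean-CI algebra and the
applicability-domain check."""

import numpy as np
import pytest

from qppr_pbpk import datasets, regression
from qppr_pbpk.regression import (
    DomainBox,
    check_domain,
    fit_multilinear,
    loo_q2,
    normality_plot_data,
    predict_mean_ci,
    stepwise_select,
    vif,
)
from qppr_pbpk.workflows import PREDICTORS, _reg_records


def _make_records(X, y, names):
    return [(dict(zip(names, row)), yi) for row, yi in zip(X, y)]


@pytest.fixture(scope="module")
def cal_records(calibration):
    return _reg_records(calibration)


class TestFitMultilinear:
    def test_matches_lstsq_oracle(self, cal_records):
        """Coefficients and R² agree with a from-scratch normal-equations
        solution (independent of statsmodels)."""
        fit = fit_multilinear(cal_records, PREDICTORS, compute_q2=False)
        X = np.column_stack(
            [np.ones(len(cal_records))]
            + [[d[p] for d, _ in cal_records] for p in PREDICTORS])
        y = np.array([v for _, v in cal_records])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.coefficients == pytest.approx(beta, rel=1e-10)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) ** 2).sum()
        assert fit.r2 == pytest.approx(r2, rel=1e-12)
        dof = len(y) - X.shape[1]
        s = np.sqrt(resid @ resid / dof)
        assert fit.s == pytest.approx(s, rel=1e-12)
        se = s * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        assert fit.coef_standard_errors == pytest.approx(se, rel=1e-10)

    def test_perfect_linear_response(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        y = 2.0 + 3.0 * X[:, 0] - 1.5 * X[:, 1]
        fit = fit_multilinear(_make_records(X, y, ("a", "b")), ("a", "b"),
                              compute_q2=False)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.s == pytest.approx(0.0, abs=1e-9)
        assert fit.coefficients == pytest.approx([2.0, 3.0, -1.5])

    def test_rank_deficient_design_names_collinear_column(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=10)
        X = np.column_stack([a, 2 * a])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_multilinear(_make_records(X, a, ("a", "b")), ("a", "b"))

    def test_too_few_observations_rejected(self):
        X = np.eye(3)
        with pytest.raises(ValueError, match="n > p"):
            fit_multilinear(_make_records(X, X[:, 0], ("a", "b", "c")),
                            ("a", "b", "c"))


class TestStepwiseSelect:
    def test_selects_all_three_calibration_descriptors(self, cal_records):
        fit = stepwise_select(cal_records, list(PREDICTORS))
        assert set(fit.predictor_names) == set(PREDICTORS)
        assert any(t.startswith("enter:") for t in fit.selection_trace)

    def test_pure_noise_column_rarely_selected(self, cal_records):
        """Under the null a noise column should enter at roughly the
        nominal rate; over 40 seeded replicates its selection frequency
        stays well below chance-plus-slack, and the three real
        descriptors are always kept."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(40):
            noisy = [({**d, "noise": rng.normal()}, y)
                     for d, y in cal_records]
            fit = stepwise_select(noisy, list(PREDICTORS) + ["noise"])
            hits += "noise" in fit.predictor_names
            assert set(PREDICTORS) <= set(fit.predictor_names)
        assert hits <= 8  # nominal 5% entry rate, generous binomial slack

    def test_single_perfect_candidate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        fit = stepwise_select(_make_records(x[:, None], 2 * x + 1, ("x",)),
                              ["x"])
        assert fit.predictor_names == ("x",)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_no_candidate_enters_gives_flagged_intercept_fit(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 1))
        y = rng.normal(size=20)  # unrelated
        fit = stepwise_select(_make_records(X, y, ("x",)), ["x"])
        assert fit.predictor_names == ()
        assert "no-candidate-entered" in fit.selection_trace
        assert fit.coefficients == pytest.approx([y.mean()])

    def test_threshold_ordering_enforced(self, cal_records):
        with pytest.raises(ValueError, match="p_enter"):
            stepwise_select(cal_records, list(PREDICTORS),
                            p_enter=0.2, p_remove=0.1)


class TestLooQ2:
    def test_brute_force_oracle_small_n(self):
        """Q² on a 5-point set equals the literal loop of 5 refits."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 1))
        y = 1.0 + 2.0 * X[:, 0] + rng.normal(scale=0.5, size=5)
        recs = _make_records(X, y, ("x",))
        Xd = np.column_stack([np.ones(5), X])
        press = 0.0
        for i in range(5):
            keep = [j for j in range(5) if j != i]
            beta = np.linalg.lstsq(Xd[keep], y[keep], rcond=None)[0]
            press += (y[i] - Xd[i] @ beta) ** 2
        expected = 1 - press / ((y - y.mean()) ** 2).sum()
        assert loo_q2(recs, ("x",)) == pytest.approx(expected, rel=1e-12)

    def test_perfect_linear_response_gives_one(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        y = 1.0 + X[:, 0] - X[:, 1]
        assert loo_q2(_make_records(X, y, ("a", "b")),
                      ("a", "b")) == pytest.approx(1.0, abs=1e-9)

    def test_q2_below_r2_on_noisy_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 2))
        y = X[:, 0] + rng.normal(scale=1.0, size=20)
        recs = _make_records(X, y, ("a", "b"))
        fit = fit_multilinear(recs, ("a", "b"))
        assert fit.q2 < fit.r2

    def test_calibration_q2_below_r2(self, cal_fit):
        assert cal_fit.q2 < cal_fit.r2

    def test_degenerate_response_rejected(self):
        X = np.arange(8.0)[:, None]
        with pytest.raises(ValueError, match="SSY"):
            loo_q2(_make_records(X, np.ones(8), ("x",)), ("x",))


class TestVif:
    def test_orthogonal_predictors_give_unity(self):
        a = np.tile([1.0, -1.0], 4)
        b = np.repeat([1.0, -1.0], 4)
        rows = [{"a": x, "b": y} for x, y in zip(a, b)]
        assert vif(rows, ("a", "b")) == pytest.approx([1.0, 1.0])

    def test_two_predictor_closed_form(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=50)
        b = 0.6 * a + rng.normal(scale=0.8, size=50)
        r = np.corrcoef(a, b)[0, 1]
        rows = [{"a": x, "b": y} for x, y in zip(a, b)]
        expected = 1 / (1 - r ** 2)
        assert vif(rows, ("a", "b")) == pytest.approx(
            [expected, expected], rel=1e-10)

    def test_perfect_collinearity_reports_infinite(self):
        a = np.arange(10.0)
        rows = [{"a": x, "b": 3 * x} for x in a]
        assert np.isinf(vif(rows, ("a", "b"))).all()


class TestPredictMeanCI:
    def test_centroid_leverage(self, cal_fit, calibration):
        """At the descriptor centroid the half-width collapses to
        t * s / sqrt(n)."""
        from scipy import stats
        X = np.array([r.descriptor_vector() for r in calibration])
        ci = predict_mean_ci(cal_fit, X.mean(axis=0))
        tq = stats.t.ppf(0.975, cal_fit.df_resid)
        assert ci.width == pytest.approx(2 * tq * cal_fit.s
                                         / np.sqrt(cal_fit.n), rel=1e-10)

    def test_bounds_bracket_point(self, cal_fit, calibration):
        for r in calibration:
            ci = predict_mean_ci(cal_fit, r.descriptor_vector())
            assert ci.lmci < ci.point < ci.umci

    def test_width_shrinks_with_sample_size(self):
        """sqrt(n) law at the centroid on synthetic chemicals with fixed
        noise."""
        widths = {}
        for n in (26, 104):
            recs = datasets.generate_synthetic_chemicals(n=n, seed=11)
            rr = [({"log_pow": r.log_pow, "log_pbw": r.log_pbw,
                    "ip": r.ip}, r.log_clint_pl_exp) for r in recs]
            fit = fit_multilinear(rr, PREDICTORS, compute_q2=False)
            centroid = np.mean([[r.log_pow, r.log_pbw, r.ip]
                                for r in recs], axis=0)
            widths[n] = predict_mean_ci(fit, centroid).width
        assert widths[104] < widths[26]
        assert widths[104] == pytest.approx(widths[26] / 2, rel=0.35)

    def test_dimension_mismatch_rejected(self, cal_fit):
        with pytest.raises(ValueError, match="shape"):
            predict_mean_ci(cal_fit, [1.0, 2.0])

    def test_coefficient_recovery_on_synthetic_chemicals(self):
        """Fitting 26 synthetic records generated from the calibrated
        coefficients plus sigma=0.3 noise recovers each coefficient within
        two standard errors."""
        recs = datasets.generate_synthetic_chemicals(n=26, seed=12,
                                                     noise_sd=0.3)
        rr = [({"log_pow": r.log_pow, "log_pbw": r.log_pbw, "ip": r.ip},
               r.log_clint_pl_exp) for r in recs]
        fit = fit_multilinear(rr, PREDICTORS, compute_q2=False)
        truth = datasets.CALIBRATED_COEFFICIENTS
        for est, se, true in zip(fit.coefficients,
                                 fit.coef_standard_errors, truth):
            assert abs(est - true) < 2 * se


class TestDomainCheck:
    BOX = DomainBox(datasets.DESCRIPTOR_DOMAIN)

    def test_benzene_inside(self):
        flags = check_domain({"log_pow": 1.99, "log_pbw": 0.820,
                              "ip": 9.743}, self.BOX)
        assert flags["overall"]

    def test_boundary_is_inside(self):
        flags = check_domain({"log_pow": 1.09, "log_pbw": 0.16,
                              "ip": 11.276}, self.BOX)
        assert flags["overall"]

    def test_evaluation_outliers_flagged_per_descriptor(self, evaluation):
        """1,2,4-trimethylbenzene sits outside the calibration box (its
        ionization potential, 9.084 eV, is below the 9.13 eV box edge);
        every other evaluation chemical's tabulated descriptors fall
        inside, halothane included (ip 11.039 < 11.276)."""
        from conftest import by_name
        ev = by_name(evaluation)
        tmb = check_domain(
            dict(zip(("log_pow", "log_pbw", "ip"),
                     ev["1,2,4-trimethylbenzene"].descriptor_vector())),
            self.BOX)
        assert not tmb["overall"]
        assert not tmb["ip"]
        assert tmb["log_pow"] and tmb["log_pbw"]
        for n in ev:
            if n == "1,2,4-trimethylbenzene":
                continue
            flags = check_domain(
                dict(zip(("log_pow", "log_pbw", "ip"),
                         ev[n].descriptor_vector())), self.BOX)
            assert flags["overall"], n

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            DomainBox({"x": (2.0, 1.0)})


class TestNormalityPlotData:
    def test_symmetric_median_pair(self):
        pairs = normality_plot_data([-1.0, 0.0, 1.0])
        assert pairs[1] == pytest.approx([0.5, 0.5])

    def test_monotone_in_both_coordinates(self, cal_fit):
        pairs = normality_plot_data(cal_fit.residuals)
        assert pairs.shape == (26, 2)
        assert (np.diff(pairs[:, 0]) > 0).all()
        assert (np.diff(pairs[:, 1]) >= 0).all()

    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(13)
        r = rng.normal(size=15)
        pairs = normality_plot_data(r)
        from scipy import stats
        z = (r - r.mean()) / r.std(ddof=1)
        order = np.argsort(z)
        expected_obs = (np.arange(1, 16) - 0.375) / 15.25
        assert pairs[:, 0] == pytest.approx(expected_obs)
        assert pairs[:, 1] == pytest.approx(stats.norm.cdf(z[order]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normality_plot_data([1.0, 1.0, 1.0])
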
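"""Time-to-onset extraction and Weibull failure-pattern modelling."""

import math

import numpy as np
import pytest
from scipy import stats

from faers_signal.cohort import DrugQuery
from faers_signal.tto_weibull import (
    TTORecord,
    WeibullFit,
    classify_failure_type,
    compute_tto,
    onset_window_summary,
    weibull_loglik,
    weibull_mle,
)
from conftest import make_report

QUERY = DrugQuery("target", ("abecma",))


class TestComputeTTO:
    def test_whole_day_interval(self):
        r = make_report("1", drugs=(("ABECMA", "PS"),), start_dt="20230101",
                        event_dt="20230103")
        (rec,) = compute_tto([r], QUERY)
        assert rec.tto_days == 2 and rec.validity == "valid"

    def test_same_day_onset_is_valid_zero(self):
        r = make_report("1", drugs=(("ABECMA", "PS"),), start_dt="20230101",
                        event_dt="20230101")
        (rec,) = compute_tto([r], QUERY)
        assert rec.tto_days == 0 and rec.validity == "valid"

    def test_negative_interval_flagged(self):
        r = make_report("1", drugs=(("ABECMA", "PS"),), start_dt="20230110",
                        event_dt="20230105")
        (rec,) = compute_tto([r], QUERY)
        assert rec.tto_days is None and rec.validity == "negative"

    def test_missing_components_encoded(self):
        no_start = make_report("1", drugs=(("ABECMA", "PS"),), event_dt="20230105")
        no_event = make_report("2", drugs=(("ABECMA", "PS"),), start_dt="20230101")
        recs = compute_tto([no_start, no_event], QUERY)
        assert [r.validity for r in recs] == ["missing_start", "missing_event"]

    def test_imprecise_dates_excluded_by_default(self):
        r = make_report("1", drugs=(("ABECMA", "PS"),), start_dt="202301",
                        event_dt="20230120")
        (rec,) = compute_tto([r], QUERY)
        assert rec.validity == "imprecise_date"
        (rec,) = compute_tto([r], QUERY, include_imprecise=True)
        assert rec.validity == "valid" and rec.tto_days == 5  # from the 15th

    def test_earliest_matching_start_used(self):
        from faers_signal.faers_io import DrugEntry, parse_faers_date

        r = make_report("1", event_dt="20230110", drugs=(("ABECMA", "PS"),))
        r.drugs = (
            DrugEntry("ABECMA", "PS", parse_faers_date("20230105")),
            DrugEntry("ABECMA", "SS", parse_faers_date("20230101")),
            DrugEntry("OTHER", "PS", parse_faers_date("20220101")),
        )
        recs = compute_tto([r], QUERY)
        assert all(rec.tto_days == 9 for rec in recs)  # other drug's start ignored

    def test_one_record_per_reaction(self):
        r = make_report("1", drugs=(("ABECMA", "PS"),), start_dt="20230101",
                        event_dt="20230103", reactions=("PT_A", "PT_B"))
        recs = compute_tto([r], QUERY)
        assert [rec.event for rec in recs] == ["PT_A", "PT_B"]


class TestOnsetWindow:
    def test_hand_computable_summary(self):
        recs = [TTORecord(str(i), "PT", v, "valid") for i, v in enumerate([0, 0, 2, 10, 40])]
        s = onset_window_summary(recs)
        assert s["median"] == 2 and s["prop_within_window"] == 0.8
        assert s["prop_day0"] == 0.4

    def test_all_within_window(self):
        s = onset_window_summary([1.0, 2.0, 30.0])
        assert s["prop_within_window"] == 1.0

    def test_empty_gives_explicit_null_summary(self):
        s = onset_window_summary([TTORecord("1", "PT", None, "missing_start")])
        assert s["n_valid"] == 0 and s["median"] is None

    def test_sampled_proportion_matches_weibull_cdf(self):
        """n=676 draws at (shape 0.43, scale 12.67): share <=30 d near the CDF."""
        rng = np.random.default_rng(42)
        t = rng.weibull(0.43, 676) * 12.67
        s = onset_window_summary(list(t))
        cdf30 = 1 - math.exp(-((30 / 12.67) ** 0.43))
        assert cdf30 == pytest.approx(0.7651, abs=1e-4)  # closed form
        # sampling error at n=676: sd ~ sqrt(p(1-p)/n) ~ 0.016
        assert s["prop_within_window"] == pytest.approx(cdf30, abs=0.05)


class TestWeibullMLE:
    def test_exponential_special_case(self):
        """Exponential data: shape CI covers 1 and loglik at beta=1 is exact."""
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 10000)
        fit = weibull_mle(t)
        assert fit.converged
        assert fit.beta_ci[0] < 1.0 < fit.beta_ci[1]
        # Weibull(alpha, beta=1) is Exponential(scale=alpha), exactly
        ll = weibull_loglik(t, 10.0, 1.0)
        assert ll == pytest.approx(stats.expon.logpdf(t, scale=10.0).sum(), rel=1e-12)

    def test_early_onset_parameter_recovery(self):
        rng = np.random.default_rng(1)
        t = rng.weibull(0.43, 10000) * 12.67
        fit = weibull_mle(t)
        assert fit.beta == pytest.approx(0.43, abs=0.02)
        assert fit.alpha == pytest.approx(12.67, rel=0.05)
        assert fit.failure_type == "early"

    def test_matches_lifelines_oracle(self):
        """Independent MLE + Wald-CI oracle: lifelines' Weibull fitter."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t = rng.weibull(0.8, 2000) * 20.0
        fit = weibull_mle(t)
        lf = lifelines.WeibullFitter().fit(t)
        assert fit.alpha == pytest.approx(lf.lambda_, rel=1e-4)
        assert fit.beta == pytest.approx(lf.rho_, rel=1e-4)
        # lifelines builds its Wald CI on the natural scale, ours on the log
        # scale; at this n the two agree to ~1%
        s = lf.summary
        assert fit.alpha_ci[0] == pytest.approx(s.loc["lambda_", "coef lower 95%"], rel=1e-2)
        assert fit.beta_ci[1] == pytest.approx(s.loc["rho_", "coef upper 95%"], rel=1e-2)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        t = rng.weibull(1.4, 500) * 30.0
        f1 = weibull_mle(t)
        f2 = weibull_mle(t * 7.0)
        assert f2.alpha == pytest.approx(7.0 * f1.alpha, rel=1e-6)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-6)

    def test_zero_handling_options(self):
        t = np.array([0, 0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        shift = weibull_mle(t, zero_handling="shift")
        drop = weibull_mle(t, zero_handling="drop")
        offset = weibull_mle(t, zero_handling="offset")
        assert shift.n_used == 12 and offset.n_used == 12 and drop.n_used == 10
        assert shift.converged and drop.converged and offset.converged

    def test_too_few_or_degenerate_data_fail_explicitly(self):
        few = weibull_mle([1.0, 2.0, 3.0])
        assert not few.converged and few.failure_type == "indeterminate"
        flat = weibull_mle([5.0] * 50)
        assert not flat.converged and "degenerate" in flat.message

    def test_records_input_uses_valid_only(self):
        recs = [TTORecord(str(i), "PT", i + 1, "valid") for i in range(20)]
        recs.append(TTORecord("x", "PT", None, "missing_start"))
        assert weibull_mle(recs).n_used == 20


class TestClassification:
    @pytest.mark.parametrize(
        "ci, expected",
        [((0.40, 0.46), "early"), ((0.9, 1.1), "random"), ((1.2, 1.5), "wear_out")],
    )
    def test_ci_rule(self, ci, expected):
        fit = WeibullFit(100, 10.0, (8, 12), sum(ci) / 2, ci, "", -1.0, True)
        assert classify_failure_type(fit) == expected

    def test_failed_fit_is_indeterminate(self):
        fit = WeibullFit(3, None, None, None, None, "", None, False)
        assert classify_failure_type(fit) == "indeterminate"
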
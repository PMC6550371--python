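"""Consensus aggregation, predictive fitting and panel-to-belief assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone

import bayeselicit as be
from bayeselicit.elicitation import (
    Answer,
    PanelPriorFitter,
    PredictiveTFitter,
    render_report,
)
from bayeselicit.model_core import predictive_distribution


def answer_set(expert_id, pam, ada, thresholds=(60, 30, 20, 10, 5), **kw):
    def ladder(prefix, probs):
        return tuple(
            Answer(f"{prefix}{k + 1}", float(t), float(p))
            for k, (t, p) in enumerate(zip(thresholds, probs))
        )

    return be.ElicitationAnswerSet(
        expert_id=expert_id,
        answers={"pamidronate": ladder("QP", pam), "adalimumab": ladder("QA", ada)},
        **kw,
    )


class TestAnswerValidation:
    def test_rejects_increasing_probability_down_the_ladder(self):
        with pytest.raises(ValueError, match="non-increasing"):
            answer_set("e1", [50, 60, 40, 30, 20], [80, 60, 40, 20, 10])

    def test_rejects_out_of_range_probability(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            answer_set("e1", [140, 60, 40, 30, 20], [80, 60, 40, 20, 10])

    def test_rejects_nondecreasing_thresholds(self):
        with pytest.raises(ValueError, match="strictly decreasing"):
            answer_set("e1", [80, 60, 40, 30, 20], [80, 60, 40, 30, 20],
                       thresholds=(60, 60, 20, 10, 5))

    def test_interval_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            answer_set(
                "e1", [80, 60, 40, 30, 20], [80, 60, 40, 20, 10],
                interval_weights={"pamidronate": (((0, 30), 0.5), ((30, 60), 0.4))},
            )

    def test_panel_requires_matching_structure(self):
        e1 = answer_set("e1", [80, 60, 40, 30, 20], [80, 60, 40, 20, 10])
        e2 = answer_set("e2", [80, 60, 40, 30, 20], [80, 60, 40, 20, 10],
                        thresholds=(50, 30, 20, 10, 5))
        with pytest.raises(ValueError, match="different question structure"):
            be.ExpertPanel(experts=(e1, e2))
        with pytest.raises(ValueError, match="at least one expert"):
            be.ExpertPanel(experts=())


class TestConsensus:
    def test_single_expert_identity(self):
        e = answer_set("solo", [80, 60, 40, 30, 20], [80, 60, 40, 20, 10])
        c = be.consensus_answers(be.ExpertPanel(experts=(e,)))
        assert c.expert_id == "consensus"
        for arm in ("pamidronate", "adalimumab"):
            assert [a.probability_pct for a in c.arm_answers(arm)] == [
                a.probability_pct for a in e.arm_answers(arm)
            ]

    def test_two_experts_average(self):
        e1 = answer_set("e1", [40] * 5, [40] * 5)
        e2 = answer_set("e2", [60] * 5, [60] * 5)
        c = be.consensus_answers(be.ExpertPanel(experts=(e1, e2)))
        assert all(a.probability_pct == 50 for a in c.arm_answers("pamidronate"))

    def test_median_method(self):
        e1 = answer_set("e1", [40] * 5, [40] * 5)
        e2 = answer_set("e2", [60] * 5, [60] * 5)
        e3 = answer_set("e3", [90] * 5, [90] * 5)
        c = be.consensus_answers(be.ExpertPanel(experts=(e1, e2, e3)), "median")
        assert all(a.probability_pct == 60 for a in c.arm_answers("adalimumab"))

    def test_mean_commutes_with_panel_duplication(self, panel):
        doubled = be.ExpertPanel(experts=panel.experts + panel.experts)
        c1 = be.consensus_answers(panel)
        c2 = be.consensus_answers(doubled)
        for arm in ("pamidronate", "adalimumab"):
            p1 = [a.probability_pct for a in c1.arm_answers(arm)]
            p2 = [a.probability_pct for a in c2.arm_answers(arm)]
            assert p1 == pytest.approx(p2, abs=1e-12)


class TestPredictiveFit:
    def test_exact_round_trip_on_t_cdf_answers(self):
        thresholds = [60, 40, 20, 10, 5]
        true = be.ScaledT(4, 30.0, 20.0)  # score scale
        probs = [100 * true.cdf(t) for t in thresholds]
        fitted = be.fit_predictive_from_answers(
            [Answer(f"Q{k}", t, p) for k, (t, p) in enumerate(zip(thresholds, probs))],
            df=4,
            baseline=60.0,
        )
        assert fitted.location == pytest.approx(-30.0, abs=1e-6)
        assert fitted.scale == pytest.approx(20.0, abs=1e-6)

    def test_two_point_interpolation(self):
        # slope spans the 20th-80th percentile gap: s = (40-20)/(2 t_{0.8,4})
        fitted = be.fit_predictive_from_answers(
            [Answer("Q1", 40.0, 80.0), Answer("Q2", 20.0, 20.0)], df=4, baseline=60.0
        )
        t80 = stats.t.ppf(0.8, 4)
        assert fitted.location == pytest.approx(30.0 - 60.0, abs=1e-9)
        assert fitted.scale == pytest.approx(20.0 / (2 * t80), abs=1e-9)
        assert fitted.scale == pytest.approx(10.63, abs=0.01)

    def test_boundary_probabilities_dropped(self):
        fitter = PredictiveTFitter(df=4, baseline=60).fit(
            [60, 40, 20, 10], [100.0, 80.0, 20.0, 0.0]
        )
        assert fitter.n_dropped_ == 2
        t80 = stats.t.ppf(0.8, 4)
        assert fitter.scale_ == pytest.approx(20.0 / (2 * t80), abs=1e-9)

    def test_too_few_interior_answers_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            PredictiveTFitter().fit([60, 40, 20], [100.0, 80.0, 0.0])

    def test_all_equal_probabilities_degenerate(self):
        with pytest.raises(ValueError, match="zero slope"):
            PredictiveTFitter().fit([60, 40, 20], [50.0, 50.0, 50.0])

    def test_nonmonotone_rejected(self):
        with pytest.raises(ValueError):
            PredictiveTFitter().fit([60, 40], [50.0, 60.0])

    def test_least_squares_minimum_against_grid_oracle(self):
        # noisy answers: fitted (m, s) must beat every grid candidate's RSS
        thresholds = np.array([60.0, 40.0, 20.0, 10.0, 5.0])
        probs = np.array([85.0, 55.0, 35.0, 20.0, 5.0])
        fitter = PredictiveTFitter(df=4, baseline=60).fit(thresholds, probs)
        z = stats.t.ppf(probs / 100, 4)

        def rss(m, s):
            return float(np.sum((thresholds - (m + s * z)) ** 2))

        best = rss(fitter.location_ + 60, fitter.scale_)
        for m in np.linspace(10, 60, 41):
            for s in np.linspace(1, 60, 41):
                assert best <= rss(m, s) + 1e-9

    def test_predict_returns_fitted_cdf_percent(self):
        fitter = PredictiveTFitter(df=4, baseline=60).fit([40, 20], [80.0, 20.0])
        out = fitter.predict([40.0, 20.0])
        assert out == pytest.approx([80.0, 20.0], abs=1e-9)

    def test_sklearn_clone_and_params(self):
        fitter = PredictiveTFitter(df=6, baseline=50)
        assert clone(fitter).get_params() == {"df": 6, "baseline": 50}


class TestPanelFit:
    def _panel_from_belief(self, belief, n_experts=5):
        spec = be.PanelGeneratorSpec(
            predictive_P=_score_scale(belief, "pamidronate"),
            predictive_A=_score_scale(belief, "adalimumab"),
            n_experts=n_experts,
            probit_noise_sd=0.0,
            rounding_grid=0.0,
            seed=7,
        )
        return be.generate_expert_panel(spec)

    def test_zero_noise_round_trip(self, consensus_prior):
        panel = self._panel_from_belief(consensus_prior)
        cfg = be.PanelFitConfig(
            a0=2.0,
            sampling_variance=consensus_prior.b0 / consensus_prior.a0,
            rho=0.0,
        )
        belief = be.fit_belief_from_panel(panel, cfg)
        for arm in ("pamidronate", "adalimumab"):
            got = predictive_distribution(belief, arm)
            want = predictive_distribution(consensus_prior, arm)
            assert got.location == pytest.approx(want.location, abs=1e-6)
            assert got.scale == pytest.approx(want.scale, rel=1e-6)

    def test_round_trip_reproduces_fitted_scales_exactly(self, panel):
        fitter = PanelPriorFitter(rho=0.5, sampling_variance=2.0).fit(panel)
        for arm, fitted in (
            ("pamidronate", fitter.predictive_P_),
            ("adalimumab", fitter.predictive_A_),
        ):
            implied = predictive_distribution(fitter.belief_, arm)
            assert implied.location == pytest.approx(fitted.location, abs=1e-12)
            assert implied.scale == pytest.approx(fitted.scale, rel=1e-9)

    def test_rho_zero_sums_parameter_variances(self, panel):
        fitter = PanelPriorFitter(rho=0.0, sampling_variance=2.0).fit(panel)
        R = fitter.belief_.R
        v_P = fitter.predictive_P_.scale ** 2
        v_A = fitter.predictive_A_.scale ** 2
        r11 = v_P / 2.0 - 1
        rAA = v_A / 2.0 - 1
        assert R[1, 1] == pytest.approx(r11 + rAA, rel=1e-12)
        assert R[0, 1] == pytest.approx(-r11, rel=1e-12)

    def test_oversized_sampling_variance_rejected(self, panel):
        big = 1e6
        with pytest.raises(ValueError, match="sampling variance"):
            PanelPriorFitter(sampling_variance=big).fit(panel)


def _score_scale(belief, arm):
    pred = predictive_distribution(belief, arm)
    return be.ScaledT(pred.df, pred.location + 60.0, pred.scale)


class TestFeedbackReport:
    def test_median_score_is_baseline_plus_location(self, consensus_prior):
        report = be.feedback_report(consensus_prior, baseline=60.0)
        pred = predictive_distribution(consensus_prior, "pamidronate")
        median = report["arms"]["pamidronate"]["percentiles"]["50"]
        assert median["score_mm"] == pytest.approx(60.0 + pred.location)
        assert median["change_mm"] == pytest.approx(pred.location)

    def test_improvement_probability_is_cdf_at_zero(self, consensus_prior):
        report = be.feedback_report(consensus_prior)
        for arm in ("pamidronate", "adalimumab"):
            pred = predictive_distribution(consensus_prior, arm)
            assert report["arms"][arm]["prob_any_improvement"] == pytest.approx(
                be.prob_below(pred, 0.0)
            )

    def test_reports_published_effect_direction_probability(self, consensus_prior):
        report = be.feedback_report(consensus_prior)
        assert report["delta"]["prob_delta_positive"] == pytest.approx(0.684, abs=0.01)

    def test_percentiles_strictly_increasing_and_renderable(self, consensus_prior):
        report = be.feedback_report(consensus_prior)
        for arm in report["arms"].values():
            vals = [p["change_mm"] for p in arm["percentiles"].values()]
            assert all(a < b for a, b in zip(vals, vals[1:]))
        text = render_report(report)
        assert "treatment effect" in text and "pamidronate:" in text


class TestHistogramCheck:
    def _answers_with_weights(self, weights):
        return answer_set(
            "e1", [80, 60, 40, 30, 20], [80, 60, 40, 20, 10],
            interval_weights={"pamidronate": weights},
        )

    def test_zero_distance_when_weights_match_fit(self, consensus_prior):
        pred = predictive_distribution(consensus_prior, "pamidronate")
        # wide edges so the fitted bins carry essentially all predictive mass
        edges = [-2000.0, 30.0, 60.0, 2000.0]
        fitted = [
            be.prob_below(pred, b - 60) - be.prob_below(pred, a - 60)
            for a, b in zip(edges, edges[1:])
        ]
        weights = tuple(
            ((a, b), w / sum(fitted))
            for (a, b), w in zip(zip(edges, edges[1:]), fitted)
        )
        out = be.histogram_check(self._answers_with_weights(weights), consensus_prior)
        assert out["pamidronate"].tv_distance == pytest.approx(0.0, abs=1e-4)

    def test_hand_arithmetic_uniform_vs_skewed(self):
        # uniform weights vs fitted {0.1, 0.2, 0.3, 0.4}: TV = 0.2 by hand
        elicited = np.array([0.25, 0.25, 0.25, 0.25])
        fitted = np.array([0.1, 0.2, 0.3, 0.4])
        assert 0.5 * np.abs(elicited - fitted).sum() == pytest.approx(0.2)

    def test_disjoint_mass_approaches_one(self, consensus_prior):
        pred = predictive_distribution(consensus_prior, "pamidronate")
        # bins cover the support; all elicited mass sits far in the upper
        # tail where the fit puts almost nothing
        weights = (
            ((-2000.0, 95.0), 0.0),
            ((95.0, 100.0), 1.0),
            ((100.0, 2000.0), 0.0),
        )
        out = be.histogram_check(self._answers_with_weights(weights), consensus_prior)
        tail = 1.0 - be.prob_below(pred, 95.0 - 60.0)
        assert out["pamidronate"].tv_distance >= 1.0 - tail - 1e-9

    def test_missing_weights_rejected(self, consensus_prior):
        plain = answer_set("e1", [80, 60, 40, 30, 20], [80, 60, 40, 20, 10])
        with pytest.raises(ValueError, match="interval weights"):
            be.histogram_check(plain, consensus_prior)
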
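"""Expert questionnaire answers, consensus aggregation and prior fitting.

Each expert answers, per treatment arm, a short sequence of questions of the
form "what is the chance that a typical patient presenting with a 60 mm pain
score records a 26-week score below t mm?" for a decreasing ladder of
thresholds t, optionally followed by a table of interval weights.  The panel
is aggregated behaviourally: the consensus answer to each question is the
arithmetic mean (the procedure the elicitation meeting itself adopted),
never a pooling of separately fitted distributions.

A predictive Student-t is fitted to one arm's answers by quantile
regression: each stated probability p is mapped to the standard-t quantile
z(p) and the thresholds are regressed on z by ordinary least squares, giving
the location (intercept) and scale (slope).  The fit is closed-form,
deterministic, and exact whenever the answers already lie on a t CDF.
Answers of exactly 0% or 100% carry no quantile information and are dropped
(logged).

From the two per-arm predictive fits a full Normal-Gamma belief is assembled
by splitting each predictive variance into a sampling part (the same for
both arms — the model assumes a common outcome variance) and a parameter
part, with a configurable between-arm opinion correlation rho.  The default
rho is high (0.99): experts' uncertainty about the two arms is mostly
shared, which is what makes the implied treatment-effect interval much
narrower than either arm's predictive spread.

The default question thresholds {60, 30, 20, 10, 5} mm are placeholders:
the exact questionnaire wording was not published with the study, so the
thresholds are configuration, not constants.  Beliefs fitted under
placeholder thresholds are *not* reproductions of the published consensus
prior; use :func:`bayeselicit.model_core.calibrate_from_summaries` for that.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .model_core import (
    CONTRAST_DELTA,
    NormalGammaBelief,
    ScaledT,
    calibrate_from_summaries,
    marginal_parameter_distribution,
    predictive_distribution,
    prob_below,
)

__all__ = [
    "Answer",
    "ElicitationAnswerSet",
    "ExpertPanel",
    "PanelFitConfig",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_BASELINE",
    "PredictiveTFitter",
    "PanelPriorFitter",
    "consensus_answers",
    "fit_predictive_from_answers",
    "fit_belief_from_panel",
    "feedback_report",
    "render_report",
    "histogram_check",
    "HistogramCheck",
]

logger = logging.getLogger(__name__)

#: Placeholder question thresholds (mm on the 0-100 score scale), decreasing
#: in question order.  The study's exact thresholds were not published.
DEFAULT_THRESHOLDS: tuple[float, ...] = (60.0, 30.0, 20.0, 10.0, 5.0)

#: Baseline pain score (mm) of the "typical patient" the questions describe.
DEFAULT_BASELINE = 60.0

ARMS = ("pamidronate", "adalimumab")


class Answer(NamedTuple):
    """One threshold question: P(26-week score < threshold) stated in percent."""

    question_id: str
    threshold_mm: float
    probability_pct: float


IntervalWeight = tuple[tuple[float, float], float]


@dataclass(frozen=True)
class ElicitationAnswerSet:
    """One expert's answers: per arm, an ordered threshold/probability ladder.

    Invariants: thresholds strictly decreasing in question order;
    probabilities in [0, 100] and non-increasing as the threshold decreases;
    optional interval weights nonnegative, ordered, disjoint, summing to 1.
    """

    expert_id: str
    answers: Mapping[str, tuple[Answer, ...]]
    baseline_score: float = DEFAULT_BASELINE
    interval_weights: Mapping[str, tuple[IntervalWeight, ...]] | None = None

    def __post_init__(self) -> None:
        answers = {arm: tuple(ans) for arm, ans in self.answers.items()}
        object.__setattr__(self, "answers", answers)
        for arm, ans in answers.items():
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}")
            if not ans:
                raise ValueError(f"{self.expert_id}/{arm}: no answers")
            thresholds = [a.threshold_mm for a in ans]
            probs = [a.probability_pct for a in ans]
            if any(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
                raise ValueError(
                    f"{self.expert_id}/{arm}: thresholds must be strictly "
                    f"decreasing in question order, got {thresholds}"
                )
            if any(not (0 <= p <= 100) for p in probs):
                raise ValueError(
                    f"{self.expert_id}/{arm}: probabilities must be in "
                    f"[0, 100], got {probs}"
                )
            if any(p2 > p1 for p1, p2 in zip(probs, probs[1:])):
                raise ValueError(
                    f"{self.expert_id}/{arm}: probabilities must be "
                    f"non-increasing as thresholds decrease, got {probs}"
                )
        if self.interval_weights is not None:
            iw = {arm: tuple(w) for arm, w in self.interval_weights.items()}
            object.__setattr__(self, "interval_weights", iw)
            for arm, rows in iw.items():
                total = 0.0
                prev_hi = -math.inf
                for (lo, hi), w in rows:
                    if w < 0:
                        raise ValueError(f"{self.expert_id}/{arm}: negative weight")
                    if not lo < hi:
                        raise ValueError(f"{self.expert_id}/{arm}: empty interval")
                    if lo < prev_hi:
                        raise ValueError(
                            f"{self.expert_id}/{arm}: intervals must be "
                            "disjoint and ordered"
                        )
                    prev_hi = hi
                    total += w
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"{self.expert_id}/{arm}: interval weights sum to "
                        f"{total}, expected 1"
                    )

    def arm_answers(self, arm: str) -> tuple[Answer, ...]:
        if arm not in self.answers:
            raise KeyError(f"{self.expert_id} has no answers for arm {arm!r}")
        return self.answers[arm]


@dataclass(frozen=True)
class ExpertPanel:
    """A panel of experts with structurally identical questionnaires."""

    experts: tuple[ElicitationAnswerSet, ...]

    def __post_init__(self) -> None:
        experts = tuple(self.experts)
        object.__setattr__(self, "experts", experts)
        if not experts:
            raise ValueError("panel must contain at least one expert")
        ref = experts[0]
        ref_struct = {
            arm: [(a.question_id, a.threshold_mm) for a in ans]
            for arm, ans in ref.answers.items()
        }
        for e in experts[1:]:
            struct = {
                arm: [(a.question_id, a.threshold_mm) for a in ans]
                for arm, ans in e.answers.items()
            }
            if struct != ref_struct:
                raise ValueError(
                    f"expert {e.expert_id} has a different question structure "
                    f"than {ref.expert_id}"
                )
            if e.baseline_score != ref.baseline_score:
                raise ValueError("experts must share the baseline score")

    def __len__(self) -> int:
        return len(self.experts)

    @property
    def baseline_score(self) -> float:
        return self.experts[0].baseline_score


def consensus_answers(panel: ExpertPanel, method: str = "mean") -> ElicitationAnswerSet:
    """Aggregate a panel to one consensus answer set, question by question.

    The arithmetic mean of the experts' stated probabilities (the meeting's
    own procedure) is the default; ``method='median'`` is also available.
    The mean of per-expert monotone ladders is monotone, which is re-checked
    on construction of the result.
    """
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    agg = np.mean if method == "mean" else np.median
    ref = panel.experts[0]
    answers = {}
    for arm, ref_ans in ref.answers.items():
        rows = []
        for k, a in enumerate(ref_ans):
            probs = [e.answers[arm][k].probability_pct for e in panel.experts]
            rows.append(Answer(a.question_id, a.threshold_mm, float(agg(probs))))
        answers[arm] = tuple(rows)
    return ElicitationAnswerSet(
        expert_id="consensus", answers=answers, baseline_score=panel.baseline_score
    )


# ---------------------------------------------------------------------------
# Predictive fit: t-quantile transform + OLS
# ---------------------------------------------------------------------------


class PredictiveTFitter(BaseEstimator, RegressorMixin):
    """Fit a predictive Student-t CDF to threshold/probability answers.

    Regression of threshold on the standard-t quantile of the stated
    probability; the OLS intercept is the predictive location on the score
    scale and the slope the scale.  sklearn-style: ``fit(X, y)`` with ``X``
    the thresholds (mm) and ``y`` the probabilities (percent);
    ``predict(X)`` returns the fitted CDF in percent.

    Parameters
    ----------
    df : float
        Degrees of freedom of the predictive t (``2 * a0`` of the opinion
        model).
    baseline : float
        Baseline score (mm) subtracted to put the fitted location on the
        change-from-baseline scale.

    Attributes
    ----------
    location_, scale_ : float
        Fitted change-scale location and scale (mm).
    predictive_ : ScaledT
        The fitted predictive on the change scale.
    n_dropped_ : int
        Number of 0%/100% answers excluded from the fit.
    """

    def __init__(self, df: float = 4.0, baseline: float = DEFAULT_BASELINE):
        self.df = df
        self.baseline = baseline

    def fit(self, X, y) -> "PredictiveTFitter":
        thresholds = np.asarray(X, dtype=float).reshape(-1)
        probs = np.asarray(y, dtype=float).reshape(-1)
        if thresholds.shape != probs.shape:
            raise ValueError("thresholds and probabilities must align")
        order = np.argsort(thresholds)
        thresholds, probs = thresholds[order], probs[order]
        if np.any(np.diff(probs) < 0):
            raise ValueError(
                "probabilities must be non-decreasing in the threshold "
                f"(non-increasing down the question ladder); got {probs}"
            )
        interior = (probs > 0.0) & (probs < 100.0)
        n_dropped = int((~interior).sum())
        if n_dropped:
            logger.info(
                "dropping %d boundary (0%%/100%%) answers from the fit", n_dropped
            )
        thresholds, probs = thresholds[interior], probs[interior]
        if len(thresholds) < 2:
            raise ValueError(
                "need at least two answers strictly inside (0, 100)% to fit"
            )
        if probs.max() == probs.min():
            raise ValueError(
                "all probabilities equal: zero slope, degenerate predictive"
            )
        z = stats.t.ppf(probs / 100.0, df=self.df)
        slope, intercept = np.polyfit(z, thresholds, 1)
        if slope < 0:
            raise ValueError("fitted scale is negative; answers are inconsistent")
        self.location_ = float(intercept - self.baseline)
        self.scale_ = float(slope)
        self.predictive_ = ScaledT(self.df, self.location_, self.scale_)
        self.n_dropped_ = n_dropped
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted CDF (percent) at the given score-scale thresholds."""
        if not hasattr(self, "predictive_"):
            raise AttributeError("fitter is not fitted")
        x = np.asarray(X, dtype=float).reshape(-1)
        return 100.0 * stats.t.cdf(
            x - self.baseline, df=self.df, loc=self.location_, scale=self.scale_
        )


def fit_predictive_from_answers(
    answers: Sequence[Answer], df: float, baseline: float = DEFAULT_BASELINE
) -> ScaledT:
    """Fit one arm's predictive t from its answer ladder (change scale)."""
    fitter = PredictiveTFitter(df=df, baseline=baseline)
    fitter.fit(
        [a.threshold_mm for a in answers], [a.probability_pct for a in answers]
    )
    return fitter.predictive_


# ---------------------------------------------------------------------------
# Panel -> belief
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelFitConfig:
    """Variance-decomposition settings for assembling a belief from a panel.

    ``sampling_variance`` (mm^2) is the common within-arm outcome variance
    split off each fitted predictive variance; ``None`` takes ``b0 / a0`` of
    the consensus prior calibrated from the published summaries.  ``rho`` is
    the between-arm correlation of parameter opinion; the high default
    reflects mostly-shared uncertainty and yields a treatment-effect
    interval much narrower than the per-arm predictive spread.
    """

    a0: float = 2.0
    sampling_variance: float | None = None
    rho: float = 0.99
    consensus_method: str = "mean"

    def __post_init__(self) -> None:
        if not self.a0 > 0:
            raise ValueError("a0 must be positive")
        if self.sampling_variance is not None and not self.sampling_variance > 0:
            raise ValueError("sampling_variance must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if self.consensus_method not in ("mean", "median"):
            raise ValueError("consensus_method must be 'mean' or 'median'")

    def resolved_sampling_variance(self) -> float:
        if self.sampling_variance is not None:
            return self.sampling_variance
        cal = calibrate_from_summaries()
        return cal.b0 / cal.a0


class PanelPriorFitter(BaseEstimator):
    """Fit a Normal-Gamma belief to an expert panel.

    Pipeline: consensus answers -> per-arm predictive t fits -> variance
    decomposition into sampling and parameter parts -> R assembled in
    (mu_P, delta) coordinates with between-arm correlation ``rho``.

    Attributes
    ----------
    belief_ : NormalGammaBelief
    consensus_ : ElicitationAnswerSet
    predictive_P_, predictive_A_ : ScaledT
        Fitted per-arm predictives on the change scale.
    """

    def __init__(
        self,
        a0: float = 2.0,
        sampling_variance: float | None = None,
        rho: float = 0.99,
        consensus_method: str = "mean",
    ):
        self.a0 = a0
        self.sampling_variance = sampling_variance
        self.rho = rho
        self.consensus_method = consensus_method

    def fit(self, X: ExpertPanel, y=None) -> "PanelPriorFitter":
        config = PanelFitConfig(
            a0=self.a0,
            sampling_variance=self.sampling_variance,
            rho=self.rho,
            consensus_method=self.consensus_method,
        )
        panel = X
        if not isinstance(panel, ExpertPanel):
            raise TypeError("X must be an ExpertPanel")
        consensus = consensus_answers(panel, method=config.consensus_method)
        df = 2.0 * config.a0
        baseline = panel.baseline_score
        pred = {
            arm: fit_predictive_from_answers(consensus.arm_answers(arm), df, baseline)
            for arm in ARMS
        }
        s2 = config.resolved_sampling_variance()
        b0 = config.a0 * s2
        v_P2 = pred["pamidronate"].scale ** 2
        v_A2 = pred["adalimumab"].scale ** 2
        if s2 >= min(v_P2, v_A2):
            raise ValueError(
                f"sampling variance {s2:.4g} mm^2 is not below both fitted "
                f"predictive variances ({v_P2:.4g}, {v_A2:.4g}): no "
                "nonnegative parameter-uncertainty solution"
            )
        r_11 = max(v_P2 / s2 - 1.0, 0.0)
        r_AA = max(v_A2 / s2 - 1.0, 0.0)
        cross = config.rho * math.sqrt(r_11 * r_AA)
        r_dd = r_11 + r_AA - 2.0 * cross
        R = np.array([[r_11, cross - r_11], [cross - r_11, r_dd]])
        belief = NormalGammaBelief(
            a0=config.a0,
            b0=b0,
            mu_P0=pred["pamidronate"].location,
            delta0=pred["adalimumab"].location - pred["pamidronate"].location,
            R=R,
        )
        self.belief_ = belief
        self.consensus_ = consensus
        self.predictive_P_ = pred["pamidronate"]
        self.predictive_A_ = pred["adalimumab"]
        return self


def fit_belief_from_panel(
    panel: ExpertPanel, config: PanelFitConfig | None = None
) -> NormalGammaBelief:
    """Assemble a Normal-Gamma belief from a panel (see PanelPriorFitter)."""
    config = config or PanelFitConfig()
    fitter = PanelPriorFitter(
        a0=config.a0,
        sampling_variance=config.sampling_variance,
        rho=config.rho,
        consensus_method=config.consensus_method,
    )
    return fitter.fit(panel).belief_


# ---------------------------------------------------------------------------
# Feedback
# ---------------------------------------------------------------------------

_PERCENTILES = (5, 25, 50, 75, 95)


def feedback_report(
    belief: NormalGammaBelief,
    baseline: float = DEFAULT_BASELINE,
    milestones: Sequence[float] = (30.0, 20.0, 10.0),
) -> dict:
    """Descriptive summary of a belief, as fed back to the expert panel.

    Per arm: predictive percentiles on the change and score scales,
    probability of any improvement, and probabilities of reaching score
    milestones; plus the treatment-effect mode, 90% interval and P(delta>0).
    """
    report: dict = {"baseline_mm": baseline, "arms": {}}
    for arm in ARMS:
        pred = predictive_distribution(belief, arm)
        change_pcts = [float(pred.ppf(p / 100.0)) for p in _PERCENTILES]
        assert all(a < b for a, b in zip(change_pcts, change_pcts[1:]))
        report["arms"][arm] = {
            "percentiles": {
                str(p): {"change_mm": c, "score_mm": baseline + c}
                for p, c in zip(_PERCENTILES, change_pcts)
            },
            "prob_any_improvement": prob_below(pred, 0.0),
            "prob_score_at_most": {
                str(m): prob_below(pred, m - baseline) for m in milestones
            },
        }
    delta = marginal_parameter_distribution(belief, CONTRAST_DELTA)
    lo, hi = delta.interval(0.90)
    report["delta"] = {
        "mode_mm": delta.location,
        "interval_90_mm": [lo, hi],
        "prob_delta_positive": 1.0 - prob_below(delta, 0.0),
    }
    return report


def render_report(report: dict) -> str:
    """Human-readable text table of a feedback report (values to 1 d.p. mm)."""
    lines = [f"baseline score: {report['baseline_mm']:.1f} mm", ""]
    for arm, block in report["arms"].items():
        lines.append(f"{arm}:")
        pcts = block["percentiles"]
        lines.append(
            "  predictive change percentiles (mm): "
            + ", ".join(f"{p}%: {pcts[p]['change_mm']:.1f}" for p in pcts)
        )
        lines.append(
            "  predictive score percentiles (mm):  "
            + ", ".join(f"{p}%: {pcts[p]['score_mm']:.1f}" for p in pcts)
        )
        lines.append(
            f"  P(any improvement) = {block['prob_any_improvement']:.3f}"
        )
        for m, pr in block["prob_score_at_most"].items():
            lines.append(f"  P(score <= {float(m):.0f} mm) = {pr:.3f}")
        lines.append("")
    d = report["delta"]
    lines.append(
        "treatment effect (adalimumab - pamidronate): "
        f"mode {d['mode_mm']:.1f} mm, 90% interval "
        f"({d['interval_90_mm'][0]:.1f}, {d['interval_90_mm'][1]:.1f}) mm, "
        f"P(delta > 0) = {d['prob_delta_positive']:.3f}"
    )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Interval-weight consistency check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistogramCheck:
    """Per-arm comparison of elicited interval weights against the fitted CDF."""

    bins: tuple[tuple[float, float, float, float], ...]  # lo, hi, elicited, fitted
    tv_distance: float


def histogram_check(
    answers: ElicitationAnswerSet, belief: NormalGammaBelief
) -> dict[str, HistogramCheck]:
    """Total-variation distance between elicited weights and fitted bin masses.

    Fitted masses come from the predictive CDF on the score scale; the
    distance is ``0.5 * sum |elicited - fitted|`` over the elicited bins,
    which lies in [0, 1].
    """
    if answers.interval_weights is None:
        raise ValueError("answer set carries no interval weights")
    out = {}
    for arm, rows in answers.interval_weights.items():
        pred = predictive_distribution(belief, arm)
        baseline = answers.baseline_score
        bins = []
        tv = 0.0
        for (lo, hi), w in rows:
            fitted = prob_below(pred, hi - baseline) - prob_below(pred, lo - baseline)
            bins.append((lo, hi, w, fitted))
            tv += abs(w - fitted)
        out[arm] = HistogramCheck(bins=tuple(bins), tv_distance=0.5 * tv)
    return out
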
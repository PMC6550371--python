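"""Exact conjugate updating with two-arm trial data, and the decision rule.

Trial data enter through their sufficient statistics (per-arm n, per-arm mean
change, pooled variance): any individual-patient dataset with the same
sufficient statistics yields the identical posterior.  The update is the
standard Normal-Gamma linear-model step for the design with columns
(intercept, adalimumab indicator), done with symmetric positive-definite
factorizations rather than explicit inverses.

The trial's decision rule declares a clinically relevant difference when the
posterior probability that either arm is beneficial on average *and* better
than the other by a relative margin (default 30%) exceeds a threshold
(default 0.2).  That probability is evaluated by direct Monte Carlo from the
closed-form joint posterior — conjugacy makes an MCMC sampler unnecessary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .model_core import (
    NormalGammaBelief,
    ScaledT,
    arm_contrast,
    marginal_parameter_distribution,
    predictive_distribution,
)

__all__ = [
    "TrialSummary",
    "DecisionRule",
    "RelevanceProbabilities",
    "NormalGammaTrialModel",
    "update",
    "credible_interval",
    "prob_clinically_relevant",
]


@dataclass(frozen=True)
class TrialSummary:
    """Sufficient statistics of a two-arm trial.

    ``s2`` is the pooled variance with denominator ``n_P + n_A - 2``; it is
    meaningful only with at least three patients, and must be ``None``
    (flagged absent) otherwise.
    """

    n_P: int
    n_A: int
    xbar_P: float
    xbar_A: float
    s2: float | None

    def __post_init__(self) -> None:
        if self.n_P < 0 or self.n_A < 0:
            raise ValueError("patient counts must be nonnegative")
        if int(self.n_P) != self.n_P or int(self.n_A) != self.n_A:
            raise ValueError("patient counts must be integers")
        n = self.n_P + self.n_A
        if self.s2 is not None:
            if n < 3:
                raise ValueError(
                    "pooled s2 is not meaningful with fewer than 3 patients; "
                    "pass s2=None"
                )
            if not (self.s2 >= 0 and math.isfinite(self.s2)):
                raise ValueError(f"s2 must be finite and nonnegative, got {self.s2}")
        elif n >= 3:
            raise ValueError("s2 is required when n_P + n_A >= 3")
        if (self.n_P > 0 and not math.isfinite(self.xbar_P)) or (
            self.n_A > 0 and not math.isfinite(self.xbar_A)
        ):
            raise ValueError("arm means must be finite when the arm has patients")


@dataclass(frozen=True)
class DecisionRule:
    """Posterior-probability rule for declaring a clinically relevant difference.

    With benefit meaning negative change, the superior arm must beat the
    other multiplicatively: arm w wins over arm l when ``mu_w < 0`` and
    ``mu_w <= (1 + margin) * mu_l``.  The rule declares when the posterior
    probability of either arm winning (``combine='union'``; the two events
    are disjoint for a positive margin) — or of the more probable single
    winner (``combine='max'``) — exceeds ``prob_threshold``.
    """

    margin: float = 0.30
    prob_threshold: float = 0.2
    benefit_sign: int = -1
    combine: str = "union"

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")
        if not (0 <= self.prob_threshold <= 1):
            raise ValueError("prob_threshold must be in [0, 1]")
        if self.benefit_sign not in (-1, 1):
            raise ValueError("benefit_sign must be -1 or +1")
        if self.combine not in ("union", "max"):
            raise ValueError("combine must be 'union' or 'max'")


@dataclass(frozen=True)
class RelevanceProbabilities:
    """Monte-Carlo estimates of the clinically-relevant-difference events."""

    p_P: float
    p_A: float
    p_union: float
    mc_se: float
    n_draws: int

    @property
    def p_max(self) -> float:
        return max(self.p_P, self.p_A)

    def decision_statistic(self, rule: DecisionRule) -> float:
        return self.p_union if rule.combine == "union" else self.p_max


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class NormalGammaTrialModel(BaseEstimator):
    """Conjugate Bayesian model of a two-arm trial with a Gaussian outcome.

    Parameters
    ----------
    prior : NormalGammaBelief or None
        Prior opinion; ``None`` selects the consensus prior calibrated from
        the published elicitation summaries.

    Attributes
    ----------
    posterior_ : NormalGammaBelief
        Updated belief after :meth:`fit` / :meth:`fit_summary` (same type as
        the prior — conjugacy).
    summary_ : TrialSummary or None
        The sufficient statistics fitted on, when fitted from a summary.
    """

    def __init__(self, prior: NormalGammaBelief | None = None):
        self.prior = prior

    def _prior(self) -> NormalGammaBelief:
        if self.prior is not None:
            return self.prior
        from .model_core import calibrate_from_summaries

        return calibrate_from_summaries()

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y) -> "NormalGammaTrialModel":
        """Update with individual-patient data.

        ``X`` is ``(n,)`` or ``(n, 1)`` of arm labels (``'pamidronate'`` /
        ``'adalimumab'`` or 0/1); ``y`` the change from baseline in mm.
        Cross-products are formed directly from the patient records, so
        agreement with :meth:`fit_summary` is a genuine check of
        summary/IPD equivalence rather than a tautology.
        """
        X = np.asarray(X)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be (n,) or (n, 1) arm labels")
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape:
            raise ValueError("X and y must have the same length")
        if X.dtype.kind in "OU":
            ada = np.array([str(a) == "adalimumab" for a in X])
            bad = ~np.isin(np.asarray([str(a) for a in X]), ("pamidronate", "adalimumab"))
            if bad.any():
                raise ValueError("arm labels must be 'pamidronate' or 'adalimumab'")
        else:
            ada = X.astype(float)
            if not np.isin(ada, (0.0, 1.0)).all():
                raise ValueError("numeric arm indicators must be 0 or 1")
            ada = ada.astype(bool)
        n = len(y)
        a = ada.astype(float)
        XtX = np.array([[n, a.sum()], [a.sum(), a.sum()]])
        Xty = np.array([y.sum(), y[ada].sum()])
        yty = float(y @ y)
        self.posterior_ = _update_crossproducts(self._prior(), XtX, Xty, yty, n)
        self.summary_ = None
        self.n_features_in_ = 1
        return self

    def fit_summary(self, summary: TrialSummary) -> "NormalGammaTrialModel":
        """Update with the trial's sufficient statistics."""
        belief = self._prior()
        n = summary.n_P + summary.n_A
        if n == 0:
            self.posterior_ = replace(belief)
        else:
            xP = summary.xbar_P if summary.n_P else 0.0
            xA = summary.xbar_A if summary.n_A else 0.0
            XtX = np.array(
                [[n, summary.n_A], [summary.n_A, summary.n_A]], dtype=float
            )
            Xty = np.array([summary.n_P * xP + summary.n_A * xA, summary.n_A * xA])
            resid_ss = (n - 2) * summary.s2 if summary.s2 is not None else 0.0
            yty = resid_ss + summary.n_P * xP**2 + summary.n_A * xA**2
            self.posterior_ = _update_crossproducts(belief, XtX, Xty, yty, n)
        self.summary_ = summary
        self.n_features_in_ = 1
        return self

    # -- fitted queries ---------------------------------------------------

    def _posterior(self) -> NormalGammaBelief:
        if not hasattr(self, "posterior_"):
            raise AttributeError("model is not fitted; call fit or fit_summary")
        return self.posterior_

    def predict(self, X) -> np.ndarray:
        """Posterior-mean change (mm) for each requested arm label."""
        X = np.asarray(X)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        post = self._posterior()
        return np.array(
            [float(np.dot(arm_contrast(str(a)), post.theta0)) for a in X]
        )

    def predictive(self, arm: str) -> ScaledT:
        """Posterior predictive for a single future patient on an arm."""
        return predictive_distribution(self._posterior(), arm)

    def credible_interval(self, contrast, level: float = 0.90) -> tuple[float, float]:
        return credible_interval(self._posterior(), contrast, level)

    def prob_clinically_relevant(
        self,
        rule: DecisionRule = DecisionRule(),
        n_draws: int = 10_000,
        rng=None,
    ) -> RelevanceProbabilities:
        return prob_clinically_relevant(self._posterior(), rule, n_draws, rng)


# ---------------------------------------------------------------------------
# Core update
# ---------------------------------------------------------------------------


def _update_crossproducts(
    belief: NormalGammaBelief,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
) -> NormalGammaBelief:
    """Normal-Gamma update from design cross-products.

    ``b_n`` uses the residual form
    ``b0 + (y'y + theta0' R^-1 theta0 - theta_n' R_n^-1 theta_n) / 2`` with
    ``R_n^-1 = R^-1 + X'X`` taken from the factorization already at hand, so
    no cancellation-prone explicit inverse appears.
    """
    try:
        cR = linalg.cho_factor(belief.R, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "prior R is singular; updating a degenerate belief is not supported"
        ) from exc
    eye = np.eye(2)
    Rinv = linalg.cho_solve(cR, eye)
    Rinv = 0.5 * (Rinv + Rinv.T)
    prec_n = Rinv + XtX
    c_n = linalg.cho_factor(prec_n, lower=True)
    R_n = linalg.cho_solve(c_n, eye)
    R_n = 0.5 * (R_n + R_n.T)
    theta0 = belief.theta0
    theta_n = linalg.cho_solve(c_n, Rinv @ theta0 + Xty)
    a_n = belief.a0 + n / 2.0
    b_n = belief.b0 + 0.5 * (yty + theta0 @ Rinv @ theta0 - theta_n @ prec_n @ theta_n)
    if not b_n > 0:
        raise ArithmeticError(
            f"computed b_n = {b_n} <= 0: numerical failure in the update"
        )
    return NormalGammaBelief(
        a0=a_n,
        b0=float(b_n),
        mu_P0=float(theta_n[0]),
        delta0=float(theta_n[1]),
        R=R_n,
    )


def update(belief: NormalGammaBelief, data: TrialSummary) -> NormalGammaBelief:
    """Posterior belief after observing the trial summary (conjugate closure)."""
    return NormalGammaTrialModel(prior=belief).fit_summary(data).posterior_


def credible_interval(
    belief: NormalGammaBelief, contrast, level: float = 0.90
) -> tuple[float, float]:
    """Equal-tailed credible interval (mm) for ``contrast . (mu_P, delta)``."""
    return marginal_parameter_distribution(belief, contrast).interval(level)


# ---------------------------------------------------------------------------
# Decision-rule probability
# ---------------------------------------------------------------------------


def _draw_joint(belief: NormalGammaBelief, n_draws: int, rng) -> np.ndarray:
    """Draws of (mu_P, mu_A) from the joint belief, shape (n_draws, 2)."""
    tau = rng.gamma(shape=belief.a0, scale=1.0 / belief.b0, size=n_draws)
    try:
        L = np.linalg.cholesky(belief.R)
    except np.linalg.LinAlgError:
        # positive semi-definite (degenerate) belief: eigen factor, clip
        w, V = np.linalg.eigh(belief.R)
        L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_draws, 2))
    theta = belief.theta0 + (z @ L.T) / np.sqrt(tau)[:, None]
    mu_P = theta[:, 0]
    return np.column_stack([mu_P, mu_P + theta[:, 1]])


def prob_clinically_relevant(
    belief: NormalGammaBelief,
    rule: DecisionRule = DecisionRule(),
    n_draws: int = 10_000,
    rng=None,
) -> RelevanceProbabilities:
    """Posterior probability of a clinically relevant difference, by Monte Carlo.

    Draws ``tau ~ Gamma(a, b)`` then ``(mu_P, delta) ~ N(theta, R / tau)``
    and evaluates the two (disjoint, for positive margin) winning events.
    Deterministic given ``rng`` (a ``numpy.random.Generator`` or an integer
    seed).  The reported ``mc_se`` is the binomial standard error of
    ``p_union``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(rng)
    mu = _draw_joint(belief, n_draws, rng)
    if rule.benefit_sign > 0:  # benefit = positive change; mirror the draws
        mu = -mu
    mu_P, mu_A = mu[:, 0], mu[:, 1]
    m = 1.0 + rule.margin
    win_P = (mu_P < 0) & (mu_P <= m * mu_A)
    win_A = (mu_A < 0) & (mu_A <= m * mu_P)
    if rule.margin > 0:
        assert not np.any(win_P & win_A), "winning events must be disjoint"
        p_union = float(np.mean(win_P | win_A))
    else:
        p_union = float(np.mean(win_P)) + float(np.mean(win_A))
    p_P = float(np.mean(win_P))
    p_A = float(np.mean(win_A))
    mc_se = math.sqrt(max(p_union * (1 - p_union), 1e-12) / n_draws)
    return RelevanceProbabilities(
        p_P=p_P, p_A=p_A, p_union=p_union, mc_se=mc_se, n_draws=n_draws
    )
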
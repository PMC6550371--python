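"""Synthetic expert panels and patient-level data for pipeline testing.

The panel generator emulates the statistical structure the elicitation
analysis assumes: each expert's stated probabilities are noisy, rounded
evaluations of a true Student-t predictive CDF.  Expert idiosyncrasy enters
as a perturbation of the predictive's location (additive Gaussian, scaled by
the predictive scale) and log-scale; answers are then the perturbed CDF at
the question thresholds, converted to percent and rounded to a grid (real
panels answer predominantly in multiples of 5).  Because the perturbed CDF
is monotone and rounding is a monotone map, generated ladders are monotone
up to ties; a running-maximum sweep (the pool-adjacent-violators solution
for this already-ordered input, and one that preserves the rounding grid)
guards the invariant.

The patient-data generator draws Gaussian change-from-baseline outcomes with
a common SD across arms.  :func:`summarize` reduces records to the
sufficient statistics that drive the conjugate update.

All randomness descends from one master seed through named substreams, so
the expert and patient components are independently reproducible.

No attempt is made to model real expert psychology (anchoring,
overconfidence); the noise model is a plain perturbation sufficient for
parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .elicitation import (
    ARMS,
    DEFAULT_BASELINE,
    DEFAULT_THRESHOLDS,
    Answer,
    ElicitationAnswerSet,
    ExpertPanel,
)
from .model_core import ScaledT
from .posterior import TrialSummary
from .trial_sim import ModelParameters

__all__ = [
    "PanelGeneratorSpec",
    "generate_expert_panel",
    "generate_patient_data",
    "summarize",
    "substream",
]

#: Registry of named substreams hung off the master seed.
_STREAMS = {"experts": 1, "patients": 2}


def substream(seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic named child stream of a master seed."""
    return np.random.SeedSequence(entropy=[int(seed), _STREAMS[name]])


@dataclass(frozen=True)
class PanelGeneratorSpec:
    """Settings for generating a synthetic expert panel.

    ``predictive_P`` / ``predictive_A`` are the true single-patient
    predictives on the *score* scale (location includes the baseline).
    ``probit_noise_sd`` perturbs each expert's location (in units of the
    predictive scale) and log-scale; ``rounding_grid`` is the percent grid
    answers are rounded to (0 disables rounding).
    """

    predictive_P: ScaledT
    predictive_A: ScaledT
    n_experts: int = 13
    probit_noise_sd: float = 0.1
    rounding_grid: float = 5.0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    baseline: float = DEFAULT_BASELINE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be at least 1")
        if self.probit_noise_sd < 0:
            raise ValueError("probit_noise_sd must be nonnegative")
        if self.rounding_grid < 0:
            raise ValueError("rounding_grid must be nonnegative")
        if self.rounding_grid > 0 and abs(100 / self.rounding_grid % 1) > 1e-9:
            raise ValueError("rounding_grid must divide 100")
        ts = tuple(float(t) for t in self.thresholds)
        if any(b >= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly decreasing")
        object.__setattr__(self, "thresholds", ts)


def generate_expert_panel(spec: PanelGeneratorSpec) -> ExpertPanel:
    """Generate a panel of noisy, rounded evaluations of the true CDFs."""
    rng = np.random.default_rng(substream(spec.seed, "experts"))
    truths = {"pamidronate": spec.predictive_P, "adalimumab": spec.predictive_A}
    experts = []
    for i in range(spec.n_experts):
        answers = {}
        for arm in ARMS:
            true = truths[arm]
            loc = true.location + rng.normal(0.0, spec.probit_noise_sd * true.scale)
            scale = true.scale * np.exp(rng.normal(0.0, spec.probit_noise_sd))
            # thresholds are decreasing; evaluate ascending, repair, flip back
            ts = np.array(spec.thresholds[::-1])
            probs = 100.0 * stats.t.cdf(ts, df=true.df, loc=loc, scale=scale)
            if spec.rounding_grid > 0:
                probs = np.round(probs / spec.rounding_grid) * spec.rounding_grid
            probs = np.clip(probs, 0.0, 100.0)
            probs = np.maximum.accumulate(probs)  # monotone guard (grid-safe)
            probs = probs[::-1]
            prefix = "QP" if arm == "pamidronate" else "QA"
            answers[arm] = tuple(
                Answer(f"{prefix}{k + 1}", t, float(p))
                for k, (t, p) in enumerate(zip(spec.thresholds, probs))
            )
        experts.append(
            ElicitationAnswerSet(
                expert_id=f"synthetic_{i + 1:03d}",
                answers=answers,
                baseline_score=spec.baseline,
            )
        )
    return ExpertPanel(experts=tuple(experts))


def generate_patient_data(
    params: ModelParameters, n_per_arm: int, seed: int = 0
) -> pd.DataFrame:
    """Individual patient records (patient_id, arm, change_mm), Gaussian per arm."""
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be at least 1")
    rng = np.random.default_rng(substream(seed, "patients"))
    rows = []
    for arm, mu in (("pamidronate", params.mu_P), ("adalimumab", params.mu_A)):
        changes = rng.normal(mu, params.sigma, n_per_arm)
        for j, c in enumerate(changes):
            rows.append((f"{arm[:3]}_{j + 1:04d}", arm, float(c)))
    return pd.DataFrame(rows, columns=["patient_id", "arm", "change_mm"])


def summarize(records: pd.DataFrame) -> TrialSummary:
    """Reduce patient records to the trial's sufficient statistics.

    Pooled variance uses denominator ``n_P + n_A - 2``; with fewer than
    three patients in total it is flagged absent (``None``).
    """
    if len(records) == 0:
        raise ValueError("no records to summarize")
    by_arm = {arm: g["change_mm"].to_numpy() for arm, g in records.groupby("arm")}
    unknown = set(by_arm) - set(ARMS)
    if unknown:
        raise ValueError(f"unknown arm labels {sorted(unknown)}")
    y_P = by_arm.get("pamidronate", np.empty(0))
    y_A = by_arm.get("adalimumab", np.empty(0))
    n_P, n_A = len(y_P), len(y_A)
    xbar_P = float(y_P.mean()) if n_P else 0.0
    xbar_A = float(y_A.mean()) if n_A else 0.0
    if n_P + n_A >= 3:
        ss = float(((y_P - xbar_P) ** 2).sum() + ((y_A - xbar_A) ** 2).sum())
        s2 = ss / (n_P + n_A - 2)
    else:
        s2 = None
    return TrialSummary(n_P=n_P, n_A=n_A, xbar_P=xbar_P, xbar_A=xbar_A, s2=s2)
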
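"""File formats, run configuration and the end-to-end pipeline.

Formats
-------
* Expert answers CSV: columns ``expert_id, arm, question_id, threshold_mm,
  probability_pct`` (UTF-8, decimal point, one row per answer).  The
  published 13-expert panel ships as a package fixture in this dialect.
* Interval-weights CSV: ``expert_id, arm, interval_lo_mm, interval_hi_mm,
  weight``.
* Trial summaries JSON: mapping of name -> ``{n_P, n_A, xbar_P_mm,
  xbar_A_mm, s2_mm2}``; the three hypothetical datasets ship as a fixture.
* Scenarios YAML: ``scenarios: [{label, mu_P_mm, mu_A_mm, sigma_mm,
  n_per_arm}]``; the six published simulation scenarios ship as a fixture.

Every file the pipeline writes re-parses through this module's own readers,
and identical configuration plus seed yields byte-identical outputs (no
timestamps are embedded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model_core, posterior, trial_sim
from .elicitation import (
    ARMS,
    DEFAULT_BASELINE,
    Answer,
    ElicitationAnswerSet,
    ExpertPanel,
    PanelFitConfig,
    PanelPriorFitter,
    consensus_answers,
    feedback_report,
    render_report,
)
from .model_core import (
    NormalGammaBelief,
    SummaryConstraints,
    belief_to_dict,
    calibrate_from_summaries,
    save_belief,
)
from .posterior import DecisionRule, TrialSummary, credible_interval, update
from .trial_sim import ModelParameters, OCResult, Scenario, run_operating_characteristics

__all__ = [
    "packaged_panel",
    "packaged_trial_summaries",
    "packaged_scenarios",
    "parse_answers_csv",
    "write_answers_csv",
    "parse_interval_weights_csv",
    "load_trial_summaries",
    "save_trial_summaries",
    "load_scenarios",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_ANSWER_COLUMNS = ["expert_id", "arm", "question_id", "threshold_mm", "probability_pct"]
_WEIGHT_COLUMNS = ["expert_id", "arm", "interval_lo_mm", "interval_hi_mm", "weight"]


def _data_path(name: str):
    return resources.files("bayeselicit.data").joinpath(name)


def packaged_panel() -> ExpertPanel:
    """The published 13-expert answer panel shipped with the package."""
    with resources.as_file(_data_path("expert_panel_answers.csv")) as p:
        return parse_answers_csv(p)


def packaged_trial_summaries() -> dict[str, TrialSummary]:
    """The three published hypothetical trial datasets."""
    with resources.as_file(_data_path("hypothetical_trial_summaries.json")) as p:
        return load_trial_summaries(p)


def packaged_scenarios() -> list[Scenario]:
    """The six published data-simulation scenarios."""
    with resources.as_file(_data_path("simulation_scenarios.yaml")) as p:
        return load_scenarios(p)


# ---------------------------------------------------------------------------
# Answers CSV
# ---------------------------------------------------------------------------


def parse_answers_csv(
    path, *, baseline_score: float = DEFAULT_BASELINE
) -> ExpertPanel:
    """Read an expert-answers CSV into a validated panel.

    Row order is irrelevant (answers are ordered by decreasing threshold);
    duplicate (expert, arm, question) rows, out-of-range probabilities and
    monotonicity violations are rejected with the offending expert/row named.
    """
    df = pd.read_csv(path)
    missing = [c for c in _ANSWER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"answers CSV is missing column(s) {missing}")
    bad = df[(df["probability_pct"] < 0) | (df["probability_pct"] > 100)]
    if len(bad):
        row = bad.index[0] + 2  # header + 1-based
        raise ValueError(
            f"probability outside [0, 100] at CSV row {row} "
            f"(value {bad.iloc[0]['probability_pct']})"
        )
    dup = df.duplicated(subset=["expert_id", "arm", "question_id"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(
            f"duplicate answer for ({r['expert_id']}, {r['arm']}, "
            f"{r['question_id']})"
        )
    experts = []
    for expert_id, g in df.groupby("expert_id", sort=True):
        answers = {}
        for arm, ga in g.groupby("arm"):
            ga = ga.sort_values("threshold_mm", ascending=False)
            answers[str(arm)] = tuple(
                Answer(str(r.question_id), float(r.threshold_mm), float(r.probability_pct))
                for r in ga.itertuples()
            )
        try:
            experts.append(
                ElicitationAnswerSet(
                    expert_id=str(expert_id),
                    answers=answers,
                    baseline_score=baseline_score,
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid answers for expert {expert_id}: {exc}") from exc
    return ExpertPanel(experts=tuple(experts))


def write_answers_csv(panel_or_answers, path) -> None:
    """Write a panel (or a single answer set) in the answers CSV dialect."""
    experts = (
        panel_or_answers.experts
        if isinstance(panel_or_answers, ExpertPanel)
        else [panel_or_answers]
    )
    rows = [
        (e.expert_id, arm, a.question_id, a.threshold_mm, a.probability_pct)
        for e in experts
        for arm, ans in e.answers.items()
        for a in ans
    ]
    pd.DataFrame(rows, columns=_ANSWER_COLUMNS).to_csv(path, index=False)


def parse_interval_weights_csv(path) -> dict[str, dict[str, tuple]]:
    """Read interval weights keyed by expert then arm."""
    df = pd.read_csv(path)
    missing = [c for c in _WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval-weights CSV is missing column(s) {missing}")
    out: dict[str, dict[str, tuple]] = {}
    for (expert_id, arm), g in df.groupby(["expert_id", "arm"]):
        g = g.sort_values("interval_lo_mm")
        out.setdefault(str(expert_id), {})[str(arm)] = tuple(
            ((float(r.interval_lo_mm), float(r.interval_hi_mm)), float(r.weight))
            for r in g.itertuples()
        )
    return out


# ---------------------------------------------------------------------------
# Trial summaries and scenarios
# ---------------------------------------------------------------------------


def load_trial_summaries(path) -> dict[str, TrialSummary]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    out = {}
    for name, d in raw.items():
        out[name] = TrialSummary(
            n_P=int(d["n_P"]),
            n_A=int(d["n_A"]),
            xbar_P=float(d["xbar_P_mm"]),
            xbar_A=float(d["xbar_A_mm"]),
            s2=None if d.get("s2_mm2") is None else float(d["s2_mm2"]),
        )
    return out


def save_trial_summaries(summaries: dict[str, TrialSummary], path) -> None:
    payload = {
        name: {
            "n_P": s.n_P,
            "n_A": s.n_A,
            "xbar_P_mm": s.xbar_P,
            "xbar_A_mm": s.xbar_A,
            "s2_mm2": s.s2,
        }
        for name, s in summaries.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_scenarios(path) -> list[Scenario]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    scenarios = []
    for d in raw["scenarios"]:
        scenarios.append(
            Scenario(
                label=str(d["label"]),
                params=ModelParameters(
                    mu_P=float(d["mu_P_mm"]),
                    mu_A=float(d["mu_A_mm"]),
                    sigma=float(d["sigma_mm"]),
                ),
                n_per_arm=int(d.get("n_per_arm", 20)),
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    ``answers_csv`` / ``scenarios_yaml`` / ``trial_summaries_json`` default
    to the packaged fixtures when None.  ``constraints`` defaults to the
    published consensus summaries.
    """

    out_dir: str | Path = "bayeselicit_out"
    answers_csv: str | Path | None = None
    trial_summaries_json: str | Path | None = None
    scenarios_yaml: str | Path | None = None
    baseline: float = DEFAULT_BASELINE
    a0: float = 2.0
    consensus_method: str = "mean"
    rho: float = 0.99
    sampling_variance: float | None = None
    constraints: SummaryConstraints = field(
        default_factory=lambda: model_core.CONSENSUS_SUMMARIES
    )
    rule: DecisionRule = field(default_factory=DecisionRule)
    n_sims: int = 1000
    n_draws: int = 10_000
    seed: int = 0
    verbose: bool = False

    def validate(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        for attr in ("answers_csv", "trial_summaries_json", "scenarios_yaml"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        rule = DecisionRule(**raw.pop("rule", {}))
        constraints_raw = raw.pop("constraints", None)
        constraints = (
            _constraints_from_dict(constraints_raw)
            if constraints_raw
            else model_core.CONSENSUS_SUMMARIES
        )
        return cls(rule=rule, constraints=constraints, **raw)


def _constraints_from_dict(d: dict) -> SummaryConstraints:
    kwargs = dict(d)
    for key in ("delta_interval", "variance_percentile"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SummaryConstraints(**kwargs)


def _log_defaults(config: RunConfig) -> dict:
    """Resolve and log every defaulted design decision of the run."""
    panel_cfg = PanelFitConfig(
        a0=config.a0,
        sampling_variance=config.sampling_variance,
        rho=config.rho,
        consensus_method=config.consensus_method,
    )
    resolved = {
        "baseline_mm": config.baseline,
        "a0": config.a0,
        "prior_df": 2 * config.a0,
        "consensus_method": config.consensus_method,
        "rho": config.rho,
        "sampling_variance_mm2": panel_cfg.resolved_sampling_variance(),
        "rule_margin": config.rule.margin,
        "rule_prob_threshold": config.rule.prob_threshold,
        "rule_combine": config.rule.combine,
        "n_sims": config.n_sims,
        "n_draws": config.n_draws,
        "seed": config.seed,
        "variance_units": "mm2",
        "interval_type": "equal-tailed",
    }
    for key, value in resolved.items():
        logger.info("resolved setting %s = %r", key, value)
    return resolved


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the staged workflow end to end and write a report bundle.

    Stages: load answers -> consensus -> panel-fitted prior -> calibrated
    prior -> feedback report -> posterior update per trial summary -> OC
    simulation per scenario.  Returns the paths written, keyed by artifact
    name.  Identical config and seed give byte-identical outputs.
    """
    config.validate()
    if config.verbose:
        logging.basicConfig(level=logging.INFO)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    resolved = _log_defaults(config)
    meta_path = out_dir / "run_settings.json"
    meta_path.write_text(json.dumps(resolved, indent=2) + "\n", encoding="utf-8")
    outputs["run_settings"] = meta_path

    # -- elicit + consensus
    panel = _stage(
        "load_answers",
        lambda: parse_answers_csv(config.answers_csv, baseline_score=config.baseline)
        if config.answers_csv
        else packaged_panel(),
    )
    consensus = _stage(
        "consensus", lambda: consensus_answers(panel, config.consensus_method)
    )
    p = out_dir / "consensus_answers.csv"
    write_answers_csv(consensus, p)
    outputs["consensus_answers"] = p

    # -- panel-fitted prior (placeholder thresholds; not the published prior)
    fitter = PanelPriorFitter(
        a0=config.a0,
        sampling_variance=config.sampling_variance,
        rho=config.rho,
        consensus_method=config.consensus_method,
    )
    panel_belief = _stage("fit_panel_prior", lambda: fitter.fit(panel).belief_)
    p = out_dir / "panel_prior.json"
    save_belief(panel_belief, p, source="panel fit (consensus answers)")
    outputs["panel_prior"] = p

    # -- calibrated consensus prior
    prior = _stage(
        "calibrate", lambda: calibrate_from_summaries(config.constraints)
    )
    p = out_dir / "calibrated_prior.json"
    save_belief(prior, p, source="calibrated from published summaries")
    outputs["calibrated_prior"] = p

    # -- feedback report
    report = _stage(
        "feedback", lambda: feedback_report(prior, baseline=config.baseline)
    )
    p = out_dir / "feedback_report.json"
    p.write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
    outputs["feedback_report"] = p
    p = out_dir / "feedback_report.txt"
    p.write_text(render_report(report) + "\n", encoding="utf-8")
    outputs["feedback_report_txt"] = p

    # -- posterior updates
    summaries = _stage(
        "load_trial_summaries",
        lambda: load_trial_summaries(config.trial_summaries_json)
        if config.trial_summaries_json
        else packaged_trial_summaries(),
    )
    posterior_rows = []
    for name, summary in summaries.items():
        post = _stage(f"update[{name}]", lambda s=summary: update(prior, s))
        p = out_dir / f"posterior_{name}.json"
        save_belief(post, p, source=f"calibrated prior + {name}")
        outputs[f"posterior_{name}"] = p
        for label, contrast in (
            ("mu_P", model_core.CONTRAST_PAMIDRONATE),
            ("mu_A", model_core.CONTRAST_ADALIMUMAB),
            ("delta", model_core.CONTRAST_DELTA),
        ):
            lo, hi = credible_interval(post, contrast, 0.90)
            posterior_rows.append((name, label, lo, hi))
    p = out_dir / "posterior_intervals.csv"
    pd.DataFrame(
        posterior_rows, columns=["dataset", "quantity", "lo_90_mm", "hi_90_mm"]
    ).to_csv(p, index=False)
    outputs["posterior_intervals"] = p

    # -- operating characteristics
    scenarios = _stage(
        "load_scenarios",
        lambda: load_scenarios(config.scenarios_yaml)
        if config.scenarios_yaml
        else packaged_scenarios(),
    )
    oc_rows = []
    ss = np.random.SeedSequence(config.seed)
    scenario_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(scenarios))]
    for scenario, sc_seed in zip(scenarios, scenario_seeds):
        result = _stage(
            f"simulate[{scenario.label}]",
            lambda sc=scenario, sd=sc_seed: run_operating_characteristics(
                sc,
                prior,
                rule=config.rule,
                n_sims=config.n_sims,
                n_draws=config.n_draws,
                seed=sd,
            ),
        )
        oc_rows.append(
            (
                scenario.label,
                result.n_sims,
                result.proportion_declared,
                result.mc_standard_error,
                result.near_boundary_fraction,
                result.seed,
            )
        )
    oc_df = pd.DataFrame(
        oc_rows,
        columns=[
            "scenario",
            "n_sims",
            "proportion_declared",
            "mc_se",
            "near_boundary_fraction",
            "seed",
        ],
    )
    p = out_dir / "oc_table.csv"
    oc_df.to_csv(p, index=False)
    outputs["oc_table"] = p
    p = out_dir / "oc_table.json"
    p.write_text(
        json.dumps(oc_df.to_dict(orient="records"), indent=2) + "\n",
        encoding="utf-8",
    )
    outputs["oc_table_json"] = p

    return outputs
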
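"""Individual-level trial simulator with MNAR missingness at both stages.

The generator draws, per subject: true tobacco abstinence; the
self-report an abstainer would give (users always report use);
survey missingness whose odds depend on true tobacco use through
``true_or1``; a latent "confirmable" status (would a urine test verify
the claim); and urine missingness whose odds depend on confirmability
through ``true_or2``.  Aggregation to :class:`~cessmiss.aggregates.ArmCounts`
mirrors the observation process: urine cells exist only for observed
self-reported abstainers.

Missingness bases: ``survey_miss_base`` is the probability a tobacco
USER misses the survey, abstainers' odds being base-odds / true_or1;
``urine_miss_base`` is the probability a CONFIRMABLE self-reported
abstainer misses urine, unconfirmable odds being base-odds * true_or2.
With honest reporting the latent tables the analysis odds ratios refer
to coincide with the generator's, so matching the assumed ORs to the
true ones removes imputation bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .aggregates import ArmCounts, TrialCounts, validate_counts

__all__ = [
    "SimArm",
    "SimScenario",
    "simulate_trial",
    "recovery_experiment",
    "odds_scale",
    "fixture_like_scenario",
]


def odds_scale(p: float, ratio: float) -> float:
    """Scale a probability on the odds scale: odds' = ratio * odds(p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"probability must be in [0,1], got {p!r}")
    if not ratio > 0 or math.isinf(ratio):
        raise ValueError(f"odds multiplier must be a positive finite real, got {ratio!r}")
    scaled = ratio * p / (1 - p + ratio * p)
    if not 0 <= scaled <= 1:  # unreachable for valid inputs; guards NaN
        raise ValueError(f"odds transform of p={p!r} by {ratio!r} is ill-defined")
    return scaled


@dataclass(frozen=True)
class SimArm:
    label: str
    n: int
    p_abstinent: float  # true probability of tobacco abstinence
    p_verify_given_abstinent: float  # P(urine test confirms | reports abstinence)


@dataclass(frozen=True)
class SimScenario:
    """One simulated-trial configuration with known latent truth."""

    arms: tuple[SimArm, ...]
    survey_miss_base: float  # P(survey missing | tobacco user)
    true_or1: float  # survey-missingness odds, users vs abstainers
    urine_miss_base: float  # P(urine missing | confirmable reporter)
    true_or2: float  # urine-missingness odds, unconfirmable vs confirmable
    self_report_honesty: float = 1.0  # P(abstainer reports abstinence)
    seed: int = 0
    contrasts: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] | None = None

    def __post_init__(self) -> None:
        for name in ("survey_miss_base", "urine_miss_base", "self_report_honesty"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v!r}")
        for name in ("true_or1", "true_or2"):
            v = getattr(self, name)
            if not v > 0 or math.isinf(v):
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")
        for arm in self.arms:
            for name in ("p_abstinent", "p_verify_given_abstinent"):
                v = getattr(arm, name)
                if not 0 <= v <= 1:
                    raise ValueError(f"{arm.label}: {name} must be in [0,1], got {v!r}")
        # Surface ill-defined odds transforms at construction time.
        odds_scale(self.survey_miss_base, 1 / self.true_or1)
        odds_scale(self.urine_miss_base, self.true_or2)

    def resolved_contrasts(self):
        if self.contrasts is not None:
            return dict(self.contrasts)
        if len(self.arms) == 4:
            a = [arm.label for arm in self.arms]
            return {
                "counseling": ((a[1], a[3]), (a[0], a[2])),
                "contests": ((a[2], a[3]), (a[0], a[1])),
            }
        raise ValueError(
            "contrasts must be given explicitly for a non-four-arm scenario"
        )


def fixture_like_scenario(
    true_or1: float = 3.0,
    true_or2: float = 3.0,
    seed: int = 0,
    n_per_arm: int = 300,
) -> SimScenario:
    """A four-arm scenario at the scale of the Enhanced Quit & Win trial.

    ~25% true abstinence, 85% of abstinence claims biochemically
    confirmable, ~20% survey missingness among users and ~30% urine
    missingness among confirmable reporters, honest reporting.
    """
    arms = tuple(
        SimArm(f"Tx{i + 1}", n_per_arm, 0.25, 0.85) for i in range(4)
    )
    return SimScenario(
        arms=arms,
        survey_miss_base=0.2,
        true_or1=true_or1,
        urine_miss_base=0.3,
        true_or2=true_or2,
        self_report_honesty=1.0,
        seed=seed,
    )


def simulate_trial(scenario: SimScenario) -> tuple[TrialCounts, pd.DataFrame]:
    """Draw one trial and aggregate it to the per-arm count schema.

    Returns ``(trial, truth)`` where ``truth`` is a per-arm frame of the
    latent counts: true abstainers, subjects who would self-report
    abstinence, and those whose report would also be biochemically
    verified.  Deterministic given the scenario (including its seed);
    per-arm substreams are derived from (seed, arm index).
    """
    p_miss_user = scenario.survey_miss_base
    p_miss_abst = odds_scale(p_miss_user, 1 / scenario.true_or1)
    p_umiss_conf = scenario.urine_miss_base
    p_umiss_unconf = odds_scale(p_umiss_conf, scenario.true_or2)

    arms = []
    truth_rows = []
    for idx, arm in enumerate(scenario.arms):
        rng = np.random.default_rng([scenario.seed, idx])
        n = arm.n
        abstinent = rng.random(n) < arm.p_abstinent
        honest = rng.random(n) < scenario.self_report_honesty
        reports_abst = abstinent & honest
        p_smiss = np.where(abstinent, p_miss_abst, p_miss_user)
        survey_missing = rng.random(n) < p_smiss
        confirmable = rng.random(n) < arm.p_verify_given_abstinent
        p_umiss = np.where(confirmable, p_umiss_conf, p_umiss_unconf)
        urine_missing = rng.random(n) < p_umiss

        observed = ~survey_missing
        sr_abst = observed & reports_abst
        sr_fail = observed & ~reports_abst
        provided = sr_abst & ~urine_missing
        arms.append(
            ArmCounts(
                arm_label=arm.label,
                n_total=n,
                sr_abstinent=int(sr_abst.sum()),
                sr_failure=int(sr_fail.sum()),
                survey_missing=int(survey_missing.sum()),
                urine_abstinent=float((provided & confirmable).sum()),
                urine_failure=float((provided & ~confirmable).sum()),
                urine_missing=float((sr_abst & urine_missing).sum()),
            )
        )
        truth_rows.append(
            {
                "arm": arm.label,
                "n": n,
                "true_abstinent": int(abstinent.sum()),
                "true_sr_abstinent": int(reports_abst.sum()),
                "true_verified_abstinent": int((reports_abst & confirmable).sum()),
            }
        )
    trial = TrialCounts(arms=tuple(arms), contrasts=scenario.resolved_contrasts())
    problems = validate_counts(trial)
    assert not problems, problems
    return trial, pd.DataFrame(truth_rows).set_index("arm")


def recovery_experiment(
    scenario: SimScenario,
    analysis_params,
    n_reps: int,
) -> pd.DataFrame:
    """Bias/RMSE of imputed pooled rates against the latent truth.

    Simulates ``n_reps`` independent trials (replicate r uses seed
    ``scenario.seed + r``), imputes every arm under ``analysis_params``,
    and compares the pooled self-report and urine-verified abstinence
    rates of each contrast pool with the replicate's latent truth.
    Returns one row per (outcome, contrast, pool) with mean bias, its
    Monte-Carlo standard error, RMSE and the mean estimated/true rates.
    """
    from .effects import pool_arms
    from .stage2 import impute_arm

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    contrasts = scenario.resolved_contrasts()
    records: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    for rep in range(n_reps):
        trial, truth = simulate_trial(replace(scenario, seed=scenario.seed + rep))
        imputed = {a.arm_label: impute_arm(a, analysis_params) for a in trial.arms}
        for cname, (exposed, control) in contrasts.items():
            for side, pool in (("exposed", exposed), ("control", control)):
                n_pool = float(truth.loc[list(pool), "n"].sum())
                for outcome, truth_col in (
                    ("self_report", "true_sr_abstinent"),
                    ("urine_verified", "true_verified_abstinent"),
                ):
                    est, total = pool_arms(imputed, pool, outcome)
                    true_rate = float(truth.loc[list(pool), truth_col].sum()) / n_pool
                    records.setdefault((outcome, cname, side), []).append(
                        (est / total, true_rate)
                    )
    rows = []
    for (outcome, cname, side), pairs in records.items():
        est = np.array([p[0] for p in pairs])
        tru = np.array([p[1] for p in pairs])
        err = est - tru
        rows.append(
            {
                "outcome": outcome,
                "contrast": cname,
                "pool": side,
                "n_reps": n_reps,
                "mean_estimate": est.mean(),
                "mean_truth": tru.mean(),
                "mean_bias": err.mean(),
                "se_bias": err.std(ddof=1) / math.sqrt(n_reps) if n_reps > 1 else math.nan,
                "rmse": math.sqrt((err**2).mean()),
            }
        )
    return pd.DataFrame(rows)
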
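"""Pool imputed arms into intervention contrasts and estimate effects.

Pooling happens after per-arm imputation, never before.  Effects are
abstinence rates, the odds ratio for abstinence (exposed vs control), and
a Pearson chi-square test (no continuity correction) on the pooled 2x2
table; imputed tables generally carry fractional counts, which the closed
form accepts as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from scipy import stats

from .aggregates import TrialCounts
from .stage2 import ImputedArm

__all__ = [
    "Outcome",
    "ContrastResult",
    "pool_arms",
    "contrast",
    "complete_case",
    "contrast_imputed",
    "format_rate",
    "format_or",
    "format_p",
]

Outcome = Literal["self_report", "urine_verified"]


@dataclass(frozen=True)
class ContrastResult:
    """A pooled 2x2 comparison of abstinence between two arm pools."""

    contrast_name: str
    exposed_abstinent: float
    exposed_total: float
    control_abstinent: float
    control_total: float
    exposed_rate: float
    control_rate: float
    odds_ratio: float
    chi2: float
    p_value: float


def pool_arms(
    imputed: Mapping[str, ImputedArm],
    pool: tuple[str, ...],
    outcome: Outcome,
) -> tuple[float, float]:
    """Sum imputed abstinent counts and denominators over a pool of arms.

    The denominator is always the full randomized n of every pooled arm;
    the numerator is n11 + n21 for the self-report outcome and
    f11. + f21 for the urine-verified outcome.
    """
    if not pool:
        raise ValueError("pool must be nonempty")
    abstinent = 0.0
    total = 0.0
    for label in pool:
        if label not in imputed:
            raise KeyError(f"no imputed results for arm {label!r}")
        ia = imputed[label]
        if outcome == "self_report":
            abstinent += ia.sr_abstinent_total
        elif outcome == "urine_verified":
            abstinent += ia.verified_abstinent_total
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        total += ia.arm.n_total
    return abstinent, total


def pearson_chi2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (1 df) on a 2x2 table [[a,b],[c,d]].

    Accepts fractional cells.  Returns (statistic, upper-tail p-value).
    """
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m <= 0 for m in margins):
        raise ValueError(f"chi-square undefined: zero margin in table {(a, b, c, d)}")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def contrast(
    exposed: tuple[float, float], control: tuple[float, float], name: str
) -> ContrastResult:
    """Rates, odds ratio and chi-square test for one pooled comparison."""
    ea, et = exposed
    ca, ct = control
    for lbl, (x, t) in (("exposed", exposed), ("control", control)):
        if t <= 0:
            raise ValueError(f"{lbl} total must be > 0, got {t!r}")
        if not 0 <= x <= t:
            raise ValueError(f"{lbl} abstinent count {x!r} outside [0, {t!r}]")
    chi2, p = pearson_chi2(ea, et - ea, ca, ct - ca)
    odds_exposed = ea / (et - ea) if et > ea else math.inf
    odds_control = ca / (ct - ca) if ct > ca else math.inf
    return ContrastResult(
        contrast_name=name,
        exposed_abstinent=ea,
        exposed_total=et,
        control_abstinent=ca,
        control_total=ct,
        exposed_rate=ea / et,
        control_rate=ca / ct,
        odds_ratio=odds_exposed / odds_control,
        chi2=chi2,
        p_value=p,
    )


def contrast_imputed(
    trial: TrialCounts, imputed: Mapping[str, ImputedArm], outcome: Outcome
) -> dict[str, ContrastResult]:
    """Evaluate every named contrast of a trial on per-arm imputed results."""
    out = {}
    for name, (exposed, control) in trial.contrasts.items():
        out[name] = contrast(
            pool_arms(imputed, exposed, outcome),
            pool_arms(imputed, control, outcome),
            name,
        )
    return out


def complete_case(trial: TrialCounts, outcome: Outcome) -> dict[str, ContrastResult]:
    """Complete-case analysis: subjects with missing outcomes are dropped.

    Self-report: numerators n11, denominators restricted to survey
    respondents.  Urine-verified: numerators f11_obs, denominators
    restricted to subjects with a urine result.
    """

    def cells(pool: tuple[str, ...]) -> tuple[float, float]:
        abstinent = 0.0
        total = 0.0
        for label in pool:
            a = trial.arm(label)
            if outcome == "self_report":
                abstinent += a.sr_abstinent
                total += a.survey_respondents
            elif outcome == "urine_verified":
                abstinent += a.urine_abstinent
                total += a.urine_provided
            else:
                raise ValueError(f"unknown outcome {outcome!r}")
        return abstinent, total

    out = {}
    for name, (exposed, control) in trial.contrasts.items():
        out[name] = contrast(cells(exposed), cells(control), name)
    return out


def format_rate(rate: float) -> str:
    """Proportion as a percentage with one decimal, e.g. '25.8%'."""
    return f"{100 * rate:.1f}%"


def format_or(odds_ratio: float) -> str:
    return f"{odds_ratio:.2f}"


def format_p(p: float) -> str:
    """P-value to three decimals without a leading zero, e.g. '.046'."""
    s = f"{p:.3f}"
    return s[1:] if s.startswith("0") else s
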
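"""Sensitivity grids: sweep (OR1 x OR2 x lambda x eta) scenarios.

The self-report grid varies OR1 only; the verified grid takes the
Cartesian product with OR1 as the outer loop and OR2 as the inner loop,
matching the layout of the published sensitivity tables.  Results are
long-format records (one row per scenario x contrast) with an optional
wide rendering styled after the published tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .aggregates import TrialCounts, validate_counts, CountsValidationError
from .effects import (
    ContrastResult,
    Outcome,
    complete_case,
    contrast_imputed,
    format_or,
    format_p,
    format_rate,
)
from .stage1 import SensitivityParams, impute_stage1
from .stage2 import ImputedArm, impute_arm, impute_stage2

__all__ = [
    "GridReport",
    "run_self_report_grid",
    "run_verified_grid",
    "DEFAULT_OR_VALUES",
    "REPORT_CSV_HEADER",
]

logger = logging.getLogger(__name__)

#: Default sensitivity values for both odds ratios: 1..5 and +inf.
DEFAULT_OR_VALUES: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, math.inf)

REPORT_CSV_HEADER = (
    "outcome",
    "or1",
    "or2",
    "lambda",
    "eta",
    "contrast",
    "exposed_rate",
    "control_rate",
    "odds_ratio",
    "chi2",
    "p_value",
    "exposed_abstinent",
    "exposed_total",
    "control_abstinent",
    "control_total",
)


@dataclass(frozen=True)
class GridReport:
    """Scenario-indexed contrast results for one outcome."""

    outcome: Outcome
    scenarios: tuple[tuple[SensitivityParams, dict[str, ContrastResult]], ...]
    includes_complete_case: bool = False
    complete_case_results: dict[str, ContrastResult] | None = None

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format records, one row per scenario x contrast.

        Infinite odds ratios appear as the literal string 'inf' in the
        or1/or2 columns; for the self-report outcome the urine-stage
        parameters are left blank.
        """
        rows = []
        sr = self.outcome == "self_report"
        if self.includes_complete_case and self.complete_case_results:
            for name, res in self.complete_case_results.items():
                rows.append(self._row("complete_case", "", "", "", name, res))
        for params, results in self.scenarios:
            for name, res in results.items():
                rows.append(
                    self._row(
                        _fmt_or(params.or1),
                        "" if sr else _fmt_or(params.or2),
                        "" if sr else f"{params.lam:g}",
                        "" if sr else f"{params.eta:g}",
                        name,
                        res,
                    )
                )
        return pd.DataFrame(rows, columns=list(REPORT_CSV_HEADER))

    def _row(self, or1, or2, lam, eta, name, res: ContrastResult) -> dict:
        return {
            "outcome": self.outcome,
            "or1": or1,
            "or2": or2,
            "lambda": lam,
            "eta": eta,
            "contrast": name,
            "exposed_rate": res.exposed_rate,
            "control_rate": res.control_rate,
            "odds_ratio": res.odds_ratio,
            "chi2": res.chi2,
            "p_value": res.p_value,
            "exposed_abstinent": res.exposed_abstinent,
            "exposed_total": res.exposed_total,
            "control_abstinent": res.control_abstinent,
            "control_total": res.control_total,
        }

    def render(self) -> str:
        """Wide, human-readable table in the style of the published grids."""
        names = list(self.scenarios[0][1]) if self.scenarios else []
        sr = self.outcome == "self_report"
        head_params = ["OR1"] if sr else ["OR1", "OR2"]
        header = head_params + [
            col
            for name in names
            for col in (f"{name}:exposed", f"{name}:control", f"{name}:OR", f"{name}:p")
        ]
        widths = [max(8, len(h) + 2) for h in header]
        lines = ["".join(h.rjust(w) for h, w in zip(header, widths))]

        def add(params_cells: list[str], results: dict[str, ContrastResult]) -> None:
            cells = list(params_cells)
            for name in names:
                r = results[name]
                cells += [
                    format_rate(r.exposed_rate),
                    format_rate(r.control_rate),
                    format_or(r.odds_ratio),
                    format_p(r.p_value),
                ]
            lines.append("".join(c.rjust(w) for c, w in zip(cells, widths)))

        if self.includes_complete_case and self.complete_case_results:
            add(["CC"] if sr else ["CC", ""], self.complete_case_results)
        for params, results in self.scenarios:
            cells = [_fmt_or(params.or1)] if sr else [
                _fmt_or(params.or1),
                _fmt_or(params.or2),
            ]
            add(cells, results)
        return "\n".join(lines)


def _fmt_or(x: float) -> str:
    return f"{x:g}"  # 'inf' for math.inf


def _check(trial: TrialCounts) -> None:
    problems = validate_counts(trial)
    if problems:
        raise CountsValidationError("; ".join(problems))
    if not trial.contrasts:
        raise CountsValidationError("trial defines no contrasts to evaluate")


def run_self_report_grid(
    trial: TrialCounts,
    or1_values: Sequence[float] = DEFAULT_OR_VALUES,
    include_complete_case: bool = True,
) -> GridReport:
    """Sweep OR1 for the self-report abstinence outcome."""
    _check(trial)
    if not or1_values:
        raise ValueError("or1_values must be nonempty")
    cc = complete_case(trial, "self_report") if include_complete_case else None
    scenarios = []
    for or1 in or1_values:
        params = SensitivityParams(or1=or1)
        imputed = {}
        for arm in trial.arms:
            s1 = impute_stage1(arm, or1)
            s2 = impute_stage2(arm, s1, params)
            imputed[arm.arm_label] = ImputedArm(arm, params, s1, s2)
            logger.debug(
                "self_report OR1=%s %s: n21=%.4f n22=%.4f pi=%.6f",
                _fmt_or(or1), arm.arm_label, s1.n21, s1.n22, s1.pi,
            )
        scenarios.append((params, contrast_imputed(trial, imputed, "self_report")))
    return GridReport(
        outcome="self_report",
        scenarios=tuple(scenarios),
        includes_complete_case=include_complete_case,
        complete_case_results=cc,
    )


def run_verified_grid(
    trial: TrialCounts,
    or1_values: Sequence[float] = DEFAULT_OR_VALUES,
    or2_values: Sequence[float] = DEFAULT_OR_VALUES,
    lam: float = 1.0,
    eta: float = 1.0,
    include_complete_case: bool = True,
) -> GridReport:
    """Sweep OR1 (outer) x OR2 (inner) for the urine-verified outcome."""
    _check(trial)
    if not or1_values or not or2_values:
        raise ValueError("or1_values and or2_values must be nonempty")
    cc = complete_case(trial, "urine_verified") if include_complete_case else None
    scenarios = []
    for or1 in or1_values:
        for or2 in or2_values:
            params = SensitivityParams(or1=or1, or2=or2, lam=lam, eta=eta)
            imputed = {a.arm_label: impute_arm(a, params) for a in trial.arms}
            for label, ia in imputed.items():
                logger.debug(
                    "verified OR1=%s OR2=%s %s: f11.=%.4f f21=%.4f verified=%.4f",
                    _fmt_or(or1), _fmt_or(or2), label,
                    ia.stage2.f11_dot, ia.stage2.f21, ia.verified_abstinent_total,
                )
            scenarios.append(
                (params, contrast_imputed(trial, imputed, "urine_verified"))
            )
    return GridReport(
        outcome="urine_verified",
        scenarios=tuple(scenarios),
        includes_complete_case=include_complete_case,
        complete_case_results=cc,
    )
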
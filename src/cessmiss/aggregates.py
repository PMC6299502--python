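"""Aggregated per-arm abstinence counts: data model, validation, fixtures.

The whole analysis runs on aggregated counts, one row per treatment arm:
the survey-stage triplet (self-reported abstinent / self-reported failure /
survey missing) and, among self-reported abstainers, the urine-stage
triplet (verified abstinent / verified failure / urine missing).  Two
accounting identities tie the table together:

    sr_abstinent + sr_failure + survey_missing == n_total
    urine_abstinent + urine_failure + urine_missing == sr_abstinent

Urine cells may be fractional: inadequate samples redistributed in
proportion to the tested ones, and all imputed quantities downstream, are
kept as reals.  Identities are checked to an absolute tolerance of 1e-9.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ArmCounts",
    "TrialCounts",
    "CountsValidationError",
    "validate_counts",
    "redistribute_untested",
    "enhanced_quit_win_fixture",
    "read_counts_csv",
    "write_counts_csv",
    "COUNTS_CSV_HEADER",
]

_TOL = 1e-9

COUNTS_CSV_HEADER = (
    "arm",
    "n_total",
    "sr_abstinent",
    "sr_failure",
    "survey_missing",
    "urine_abstinent",
    "urine_failure",
    "urine_missing",
)


class CountsValidationError(ValueError):
    """Aggregated counts violate an accounting identity."""


@dataclass(frozen=True)
class ArmCounts:
    """Observed aggregated counts for one treatment arm."""

    arm_label: str
    n_total: int
    sr_abstinent: int
    sr_failure: int
    survey_missing: int
    urine_abstinent: float
    urine_failure: float
    urine_missing: float

    @property
    def survey_respondents(self) -> int:
        """Number of survey completers (observed self-report outcomes)."""
        return self.sr_abstinent + self.sr_failure

    @property
    def urine_provided(self) -> float:
        """Urine samples with a result among self-reported abstainers."""
        return self.urine_abstinent + self.urine_failure

    def violations(self) -> list[str]:
        out: list[str] = []
        lab = self.arm_label
        for name in (
            "n_total",
            "sr_abstinent",
            "sr_failure",
            "survey_missing",
            "urine_abstinent",
            "urine_failure",
            "urine_missing",
        ):
            if getattr(self, name) < 0:
                out.append(f"{lab}: {name} is negative ({getattr(self, name)!r})")
        sr_sum = self.sr_abstinent + self.sr_failure + self.survey_missing
        if abs(sr_sum - self.n_total) > _TOL:
            out.append(
                f"{lab}: sr_abstinent + sr_failure + survey_missing = {sr_sum} "
                f"!= n_total = {self.n_total}"
            )
        ur_sum = self.urine_abstinent + self.urine_failure + self.urine_missing
        if abs(ur_sum - self.sr_abstinent) > _TOL:
            out.append(
                f"{lab}: urine_abstinent + urine_failure + urine_missing = {ur_sum} "
                f"!= sr_abstinent = {self.sr_abstinent}"
            )
        return out


@dataclass(frozen=True)
class TrialCounts:
    """An ordered collection of arms plus named pooled contrasts.

    ``contrasts`` maps a contrast name to an ``(exposed, control)`` pair of
    disjoint, nonempty tuples of arm labels, e.g. counseling vs no
    counseling pooling the two counseling arms against the two others.
    """

    arms: tuple[ArmCounts, ...]
    contrasts: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=dict
    )

    def arm(self, label: str) -> ArmCounts:
        for a in self.arms:
            if a.arm_label == label:
                return a
        raise KeyError(f"unknown arm label {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.arm_label for a in self.arms)


def validate_counts(trial: TrialCounts) -> list[str]:
    """Return a description of every violated invariant (empty list = valid).

    Checks per-arm accounting identities and nonnegativity, label
    uniqueness, and that every contrast names existing arms in two
    disjoint nonempty pools.  Reporting only; loaders raise
    :class:`CountsValidationError` when the result is non-empty.
    """
    out: list[str] = []
    for a in trial.arms:
        out.extend(a.violations())
    labels = trial.labels
    if len(set(labels)) != len(labels):
        out.append(f"duplicate arm labels: {labels}")
    known = set(labels)
    for name, (exposed, control) in trial.contrasts.items():
        if not exposed or not control:
            out.append(f"contrast {name!r}: both pools must be nonempty")
        unknown = (set(exposed) | set(control)) - known
        if unknown:
            out.append(f"contrast {name!r}: unknown arm labels {sorted(unknown)}")
        overlap = set(exposed) & set(control)
        if overlap:
            out.append(f"contrast {name!r}: pools overlap on {sorted(overlap)}")
    return out


def redistribute_untested(
    abst_tested: float, fail_tested: float, n_untested: float
) -> tuple[float, float]:
    """Redistribute urine samples that were provided but could not be tested.

    The untested samples are assumed to follow the same verified
    abstinent/failure distribution as the tested ones, so the additions are
    ``n_untested * abst_tested / (abst_tested + fail_tested)`` and the
    complement.  The results (generally fractional) are added to the
    verified-abstinent and verified-failure cells and the untested pool is
    emptied before any imputation.
    """
    if n_untested < 0:
        raise ValueError(f"n_untested must be >= 0, got {n_untested!r}")
    if n_untested == 0:
        return 0.0, 0.0
    tested = abst_tested + fail_tested
    if tested <= 0:
        raise ValueError(
            "cannot redistribute untested samples: no tested samples to "
            "estimate the verified-abstinence proportion from"
        )
    abst_add = n_untested * abst_tested / tested
    return abst_add, n_untested - abst_add


#: Factorial contrasts of the Enhanced Quit & Win trial: counseling
#: (Tx2+Tx4 vs Tx1+Tx3) and multiple vs single contests (Tx3+Tx4 vs Tx1+Tx2).
QUIT_WIN_CONTRASTS: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "counseling": (("Tx2", "Tx4"), ("Tx1", "Tx3")),
    "contests": (("Tx3", "Tx4"), ("Tx1", "Tx2")),
}


def enhanced_quit_win_fixture() -> TrialCounts:
    """Six-month aggregated counts of the Enhanced Quit & Win trial.

    Four arms of a 2x2 factorial design (single/multiple Quit & Win
    contests crossed with counseling / no counseling), 1217 college
    smokers.  Urine cells are the published per-arm values after the five
    inadequate urine samples were redistributed in proportion to the 177
    tested ones, as printed (integers).
    """
    rows = [
        # label,  n, sr_abst, sr_fail, survey_miss, ur_abst, ur_fail, ur_miss
        ("Tx1", 306, 65, 194, 47, 38.0, 6.0, 21.0),
        ("Tx2", 296, 59, 170, 67, 34.0, 6.0, 19.0),
        ("Tx3", 309, 61, 197, 51, 35.0, 6.0, 20.0),
        ("Tx4", 306, 79, 156, 71, 50.0, 7.0, 22.0),
    ]
    trial = TrialCounts(
        arms=tuple(ArmCounts(*row) for row in rows),
        contrasts=dict(QUIT_WIN_CONTRASTS),
    )
    problems = validate_counts(trial)
    assert not problems, problems
    return trial


def read_counts_csv(
    path,
    contrasts: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
) -> TrialCounts:
    """Read per-arm aggregated counts from CSV (header ``arm,n_total,...``)."""
    arms = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(COUNTS_CSV_HEADER) - set(reader.fieldnames or ())
        if missing:
            raise CountsValidationError(
                f"counts CSV {path} is missing columns: {sorted(missing)}"
            )
        for row in reader:
            arms.append(
                ArmCounts(
                    arm_label=row["arm"],
                    n_total=int(row["n_total"]),
                    sr_abstinent=int(row["sr_abstinent"]),
                    sr_failure=int(row["sr_failure"]),
                    survey_missing=int(row["survey_missing"]),
                    urine_abstinent=float(row["urine_abstinent"]),
                    urine_failure=float(row["urine_failure"]),
                    urine_missing=float(row["urine_missing"]),
                )
            )
    trial = TrialCounts(arms=tuple(arms), contrasts=dict(contrasts or {}))
    problems = validate_counts(trial)
    if problems:
        raise CountsValidationError("; ".join(problems))
    return trial


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_counts_csv(trial: TrialCounts, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COUNTS_CSV_HEADER)
        for a in trial.arms:
            writer.writerow(
                [
                    a.arm_label,
                    a.n_total,
                    a.sr_abstinent,
                    a.sr_failure,
                    a.survey_missing,
                    _fmt(a.urine_abstinent),
                    _fmt(a.urine_failure),
                    _fmt(a.urine_missing),
                ]
            )
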
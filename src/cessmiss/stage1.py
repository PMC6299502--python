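"""Stage 1: impute self-report outcomes for survey non-respondents.

A single sensitivity parameter OR1 indexes the assumed association between
survey missingness and tobacco use.  Writing Odds = n12/n11 for the
observed odds of tobacco use among respondents, the survey-missing pool
n2. is allocated as

    pi  = OR1 * Odds / (1 + OR1 * Odds)
    n22 = pi * n2.          (imputed failures)
    n21 = n2. - n22         (imputed abstainers)

OR1 = 1 reproduces the complete-case (MAR) abstinence rate exactly;
OR1 = +inf is the classical "missing = smoking" imputation (pi = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._alloc import ImputationError, allocation_fraction, odds_allocate
from .aggregates import ArmCounts

__all__ = ["SensitivityParams", "Stage1Result", "impute_stage1"]


@dataclass(frozen=True)
class SensitivityParams:
    """One missingness scenario: (OR1, OR2, lambda, eta).

    OR1, OR2 are positive odds ratios (math.inf allowed) linking
    missingness to failure at the survey and urine stages.  ``lam`` scales
    the provided:missing urine odds for survey non-respondents relative to
    respondents; ``eta`` scales the verified-abstinent:verified-failure
    odds of would-be urine samples relative to observed ones.
    """

    or1: float
    or2: float = 1.0
    lam: float = 1.0
    eta: float = 1.0

    def __post_init__(self) -> None:
        if not self.or1 > 0:
            raise ValueError(f"or1 must be > 0, got {self.or1!r}")
        if not self.or2 > 0:
            raise ValueError(f"or2 must be > 0, got {self.or2!r}")
        if not (self.lam > 0 and math.isfinite(self.lam)):
            raise ValueError(f"lam must be a positive finite real, got {self.lam!r}")
        if not (self.eta > 0 and math.isfinite(self.eta)):
            raise ValueError(f"eta must be a positive finite real, got {self.eta!r}")


@dataclass(frozen=True)
class Stage1Result:
    """Imputed survey-stage quantities for one arm under one OR1."""

    n21: float  # imputed self-report abstinent among non-respondents
    n22: float  # imputed self-report failures among non-respondents
    pi: float  # allocation fraction sending non-respondents to failure
    sr_abstinent_total: float  # n.1 = n11 + n21
    sr_failure_total: float  # n.2 = n12 + n22


def impute_stage1(arm: ArmCounts, or1: float) -> Stage1Result:
    """Allocate an arm's survey non-respondents under an assumed OR1.

    Degenerate observed cells: n11 = 0 (no observed abstainers) forces
    pi = 1 for any OR1; n12 = 0 (no observed failures) forces pi = 0 even
    under OR1 = +inf, favouring the observed odds of zero.  Both observed
    cells zero with a nonempty missing pool raises
    :class:`~cessmiss._alloc.ImputationError`.
    """
    if not or1 > 0:
        raise ImputationError(f"OR1 must be > 0, got {or1!r}")
    n11, n12 = float(arm.sr_abstinent), float(arm.sr_failure)
    n2dot = float(arm.survey_missing)
    # n22 is the cell proportional to the observed failure odds n12/n11.
    n22, n21 = odds_allocate(n2dot, n12, n11, or1)
    pi = allocation_fraction(n12, n11, or1)
    return Stage1Result(
        n21=n21,
        n22=n22,
        pi=pi,
        sr_abstinent_total=n11 + n21,
        sr_failure_total=n12 + n22,
    )
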
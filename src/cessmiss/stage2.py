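"""Stage 2: impute urine-verification outcomes on top of stage-1 results.

Three steps, applied in a fixed order within each arm:

1. lambda-split: the stage-1 imputed abstainers n21 are divided into
   would-be urine providers u_imp and non-providers v_imp so that
   u_imp/v_imp = lambda * u_obs/v_obs.
2. eta-split: the would-be samples u_imp are divided into verified
   abstinent f11_imp and verified failure f12_imp so that
   f11_imp/f12_imp = eta * f11_obs/f12_obs.
3. OR2 allocation: the combined missing-urine pool
   v = v_obs + v_imp is allocated with Odds' = f12./f11. (the verified
   failure odds among all available samples, observed plus imputed):
   pi' = OR2*Odds'/(1 + OR2*Odds'), f22 = v*pi', f21 = v - f22.

The arm's verified-abstinent total is f11. + f21; everyone else counts as
failure for the arm-level rate, so the denominator is the full n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._alloc import ImputationError, allocation_fraction, odds_allocate
from .aggregates import ArmCounts
from .stage1 import SensitivityParams, Stage1Result, impute_stage1

__all__ = [
    "Stage2Result",
    "ImputedArm",
    "split_urine_availability",
    "split_imputed_urine_outcomes",
    "allocate_missing_urine",
    "impute_stage2",
    "impute_arm",
]


@dataclass(frozen=True)
class Stage2Result:
    """All imputed urine-stage quantities for one arm under one scenario."""

    u_obs: float  # observed urine samples with a result, f11_obs + f12_obs
    v_obs: float  # observed missing urine among self-reported abstainers
    u_imp: float  # would-be urine samples among imputed abstainers
    v_imp: float  # would-be missing urine among imputed abstainers
    f11_imp: float  # verified abstinent among would-be samples
    f12_imp: float  # verified failure among would-be samples
    f11_dot: float  # f11_obs + f11_imp
    f12_dot: float  # f12_obs + f12_imp
    v_total: float  # v_obs + v_imp, the pool allocated under OR2
    f21: float  # verified abstinent among the missing-urine pool
    f22: float  # verified failure among the missing-urine pool
    pi_prime: float  # allocation fraction sending the pool to failure
    verified_abstinent_total: float  # f11_dot + f21
    verified_failure_total: float  # n - verified_abstinent_total


def split_urine_availability(
    stage1: Stage1Result, arm: ArmCounts, lam: float
) -> tuple[float, float]:
    """Divide the imputed abstainers n21 into urine providers/non-providers.

    ``u_imp/v_imp = lam * u_obs/v_obs`` with ``u_imp + v_imp = n21``.
    ``v_obs = 0`` sends everyone to the provider side; both observed cells
    zero with n21 > 0 is an error.
    """
    if not (lam > 0 and math.isfinite(lam)):
        raise ImputationError(f"lambda must be a positive finite real, got {lam!r}")
    u_obs = float(arm.urine_provided)
    v_obs = float(arm.urine_missing)
    return odds_allocate(stage1.n21, u_obs, v_obs, lam)


def split_imputed_urine_outcomes(
    u_imp: float, f11_obs: float, f12_obs: float, eta: float
) -> tuple[float, float]:
    """Divide the would-be samples u_imp into verified abstinent/failure.

    ``f11_imp/f12_imp = eta * f11_obs/f12_obs`` with
    ``f11_imp + f12_imp = u_imp``; ``f12_obs = 0`` sends all of u_imp to
    the abstinent side.
    """
    if not (eta > 0 and math.isfinite(eta)):
        raise ImputationError(f"eta must be a positive finite real, got {eta!r}")
    return odds_allocate(u_imp, float(f11_obs), float(f12_obs), eta)


def allocate_missing_urine(
    f11_dot: float, f12_dot: float, v_total: float, or2: float
) -> tuple[float, float, float]:
    """Allocate the combined missing-urine pool under an assumed OR2.

    Returns ``(f21, f22, pi_prime)`` with ``f22 = v_total * pi_prime``.
    OR2 = +inf is the naive treatment-failure allocation (f21 = 0) except
    when f12_dot = 0, where the observed zero failure odds win (f22 = 0).
    """
    if not or2 > 0:
        raise ImputationError(f"OR2 must be > 0, got {or2!r}")
    f22, f21 = odds_allocate(v_total, float(f12_dot), float(f11_dot), or2)
    pi_prime = allocation_fraction(float(f12_dot), float(f11_dot), or2)
    return f21, f22, pi_prime


def impute_stage2(
    arm: ArmCounts, stage1: Stage1Result, params: SensitivityParams
) -> Stage2Result:
    """Compose the lambda-split, eta-split and OR2 allocation for one arm."""
    u_imp, v_imp = split_urine_availability(stage1, arm, params.lam)
    f11_imp, f12_imp = split_imputed_urine_outcomes(
        u_imp, arm.urine_abstinent, arm.urine_failure, params.eta
    )
    f11_dot = arm.urine_abstinent + f11_imp
    f12_dot = arm.urine_failure + f12_imp
    v_total = arm.urine_missing + v_imp
    f21, f22, pi_prime = allocate_missing_urine(f11_dot, f12_dot, v_total, params.or2)
    verified = f11_dot + f21
    return Stage2Result(
        u_obs=float(arm.urine_provided),
        v_obs=float(arm.urine_missing),
        u_imp=u_imp,
        v_imp=v_imp,
        f11_imp=f11_imp,
        f12_imp=f12_imp,
        f11_dot=f11_dot,
        f12_dot=f12_dot,
        v_total=v_total,
        f21=f21,
        f22=f22,
        pi_prime=pi_prime,
        verified_abstinent_total=verified,
        verified_failure_total=arm.n_total - verified,
    )


@dataclass(frozen=True)
class ImputedArm:
    """One arm fully imputed under one sensitivity scenario."""

    arm: ArmCounts
    params: SensitivityParams
    stage1: Stage1Result
    stage2: Stage2Result

    @property
    def sr_abstinent_total(self) -> float:
        return self.stage1.sr_abstinent_total

    @property
    def verified_abstinent_total(self) -> float:
        return self.stage2.verified_abstinent_total


def impute_arm(arm: ArmCounts, params: SensitivityParams) -> ImputedArm:
    """Run both imputation stages for one arm under one scenario."""
    s1 = impute_stage1(arm, params.or1)
    s2 = impute_stage2(arm, s1, params)
    return ImputedArm(arm=arm, params=params, stage1=s1, stage2=s2)
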
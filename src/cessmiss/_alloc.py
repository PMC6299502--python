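"""Shared odds-based allocation of a missing pool into two cells.

Every imputation step in the two-stage procedure has the same shape: a
pool of ``total`` unobserved subjects is split into two cells so that the
ratio of the two imputed cells equals ``factor`` times the observed odds
``odds_num / odds_den``.  The closed form is

    share_num = total * factor * odds_num / (factor * odds_num + odds_den)

Degenerate observed cells are resolved with a fixed precedence that keeps
the allocation continuous in ``factor`` for fixed observed data:

1. ``odds_num == odds_den == 0`` with a nonempty pool: error — there is
   nothing observed to anchor the split.
2. ``odds_num == 0``: the numerator cell gets nothing, even when
   ``factor`` is infinite (the observed odds of zero win the 0*inf
   indeterminacy).
3. ``odds_den == 0`` or ``factor == +inf``: the numerator cell gets the
   whole pool.
"""

from __future__ import annotations

import math


class ImputationError(ValueError):
    """Observed cells cannot anchor the requested imputation."""


def odds_allocate(
    total: float, odds_num: float, odds_den: float, factor: float
) -> tuple[float, float]:
    """Split ``total`` into ``(share_num, share_den)``.

    ``share_num / share_den = factor * odds_num / odds_den`` and
    ``share_num + share_den = total``.
    """
    if total < 0:
        raise ImputationError(f"negative pool size {total!r}")
    if odds_num == 0.0 and odds_den == 0.0:
        if total > 0:
            raise ImputationError(
                "both observed cells are zero with a nonempty pool "
                f"({total!r}); the allocation odds are undefined"
            )
        return 0.0, 0.0
    frac = allocation_fraction(odds_num, odds_den, factor)
    share_num = total * frac
    return share_num, total - share_num


def allocation_fraction(odds_num: float, odds_den: float, factor: float) -> float:
    """The multiplicative factor (pi in stage 1, pi' in stage 2) sending a
    missing pool to the ``odds_num`` side cell.

    Returns 0.0 when both observed cells are zero (nothing to allocate,
    callers guarantee the pool is empty in that case).
    """
    if factor <= 0:
        raise ImputationError(f"odds-ratio factor must be > 0, got {factor!r}")
    if odds_num == 0.0 and odds_den == 0.0:
        return 0.0
    if odds_num == 0.0:
        return 0.0
    if odds_den == 0.0 or math.isinf(factor):
        return 1.0
    odds = odds_num / odds_den
    return factor * odds / (1.0 + factor * odds)
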
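"""Arm-contrast log odds ratios and their variances.

Three constructors, all returning :class:`~maiclab.trial_data.EffectEstimate`:

* :func:`log_or_from_counts` — the Woolf estimator on a 2x2 table, with a
  0.5 continuity correction applied to all cells only when a zero cell
  is present;
* :func:`weighted_log_or` — the treatment coefficient of a weighted
  binomial-logit model containing only the treatment indicator (no
  covariate adjustment of the reweighted outcome), with a robust
  Huber–White sandwich standard error in which each participant is one
  independent unit and the weights enter the score linearly;
* :func:`effect_from_or_ci` — back-conversion of a published odds ratio
  and confidence interval to a log OR and standard error.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import EstimationError, SeparationError, ValidationError
from .maic_core import effective_sample_size
from .trial_data import ARM_ACTIVE, ARM_CONTROL, EffectEstimate


def _as_cells(table) -> tuple[float, float, float, float]:
    arr = np.asarray(table, dtype=float).reshape(-1)
    if arr.size != 4 or np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValidationError("2x2 table must be 4 non-negative finite numbers")
    return tuple(arr)  # a, b, c, d


def log_or_from_counts(table, correction: float = 0.5) -> EffectEstimate:
    """Woolf log odds ratio and SE from (a, b, c, d) cell counts.

    Cells are ordered (active events, active non-events, control events,
    control non-events).  When any cell is zero, ``correction`` is added
    to all four cells before computing ln(ad/bc) and
    sqrt(1/a + 1/b + 1/c + 1/d).
    """
    a, b, c, d = _as_cells(table)
    if correction < 0:
        raise ValidationError("correction must be >= 0")
    if a + b <= 0 or c + d <= 0:
        raise EstimationError("undefined contrast: a row (arm) total is zero")
    if min(a, b, c, d) == 0:
        if correction == 0:
            raise EstimationError("zero cell with no continuity correction")
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(log_or=log_or, se=se, method="woolf")


def weighted_log_or(
    arm: Sequence[str],
    outcome: Sequence[float],
    weights: Sequence[float],
    df_correction: bool = False,
) -> EffectEstimate:
    """Weighted treatment-only logit contrast with sandwich standard error.

    The point estimate is the treatment coefficient of the weighted
    logistic fit ``logit P(y=1) = alpha + beta * T`` — equivalently the
    difference of weighted-proportion logits between arms, since the
    model is saturated in the treatment indicator.  The variance is the
    sandwich A^{-1} B A^{-1} with A the weighted expected information and
    B the sum of squared weighted score contributions.

    ``n_effective`` records the effective sample size of the supplied
    weights.  Set ``df_correction=True`` for the finite-sample factor
    n / (n - 2).
    """
    arm = np.asarray(arm)
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(arm) == len(y) == len(w)):
        raise ValidationError("arm, outcome and weights must have equal length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be positive and finite")
    keep = ~np.isnan(y)
    arm, y, w = arm[keep], y[keep], w[keep]
    if not np.isin(arm, (ARM_ACTIVE, ARM_CONTROL)).all():
        raise ValidationError(f"arm values must be '{ARM_ACTIVE}' or '{ARM_CONTROL}'")
    t = (arm == ARM_ACTIVE).astype(float)
    if t.sum() == 0 or (1 - t).sum() == 0:
        raise EstimationError("both arms must be represented")

    # weighted event proportions per arm = MLE of the saturated logit model
    p1 = float(w[t == 1] @ y[t == 1] / w[t == 1].sum())
    p0 = float(w[t == 0] @ y[t == 0] / w[t == 0].sum())
    for arm_name, p in ((ARM_ACTIVE, p1), (ARM_CONTROL, p0)):
        if not (0.0 < p < 1.0):
            raise SeparationError(
                f"weighted event proportion in the {arm_name} arm is {p:g}; "
                "the log-odds contrast is undefined"
            )
    beta = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))

    # sandwich on the two-parameter score sum_i w_i (y_i - p_i) (1, t_i)
    p = np.where(t == 1, p1, p0)
    v = p * (1 - p)
    x = np.column_stack([np.ones_like(t), t])
    A = (x * (w * v)[:, None]).T @ x
    r2 = (w * (y - p)) ** 2
    B = (x * r2[:, None]).T @ x
    Ainv = np.linalg.inv(A)
    V = Ainv @ B @ Ainv
    var_beta = float(V[1, 1])
    n = len(y)
    if df_correction:
        var_beta *= n / (n - 2)
    return EffectEstimate(
        log_or=beta,
        se=math.sqrt(var_beta),
        method="weighted_sandwich",
        n_effective=effective_sample_size(w),
    )


def effect_from_or_ci(
    odds_ratio: float, lcl: float, ucl: float, level: float = 0.95
) -> EffectEstimate:
    """Recover log OR and SE from a published OR with its confidence interval.

    Uses the exact normal quantile at (1 + level)/2 so the CI round-trips
    tightly: se = (ln ucl - ln lcl) / (2 z).
    """
    if not (0.0 < level < 1.0):
        raise ValidationError(f"level must be in (0, 1), got {level!r}")
    if min(odds_ratio, lcl, ucl) <= 0:
        raise ValidationError("odds ratio and CI limits must be positive")
    if not (lcl < odds_ratio < ucl):
        raise ValidationError(
            f"require lcl < OR < ucl, got ({lcl!r}, {odds_ratio!r}, {ucl!r})"
        )
    z = norm.ppf(0.5 + level / 2.0)
    se = (math.log(ucl) - math.log(lcl)) / (2.0 * z)
    return EffectEstimate(log_or=math.log(odds_ratio), se=se, method="from_ci")
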
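"""Anchored indirect comparisons through a common control arm.

The evidence network is a two-edge star: the index treatment and the
comparator treatment each have placebo-anchored randomised evidence, but
no head-to-head trial.  The anchored (Bucher) contrast is

    d_AB = d_A,anchor - d_B,anchor,      var(d_AB) = var(d_A) + var(d_B),

on the log-odds-ratio scale.  The index-vs-anchor edge can be formed by
fixed-effect inverse-variance pooling of per-trial Woolf estimates, by
Mantel–Haenszel pooling of the per-trial 2x2 tables (preferred when
events are rare), or — for the population-adjusted analysis — by a
weighted treatment-only logit on the reweighted pooled IPD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .effect_models import log_or_from_counts, weighted_log_or
from .errors import ConfigurationError, EstimationError, ValidationError
from .maic_core import fit_weights
from .trial_data import (
    AggregateTarget,
    ComparatorEffect,
    EffectEstimate,
    IPDTable,
    ModifierSet,
)

UNADJUSTED = "unadjusted"


@dataclass(frozen=True)
class ITCResult:
    """One indirect-comparison estimate: OR with CI, z and p.

    ``method`` is one of ``bucher_iv``, ``bucher_mh`` or ``bucher_maic``;
    ``modifier_set`` names the balanced covariate set (or ``"unadjusted"``).
    ``ess_index`` carries the effective sample size of the reweighted
    index IPD when the estimate is population-adjusted.
    """

    or_: float
    ci_low: float
    ci_high: float
    z_stat: float
    p_value: float
    method: str
    modifier_set: str
    anchored: bool
    level: float
    log_or: float
    se: float
    ess_index: float | None = None

    def __post_init__(self):
        if not (self.ci_low < self.or_ < self.ci_high):
            raise ValidationError(
                f"CI must bracket the OR: {self.ci_low} < {self.or_} < {self.ci_high}"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0,1]: {self.p_value}")


def _itc_from_contrast(
    log_or: float,
    se: float,
    method: str,
    modifier_set: str,
    level: float,
    anchored: bool = True,
    ess_index: float | None = None,
) -> ITCResult:
    z_crit = norm.ppf(0.5 + level / 2.0)
    z = log_or / se
    p = 2.0 * norm.sf(abs(z))
    return ITCResult(
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - z_crit * se),
        ci_high=math.exp(log_or + z_crit * se),
        z_stat=z,
        p_value=float(p),
        method=method,
        modifier_set=modifier_set,
        anchored=anchored,
        level=level,
        log_or=log_or,
        se=se,
        ess_index=ess_index,
    )


def pool_inverse_variance(estimates: Sequence[EffectEstimate]) -> EffectEstimate:
    """Fixed-effect inverse-variance pooling of log odds ratios.

    Pooled d = sum(d_k / v_k) / sum(1 / v_k) with v_k = se_k^2, pooled
    se = sqrt(1 / sum(1/v_k)).
    """
    if not estimates:
        raise ValidationError("cannot pool an empty list of estimates")
    d = np.array([e.log_or for e in estimates])
    v = np.array([e.se**2 for e in estimates])
    inv = 1.0 / v
    pooled = float(d @ inv / inv.sum())
    se = float(math.sqrt(1.0 / inv.sum()))
    return EffectEstimate(log_or=pooled, se=se, method="iv_pooled")


def bucher_contrast(
    d_index_vs_anchor: EffectEstimate,
    d_comparator_vs_anchor: EffectEstimate,
    level: float = 0.95,
    method: str = "bucher_iv",
    modifier_set: str = UNADJUSTED,
    ess_index: float | None = None,
) -> ITCResult:
    """Anchored contrast of two against-anchor estimates sharing the anchor.

    Subtracts the comparator edge from the index edge and sums the
    variances; both inputs must be estimated against the same anchor
    (the caller's responsibility, recorded in labels upstream).
    """
    log_or = d_index_vs_anchor.log_or - d_comparator_vs_anchor.log_or
    se = math.sqrt(d_index_vs_anchor.se**2 + d_comparator_vs_anchor.se**2)
    if ess_index is None:
        ess_index = d_index_vs_anchor.n_effective
    return _itc_from_contrast(
        log_or, se, method=method, modifier_set=modifier_set, level=level,
        anchored=True, ess_index=ess_index,
    )


def mantel_haenszel_pool(tables: Sequence, level: float = 0.95) -> EffectEstimate:
    """Mantel–Haenszel pooled odds ratio over 2x2 strata.

    OR_MH = sum_k(a_k d_k / n_k) / sum_k(b_k c_k / n_k); the variance of
    ln OR_MH uses the Robins–Breslow–Greenland formula.  Zero cells get
    no continuity correction: strata with no events (or no non-events)
    in either arm contribute nothing and are dropped.
    """
    if not tables:
        raise ValidationError("need at least one stratum")
    kept = []
    for tbl in tables:
        arr = np.asarray(tbl, dtype=float).reshape(-1)
        if arr.size != 4 or np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValidationError("each stratum must be 4 non-negative finite counts")
        a, b, c, d = arr
        if a + b <= 0 or c + d <= 0:
            raise EstimationError("undefined contrast: a stratum has an empty arm")
        if (a == 0 and c == 0) or (b == 0 and d == 0):
            continue  # double-zero stratum: no information about the OR
        kept.append((a, b, c, d))
    if not kept:
        raise EstimationError("all strata are double-zero; the MH odds ratio is undefined")

    R = S = 0.0  # sums of a*d/n and b*c/n
    sum_PR = sum_PSQR = sum_QS = 0.0
    for a, b, c, d in kept:
        n = a + b + c + d
        P = (a + d) / n
        Q = (b + c) / n
        Rk = a * d / n
        Sk = b * c / n
        R += Rk
        S += Sk
        sum_PR += P * Rk
        sum_PSQR += P * Sk + Q * Rk
        sum_QS += Q * Sk
    if R == 0.0 or S == 0.0:
        raise EstimationError(
            "MH odds ratio is 0 or infinite (one direction has no discordant pairs)"
        )
    log_or = math.log(R / S)
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    return EffectEstimate(log_or=log_or, se=math.sqrt(var), method="mh_pooled")


def _comparator_estimate(comparator: ComparatorEffect, engine: str) -> EffectEstimate:
    if engine == "mantel_haenszel":
        if comparator.form != "counts":
            raise ConfigurationError(
                f"comparator '{comparator.label}': the Mantel–Haenszel engine "
                "needs arm-level counts, not a log OR with SE"
            )
        return mantel_haenszel_pool([comparator.counts])
    if comparator.form == "counts":
        return log_or_from_counts(comparator.counts)
    return EffectEstimate(log_or=comparator.log_or, se=comparator.se, method="from_ci")


def run_unadjusted_itc(
    index_tables: Sequence,
    comparator: ComparatorEffect,
    engine: str = "inverse_variance",
    level: float = 0.95,
) -> ITCResult:
    """Unadjusted anchored ITC from per-trial index 2x2 tables.

    ``engine="inverse_variance"`` pools per-trial Woolf estimates by
    fixed-effect inverse variance; ``engine="mantel_haenszel"`` pools the
    raw tables by Mantel–Haenszel (and requires the comparator in counts
    form, pooled the same way as a single stratum).  Either way the final
    step is the Bucher contrast against the comparator's own
    against-anchor estimate.
    """
    if engine not in ("inverse_variance", "mantel_haenszel"):
        raise ConfigurationError(f"unknown engine {engine!r}")
    if not index_tables:
        raise ValidationError("need at least one index-trial table")
    d_cmp = _comparator_estimate(comparator, engine)
    if engine == "inverse_variance":
        d_index = pool_inverse_variance([log_or_from_counts(t) for t in index_tables])
        method = "bucher_iv"
    else:
        d_index = mantel_haenszel_pool(index_tables)
        method = "bucher_mh"
    return bucher_contrast(
        d_index, d_cmp, level=level, method=method, modifier_set=UNADJUSTED
    )


def run_adjusted_itc(
    ipd: IPDTable,
    mset: ModifierSet,
    target: AggregateTarget,
    outcome: str,
    comparator: ComparatorEffect,
    level: float = 0.95,
    anchored: bool = True,
) -> ITCResult:
    """Population-adjusted anchored ITC on the pooled index IPD.

    Pipeline: estimate moment-matching weights for the modifier set,
    compute the weighted treatment-only log OR with sandwich SE on the
    pooled index trials, then form the Bucher contrast against the
    comparator evidence.  The returned result carries the effective
    sample size of the reweighted IPD.

    With ``anchored=False`` the contrast instead compares the weighted
    active-arm log-odds directly against the comparator's active-arm
    log-odds (no anchoring through the control arms); this discards the
    randomisation anchor and is provided for sensitivity analyses only.
    """
    if outcome not in ipd.outcome_names:
        raise ValidationError(f"outcome '{outcome}' not present in IPD")
    sol = fit_weights(ipd, mset, target)
    observed = ipd.data[outcome].notna().to_numpy()
    arm = ipd.data["arm"].to_numpy()[observed]
    y = ipd.data[outcome].to_numpy(dtype=float)[observed]
    w = sol.weights[observed]

    if anchored:
        d_index = weighted_log_or(arm, y, w)
        d_cmp = _comparator_estimate(comparator, "inverse_variance")
        return bucher_contrast(
            d_index, d_cmp, level=level, method="bucher_maic",
            modifier_set=mset.name, ess_index=sol.ess,
        )

    # unanchored sensitivity path: active arms only
    if comparator.form != "counts":
        raise ConfigurationError(
            "unanchored comparison needs the comparator's active-arm counts"
        )
    act = arm == "active"
    p = float(w[act] @ y[act] / w[act].sum())
    if not (0.0 < p < 1.0):
        raise EstimationError("weighted active-arm proportion is degenerate")
    # SE of the weighted logit via the linearisation  var(logit p) = var(p)/(p(1-p))^2
    wa = w[act] / w[act].sum()
    var_p = float(np.sum((wa * (y[act] - p)) ** 2))
    se_idx = math.sqrt(var_p) / (p * (1 - p))
    a, b, _, _ = comparator.counts
    if a == 0 or b == 0:
        raise EstimationError("comparator active arm has a zero cell")
    log_odds_cmp = math.log(a / b)
    se_cmp = math.sqrt(1 / a + 1 / b)
    return _itc_from_contrast(
        math.log(p / (1 - p)) - log_odds_cmp,
        math.sqrt(se_idx**2 + se_cmp**2),
        method="bucher_maic",
        modifier_set=mset.name,
        level=level,
        anchored=False,
        ess_index=sol.ess,
    )
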
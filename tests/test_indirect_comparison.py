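"""Pooling and anchored contrasts: IV, Bucher, Mantel-Haenszel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maiclab.effect_models import log_or_from_counts, weighted_log_or
from maiclab.errors import ConfigurationError, EstimationError, ValidationError
from maiclab.indirect_comparison import (
    bucher_contrast,
    mantel_haenszel_pool,
    pool_inverse_variance,
    run_adjusted_itc,
    run_unadjusted_itc,
)
from maiclab.synthetic_data import summarize_to_target
from maiclab.trial_data import ComparatorEffect, EffectEstimate, ModifierSet


def rbg_oracle(tables):
    """Independent stratified-2x2 oracle: textbook Mantel-Haenszel point
    estimate with the Robins-Breslow-Greenland variance, written as plain
    per-stratum accumulation (fractions first, no shared code)."""
    num = 0.0
    den = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        num += a * d / n
        den += b * c / n
    or_mh = num / den
    term1 = term2 = term3 = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        p = (a + d) / n
        q = (b + c) / n
        r = a * d / n
        s = b * c / n
        term1 += p * r
        term2 += p * s + q * r
        term3 += q * s
    var = term1 / (2 * num**2) + term2 / (2 * num * den) + term3 / (2 * den**2)
    return math.log(or_mh), math.sqrt(var)


class TestInverseVariancePooling:
    def test_single_estimate_identity(self):
        e = EffectEstimate(0.3, 0.15, "woolf")
        pooled = pool_inverse_variance([e])
        assert pooled.log_or == pytest.approx(0.3)
        assert pooled.se == pytest.approx(0.15)

    def test_equal_se_is_arithmetic_mean(self):
        pooled = pool_inverse_variance(
            [EffectEstimate(0.2, 0.1, "woolf"), EffectEstimate(0.6, 0.1, "woolf")]
        )
        assert pooled.log_or == pytest.approx(0.4)
        assert pooled.se == pytest.approx(0.1 / math.sqrt(2))

    def test_hand_formula(self):
        pooled = pool_inverse_variance(
            [EffectEstimate(0.2, 0.1, "woolf"), EffectEstimate(0.8, 0.3, "woolf")]
        )
        expected = (0.2 / 0.01 + 0.8 / 0.09) / (1 / 0.01 + 1 / 0.09)
        assert pooled.log_or == pytest.approx(expected, abs=1e-12)
        assert pooled.se == pytest.approx(math.sqrt(1 / (1 / 0.01 + 1 / 0.09)), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pool_inverse_variance([])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-2, max_value=2),
                st.floats(min_value=0.05, max_value=1.0),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_pooled_variance_never_exceeds_min_input(self, specs):
        ests = [EffectEstimate(d, s, "woolf") for d, s in specs]
        pooled = pool_inverse_variance(ests)
        assert pooled.se**2 <= min(e.se**2 for e in ests) + 1e-12


class TestBucher:
    def test_direct_formula(self):
        res = bucher_contrast(
            EffectEstimate(0.5, 0.2, "iv_pooled"), EffectEstimate(0.1, 0.2, "from_ci")
        )
        assert res.log_or == pytest.approx(0.4)
        assert res.se == pytest.approx(math.sqrt(0.08), abs=1e-12)
        assert res.or_ == pytest.approx(math.exp(0.4), abs=1e-9)
        assert res.anchored

    def test_identical_inputs_null(self):
        e = EffectEstimate(0.6152, 0.285, "from_ci")
        res = bucher_contrast(e, e)
        assert res.or_ == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_p_consistent_with_z(self):
        from scipy.stats import norm

        res = bucher_contrast(
            EffectEstimate(0.9, 0.25, "iv_pooled"), EffectEstimate(0.1, 0.15, "from_ci")
        )
        assert res.p_value == pytest.approx(2 * norm.sf(abs(res.z_stat)), abs=1e-9)
        assert res.ci_low < res.or_ < res.ci_high

    def test_transitivity_sign_flip(self):
        d_ac = EffectEstimate(0.7, 0.2, "iv_pooled")
        d_bc = EffectEstimate(0.2, 0.3, "from_ci")
        ab = bucher_contrast(d_ac, d_bc)
        ba = bucher_contrast(d_bc, d_ac)
        assert ab.log_or == pytest.approx(-ba.log_or, abs=1e-12)
        assert ab.se == pytest.approx(ba.se, abs=1e-12)

    def test_zero_se_inputs_rejected_upstream(self):
        with pytest.raises(ValidationError):
            EffectEstimate(0.6152, 0.0, "from_ci")


class TestMantelHaenszel:
    def test_single_stratum_equals_simple_or(self):
        est = mantel_haenszel_pool([(10, 90, 5, 95)])
        assert math.exp(est.log_or) == pytest.approx(950 / 450, abs=1e-12)

    def test_replicated_strata_invariance(self):
        single = mantel_haenszel_pool([(10, 90, 5, 95)])
        double = mantel_haenszel_pool([(10, 90, 5, 95)] * 2)
        assert double.log_or == pytest.approx(single.log_or, abs=1e-12)

    @pytest.mark.parametrize(
        "tables",
        [
            [(4, 96, 2, 98), (6, 94, 3, 97)],
            [(10, 90, 5, 95), (30, 70, 12, 88)],
            [(3, 197, 9, 191), (1, 99, 4, 96), (12, 188, 7, 193)],
        ],
    )
    def test_matches_independent_rbg_oracle(self, tables):
        est = mantel_haenszel_pool(tables)
        lor, se = rbg_oracle(tables)
        assert est.log_or == pytest.approx(lor, abs=1e-8)
        assert est.se == pytest.approx(se, abs=1e-8)

    def test_single_stratum_rbg_variance_equals_woolf(self):
        # one zero-free stratum: RBG reduces to 1/a + 1/b + 1/c + 1/d
        est = mantel_haenszel_pool([(10, 90, 5, 95)])
        woolf = log_or_from_counts((10, 90, 5, 95))
        assert est.se == pytest.approx(woolf.se, abs=1e-12)

    def test_double_zero_strata_dropped_without_correction(self):
        with_empty = mantel_haenszel_pool([(4, 96, 2, 98), (0, 100, 0, 100)])
        without = mantel_haenszel_pool([(4, 96, 2, 98)])
        assert with_empty.log_or == pytest.approx(without.log_or, abs=1e-12)
        assert with_empty.se == pytest.approx(without.se, abs=1e-12)

    def test_all_double_zero_rejected(self):
        with pytest.raises(EstimationError):
            mantel_haenszel_pool([(0, 100, 0, 100), (0, 50, 0, 50)])

    def test_zero_cells_no_continuity_correction(self):
        # a=0 in one stratum: OR_MH uses the raw cross-products
        est = mantel_haenszel_pool([(0, 100, 2, 98), (5, 95, 5, 95)])
        expected = (5 * 95 / 200) / (100 * 2 / 200 + 95 * 5 / 200)
        assert math.exp(est.log_or) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(*[st.integers(min_value=1, max_value=300)] * 4),
            min_size=1,
            max_size=5,
        )
    )
    def test_pooled_or_within_stratum_or_range(self, tables):
        est = mantel_haenszel_pool(tables)
        ors = [a * d / (b * c) for a, b, c, d in tables]
        assert min(ors) - 1e-9 <= math.exp(est.log_or) <= max(ors) + 1e-9


class TestUnadjustedITC:
    INDEX = [(35, 65, 10, 90), (30, 70, 12, 88)]
    COMPARATOR = ComparatorEffect(label="cmp", counts=(40, 60, 15, 85))

    def test_engines_agree_on_single_stratum(self):
        tables = [(12, 88, 7, 93)]
        iv = run_unadjusted_itc(tables, self.COMPARATOR, engine="inverse_variance")
        mh = run_unadjusted_itc(tables, self.COMPARATOR, engine="mantel_haenszel")
        assert iv.log_or == pytest.approx(mh.log_or, abs=1e-10)
        assert iv.modifier_set == mh.modifier_set == "unadjusted"

    def test_two_trial_network_finite_and_positive(self):
        for engine in ("inverse_variance", "mantel_haenszel"):
            res = run_unadjusted_itc(self.INDEX, self.COMPARATOR, engine=engine)
            assert res.or_ > 1.0
            assert np.isfinite([res.or_, res.ci_low, res.ci_high, res.p_value]).all()

    def test_iv_path_matches_hand_computation(self):
        woolf = [log_or_from_counts(t) for t in self.INDEX]
        pooled = pool_inverse_variance(woolf)
        cmp_est = log_or_from_counts(self.COMPARATOR.counts)
        res = run_unadjusted_itc(self.INDEX, self.COMPARATOR, engine="inverse_variance")
        assert res.log_or == pytest.approx(pooled.log_or - cmp_est.log_or, abs=1e-12)
        assert res.se == pytest.approx(math.hypot(pooled.se, cmp_est.se), abs=1e-12)

    def test_lor_comparator_with_mh_engine_rejected(self):
        lor_cmp = ComparatorEffect(label="cmp", log_or=0.8, se=0.2)
        with pytest.raises(ConfigurationError):
            run_unadjusted_itc(self.INDEX, lor_cmp, engine="mantel_haenszel")

    def test_unknown_engine_rejected(self):
        with pytest.raises(ConfigurationError):
            run_unadjusted_itc(self.INDEX, self.COMPARATOR, engine="bayesian")


class TestAdjustedITC:
    def test_identity_weights_reduction(self, default_bundle):
        # target set to the IPD's own sample moments: weights are unit and
        # the adjusted contrast equals the unweighted sandwich contrast
        ipd = default_bundle["ipd"]
        comparator = default_bundle["comparators"]["abstinence_9_12"]
        own_target, _ = summarize_to_target(ipd, label="self")
        mset = ModifierSet("set1", ("race", "cigarettes_per_day"))
        res = run_adjusted_itc(ipd, mset, own_target, "abstinence_9_12", comparator)
        d_index = weighted_log_or(
            ipd.data["arm"].to_numpy(),
            ipd.data["abstinence_9_12"].to_numpy(dtype=float),
            np.ones(ipd.n),
        )
        d_cmp = log_or_from_counts(comparator.counts)
        assert res.log_or == pytest.approx(d_index.log_or - d_cmp.log_or, abs=1e-8)
        assert res.ess_index == pytest.approx(ipd.n, rel=1e-8)

    def test_result_metadata(self, default_bundle):
        ipd, target = default_bundle["ipd"], default_bundle["target"]
        comparator = default_bundle["comparators"]["nausea"]
        mset = ModifierSet("set1", ("race", "cigarettes_per_day"))
        res = run_adjusted_itc(ipd, mset, target, "nausea", comparator)
        assert res.method == "bucher_maic"
        assert res.modifier_set == "set1"
        assert res.anchored
        assert 0 < res.ess_index < ipd.n

    def test_missing_outcome_rejected(self, default_bundle):
        ipd, target = default_bundle["ipd"], default_bundle["target"]
        mset = ModifierSet("set1", ("race", "cigarettes_per_day"))
        with pytest.raises(ValidationError, match="no_such_outcome"):
            run_adjusted_itc(
                ipd, mset, target, "no_such_outcome",
                default_bundle["comparators"]["nausea"],
            )

    def test_unanchored_sensitivity_path(self, default_bundle):
        ipd, target = default_bundle["ipd"], default_bundle["target"]
        comparator = default_bundle["comparators"]["abstinence_9_12"]
        mset = ModifierSet("set1", ("race", "cigarettes_per_day"))
        res = run_adjusted_itc(
            ipd, mset, target, "abstinence_9_12", comparator, anchored=False
        )
        assert not res.anchored
        assert np.isfinite([res.or_, res.ci_low, res.ci_high]).all()
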
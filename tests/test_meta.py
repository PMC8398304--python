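"""Fixed-effects meta-analysis and heterogeneity: frozen pairs, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from snpmr import GwasAssociation, fixed_effects_meta, heterogeneity, per_allele_estimate


def estimates(pairs):
    return [
        per_allele_estimate(
            GwasAssociation(
                study_label=f"s{i}", variant_id="rs1", effect_allele="T", other_allele="C", beta=b, se=s
            )
        )
        for i, (b, s) in enumerate(pairs)
    ]


def grid_search_combined(betas, weights, tol=1e-8):
    """Independent oracle: minimize the weighted sum of squares by refined grid search."""
    lo, hi = min(betas) - 1e-6, max(betas) + 1e-6
    for _ in range(40):
        grid = np.linspace(lo, hi, 101)
        losses = [(np.array(weights) * (np.array(betas) - m) ** 2).sum() for m in grid]
        best = int(np.argmin(losses))
        lo, hi = grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)]
        if hi - lo < tol:
            break
    return (lo + hi) / 2


class TestFrozenPairs:
    @pytest.mark.parametrize(
        "pairs, or_2dp, lo_2dp, hi_2dp, i2",
        [
            ([(-0.054, 0.025), (-0.063, 0.020)], 0.94, 0.91, 0.97, 0.0),  # MS
            ([(-0.028, 0.016), (-0.048, 0.029)], 0.97, 0.94, 0.99, 0.0),  # AD
            ([(0.048, 0.021), (0.117, 0.020)], 1.09, 1.06, 1.12, None),  # PD (heterogeneous)
        ],
    )
    def test_combined_or_ci_at_2dp(self, pairs, or_2dp, lo_2dp, hi_2dp, i2):
        result = fixed_effects_meta(estimates(pairs), "disease")
        assert round(result.or_point, 2) == or_2dp
        assert round(result.ci_low, 2) == lo_2dp
        assert round(result.ci_high, 2) == hi_2dp
        if i2 is not None:
            assert result.i2_percent == i2

    def test_heterogeneity_p_reported_even_when_i2_floors_at_zero(self):
        ms = fixed_effects_meta(estimates([(-0.054, 0.025), (-0.063, 0.020)]), "MS")
        assert ms.i2_percent == 0.0
        assert 0.0 < ms.p_het < 1.0

    def test_identical_pair_combines_to_se_over_sqrt2(self):
        result = fixed_effects_meta(estimates([(0.1, 0.05), (0.1, 0.05)]), "d")
        assert result.beta_combined == pytest.approx(0.1, rel=1e-12)
        assert result.se_combined == pytest.approx(0.05 / math.sqrt(2), rel=1e-12)
        assert result.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_single_estimate_passes_through(self):
        (only,) = estimates([(-0.028, 0.019)])
        result = fixed_effects_meta([only], "ALS")
        assert result.beta_combined == only.beta
        assert result.se_combined == only.se
        assert result.q_df == 0 and result.i2_percent == 0.0


class TestHeterogeneity:
    def test_hand_computed_q_and_i2(self):
        # w = 100 each, combined 0.5, Q = 100*0.25*2 = 50, I2 = 49/50 = 98%
        ests = estimates([(0.0, 0.1), (1.0, 0.1)])
        beta = fixed_effects_meta(ests, "d").beta_combined
        q, df, p_het, i2 = heterogeneity(ests, beta)
        assert beta == pytest.approx(0.5, rel=1e-12)
        assert q == pytest.approx(50.0, rel=1e-12)
        assert df == 1
        assert i2 == pytest.approx(98.0, rel=1e-12)

    def test_fewer_than_two_estimates_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            q, df, p_het, i2 = heterogeneity(estimates([(0.1, 0.1)]), 0.1)
        assert (q, df, i2) == (0.0, 0, 0.0)

    def test_i2_zero_exactly_when_q_at_most_df(self):
        near = estimates([(0.100, 0.1), (0.101, 0.1)])
        beta = fixed_effects_meta(near, "d").beta_combined
        q, df, _, i2 = heterogeneity(near, beta)
        assert q <= df and i2 == 0.0
        far = estimates([(0.0, 0.1), (0.5, 0.1)])
        beta = fixed_effects_meta(far, "d").beta_combined
        q, df, _, i2 = heterogeneity(far, beta)
        assert q > df and i2 > 0.0


class TestOracles:
    @given(
        data=st.lists(
            st.tuples(st.floats(-1, 1, allow_nan=False), st.floats(0.01, 1.0)), min_size=2, max_size=6
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_combined_beta_matches_grid_search_minimizer(self, data):
        """The inverse-variance combination minimizes the weighted sum of squares."""
        ests = estimates(data)
        result = fixed_effects_meta(ests, "d")
        oracle = grid_search_combined([e.beta for e in ests], [e.weight for e in ests])
        assert result.beta_combined == pytest.approx(oracle, abs=1e-6)

    def test_against_statsmodels_combine_effects(self):
        pairs = [(-0.054, 0.025), (-0.063, 0.020), (0.02, 0.04)]
        ests = estimates(pairs)
        result = fixed_effects_meta(ests, "d")
        sm_result = combine_effects(
            np.array([b for b, _ in pairs]), np.array([s**2 for _, s in pairs])
        )
        assert result.beta_combined == pytest.approx(float(sm_result.mean_effect_fe), rel=1e-10)
        assert result.se_combined == pytest.approx(float(sm_result.sd_eff_w_fe), rel=1e-10)
        assert result.q_stat == pytest.approx(float(sm_result.q), rel=1e-10)
        assert result.i2_percent == pytest.approx(100 * float(sm_result.i2), rel=1e-8)


class TestInvariants:
    @given(
        data=st.lists(
            st.tuples(st.floats(-1, 1, allow_nan=False), st.floats(0.01, 1.0)), min_size=2, max_size=6
        ),
        seed=st.integers(0, 100),
    )
    @settings(derandomize=True, max_examples=60)
    def test_permutation_invariance_and_se_bound(self, data, seed):
        ests = estimates(data)
        result = fixed_effects_meta(ests, "d")
        rng = np.random.default_rng(seed)
        shuffled = list(ests)
        rng.shuffle(shuffled)
        permuted = fixed_effects_meta(shuffled, "d")
        assert permuted.beta_combined == pytest.approx(result.beta_combined, rel=1e-12, abs=1e-15)
        assert permuted.q_stat == pytest.approx(result.q_stat, rel=1e-9, abs=1e-12)
        assert permuted.i2_percent == pytest.approx(result.i2_percent, rel=1e-6, abs=1e-9)
        assert result.se_combined <= min(e.se for e in ests)

    def test_empty_and_mixed_scale_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fixed_effects_meta([], "d")
        from snpmr import InstrumentRecord, wald_ratio

        a = GwasAssociation(
            study_label="a", variant_id="rs1", effect_allele="T", other_allele="C", beta=0.1, se=0.05
        )
        instrument = InstrumentRecord(
            variant_id="rs1", effect_allele="T", beta_exposure=17.1, se_exposure=3.3, units="g/day"
        )
        mixed = [per_allele_estimate(a), wald_ratio(a, instrument)]
        with pytest.raises(ValueError, match="mixed scales"):
            fixed_effects_meta(mixed, "d")
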
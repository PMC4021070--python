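"""LMS transform, population adjustment and band-probability integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import pedarv
from pedarv.growth import (
    GrowthModelError,
    IDENTITY_ADJUSTMENT,
    LMSRecord,
    PAPER_AGE_GRID,
    PopulationAdjustment,
    adjusted_zscore,
    average_sexes,
    band_probabilities,
    interpolate_lms,
    lms_weight_from_zscore,
    lms_zscore,
)
from pedarv.reference_data import WEIGHT_BANDS


def rec(L=1.0, M=10.0, S=0.1, age=24.0, sex="male"):
    return LMSRecord(age_months=age, sex=sex, L=L, M=M, S=S)


class TestLMSZScore:
    def test_median_is_zero(self):
        assert lms_zscore(10.0, rec()) == pytest.approx(0.0)

    def test_unit_power_reduces_to_relative_deviation(self):
        # L=1: z = (w/M - 1)/S
        assert lms_zscore(11.0, rec(L=1, M=10, S=0.1)) == pytest.approx(1.0)

    def test_log_branch_closed_form(self):
        # L=0: z = ln(w/M)/S
        assert lms_zscore(10.0 * math.e ** 0.1, rec(L=0, M=10, S=0.1)) == \
            pytest.approx(1.0)

    def test_rejects_non_positive_weight(self):
        with pytest.raises(GrowthModelError):
            lms_zscore(0.0, rec())

    @given(st.floats(min_value=-0.5, max_value=2.0),
           st.floats(min_value=4.0, max_value=30.0),
           st.floats(min_value=0.05, max_value=0.3))
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_in_weight_and_invertible(self, L, M, S):
        r = rec(L=L, M=M, S=S)
        weights = np.linspace(1.0, 60.0, 40)
        zs = [lms_zscore(w, r) for w in weights]
        assert all(a < b for a, b in zip(zs, zs[1:]))
        for w, z in zip(weights[::7], zs[::7]):
            assert lms_weight_from_zscore(z, r) == pytest.approx(w, rel=1e-9)


class TestAdjustment:
    def test_identity_adjustment_is_reference_zscore(self):
        r = rec()
        for w in (5.0, 10.0, 17.5):
            assert adjusted_zscore(w, r, IDENTITY_ADJUSTMENT) == \
                pytest.approx(lms_zscore(w, r))

    def test_shifted_child_becomes_new_median(self):
        r = rec()
        w = lms_weight_from_zscore(-1.5, r)
        adj = PopulationAdjustment(z_shift=-1.5)
        assert adjusted_zscore(w, r, adj) == pytest.approx(0.0, abs=1e-12)

    def test_cv_multiplier_rescales_shifted_zscore(self):
        r = rec()
        base = PopulationAdjustment(z_shift=-1.5, cv_multiplier=1.0)
        doubled = PopulationAdjustment(z_shift=-1.5, cv_multiplier=2.0)
        for w in (6.0, 9.0, 12.0):
            assert adjusted_zscore(w, r, doubled) == \
                pytest.approx(adjusted_zscore(w, r, base) / 2.0)

    def test_rejects_non_positive_cv_multiplier(self):
        with pytest.raises(GrowthModelError):
            PopulationAdjustment(cv_multiplier=0.0)


class TestBandProbabilities:
    def test_rows_normalize_to_one(self, synthetic_lms):
        for age in PAPER_AGE_GRID:
            for adj in (IDENTITY_ADJUSTMENT, PopulationAdjustment(-1.5, 1.0),
                        PopulationAdjustment(-2.0, 0.5)):
                row = band_probabilities(age, "male", synthetic_lms, adj)
                assert abs(sum(row.probs) - 1.0) <= 1e-9

    def test_single_band_closed_form(self):
        # synthetic chart: L=1, M=8, S=0.25 and no adjustment -> the
        # 6-9.9 kg band mass is Phi((10/8-1)/.25) - Phi((6/8-1)/.25),
        # renormalized over the truncation at 3 kg.
        table = [rec(L=1, M=8, S=0.25, age=12.0)]
        row = band_probabilities(1.0, "male", table, IDENTITY_ADJUSTMENT)
        z = lambda w: (w / 8.0 - 1.0) / 0.25
        renorm = 1.0 - norm.cdf(z(3.0))
        expected = (norm.cdf(z(10.0)) - norm.cdf(z(6.0))) / renorm
        assert row.probs[1] == pytest.approx(expected, abs=1e-12)

    def test_open_ended_top_band(self):
        table = [rec(L=1, M=30, S=0.2, age=120.0)]
        row = band_probabilities(10.0, "male", table, IDENTITY_ADJUSTMENT)
        z35 = (35.0 / 30.0 - 1.0) / 0.2
        renorm = 1.0 - norm.cdf((3.0 / 30.0 - 1.0) / 0.2)
        assert row.probs[-1] == pytest.approx((1 - norm.cdf(z35)) / renorm,
                                              abs=1e-9)

    def test_degenerate_adjustment_raises_not_silent_zeros(self, synthetic_lms):
        with pytest.raises(GrowthModelError, match="no probability mass"):
            band_probabilities(1.0, "male", synthetic_lms,
                               PopulationAdjustment(z_shift=-60.0))

    def test_age_outside_coverage_and_missing_sex(self, synthetic_lms):
        with pytest.raises(GrowthModelError, match="coverage"):
            band_probabilities(40.0, "male", synthetic_lms)
        with pytest.raises(GrowthModelError, match="no LMS records"):
            band_probabilities(2.0, "female", synthetic_lms)

    def test_monotone_shift_toward_lighter_bands(self, synthetic_lms):
        """Lower z-shift => stochastically smaller band distribution."""
        shifts = [0.0, -0.5, -1.0, -1.5, -2.0, -2.5, -3.0]
        for age in (1.0, 5.0, 10.0):
            rows = [band_probabilities(age, "male", synthetic_lms,
                                       PopulationAdjustment(z_shift=z))
                    for z in shifts]
            for lighter, heavier in zip(rows[1:], rows):
                # cumulative mass up to each band boundary can only grow
                cum_light = np.cumsum(lighter.probs)
                cum_heavy = np.cumsum(heavier.probs)
                assert np.all(cum_light >= cum_heavy - 1e-12)

    def test_trapezoid_integration_oracle(self, synthetic_lms):
        """Band masses agree with numeric integration of the implied density."""
        adj = PopulationAdjustment(z_shift=-1.5, cv_multiplier=1.3)
        for age in (0.5, 3.0, 9.0, 13.0):
            r = interpolate_lms(age * 12.0, "male", synthetic_lms)
            row = band_probabilities(age, "male", synthetic_lms, adj)

            def density(w):
                z_adj = (lms_zscore(w, r) - adj.z_shift) / adj.cv_multiplier
                dz_dw = (w / r.M) ** (r.L - 1.0) / (r.M * r.S) if r.L != 0 \
                    else 1.0 / (w * r.S)
                return norm.pdf(z_adj) * dz_dw / adj.cv_multiplier

            masses = []
            cap = lms_weight_from_zscore(
                adj.z_shift + 10.0 * adj.cv_multiplier, r)
            bounds = [b.lower_kg for b in WEIGHT_BANDS] + [max(cap, 40.0)]
            for lo, hi in zip(bounds, bounds[1:]):
                w = np.linspace(lo, hi, 4001)
                masses.append(np.trapezoid([density(x) for x in w], w))
            masses = np.asarray(masses) / sum(masses)
            assert np.allclose(row.probs, masses, atol=1e-6)


class TestAverageSexes:
    def test_identical_rows_unchanged(self, synthetic_lms):
        row = band_probabilities(2.0, "male", synthetic_lms)
        avg = average_sexes(row, row)
        assert avg.probs == pytest.approx(row.probs)

    def test_elementwise_mean(self):
        a = pedarv.BandProbabilityRow(2.0, (0.2, 0.8, 0, 0, 0, 0, 0))
        b = pedarv.BandProbabilityRow(2.0, (0.4, 0.6, 0, 0, 0, 0, 0))
        assert average_sexes(a, b).probs[0] == pytest.approx(0.3)

    def test_age_mismatch_rejected(self):
        a = pedarv.BandProbabilityRow(2.0, (1, 0, 0, 0, 0, 0, 0))
        b = pedarv.BandProbabilityRow(3.0, (1, 0, 0, 0, 0, 0, 0))
        with pytest.raises(GrowthModelError, match="age mismatch"):
            average_sexes(a, b)


class TestSyntheticGenerator:
    def test_grid_count_and_determinism(self):
        a = pedarv.generate_synthetic_lms(seed=11)
        b = pedarv.generate_synthetic_lms(seed=11)
        c = pedarv.generate_synthetic_lms(seed=12)
        assert len(a) == len(PAPER_AGE_GRID) == 14
        assert a == b
        assert a != c

    def test_median_strictly_increasing(self, synthetic_lms):
        medians = [r.M for r in sorted(synthetic_lms, key=lambda r: r.age_months)]
        assert all(x < y for x, y in zip(medians, medians[1:]))

    def test_non_monotone_median_rejected(self):
        with pytest.raises(GrowthModelError, match="increasing"):
            pedarv.generate_synthetic_lms(median_curve=(40.0, 3.0))

    def test_interpolation_between_tabulated_ages(self, synthetic_lms):
        lo = interpolate_lms(12.0, "male", synthetic_lms)
        hi = interpolate_lms(24.0, "male", synthetic_lms)
        mid = interpolate_lms(18.0, "male", synthetic_lms)
        assert mid.M == pytest.approx((lo.M + hi.M) / 2)
        assert mid.S == pytest.approx((lo.S + hi.S) / 2)

    def test_lms_csv_round_trip(self, tmp_path, synthetic_lms):
        path = tmp_path / "lms.csv"
        pedarv.write_lms_table(synthetic_lms, path)
        again = pedarv.load_lms_table(path)
        assert again == synthetic_lms
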
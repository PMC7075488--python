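"""Closed-form criteria: frozen oracles and algebraic invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mfl
from mfl.errors import (
    DegenerateInputError,
    DivisionImpossibleError,
    InvalidInputError,
)
from .conftest import constant_corr

TAU_ALPHA = 3 * 0.49 / (1 + 2 * 0.49)  # population alpha of the equal-0.70 pattern
TAU_R = 0.6 * TAU_ALPHA  # its composite correlation at phi = 0.6


class TestStandardizedAlpha:
    @pytest.mark.parametrize(
        "k, r, expected",
        [
            (3, 0.49, 1.47 / 1.98),
            (4, 0.0, 0.0),  # identity matrix
            (2, 1.0, 1.0),  # perfect inter-item correlation
        ],
    )
    def test_constant_offdiagonal(self, k, r, expected):
        assert mfl.standardized_alpha(constant_corr(k, r)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_mixed_offdiagonals_use_mean(self):
        m = np.array([[1.0, 0.3, 0.5], [0.3, 1.0, 0.7], [0.5, 0.7, 1.0]])
        rbar = (0.3 + 0.5 + 0.7) / 3
        assert mfl.standardized_alpha(m) == pytest.approx(3 * rbar / (1 + 2 * rbar))

    @pytest.mark.parametrize(
        "bad",
        [np.ones((1, 1)), np.ones((2, 3)), [[1.0, 0.2], [0.4, 1.0]]],
        ids=["too-small", "non-square", "asymmetric"],
    )
    def test_invalid_input(self, bad):
        with pytest.raises(InvalidInputError):
            mfl.standardized_alpha(np.asarray(bad))

    def test_degenerate_mean_correlation(self):
        # K=3, rbar = -0.5 = -1/(K-1): denominator hits zero
        with pytest.raises(DegenerateInputError):
            mfl.standardized_alpha(constant_corr(3, -0.5))


class TestAve:
    @pytest.mark.parametrize(
        "loadings, expected",
        [
            ((0.70, 0.70, 0.70), 0.49),
            ((0.45, 0.70, 0.95), (0.2025 + 0.49 + 0.9025) / 3),
            ((1.0, 1.0), 1.0),
        ],
    )
    def test_from_loadings(self, loadings, expected):
        assert mfl.ave_from_loadings(loadings) == pytest.approx(expected, abs=1e-12)

    def test_from_loadings_empty(self):
        with pytest.raises(InvalidInputError):
            mfl.ave_from_loadings([])

    @pytest.mark.parametrize(
        "alpha, k, expected",
        [
            (TAU_ALPHA, 3, 0.49),
            (1.0, 2, 1.0),
            (1.0, 7, 1.0),
            (0.9, 4, 0.9 / 1.3),
            (0.6, 4, 0.6 / 2.2),
        ],
    )
    def test_from_alpha(self, alpha, k, expected):
        assert mfl.ave_from_alpha(alpha, k) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("alpha", [0.0, -0.2, 1.1])
    def test_from_alpha_range(self, alpha):
        with pytest.raises(InvalidInputError):
            mfl.ave_from_alpha(alpha, 3)

    @given(
        k=st.integers(min_value=2, max_value=50),
        rbar=st.floats(min_value=1e-6, max_value=1.0 - 1e-9),
    )
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_inverts_alpha(self, k, rbar):
        """ave_from_alpha is the exact inverse of standardized alpha for
        constant inter-item correlation matrices."""
        alpha = mfl.standardized_alpha(constant_corr(k, rbar))
        assert mfl.ave_from_alpha(alpha, k) == pytest.approx(rbar, rel=1e-12)


class TestDisattenuate:
    def test_recovers_latent_correlation(self):
        # tau-equivalent population: r = alpha * phi, double correction
        # divides by alpha and returns phi
        assert mfl.disattenuate(TAU_R, TAU_ALPHA, TAU_ALPHA, "double") == pytest.approx(
            0.6, abs=1e-12
        )

    @pytest.mark.parametrize("mode", ["double", "single"])
    def test_perfect_reliability_is_identity(self, mode):
        assert mfl.disattenuate(0.5, 1.0, 1.0, mode) == 0.5

    def test_single_uses_min_alpha_only(self):
        assert mfl.disattenuate(0.5, 0.9, 0.6, "single") == pytest.approx(
            0.5 / np.sqrt(0.6)
        )
        assert mfl.disattenuate(0.5, 0.9, 0.6, "double") == pytest.approx(
            0.5 / np.sqrt(0.54)
        )

    def test_no_clamping_beyond_one(self):
        assert mfl.disattenuate(0.9, 0.5, 0.5, "double") == pytest.approx(1.8)

    def test_zero_alpha_division_impossible(self):
        with pytest.raises(DivisionImpossibleError):
            mfl.disattenuate(0.5, 0.0, 0.9)

    @given(
        r=st.floats(min_value=-1.0, max_value=1.0),
        ax=st.floats(min_value=0.05, max_value=1.0),
        ay=st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_single_never_exceeds_double_in_magnitude(self, r, ax, ay):
        single = mfl.disattenuate(r, ax, ay, "single")
        double = mfl.disattenuate(r, ax, ay, "double")
        assert abs(single) <= abs(double) + 1e-12


class TestPairDecisions:
    @pytest.mark.parametrize(
        "ave_x, ave_y, phi, expected",
        [
            (0.49, 0.49, 0.60, True),
            (0.49, 0.49, 0.72, False),
            (0.2, 0.9, 0.0, True),
            (0.3, 0.9, 0.6, False),  # one AVE below phi^2 suffices to violate
        ],
    )
    def test_ofl(self, ave_x, ave_y, phi, expected):
        assert mfl.ofl_pair(ave_x, ave_y, phi) is expected

    def test_mfl_double_matches_ofl_under_tau_equivalence(self):
        dim = mfl.DimensionSummary("x", TAU_ALPHA, 3)
        assert mfl.mfl_pair(dim, dim, TAU_R, "double") is True
        assert mfl.mfl_pair(dim, dim, TAU_R, "double") == mfl.ofl_pair(0.49, 0.49, 0.6)

    def test_mfl_single_violation(self):
        dx = mfl.DimensionSummary("x", 0.9, 4)
        dy = mfl.DimensionSummary("y", 0.6, 4)
        # AVE_y = 0.272727 < 0.25/0.6 = 0.416667
        assert mfl.mfl_pair(dx, dy, 0.5, "single") is False

    def test_zero_correlation_always_met(self):
        dx = mfl.DimensionSummary("x", 0.55, 9)
        dy = mfl.DimensionSummary("y", 0.95, 2)
        for mode in ("double", "single"):
            assert mfl.mfl_pair(dx, dy, 0.0, mode) is True

    @given(
        ax=st.floats(min_value=0.3, max_value=0.999),
        ay=st.floats(min_value=0.3, max_value=0.999),
        kx=st.integers(min_value=2, max_value=12),
        ky=st.integers(min_value=2, max_value=12),
        r=st.floats(min_value=-0.95, max_value=0.95),
    )
    @settings(max_examples=300, derandomize=True)
    def test_single_decision_bounds_double(self, ax, ay, kx, ky, r):
        """Single correction can never flag a violation double misses."""
        dx = mfl.DimensionSummary("x", ax, kx)
        dy = mfl.DimensionSummary("y", ay, ky)
        if mfl.mfl_pair(dx, dy, r, "double"):
            assert mfl.mfl_pair(dx, dy, r, "single")

    @given(
        ax=st.floats(min_value=0.3, max_value=0.999),
        r_lo=st.floats(min_value=0.0, max_value=0.95),
        r_hi=st.floats(min_value=0.0, max_value=0.95),
    )
    @settings(max_examples=200, derandomize=True)
    @pytest.mark.parametrize("mode", ["double", "single"])
    def test_monotone_in_correlation_magnitude(self, ax, r_lo, r_hi, mode):
        """Raising |r| can only flip met -> violated, never the reverse."""
        r_lo, r_hi = sorted((r_lo, r_hi))
        dx = mfl.DimensionSummary("x", ax, 4)
        dy = mfl.DimensionSummary("y", 0.8, 5)
        if mfl.mfl_pair(dx, dy, r_hi, mode):
            assert mfl.mfl_pair(dx, dy, r_lo, mode)


class TestAssessPair:
    def test_distinct_certain(self):
        dim = mfl.DimensionSummary("x", TAU_ALPHA, 3)
        pa = mfl.assess_pair(dim, mfl.DimensionSummary("y", TAU_ALPHA, 3), TAU_R)
        assert pa.verdict == "distinct_certain"
        assert pa.double_met and pa.single_met
        assert not pa.overcorrected_flag
        assert pa.ave_x == pytest.approx(0.49, abs=1e-9)

    def test_violation_certain(self):
        pa = mfl.assess_pair(
            mfl.DimensionSummary("x", 0.9, 4), mfl.DimensionSummary("y", 0.6, 4), 0.5
        )
        assert pa.verdict == "violation_certain"
        assert not pa.double_met and not pa.single_met

    def test_uncertain_straddles_the_bound(self):
        dim = mfl.DimensionSummary("x", 0.742424, 3)
        pa = mfl.assess_pair(dim, mfl.DimensionSummary("y", 0.742424, 3), 0.52)
        assert pa.verdict == "uncertain"
        assert pa.single_met and not pa.double_met
        assert pa.r_hat_double**2 == pytest.approx(0.490571, abs=1e-5)
        assert pa.r_hat_single**2 == pytest.approx(0.364212, abs=1e-5)

    def test_corrected_magnitudes_ordered_and_flagged(self):
        pa = mfl.assess_pair(
            mfl.DimensionSummary("x", 0.5, 4), mfl.DimensionSummary("y", 0.7, 4), 0.8
        )
        assert abs(pa.r_hat_single) <= abs(pa.r_hat_double)
        assert pa.overcorrected_flag  # 0.8 / sqrt(0.35) > 1

    def test_sign_symmetric_in_r(self):
        dx = mfl.DimensionSummary("x", 0.85, 5)
        dy = mfl.DimensionSummary("y", 0.75, 6)
        for r in (0.3, 0.62, 0.9):
            assert (
                mfl.assess_pair(dx, dy, r).verdict
                == mfl.assess_pair(dx, dy, -r).verdict
            )


class TestAssessInstrument:
    def _instrument(self, d, r=0.0):
        m = np.full((d, d), r)
        np.fill_diagonal(m, 1.0)
        dims = tuple(mfl.DimensionSummary(f"d{i}", 0.8, 4) for i in range(d))
        return mfl.InstrumentSummary(dims, m)

    @pytest.mark.parametrize("d, n_pairs", [(2, 1), (5, 10)])
    def test_pair_count(self, d, n_pairs):
        result = mfl.assess_instrument(self._instrument(d))
        assert result.n_pairs == n_pairs

    def test_all_zero_correlations_met(self):
        result = mfl.assess_instrument(self._instrument(4, 0.0))
        assert result.mfl_met
        assert result.frac_not_distinct == 0.0
        assert result.frac_violation_certain == 0.0

    def test_mixed_verdict_fractions(self):
        # alpha 0.8, K=4 -> AVE = 0.5; r = 0.75 -> r^2/alpha = 0.703 > 0.5
        dims = tuple(mfl.DimensionSummary(f"d{i}", 0.8, 4) for i in range(3))
        m = np.array([[1.0, 0.75, 0.1], [0.75, 1.0, 0.1], [0.1, 0.1, 1.0]])
        result = mfl.assess_instrument(mfl.InstrumentSummary(dims, m))
        assert not result.mfl_met
        assert result.frac_violation_certain == pytest.approx(1 / 3)
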
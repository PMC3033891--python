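"""Potential terms, analytic derivatives and unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtug import (
    ModelParameters,
    UnitSystem,
    beta_from_hooke,
    hydrophobic_length,
    mismatch_energy,
    morse_energy,
    potential_curvature,
    potential_gradient,
    reduced_unit_system,
    to_physical,
    to_reduced,
    total_potential,
)

# randomized-but-bounded parameter sets for property tests
params_strategy = st.builds(
    ModelParameters,
    D_e=st.floats(2.0, 30.0),
    r_e=st.floats(0.8, 1.8),
    beta=st.floats(2.0, 25.0),
    l0=st.floats(1.5, 3.0),
    d=st.floats(1.2, 4.5),
    H_B=st.floats(0.0, 50.0),
)


class TestHydrophobicLength:
    def test_equilibrium_value(self, reduced_params):
        assert hydrophobic_length(reduced_params.r_e, reduced_params) == reduced_params.l0

    def test_unit_slope(self, reduced_params):
        p = reduced_params
        assert hydrophobic_length(p.r_e + 0.5, p) == pytest.approx(p.l0 + 0.5, abs=1e-14)

    def test_mismatch_relieved(self, reduced_params):
        p = reduced_params
        r_star = p.r_e + (p.d - p.l0)
        assert hydrophobic_length(r_star, p) == pytest.approx(p.d, abs=1e-14)

    def test_nonpositive_separation_rejected(self, reduced_params):
        with pytest.raises(ValueError):
            hydrophobic_length(0.0, reduced_params)
        with pytest.raises(ValueError):
            hydrophobic_length(-1.0, reduced_params)


class TestMorse:
    def test_minimum_depth(self, reduced_params):
        p = reduced_params
        assert morse_energy(p.r_e, p) == pytest.approx(-p.D_e, abs=1e-14)

    def test_plateau(self, reduced_params):
        p = reduced_params
        r_far = p.r_e + 30.0 / p.beta
        assert abs(morse_energy(r_far, p)) <= 1e-12 * p.D_e

    def test_curvature_at_minimum_matches_second_difference(self, reduced_params):
        p = reduced_params
        h = 1e-5
        second = (
            morse_energy(p.r_e + h, p) - 2 * morse_energy(p.r_e, p) + morse_energy(p.r_e - h, p)
        ) / h**2
        assert second == pytest.approx(2 * p.D_e * p.beta**2, rel=1e-4)

    def test_bounded_in_well_depth_beyond_minimum(self, reduced_params):
        # on the dissociation side the bond energy stays in [-D_e, 0)
        p = reduced_params
        r = np.linspace(p.r_e, p.r_e + 5.0, 200)
        v = morse_energy(r, p)
        assert np.all(v >= -p.D_e)
        assert np.all(v <= 0.0)  # plateau underflows to exactly 0 at large r


class TestMismatch:
    def test_zero_where_relieved(self, reduced_params):
        p = reduced_params
        assert mismatch_energy(p.r_e + (p.d - p.l0), p) == pytest.approx(0.0, abs=1e-14)

    def test_zero_without_membrane_coupling(self, reduced_params):
        p = reduced_params.replace(H_B=0.0)
        r = np.linspace(0.5, 3.0, 50)
        assert np.all(mismatch_energy(r, p) == 0.0)

    def test_half_k_x_squared(self):
        p = ModelParameters(D_e=5.0, r_e=1.0, beta=5.0, l0=2.0, d=2.8, H_B=1.0)
        # residual mismatch 0.8 nm at r_e: (1/2)*1*0.8^2
        assert mismatch_energy(p.r_e, p) == pytest.approx(0.32, abs=1e-12)

    def test_symmetric_in_residual_sign(self, reduced_params):
        p = reduced_params
        delta = 0.3
        r_star = p.r_e + (p.d - p.l0)
        assert mismatch_energy(r_star + delta, p) == pytest.approx(
            mismatch_energy(r_star - delta, p), rel=1e-12
        )


class TestTotalPotential:
    def test_value_at_equilibrium(self, reduced_params):
        # -D_e + (H_B/2)*(d-l0)^2 = -1 + 0.32
        assert total_potential(1.0, reduced_params) == pytest.approx(-0.68, abs=1e-12)

    def test_both_terms_at_minimum(self):
        p = ModelParameters(D_e=3.0, r_e=1.2, beta=8.0, l0=2.2, d=2.2, H_B=4.0)
        assert total_potential(p.r_e, p) == pytest.approx(-p.D_e, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=params_strategy, x=st.floats(0.05, 3.0))
    def test_exact_decomposition(self, p, x):
        r = p.r_e + x - 0.5  # spans both sides of the well, always positive
        if r <= 0:
            return
        total = total_potential(r, p)
        # bitwise-exact decomposition: the total is the float sum of its terms
        assert total == morse_energy(r, p) + mismatch_energy(r, p)
        assert mismatch_energy(r, p) >= 0.0
        assert -p.D_e <= morse_energy(r, p)


class TestDerivatives:
    def test_morse_minimum_is_stationary(self, reduced_params):
        p = reduced_params.replace(H_B=0.0)
        assert potential_gradient(p.r_e, p) == pytest.approx(0.0, abs=1e-14)
        assert potential_curvature(p.r_e, p) == pytest.approx(2 * p.D_e * p.beta**2, rel=1e-12)

    def test_aligned_minima_stationary(self):
        p = ModelParameters(D_e=3.0, r_e=1.2, beta=8.0, l0=2.2, d=2.2, H_B=4.0)
        assert potential_gradient(p.r_e, p) == pytest.approx(0.0, abs=1e-14)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(p=params_strategy)
    def test_gradient_matches_finite_difference_on_grid(self, p):
        h = 1e-6
        r = np.linspace(max(p.r_e - 3.0 / p.beta, 2 * h), p.r_e + 1.5, 100)
        fd = (total_potential(r + h, p) - total_potential(r - h, p)) / (2 * h)
        grad = potential_gradient(r, p)
        scale = np.max(np.abs(grad)) + p.D_e * p.beta  # avoid 0/0 near roots
        np.testing.assert_allclose(grad, fd, atol=1e-5 * scale)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(p=params_strategy)
    def test_curvature_matches_finite_difference(self, p):
        h = 1e-4
        r = np.linspace(max(p.r_e - 2.0 / p.beta, 2 * h), p.r_e + 1.0, 30)
        fd = (total_potential(r + h, p) - 2 * total_potential(r, p) + total_potential(r - h, p)) / h**2
        curv = potential_curvature(r, p)
        scale = np.max(np.abs(curv)) + p.D_e * p.beta**2
        np.testing.assert_allclose(curv, fd, atol=1e-4 * scale)


class TestBetaFromHooke:
    @pytest.mark.parametrize("k,D_e,expected", [(2.0, 1.0, 1.0), (8.0, 1.0, 2.0)])
    def test_algebra(self, k, D_e, expected):
        assert beta_from_hooke(k, D_e) == pytest.approx(expected, rel=1e-15)

    @pytest.mark.parametrize("k", [50.0, 330.0, 920.0])
    def test_round_trip_recovers_hookean_constant(self, k):
        D_e = 4.0
        beta = beta_from_hooke(k, D_e)
        p = ModelParameters(D_e=D_e, r_e=1.3, beta=beta, l0=2.2, d=2.8, H_B=0.0)
        assert potential_curvature(p.r_e, p) == pytest.approx(k, rel=1e-10)

    @pytest.mark.parametrize("k,D_e", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_domain_errors(self, k, D_e):
        with pytest.raises(ValueError):
            beta_from_hooke(k, D_e)


class TestUnits:
    def test_identity_system_is_noop(self, reduced_params):
        assert to_physical(reduced_params, UnitSystem()) == reduced_params

    def test_reduction_normalizes_r_e_and_kBT(self, paper_params):
        red = to_reduced(paper_params)
        assert red.r_e == pytest.approx(1.0, rel=1e-14)
        assert red.kBT == pytest.approx(1.0, rel=1e-14)

    def test_round_trip_is_identity(self, paper_params):
        p = paper_params.replace(kBT=2.5)  # physical-ish energy unit
        back = to_physical(to_reduced(p), reduced_unit_system(p))
        for name in ("D_e", "r_e", "beta", "l0", "d", "H_B", "A", "kBT"):
            assert getattr(back, name) == pytest.approx(getattr(p, name), rel=1e-12)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            UnitSystem(energy_scale=0.0)
        with pytest.raises(ValueError):
            UnitSystem(length_scale=-1.0)


class TestParameterInvariants:
    @pytest.mark.parametrize(
        "field,value",
        [("D_e", -1.0), ("r_e", 0.0), ("beta", -2.0), ("l0", 0.0), ("d", -0.1),
         ("H_B", -1.0), ("A", 0.0), ("kBT", -1.0)],
    )
    def test_invalid_field_rejected(self, reduced_params, field, value):
        with pytest.raises(ValueError, match=field):
            reduced_params.replace(**{field: value})

    def test_negative_mismatch_is_valid(self):
        p = ModelParameters(D_e=5.0, r_e=1.0, beta=10.0, l0=2.5, d=2.2, H_B=3.0)
        assert p.mismatch < 0
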
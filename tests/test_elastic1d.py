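"""Unit and property tests of the analytic 1D wedge-interaction solver."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from wedgelat.elastic1d import (
    DEFAULT_SLOPE_H,
    BilayerParameters,
    WedgeParameters,
    critical_immersion_depth,
    decay_constants,
    dimerization_energy,
    interaction_curve,
    pair_interaction_energy,
    profile_energy,
    profile_energy_quadrature,
    solve_isolated_profile,
    solve_pair_profile,
)
from wedgelat.errors import (
    BracketError,
    OverlapError,
    ParameterError,
)
from wedgelat.iocli import make_fixture


class TestDecayConstants:
    def test_thickness_decay_length_closed_form(self, bilayer):
        dc = decay_constants(bilayer)
        assert dc.lambda_s == pytest.approx((1.0 / 6.0) ** 0.25, rel=1e-12)

    def test_zero_tension_roots_are_imaginary_conjugates(self, bilayer):
        dc = decay_constants(bilayer)
        assert math.isinf(dc.lambda_t)
        assert dc.nu_plus.real == pytest.approx(0.0, abs=1e-14)
        assert dc.nu_plus == pytest.approx(dc.nu_minus.conjugate())
        assert dc.k_plus.real > 0 and dc.k_minus.real > 0

    def test_tension_length(self):
        dc = decay_constants(BilayerParameters(tau=0.05))
        assert dc.lambda_t == pytest.approx(20.0)

    def test_invalid_moduli_rejected(self):
        with pytest.raises(ParameterError):
            BilayerParameters(K_b=-1.0)
        with pytest.raises(ParameterError):
            BilayerParameters(K_t=0.0)


class TestProfiles:
    @pytest.mark.parametrize("tau", [0.0, 0.05])
    def test_pair_boundary_conditions(self, tau):
        """All six contact conditions hold on an asymmetric pair."""
        bil = BilayerParameters(tau=tau)
        wa = WedgeParameters(U=-0.9, slope_u=0.05)
        wb = WedgeParameters(U=-0.3, slope_u=-0.02)
        pr = solve_pair_profile(bil, wa, wb, 2.7)
        rl, rr = pr.r_left, pr.r_right
        assert pr.u_plus(rl) == pytest.approx(wa.U, abs=1e-9)
        assert pr.u_plus(rr) == pytest.approx(wb.U, abs=1e-9)
        # outward normal is +r at the left edge, -r at the right edge
        assert pr.du_plus(rl) == pytest.approx(wa.slope_u, abs=1e-9)
        assert -pr.du_plus(rr) == pytest.approx(wb.slope_u, abs=1e-9)
        assert pr.dh_plus(rl) == pytest.approx(wa.slope_h, abs=1e-9)
        assert -pr.dh_plus(rr) == pytest.approx(wb.slope_h, abs=1e-9)

    def test_symmetric_pair_has_flat_midpoint(self, bilayer, deep_wedge):
        pr = solve_pair_profile(bilayer, deep_wedge, deep_wedge, 3.0)
        assert pr.du_plus(0.0) == pytest.approx(0.0, abs=1e-10)

    def test_wide_pair_relaxes_at_midspan(self, bilayer, deep_wedge):
        pr = solve_pair_profile(bilayer, deep_wedge, deep_wedge, 40.0)
        assert abs(pr.u_plus(0.0)) < 1e-3

    def test_unperturbed_wedge_gives_flat_zero_energy_profile(self, bilayer):
        w = WedgeParameters(U=0.0, slope_h=0.0, slope_u=0.0)
        iso = solve_isolated_profile(bilayer, w)
        assert iso.u_plus(1.7) == pytest.approx(0.0, abs=1e-12)
        assert profile_energy(iso, bilayer, w.L) == pytest.approx(0.0, abs=1e-12)

    def test_exterior_decay_envelope(self, bilayer, deep_wedge):
        """u decays under the envelope |U| exp(-Re(k) r), Re(k) ~ 0.5/lambda_s."""
        iso = solve_isolated_profile(bilayer, deep_wedge)
        k_re = decay_constants(bilayer).k_plus.real
        for r in (5.0, 10.0 * bilayer.lambda_s, 20.0 * bilayer.lambda_s):
            assert abs(iso.u_plus(r)) < 1.5 * abs(deep_wedge.U) * math.exp(-k_re * r)
        assert abs(iso.u_plus(20.0 * bilayer.lambda_s)) < 1e-4 * abs(deep_wedge.U)

    def test_overlap_rejected(self, bilayer, deep_wedge):
        with pytest.raises(OverlapError):
            solve_pair_profile(bilayer, deep_wedge, deep_wedge, 1.0)


class TestEnergies:
    def test_boundary_form_matches_quadrature_on_random_draws(self):
        """Closed-form boundary energy == direct quadrature of the density."""
        draws = make_fixture("parameter-sweep", seed=11, n=30)
        for s in draws:
            bil, w = s["bilayer"], s["wedge"]
            d = max(s["d"], 2.0 * w.r0 + 0.05)
            pr = solve_pair_profile(bil, w, w, d)
            assert profile_energy(pr, bil, w.L) == pytest.approx(
                profile_energy_quadrature(pr, bil, w.L), abs=1e-6
            )
            iso = solve_isolated_profile(bil, w)
            assert profile_energy(iso, bil, w.L) == pytest.approx(
                profile_energy_quadrature(iso, bil, w.L), abs=1e-6
            )

    def test_energy_invariant_under_height_shift(self, bilayer, deep_wedge):
        pr = solve_pair_profile(bilayer, deep_wedge, deep_wedge, 2.2)
        e0 = profile_energy(pr, bilayer, 3.0)
        b0, b1, b2 = pr.p_poly
        pr.p_poly = (b0 + 1.7, b1, b2)
        assert profile_energy(pr, bilayer, 3.0) == pytest.approx(e0, abs=1e-9)

    def test_swap_symmetry(self, bilayer):
        wa = WedgeParameters(U=-0.9)
        wb = WedgeParameters(U=-0.2)
        for d in (1.6, 2.5, 5.0):
            assert pair_interaction_energy(bilayer, wa, wb, d) == pytest.approx(
                pair_interaction_energy(bilayer, wb, wa, d), rel=1e-10
            )


class TestInteractionCurve:
    def test_shallow_state_is_repulsive_everywhere(self, bilayer, shallow_wedge):
        ds = np.linspace(1.3, 20.0, 60)
        curve = interaction_curve(bilayer, shallow_wedge, shallow_wedge, ds)
        assert np.all(curve.g_int > 0)

    def test_deep_state_has_attractive_window(self, bilayer, deep_wedge):
        ds = np.linspace(1.5, 5.0, 30)
        curve = interaction_curve(bilayer, deep_wedge, deep_wedge, ds)
        assert curve.g_int.min() < 0

    def test_far_field_structure(self, bilayer, deep_wedge):
        """The thickness-mediated part decays exponentially; the full curve
        approaches the analytic height-mediated tail 2 K_b s_h^2 L/(d-2r0)."""
        flat_h = replace(deep_wedge, slope_h=0.0)
        assert abs(pair_interaction_energy(bilayer, flat_h, flat_h, 40.0)) < 1e-3
        tail = (
            2.0
            * bilayer.K_b
            * DEFAULT_SLOPE_H**2
            * deep_wedge.L
            / (40.0 - 2.0 * deep_wedge.r0)
        )
        full = pair_interaction_energy(bilayer, deep_wedge, deep_wedge, 40.0)
        assert full == pytest.approx(tail, abs=1e-3)

    def test_interaction_grid_below_contact_rejected(self, bilayer, deep_wedge):
        with pytest.raises(OverlapError):
            interaction_curve(bilayer, deep_wedge, deep_wedge, np.array([1.0, 2.0]))


class TestDimerization:
    def test_gain_grows_with_immersion_depth(self, bilayer):
        gains = []
        for U in (-0.5, -0.6, -0.7, -0.8, -0.9):
            w = WedgeParameters(U=U)
            gain, _ = dimerization_energy(bilayer, w, w)
            gains.append(gain)
        assert np.all(np.diff(gains) > 0)

    def test_zero_depth_flat_slopes_gives_zero(self, bilayer):
        w = WedgeParameters(U=0.0, slope_h=0.0, slope_u=0.0)
        gain, _ = dimerization_energy(bilayer, w, w)
        assert gain == pytest.approx(0.0, abs=1e-9)

    def test_empty_bracket_rejected(self, bilayer, deep_wedge):
        with pytest.raises(ParameterError):
            dimerization_energy(bilayer, deep_wedge, deep_wedge, d_min=5.0, d_max=2.0)

    def test_tension_dependence(self, deep_wedge, shallow_wedge):
        """Moderate-to-high tension weakens the deep-state dimerization; the
        shallow-state repulsion shifts less.  At very small tension the
        O(sqrt(tau)) height-field reference term produces a slight rise
        before the thickness-shift term takes over."""
        gains = {}
        for tau in (0.0, 0.02, 0.1, 0.3, 1.0):
            gains[tau] = dimerization_energy(
                BilayerParameters(tau=tau), deep_wedge, deep_wedge
            )[0]
        assert gains[1.0] < gains[0.3] < gains[0.1] < gains[0.02]
        assert gains[1.0] < gains[0.0]
        # the documented small-tension rise (height-field reference term)
        assert 0 < gains[0.02] - gains[0.0] < 0.05
        # shallow-state curves shift less than deep-state curves
        def shallow_at(tau):
            return pair_interaction_energy(
                BilayerParameters(tau=tau), shallow_wedge, shallow_wedge, 2.0
            )
        deep_shift = abs(gains[1.0] - gains[0.0])
        shallow_shift = abs(shallow_at(1.0) - shallow_at(0.0))
        assert shallow_shift < deep_shift

    def test_zero_tension_is_small_tension_limit(self, bilayer, deep_wedge):
        """The dedicated tau = 0 branch continues the tau > 0 solution with
        an O(sqrt(tau)) difference from the exterior height term."""
        g0 = pair_interaction_energy(bilayer, deep_wedge, deep_wedge, 2.0)
        for tau in (1e-6, 1e-8):
            gt = pair_interaction_energy(
                BilayerParameters(tau=tau), deep_wedge, deep_wedge, 2.0
            )
            bound = 2.0 * deep_wedge.L * DEFAULT_SLOPE_H**2 * math.sqrt(
                bilayer.K_b * tau
            ) + 1e-5
            assert abs(gt - g0) < bound


class TestPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        K_b=st.floats(10.0, 40.0),
        K_t=st.floats(30.0, 120.0),
        a=st.floats(1.5, 2.5),
        tau=st.floats(0.0, 0.3),
        U=st.floats(-1.2, 0.3),
        d=st.floats(1.8, 10.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_energy_identities_hold_for_arbitrary_parameters(
        self, K_b, K_t, a, tau, U, d
    ):
        """Boundary-form/quadrature agreement and wedge-swap symmetry are
        exact for any valid parameter combination."""
        bil = BilayerParameters(K_b=K_b, K_t=K_t, a=a, tau=tau)
        wa = WedgeParameters(U=U)
        wb = WedgeParameters(U=-0.5 * U - 0.2)
        pr = solve_pair_profile(bil, wa, wb, d)
        assert profile_energy(pr, bil, 3.0) == pytest.approx(
            profile_energy_quadrature(pr, bil, 3.0), abs=1e-6
        )
        assert pair_interaction_energy(bil, wa, wb, d) == pytest.approx(
            pair_interaction_energy(bil, wb, wa, d), rel=1e-9, abs=1e-12
        )


class TestCriticalDepth:
    def test_crossover_separates_regimes(self, bilayer):
        uc = critical_immersion_depth(bilayer, WedgeParameters())
        shallow = WedgeParameters(U=uc + 0.05)
        deep = WedgeParameters(U=uc - 0.05)
        assert dimerization_energy(bilayer, shallow, shallow)[0] < 0
        assert dimerization_energy(bilayer, deep, deep)[0] > 0

    def test_robust_to_grid_refinement(self, bilayer):
        u1 = critical_immersion_depth(bilayer, WedgeParameters())

        def min_g(U, n):
            w = WedgeParameters(U=U)
            return -dimerization_energy(bilayer, w, w, n_grid=n)[0]

        from scipy.optimize import brentq

        u2 = brentq(lambda U: min_g(U, 800), -0.7, -0.2, xtol=1e-4)
        assert abs(u1 - u2) < 1e-3

    def test_bad_bracket_rejected(self, bilayer):
        with pytest.raises(BracketError):
            critical_immersion_depth(
                bilayer, WedgeParameters(), U_bracket=(-0.1, -0.05)
            )
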
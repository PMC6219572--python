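"""Tests of the 2D pinned-height thickness solver and pair tables."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wedgelat.elastic1d import BilayerParameters
from wedgelat.errors import GeometryError, ParameterError
from wedgelat.thickness2d import (
    additivity_check,
    build_footprint,
    footprints_overlap,
    isolated_footprint_energy,
    pinned_height_energy_per_length,
    pinned_height_transect,
    solve_thickness_field,
)


class TestFootprint:
    def test_perimeter_is_stadium_formula(self):
        f = build_footprint(-0.9, L=3.0, r0=0.6)
        assert f.perimeter == pytest.approx(2 * (3.0 - 1.2) + 2 * math.pi * 0.6)

    def test_immersion_profile_on_outline(self):
        f = build_footprint(-0.9)
        assert f.boundary_immersion((0.0, 0.6)) == pytest.approx(-0.9)  # side
        assert f.boundary_immersion((1.5, 0.0)) == pytest.approx(0.0)  # tip centre
        # halfway along the cap arc the linear taper gives U/2
        c = 0.9 + 0.6 / math.sqrt(2.0)
        assert f.boundary_immersion((c, 0.6 / math.sqrt(2.0))) == pytest.approx(
            -0.45, abs=1e-9
        )

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ParameterError):
            build_footprint(-0.9, L=1.0, r0=0.6)

    def test_overlap_test_is_symmetric(self):
        fa = build_footprint(-0.9)
        fb = build_footprint(-0.9, pose=(1.0, 0.5, 0.4))
        assert footprints_overlap(fa, fb) == footprints_overlap(fb, fa) is True
        fc = build_footprint(-0.9, pose=(0.0, 5.0, 0.0))
        assert not footprints_overlap(fa, fc)


class TestFieldSolver:
    def test_empty_patch_is_flat_and_free(self, bilayer):
        fld = solve_thickness_field(bilayer, [], (-4, 4), (-4, 4), 0.2)
        assert fld.energy == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fld.u, 0.0)

    def test_too_coarse_resolution_rejected(self, bilayer):
        with pytest.raises(ParameterError):
            solve_thickness_field(
                bilayer, [build_footprint(-0.9)], (-5, 5), (-5, 5), 0.3
            )

    def test_overlapping_footprints_rejected(self, bilayer):
        fps = [build_footprint(-0.9), build_footprint(-0.9, pose=(0.5, 0.2, 0.1))]
        with pytest.raises(GeometryError):
            solve_thickness_field(bilayer, fps, (-6, 6), (-6, 6), 0.15)

    def test_long_wedge_transect_matches_1d_solution(self, bilayer):
        """Mid-length transect of a long footprint reproduces the hinged 1D
        pinned-height profile within 5%."""
        f = build_footprint(-0.9, L=20.0)
        fld = solve_thickness_field(bilayer, [f], (-16, 16), (-7, 7), 0.1)
        ys, tr = fld.transect_y(0.0)
        ref = pinned_height_transect(bilayer, -0.9, 0.6, ys)
        sel = (np.abs(ys) > 0.6) & (np.abs(ys) < 4.0)
        assert np.max(np.abs(tr[sel] - ref[sel])) / 0.9 < 0.05

    def test_long_wedge_energy_per_length(self, bilayer):
        """Incremental energy per unit length (L 20 -> 26) matches the 1D
        closed form within 10%."""
        e20 = solve_thickness_field(
            bilayer, [build_footprint(-0.9, L=20.0)], (-16, 16), (-7, 7), 0.1
        ).energy
        e26 = solve_thickness_field(
            bilayer, [build_footprint(-0.9, L=26.0)], (-19, 19), (-7, 7), 0.1
        ).energy
        g1d = pinned_height_energy_per_length(bilayer, -0.9)
        assert (e26 - e20) / 6.0 == pytest.approx(g1d, rel=0.10)

    def test_linear_scaling_in_immersion_depth(self, bilayer):
        """Doubling U doubles the field and quadruples the energy exactly
        (quadratic functional, linear Dirichlet data, identical grids)."""
        kw = dict(xlim=(-6, 6), ylim=(-6, 6), resolution=0.15)
        f1 = solve_thickness_field(bilayer, [build_footprint(-0.45)], **kw)
        f2 = solve_thickness_field(bilayer, [build_footprint(-0.9)], **kw)
        assert np.allclose(f2.u, 2.0 * f1.u, atol=1e-9)
        assert f2.energy == pytest.approx(4.0 * f1.energy, rel=1e-9)

    def test_refinement_stability(self, bilayer):
        """Embedded-boundary staircase converges O(dx): the isolated energy
        moves by < 5% from dx = 0.15 to dx = 0.1."""
        e_coarse = isolated_footprint_energy(bilayer, -0.9, resolution=0.15)
        e_fine = isolated_footprint_energy(bilayer, -0.9, resolution=0.1)
        assert abs(e_fine - e_coarse) / abs(e_fine) < 0.05


class TestPairTable:
    def test_face_on_attractive_well(self, h0_table):
        e = h0_table.lookup(0.0, 1.5, 0.0)
        assert e < -3.0

    def test_far_pose_is_zero(self, h0_table):
        assert h0_table.lookup(0.0, 20.0, 0.0) == 0.0
        # smooth truncation makes the table edge exactly zero
        assert abs(h0_table.lookup(0.0, h0_table.dy_grid[-1], 0.0)) < 1e-2

    def test_overlap_is_hardcore_infinite(self, h0_table):
        assert math.isinf(h0_table.lookup(0.0, 0.8, 0.0))
        assert math.isinf(h0_table.lookup(1.0, 0.5, 0.3))

    def test_swap_symmetry(self, h0_table):
        """E(dx, dy, th) equals the energy seen from the second wedge's
        frame, E(-(dx cos th + dy sin th), ..., -th) -- checked through the
        stored quadrant symmetries."""
        for (dx, dy, th) in [(2.0, 2.0, 0.5), (0.5, 2.5, 1.2), (3.0, 1.5, 2.4)]:
            c, s = math.cos(th), math.sin(th)
            bx = -(c * dx + s * dy)
            by = -(-s * dx + c * dy)
            e_ab = h0_table.lookup(dx, dy, th)
            e_ba = h0_table.lookup(bx, by, -th)
            assert e_ab == pytest.approx(e_ba, abs=0.35)

    def test_tip_to_tip_weaker_than_face_on_at_equal_gap(self, h0_table):
        gap = 0.5
        face = h0_table.lookup(0.0, 2 * 0.6 + gap, 0.0)
        tip = h0_table.lookup(3.0 + gap, 0.0, 0.0)
        assert abs(tip) < abs(face)

    def test_quadrant_symmetry_of_lookup(self, h0_table):
        e = h0_table.lookup(2.0, 1.5, 0.7)
        assert h0_table.lookup(-2.0, 1.5, -0.7) == pytest.approx(e)
        assert h0_table.lookup(2.0, -1.5, -0.7) == pytest.approx(e)

    def test_roundtrip_save_load(self, h0_table, tmp_path):
        from wedgelat.thickness2d import PairPotentialTable

        prefix = str(tmp_path / "tab")
        h0_table.save(prefix)
        tab2 = PairPotentialTable.load(prefix)
        assert np.array_equal(tab2.energies, h0_table.energies)
        assert tab2.lookup(0.0, 1.5, 0.0) == h0_table.lookup(0.0, 1.5, 0.0)


class TestAdditivity:
    def test_collinear_triple_is_nearly_pairwise_additive(self, bilayer):
        s = 4.0  # tip-to-tip centre spacing, 1 nm outline gap
        fps = [
            build_footprint(-0.9, pose=(-s, 0.0, 0.0)),
            build_footprint(-0.9, pose=(0.0, 0.0, 0.0)),
            build_footprint(-0.9, pose=(s, 0.0, 0.0)),
        ]
        triple, pair_sum = additivity_check(bilayer, fps, resolution=0.15, margin=5.0)
        assert abs(triple - pair_sum) / abs(pair_sum) < 0.20

    def test_remote_third_wedge_does_not_disturb_a_pair(self, bilayer):
        fps = [
            build_footprint(-0.9, pose=(0.0, 0.0, 0.0)),
            build_footprint(-0.9, pose=(0.0, 1.8, 0.0)),
            build_footprint(-0.9, pose=(8.0, 6.0, 1.2)),
        ]
        triple, pair_sum = additivity_check(bilayer, fps, resolution=0.15, margin=5.0)
        assert triple == pytest.approx(pair_sum, abs=0.25)

    def test_overlapping_triple_rejected(self, bilayer):
        fps = [
            build_footprint(-0.9),
            build_footprint(-0.9, pose=(0.4, 0.4, 0.0)),
            build_footprint(-0.9, pose=(6.0, 0.0, 0.0)),
        ]
        with pytest.raises(GeometryError):
            additivity_check(bilayer, fps)
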
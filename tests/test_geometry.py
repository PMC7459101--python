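"""Nuclear geometry: ellipsoid fitting, radii, flattening, distance index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucorg import (
    NucleusModel,
    Spot,
    VoxelMask,
    feret_diameter,
    fit_ellipsoid_from_mask,
    flattening,
    normalized_distance_index,
    radial_ratio,
    radius_along_ray,
    voxelize,
)
from nucorg.errors import InvalidInputError, OutOfNucleusError, PairingError

from conftest import random_ellipsoid


class TestNucleusModel:
    def test_parametric_volume_and_feret(self):
        n = NucleusModel.parametric("n", (0, 0, 0), (6, 4, 2))
        assert n.volume == pytest.approx(4 / 3 * math.pi * 48, rel=1e-12)
        assert n.feret == 12.0

    def test_rejects_unsorted_or_nonpositive_axes(self):
        with pytest.raises(InvalidInputError):
            NucleusModel("n", np.zeros(3), np.array([2.0, 4.0, 6.0]), np.eye(3), 1.0, 1.0)
        with pytest.raises(InvalidInputError):
            NucleusModel("n", np.zeros(3), np.array([6.0, 4.0, -2.0]), np.eye(3), 1.0, 1.0)

    def test_rejects_improper_rotation(self):
        flip = np.diag([1.0, 1.0, -1.0])  # det -1
        with pytest.raises(InvalidInputError):
            NucleusModel("n", np.zeros(3), np.array([6.0, 4.0, 2.0]), flip, 1.0, 1.0)


class TestMaskFitting:
    def test_voxelized_sphere_recovers_radius(self):
        nuc = NucleusModel.parametric("s", (0, 0, 0), (5.0, 5.0, 5.0))
        model = fit_ellipsoid_from_mask(voxelize(nuc))
        assert np.allclose(model.semi_axes, 5.0, rtol=0.02)
        # mask volume close to the analytic sphere volume
        assert model.volume == pytest.approx(4 / 3 * math.pi * 125, rel=0.02)

    def test_axis_aligned_ellipsoid_axes_and_orientation(self):
        nuc = NucleusModel.parametric("e", (0, 0, 0), (6.0, 4.0, 2.0))
        model = fit_ellipsoid_from_mask(voxelize(nuc))
        assert np.allclose(model.semi_axes, [6, 4, 2], rtol=0.05)
        # principal axes must align with the lab axes up to sign
        assert np.allclose(np.abs(model.orientation), np.eye(3), atol=0.05)

    def test_round_trip_is_a_contraction(self, rng):
        nuc = random_ellipsoid(rng)
        fit1 = fit_ellipsoid_from_mask(voxelize(nuc))
        fit2 = fit_ellipsoid_from_mask(voxelize(fit1))
        assert np.allclose(fit2.semi_axes, fit1.semi_axes, rtol=0.01)

    def test_empty_or_tiny_mask_rejected(self):
        empty = VoxelMask(np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(InvalidInputError, match="nuc7"):
            fit_ellipsoid_from_mask(empty, nucleus_id="nuc7")
        tiny = np.zeros((5, 5, 5), dtype=bool)
        tiny[2, 2, :4] = True
        with pytest.raises(InvalidInputError):
            fit_ellipsoid_from_mask(VoxelMask(tiny))


class TestFlattening:
    def test_sphere_is_zero(self):
        v = 4 / 3 * math.pi * 125
        assert flattening(v, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_oblate_value(self):
        # polar radius 20% of equatorial: f = (0.2a - a)/a = -0.8
        a = 5.0
        v = 4 / 3 * math.pi * a * a * (0.2 * a)
        assert flattening(v, 2 * a) == pytest.approx(-0.8, rel=1e-12)

    @pytest.mark.parametrize("vol,diam", [(0.0, 10.0), (100.0, 0.0), (-5.0, 10.0)])
    def test_nonpositive_inputs_rejected(self, vol, diam):
        with pytest.raises(InvalidInputError):
            flattening(vol, diam)

    @given(
        a=st.floats(1.0, 10.0),
        c_frac=st.floats(0.05, 2.0),
        s=st.floats(0.1, 10.0),
    )
    def test_invariant_to_isotropic_scaling(self, a, c_frac, s):
        v = 4 / 3 * math.pi * a * a * (c_frac * a)
        f1 = flattening(v, 2 * a)
        f2 = flattening(v * s**3, 2 * a * s)
        assert f1 == pytest.approx(f2, rel=1e-9, abs=1e-9)


def _ray_march_radius(nucleus, direction, tol=1e-9):
    """Bisection oracle: largest t with center + t*direction inside."""
    def inside(t):
        p = nucleus.center + t * direction
        q = nucleus.orientation.T @ (p - nucleus.center)
        return np.sum((q / nucleus.semi_axes) ** 2) <= 1.0

    lo, hi = 0.0, 2.0 * nucleus.semi_axes[0]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if inside(mid) else (lo, mid)
    return 0.5 * (lo + hi)


class TestRadiusAlongRay:
    def test_sphere_any_direction(self, sphere, rng):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        assert radius_along_ray(sphere, d) == pytest.approx(5.0, abs=1e-9)

    def test_principal_axis(self, ellipsoid_642):
        assert radius_along_ray(ellipsoid_642, [1, 0, 0]) == pytest.approx(6.0)

    def test_diagonal_closed_form(self, ellipsoid_642):
        d = np.ones(3) / math.sqrt(3)
        expected = 1.0 / math.sqrt((1 / 36 + 1 / 16 + 1 / 4) / 3)
        r = radius_along_ray(ellipsoid_642, d)
        assert r == pytest.approx(expected, abs=1e-9)
        assert r == pytest.approx(2.969, abs=1e-3)

    def test_matches_bisection_oracle(self, rng):
        for _ in range(30):
            nuc = random_ellipsoid(rng)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            assert radius_along_ray(nuc, d) == pytest.approx(
                _ray_march_radius(nuc, d), abs=1e-6
            )

    def test_zero_and_nonunit_vectors_rejected(self, sphere):
        with pytest.raises(InvalidInputError):
            radius_along_ray(sphere, [0, 0, 0])
        with pytest.raises(InvalidInputError):
            radius_along_ray(sphere, [1, 1, 0])


class TestRadialRatio:
    def test_center_surface_and_interior(self, sphere):
        mk = lambda pos: Spot("s", "sphere", "p", pos)
        assert radial_ratio(sphere, mk((0, 0, 0))) == 0.0
        assert radial_ratio(sphere, mk((5, 0, 0))) == pytest.approx(1.0)
        assert radial_ratio(sphere, mk((3, 0, 0))) == pytest.approx(0.6)

    def test_clamping_and_rejection(self, sphere, caplog):
        just_out = Spot("s1", "sphere", "p", (5.15, 0, 0))  # rho = 1.03
        with caplog.at_level("WARNING"):
            assert radial_ratio(sphere, just_out) == 1.0
        assert any("clamped" in r.message for r in caplog.records)
        far_out = Spot("s2", "sphere", "p", (5.3, 0, 0))  # rho = 1.06
        with pytest.raises(OutOfNucleusError):
            radial_ratio(sphere, far_out)

    def test_wrong_nucleus_rejected(self, sphere):
        with pytest.raises(PairingError):
            radial_ratio(sphere, Spot("s", "other", "p", (1, 0, 0)))


class TestDistanceIndex:
    @pytest.mark.parametrize(
        "rho,index,shell",
        [
            (0.0, 0.0, 1),
            (1.0, 1.0, 10_000),
            (0.5 ** (1 / 3), 0.5, 5000),
        ],
    )
    def test_volume_mode_examples(self, rho, index, shell):
        r = normalized_distance_index(rho)
        assert r.normalized_distance_index == pytest.approx(index, abs=1e-12)
        assert r.shell_index == shell

    def test_out_of_range_rejected(self):
        for rho in (-0.1, 1.1):
            with pytest.raises(InvalidInputError):
                normalized_distance_index(rho)

    @given(rho=st.floats(0.0, 1.0))
    def test_volume_index_is_cube_of_linear(self, rho):
        v = normalized_distance_index(rho, mode="volume")
        l = normalized_distance_index(rho, mode="linear")
        assert v.normalized_distance_index == pytest.approx(
            l.normalized_distance_index ** 3, abs=1e-12
        )

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    def test_index_and_shell_nondecreasing_in_rho(self, rhos):
        rhos = sorted(rhos)
        results = [normalized_distance_index(r) for r in rhos]
        idx = [r.normalized_distance_index for r in results]
        shells = [r.shell_index for r in results]
        assert idx == sorted(idx)
        assert shells == sorted(shells)

    def test_uniform_volume_population_is_flat(self, rng):
        # uniform points in a random ellipsoid -> uniform volume-mode index
        from scipy import stats as ss

        nuc = random_ellipsoid(rng)
        n = 20_000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rho = rng.random(n) ** (1 / 3)
        pts = nuc.center + (rho[:, None] * u * nuc.semi_axes) @ nuc.orientation.T
        idx = [
            normalized_distance_index(
                radial_ratio(nuc, Spot(f"s{i}", nuc.nucleus_id, "p", p))
            ).normalized_distance_index
            for i, p in enumerate(pts)
        ]
        ks = ss.kstest(idx, "uniform").statistic
        assert ks < 0.015


class TestFeret:
    def test_parametric(self, ellipsoid_642):
        assert feret_diameter(ellipsoid_642) == 12.0

    def test_voxelized_sphere_within_voxel_diagonal(self):
        nuc = NucleusModel.parametric("s", (0, 0, 0), (5.0, 5.0, 5.0))
        mask = voxelize(nuc)
        diag = math.sqrt(sum(s**2 for s in mask.spacing))
        assert abs(feret_diameter(mask) - 10.0) < diag

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            feret_diameter(VoxelMask(np.zeros((4, 4, 4), dtype=bool)))
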
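"""Heaviside/delta regularization, initialization, curvature, masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridac import (
    ConfigurationError,
    ParameterError,
    curvature,
    delta_eps,
    heaviside_eps,
    init_levelset,
    mask_from_levelset,
    orient_levelset,
    region_mask,
)
from hybridac.evolve import length_term


class TestHeavisideDelta:
    def test_heaviside_values(self):
        assert heaviside_eps(0.0, 1.0) == pytest.approx(0.5)
        assert heaviside_eps(0.0, 17.3) == pytest.approx(0.5)
        assert heaviside_eps(1.0, 1.0) == pytest.approx(0.75)  # atan(1) = pi/4

    @given(st.floats(-1e6, 1e6), st.floats(1e-3, 1e3))
    @settings(max_examples=200, deadline=None)
    def test_heaviside_antisymmetry_and_range(self, z, eps):
        h = heaviside_eps(z, eps)
        assert 0.0 < h < 1.0
        assert h + heaviside_eps(-z, eps) == pytest.approx(1.0, abs=1e-14)

    def test_heaviside_monotone(self, rng):
        z = np.sort(rng.uniform(-50, 50, 1000))
        h = heaviside_eps(z, 0.7)
        assert np.all(np.diff(h) >= 0)

    def test_delta_values_and_symmetry(self, rng):
        assert delta_eps(0.0, 2.0) == pytest.approx(1.0 / (np.pi * 2.0))
        z = rng.uniform(-10, 10, 100)
        assert np.allclose(delta_eps(z, 1.3), delta_eps(-z, 1.3))
        assert np.all(delta_eps(z, 1.3) > 0)

    def test_delta_integrates_to_one(self):
        z = np.linspace(-1000, 1000, 2_000_001)
        total = np.trapezoid(delta_eps(z, 1.0), z)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_delta_is_heaviside_derivative(self):
        h = 1e-5
        for z in [-3.2, -0.4, 0.0, 0.7, 5.1]:
            num = (heaviside_eps(z + h, 1.5) - heaviside_eps(z - h, 1.5)) / (2 * h)
            assert num == pytest.approx(delta_eps(z, 1.5), abs=1e-6)

    @pytest.mark.parametrize("fn", [heaviside_eps, delta_eps])
    @pytest.mark.parametrize("bad_eps", [0.0, -1.0])
    def test_nonpositive_eps_rejected(self, fn, bad_eps):
        with pytest.raises(ParameterError):
            fn(0.5, bad_eps)


class TestInitLevelset:
    def test_circle_step_function(self):
        phi = init_levelset((8, 8), ("circle", 4, 4, 2), c0=2.0)
        assert set(np.unique(phi)) == {-2.0, 2.0}
        rows, cols = np.mgrid[0:8, 0:8]
        inside = (rows - 4) ** 2 + (cols - 4) ** 2 <= 4
        assert np.array_equal(phi > 0, inside)

    def test_string_grammar_matches_tuple(self):
        a = init_levelset((20, 30), "circle:10,15,6")
        b = init_levelset((20, 30), ("circle", 10, 15, 6))
        assert np.array_equal(a, b)
        r = init_levelset((20, 30), "rect:2,3,10,12")
        assert (r > 0).sum() == 8 * 9  # half-open ranges

    def test_mask_roundtrip_identity(self, rng):
        mask = rng.random((12, 13)) > 0.6
        mask[0, 0] = True
        mask[-1, -1] = False
        phi = init_levelset(mask.shape, mask, c0=3.0)
        assert np.array_equal(mask_from_levelset(phi), mask)

    def test_invert_flag(self):
        phi = init_levelset((8, 8), "circle:4,4,2", invert=True)
        assert phi[4, 4] < 0

    def test_degenerate_regions_rejected(self):
        with pytest.raises(ConfigurationError):
            init_levelset((8, 8), np.ones((8, 8), bool))
        with pytest.raises(ConfigurationError):
            init_levelset((8, 8), np.zeros((8, 8), bool))
        with pytest.raises(ConfigurationError):
            init_levelset((8, 8), "circle:-5,-5,1")  # empty

    def test_bad_region_spec(self):
        with pytest.raises(ConfigurationError):
            region_mask((8, 8), "blob:1,2,3")
        with pytest.raises(ConfigurationError):
            region_mask((8, 8), np.zeros((4, 4), bool))

    def test_orient_levelset_picks_bright_interior(self):
        img = np.full((16, 16), 0.2)
        img[4:12, 4:12] = 0.9
        phi = init_levelset((16, 16), "rect:4,4,12,12")
        assert np.array_equal(orient_levelset(img, phi), phi)
        assert np.array_equal(orient_levelset(1.0 - img, phi), -phi)


class TestCurvature:
    def test_affine_field_is_flat(self):
        rows, cols = np.mgrid[0:30, 0:30].astype(float)
        kap = curvature(rows + 2.0 * cols)
        assert np.abs(kap[2:-2, 2:-2]).max() < 1e-6

    def test_constant_field_is_zero(self):
        assert np.abs(curvature(np.full((20, 20), 3.0))).max() == 0.0

    def test_circle_curvature_near_1_over_R(self):
        R = 20.0
        rows, cols = np.mgrid[0:101, 0:101].astype(float)
        phi = R - np.hypot(rows - 50, cols - 50)  # signed distance, >0 inside
        kap = curvature(phi)
        r_pix = np.hypot(rows - 50, cols - 50)
        near = np.abs(r_pix - R) < 2.0
        # level lines of R - distance have kappa = -1/r at radius r
        assert np.abs(-kap[near] * r_pix[near] - 1.0).max() < 0.1  # within 10%

    def test_length_of_circle_contour(self):
        R = 20.0
        rows, cols = np.mgrid[0:101, 0:101].astype(float)
        phi = R - np.hypot(rows - 50, cols - 50)
        est = length_term(phi, eps=1.0)
        assert est == pytest.approx(2 * np.pi * R, rel=0.15)

    def test_length_constant_field_zero(self):
        assert length_term(np.full((40, 40), 1.7), eps=1.0) == 0.0

    def test_length_penalizes_wiggles(self):
        rows, cols = np.mgrid[0:101, 0:101].astype(float)
        d = np.hypot(rows - 50, cols - 50)
        theta = np.arctan2(rows - 50, cols - 50)
        smooth = 20.0 - d
        wiggly = 20.0 + 4.0 * np.sin(8 * theta) - d
        assert length_term(wiggly, 1.0) > length_term(smooth, 1.0)


class TestMask:
    def test_zero_phi_counts_as_outside(self):
        phi = np.array([[-1.0, 0.0], [0.5, 2.0]])
        assert np.array_equal(mask_from_levelset(phi), [[False, False], [True, True]])

    def test_all_negative(self):
        assert not mask_from_levelset(-np.ones((5, 5))).any()
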
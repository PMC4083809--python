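"""Ball kernel, localized statistics, energies and force vs brute-force oracles."""

import numpy as np
import pytest

from hybridac import (
    ParameterError,
    ball_kernel,
    global_means,
    init_levelset,
    local_energy,
    local_force,
    local_residual_energy,
    local_stats,
)
from hybridac.local_energy import (
    local_energy_bruteforce,
    local_force_bruteforce,
    local_residual_energy_bruteforce,
    local_stats_bruteforce,
)


def random_instance(rng, shape=(24, 24)):
    I = rng.random(shape)
    phi = rng.uniform(-3, 3, shape)
    return I, phi


class TestBallKernel:
    def test_r1_is_single_pixel(self):
        k = ball_kernel(1.0)
        assert k.size == 1
        assert k.window[k.k, k.k] == 1.0

    def test_r15_includes_full_3x3(self):
        # norms 0, 1 and sqrt(2)~1.414 are all < 1.5
        k = ball_kernel(1.5)
        assert k.size == 9

    def test_count_matches_double_loop(self):
        r = 9.0
        k = ball_kernel(r)
        count = 0
        kk = int(np.ceil(r))
        for dy in range(-kk, kk + 1):
            for dx in range(-kk, kk + 1):
                if np.hypot(dy, dx) < r:
                    count += 1
        assert k.size == count
        assert k.window.shape == (2 * kk + 1, 2 * kk + 1)

    def test_symmetry(self):
        w = ball_kernel(4.3).window
        assert np.array_equal(w, w.T)
        assert np.array_equal(w, w[::-1, ::-1])

    def test_small_radius_rejected(self):
        with pytest.raises(ParameterError):
            ball_kernel(0.5)


class TestLocalStats:
    def test_oracle_equivalence(self, rng):
        I, phi = random_instance(rng, (32, 32))
        k = ball_kernel(4.5)
        fast = local_stats(I, phi, k, 1.0)
        slow = local_stats_bruteforce(I, phi, k, 1.0)
        for name in ("u", "v", "au", "av"):
            assert np.abs(getattr(fast, name) - getattr(slow, name)).max() < 1e-10

    def test_conservation_of_ball_mass(self, rng):
        I, phi = random_instance(rng)
        k = ball_kernel(3.5)
        st = local_stats(I, phi, k, 1.0)
        assert np.allclose(st.au + st.av, float(k.size), atol=1e-9)

    def test_reduction_to_global_means(self, rng):
        I = rng.random((16, 16))
        phi = rng.uniform(-2, 2, (16, 16))
        k = ball_kernel(30.0)  # radius exceeds the image diagonal
        st = local_stats(I, phi, k, 1.0, mode="constant")
        g = global_means(I, phi, 1.0)
        assert np.abs(st.u - g.m).max() < 1e-6
        assert np.abs(st.v - g.n).max() < 1e-6

    def test_constant_image_means_equal(self):
        I = np.full((20, 20), 0.63)
        phi = init_levelset((20, 20), "circle:10,10,6")
        st = local_stats(I, phi, ball_kernel(5.0), 1.0)
        ok = st.u_defined & st.v_defined
        assert np.allclose(st.u[ok], 0.63) and np.allclose(st.v[ok], 0.63)

    def test_transpose_symmetry(self, rng):
        I, phi = random_instance(rng, (20, 26))
        k = ball_kernel(3.5)
        a = local_stats(I, phi, k, 1.0)
        b = local_stats(I.T, phi.T, k, 1.0)
        for name in ("u", "v", "au", "av"):
            assert np.allclose(getattr(a, name).T, getattr(b, name), atol=1e-11)


class TestLocalEnergies:
    def test_constant_image_zero_separation(self):
        I = np.full((18, 18), 0.4)
        phi = init_levelset(I.shape, "circle:9,9,5")
        assert local_energy(I, phi, ball_kernel(4.0), 1.0) == pytest.approx(0.0, abs=1e-18)

    def test_energy_matches_double_loop(self, rng):
        I, phi = random_instance(rng, (16, 16))
        k = ball_kernel(3.5)
        assert local_energy(I, phi, k, 1.0) == pytest.approx(
            local_energy_bruteforce(I, phi, k, 1.0), abs=1e-9
        )

    def test_residual_energy_matches_double_loop(self, rng):
        I, phi = random_instance(rng, (16, 16))
        k = ball_kernel(3.5)
        assert local_residual_energy(I, phi, k, 1.0) == pytest.approx(
            local_residual_energy_bruteforce(I, phi, k, 1.0), abs=1e-9
        )

    def test_separation_maximal_at_ground_truth(self, two_phase_16x16):
        I, truth = two_phase_16x16
        k = ball_kernel(4.0)
        candidates = {
            "truth": init_levelset(I.shape, truth),
            "shifted": init_levelset(I.shape, "rect:6,6,14,14"),
            "half": init_levelset(I.shape, "rect:0,0,16,8"),
        }
        energies = {n: local_energy(I, p, k, 1.0) for n, p in candidates.items()}
        assert energies["truth"] == max(energies.values())


class TestLocalForce:
    def test_oracle_equivalence(self, rng):
        I, phi = random_instance(rng, (24, 24))
        k = ball_kernel(3.5)
        st = local_stats(I, phi, k, 1.0)
        fast = local_force(I, phi, st, k, 1.0)
        slow = local_force_bruteforce(I, phi, k, 1.0)
        assert np.abs(fast - slow).max() < 1e-8

    def test_constant_image_zero_force(self):
        I = np.full((20, 20), 0.5)
        phi = init_levelset(I.shape, "circle:10,10,6")
        k = ball_kernel(4.0)
        st = local_stats(I, phi, k, 1.0)
        assert np.abs(local_force(I, phi, st, k, 1.0)).max() < 1e-12

    def test_vanishes_far_from_contour_when_sharp(self, two_phase_16x16):
        I, truth = two_phase_16x16
        phi = init_levelset(I.shape, truth, c0=2.0)
        k = ball_kernel(3.0)
        eps = 0.01
        st = local_stats(I, phi, k, eps)
        F = local_force(I, phi, st, k, eps)
        # interior pixels whose ball does not reach the contour
        assert abs(F[7, 7]) < 1e-4
        assert abs(F[0, 0]) < 1e-4

    def test_transpose_symmetry(self, rng):
        I, phi = random_instance(rng, (20, 26))
        k = ball_kernel(3.5)
        a = local_force(I, phi, local_stats(I, phi, k, 1.0), k, 1.0)
        b = local_force(I.T, phi.T, local_stats(I.T, phi.T, k, 1.0), k, 1.0)
        assert np.allclose(a.T, b, atol=1e-11)
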
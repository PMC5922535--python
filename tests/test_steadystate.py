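"""Harmonic-balance residual, Jacobian, Newton solver, and resonance."""

import numpy as np
import pytest

import critnet as cn
from critnet.errors import InvalidArgumentError, SingularJacobianError

from conftest import random_skew


@pytest.fixture(scope="module")
def ring8():
    conn = cn.build_ring_connectivity(8, 1.0)
    mode = cn.spectrum(conn)[0]
    return conn, mode


class TestForcingPattern:
    def test_single_neuron_window(self, line64_modes):
        mode = line64_modes[0]
        fp = cn.forcing_pattern(mode, 10, 0, 2.0)
        assert np.count_nonzero(fp.vector) == 1
        assert fp.vector[10] == 2.0 * mode.eigenvector[10]
        assert fp.input_length == 1

    def test_full_coverage_clips(self, line64_modes):
        mode = line64_modes[0]
        fp = cn.forcing_pattern(mode, 32, 40, 1.5)
        assert np.allclose(fp.vector, 1.5 * mode.eigenvector)
        assert fp.input_length == 64

    def test_zero_strength(self, line64_modes):
        fp = cn.forcing_pattern(line64_modes[0], 32, 5, 0.0)
        assert np.all(fp.vector == 0)

    def test_window_size(self, line64_modes):
        fp = cn.forcing_pattern(line64_modes[0], 32, 5, 1.0)
        assert np.count_nonzero(fp.vector) == 11

    def test_out_of_range_center(self, line64_modes):
        with pytest.raises(InvalidArgumentError):
            cn.forcing_pattern(line64_modes[0], 64, 1, 1.0)


class TestResidual:
    def test_scalar_cubic_balance(self, single_oscillator):
        g = cn.residual(np.array([2.0 + 0j]), single_oscillator, 0.0, np.array([8.0 + 0j]))
        assert g[0] == 0

    def test_zero_amplitude_returns_forcing(self, line64):
        F = np.arange(64).astype(complex)
        g = cn.residual(np.zeros(64, complex), line64, 0.7, F)
        assert np.array_equal(g, F)

    def test_ring_resonant_closed_form(self, ring8):
        """F = B v at the eigenfrequency balances Z = (NB)^{1/3} v exactly."""
        conn, mode = ring8
        B = 0.7
        Z = (8 * B) ** (1 / 3) * mode.eigenvector
        g = cn.residual(Z, conn, mode.omega, B * mode.eigenvector)
        assert np.max(np.abs(g)) < 1e-10

    def test_length_mismatch(self, line64):
        with pytest.raises(InvalidArgumentError):
            cn.residual(np.zeros(32, complex), line64, 0.0, np.zeros(64, complex))


class TestJacobian:
    def test_single_oscillator_real_amplitude(self, single_oscillator):
        u = 1.7
        J = cn.jacobian_realified(np.array([u + 0j]), single_oscillator, 0.0)
        assert np.allclose(J, [[-3 * u * u, 0.0], [0.0, -u * u]])

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(42)
        N = 6
        conn = cn.custom_connectivity(random_skew(N, 3))
        Z = rng.standard_normal(N) + 1j * rng.standard_normal(N)
        omega = 0.9
        J = cn.jacobian_realified(Z, conn, omega)
        F = np.zeros(N, complex)
        y0 = np.concatenate([Z.real, Z.imag])
        eps = 1e-6

        def g(y):
            z = y[:N] + 1j * y[N:]
            r = cn.residual(z, conn, omega, F)
            return np.concatenate([r.real, r.imag])

        Jfd = np.empty((2 * N, 2 * N))
        for k in range(2 * N):
            e = np.zeros(2 * N)
            e[k] = eps
            Jfd[:, k] = (g(y0 + e) - g(y0 - e)) / (2 * eps)
        assert np.max(np.abs(J - Jfd)) < 1e-6

    def test_singular_at_origin_on_resonance(self, line64, line64_modes):
        J = cn.jacobian_realified(np.zeros(64, complex), line64, line64_modes[0].omega)
        assert np.linalg.svd(J, compute_uv=False)[-1] < 1e-8


class TestNewtonSolve:
    def test_cube_root(self, single_oscillator):
        st = cn.newton_solve(
            single_oscillator, 0.0, np.array([8.0 + 0j]), initial_guess=np.array([1.0 + 0j])
        )
        assert st.converged
        assert abs(st.amplitude[0] - 2.0) < 1e-10

    @pytest.mark.parametrize("B", [1e-3, 1.0, 1e3])
    def test_resonant_cubic_compression(self, single_oscillator, B):
        st = cn.newton_solve(single_oscillator, 0.0, np.array([B + 0j]))
        assert st.converged
        assert abs(st.amplitude[0]) == pytest.approx(B ** (1 / 3), rel=1e-10)

    def test_ring_resonant_solution(self, ring8):
        conn, mode = ring8
        B = 0.3
        st = cn.newton_solve(conn, mode.omega, B * mode.eigenvector)
        assert st.converged
        expected = (8 * B) ** (1 / 3) * np.abs(mode.eigenvector)
        assert np.max(np.abs(np.abs(st.amplitude) - expected)) < 1e-8

    def test_singular_jacobian_from_zero_guess(self, line64, line64_modes):
        mode = line64_modes[0]
        F = cn.forcing_pattern(mode, 32, 5, 1.0).vector
        with pytest.raises(SingularJacobianError):
            cn.newton_solve(line64, mode.omega, F, initial_guess=np.zeros(64, complex))

    def test_non_converged_flagged(self, line64, line64_modes):
        mode = line64_modes[0]
        F = cn.forcing_pattern(mode, 32, 5, 1.0).vector
        st = cn.newton_solve(line64, mode.omega, F, max_iterations=1)
        assert not st.converged
        assert st.iterations == 1

    def test_dc_mode_real_solution(self):
        """Odd network, omega = 0: the amplitude equation is real."""
        conn = cn.build_line_connectivity(9, 1.0)
        mode = min(cn.spectrum(conn), key=lambda m: m.omega)
        assert mode.omega == 0.0
        F = cn.forcing_pattern(mode, 4, 4, 0.5).vector
        st = cn.newton_solve(conn, 0.0, F)
        assert st.converged
        assert np.max(np.abs(st.amplitude.imag)) == 0.0

    def test_gauge_invariance(self, line64, line64_modes):
        """A global phase on F rotates Z by the same phase."""
        mode = line64_modes[2]
        F = cn.forcing_pattern(mode, 32, 8, 0.5).vector
        st1 = cn.newton_solve(line64, mode.omega, F)
        phi = np.exp(1j * np.pi / 3)
        st2 = cn.newton_solve(line64, mode.omega, phi * F)
        assert st1.converged and st2.converged
        assert np.max(np.abs(st2.amplitude - phi * st1.amplitude)) < 1e-8

    def test_scaling_covariance(self):
        """(A, omega, F) -> (sigma A, sigma omega, sigma^{3/2} F) maps Z -> sigma^{1/2} Z."""
        sigma = 4.0
        conn1 = cn.build_line_connectivity(16, 1.0)
        conn2 = cn.build_line_connectivity(16, sigma)
        mode = cn.spectrum(conn1)[1]
        F = cn.forcing_pattern(mode, 8, 4, 0.7).vector
        st1 = cn.newton_solve(conn1, mode.omega, F)
        st2 = cn.newton_solve(conn2, sigma * mode.omega, sigma**1.5 * F)
        assert st1.converged and st2.converged
        assert np.max(np.abs(st2.amplitude - np.sqrt(sigma) * st1.amplitude)) < 1e-7


class TestContinuationSweep:
    def test_single_oscillator_grid(self, single_oscillator):
        mode = cn.EigenMode(
            omega=0.0, eigenvector=np.ones(1, complex), mode_rank=1, spatial_frequency=0.0
        )
        strengths = [2.0**i for i in range(-6, 4)]
        grid = cn.continuation_sweep(single_oscillator, mode, 0, strengths, [0])
        for B, row in zip(strengths, grid):
            assert row[0].converged
            assert abs(row[0].amplitude[0]) == pytest.approx(B ** (1 / 3), rel=1e-9)

    def test_full_grid_converges_and_warm_start_helps(self, line64, line64_modes):
        mode = line64_modes[5]
        strengths = [0.25, 1.0, 4.0]
        half_lengths = list(range(0, 33, 4))
        grid = cn.continuation_sweep(line64, mode, 32, strengths, half_lengths)
        warm_iters = []
        for row in grid:
            for state in row:
                assert state.converged
                warm_iters.append(state.iterations)
        cold_iters = []
        for B in strengths:
            for l in half_lengths:
                F = cn.forcing_pattern(mode, 32, l, B).vector
                cold_iters.append(cn.newton_solve(line64, mode.omega, F).iterations)
        assert np.median(warm_iters) <= np.median(cold_iters)

    def test_rejects_unsorted(self, single_oscillator):
        mode = cn.EigenMode(
            omega=0.0, eigenvector=np.ones(1, complex), mode_rank=1, spatial_frequency=0.0
        )
        with pytest.raises(InvalidArgumentError):
            cn.continuation_sweep(single_oscillator, mode, 0, [1.0, 0.5], [0])


class TestStability:
    def test_single_oscillator_stable(self, single_oscillator):
        F = np.array([2.0 + 0j])
        st = cn.newton_solve(single_oscillator, 0.0, F)
        assert cn.verify_stability(st, single_oscillator, F)
        assert cn.linear_stability(st, single_oscillator)

    def test_corrupted_state_not_certified(self, single_oscillator):
        F = np.array([2.0 + 0j])
        st = cn.newton_solve(single_oscillator, 0.0, F)
        fake = cn.SteadyState(
            amplitude=st.amplitude * 1.1,
            omega=0.0,
            residual_norm=0.0,
            iterations=0,
            converged=True,
        )
        assert not cn.verify_stability(fake, single_oscillator, F)

    def test_ring_resonant_stable(self, ring8):
        conn, mode = ring8
        F = 0.5 * mode.eigenvector
        st = cn.newton_solve(conn, mode.omega, F)
        assert cn.verify_stability(st, conn, F)


class TestResonanceProfile:
    def test_peak_at_resonance(self):
        B = 1.0
        grid = np.linspace(-4, 4, 401)
        prof = cn.resonance_profile(B, grid)
        assert prof.responses.max() == pytest.approx(B ** (1 / 3), rel=1e-8)
        assert abs(prof.frequency_grid[np.argmax(prof.responses)]) < 0.05

    def test_halfwidth_scaling(self):
        """Gamma ~ B^{2/3}: an 8-fold strength ratio quadruples the width."""

        def gamma(B):
            w = 6 * B ** (2 / 3)
            return cn.resonance_profile(B, np.linspace(-w, w, 801)).halfwidth

        assert gamma(8.0) / gamma(1.0) == pytest.approx(4.0, rel=0.02)

    def test_profile_symmetric(self):
        grid = np.linspace(-3, 3, 301)
        prof = cn.resonance_profile(0.5, grid)
        assert np.allclose(prof.responses, prof.responses[::-1], rtol=1e-6)

    def test_unbracketed_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cn.resonance_profile(1.0, np.linspace(-0.1, 0.1, 11))
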
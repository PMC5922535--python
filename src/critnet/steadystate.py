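"""Forced limit cycles by harmonic balance and damped Newton iteration.

Under monochromatic input ``I(t) = F e^{i omega t}`` the normal-form network

    dx_i/dt = sum_j A_ij x_j - |x_i|^2 x_i + I_i(t)

admits limit-cycle solutions ``X(t) = Z e^{i omega t}``.  Substituting the
ansatz reduces the stiff ODE to the algebraic harmonic-balance equation

    g(Z) = (A - i omega I) Z - |Z|^2 ∘ Z + F = 0,

solved here with a damped multivariable Newton-Raphson iteration on the
realified (2N-dimensional) system.  The forcing patterns are windowed
eigenvector segments: ``F_k = B v_k`` on a window of ``2l+1`` neurons around
a center ``c`` and zero elsewhere, with input strength ``B`` proportional to
stimulus contrast.

At resonance (``omega`` an eigenfrequency) the response follows the
cubic-root compression law of the critical Hopf oscillator: ``|Z| = B^{1/3}``
for a single oscillator, with resonance half-width ``Gamma ∝ B^{2/3}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import lu_factor, lu_solve
from scipy.linalg.lapack import dgecon

from .errors import (
    DivergenceError,
    InvalidArgumentError,
    NumericalFailureError,
    SingularJacobianError,
)
from .network import ConnectivityMatrix, EigenMode

__all__ = [
    "ForcingPattern",
    "SteadyState",
    "ResonanceProfile",
    "forcing_pattern",
    "residual",
    "jacobian_realified",
    "newton_solve",
    "continuation_sweep",
    "verify_stability",
    "linear_stability",
    "resonance_profile",
    "DEFAULT_TOLERANCE",
    "DEFAULT_MAX_ITERATIONS",
]

DEFAULT_TOLERANCE = 1e-10
DEFAULT_MAX_ITERATIONS = 100
_MAX_HALVINGS = 20


@dataclass(frozen=True)
class ForcingPattern:
    """Windowed eigenvector input ``F_k = B v_k`` for ``k in [c-l, c+l]``.

    ``strength`` is linear in stimulus contrast; ``2*half_length + 1`` is
    the input length in number of neurons before boundary clipping.
    """

    strength: float
    center: int
    half_length: int
    mode: EigenMode
    vector: np.ndarray = field(repr=False)

    @property
    def input_length(self) -> int:
        """Covered neurons after clipping at the network boundary."""
        N = len(self.vector)
        lo = max(0, self.center - self.half_length)
        hi = min(N - 1, self.center + self.half_length)
        return hi - lo + 1


@dataclass(frozen=True)
class SteadyState:
    """A (possibly non-converged) harmonic-balance solution with diagnostics."""

    amplitude: np.ndarray = field(repr=False)
    omega: float
    residual_norm: float
    iterations: int
    converged: bool
    stable: bool | None = None

    def response(self, neuron: int) -> float:
        """Response modulus |Z_c| of the readout neuron."""
        return float(np.abs(self.amplitude[neuron]))


@dataclass(frozen=True)
class ResonanceProfile:
    """|Z(omega)| of a single resonantly forced critical oscillator."""

    strength: float
    frequency_grid: np.ndarray
    responses: np.ndarray
    halfwidth: float


def forcing_pattern(
    mode: EigenMode,
    center: int,
    half_length: int,
    strength: float,
) -> ForcingPattern:
    """Build ``F_k = B v_k`` on the window ``[c-l, c+l]`` (clipped), else 0."""
    v = mode.eigenvector
    N = len(v)
    if not 0 <= center < N:
        raise InvalidArgumentError(f"center {center} outside [0, {N - 1}]")
    if half_length < 0:
        raise InvalidArgumentError("half_length must be nonnegative")
    if strength < 0:
        raise InvalidArgumentError("strength must be nonnegative")
    F = np.zeros(N, dtype=complex)
    lo = max(0, center - half_length)
    hi = min(N - 1, center + half_length)
    F[lo : hi + 1] = strength * v[lo : hi + 1]
    return ForcingPattern(
        strength=float(strength),
        center=int(center),
        half_length=int(half_length),
        mode=mode,
        vector=F,
    )


def residual(
    amplitude: np.ndarray,
    connectivity: ConnectivityMatrix,
    omega: float,
    forcing: np.ndarray,
) -> np.ndarray:
    """Harmonic-balance residual ``g(Z) = (A - i omega) Z - |Z|^2 ∘ Z + F``."""
    Z = np.asarray(amplitude, dtype=complex)
    F = np.asarray(forcing, dtype=complex)
    A = connectivity.entries
    if Z.shape != (connectivity.n_neurons,) or F.shape != Z.shape:
        raise InvalidArgumentError(
            f"shape mismatch: Z {Z.shape}, F {F.shape}, N={connectivity.n_neurons}"
        )
    return A @ Z - 1j * omega * Z - (np.abs(Z) ** 2) * Z + F


def _realify(Z: np.ndarray) -> np.ndarray:
    return np.concatenate([Z.real, Z.imag])


def _complexify(y: np.ndarray) -> np.ndarray:
    n = len(y) // 2
    return y[:n] + 1j * y[n:]


def jacobian_realified(
    amplitude: np.ndarray,
    connectivity: ConnectivityMatrix,
    omega: float,
) -> np.ndarray:
    """Analytic Jacobian of the realified residual, shape (2N, 2N).

    With ``Z = u + i v`` the residual splits into

        Re g = A u + omega v - (u^2 + v^2) u + Re F
        Im g = A v - omega u - (u^2 + v^2) v + Im F

    whose Jacobian combines ``A``, ``±omega I`` and diagonal cubic terms.
    """
    Z = np.asarray(amplitude, dtype=complex)
    A = connectivity.entries
    N = connectivity.n_neurons
    if Z.shape != (N,):
        raise InvalidArgumentError(f"amplitude shape {Z.shape} != ({N},)")
    u, v = Z.real, Z.imag
    J = np.zeros((2 * N, 2 * N))
    I = np.eye(N)
    J[:N, :N] = A - np.diag(3 * u * u + v * v)
    J[:N, N:] = omega * I - np.diag(2 * u * v)
    J[N:, :N] = -omega * I - np.diag(2 * u * v)
    J[N:, N:] = A - np.diag(u * u + 3 * v * v)
    return J


def _default_seed(forcing: np.ndarray) -> np.ndarray:
    """Componentwise signed cube root of the forcing.

    Newton cannot start from Z = 0 at an eigenfrequency (singular Jacobian);
    the cube-root seed matches the resonant balance |Z|^2 Z = F and is exact
    in the uniform-mode limit.  Unforced components receive a small
    background (1e-3 of the seed scale): at a degenerate eigenfrequency a
    narrowly windowed seed can leave part of the (A - i omega) nullspace
    unlifted by the cubic terms, and the background moves the start off
    that singular manifold.
    """
    F = np.asarray(forcing, dtype=complex)
    mag = np.cbrt(np.abs(F))
    with np.errstate(invalid="ignore", divide="ignore"):
        phase = np.where(np.abs(F) > 0, F / np.where(np.abs(F) > 0, np.abs(F), 1.0), 0)
    seed = mag * phase
    if mag.max() > 0:
        seed[np.abs(F) == 0] = 1e-3 * mag.max()
    return seed


def newton_solve(
    connectivity: ConnectivityMatrix,
    omega: float,
    forcing: np.ndarray,
    initial_guess: np.ndarray | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    damping: bool = True,
) -> SteadyState:
    """Damped Newton-Raphson on the realified harmonic-balance system.

    Convergence criterion is the max-norm of the realified residual.  When a
    full Newton step does not decrease the residual norm the step is halved
    (up to 20 times); with damping disabled the update is the plain
    iteration ``Z <- Z - J^{-1} g``.

    For a DC drive (``omega == 0`` with real forcing, the odd-N zero mode)
    the amplitude equation is real and the iteration runs on the
    N-dimensional real system; the returned amplitude is real.
    """
    if tolerance <= 0:
        raise InvalidArgumentError("tolerance must be positive")
    if max_iterations < 1:
        raise InvalidArgumentError("max_iterations must be >= 1")
    F = np.asarray(forcing, dtype=complex)
    N = connectivity.n_neurons
    A = connectivity.entries
    dc = omega == 0.0 and np.max(np.abs(F.imag)) == 0.0

    Z = _default_seed(F) if initial_guess is None else np.asarray(initial_guess, dtype=complex)
    if dc:
        Z = Z.real.astype(float)

    def res_vec(Zc):
        if dc:
            return A @ Zc - Zc**3 + F.real
        g = residual(Zc, connectivity, omega, F)
        return _realify(g)

    def jac(Zc):
        if dc:
            return A - np.diag(3 * Zc * Zc)
        return jacobian_realified(Zc, connectivity, omega)

    g = res_vec(Z)
    rnorm = float(np.max(np.abs(g)))
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        if rnorm <= tolerance:
            iterations -= 1
            break
        J = jac(Z)
        try:
            lu, piv = lu_factor(J)
            rcond, _ = dgecon(lu, np.linalg.norm(J, 1), norm="1")
            if rcond < 1e-14:
                raise np.linalg.LinAlgError(f"rcond {rcond:.2e}")
            step = lu_solve((lu, piv), g)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise SingularJacobianError(
                f"singular Jacobian at iteration {iterations}", iterate=Z.copy()
            ) from exc
        if not np.all(np.isfinite(step)):
            raise SingularJacobianError(
                f"non-finite Newton step at iteration {iterations}", iterate=Z.copy()
            )
        if dc:
            dZ = step
        else:
            dZ = _complexify(step)
        lam = 1.0
        for _ in range(_MAX_HALVINGS + 1):
            Znew = Z - lam * dZ
            gnew = res_vec(Znew)
            rnew = float(np.max(np.abs(gnew)))
            if not damping or rnew < rnorm:
                break
            lam *= 0.5
        Z, g, rnorm = Znew, gnew, rnew
        if not np.all(np.isfinite(Z)):
            raise DivergenceError("iterate became non-finite", iterate=Z)
    converged = rnorm <= tolerance
    return SteadyState(
        amplitude=Z.astype(complex),
        omega=float(omega),
        residual_norm=rnorm,
        iterations=iterations,
        converged=bool(converged),
    )


def continuation_sweep(
    connectivity: ConnectivityMatrix,
    mode: EigenMode,
    center: int,
    strengths,
    half_lengths,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> list[list[SteadyState]]:
    """Warm-started Newton grid over (strength, half_length).

    Returns ``grid[si][li]``.  Each solve is warm-started from the nearest
    previously solved neighbor (same strength, previous half-length, else
    previous strength, same half-length); the first cell uses the cube-root
    seed.  Non-converged cells are kept in place (flagged on the
    SteadyState) so callers can report their grid coordinates.
    """
    strengths = list(strengths)
    half_lengths = list(half_lengths)
    if not strengths or not half_lengths:
        raise InvalidArgumentError("strengths and half_lengths must be nonempty")
    if sorted(strengths) != strengths or sorted(half_lengths) != half_lengths:
        raise InvalidArgumentError("strengths and half_lengths must be ascending")
    grid: list[list[SteadyState]] = []
    for si, B in enumerate(strengths):
        row: list[SteadyState] = []
        for li, l in enumerate(half_lengths):
            F = forcing_pattern(mode, center, l, B).vector
            guess = None
            if li > 0 and row[li - 1].converged:
                guess = row[li - 1].amplitude
            elif si > 0 and grid[si - 1][li].converged:
                guess = grid[si - 1][li].amplitude
            state = newton_solve(
                connectivity,
                mode.omega,
                F,
                initial_guess=guess,
                tolerance=tolerance,
                max_iterations=max_iterations,
            )
            row.append(state)
        grid.append(row)
    return grid


def linear_stability(
    state: SteadyState,
    connectivity: ConnectivityMatrix,
    margin: float = 1e-9,
) -> bool:
    """Linear (Jacobian-eigenvalue) stability of the rotating-frame fixed point.

    True when every eigenvalue of the realified Jacobian at Z has real part
    below ``margin``.  Cheap screen used by the experiment sweeps; the
    integration-based certificate is :func:`verify_stability`.
    """
    J = jacobian_realified(state.amplitude, connectivity, state.omega)
    lam = np.linalg.eigvals(J)
    return bool(np.max(lam.real) < margin)


def verify_stability(
    state: SteadyState,
    connectivity: ConnectivityMatrix,
    forcing: np.ndarray,
    rel_perturbation: float = 1e-3,
    capture_tol: float = 1e-6,
    max_time: float | None = None,
) -> bool:
    """Integration certificate: perturb Z and watch the flow return.

    The rotating-frame dynamics are integrated from ``Z`` perturbed by a
    relative ``1e-3``; the state is declared stable iff the trajectory
    re-enters a ``1e-6`` max-norm neighborhood of ``Z``.  A corrupted
    "steady state" that is not actually a fixed point drifts away instead
    and is not certified.
    """
    if not state.converged:
        raise InvalidArgumentError("verify_stability requires a converged state")
    Z = state.amplitude
    F = np.asarray(forcing, dtype=complex)
    A = connectivity.entries
    N = connectivity.n_neurons
    omega = state.omega
    scale = float(np.max(np.abs(Z))) or 1.0
    y0 = Z * (1.0 + rel_perturbation) + 0.1 * rel_perturbation * scale * (1 + 1j)

    def rhs(t, y):
        z = _complexify(y)
        g = A @ z - 1j * omega * z - (np.abs(z) ** 2) * z + F
        return _realify(g)

    def jac(t, y):
        return jacobian_realified(_complexify(y), connectivity, omega)

    def captured(t, y):
        return float(np.max(np.abs(_complexify(y) - Z))) - capture_tol

    captured.terminal = True
    captured.direction = -1

    # time to contract the 1e-3 perturbation below 1e-6 at the cubic rate
    if max_time is None:
        rate = max(scale**2, 1e-6)
        max_time = 100.0 / rate
    sol = solve_ivp(
        rhs,
        (0.0, max_time),
        _realify(y0),
        method="BDF",
        jac=jac,
        rtol=1e-9,
        atol=1e-12,
        events=captured,
    )
    if not sol.success:
        raise NumericalFailureError(
            "stability integration failed", details={"message": sol.message}
        )
    if sol.t_events[0].size > 0:
        return True
    return float(np.max(np.abs(_complexify(sol.y[:, -1]) - Z))) <= capture_tol


def resonance_profile(
    strength: float,
    frequency_grid,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ResonanceProfile:
    """Response curve |Z(omega)| of a single critical oscillator (N=1, omega0=0).

    The half-width ``Gamma`` is the frequency span over which the response
    stays at or above half its maximum (crossings located by linear
    interpolation); it scales as ``B^{2/3}``, hence Gamma(8B)/Gamma(B) = 4.
    """
    from .network import custom_connectivity

    if strength <= 0:
        raise InvalidArgumentError("strength must be positive")
    grid = np.asarray(sorted(frequency_grid), dtype=float)
    if grid.size < 3:
        raise InvalidArgumentError("frequency grid needs at least 3 points")
    conn = custom_connectivity(np.zeros((1, 1)))
    F = np.array([strength], dtype=complex)
    resp = np.empty(grid.size)
    guess = None
    for i, om in enumerate(grid):
        st = newton_solve(conn, float(om), F, initial_guess=guess, tolerance=tolerance)
        guess = st.amplitude
        resp[i] = np.abs(st.amplitude[0])
    half = resp.max() / 2.0
    above = resp >= half
    if above[0] or above[-1] or not above.any():
        raise InvalidArgumentError(
            "frequency grid does not bracket the half-maximum response"
        )
    idx = np.where(above)[0]
    i0, i1 = idx[0], idx[-1]
    # interpolate the two half-maximum crossings
    left = np.interp(half, [resp[i0 - 1], resp[i0]], [grid[i0 - 1], grid[i0]])
    right = np.interp(half, [resp[i1 + 1], resp[i1]], [grid[i1 + 1], grid[i1]])
    return ResonanceProfile(
        strength=float(strength),
        frequency_grid=grid,
        responses=resp,
        halfwidth=float(right - left),
    )
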
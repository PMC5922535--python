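"""The three headline analyses of the critically balanced V1 model.

* Length-response curves: steady response ``|Z_c|`` of a center neuron as a
  function of the input length ``2l+1``, per input strength ``B = 2**i``.
  Weak input integrates over the whole network (monotone curves); strong
  input produces a peak followed by surround suppression, and the peak
  shifts to larger lengths as the strength decreases.
* Suppression versus eigenvector position: centers near zeros of the driving
  eigenvector's modulus are suppressed most; antinode centers are barely
  suppressed.
* Decay-constant scaling: transient decay constants grow with input strength
  as ``B^{2/3}``, in a fast regime and (for stronger input) a slow regime.

A ring variant models orientation space: surround suppression in orientation
appears once long-range couplings are added on top of the nearest-neighbor
ring, which make the DC eigenvector spatially periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    DecayFit,
    PowerLawFit,
    fit_decay_segments,
    integrate_rotating_frame,
    power_law_fit,
)
from .errors import FitUndeterminedError, InvalidArgumentError
from .network import ConnectivityMatrix, EigenMode, build_line_connectivity, build_ring_connectivity, spectrum
from .steadystate import (
    SteadyState,
    continuation_sweep,
    forcing_pattern,
    linear_stability,
    newton_solve,
)

__all__ = [
    "LengthResponseCurve",
    "SuppressionMap",
    "DecayScalingResult",
    "length_response_experiment",
    "suppression_vs_position",
    "decay_scaling_experiment",
    "orientation_ring_experiment",
    "envelope_zeros",
    "envelope_antinodes",
    "fig3_preset",
    "fig4_preset",
    "fig56_preset",
    "orientation_ring_preset",
]


@dataclass(frozen=True)
class LengthResponseCurve:
    """Response of one center neuron versus input length, at one strength."""

    omega: float
    strength: float
    center: int
    input_lengths: np.ndarray
    responses: np.ndarray
    converged: np.ndarray = field(repr=False)
    stable: np.ndarray = field(repr=False)

    @property
    def peak_length(self) -> int:
        return int(self.input_lengths[int(np.argmax(self.responses))])

    @property
    def suppression_index(self) -> float:
        """Relative drop from the curve maximum to the longest input.

        ``(max response - response at max length) / max response``; zero for
        monotone (never-peaking) curves.
        """
        peak = float(self.responses.max())
        if peak <= 0:
            return 0.0
        return float((peak - self.responses[-1]) / peak)


@dataclass(frozen=True)
class SuppressionMap:
    """Suppression index per center neuron, with the |v| profile attached."""

    omega: float
    centers: np.ndarray
    suppression_indices: np.ndarray
    eigenvector_modulus: np.ndarray = field(repr=False)
    curves: tuple[LengthResponseCurve, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class DecayScalingResult:
    """Power-law fits of decay constants versus strength, per regime."""

    fast: PowerLawFit
    slow: PowerLawFit | None
    fits: dict = field(repr=False, default_factory=dict)  # strength -> DecayFit
    excluded: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# eigenvector landmark helpers


def envelope_zeros(mode: EigenMode) -> np.ndarray:
    """Indices of local minima of |v| that are deep (below 25% of max)."""
    env = np.abs(mode.eigenvector)
    idx = [
        j
        for j in range(1, len(env) - 1)
        if env[j] <= env[j - 1] and env[j] <= env[j + 1] and env[j] < 0.25 * env.max()
    ]
    return np.array(idx, dtype=int)


def envelope_antinodes(mode: EigenMode) -> np.ndarray:
    """Indices of local maxima of |v| above 75% of the global maximum."""
    env = np.abs(mode.eigenvector)
    idx = [
        j
        for j in range(1, len(env) - 1)
        if env[j] >= env[j - 1] and env[j] >= env[j + 1] and env[j] > 0.75 * env.max()
    ]
    return np.array(idx, dtype=int)


def distance_to_nearest_zero(mode: EigenMode, centers) -> np.ndarray:
    zeros = envelope_zeros(mode)
    if zeros.size == 0:
        return np.full(len(centers), np.nan)
    return np.array([np.min(np.abs(zeros - c)) for c in centers], dtype=float)


# ---------------------------------------------------------------------------
# experiments


def _curve_from_row(
    row: list[SteadyState],
    connectivity: ConnectivityMatrix,
    mode: EigenMode,
    center: int,
    half_lengths,
    strength: float,
    check_stability: bool,
) -> LengthResponseCurve:
    N = connectivity.n_neurons
    lengths = np.array(
        [min(center + l, N - 1) - max(0, center - l) + 1 for l in half_lengths]
    )
    responses = np.array([st.response(center) for st in row])
    converged = np.array([st.converged for st in row])
    if check_stability:
        stable = np.array(
            [st.converged and linear_stability(st, connectivity) for st in row]
        )
    else:
        stable = np.full(len(row), True)
    return LengthResponseCurve(
        omega=mode.omega,
        strength=strength,
        center=center,
        input_lengths=lengths,
        responses=responses,
        converged=converged,
        stable=stable,
    )


def length_response_experiment(
    connectivity: ConnectivityMatrix,
    mode: EigenMode,
    center: int,
    strengths,
    max_half_length: int,
    check_stability: bool = True,
    tolerance: float = 1e-10,
    max_iterations: int = 100,
) -> list[LengthResponseCurve]:
    """One length-response curve per input strength (warm-started Newton grid).

    Every point is a converged steady state of the harmonic-balance
    equation at the mode's eigenfrequency; stability is screened through
    the Jacobian spectrum at each solution when ``check_stability``.
    """
    strengths = sorted(float(B) for B in strengths)
    half_lengths = list(range(0, max_half_length + 1))
    grid = continuation_sweep(
        connectivity,
        mode,
        center,
        strengths,
        half_lengths,
        tolerance=tolerance,
        max_iterations=max_iterations,
    )
    return [
        _curve_from_row(
            row, connectivity, mode, center, half_lengths, B, check_stability
        )
        for B, row in zip(strengths, grid)
    ]


def suppression_vs_position(
    connectivity: ConnectivityMatrix,
    mode: EigenMode,
    centers,
    strength: float,
    max_half_length: int,
    check_stability: bool = True,
) -> SuppressionMap:
    """Suppression index of each center neuron at one (strong) input level."""
    curves = []
    for c in centers:
        curve = length_response_experiment(
            connectivity,
            mode,
            int(c),
            [strength],
            max_half_length,
            check_stability=check_stability,
        )[0]
        curves.append(curve)
    return SuppressionMap(
        omega=mode.omega,
        centers=np.asarray(list(centers), dtype=int),
        suppression_indices=np.array([c.suppression_index for c in curves]),
        eigenvector_modulus=np.abs(mode.eigenvector),
        curves=tuple(curves),
    )


def decay_scaling_experiment(
    connectivity: ConnectivityMatrix,
    mode: EigenMode,
    center: int,
    strengths,
    half_length: int,
    min_segment_points: int = 30,
    fit_floor_rel: float = 1e-7,
    horizon: float = 600.0,
    n_samples: int = 3000,
) -> DecayScalingResult:
    """Decay constants versus input strength, fitted per regime in log-log.

    For each strength the network is driven from rest by the windowed
    eigenvector input, the transient to the limit cycle is integrated in
    the rotating frame, and the readout residual is fitted with the
    one-/two-segment piecewise log-linear model.  Decay constants
    ``b = -slope`` are regressed against ``B`` on a log-log scale, per
    regime.  The integration horizon scales as ``B^{-2/3}`` with the
    expected decay rate.  Strengths yielding no valid decaying segment are
    excluded and reported.
    """
    fits: dict[float, DecayFit] = {}
    excluded = []
    fast_B, fast_b, slow_B, slow_b = [], [], [], []
    for B in sorted(float(b) for b in strengths):
        F = forcing_pattern(mode, center, half_length, B).vector
        state = newton_solve(connectivity, mode.omega, F)
        if not state.converged:
            excluded.append(B)
            continue
        zmax = float(np.max(np.abs(state.amplitude)))
        trace = integrate_rotating_frame(
            connectivity,
            mode.omega,
            F,
            max_time=horizon / B ** (2.0 / 3.0),
            steady_state=state,
            n_samples=n_samples,
        )
        try:
            fit = fit_decay_segments(
                trace,
                state,
                neuron=center,
                min_segment_points=min_segment_points,
                floor=fit_floor_rel * zmax,
            )
        except FitUndeterminedError:
            excluded.append(B)
            continue
        fits[B] = fit
        if fit.fast is not None:
            fast_B.append(B)
            fast_b.append(-fit.fast.slope)
        if fit.slow is not None:
            slow_B.append(B)
            slow_b.append(-fit.slow.slope)
    if len(fast_B) < 3:
        raise FitUndeterminedError("fewer than 3 strengths produced a fast regime")
    fast = power_law_fit(fast_B, fast_b, "fast")
    slow = (
        power_law_fit(slow_B, slow_b, "slow") if len(slow_B) >= 3 else None
    )
    return DecayScalingResult(
        fast=fast, slow=slow, fits=fits, excluded=tuple(excluded)
    )


def orientation_ring_experiment(
    connectivity: ConnectivityMatrix,
    mode: EigenMode,
    center: int,
    strengths,
    max_half_length: int,
    check_stability: bool = True,
) -> list[LengthResponseCurve]:
    """Length-response curves on a ring (arc length = orientation extent).

    Identical protocol to the line experiment; with long-range couplings the
    driving eigenvector becomes spatially periodic and the curves develop
    surround suppression, while the bare nearest-neighbor ring integrates
    monotonically.
    """
    if connectivity.topology != "ring":
        raise InvalidArgumentError("orientation experiment requires ring topology")
    return length_response_experiment(
        connectivity, mode, center, strengths, max_half_length, check_stability
    )


# ---------------------------------------------------------------------------
# figure-scale presets


def _mode_closest_to(modes: list[EigenMode], omega: float) -> EigenMode:
    return min(modes, key=lambda m: abs(m.omega - omega))


def fig3_preset():
    """Line N=64, s=1, center N/2, strengths 2^i for i = -10..2, 6 top modes."""
    conn = build_line_connectivity(64, 1.0)
    modes = spectrum(conn)
    return {
        "connectivity": conn,
        "modes": modes[:6],
        "center": 32,
        "strengths": [2.0**i for i in range(-10, 3)],
        "max_half_length": 32,
    }


def fig4_preset():
    """Suppression-map configuration at the omega ~ 1.92 mode, strong drive.

    Centers are selected programmatically at the zeros and antinodes of the
    driving eigenvector's modulus envelope.
    """
    conn = build_line_connectivity(64, 1.0)
    modes = spectrum(conn)
    mode = _mode_closest_to(modes, 1.92)
    zeros = envelope_zeros(mode)
    antinodes = envelope_antinodes(mode)
    centers = sorted(set(zeros.tolist()) | set(antinodes.tolist()))
    return {
        "connectivity": conn,
        "mode": mode,
        "centers": centers,
        "strength": 4.0,
        "max_half_length": 32,
    }


def fig56_preset():
    """Decay-scaling configuration: N=32, input length 29, strengths 2^-10..2^2.

    The drive mode is the smallest positive eigenfrequency of the chain —
    the closest analogue of the direct-current input used in physiology
    experiments.
    """
    conn = build_line_connectivity(32, 1.0)
    modes = spectrum(conn)
    mode = modes[-1]  # smallest positive eigenfrequency
    return {
        "connectivity": conn,
        "mode": mode,
        "center": 16,
        "strengths": [2.0**i for i in range(-10, 3)],
        "half_length": 14,  # input length 2*14 + 1 = 29
    }


def orientation_ring_preset(with_long_range: bool = True):
    """Odd ring (N=65) driven at its DC (omega = 0) mode.

    With even-offset long-range couplings the DC eigenvector is spatially
    periodic and the ring shows surround suppression in orientation space;
    without them it is exactly uniform.
    """
    lr = [(4, 0.5)] if with_long_range else []
    conn = build_ring_connectivity(65, 1.0, lr)
    modes = spectrum(conn)
    mode = min(modes, key=lambda m: m.omega)  # the DC mode
    return {
        "connectivity": conn,
        "mode": mode,
        "center": 32,
        "strengths": [1.0, 4.0],
        "max_half_length": 32,
    }
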
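"""Critically balanced connectivity matrices and their eigenmode structure.

A network of excitatory and inhibitory neurons is critically balanced when
its connectivity matrix ``A`` is skew-symmetric: every eigenvalue is purely
imaginary, so every mode sits at the edge of instability and the dynamics
live on a full-dimensional center manifold.  The canonical construction is
a one-dimensional "checkerboard" chain of alternating excitatory and
inhibitory neurons with equal-strength nearest-neighbor couplings,

    A[i, j] = (-1)**j * s * (delta(i, j+1) + delta(i, j-1)),   i, j = 0..N-1,

with activity pinned to zero outside the chain (Dirichlet boundaries).  A
periodic (ring) variant models orientation space and accepts optional
long-range couplings.

This module builds such matrices, computes their eigenfrequency spectra
(``A v = i omega v``), annotates each mode with the spatial frequency of its
modulus envelope, and fits the elliptical dispersion relation
``omega**2 = scale - c**2 * k**2`` linking temporal and spatial frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FitUndeterminedError, InvalidArgumentError, NumericalFailureError

__all__ = [
    "ConnectivityMatrix",
    "EigenMode",
    "DispersionFit",
    "build_line_connectivity",
    "build_ring_connectivity",
    "custom_connectivity",
    "spectrum",
    "spatial_frequency",
    "dispersion_fit",
    "line_eigenfrequencies_closed_form",
    "save_connectivity",
    "load_connectivity",
    "spectrum_to_csv",
]

#: absolute skew-symmetry tolerance for user-supplied matrices
SKEW_TOL = 1e-12

#: residual tolerance for the eigenmode relation A v = i omega v
MODE_RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A skew-symmetric coupling matrix together with its topology metadata.

    Attributes
    ----------
    n_neurons:
        Network size ``N``.
    coupling_strength:
        Nearest-neighbor synaptic strength ``s`` (dimensionless).
    topology:
        One of ``"line"``, ``"ring"``, ``"custom"``.
    long_range:
        Tuple of ``(offset, strength)`` pairs for ring topologies.
    entries:
        The dense ``N x N`` real matrix ``A``.
    """

    n_neurons: int
    coupling_strength: float
    topology: str
    long_range: tuple[tuple[int, float], ...]
    entries: np.ndarray = field(repr=False)

    def __post_init__(self):
        A = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", A)
        if A.shape != (self.n_neurons, self.n_neurons):
            raise InvalidArgumentError(
                f"entries shape {A.shape} does not match n_neurons={self.n_neurons}"
            )
        scale = max(1.0, float(np.max(np.abs(A))) if A.size else 1.0)
        if np.max(np.abs(A + A.T)) > SKEW_TOL * scale:
            raise InvalidArgumentError(
                "connectivity must be skew-symmetric (A + A.T = 0) within "
                f"{SKEW_TOL:g}; criticality of the model depends on it"
            )


@dataclass(frozen=True)
class EigenMode:
    """One eigenmode ``A v = i omega v`` of a critically balanced network.

    ``omega >= 0`` by convention; the ``-i omega`` conjugate partner is
    implicit.  The eigenvector has unit Euclidean norm and its largest-
    modulus component is rotated to be real and positive.
    """

    omega: float
    eigenvector: np.ndarray = field(repr=False)
    mode_rank: int
    spatial_frequency: float


@dataclass(frozen=True)
class DispersionFit:
    """Least-squares fit of the elliptical dispersion relation.

    ``omega**2 = scale - c**2 * k**2`` over (spatial frequency k, omega)
    pairs; ``goodness`` is the coefficient of determination of the linear
    fit in the omega**2 variable, clipped to [0, 1].
    """

    pairs: tuple[tuple[float, float], ...]
    ellipse_constant: float
    scale: float
    goodness: float


def _check_positive(name: str, value, integer: bool = False):
    if integer and (not float(value).is_integer() or value < 1):
        raise InvalidArgumentError(f"{name} must be a positive integer, got {value!r}")
    if value <= 0:
        raise InvalidArgumentError(f"{name} must be positive, got {value!r}")


def build_line_connectivity(n_neurons: int, coupling_strength: float) -> ConnectivityMatrix:
    """Alternating-sign nearest-neighbor chain with Dirichlet boundaries.

    ``A[i, j] = (-1)**j * s`` for ``|i - j| == 1``; activity terminates to
    zero outside the finite network.  The matrix is exactly skew-symmetric,
    so its spectrum is purely imaginary with eigenfrequencies
    ``|2 s cos(k pi / (N+1))|``, ``k = 1..N``.
    """
    _check_positive("n_neurons", n_neurons, integer=True)
    _check_positive("coupling_strength", coupling_strength)
    N, s = int(n_neurons), float(coupling_strength)
    A = np.zeros((N, N))
    i = np.arange(N - 1)
    A[i, i + 1] = (-1.0) ** (i + 1) * s  # column sign convention (-1)**j
    A[i + 1, i] = (-1.0) ** i * s
    return ConnectivityMatrix(N, s, "line", (), A)


def build_ring_connectivity(
    n_neurons: int,
    coupling_strength: float,
    long_range: list[tuple[int, float]] | tuple = (),
) -> ConnectivityMatrix:
    """Periodic alternating chain, optionally with long-range couplings.

    Nearest-neighbor entries follow the same ``(-1)**j`` column sign rule as
    the line.  For even ``N`` this closes consistently around the ring; for
    odd ``N`` a consistent alternation is impossible and the wrap bond
    ``(N-1, 0)`` falls back to the plain skew convention
    ``A[N-1, 0] = +s, A[0, N-1] = -s`` (the model only requires
    skew-symmetry).  Long-range couplings at ``offset d`` in
    ``[2, floor(N/2)]`` use the alternating rule when ``d`` is odd (it stays
    consistent with periodic closure) and the plain skew-circulant rule
    ``A[i, (i+d) % N] = +sigma``, ``A[i, (i-d) % N] = -sigma`` when ``d`` is
    even.  ``d == N/2`` couples antipodal pairs through a single bond and is
    rejected for even ``d`` (the two conventions cancel identically).
    """
    _check_positive("n_neurons", n_neurons, integer=True)
    _check_positive("coupling_strength", coupling_strength)
    N, s = int(n_neurons), float(coupling_strength)
    if N < 3:
        raise InvalidArgumentError("ring topology needs at least 3 neurons")
    A = np.zeros((N, N))
    for i in range(N):
        for j in ((i + 1) % N, (i - 1) % N):
            A[i, j] = (-1.0) ** j * s
    if N % 2 == 1:
        # odd ring cannot alternate consistently; patch the wrap bond
        A[N - 1, 0] = s
        A[0, N - 1] = -s

    seen = set()
    lr_norm = []
    for offset, sigma in long_range:
        offset = int(offset)
        if offset < 2 or offset > N // 2:
            raise InvalidArgumentError(
                f"long-range offset {offset} outside [2, {N // 2}] "
                "(offset 1 collides with the nearest-neighbor band)"
            )
        if offset in seen:
            raise InvalidArgumentError(f"duplicate long-range offset {offset}")
        seen.add(offset)
        sigma = float(sigma)
        single_bond = 2 * offset == N
        if single_bond and offset % 2 == 0:
            raise InvalidArgumentError(
                f"offset N/2={offset} with even parity: the skew-circulant "
                "entries cancel identically"
            )
        if offset % 2 == 1 and N % 2 == 0:
            for i in range(N):
                j = (i + offset) % N
                A[i, j] = (-1.0) ** j * sigma
                if not single_bond:
                    j = (i - offset) % N
                    A[i, j] = (-1.0) ** j * sigma
        else:
            # plain skew-circulant convention (documented fallback)
            for i in range(N):
                A[i, (i + offset) % N] += sigma
                A[(i + offset) % N, i] -= sigma
        lr_norm.append((offset, sigma))
    return ConnectivityMatrix(N, s, "ring", tuple(lr_norm), A)


def custom_connectivity(entries: np.ndarray) -> ConnectivityMatrix:
    """Wrap a user-supplied matrix; rejected unless skew-symmetric within 1e-12."""
    A = np.asarray(entries, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidArgumentError(f"connectivity must be square, got shape {A.shape}")
    return ConnectivityMatrix(A.shape[0], 1.0, "custom", (), A)


# ---------------------------------------------------------------------------
# spectra


def line_eigenfrequencies_closed_form(n_neurons: int, coupling_strength: float) -> np.ndarray:
    """Eigenfrequency multiset ``|2 s cos(k pi/(N+1))|``, k = 1..N, of the line.

    The alternating sign pattern is removable by a diagonal similarity, so
    the line network shares the spectrum magnitude structure of the plain
    tridiagonal chain.  Returned unsorted, one entry per eigenvalue.
    """
    k = np.arange(1, n_neurons + 1)
    return np.abs(2.0 * coupling_strength * np.cos(k * np.pi / (n_neurons + 1)))


def _phase_normalize(v: np.ndarray) -> np.ndarray:
    """Rotate so the (first) largest-modulus component is real and positive."""
    mods = np.abs(v)
    p = int(np.argmax(mods > mods.max() - 1e-12 * max(mods.max(), 1.0)))
    ph = v[p]
    if np.abs(ph) == 0:
        return v
    return v * (np.abs(ph) / ph)


def _ring_analytic_modes(conn: ConnectivityMatrix):
    """Closed-form eigenbasis of an even-N (modulated-circulant) ring.

    ``v_m(j) = e^{i q j} (1 + i (-1)^j) / sqrt(2N)`` with ``q = 2 pi m / N``
    diagonalizes the alternating nearest-neighbor ring together with any
    long-range couplings built by :func:`build_ring_connectivity`:

        omega_m = 2 s cos q
                  + sum_{d odd} 2 sigma_d cos(q d)   (x1/2 when d = N/2)
                  + sum_{d even} 2 sigma_d sin(q d)

    Unlike the LAPACK eigendecomposition, which mixes degenerate pairs
    arbitrarily, this basis has exactly uniform modulus per mode.
    """
    N = conn.n_neurons
    s = conn.coupling_strength
    j = np.arange(N)
    carrier = (1.0 + 1j * (-1.0) ** j) / np.sqrt(2 * N)
    out = []
    for m in range(N):
        q = 2 * np.pi * m / N
        omega = 2 * s * np.cos(q)
        for d, sigma in conn.long_range:
            w = np.cos(q * d) if d % 2 == 1 else np.sin(q * d)
            factor = 1.0 if 2 * d == N else 2.0
            omega += factor * sigma * w
        v = np.exp(1j * q * j) * carrier
        out.append((omega, v))
    return out


def _real_span(vectors: list[np.ndarray], dim: int) -> list[np.ndarray]:
    """Orthonormal real basis (length ``dim``) of the span of complex vectors."""
    parts = []
    for v in vectors:
        parts.append(v.real)
        parts.append(v.imag)
    M = np.column_stack(parts)
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    basis = [u[:, i] for i in range(len(s)) if s[i] > 1e-10 * s[0]]
    return basis[:dim]


def spectrum(connectivity: ConnectivityMatrix) -> list[EigenMode]:
    """All eigenmodes with ``omega >= 0``, sorted descending by eigenfrequency.

    Each ``-i omega`` conjugate partner is suppressed; zero eigenvalues are
    kept once per kernel dimension with real eigenvectors.  Every returned
    mode satisfies ``||A v - i omega v|| <= 1e-9`` and carries the spatial
    frequency of its modulus envelope.
    """
    A = connectivity.entries
    N = connectivity.n_neurons
    scale = max(1.0, float(np.max(np.abs(A))))
    zero_tol = 1e-12 * scale

    raw: list[tuple[float, np.ndarray]] = []
    zeros: list[np.ndarray] = []
    if connectivity.topology == "ring" and N % 2 == 0:
        for omega, v in _ring_analytic_modes(connectivity):
            if omega > zero_tol:
                raw.append((omega, v))
            elif abs(omega) <= zero_tol:
                zeros.append(v)
    else:
        try:
            mu, V = np.linalg.eigh(1j * A)  # Hermitian; A v = -i mu v
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalFailureError(
                "eigendecomposition failed",
                details={"n_neurons": N, "max_abs_entry": scale},
            ) from exc
        for k in range(N):
            omega = -mu[k]
            if omega > zero_tol:
                raw.append((float(omega), V[:, k]))
            elif abs(omega) <= zero_tol:
                zeros.append(V[:, k])

    modes_data: list[tuple[float, np.ndarray]] = raw
    if zeros:
        # the kernel of a real skew matrix is real; keep one real mode per
        # kernel dimension (a zero eigenvalue has no distinct conjugate)
        kernel_dim = len(zeros)
        for w in _real_span(zeros, kernel_dim)[:kernel_dim]:
            modes_data.append((0.0, w.astype(complex)))

    modes_data.sort(key=lambda t: -t[0])
    modes = []
    for rank, (omega, v) in enumerate(modes_data, start=1):
        v = v / np.linalg.norm(v)
        v = _phase_normalize(v)
        resid = np.linalg.norm(A @ v - 1j * omega * v)
        if resid > MODE_RESIDUAL_TOL:
            raise NumericalFailureError(
                f"eigenmode residual {resid:.3e} exceeds {MODE_RESIDUAL_TOL:g}",
                details={"omega": omega, "mode_rank": rank},
            )
        modes.append(
            EigenMode(
                omega=float(omega),
                eigenvector=v,
                mode_rank=rank,
                spatial_frequency=_envelope_frequency(v),
            )
        )
    return modes


def _envelope_frequency(v: np.ndarray, pad_factor: int = 16) -> float:
    """Dominant spatial frequency (cycles/neuron) of the eigenvector modulus.

    The modulus envelope of a spatially oscillating mode is a rectified
    sinusoid, which oscillates at twice the underlying spatial frequency;
    the dominant DFT frequency of the mean-removed envelope is therefore
    halved.  Constant-modulus vectors return 0.
    """
    env = np.abs(np.asarray(v))
    n = len(env)
    if n < 2 or np.ptp(env) <= 1e-8 * max(env.max(), 1e-300):
        return 0.0
    env = env - env.mean()
    npad = pad_factor * n
    power = np.abs(np.fft.rfft(env, n=npad))
    power[0] = 0.0
    peak = int(np.argmax(power))
    f_env = peak / npad  # cycles per neuron of the rectified envelope
    return float(f_env / 2.0)


def spatial_frequency(mode: EigenMode | np.ndarray) -> float:
    """Spatial frequency (cycles/neuron) of a mode's modulus envelope."""
    v = mode.eigenvector if isinstance(mode, EigenMode) else np.asarray(mode)
    return _envelope_frequency(v)


def dispersion_fit(modes: list[EigenMode]) -> DispersionFit:
    """Fit ``omega**2 = scale - c**2 k**2`` over (spatial frequency, omega) pairs.

    Requires at least 5 modes with distinct spatial frequencies; raises
    :class:`FitUndeterminedError` otherwise, or when the fitted ``c**2`` is
    not positive (no elliptical branch).
    """
    pairs = sorted({(round(m.spatial_frequency, 12), m.omega) for m in modes})
    ks = np.array([p[0] for p in pairs])
    oms = np.array([p[1] for p in pairs])
    if len(np.unique(ks)) < 5:
        raise FitUndeterminedError(
            f"need >= 5 modes with distinct spatial frequencies, got {len(np.unique(ks))}"
        )
    if np.ptp(ks) <= 1e-12:
        raise FitUndeterminedError("degenerate spatial-frequency range")
    X = np.column_stack([np.ones_like(ks), ks**2])
    y = oms**2
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale, slope = float(coef[0]), float(coef[1])
    if slope >= 0:
        raise FitUndeterminedError(
            "omega**2 increases with k**2; no elliptical dispersion branch"
        )
    c = float(np.sqrt(-slope))
    yhat = X @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    goodness = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return DispersionFit(
        pairs=tuple((float(k), float(o)) for k, o in pairs),
        ellipse_constant=c,
        scale=scale,
        goodness=goodness,
    )


# ---------------------------------------------------------------------------
# plain-text serialization


def save_connectivity(conn: ConnectivityMatrix, csv_path: str | Path) -> None:
    """Dense CSV of the matrix plus a JSON sidecar with the metadata."""
    csv_path = Path(csv_path)
    np.savetxt(csv_path, conn.entries, delimiter=",", fmt="%.12g")
    sidecar = csv_path.with_suffix(csv_path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "n_neurons": conn.n_neurons,
                "coupling_strength": conn.coupling_strength,
                "topology": conn.topology,
                "long_range": [list(p) for p in conn.long_range],
            },
            indent=2,
        )
    )


def load_connectivity(csv_path: str | Path) -> ConnectivityMatrix:
    """Inverse of :func:`save_connectivity`; validates skew-symmetry."""
    csv_path = Path(csv_path)
    A = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    sidecar = csv_path.with_suffix(csv_path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return ConnectivityMatrix(
            n_neurons=int(meta["n_neurons"]),
            coupling_strength=float(meta["coupling_strength"]),
            topology=str(meta["topology"]),
            long_range=tuple((int(d), float(s)) for d, s in meta.get("long_range", [])),
            entries=A,
        )
    return custom_connectivity(A)


def spectrum_to_csv(modes: list[EigenMode], path: str | Path) -> None:
    """CSV with columns mode_rank, omega, spatial_frequency."""
    import pandas as pd

    pd.DataFrame(
        {
            "mode_rank": [m.mode_rank for m in modes],
            "omega": [m.omega for m in modes],
            "spatial_frequency": [m.spatial_frequency for m in modes],
        }
    ).to_csv(path, index=False, float_format="%.12g")
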
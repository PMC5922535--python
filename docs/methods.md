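# Methods

## Model

The network state `x ∈ C^N` evolves under the Hopf normal-form equation

    dx_i/dt = Σ_j A_ij x_j − |x_i|² x_i + I_i(t).

Two structural assumptions define the model class:

1. **Critical balance.** `A` is exactly skew-symmetric, so its spectrum is
   purely imaginary and the whole phase space is a center manifold.  The
   package enforces this at construction (`A + Aᵀ = 0` exactly for built
   topologies; within 10⁻¹² for user matrices, which are otherwise
   rejected — the model's behavior degenerates qualitatively off the
   imaginary axis).
2. **Local nonlinearity.** The cubic term is componentwise; all coupling
   between neurons lives in `A`.

### Topologies

* **Line** (`build_line_connectivity`): `A_ij = (−1)^j s (δ_{i,j+1} +
  δ_{i,j−1})`, indices `0..N−1`, Dirichlet boundaries (activity is zero
  outside the chain).  Eigenfrequencies are `|2s cos(kπ/(N+1))|`,
  `k = 1..N` (the alternating sign is removable by a diagonal similarity);
  this closed form is the test oracle for the numerical spectrum.
* **Ring** (`build_ring_connectivity`): periodic closure of the same rule.
  The `(−1)^j` alternation is consistent around the ring only for even
  `N`; for odd `N` the wrap bond falls back to the plain skew convention
  `A[N−1,0] = +s`, `A[0,N−1] = −s` and translation symmetry is (by
  necessity) broken.  Long-range couplings at offset `d ∈ [2, ⌊N/2⌋]` use
  the alternating rule for odd `d` and the plain skew-circulant rule for
  even `d`; `d = N/2` is a single antipodal bond (rejected for even `d`,
  where the two orientations cancel identically).
* **Custom**: any skew-symmetric matrix, via `custom_connectivity` or a
  CSV import.

### Spectra

`spectrum` returns one mode per conjugate pair (`ω > 0`), plus one real
mode per kernel dimension (`ω = 0`), sorted by descending eigenfrequency.
For generic matrices it diagonalizes the Hermitian matrix `iA`.  Even-`N`
rings are doubly degenerate at almost every eigenfrequency and LAPACK
returns arbitrary mixtures within each eigenspace; for them the package
instead uses the closed-form eigenbasis

    v_m(j) = e^{iqj} (1 + i(−1)^j) / √(2N),   q = 2πm/N,
    ω_m = 2s cos q + Σ_{d odd} 2σ_d cos(qd) + Σ_{d even} 2σ_d sin(qd)

(the antipodal bond contributes half weight), which is exact for every
ring the builder can produce and has uniform modulus per mode — the
physically meaningful representative for translation-invariant rings.
Every returned mode is verified against `‖Av − iωv‖ ≤ 10⁻⁹`.  Phase
convention: the first component of largest modulus is rotated real and
positive.

### Spatial frequency and dispersion

The spatial frequency attached to each mode is measured from the modulus
envelope `|v_j|`: the envelope of a spatially oscillating mode is a
rectified sinusoid, which oscillates at twice the underlying spatial
frequency, so the dominant DFT frequency of the mean-removed envelope
(zero-padded ×16 for sub-bin resolution) is halved.  Constant-modulus
vectors report zero.  This reproduces `k/(2(N+1))` cycles/neuron for the
`k`-th line mode.  `dispersion_fit` then fits `ω² = scale − c²k²` by
linear least squares in the `ω²` variable and reports the coefficient of
determination rather than asserting ellipticity: for the 1-D chain the
exact relation is `ω = 2s cos(2πk)`, which the ellipse approximates well
only at low spatial frequency (R² ≈ 0.93 for the 64-neuron line).

## Steady states

Monochromatic drive `I = F e^{iωt}` with the limit-cycle ansatz
`X = Z e^{iωt}` gives the harmonic-balance residual

    g(Z) = (A − iω)Z − |Z|²∘Z + F.

`newton_solve` iterates damped Newton–Raphson on the realified system
(concatenated real and imaginary parts).  Choices that matter:

* **Seeding.** `Z = 0` is a singular point of the Jacobian whenever `ω` is
  an eigenfrequency, so the default seed is the componentwise signed cube
  root `Z0_k = |F_k|^{1/3} · phase(F_k)` — the exact resonant balance in
  the uniform-mode limit.  Unforced components receive a small background
  (10⁻³ of the seed scale): at a *degenerate* eigenfrequency a narrowly
  windowed seed leaves part of the `(A − iω)` nullspace unlifted by the
  cubic terms and the bare seed itself sits on a singular manifold.
  User-supplied guesses are used as given; a singular Jacobian there
  raises an error carrying the iterate.
* **Damping.** When a full Newton step fails to reduce the residual
  max-norm, the step is halved (≤ 20 times); accepted steps reproduce the
  undamped iteration.
* **Singularity detection.** LU factorization with a reciprocal-condition
  estimate; `rcond < 10⁻¹⁴` is treated as singular.
* **Tolerances.** Residual max-norm ≤ 10⁻¹⁰ within ≤ 100 iterations, by
  default.
* **DC drive.** For `ω = 0` with real forcing (the odd-`N` zero mode —
  direct-current input, the un-flashed stimulus of physiology
  experiments) the amplitude equation is real and the solver runs on the
  `N`-dimensional real system.
* **Continuation.** Grids over (strength, length) are solved warm-started
  from the nearest solved neighbor; the canonical branch is the one
  continued from weak forcing.
* **Stability.** Experiment sweeps screen every converged point through
  the eigenvalues of the realified Jacobian (all real parts negative).
  The integration certificate `verify_stability` — perturb `Z` by a
  relative 10⁻³, integrate the rotating frame, require return to within
  10⁻⁶ — is exact but costs an ODE solve per point, so it backs the
  Jacobian screen in tests rather than running on every grid cell.

The response readout is the modulus `|Z_c|` of the center neuron.
Useful invariants, all under test: gauge covariance (`F → e^{iφ}F` maps
`Z → e^{iφ}Z`), scaling covariance (`(A, ω, F) → (σA, σω, σ^{3/2}F)` maps
`Z → σ^{1/2}Z`), the single-oscillator cubic-root law `|Z| = B^{1/3}`, the
ring resonant solution `|Z| = (NB)^{1/3}|v|`, and the resonance half-width
ratio `Γ(8B)/Γ(B) = 4`.

## Transients and decay constants

`integrate_rotating_frame` substitutes `x = y e^{iωt}`, yielding the
autonomous, non-oscillatory system `ẏ = (A − iω)y − |y|²∘y + F` — the
substitution that makes the otherwise stiff oscillatory problem tractable.
Integration uses BDF with the analytic Jacobian, rtol 10⁻⁹, atol 10⁻¹²,
and stops once `max_i ||y_i| − |Z_i||` falls below the floor
`max(10⁻¹⁰, 10⁻⁸ max|Z|)`, below which the log-residual is integrator
noise.  Transient experiments start from rest (`x(0) = 0`), the natural
stimulus-onset condition.

The decay analysis follows the readout residual `r(t) = ||x_c(t)| − |Z_c||`.
Because the approach to the limit cycle mixes many eigendirections of the
Jacobian, `r(t)` carries oscillatory interference — near-cancellations
that appear as deep downward spikes on a log scale.  `fit_decay_segments`
therefore:

1. takes the monotone (right-running-max) envelope of `r`,
2. truncates at the fit floor and drops the onset (points before `log r`
   first falls 0.5 below its peak),
3. resamples to 400 uniform times and runs an exhaustive
   single-changepoint two-line least-squares search,
4. accepts the two-segment model only when both slopes are negative, the
   fast/slow slope-magnitude ratio is ≥ 1.5, and both segments hold ≥ 30
   samples (single-segment decays are labeled fast, the regime present at
   every strength),
5. on acceptance, refits the slow slope away from the changepoint and
   *peels* the slow exponential off before refitting the fast slope — the
   standard multi-exponential correction for crossover blending, which
   recovers synthetic two-exponential slopes to well under 1%.

`decay_scaling_experiment` runs this per strength and regresses
`log(decay constant)` on `log B` per regime.  Defaults for the
figure-scale scan: N = 32 line, input length 29 centered at N/2,
strengths `2^i` for `i = −10..2`, drive at the *smallest* positive
eigenfrequency (ω ≈ 0.095) — the closest analogue of the DC drive used in
physiology, and the configuration in which the two-regime structure is
cleanest.  The integration horizon scales as `600 · B^{−2/3}` with the
expected decay rate; the segment fit is truncated at `10⁻⁷ max|Z|`
because the bottom decade above the integrator floor is dominated by
interference noise.  Driving instead at a high-frequency mode leaves the
fast-regime scaling unchanged but lets the slow-regime rate constant
drift downward with `B` (the slowest Jacobian eigenvalue of the windowed
chain falls from ≈ 0.36·B^{2/3} to ≈ 0.21·B^{2/3} across the 12-octave
strength range), flattening the fitted slow exponent — a property of the
windowed line network itself, not of the fitting.

Caveat on the single oscillator: from rest with real forcing the
trajectory stays exactly real, so only the radial eigendirection (rate
`3B^{2/3}`) is excited, and a tangential (phase) perturbation is invisible
to the modulus readout at first order.  The 3:1 rate-pair oracle is
therefore exercised with direction-specific perturbations of the fixed
point rather than from rest.

## Experiments and presets

* `fig3`-scale: line N = 64, s = 1, center 32, strengths `2^i, i = −10..2`
  (a weak-to-strong span), the six largest-ω modes.  Centers at
  index N/2 sit near a zero of |v| for even-rank modes (strong surround
  suppression: ranks 2, 4, 6 at ω ≈ 1.99, 1.96, 1.92) and near an antinode
  for odd-rank modes (little suppression) — which is why neighboring
  panels behave so differently.
* `fig4`-scale: the ω ≈ 1.92 mode at strength 4, centers selected
  programmatically at the zeros and antinodes of |v| (local minima below
  25% / maxima above 75% of the envelope peak).
* `fig56`-scale: the decay scan described above.
* Orientation ring: N = 65 ring driven at its DC mode.  Without long-range
  couplings the DC eigenvector is exactly uniform and integration is
  monotone in arc length; with the preset long-range pattern
  `[(offset 4, strength 0.5)]` the eigenvector becomes spatially periodic
  (modulus peak-to-peak ≈ 0.19) and the curves develop pronounced surround
  suppression (index ≈ 0.7–0.8 at B = 1–4).  Which long-range pattern to
  use is genuinely open — any pattern that makes the DC eigenvector
  periodic qualifies; this one is the package's choice.  Ring input
  windows use the same clipped `[c−l, c+l] ∩ [0, N−1]` convention as the
  line, so exact rotation equivariance holds for windows away from the
  index seam (and is tested there).

The suppression index of a curve is `(max response − response at the
longest input) / max response`, zero for monotone curves — this package's
quantitative stand-in for the qualitative notion of "suppression beyond
the maximum".

## Determinism, sizes, and limitations

All experiments are deterministic; the only randomness in the package is
the seed-controlled noise of the synthetic trace fixture generator.  The
shipped configurations (N ≤ 64 grids, 13-strength decay scans) run in
tens of seconds to a few minutes on one core; larger N is limited mainly
by the dense `2N × 2N` Jacobian factorizations.

What the model does *not* cover: non-monochromatic or stochastic input,
learned/plastic connectivity, dissipative (non-skew) matrices, 2-D
lattices, and any quantitative fit of physiological tuning curves beyond
the assumed linearity between stimulus contrast and input strength.
Passing tests demonstrate the mechanism inside this idealized model — a
toy-model existence proof, not a neuroanatomical account of V1.
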
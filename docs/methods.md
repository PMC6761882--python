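# Methods

## Scope and model

`tta2d` models triplet–triplet annihilation (TTA) confined to a plane:
T₁ + T₁ → S₁ + S₀, second order in the triplet surface concentration
T\*(t) (mol m⁻²). First-order triplet decay is neglected throughout — at
interfaces its millisecond timescale is four orders of magnitude slower
than the observed sub-microsecond TTA. Three kinetic descriptions are
implemented:

1. **Classical second order**, dT\*/dt = −k T\*², closed form
   T\* = T0/(1 + k T0 t), half-life 1/(k T0) (inversely proportional to
   the initial triplet concentration — the experimental fingerprint of
   second-order control).
2. **2D diffusion control**: the cylindrical-coordinate Smoluchowski
   problem (absorbing disk, radius R) yields the time-dependent molar
   coefficient
   k(t) = N_A (8D/π) ∫₀^∞ e^(−Du²t) / (u [J₀²(uR) + Y₀²(uR)]) du.
   There is no steady state: 1/k grows like ln t indefinitely, because 2D
   random walks are recurrent (compact exploration). The decay ODE with
   this coefficient has no closed form in T\*(t) but is separable,
   1/T\*(t) = 1/T0 + ∫ k ds, which the fitting path exploits.
3. **Fractal kinetics**, dT\*/dt = −k_f t^(−h) T\*², for crowded media
   where transport is anomalous; 1/T\* is affine in t^(1−h). Units of k_f
   are m² mol⁻¹ s^(h−1), fixed by dimensional consistency (h = 0 recovers
   the classical law and units).

## Numerical treatment of the 2D coefficient

The Bessel-modulus integrand is evaluated in the log variable s = ln(uR):

- below s = −40 the exact small-argument limit
  1/(1 + (2/π)²(s + γ − ln 2)²) is integrated in closed form (arctan);
- the central region uses adaptive quadrature (target relative error
  1e−11; a `NumericalError` is raised if the estimate degrades past 1e−6);
- above u_max = max(6/√τ, 30)/R the large-argument form
  J₀² + Y₀² → 2/(πuR) gives an analytic erfc tail.

k depends on (t, D, R) only through τ = Dt/R² (up to the D prefactor), so
a single monotone PCHIP interpolant of ln I(τ) on a log grid (32
points/decade, τ ∈ [1e−9, 1e12], relative error < 1e−5) serves every
(D, R) during fitting, where k is evaluated thousands of times. The
public evaluator defaults to full quadrature per point.

**Certification.** The transcribed coefficient is cross-checked against an
independent oracle that shares no code path: a finite-difference
method-of-lines solution of the radial diffusion equation with an
absorbing boundary at r = R (log-spaced grid, 2500 nodes, outer boundary
at 150 R), whose absorbing flux 2πRD ∂c/∂r|_R reproduces the quadrature
to ≲0.01% over two decades of time.

The decay with k(t) starts at a configurable t_min (default 20 ns, the
pump–probe instrument resolution); the t → 0 divergence of k is thereby
excluded, mirroring the fact that sub-resolution annihilation between
initially adjacent triplets is not probed. `solve_tta_2d` uses LSODA at
rtol 1e−8; the fitting path uses the separable closed form on a dense log
grid (64 points/decade cumulative trapezoid), which agrees with the ODE
route to ~2e−4 relative.

## Fitting

Unweighted least squares on concentration (optionally 1/σ²-weighted; the
choice of weighting on the original instrument data is not knowable from
a digitised trace, so unweighted is the documented default). Positive
parameters (k, D, k_f, T0) are log-parameterised, h is box-bounded to
[0, 0.99]; residuals are normalised by T0 to condition the Jacobian, and
parameters are reported back in SI. Starting values are automatic: k from
the two-point inverse-concentration slope, D from a Brownian-order
inversion at the half-life scale, h from 0.1. Standard errors come from
the SVD pseudo-inverse of the Jacobian. Degenerate inputs are flagged
rather than silently fitted: a trace with k·T0·t ≪ 1 everywhere (no
curvature) or one that barely decays sets `converged=False` with a
message; an h estimate pinned at its bound does the same.

The fractal law is non-autonomous (absolute time enters through t^(−h)),
so T0 — the t = 0 concentration, not the first sample — is a third free
parameter. The second-order law is autonomous and is fitted with the time
origin shifted to the first sample.

Note on interpretation: fitted on decays of *annihilating walkers*, the
2D model returns the **relative** diffusion coefficient of a reacting
pair, ≈ 2× the single-particle D, since both partners move. This is
correct physics, not a bias.

## Trajectory analytics

- **tMSD** over all sliding origins (FFT algorithm, O(n log n);
  brute-force cross-checked), lags capped at half the trajectory — the
  overlapping-origin choice maximises averaging at short lags where the
  anomalous exponent lives. **teMSD** is the particle mean.
- **Exponent fits** are log–log least squares of teMSD on a lag window;
  MSD = D_i t^d.
- **Displacement autocorrelation** C(τ) of displacement vectors over an
  interval δ (default 200 ps at the 20 ps frame step), normalised by
  ⟨|δr|²⟩ so C(0) = 1. Brownian motion gives C ≈ 0 beyond δ; FBM/FLE
  motion with H < ½ gives the antipersistent negative dip at τ = δ,
  matching the closed-form increment autocovariance
  (|u+1|^2H − 2|u|^2H + |u−1|^2H)/2, which serves as the quantitative
  reference curve (the original study's exact fitting function is not
  public; this standard substitution is exact for FBM).
- **Ergodicity scatter**: Var_i[tMSD_i]/teMSD² per lag. Ergodic dynamics
  (Brownian, FBM/FLE) give small values shrinking with ensemble size;
  CTRW-like ergodicity breaking or frozen/mobile mixtures give order-one
  values.
- **New encounters**: per focal particle, the cumulative count of
  *distinct* partners that ever came within the encounter radius
  (default 1.5 nm), minimum-image distances, each partner counted once.
  Partners already inside the radius at t₀ form a separately reported
  initial-neighbour list and are never re-counted, keeping the growth
  curve zero-based. The production counter uses cell lists (falling back
  to the vectorised pairwise path when the box holds fewer than 3 cells
  per side) and is tested for exact equality against a naive pure-Python
  O(N²·frames) scan. Power-law fits truncate at 2/3 of the duration to
  limit finite-size effects. The collision-theory bridge converts
  N_enc(τ) to a molar surface rate: rate = N_enc f_T²/(A τ N_A), with
  f_T² the both-partners-triplet probability (0.0225 at 15% excitation).

## Synthetic-data generators

The generators emulate the two data sources of the study design — MD-like
interfacial trajectories and ~20 ns-resolution SHG decays — under the
study geometry: a 15 × 15 nm periodic interface, maximum adsorption
density 3.6e−7 mol m⁻² (0.22 nm⁻²; 24 molecules at half coverage,
48.78 at full — the nearest-integer and floor conventions are both
exposed since the printed counts mix them), reaction radius 1.5 nm,
frame step 20 ps.

- **Brownian**: Gaussian steps of variance 2D dt per axis; D defaults to
  2e−9 m² s⁻¹, the simulated dilute-interface mobility scale.
- **FBM**: exact-covariance fractional Gaussian noise by Davies–Harte
  circulant embedding (two independent 1D processes per particle —
  isotropy), per-axis variance 2D t^2H. H = 0.4 reproduces the t^0.8
  full-coverage MSD scaling with stationary, antipersistent,
  FLE-consistent increments; H = 0.5 reduces to Brownian.
- **Crowded soft disks**: overdamped Euler–Maruyama dynamics with
  harmonic soft-core repulsion (mobility × spring constant = 1e10 s⁻¹,
  diameter 2.0 nm — the molecule's physical footprint with its four
  peripheral arms exceeds the 1.5 nm core contact distance). Initial
  placement by random sequential addition with a jittered-lattice
  fallback at densities where RSA jams, plus a 200-step burn-in. At full
  coverage the short-lag exponent drops to ≈0.87 and linearity returns
  at long lags; the model is a mechanistic illustration of transient
  crowding-induced subdiffusion, not a quantitative stand-in for
  atomistic forces, and the exact 0.8 exponent is *not* asserted for it.
- **Annihilating walkers**: a fraction p0 of particles starts as
  triplets; at every frame (including t = 0) triplet pairs within R
  annihilate, resolved greedily closest-pair-first with re-scanning —
  deterministic and label-order independent. Reacted molecules persist
  as ground-state crowders. The frame step must keep the RMS step below
  R/3 so pairs cannot tunnel through the reaction radius (validated,
  error otherwise). Triplet counts are returned as mol m⁻² via the box
  area.
- **SHG emulation**: bin a decay to the instrument resolution, map
  concentration linearly to normalised ground-state depletion (depletion
  is proportional to triplet concentration), add seeded Gaussian noise.

Every generator takes a mandatory seed; identical seeds give bit-identical
output, and every written artifact embeds its seed and parameters.

### Coverage-conditioned motion

Where a single knob for "surface coverage" is needed (the kinetics trend
analyses), coverage maps onto the motion model: Brownian at 12% coverage
grading linearly in H to FBM with H = 0.4 at full coverage — exactly the
two transport regimes observed in the interfacial trajectories (always-
linear MSD at low coverage; t^0.8 at full coverage). The per-frame RMS
step is held fixed across H so that only the *memory* of the motion
changes, and the triplet number and box are held fixed so T0 and the
observation window are identical across coverages. Under this mapping the
effective second-order constant falls monotonically with coverage
(ratio ≈ 1.9 from 12% to 93%). The intermediate-coverage H is an
interpolation choice of this package; only the endpoints are
independently characterised. The explicit soft-disk route slows effective
mobility only ~2×, which excluded-area pair enrichment largely offsets,
so it demonstrates the MSD signature of crowding but not the rate-constant
trend — a known limitation of soft-core models at this coarseness.

## What the synthetic tests do and do not show

Passing tests certify the *machinery*: evaluators agree with independent
oracles (PDE flux, ODE integration, brute-force counting, closed-form
FBM covariance), fitters recover generating parameters at stated noise
levels, and the qualitative crowding signatures emerge from the
generators. They do not validate atomistic transport coefficients,
instrument-specific noise structure (noise here is additive Gaussian, not
the full shot/laser-drift mixture), adsorption/desorption exchange with
the bulk, or the third dimension (the generators are strictly planar).

## Numerical details and tie-breaks

- Replicate-averaged annihilation decays are used for model-comparison
  residuals: a single 100-walker decay's counting noise (~2%/point)
  swamps model misfit; 24 replicates bring the noise floor to ~0.5%.
  A *markedly* subdiffusive case (H = 0.3) is the misfit demonstrator —
  at H = 0.4 the log-decaying 2D coefficient can imitate the mild
  power-law kinetics well enough that residuals alone do not separate
  the models, though the fitted D still collapses far below the
  microscopic mobility.
- Encounter-vs-kinetics consistency is evaluated with both sides averaged
  over the same half-decay window, since effective second-order constants
  are window averages of a falling coefficient.
- Half-life extraction interpolates linearly at the first crossing of
  half the first sample; traces that never cross raise an error.
- Fit determinism: all fitters are deterministic given the trace; all
  simulation studies fix seeds.
- Problem sizes in the shipped analyses (hundreds of particles, a few
  thousand frames, tens of replicates) were chosen to make every
  statistical assertion resolvable at its stated tolerance on a single
  core in minutes.
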
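# Methods

## Model and scope

The package computes quadrupolar NMR relaxation observables for a spin-3/2
probe nucleus (²³Na⁺, Q = 104 × 10⁻³¹ m², I = 3/2) from classical
point-charge configurations. The chain is: periodic EFG tensors at the ion
site → electron-cloud (Sternheimer) rescaling → EFG autocorrelation and its
time integral → the extreme-narrowing rate formula. A parallel transport
chain (viscosity, diffusion, reorientation, structural relaxation) supplies
the quantities needed to confront the rate with hydrodynamic relaxation
models. Electronic-structure calculations are out of scope: ab initio EFGs
enter only as tables paired with classical EFGs on the same configurations.

Internal units are Å, fs, elementary charge and kelvin. EFGs are carried in
e/Å³ (lattice sums of order unity) and converted to SI with
e/(4πε₀·10⁻³⁰) ≈ 1.44 × 10²¹ V m⁻² per e/Å³ only inside the rate formulas.
In the NMR literature the symbol V is overloaded (EFG tensor vs box
volume); the code
always says `efg`/`tensor` for the former and `volume` for the latter.

## Ewald EFG engine

The EFG is the second-derivative lattice sum
V_ab = Σ_i q_i (3r_a r_b − r²δ_ab)/r⁵ under cubic periodic boundary
conditions, evaluated with a standard Ewald split (tinfoil boundary, no
surface-dipole term). The real-space part uses erfc screening plus the
Gaussian second-derivative term; the reciprocal part applies −k_a k_b
weights to the Gaussian-filtered structure factor; the probe's own
compensating-Gaussian self-term (isotropic) is removed analytically. The
probe charge is always excluded; all other charges contribute regardless of
species. The residual trace is monitored as a convergence diagnostic
(relative to a typical single-charge EFG magnitude, since symmetric sites
have near-zero tensors) and projected out at the end.

Parameters are auto-tuned from the Gaussian error bounds for a requested
relative accuracy (default 10⁻⁸): with the default splitting the real-space
cutoff is L/2 (minimum image); an explicitly small splitting parameter gets
a cutoff erfc(αr_c) ≈ accuracy which may extend over several periodic image
shells — the implementation sums whatever shells the cutoff requires, so
results are α-invariant to ~10⁻¹⁰ for any reasonable choice.

**Direct-sum oracle.** The independent check is a brute-force sum over
image cells. A sharply truncated cube converges only ~1/s² in the shell
count because each neutral cell carries the same quadrupole moment, leaving
a shape-dependent tail; the oracle therefore weights cells with a quintic
radial taper (full weight inside half the summation radius, smoothly zero
at the edge), which cancels the continuum tail by spherical symmetry and
reaches ~10⁻⁷ relative agreement with the Ewald value by 8–12 shells. The
sharp cube is retained for closed-form few-charge examples.

**Shell decomposition** uses minimum-image direct sums (shells are local by
construction); the remainder term absorbs the difference from the full
periodic sum and is reported. Molecule grouping assigns a whole molecule to
the shell of its oxygen (or first) atom so waters are never split across a
boundary; atom grouping is available for sensitivity checks. Default shell
radii come from the first/second minima of the relevant radial distribution
function computed from the input trajectory; explicit radii override.

## Sternheimer calibration

The slope factor comes from an intercept-free least-squares fit pooled over
all six independent tensor components (equal weights; the fit form
V^AI = (1+γ)V^ext has no intercept by definition — an OLS intercept is
reported as a diagnostic only). The variance factor is
√(ΣV_AI²/ΣV_ext²) − 1. Both are invariant under global unit rescaling and
coincide exactly on noiseless proportional tables; additive contributions
uncorrelated with V_ext inflate the variance ratio but not the slope, which
is why the variance factor is the one used to predict total EFG variances,
⟨V²⟩ = (1+γ′)²⟨V_ext²⟩. Uncertainties resample whole configurations (the
estimators depend on the data only through per-configuration sums of
squares, so the bootstrap is vectorized over sufficient statistics).

## Correlation analysis

ACFs are multi-origin estimates summed over tensor components and averaged
over probes/series, computed by FFT (default) or directly; the two agree to
machine precision. No mean is subtracted (EFG processes are zero-mean by
symmetry).

τ_c is the trapezoidal integral of the normalized ACF up to a cutoff.
The plateau rule takes the first lag from which the running integral's mean
slope over a trailing window (default 5 ps, shrunk to a fifth of the
available span for short series) stays below 10⁻³ of its peak slope; the
windowed mean — rather than a pointwise bound — makes the detector robust
to estimator noise at long lags. An optional fitted-tail term adds the
analytic integral of a decay model beyond the cutoff (exponential tails in
closed form, stretched tails via the upper incomplete gamma function). The
running integral is exposed for plateau inspection and a non-plateauing
integral is returned flagged.

Fits are multi-start bounded nonlinear least squares on the normalized ACF
(≈3 starting time constants per decade of window; composite models
constrain the start grid to separated time scales). Windows with more than
600 lags are subsampled (dense early lags plus log-spaced later ones),
since a smooth ACF carries information logarithmically in lag. Parameter
covariance comes from the Jacobian; non-convergence is flagged in the
result, never silent. The slow-mode fraction of a composite fit is the
amplitude-weighted mean-time share, with the stretched mean time
τ·Γ(1/β)/β — one consistent reading of "slow-mode contribution", documented
as such. Model selection between two-exponential and stretched alternatives
is reported (residual norms), not automated.

The tail diagnostic fits a log-log slope over a window restricted to
positive ACF values (auto-shrunk and flagged otherwise) and scores
compensated curves t^|α|·C(t) by the variance of their logarithm; stability
compares the slopes of the two window halves. On mixtures of a stretched
decay and a faint algebraic tail, the correct exponent appears only for
windows past the crossover lag, which the tests construct explicitly.

## Rates

1/T₁ uses the (2I+3)/(20I²(2I−1)) prefactor — 1/15 for I = 3/2 — and is
exactly C_Q²τ_c/10 with the QCC definition C_Q² = (2/3)(eQ/ħ)²⟨V²⟩; the
identity holds to 10⁻¹² by construction and is asserted end-to-end.
⟨V²⟩ defaults to the γ′-corrected classical variance; the γ′ bootstrap
error propagates into the rate in quadrature with the τ_c error (the exact
propagation rule is a package choice). The extreme-narrowing product is
evaluated under both ω₀ = 2πf and ω₀ = f conventions and both are reported;
the angular one decides the pass at threshold 0.01.

## Transport

The stress ACF symmetrizes and detraces per frame (P_ab = sym − tr/3) with
the 1/10 component prefactor; it is invariant to isotropic pressure offsets
and antisymmetric additions by construction. Green–Kubo viscosity
η = V/(k_BT)∫C dt shares the plateau policy with τ_c (both are Green–Kubo
type integrals).

MSD diffusion uses the FFT decomposition of the multi-origin MSD and a
linear fit over [10%, 50%] of the trajectory by default, guarded by a
log-log local-slope check (1 ± 0.1) that rejects ballistic or caged input;
wrapped trajectories are unwrapped by minimum-image displacement
accumulation. A single 64-walker, 10⁴-step ensemble estimates D with ~6–7%
intrinsic spread (MSD values are strongly correlated across lags), so
quantitative checks average several independent runs, mirroring the
multi-run protocol used for error bars throughout.

ξ ≈ 2.837297 is computed from its definition — the Ewald-split lattice sum
for the periodic self-interaction of a unit charge with neutralizing
background in a unit cube — with tolerance-driven shell counts, an
α-invariance check, and an explicit under-convergence flag. The value
agrees with the printed constant to 10⁻⁶ and is what `scripts/acceptance.py`
reports.

The effective-SED fit regresses τ_c on η/k_BT with an intercept;
r₀ᵉᶠᶠ = (3·slope/4π)^{1/3}, and a negative slope is flagged (no real
radius). The dipole reorientation time integrates the P₁ orientational ACF
with the standard cutoff policy; non-decaying input is flagged as
divergent. The structural relaxation time fits a stretched exponential to
the stress-ACF tail starting, by default, at the first local minimum of
|C(t)| after the initial elastic/vibrational oscillations, and reports
τ_struct = τ_K Γ(1/β_K)/β_K.

## Synthetic data

The generators define the study conditions for all tests:

* **EFG processes** map five independent scalar processes onto an
  orthonormal symmetric-traceless basis, so every frame is exactly
  symmetric-traceless and ⟨V:V⟩ equals the five-fold coefficient variance.
  Exponential modes use the exact stationary OU (AR(1)) recursion run as an
  IIR filter. Stretched modes are Prony superpositions: non-negative
  weights on ~48 log-spaced exponentials fitted by NNLS to the Kohlrausch
  target (completely monotone, so a non-negative representation exists),
  with the achieved sup-norm (~10⁻⁴ for β ≥ 0.5 at the default sampling)
  recorded in the ground truth and a 1% hard bound. The default spec is the
  two-step shape seen for small aqueous cations — 70% fast exponential at
  62 fs and 30% stretched with β = 0.67 at 1 ps, variance 10⁻² e²/Å⁶ —
  giving an analytic τ_c = 0.44 ps.
* **The toy Langevin fluid** (BAOAB integrator; soft r⁻¹² spheres plus
  damped minimum-image Coulomb; virial stress in Pa) provides physically
  structured input for the Ewald, RDF, MSD and stress plumbing. It is a
  deliberately small Brownian system — reduced charges, 64 particles,
  tens of picoseconds — and makes no claim to reproduce any production
  force field or the solution's real transport coefficients; tests that use
  it check estimator correctness (equipartition, neutrality, overdamped
  diffusion, internal consistency), not solution physics.
* **Maxwell stress, Brownian walkers/rotors and pair tables** plant known
  (G, τ), D, D_r, and (γ, noise) with the analytic consequences attached
  (η = VGτ/k_BT, ⟨P₁⟩-decay 2D_r, variance-ratio inflation
  √(1 + σ_n²/((1+γ)²σ_x²))).

All generators take explicit seeds and are bit-reproducible; no global
random state is used anywhere. Bootstrap defaults (1000 resamples, 95%
intervals) are configurable since no canonical values are prescribed.

What passing tests show — and what they do not: the synthetic processes are
stationary Gaussian surrogates with the right ACF shapes, so the tests
validate the estimators and the formula chain quantitatively; they do not
validate force fields, finite-size effects of real electrolytes, or the
physical accuracy of computed rates for real solutions, which require
nanosecond production trajectories as input.

## Problem sizes and numerical choices

Test problem sizes are chosen so the full suite runs in a few minutes on
one CPU: Ewald/oracle checks on 64-particle boxes; 2×10⁵–10⁶-frame
processes for fit recovery (5% tolerances); 5×10⁵-frame Maxwell stress for
Green–Kubo (5%); 16 × (64 walkers × 10⁴ steps) for diffusion (5% on the
multi-run mean); 256 rotors × 6000 frames for τ_dip (3%). Deterministic
closed-form checks are asserted at 10⁻³–10⁻¹² as appropriate. Stochastic
tolerances were sized from the measured estimator spread at those problem
sizes, with fixed seeds recorded in the tests.

## Known limitations

* Plain Ewald only; no mesh acceleration (desk-scale boxes do not need it)
  and no polarizable/induced-dipole EFG terms.
* Cubic boxes only; no triclinic cells or pressure coupling.
* The stretched-process generator is a finite Prony approximation; its
  ground-truth τ_c is quoted both analytically (Γ formula) and as realized
  (Prony sum), which differ by less than the approximation sup-norm times
  the slow time.
* The inverse-Laplace relaxation-mode distribution and beyond-narrowing
  (spectral-density) relaxation are not implemented.
* Fit residuals against multi-origin ACF estimates are smooth in lag
  (adjacent lags share origins), so residual whiteness is only meaningful —
  and only asserted — for independent per-point noise.
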
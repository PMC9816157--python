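# efgrelax

Quadrupolar NMR relaxation rates of ²³Na⁺ in electrolyte solutions, computed
from classical electric-field-gradient (EFG) fluctuations.

The relaxation of a spin-3/2 nucleus such as ²³Na is dominated by the coupling
of its quadrupole moment *eQ* to the fluctuating EFG tensor **V** at the
nucleus. In the extreme-narrowing regime (ω₀τ_c ≪ 1) the longitudinal rate is

    1/T₁ = (2I+3) / (20 I² (2I−1)) · (eQ/ħ)² ⟨V²⟩ τ_c ,

with the EFG variance ⟨V²⟩ = ⟨V(0):V(0)⟩ and the effective correlation time

    τ_c = ⟨V²⟩⁻¹ ∫₀^∞ ⟨V(0):V(t)⟩ dt .

For I = 3/2 this can be recast as 1/T₁ = C_Q² τ_c / 10 with the quadrupolar
coupling constant C_Q² = (2/3)(eQ/ħ)² ⟨V²⟩. The package computes every
ingredient of this formula from particle configurations, plus the transport
quantities used to assess rotational relaxation models:

* **`efgrelax.efg`** — classical point-charge EFG tensors at probe-ion sites
  under periodic boundary conditions via full Ewald summation (tinfoil
  boundary), with a brute-force direct-lattice-sum oracle, solvation-shell
  decompositions, radial distribution functions and coordination-conditioned
  variances.
* **`efgrelax.sternheimer`** — electron-cloud calibration against ab initio
  EFG tables: the slope factor γ_eff from the intercept-free fit
  V^AI = (1+γ_eff)V^ext and the variance-ratio factor
  (1+γ′_eff)² = ⟨V_AI²⟩/⟨V_ext²⟩, with configuration-level bootstrap errors.
* **`efgrelax.correlation`** — multi-origin tensor ACFs (FFT and direct
  estimators), plateau-detected correlation-time integrals with fitted-tail
  extrapolation, exponential / two-exponential / stretched (Kohlrausch) /
  fast-plus-stretched fits, slow-mode fractions and a t^(−5/2) hydrodynamic
  tail diagnostic.
* **`efgrelax.relaxation`** — C_Q, 1/T₁ and the extreme-narrowing check.
* **`efgrelax.transport`** — Green–Kubo shear viscosity from the traceless
  symmetrized stress ACF, MSD diffusion with the Yeh–Hummer finite-size
  correction D_∞ = D + k_BTξ/6πηL (ξ ≈ 2.837297 computed from its defining
  lattice sum), Stokes radii, Stokes–Einstein–Debye times, the effective-SED
  fit with intercept, water-dipole reorientation times and structural
  relaxation times from stretched stress-ACF tails.
* **`efgrelax.synthetic`** — seed-deterministic generators with attached
  ground truth: prescribed-ACF tensor processes, a toy Langevin ionic fluid,
  Maxwell-mode stress, Brownian walkers and rotors, pseudo-ab-initio pair
  tables.
* **`efgrelax.io` / `efgrelax.cli`** — extended-XYZ and CSV/YAML formats and
  a `efgrelax` command with `synth`, `efg`, `calibrate`, `acf`, `relax`,
  `transport` and `pipeline` subcommands.

## Worked example

Compute 1/T₁ for a synthetic EFG process with the two-step relaxation typical
of aqueous Na⁺ (70% fast exponential at 62 fs, 30% stretched with
β = 0.67 at 1 ps), using the infinite-dilution electron-cloud factor
γ′ = 12.09:

```python
from efgrelax import (ProcessSpec, gen_efg_process, tensor_acf, fit_acf,
                      correlation_time, quadrupolar_rate, efg_to_si,
                      predict_total_variance)

spec = ProcessSpec(variance=8.2e-3, n_frames=200_000, dt=10.0, seed=42)
series, truth = gen_efg_process(spec)
acf = tensor_acf(series, max_lag=10_000.0)
fit = fit_acf(acf, "fast_stretched", window=(0.0, 8000.0))
ct = correlation_time(acf, cutoff=4000.0, tail_fit=fit)
v_tot, _ = predict_total_variance(series.variance(), 12.09)
res = quadrupolar_rate(float(efg_to_si(1.0) ** 2 * v_tot),
                       ct.tau_c * 1e-15, larmor_frequency=132.3e6)
```

Output of the accompanying print statements:

```
<V_ext^2>      = 8.1661e-03 e^2/A^6
tau_c          = 0.413 ps  (planted 0.440 ps)
C_Q            = 21.97e6 rad/s
1/T1           = 19.95 1/s
omega0*tau_c   = 3.43e-04  (narrowing ok: True)
```

`<V_ext^2>` is the sampled classical EFG variance; `tau_c` is the
fit-assisted integral of the normalized EFG ACF (within 6% of the planted
ground truth at this sample size); `C_Q` and `1/T1` land in the range
measured for ²³Na⁺ in aqueous NaCl (C_Q ≈ 20 × 10⁶ rad/s, rates of tens of
s⁻¹), and the narrowing product confirms the extreme-narrowing assumption at
132.3 MHz.

The same analysis runs from the shell:

```sh
efgrelax synth --kind langevin --outdir lang            # toy trajectory
efgrelax efg lang/trajectory.extxyz --probes 0 --out efg.csv
efgrelax acf efg.csv --out acf_out
efgrelax pipeline -c run.yaml                           # everything at once
```

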
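# nanolever

Simulation and analysis of **electro-switchable DNA nanolever** biosensing.

Short double-stranded DNA levers (48 bp) tethered to gold microelectrodes
are driven between lying and standing orientations by an alternating
electrode potential; a tip dye quenched near the metal reports the motion
as time-resolved fluorescence.  A protein bound at the lever tip adds
hydrodynamic friction and slows the switching.  This package implements
the "lollipop" biophysical model of that motion — a rigid charged rod
with a charged sphere at its tip in a screened exponential surface field
— and the analyses built on it:

* **Forward model** — free energy G(α) = U(α) − T·S(α) over the
  out-of-plane angle α, exponential electrode charging (τ = 4RC/3), and a
  drift-diffusion (Fokker–Planck) solver
  ∂p/∂t = D_r ∂/∂α[∂p/∂α + p ∂(G/k_BT)/∂α] with reflecting boundaries,
  converted to fluorescence via the distance-dependent quantum yield.
* **Protein sizing** — one-parameter fit of the rotational diffusion
  coefficient D_r^comp to a measured trace, inverted through a modified
  Stokes–Einstein relation D_r = k_BT/(ζ_DNA + 3πηD_H(L + D_H/2)²) to the
  effective hydrodynamic diameter D_H; Tirado–de la Torre rod mobility for
  the bare lever (0.49 μs⁻¹ at default conditions); Perrin prolate-ellipsoid
  equivalent diameters from structure bounding boxes.
* **Dynamic Response (DR)** — area under (up) or above (down) the
  normalized fluorescence within a time window; insensitive to absolute
  intensity and unmodulated background.
* **Kinetics** — single-exponential 1:1 Langmuir association/dissociation
  fits (k_on, k_off, K_D with error propagation).
* **Assays** — mixture fractions by linear DR interpolation,
  viscosity-corrected unfolding-transition detection (urea vs glycerin
  control), replicate group comparison (Welch SE, 3σ rule).
* **Synthetic data** — seeded generators for Poisson photon histograms,
  binding traces and assay tables, each returning a truth record, so the
  whole inference chain is testable without instrument data.

See `docs/methods.md` for the model, numerical schemes and limitations.

## Worked example: sizing a 4 nm protein from a noisy histogram

```python
import nanolever as nl

system = nl.LeverSystem()                      # default 48-bp lever, 10 kHz drive
d_true = 4.0                                   # nm
d_r = 1.0 / nl.complex_friction(system.geometry, system.env, d_true)
print(f"true D_r = {d_r:.4f} /us")

up, down, truth = nl.simulate_tr_histogram(    # Poisson TCSPC histograms
    system.with_protein(d_true), d_r, nl.AcquisitionSettings(seed=42))
up_norm, _ = nl.normalize_trace_pair(up, down)

est = nl.fit_Dr_from_trace(up_norm, system)
print(f"fit  D_r = {est.D_r_comp:.4f} /us (bare lever {est.D_r_dna:.4f} /us)")
print(f"D_H = {est.D_H:.2f} nm, 95% CI {est.ci[0]:.2f}-{est.ci[1]:.2f} nm")
```

Output:

```
true D_r = 0.2099 /us
fit  D_r = 0.2057 /us (bare lever 0.4930 /us)
D_H = 4.12 nm, 95% CI 3.75-4.48 nm
```

The bare 48-bp lever pivots at 0.493 μs⁻¹; the 4 nm head roughly halves
the mobility, and the fit recovers the diameter to within a tenth of a
nanometre of the generating truth at the default acquisition statistics
(5×10⁴ switching cycles, 32 ns bins).

The same pipeline is available from the shell:

```bash
nanolever simulate --kind trace --seed 42 --d-h 4.0 --out sim
nanolever fit-size --up sim_up.tsv --down sim_down.tsv
nanolever --help     # dr, fit-kinetics, mixture, unfold, compare
```

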
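# Methods

## The physical model

`nanolever` simulates and analyses electro-switchable DNA nanolever
biosensing.  A short double-stranded DNA "lever" (48 bp by default,
contour length L = n_bp·b = 16.32 nm, hydrodynamic rod radius R = 1.3 nm)
is tethered by one end to a gold microelectrode.  An alternating electrode
potential, screened by the electrolyte, repels or attracts the polyanionic
DNA and drives it between a lying and a standing orientation.  A dye at
the lever tip is quenched near the metal, so the tip height — and with it
the lever's angular motion — is read out as time-resolved fluorescence.
A globular protein bound at the lever tip adds hydrodynamic friction and
slows the motion; comparing measured switching dynamics with the model
yields the protein's effective hydrodynamic diameter D_H.

The lever-plus-sphere ("lollipop") system is described by the
out-of-plane angle α (α = π/2 standing), with free energy per k_BT

    G(α) = U(α) − S(α)/k_B,
    U(α) = −(γ e Φ / k_BT) Σ_{i=1..n_bp} exp(−κ i b sin α)
           + m (γ e Φ / k_BT) exp(−κ L sin α),
    S(α)/k_B = ln cos α.

One effective charge of −e sits at each base pair at height i·b·sin α; γ
(default 0.016) is a dimensionless screening/attenuation parameter that
absorbs counterion condensation and field attenuation; κ is the inverse
Debye length (derived from the ionic strength, 1.36 nm at 50 mM monovalent
salt); m is the signed protein charge in elementary charges (default 0 —
screening makes the protein-charge contribution negligible beyond the
Debye length).  The geometric series in U is evaluated in closed form and
agrees with the explicit site sum to better than 1e-10 relative.  The
entropy ln cos α is the solid-angle density of rod orientations on the
hemisphere; it is a single swappable callable (`rod_entropy`), and passing
`entropy=None` disables it.  With this sign convention a *negative*
potential (relative to the potential of zero charge) repels the DNA and
stands the lever up, which is what the drive's `phi_up = −0.3 V` plateau
does.

A hard steric wall keeps the protein sphere above the surface:
α ≥ arcsin((D_H/2)/L), with a numerical floor of 0.01 rad for the bare
lever.  This is the simplest exclusion consistent with a rigid-sphere
head; a soft repulsive potential would smear the floor by roughly the
Debye length but adds an unconstrained parameter.

The electrode charges exponentially after each square-wave edge,
Φ(t) = Φ_target + (Φ_start − Φ_target) e^{−t/τ} with τ = 4·RC/3 (the 4/3
from area weighting of the circular electrode).  Default RC = 0.3 μs
(τ = 0.4 μs), fast compared with the 50 μs half-period of the 10 kHz
drive, so the electrode is fully charged well before the lever finishes
moving.

## Angular dynamics

The density p(α, t) obeys the drift-diffusion (Smoluchowski) equation

    ∂p/∂t = D_r ∂/∂α [ ∂p/∂α + p ∂(G/k_BT)/∂α ],

with reflecting boundaries at the steric floor and π/2 and a constant
rotational diffusion coefficient D_r (no angle-dependent wall
corrections).  The solver is a finite-volume scheme with exponentially
fitted (Scharfetter–Gummel / Chang–Cooper-type) interface fluxes and
Crank–Nicolson time stepping on a uniform cell-centered grid.  Its
discrete stationary state is exactly the grid Boltzmann distribution
e^{−G}/Z, column sums of the generator vanish (mass conserved to solver
round-off, checked to 1e-8 each step), and it is unconditionally stable.
The drift is re-evaluated at each step's mid-time potential Φ(t); because
U is linear in Φ only a scalar changes per step, keeping a step O(n).
The first 0.2 μs after each voltage edge are integrated with dt ≤ 5e-4 μs
(the drift changes fastest there); rare negative undershoots are clipped
and renormalized with their magnitude logged, and a warning fires if the
clip exceeds 1e-8.

An optional `metric="hemisphere"` variant includes the spherical Jacobian,
implemented exactly as the flat operator with G → G − ln sin α (the two
are related by p = sin α · q).  The flat-interval operator is the default.

Production defaults are dt = 0.001 μs on 256 grid points; the sizing
pipeline uses dt = 0.004 μs on 192 points (`SolverSettings.fast()`), which
changes the simulated fluorescence trace by < 0.5 % (covered by the
convergence test) at a quarter of the cost.

## Fluorescence and the Dynamic Response

Quantum yield near gold: f(z) = floor + (1 − floor)·z⁴/(z⁴ + z0⁴) with
z0 = 6 nm, floor = 0.02 — a monotone energy-transfer-type curve whose
sensitive range spans the 0–16 nm tip-height range of the 48-bp lever.
The true calibration is instrument-specific; these are fixed configuration
values and are never co-fitted with D_r.

F(t) = ∫ p(α, t) f(L sin α) dα is normalized min-max between the lying and
standing plateau levels.  For simulated traces the plateaus are the exact
discrete Boltzmann plateau fluorescences (which the scheme reaches
identically); for measured/counts traces they are estimated as the mean of
the final 10 % of each half-cycle.  Because the normalization is affine it
cancels the absolute intensity and any unmodulated background exactly.

The Dynamic Response within a window [t0, t1] is the trapezoidal area
under F_norm (upward) or above it (downward), in μs; the default sizing
window is 0–3 μs and the mixture window 3–9 μs.

## Hydrodynamics and sizing

D_r^DNA of the end-tethered rod uses the Tirado–García de la Torre
cylinder result with the image-rod construction (a rod pivoting on a
plane is the upper half of a 2L rod rotating about its center):
D_r = 3 k_BT [ln(L/R) + δ(L/R)] / (4πηL³) with
δ(p) = −0.662 + 0.917/p − 0.050/p².  The 1/4 prefactor relative to
center rotation is the end-rotation correction (the friction moment about
an end is 4× that about the center).  Default conditions (water,
η = 0.89 mPa·s, 298.15 K) give 0.493 μs⁻¹ for the 48-bp lever.  The
protein head adds ζ_head = 3πη D_H (L + D_H/2)², a Stokes sphere
translating at the lever arm of its center, so
D_r^comp = k_BT / (ζ_DNA + ζ_head) — strictly decreasing in D_H — and
the inversion D_r → D_H is a bracketed Brent root-find on [0, L] to
1e-4 nm.  A validity warning fires for D_H ≥ L/2, where steric
interactions invalidate quantitative sizing.

The trace fit has a single free parameter, D_r^comp.  Because the steric
floor depends on the (unknown) D_H, the 1-D objective makes it
self-consistent: each candidate D_r is inverted to a D_H, which sets the
floor for that forward simulation.  The simulation starts at the lying
equilibrium, runs over the fit window (default 0–12 μs — long enough to
capture the upswing of the slowest valid complexes), and is compared
with the measured normalized trace at its own time bins by least squares
(bounded Brent).  An approximate 95 % interval on D_H comes from the
local curvature of the SSE profile propagated through the inversion.

The prolate-ellipsoid equivalent diameter (for sizing from structure
bounding boxes) uses the Perrin translational friction factor with the
long box dimension as 2a and the geometric mean of the two short
dimensions as 2b: D_H = 2aξ / ln[(1+ξ)/(b/a)], ξ = √(1 − (b/a)²),
with a series expansion near the sphere limit.

## Kinetics and assays

Binding follows a 1:1 Langmuir model in the reaction-limited regime:
single-exponential association (k_obs = k_on c + k_off) and dissociation
(k_off) fits with an offset, plain least squares by default (soft-L1
optional), no baseline-drift term.  Fits are flagged when the amplitude
is within 3× the residual scatter (no resolvable signal).
K_D = k_off/k_on with first-order error propagation.

Mixture fractions come from linear DR interpolation between pure-species
endpoints, clipped to [0, 1] with a warning (extrapolation is invalid but
numerically common).  The unfolding analysis fits the glycerin control's
normalized DR linearly in relative viscosity (requiring R² ≥ 0.98),
subtracts the prediction from the urea series at matched viscosity, and
fits a 4-parameter logistic to the residual; a transition is declared
when the amplitude exceeds 3× the pooled s.d. and the midpoint lies in
the sampled range, with the reported range covering 10–90 % of the
amplitude.  Group comparison reports the difference of replicate means
with the Welch standard error and a 3σ separation rule — replicate-level
descriptive statistics, not hypothesis tests.  Relative viscosities of
urea (per M) and glycerin (per % v/v) at 25 °C come from a built-in
handbook-level lookup table, overridable with measured values.

## Synthetic data

The generators define the study conditions: 10 kHz drive, ±0.3 V
effective plateau potentials, 32 ns photon bins, 5×10⁴ integrated cycles
(≈5 s of acquisition), 0.05 signal counts/bin/cycle at unit fluorescence
and 0.005 background counts/bin/cycle, Poisson counting noise.  Binding
traces use the DHFR-like rates (k_on = 1.25e5 M⁻¹s⁻¹,
k_off = 5.7e-4 s⁻¹) at 10 nM with Gaussian noise; assay tables use 3 %
relative DR noise (mixtures), 1 % absolute noise on normalized DR
(viscosity series) and Gaussian replicates (groups).

What the generators do *not* emulate: photobleaching and blinking,
instrument response functions, layer-density heterogeneity and steric
crowding, nonspecific adsorption, baseline drift, and mass-transport
limitation.  Passing recovery tests therefore demonstrate the internal
consistency and statistical calibration of the inference chain under the
model's own assumptions, not robustness to those instrumental and
surface effects in real data.

## Numerical choices and limitations

* Internal units: nm, μs, k_BT, volts; conversions centralized in
  `constants.py`.
* Quadrature is the midpoint rule on the cell-centered grid everywhere,
  matching the finite-volume mass exactly.
* The equilibrium at a plateau potential is used to initialize each
  half-cycle; at 10 kHz the half-period (50 μs) exceeds all relaxation
  times of valid systems, making the cycle periodic to < 1e-6 (L1).
* Degenerate inputs are rejected early (grids < 8 points, non-normalized
  densities, windows outside trace support, aspect ratios < 2 for the rod
  formula, D_r^comp > D_r^DNA).
* The model is rigid-rod only: no DNA bending, no explicit double-layer
  electrostatics, no hydrodynamic wall corrections to D_r.  Sizing is
  quantitative only for D_H < L/2 (≈8 nm for the 48-bp lever) and loses
  sensitivity when ζ_head ≪ ζ_DNA (sub-kDa analytes).
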
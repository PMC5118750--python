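# Methods

## Continuum model of the grafted film

The film is treated as a polyelectrolyte brush at high grafting density:
strands stretched into rods normal to the electrode, so all structure
collapses onto the coordinate `z`. The fixed charge is piecewise constant
over three bands — neutral thiol (`0 ≤ z < 1` nm by default), linker
(35 bases over 14 nm, i.e. 0.4 nm per base), aptamer head (15 bases over the
1.6 nm axial height of the folded quadruplex) — with band edges half-open
`[low, high)` so the density is single-valued everywhere. The volumetric
charge of a band holding `N` bases of height `H` at grafting density `σ` is
`−e f N σ / H`.

**Manning renormalisation.** Counterions condense on a line charge whose
spacing `b` is below the Bjerrum length `l_B = e²/(4π ε₀ ε_r k_B T)`,
leaving the fraction `f = b/l_B` of the bare charge effective; `f` is capped
at 1 for `b ≥ l_B`, where the theory predicts no condensation. The formula
is evaluated in SI units with the explicit `4π ε₀` (the compact
Gaussian-units form `e²/εkT` is the same quantity). With the default
`ε_r = 78.5` at 300 K, `l_B = 0.710` nm and `f = 0.564`; quoting `l_B` to
one digit (0.7 nm) gives the commonly cited `f = 0.57`.

**Electrolyte.** Symmetric 1:1 salt, default 0.1 M at 300 K. The screening
length is `λ_D = (8π l_B n₀)^(−1/2)` (0.965 nm at 0.1 M). Finite ion size
enters through the Borukhov lattice-gas correction with packing fraction
`ν = 2 n₀ a³`; the default ion radius `a = 1.96` nm gives `ν ≈ 0.91` at
0.1 M. That radius is much larger than a hydrated ion and is kept as the
model's stated operating point rather than re-derived; with ion exclusion
from the film (the default), ν only shapes the diffuse layer outside, where
its main effect is to soften the ion-density saturation. Setting
`ion_radius = 0` recovers point-ion Gouy–Chapman behaviour exactly.

**Governing equation.** In dimensionless variables `u = eψ/k_BT`,
`x = z/λ_D`:

```
u'' = χ_out(x) · sinh(u)/(1 − ν + ν cosh u)  −  ρ_DNA(x)/(2 e n₀)
```

where `χ_out` switches the ion term off inside the film when exclusion is
enabled. The per-band magnitude of the fixed-charge term is the
dimensionless brush coefficient `N f σ / (2 H n₀)` (≈0.12 for the linker
band and ≈0.44 for the head band at σ = 10¹² cm⁻²). Boundary conditions:
`u(0)` set by the electrode potential; `u'` = 0 at the truncated far
boundary `z = total_height + 10 λ_D`. Ion exclusion covers the whole film
including the thiol band (the dense self-assembled monolayer picture); both
the exclusion toggle and the pad width are settable.

## Numerics

Uniform grid (default 0.005 nm), second-order central differences, with the
Neumann end closed by a reflected ghost node (second order). The interior
residual rows are scaled by `h²` — i.e. the solver drives
`u_{i−1} − 2u_i + u_{i+1} − h² g(u_i)` to below `residual_tol` (default
1e−10) — which keeps the max-norm target attainable near machine precision
independent of grid spacing; in unscaled terms the default tolerance bounds
`|u'' − g|` by about 4e−6, and the Gauss-law self-consistency test shows the
discrete Laplacian reproduces the charge density to better than 1e−6
relative when the tolerance is tightened one notch.

The nonlinear system is solved by Newton iteration with a tridiagonal
banded Jacobian and a halving line search on the residual max-norm, started
from the Debye–Hückel decay `u₀ e^{−z/λ_D}`. If the direct solve stalls, a
four-stage continuation ramps the fixed-charge source (¼, ½, ¾, 1 of full
strength), always finishing at full strength so the returned profile solves
the intended problem or is flagged unconverged (and raises in strict mode).
The field is `E = −dψ/dz` by central differences (one-sided second-order at
the ends), positive pointing from electrode into solution. Accuracy against
the closed-form Gouy–Chapman solution at +100 mV is ~5e−6 relative on the
default grid; halving the grid spacing changes the film-scale field change
by <0.5%.

Degenerate inputs: zero grafting density and/or zero electrode potential are
ordinary cases (the zero solution is reached in one iteration); a band with
zero bases or zero height simply contributes no charge; potentials above
1 V are rejected as outside the model's sanity range.

## Field analysis conventions

"Top of the layer" is `z = total_height` (16.6 nm default), the head band is
15–16.6 nm, and the film-scale field change is measured thiol-top → layer-top.
These readings make the reported ~0.06 V/nm (σ = 10¹², +300 mV, full film)
and ~0.002 V/nm (σ = 10¹¹, head band) changes direct consequences of
Gauss's law: with ions excluded, the change across a band equals its
enclosed charge per area over `ε ε₀`, and the head/linker slope ratio is
`(15/1.6)/(35/14) = 3.75` exactly. The sweep's sign column classifies the
field over the whole charged film (thiol top to layer top): "positive" /
"negative" when it keeps one sign, "mixed" when it changes sign inside the
film. Linker condensation is modelled charge-conservingly: the same 35
bases compressed into a shorter band, head geometry unchanged and shifted
down; the 15-mer-only limit is a separate constructor, not the
`new_height → 0` limit.

Two field magnitudes quoted in the source literature for the layer top
(+0.006 and +0.18 V/nm at +100/+300 mV, and 0.04/0.03 V/nm for the
15-mer-only geometry) have an ambiguous density/geometry assignment, and
0.18 V/nm exceeds what a 300 mV total drop can sustain over the film; the
package checks only sign and order of magnitude for these, not the numbers.

## WHAM stage

Standard self-consistent WHAM on shared histogram bins (default 100 bins,
matching the bootstrap convention of the emulated study): iterate the
`P_b`/`f_i` pair from `f_i = 0`, anchor `f₁ = 0`, stop when
`max|Δf_i| <` tolerance (default 1e−8 k_BT, max 1e5 iterations). The
iteration is evaluated in log space (log-sum-exp) so large well depths and
stiff biases cannot overflow. Bins with zero total counts are masked NaN,
never interpolated. ΔG_binding is the mean PMF over the unbound plateau
minus the minimum over the bound region, positive for a well, reported in
kcal/mol (kJ/mol available); the plateau-mean reference makes the estimate
insensitive to single-bin noise at the PMF tail. The bootstrap resamples
whole observations within each window (appropriate for independent
samples; a Langevin sampler exists to produce correlated inputs when a
block-resampling path needs exercising), re-runs WHAM per replicate, and
reports the ΔG standard deviation and per-bin PMF spread after
re-referencing each replicate to its plateau; replicates that fail to
converge are dropped with a warning, >10% dropped is an error.

## Synthetic umbrella-sampling generator

The generator defines the study conditions the estimator is validated
under: 42 windows uniform on 1.2–4.0 nm, force constant 1000 kJ/mol/nm²,
5000 samples per window, 300 K (k_BT = 2.494 kJ/mol). Samples are exact
i.i.d. inverse-CDF draws from the biased Boltzmann density tabulated on the
true PMF's 10⁴-point grid — so tests of the estimator are sharp: deviations
are estimator error, not sampling-dynamics error. The default true PMF is a
double well: a 20 k_BT (≈12 kcal/mol, the scale of a strong aptamer–protein
complex) bound well at ξ = 1.6 nm, an 8 k_BT intermediate at 2.4 nm, and a
flat plateau (zero) reached by ξ ≈ 3 nm; harmonic, Morse-like and tabulated
profiles are also available. A bias whose density would pile onto a grid
edge (>50% of mass in the outer 1% of the range) is rejected rather than
silently clipped.

What the generator does **not** emulate: trajectory autocorrelation,
equilibration transients, pulling hysteresis, solvent/field physics, or any
3-D structure. Passing the recovery tests therefore demonstrates estimator
correctness on ideal data, not the adequacy of any molecular simulation.

## Problem sizes used in the validation suite

Continuum checks run on the default 0.005 nm grid (~5200 nodes, milliseconds
per solve); qualitative sweep properties use a 0.01 nm grid. The WHAM
recovery checks use the full 42 × 5000 study; the bootstrap sample-size
scaling check uses 1000- vs 4000-sample windows with 24 replicates each and
a 1e−6 k_BT replicate tolerance, sizes at which the recovered RMSE and the
scaling ratio are stable across seeds.

## Known limitations

1-D mean-field electrostatics: no Stern layer, image charges, dielectric
inhomogeneity, ion–ion correlations, multivalent or mixed salts, or lateral
structure; the protein is absent from the continuum model. The stretched-rod
charge model brackets, but does not resolve, linker flexibility. WHAM here
is 1-D with harmonic biases only; no MBAR, no autocorrelation-time
estimation — error bars on correlated (e.g. Langevin) input require block
resampling, and the plain bootstrap will understate them.
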
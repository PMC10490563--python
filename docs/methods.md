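# Methods

## Problem and model

`eisr` quantifies the achievable resolution of far-field electromagnetic
inverse scattering (EIS) in the weak-scattering regime relevant to microwave
medical imaging.  The setting is 2-D and transverse-magnetic: scatterers are
dielectric profiles ε(r) in a homogeneous background inside an imaging domain
D, illuminated by unit plane waves from a far-field ring, with point receivers
on the same ring.  The unknowns are the contrast χ = (ε − ε₀)/ε₀ and the
contrast current J = χE.  On the discretised grid the model is

    J  = χ (Ei + GD J),      Es = GS J,

with GD and GS the domain and surface Green operators (k₀² and cell area
folded in).  The Born approximation (BA) linearises J ≈ χ Ei, splitting the
inversion into two linear steps: a minimum-norm current from the data
(truncated SVD pseudo-inverse of GS) and a cell-wise least-squares contrast
over the incidences.

## Why the point image is [J0(k0 x)]²

Far-field data sample the 2-D Fourier transform of the current on a ring of
radius k₀/2π (the accessible shell of spatial frequencies).  Inverting data
supported on a thin ring of effective thickness ΔR produces the kernel
k₀ ΔR J0(k₀ρ); the least-squares contrast step against the conjugate plane
waves contributes a second angular average with the same Bessel form.  A point
scatterer therefore images as

    PSF(x) ∝ [J0(k0 x)]²,

and, because BA is linear in χ, an extended weak scatterer images as the
convolution χ ∗ PSF (the general spread function, GSF).  ΔR only scales
amplitude; all analysis in this package is on normalised profiles, so ΔR is
never quantified.

## Resolution criteria

All criteria are bracketed root finds on analytic 1-D joint profiles along
the axis through both scatterers, with closed-form derivatives via
d/du J0²(u) = −2 J0(u) J1(u):

* **Rayleigh** — first null of the PSF: σ = 0.383 λ (first root of J0 over
  2π).  Only meaningful for point-like scatterers.
* **Sparrow, points** — smallest d with f''(0; d) = 0 for
  f = PSF(x+d/2) + PSF(x−d/2): σ = 0.344 λ.
* **Sparrow, cylinders** — each cylinder of radius r contributes the interval
  integral of the PSF over [x−c−r, x−c+r] (the 1-D reduction of the disk
  convolution; see "1-D vs 2-D profiles" below).  The second derivative is a
  four-boundary-term closed form in J0·J1.  The criterion is applied
  edge-to-edge, σ = d − 2r.  For r = 0.1 m at 300 MHz: σ = 0.152 m — beyond
  the half-wavelength diffraction limit.  An inverse query (nested bisection
  on r) finds the radius whose pair resolves at a target σ; σ = 0.25 λ needs
  r = 0.048 λ.
* **Modified Sparrow** — for unequal weights or radii the emerging dip is not
  at the midpoint, so the midpoint-curvature condition is replaced by a
  saddle condition at the profile's interior stationary point g (the
  "Gaussian point"): the critical separation d* is where f'(g) = 0 and
  f''(g) = 0 simultaneously — below d* the profile rises monotonically into
  the single surviving peak, above d* a dip and a second maximum exist.
  σ = d* − a₁ − a₂.  This reading is chosen because it reduces exactly to the
  symmetric criterion (g = 0) for identical scatterers and is the only
  formulation that stays well defined for asymmetric profiles.  Weights
  default to the scatterer contrasts, which is what the linearity of the GSF
  in χ prescribes and what makes unequal-permittivity pairs computable.

Numerically, d* is located by bisection on the count of interior stationary
points (dense sign-change scan of f' at 2000 samples per wavelength inside a
window extending 0.2 λ beyond the two centres, each bracket refined by Brent),
then polished on the two-equation saddle system.  Near dip emergence the
saddle can sit slightly *outside* the open interval between the centres (for
the 1.1/1.2 point pair, g = −0.201 m with centres at ±0.191 m), which is why
the stationary-point search window carries a margin.  Search constants:
separation tolerance 1e−6 λ, Gaussian-point tolerance 1e−8 m, window margins
0.2 λ (criterion) and 0.05 λ (standalone Gaussian-point query); all are
module constants and logged per run.

Reference values at 300 MHz, all computed by the acceptance script at run
time: 0.383 λ, 0.344 λ, 0.152 m, 0.048 λ, 0.382 m, 0.147 m.

## Forward solver

Pulse-basis, point-matching method of moments on square cells.  The
self-interaction integrates the kernel over the equal-area circle of a cell,
the canonical closed form for this discretisation; the residual square-vs-
circle geometric difference is ~0.3% of the self term (measured against
nested adaptive quadrature) and enters solutions only at second order in χ.
The solve is restricted to the scatterer support — exact, since J = 0
wherever χ = 0 — so the dense cells×cells operator is never formed on large
grids.  Solutions are accepted only if the relative residual is ≤ 1e−10;
singular (resonant) systems raise instead of returning garbage.

**Sign convention.**  The kernel is g = −(j/4) H0⁽¹⁾(k₀|r−r'|) with time
convention exp(−jωt).  This is the negative of the radiating Helmholtz Green
function; the choice leaves every reconstruction invariant (forward data and
pseudo-inverse share GS, so the sign cancels in the recovered current), but
it does mean the solved far field for contrast χ equals the physical
scattered field for contrast −χ.  The dual-route validation against the
cylindrical-harmonic mode-matching series uses exactly that equivalence
(εr → 2 − εr) and agrees to 0.5% RMS at λ/100 cells.

## Synthetic scenes and study conditions

No external data exist; all inputs are generated in-repo.  The default study
configuration is 300 MHz with the speed of light rounded to 3e8 m/s so that
λ = 1 m exactly (wavelength-denominated and metre-denominated results then
agree digit-for-digit; the CODATA value is a flag away).  The imaging grid is
2 m × 2 m with 0.02 m (λ/50) cells centred at the origin; the antenna ring has
radius 10 m (10 λ, comfortably far-field) with 36 transmitters and 36
receivers.  Point scatterers occupy one grid cell with εr = 1.1 unless
overridden — weak contrast keeps BA valid.  The named fixtures reproduce the
two-scatterer studies: point pairs at 0.30/0.34/0.38 m, r = 0.1 m cylinder
pairs at edge gaps 0.12/0.16/0.20 m, εr 1.1/1.2 point pairs at
0.34/0.38/0.42 m, and r = 0.1/0.15 m cylinder pairs at edge gaps
0.11/0.15/0.19 m.  Point separations are centre-to-centre; cylinder
separations are edge-to-edge, consistent with the d − 2a convention of the
extended criteria.

What the generator does *not* emulate: measurement noise (no noise model is
defined for the pipeline, so none is implemented; the `--seed` flag is
reserved), antenna patterns (receivers are ideal point samplers), lossy
tissue-like media (real permittivities only), multiple-scatterer mutual
coupling beyond what the exact forward solve provides, and any 3-D effect.
Passing tests therefore demonstrate the internal consistency of the BA
resolution theory under its own assumptions, not robustness on measured
antenna-array data.

## 1-D vs 2-D extended-scatterer profiles

The interval-integral profile treats a cylinder as a 1-D segment along the
scan axis.  It is the form all resolution numbers are computed from; the full
2-D disk convolution is also implemented (`gsf`) for images.  The two are
different reductions of the same object: at the r = 0.1 m Sparrow separation
their normalised cross-sections differ by ≈ 0.9% RMS over |x| ≤ λ (the test
suite pins a 5% ceiling).  This is a modelling discrepancy, measured rather
than hidden.

## Numerical choices

* SVD truncation at 1e−3 × σ_max by default (config knob, logged): an
  explicit, reproducible stand-in for the implicit regularisation that
  finite receiver counts provide.  36 of 36 receiver modes keep 27 values at
  the default geometry.
* Only |χsol| is used for peak/dip analysis and display; phase is retained in
  outputs.  Displayed images are normalised to peak 1.
* Interval-profile quadrature: adaptive with absolute tolerance 1e−10;
  2-D GSF kernel truncated at 3 λ, where J0² is below 1% of its peak.
* 36 incidences approximate the continuous angular average; doubling to 72
  moves the point-image cross-section by < 1% (test-covered).
* Dip detection on reconstructions counts local maxima of the midline
  cross-section within |x| ≤ d/2 + 0.15 λ, keeping the analysis away from PSF
  side lobes.
* Degenerate cases: empty scenes produce zero fields/profiles; merged
  profiles with no interior dip report the lowest interior critical point;
  criterion brackets that never change sign raise with the scanned range.

## Problem sizes

Test and acceptance runs use the default 100 × 100 grid (10⁴ cells) for
pipeline checks, a 150 × 150 λ/100 grid for the resolvability-transition
scan, and a 40 × 40 λ/100 grid for the forward-solver series validation;
these sizes make every claimed number reproducible on a laptop-class single
core in seconds while keeping discretisation error far below the tolerances
asserted.

## Known limitations

* The criteria describe the *linear* (BA) reconstruction; iterative schemes
  (Born iterative and distorted-Born) inherit the analysis only onto their
  per-iteration linear steps and are out of scope.
* Arbitrary scatterer shapes (squares, concave profiles) have no closed-form
  1-D profile here; only points and circular cylinders do.
* Resolution claims are noiseless; any measurement noise interacts with the
  SVD truncation level in ways this package does not model.
* The asymmetric-pair criterion assumes exactly two scatterers with the
  dip emerging between them.
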
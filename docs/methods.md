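# Methods

## The device and the question it poses

A multimode fiber (100 um diameter, core/cladding indices 1.4613/1.4562) is
drawn to a 280 um taper ending in a 1 um tip, embedded in a transparent
polyester patch (PMCL, n = 1.49, 125 um thick, 25 mm across), and pulled back
by a distance *d*, leaving an air cavity that is the exact mold of the taper.
Light leaving the sub-wavelength tip diffracts into a wide cone; the cone
refracts at the air/patch cavity wall and is redirected sideways, then the
high-index patch guides and spreads it over the patch area and into the
tissue below. The design question is the choice of *d*: the model computes
the lateral power fraction P_s/P as a function of *d* and the resulting
illumination geometry.

## Model structure and assumptions

1. **Geometric optics throughout.** Interference, diffraction ringing and
   modal structure are not modelled; the tip's diffraction is represented by
   its *outcome*, a wide emission cone. Published wave-optics divergence
   values (for example a simulated 97 deg for the bare taper in air) are
   therefore not targets of this model; only ray-optics observables are.
2. **Point-source emission.** The 1 um tip is below the working wavelength,
   so emission is a point source at the retracted tip apex. The default
   density is uniform per solid angle inside a cone of half-angle 65 deg
   (130 deg full divergence, the value the geometric design argument uses).
   A cosine-weighted and a side-weighted density (power proportional to
   sin(theta) beyond a 30 deg knee) are provided for sensitivity runs,
   because the taper is known to push light sideways but no measured
   distribution exists.
3. **Taper profile.** The exact drawn profile is not public; the default is
   a convex power law `F(z) = 0.5 + 49.5 (z/280)^2` um (heat-pulled tapers
   are convex), with the endpoints fixed by the measured tip (1 um diameter),
   fiber (100 um) and taper length (280 um). The profile is an injectable
   callable; endpoint behaviour dominates the downstream statistic, and the
   exponent is exposed for sensitivity analysis.
4. **Unpolarized Fresnel splitting.** The source is a multimode fiber with
   no defined polarization, so power splits by the s/p average. Incidence
   exactly at the critical angle counts as total internal reflection (the
   grazing transmitted wave carries no power). All media are lossless in the
   device; absorption exists only in tissue.
5. **Deterministic two-branch splitting.** At every interface the transmitted
   branch terminates (recorded, or ledgered as a loss) and the reflected
   branch continues with weight x R, so each ray is a single weighted path.
   Compared with Russian roulette this is bias-free, bit-reproducible, and
   cheap at this problem scale. Paths stop at depth 8 or when their weight
   falls below 1e-4 of the ray's initial weight; stopped power goes to the
   loss ledger, never silently dropped. Power re-entering the retracted
   fiber through its cladding is terminated into the ledger: the model
   tracks only power that leaves the gap, and re-guiding along the fiber is
   out of scope.
6. **Slab transport.** The patch is a disk with the fiber axis in its
   mid-plane: air above, tissue (n = 1.4) below, air at the rim. The
   adhesive/epicardium stack is collapsed to a single patch/tissue index
   step. Straight rays with Fresnel/TIR at each face; exits record side,
   position, refracted angle and weight.

## The forward propagation region and P_s/P

The forward propagation region is the cone of half-angle 43 deg about the
fiber axis **with vertex at the fiber tip** — a spatial region, not a set of
directions. P_s/P is the fraction of gap-exiting power that leaves this
region. Two scoring modes are implemented:

* **Near-field (default).** Each exiting ray is advanced to a sphere of
  radius 100 um around the tip and classified by its position angle there
  (rays already beyond the sphere are classified where they stand). The
  100 um default is the scale at which the patch-slab faces take over the
  optics (the first face is 62.5 um from the axis) and matches the
  near-field windows on which such device simulations are scored. The
  design curve is robust to this choice: windows from 80 to 300 um give the
  same rise / plateau / decline shape.
* **Far-field** (`eval_range_um=None`). Classification by exit direction
  alone. This statistic is *monotone increasing* in d — a result of the
  model worth stating: refraction at a wall that makes angle alpha_t with
  the axis sends every transmitted ray to a polar angle of at least
  47.8 - alpha_t degrees, and for a point source the self-selected hit
  points keep alpha_t below ~5 deg at every d, so in the far field
  essentially all power is lateral once d exceeds a few um. The observed
  fall-off at large d is a near-field effect: light exits the long cavity
  close to the axis and far ahead of the tip, inside the spatial forward
  cone, even though its direction is oblique.

The 43.0 deg half-angle is the printed design constant; the value computed
from the shipped indices is arcsin(1.0003/1.49) = 42.17 deg and can be set
via configuration. The 0.8 deg difference moves P_s/P by under one
percentage point.

## Divergence estimation

From an angular distribution: the beam edge is the largest polar angle whose
per-steradian density still reaches 5% of the peak (threshold exposed), with
sub-bin linear interpolation; the divergence is twice the edge. From a beam
image (the synthetic analogue of the fluorescent-dye light-path photographs,
imaging medium n = 1.40): per axial column, the transverse positions where
intensity falls below 5% of the column maximum define the two beam edges;
two least-squares lines over the central 20–95% of the beam span give the
edge directions and the angle between them. Images carry Gaussian blur
(sigma = 2 px) and optional Poisson shot noise at peak counts 2^16 / 2^12 /
2^8 for the none / moderate / high fixture noise levels. The estimator
recovers ground-truth cones of 20–130 deg within 2 deg on clean and 5 deg on
moderately noisy images; threshold sensitivity (0.05 vs 0.10) stays under
3 deg.

## Tissue calculators

Tissue transport is pure Beer–Lambert along straight rays,
`exp(-mu_eff * s)` — no scattering phase function, the model's main
simplification. `mu_eff = ln(100)/0.5 = 9.21 /cm` is a **calibration**, not
a measurement: it is back-solved so the 1% detection threshold is reached at
the empirically observed 0.5 cm red-light penetration. Illumination volumes
are closed forms per device class: flat-end cone (divergence 20 deg),
matt-tip hemisphere (radius = its penetration depth; the reference
comparison uses the observed ~1.5 cm diameter), side-glow column (radius =
penetration, height = emitting length + penetration; for inserted fibers the
height adds the insertion length), and the patch's footprint disk (patch
diameter + 2 x 0.5 cm outskirt, uniform depth). The footprint closed form
with the 2.5 cm patch gives 3.5 cm; the ex-vivo report of a 3 cm illuminated
circle is internally inconsistent with a 2.5 cm patch plus 0.5 cm outskirts
(the patch diameter of that particular run was not stated), and the
inconsistency is left documented rather than resolved. Likewise the observed
~2 cm side-glow column diameter does not follow from the radius =
penetration formula at 0.5 cm; both the formula and the observation are
exposed.

## What the synthetic data does and does not emulate

The generator supplies (a) the reference device and the standard pull
distance plan {0.5, 1, 2, 5, 10, 15, 20, 25, 40, 60, 80, 120} um with seeds
derived as base + index, (b) beam-image fixtures with known ground-truth
divergence rendered as meridional ray fans with blur and shot noise, and
(c) degenerate oracle geometries (flat-wall cavity, symmetric slab,
index-matched slab) carrying their closed-form expectations. The images
emulate edge geometry and counting noise of the dye-visualization
photographs, not photographic realism: no camera optics, fluorophore
saturation or photobleaching. Passing the round-trip tests shows the
estimator is correct on beams whose edges are straight lines with known
noise; real photographs add background gradients and scattering halos that
are not represented.

## Numerical choices

* Surfaces of revolution are intersected by adaptive marching (step
  proportional to the radial gap, floored at 0.02 um) plus bisection to
  ~1e-10 um; after each reflection the path restarts nudged 1e-6 um into the
  air region so grazing paths cannot re-trigger the same surface.
* The compiled (numba) tracer handles the power-law profile; a pure-Python
  tracer with identical physics handles arbitrary injected profiles and is
  cross-checked against the compiled path in the tests.
* Angular distributions use 1 deg polar bins, power-weighted; Monte Carlo
  standard errors for P_s/P use the binomial formula at the run's ray count.
* Default run size is 1e5 rays (the full 12-point design sweep takes ~15 s
  on one CPU); tests use 2e4–2e5 rays depending on the tolerance they
  assert.
* d = 0 is traced as the no-gap limit (the emission cone refracted at a flat
  virtual index step into the patch); d values outside (0, 120] um are
  accepted with a warning.

## Known limitations

Wave effects (the forward "dark region" is reproduced only as low forward
power, not as an interference null), polarization, wavelength dispersion
(indices are for red light; blue/green shift them slightly), volumetric
scattering in the patch, the adhesive layer, patch bending, and re-guiding
of light that re-enters the fiber are all out of scope. The taper profile
exponent and the emission density are the two model inputs with no measured
values; both are exposed as configuration for sensitivity analysis.
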
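# Methods

This note documents the models implemented in `ribpet`, the synthetic
generators that stand in for Monte Carlo particle transport, the default
parameters and why they were chosen, and the limitations that follow.

## Range–energy law and depth-dose model

Ion ranges follow a Bragg–Kleeman power law,
R = c·(A/Z²)·(E/MeV·u⁻¹)^p with p = 1.75, the standard ion-therapy
approximation. The single constant c is calibrated so a 290 MeV/u carbon
beam has a 160 mm range in water — a conventional anchor for that beam
energy, chosen once; in other materials the water range is divided by the
material's water-equivalent ratio (wer). Default wer values (water 1.0,
PMMA 1.16, bone 1.6, brain-as-muscle 1.04) are config constants and
overridable, as is the exponent. Because the law is a pure power law it is
analytically invertible, which the energy-from-range helper and the
stable→radioactive spectrum mapping exploit.

The pristine depth-dose curve is a documented closed form: an entrance
plateau `1 + 0.3·z/R` cut off by an erfc step of width σ at the range, plus
a Gaussian peak of amplitude 4 (relative to the entrance) and width σ, plus
an exponential fragmentation tail (amplitude 3 % of the peak, 30 mm decay
length) beyond the peak. Range straggling σ defaults to 1 % of the range;
the plateau and peak terms are hard-truncated at R + 3σ so that switching
the tail off makes the dose vanish identically there. The curve is a shape
stand-in — peak-to-entrance ratios of real beams vary with energy spread
and nozzle design — but it has the three features the analyses depend on:
a plateau, a narrow peak at a controllable depth, and a small tail.

Layered phantoms convert physical depth to water-equivalent depth by
piecewise-linear accumulation of thickness × wer. The reference skull
phantom is 10 mm bone over 240 mm brain tissue modelled as muscle. Plans,
RBE profiles and annihilation maps are expressed in *physical* depth;
depth-dose evaluation maps each physical grid point to its water-equivalent
depth internally.

## Modified MKM

The saturation-corrected dose-mean lineal energy y*, the linear-quadratic
α, and RBE₁₀ are implemented exactly as stated in the README. Numerical
choices:

* `log(0.1)` is the **natural** logarithm. Only ln makes a radiation field
  whose own 10 %-survival dose equals the 5 Gy reference return
  RBE₁₀ = 1 exactly; the test suite locks this convention.
* β in the RBE₁₀ expression equals β₀ — the MKM treats the dose-squared
  coefficient as radiation-independent.
* y* is computed by trapezoidal quadrature on the spectrum's own grid; a
  single-point grid is treated as a delta spectrum. The result is
  invariant to rescaling f(y) by any positive constant.
* The unit constant 0.1602 converts keV/µm (with ρ in g/cm³ and r_d in µm)
  to Gy in the α formula.
* y₀ defaults to 150 keV/µm, the canonical saturation parameter of the MKM
  literature; it is a config field.
* The sensitive volume is a 1 mm × 1 mm × 10 µm slab scored every 100 µm
  along the beam; for a forward-directed field the mean path length through
  such a slab is taken equal to its 10 µm thickness. Both are fields of
  `SensitiveVolumeSpec` so users can substitute their own geometry.

RBE-versus-depth profiles report, at each depth, the mean and population SD
of RBE₁₀ over 11 consecutive sensitive volumes centred on it; the 95 %
band is mean ± 2 SD. In brain-as-muscle a stopping-power/density
correction of 1.05 is applied, by default as a depth scaling (the
water-equivalent depth is multiplied by 1.05 before the field is
evaluated); a config switch (`correction_mode: dose`) applies it to the
sampled lineal energies instead, since either reading of a bulk
stopping-power correction is defensible.

## Synthetic lineal-energy generator

Scored microdosimetric spectra are emulated by a log-normal mixture. Each
beam component (energy E, weight w) contributes events in proportion to
w times its local closed-form dose. The component's mean lineal energy is

    ȳ(z) = y_ent · (R / (R − z + σ))^(3/7),   y_ent = 3.2 · Z² / R^(3/7),

capped by the smoothing term σ (the straggling width) at the peak and
dropping to 0.3·y_ent beyond R + 3σ (low-LET fragment field). The 3/7
exponent is the Bragg–Kleeman stopping-power exponent (1/p − 1); the
constant 3.2 anchors the entrance value at ~13 keV/µm for a 160 mm-range
carbon beam. Single-event lineal energies are log-normal with shape
σ_ln = 0.8 (broad, as microdosimetric single-event spectra are) and mean
ȳ(z); sampled events are histogrammed on a log grid into a spectrum.

Two deliberate properties of this parameterisation:

* ȳ depends on charge and **residual range**, not on E/u directly. Two
  isotopes of the same element matched to the same range therefore produce
  the same field. This encodes the physical near-equivalence that the
  radioactive-vs-stable comparison probes; the sub-percent velocity offset
  between isotopes at equal range is below the generator's fidelity and is
  deliberately not modelled.
* The analytic frequency-mean of the mixture is exported
  (`mixture_mean_lineal_energy`) so tests can check the sampler against a
  closed form rather than against itself.

The default 4000 events per sensitive volume corresponds roughly to the
number of primaries crossing a 1 mm² scoring area when ~10⁷ primaries are
spread over a 50 mm field, and gives per-volume RBE₁₀ spreads of a few
percent — the same order as scored-transport studies report.

What the generator does *not* emulate: detector response, δ-ray escape,
energy-loss straggling correlations between adjacent volumes, the build-up
of heavy target fragments near the peak, and beam-specific nuclear physics.
Passing tests therefore demonstrate the correctness of the MKM chain, the
optimizer and the statistics on a controlled field — not agreement with
measured RBE of any specific beamline.

## SOBP design

Weight optimization minimises Σ_z (Σ_e w_e·b_e(z) − 1)² over the target
depths (1 mm bins) with w ≥ 0 via `scipy.optimize.nnls` on the
*biological* dose curves; achieved flatness (max |relative deviation from
the mean| inside the target range) must not exceed the plan tolerance,
default 2 % — "flat" needs a number and 2 % is a common clinical flatness
criterion. An infeasible request raises with the achieved flatness. The
same optimizer builds both the carbon and the oxygen SOBP; no
passively-scattered beamline model is reproduced.

Two profile-set builders exist. `interpolate_profiles` linearly
interpolates user-supplied simulated profiles between anchor energies at
fixed depth (endpoints reproduced bit-exactly; no extrapolation). For the
synthetic study this is not used to *create* intermediate peaks — a convex
combination of narrow anchor peaks is bimodal, not shifted — so
`dense_profile_set` instead evaluates the closed-form curve at every dense
energy (1 MeV/u steps) directly, and interpolates only RBE₁₀, which is
expensive to sample, between ~5 anchor energies. That interpolation aligns
the anchors on residual range before blending, because RBE of a pristine
beam is a sharp ridge along its own range and pointwise blending would
misplace the ridge.

The stable→radioactive mapping finds the radioactive energies whose
Bragg peaks sit at the stable spectrum's proximal and distal peak depths
(Brent inversion of the range law) and affinely rescales all component
energies into that interval, preserving weights. Endpoint peak depths are
reproduced exactly; interior components are off by at most the deviation of
the affine map from the exact per-component inversion, which is well below
a grid step for the spectra used here.

## Annihilation simulation

Primaries are assigned uniformly to the spills of the schedule (default
20 × 1.9 s on / 1.4 s off at 10⁹ primaries/s; t = 0 at the start of spill
1) and uniformly within beam-on time. A fraction (default 0.2 — the
per-primary fragmentation probability is exposed as a config parameter
rather than asserted as truth) undergoes fragmentation; the fragment is a
positron emitter drawn from the per-element mix (carbon beams
¹¹C/¹⁰C/¹⁵O = 80/5/15 %, oxygen beams 44/7/49 %) and stops along the
entrance path with a half-uniform, half-triangular-rising-to-R profile —
production grows along the track but is present from the surface.
Non-fragmented radioactive primaries stop at their straggled range
(Gaussian, σ = 1 % of range) and decay after an exponential delay with
their half-life; stable primaries contribute nothing at their stopping
point. Annihilation positions get an isotropic 1 mm Gaussian positron-range
blur; photon acollinearity is folded into the 3.5 mm system PSF applied at
map level (Gaussian, σ = FWHM/2.3548, reflective boundaries, intensity
conserving). Transit time of the ion and the positron are neglected
(sub-ns versus second-scale half-lives).

Maps count events with t in a half-open window into half-open 1.5 mm
voxels. The desk-scale default of 10⁶ primaries per treatment records an
event weight so maps can be rescaled to the 3.8 × 10¹⁰ primaries of the
full schedule; all reported structure (peak locations, CNR orderings) is
scale-robust, though absolute CNR values grow with count statistics.
Coincidence detection, scanner geometry, randoms/scatter and iterative
reconstruction are out of scope — the "image" is the ground-truth
annihilation map blurred with the system PSF.

## CNR and edge regions

CNR uses **population** standard deviations (the definition carries no
n − 1 convention) and is symmetric and affine-invariant. Degenerate cases:
both regions constant and equal → 0; constant but different → +inf with a
warning. Edge regions are mirrored 10 mm slabs just inside/outside each
SOBP boundary (margin 0 by default), restricted to the central 50 % of the
transverse field for the proximal/distal edges; the lateral pair sits at
the +x field edge spanning the target depths. Region geometry is not
prescribed by any reference — slab thickness, margin and the blurred-vs-raw
choice (default: blurred, matching the imaging context) are parameters.

## Time-activity curves

The activity model is linear in the initial activities once the half-lives
are fixed, so fitting is NNLS on an exponential design matrix —
non-negativity is physical and the linear problem needs no starting values.
Frame values are treated as frame-averaged activity, so the basis functions
are frame averages of the exponentials (instantaneous values for
zero-length frames; the averaged basis converges to the instantaneous one
as frames shrink). Duplicate half-lives make the design rank-deficient and
raise. The fit covariance is the unweighted least-squares estimate
σ̂²(XᵀX)⁻¹. A flag supports decay-correcting frames against a reference
half-life, since dynamic PET data may be reported either way.

The analysis ROI ("5 % rule") runs from the first depth where the dose
exceeds the entrance plateau by 5 % to the last depth still above 5 % of
the peak. The entrance plateau is estimated as the mean over the first
10 % of the depth grid — the plateau needs a numerical definition and the
first tenth of the profile is upstream of any peak for every beam
considered here.

## Incidental dose

A₀/V = N·ln2/T½/V converts stopped-primary counts to activity
concentration. The decay dose is N·(Ē_β + f_γ·1.022 MeV)/mass with
radiation weighting 1 (positrons and photons), mean ¹¹C positron energy
0.386 MeV (physical constant), and a locally absorbed annihilation-photon
fraction f_γ = 0.3 for a head-sized volume — both assumptions are echoed
in the report and configurable. This is a bulk order-of-magnitude
estimate; no photon transport kernel is applied.

Note an internal tension in the published reference values this estimate
is usually compared against: 2.3 × 10¹¹ ¹¹C ions in a 1000 cc volume give
λN/V ≈ 0.13 MBq/cc, an order of magnitude below the 1.3 MBq/cc sometimes
quoted for that scenario. The package implements the physics formula and
reports its value rather than reproducing the quoted number.

## Convergence study

`convergence_study` doubles the sample size N, running M = 50 seeded
replicates at each step, until SD/mean drops below a threshold (default
1 %), returning the first qualifying N and the full trace. Replicate seeds
derive from a `SeedSequence` spawn, so the procedure is reproducible and
the estimator callable receives independent, stable seeds.

## Reference study and problem sizes

The end-to-end study (empty config = reference conditions) uses: skull
phantom; C12→{C11, C10} and O16→{O15}; 78–138 mm plan at 5 Gy(RBE)/min;
20 × 1.9/1.4 s spills at 10⁹ primaries/s; five RBE anchor energies; RBE
reported at 50, 81, 111, 131 and 171 mm; 10⁶ simulated primaries per beam;
1.5 mm voxels and 3.5 mm PSF. These sizes keep a full run in a few seconds
while leaving per-window event counts (tens to thousands per map) large
enough for the qualitative comparisons; all of them are config fields.
Per-stage seeds (spectra / simulation / noise) are explicit in the config —
no wall-clock seeding — and every output of a run is reproducible byte for
byte from the same config.

## Known limitations

* No transport physics: nuclear cross-sections, lateral scattering,
  neutron production and detector effects are absent; all absolute dose,
  yield and CNR values are generator-dependent.
* The depth-dose curve's plateau slope, peak amplitude and tail are fixed
  shapes, not fitted to any measured beam.
* Fragment yields per element are treatment inputs, not predictions; the
  simulated TAC yields reflect them only after decay-during-irradiation is
  accounted for.
* The MKM is applied with HSG-cell constants; other cell lines require
  their own α₀, β₀, r_d via `MKMParams`.
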
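# ribpet

Analysis tools for **positron-emitting radioactive ion beams** in heavy ion
therapy: relative biological effectiveness (RBE) along the beam path,
spread-out Bragg peak (SOBP) design for a flat biological dose, simulation
and scoring of the positron-annihilation maps used for PET range
verification, decomposition of time-activity curves into radionuclide
yields, and the incidental dose from beam decays.

Beams of ¹⁰C, ¹¹C and ¹⁵O stop inside the target and then decay by positron
emission at their stopping point, so a PET scanner can image the delivered
dose distribution directly — unlike stable ¹²C/¹⁶O beams, whose only PET
signal is the diffuse fragment background produced along the entrance path.
`ribpet` is aimed at physicists studying whether such beams are
therapeutically equivalent to their stable analogs and how much better their
range-verification images are. A documented parametric generator stands in
for Monte Carlo particle transport throughout, so every pipeline runs in
seconds on a laptop.

## The models

**RBE₁₀ via the modified microdosimetric kinetic model (MKM).** From a
lineal-energy spectrum *f*(*y*) scored in a 0.42 µm sub-cellular domain:

    y*    = y₀² ∫(1 − exp(−(y/y₀)²)) f(y) dy / ∫ y f(y) dy
    α     = α₀ + β₀ · y* / (ρ π r_d²)
    RBE₁₀ = 2 β D₁₀,X / (√(α² − 4β ln 0.1) − α)

with HSG-cell constants α₀ = 0.13 Gy⁻¹, β₀ = 0.05 Gy⁻², ρ = 1 g/cm³,
r_d = 0.42 µm, saturation parameter y₀ = 150 keV/µm, and the 200 kVp X-ray
reference D₁₀,X = 5 Gy. RBE₁₀ is the X-ray dose divided by the ion dose
giving 10 % cell survival.

**SOBP construction.** Weights *w*ₑ ≥ 0 of monoenergetic Bragg curves
*b*ₑ(*z*) are found by non-negative least squares so that
Σₑ *w*ₑ·RBE₁₀(*z*)·*b*ₑ(*z*) is flat over the target depths (default
78–138 mm in a skull phantom, 10 mm bone + 240 mm brain). A stable-ion
spectrum is mapped onto its radioactive analog by matching Bragg-peak depths
at the spectrum edges and affinely rescaling the energies in between.

**Annihilation maps and CNR.** Primaries arrive in synchrotron spills
(20 × 1.9 s on / 1.4 s off), stop at their straggled range, and decay
exponentially (T½: ¹⁰C 19.29 s, ¹⁵O 122.24 s, ¹¹C 20.334 min); a
configurable fraction fragments along the entrance path instead. Decays are
binned into 1.5 mm voxels per acquisition window, blurred with the 3.5 mm
scanner PSF, and scored with the contrast-to-noise ratio
CNR = |μ_a − μ_b| / √(σ_a² + σ_b²) between paired regions at the SOBP
proximal, distal and lateral edges.

**Yields and dose.** A region's total activity
A(t) = Σ_s A₀,ₛ e^(−ln2·t/Tₛ) is decomposed into per-nuclide initial
activities by NNLS with the half-lives fixed; the incidental dose counts
the positron kinetic energy plus the locally absorbed annihilation-photon
energy of every stopped radioactive primary.

## Worked example

```
$ python examples/03_annihilation_maps_cnr.py
first inter-spill window: 1.9-3.3 s
C12:       44 counts, depth-profile peak at  53.2 mm, CNR proximal=0.06, distal=0.15, lateral=0.08
C10:     1966 counts, depth-profile peak at 137.2 mm, CNR proximal=0.51, distal=0.52, lateral=0.66
```

With 10⁶ simulated primaries, the ¹⁰C beam yields ~45× more annihilations
than ¹²C within the first beam-off interval, its depth profile peaks at the
SOBP distal edge (137 mm vs the planned 138 mm) rather than in the entrance
region, and its edge CNRs are 3–8× higher — the radioactive beam delineates
the treatment volume after a single spill, the stable beam does not.

The other examples cover the MKM chain (`01`), SOBP design and the
stable-to-radioactive mapping (`02`), TAC decomposition (`04`) and
incidental dose plus the variance-based sample-size study (`05`). The same
stages are available from a thin CLI:

```
ribpet study --seed 1 --out study_out     # full end-to-end bundle
ribpet sobp / rbe / simulate / tacfit / cnr / dose
```

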
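"""Ion species, layered phantoms and a parametric depth-dose model.

The depth-dose model is an analytic stand-in for full Monte Carlo
transport: a Bragg-Kleeman range-energy law, an entrance plateau with a
gentle build-up, a Gaussian Bragg peak with configurable range straggling,
and an exponential fragmentation tail beyond the peak.  Every formula is
closed-form so tests can evaluate it independently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

log = logging.getLogger(__name__)

__all__ = [
    "IonSpecies",
    "PhantomSlab",
    "Phantom",
    "DepthDoseProfile",
    "SPECIES",
    "WER_DEFAULTS",
    "range_from_energy",
    "energy_from_range",
    "depth_dose_profile",
    "water_equivalent_depth",
]


@dataclass(frozen=True)
class IonSpecies:
    """A (possibly radioactive) ion species in the beam.

    half_life is in seconds and must be given iff the species is unstable.
    """

    name: str
    Z: int
    A: int
    stable: bool
    half_life: float | None = None

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A < self.Z:
            raise ValueError(f"A must be >= Z, got A={self.A}, Z={self.Z}")
        if self.stable and self.half_life is not None:
            raise ValueError(f"{self.name}: stable species cannot have a half-life")
        if not self.stable and (self.half_life is None or self.half_life <= 0):
            raise ValueError(f"{self.name}: unstable species needs half_life > 0")

    @property
    def decay_constant(self) -> float:
        """ln2 / T_half in 1/s."""
        if self.stable:
            raise ValueError(f"{self.name} is stable")
        return float(np.log(2.0) / self.half_life)


# The five species of the study.  Half-lives: 11C 20.334 min, 10C 19.29 s,
# 15O 122.24 s.
SPECIES: dict[str, IonSpecies] = {
    "C12": IonSpecies("C12", Z=6, A=12, stable=True),
    "C11": IonSpecies("C11", Z=6, A=11, stable=False, half_life=20.334 * 60.0),
    "C10": IonSpecies("C10", Z=6, A=10, stable=False, half_life=19.29),
    "O16": IonSpecies("O16", Z=8, A=16, stable=True),
    "O15": IonSpecies("O15", Z=8, A=15, stable=False, half_life=122.24),
}

# Water-equivalent ratios per material; overridable per-slab.
WER_DEFAULTS: dict[str, float] = {
    "water": 1.0,
    "PMMA": 1.16,
    "bone": 1.6,
    "brain-as-muscle": 1.04,
}

# Bulk densities (g/cm3) used when a slab does not specify one.
DENSITY_DEFAULTS: dict[str, float] = {
    "water": 1.0,
    "PMMA": 1.19,
    "bone": 1.85,
    "brain-as-muscle": 1.05,
}


@dataclass(frozen=True)
class PhantomSlab:
    material: str
    thickness: float  # mm
    density: float  # g/cm3
    wer: float  # water-equivalent ratio

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("slab thickness must be > 0")
        if self.density <= 0 or self.wer <= 0:
            raise ValueError("slab density and wer must be > 0")


def make_slab(material: str, thickness: float, density: float | None = None,
              wer: float | None = None) -> PhantomSlab:
    """Build a slab using per-material defaults for density and wer."""
    if material not in WER_DEFAULTS:
        raise ValueError(f"unknown material {material!r}; known: {sorted(WER_DEFAULTS)}")
    return PhantomSlab(
        material=material,
        thickness=thickness,
        density=DENSITY_DEFAULTS[material] if density is None else density,
        wer=WER_DEFAULTS[material] if wer is None else wer,
    )


@dataclass(frozen=True)
class Phantom:
    """Ordered, contiguous stack of slabs along the beam axis.

    Depth is measured in mm from the entry face (depth 0).
    """

    slabs: tuple[PhantomSlab, ...]
    entry_face_position: float = 0.0

    def __post_init__(self) -> None:
        if not self.slabs:
            raise ValueError("phantom needs at least one slab")

    @property
    def thickness(self) -> float:
        return float(sum(s.thickness for s in self.slabs))

    @property
    def water_equivalent_thickness(self) -> float:
        return float(sum(s.thickness * s.wer for s in self.slabs))

    def materials(self) -> set[str]:
        return {s.material for s in self.slabs}


def water_phantom(thickness: float = 250.0) -> Phantom:
    return Phantom((make_slab("water", thickness),))


def skull_phantom() -> Phantom:
    """10 mm bone plate followed by 240 mm brain tissue (modelled as muscle)."""
    return Phantom((make_slab("bone", 10.0), make_slab("brain-as-muscle", 240.0)))


# --------------------------------------------------------------------------
# Range-energy law
# --------------------------------------------------------------------------

#: Bragg-Kleeman exponent.
RANGE_EXPONENT_DEFAULT = 1.75

#: Calibration anchor: 290 MeV/u 12C has a range of 160 mm in water.
_CAL_ENERGY = 290.0
_CAL_RANGE_MM = 160.0
_CAL_A_OVER_Z2 = 12.0 / 36.0


def _range_constant(p: float) -> float:
    return _CAL_RANGE_MM / (_CAL_A_OVER_Z2 * _CAL_ENERGY**p)


def range_from_energy(energy: float, species: IonSpecies, material: str = "water",
                      p: float = RANGE_EXPONENT_DEFAULT,
                      wer_overrides: dict[str, float] | None = None) -> float:
    """Ion range in mm: R = c (A/Z^2) E^p, divided by the material's wer.

    ``energy`` is in MeV/u.  The constant ``c`` is calibrated so that
    290 MeV/u 12C gives 160 mm in water.
    """
    energy = np.asarray(energy, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy must be > 0")
    wers = dict(WER_DEFAULTS)
    if wer_overrides:
        wers.update(wer_overrides)
    if material not in wers:
        raise ValueError(f"unknown material {material!r}; known: {sorted(wers)}")
    c = _range_constant(p)
    r_water = c * (species.A / species.Z**2) * energy**p
    out = r_water / wers[material]
    return float(out) if out.ndim == 0 else out


def energy_from_range(range_mm: float, species: IonSpecies, material: str = "water",
                      p: float = RANGE_EXPONENT_DEFAULT) -> float:
    """Invert the range-energy law (exact since the law is a power law)."""
    if range_mm <= 0:
        raise ValueError("range must be > 0")
    wer = WER_DEFAULTS[material] if material in WER_DEFAULTS else None
    if wer is None:
        raise ValueError(f"unknown material {material!r}")
    c = _range_constant(p)
    return float((range_mm * wer / (c * species.A / species.Z**2)) ** (1.0 / p))


# --------------------------------------------------------------------------
# Depth-dose model
# --------------------------------------------------------------------------


@dataclass
class DepthDoseProfile:
    """Dose versus water-equivalent depth for one species and energy.

    ``depth`` is a strictly increasing mm grid; ``dose`` is in arbitrary
    per-primary units (the entrance plateau is ~1 by construction).
    """

    depth: np.ndarray
    dose: np.ndarray
    species: IonSpecies
    energy: float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depth.ndim != 1 or self.depth.shape != self.dose.shape:
            raise ValueError("depth and dose must be equal-length 1-D arrays")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")

    @property
    def peak_depth(self) -> float:
        return float(self.depth[int(np.argmax(self.dose))])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"depth_mm": self.depth, "dose": self.dose}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, species: IonSpecies, energy: float) -> "DepthDoseProfile":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["depth_mm"].to_numpy(), df["dose"].to_numpy(), species, energy)


#: entrance plateau slope (fractional rise over the full range)
PLATEAU_SLOPE_DEFAULT = 0.3
#: Bragg peak amplitude relative to the entrance plateau
PEAK_AMPLITUDE_DEFAULT = 4.0
#: range straggling sigma as a fraction of range
STRAGGLING_FRACTION_DEFAULT = 0.01
#: fragmentation tail amplitude as a fraction of the peak
TAIL_AMPLITUDE_DEFAULT = 0.03
#: fragmentation tail decay length, mm
TAIL_LENGTH_DEFAULT = 30.0


def bragg_curve(depth: np.ndarray, range_mm: float, sigma_mm: float,
                plateau_slope: float = PLATEAU_SLOPE_DEFAULT,
                peak_amplitude: float = PEAK_AMPLITUDE_DEFAULT,
                tail_amplitude: float = TAIL_AMPLITUDE_DEFAULT,
                tail_length: float = TAIL_LENGTH_DEFAULT) -> np.ndarray:
    """Closed-form pristine Bragg curve.

    dose(z) = plateau(z) * cutoff(z) + peak * G(z) + tail(z), where

    * plateau(z) = 1 + plateau_slope * z / R  (slow build-up),
    * cutoff(z) = erfc((z - R) / (sqrt(2) sigma)) / 2,
    * G(z) a Gaussian of width sigma centred at R, truncated at |z-R| > 3 sigma,
    * tail(z) = tail_amplitude * peak_amplitude * exp(-(z - R)/tail_length)
      for z > R.

    The plateau and peak terms are hard-truncated beyond R + 3 sigma so
    that with tail_amplitude = 0 the dose vanishes identically there.
    """
    z = np.asarray(depth, dtype=float)
    R = float(range_mm)
    s = float(sigma_mm)
    plateau = (1.0 + plateau_slope * z / R) * 0.5 * special.erfc((z - R) / (np.sqrt(2) * s))
    gauss = peak_amplitude * np.exp(-0.5 * ((z - R) / s) ** 2)
    core = np.where(z <= R + 3.0 * s, plateau + gauss, 0.0)
    tail = np.where(z > R, tail_amplitude * peak_amplitude * np.exp(-(z - R) / tail_length), 0.0)
    return core + tail


def depth_dose_profile(energy: float, species: IonSpecies, phantom: Phantom,
                       grid_step: float = 1.0,
                       straggling_fraction: float = STRAGGLING_FRACTION_DEFAULT,
                       plateau_slope: float = PLATEAU_SLOPE_DEFAULT,
                       peak_amplitude: float = PEAK_AMPLITUDE_DEFAULT,
                       tail_amplitude: float = TAIL_AMPLITUDE_DEFAULT,
                       tail_length: float = TAIL_LENGTH_DEFAULT) -> DepthDoseProfile:
    """Analytic depth-dose curve on a water-equivalent depth grid.

    The grid spans [0, water-equivalent phantom thickness) in steps of
    ``grid_step`` (closed at 0, half-open at the far face).  If the beam
    range exceeds the phantom the profile is truncated with a warning.
    """
    if energy <= 0 or grid_step <= 0:
        raise ValueError("energy and grid_step must be > 0")
    R = range_from_energy(energy, species, "water")
    wet = phantom.water_equivalent_thickness
    if R > wet:
        warnings.warn(
            f"beam range {R:.1f} mm exceeds phantom water-equivalent "
            f"thickness {wet:.1f} mm; profile truncated", stacklevel=2)
        log.warning("range %.1f mm beyond phantom extent %.1f mm", R, wet)
    depth = np.arange(0.0, wet, grid_step)
    sigma = straggling_fraction * R
    dose = bragg_curve(depth, R, sigma, plateau_slope, peak_amplitude,
                       tail_amplitude, tail_length)
    return DepthDoseProfile(depth, dose, species, energy)


def water_equivalent_depth(phantom: Phantom, physical_depth: float) -> float:
    """Convert a physical depth to water-equivalent depth.

    Accumulates thickness x wer over the traversed slabs; piecewise linear
    and continuous across slab boundaries.
    """
    d = float(physical_depth)
    if d < 0:
        raise ValueError("physical depth must be >= 0")
    if d > phantom.thickness + 1e-9:
        raise ValueError(
            f"physical depth {d} mm exceeds phantom thickness {phantom.thickness} mm")
    wed = 0.0
    remaining = d
    for slab in phantom.slabs:
        step = min(remaining, slab.thickness)
        wed += step * slab.wer
        remaining -= step
        if remaining <= 0:
            break
    return wed


def physical_depth_from_wed(phantom: Phantom, wed: float) -> float:
    """Inverse of :func:`water_equivalent_depth` (piecewise linear)."""
    if wed < 0:
        raise ValueError("water-equivalent depth must be >= 0")
    remaining = float(wed)
    phys = 0.0
    for slab in phantom.slabs:
        slab_wed = slab.thickness * slab.wer
        if remaining <= slab_wed:
            return phys + remaining / slab.wer
        phys += slab.thickness
        remaining -= slab_wed
    raise ValueError(f"wed {wed} mm beyond phantom water-equivalent thickness")


def _wed_breakpoints(phantom: Phantom) -> tuple[np.ndarray, np.ndarray]:
    """(physical, water-equivalent) cumulative depths at slab boundaries."""
    phys = np.concatenate([[0.0], np.cumsum([s.thickness for s in phantom.slabs])])
    wed = np.concatenate([[0.0], np.cumsum([s.thickness * s.wer
                                            for s in phantom.slabs])])
    return phys, wed


def wed_of_depths(phantom: Phantom, physical_depths: np.ndarray) -> np.ndarray:
    """Vectorised water-equivalent depth (piecewise linear in depth)."""
    phys, wed = _wed_breakpoints(phantom)
    return np.interp(np.asarray(physical_depths, dtype=float), phys, wed)


def depths_of_wed(phantom: Phantom, wed_values: np.ndarray) -> np.ndarray:
    """Vectorised inverse of :func:`wed_of_depths`."""
    phys, wed = _wed_breakpoints(phantom)
    return np.interp(np.asarray(wed_values, dtype=float), wed, phys)


def material_at_depth(phantom: Phantom, physical_depth: float) -> str:
    """Material label of the slab containing a physical depth."""
    d = float(physical_depth)
    if d < 0 or d > phantom.thickness + 1e-9:
        raise ValueError("depth outside phantom")
    acc = 0.0
    for slab in phantom.slabs:
        acc += slab.thickness
        if d <= acc:
            return slab.material
    return phantom.slabs[-1].material
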
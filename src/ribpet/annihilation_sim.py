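"""Positron-decay event simulation under a synchrotron spill schedule.

Stands in for full Monte Carlo transport: primaries are born during
beam-on intervals, radioactive primaries stop at their (straggled) range
and decay after an exponential delay, and a configurable fraction of
primaries instead produces positron-emitting fragments distributed along
the entrance path.  Events are binned into voxel maps per acquisition
window and blurred with the imaging system's PSF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom_beam import SPECIES, Phantom
from .sobp import BeamSpectrum

log = logging.getLogger(__name__)

__all__ = [
    "SpillSchedule",
    "AnnihilationEventSet",
    "AnnihilationMap",
    "FRAGMENT_FRACTIONS",
    "simulate_treatment",
    "bin_events",
    "blur_map",
    "interspill_window",
    "estimate_half_life",
]


@dataclass(frozen=True)
class SpillSchedule:
    """Beam-on/off cycle: defaults are 20 spills of 1.9 s on / 1.4 s off
    at 1e9 primaries per second.  t = 0 is the start of spill 1."""

    n_spills: int = 20
    beam_on: float = 1.9  # s
    beam_off: float = 1.4  # s
    intensity: float = 1.0e9  # primaries / s

    def __post_init__(self) -> None:
        if min(self.n_spills, self.beam_on, self.beam_off, self.intensity) <= 0:
            raise ValueError("all spill-schedule fields must be positive")

    @property
    def period(self) -> float:
        return self.beam_on + self.beam_off

    @property
    def total_primaries(self) -> float:
        return self.n_spills * self.beam_on * self.intensity

    @property
    def end_of_last_spill(self) -> float:
        return (self.n_spills - 1) * self.period + self.beam_on


def interspill_window(schedule: SpillSchedule, k: int) -> tuple[float, float]:
    """The k-th (1-based) beam-off interval [k*period - beam_off, k*period)."""
    if not 1 <= k <= schedule.n_spills:
        raise ValueError(f"spill index {k} outside 1..{schedule.n_spills}")
    return (k * schedule.period - schedule.beam_off, k * schedule.period)


#: Default fragment species mix (fractions of positron-emitting fragments)
#: per primary beam element: C11/C10/O15.
FRAGMENT_FRACTIONS: dict[str, dict[str, float]] = {
    "C": {"C11": 0.80, "C10": 0.05, "O15": 0.15},
    "O": {"C11": 0.44, "C10": 0.07, "O15": 0.49},
}


@dataclass
class AnnihilationEventSet:
    """Positron annihilation events with position, time and provenance.

    ``t`` is the annihilation (decay) time, ``t_birth`` the primary's
    arrival time; ``weight`` rescales each simulated event to the clinical
    primary count.
    """

    x: np.ndarray  # mm
    y: np.ndarray  # mm
    z: np.ndarray  # mm, depth from the phantom entry face
    t: np.ndarray  # s
    t_birth: np.ndarray  # s
    species: np.ndarray  # str labels
    origin: np.ndarray  # "primary" | "fragment"
    weight: float = 1.0

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("x", "y", "z", "t_birth", "species", "origin"):
            if getattr(self, name).size != n:
                raise ValueError("all event columns must have equal length")
        if n and self.t.min() < 0:
            raise ValueError("event times must be >= 0")

    def __len__(self) -> int:
        return int(self.t.size)

    def select(self, mask: np.ndarray) -> "AnnihilationEventSet":
        return AnnihilationEventSet(
            self.x[mask], self.y[mask], self.z[mask], self.t[mask],
            self.t_birth[mask], self.species[mask], self.origin[mask],
            self.weight)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "x_mm": self.x, "y_mm": self.y, "z_mm": self.z, "t_s": self.t,
            "t_birth_s": self.t_birth, "species": self.species,
            "origin": self.origin})

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, weight: float = 1.0) -> "AnnihilationEventSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["x_mm"].to_numpy(float), df["y_mm"].to_numpy(float),
                   df["z_mm"].to_numpy(float), df["t_s"].to_numpy(float),
                   df["t_birth_s"].to_numpy(float),
                   df["species"].to_numpy(str), df["origin"].to_numpy(str),
                   weight)


@dataclass
class AnnihilationMap:
    """Event counts on an isotropic voxel grid over one time window."""

    counts: np.ndarray  # (nx, ny, nz)
    voxel: float  # mm
    window: tuple[float, float]  # s
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def depth_profile(self) -> np.ndarray:
        """Counts summed over the transverse axes, indexed by depth voxel."""
        return self.counts.sum(axis=(0, 1))

    def voxel_centres(self, axis: int) -> np.ndarray:
        n = self.counts.shape[axis]
        return self.origin_mm[axis] + self.voxel * (np.arange(n) + 0.5)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel, self.voxel, self.voxel, 1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(self.counts, dtype=np.float32),
                                 affine), str(path))

    def to_npy(self, path) -> None:
        np.save(path, self.counts)


def _sample_fragment_depths(rng: np.random.Generator, ranges: np.ndarray
                            ) -> np.ndarray:
    """Fragment stopping depths along [0, R]: half uniform, half triangular
    rising toward the primary range (emitter production accumulates with
    depth before dropping at the range)."""
    u = rng.random(ranges.size)
    tri = rng.triangular(0.0, ranges, ranges) if ranges.size else ranges
    uni = rng.random(ranges.size) * ranges
    return np.where(u < 0.5, uni, tri)


def simulate_treatment(beam: BeamSpectrum, phantom: Phantom,
                       schedule: SpillSchedule = SpillSchedule(),
                       n_primaries: int = 1_000_000,
                       fragment_fractions: dict[str, float] | None = None,
                       seed: int = 0,
                       *,
                       fragmentation_probability: float = 0.2,
                       straggling_fraction: float = 0.01,
                       positron_blur_mm: float = 1.0,
                       field_mm: float = 50.0) -> AnnihilationEventSet:
    """Simulate annihilation events for one treatment (deterministic per seed).

    Primaries are spread uniformly over beam-on time; a fraction
    ``fragmentation_probability`` undergoes nuclear fragmentation and
    deposits a positron-emitting fragment along the entrance path
    (species mix ``fragment_fractions``, default per beam element from
    the relative-yield table), the rest stop at their straggled range and
    — if the primary itself is a positron emitter — decay there after an
    exponential delay.  Annihilation positions get an isotropic Gaussian
    positron-range blur.  Events are weighted so that maps can be
    rescaled to the full clinical primary count.
    """
    if n_primaries < 1:
        raise ValueError("n_primaries must be >= 1")
    if fragment_fractions is None:
        element = "O" if beam.species.Z == 8 else "C"
        fragment_fractions = FRAGMENT_FRACTIONS[element]
    frac_sum = sum(fragment_fractions.values())
    if abs(frac_sum - 1.0) > 1e-9:
        raise ValueError(f"fragment fractions must sum to 1, got {frac_sum}")

    rng = np.random.default_rng(seed)
    beam_n = beam.normalized()
    weights = beam_n.weights
    ranges_wed = beam_n.peak_depths("water")

    # birth times: spill chosen uniformly, time uniform within beam-on
    spill = rng.integers(0, schedule.n_spills, n_primaries)
    t_birth = spill * schedule.period + rng.random(n_primaries) * schedule.beam_on

    comp = rng.choice(weights.size, size=n_primaries, p=weights)
    r_wed = ranges_wed[comp] * (
        1.0 + straggling_fraction * rng.standard_normal(n_primaries))

    fragments = rng.random(n_primaries) < fragmentation_probability

    species_list: list[np.ndarray] = []
    origin_list: list[np.ndarray] = []
    z_wed_list: list[np.ndarray] = []
    tb_list: list[np.ndarray] = []
    delay_list: list[np.ndarray] = []

    # primary stopping-point decays (radioactive primaries only)
    if not beam.species.stable:
        prim = ~fragments
        n_prim = int(prim.sum())
        lam = beam.species.decay_constant
        delay = rng.exponential(1.0 / lam, n_prim)
        species_list.append(np.full(n_prim, beam.species.name))
        origin_list.append(np.full(n_prim, "primary"))
        z_wed_list.append(r_wed[prim])
        tb_list.append(t_birth[prim])
        delay_list.append(delay)

    # fragment decays (both stable and radioactive beams)
    frag_names = list(fragment_fractions)
    frag_p = np.array([fragment_fractions[s] for s in frag_names])
    n_frag = int(fragments.sum())
    if n_frag:
        choice = rng.choice(len(frag_names), size=n_frag, p=frag_p)
        z_frag = _sample_fragment_depths(rng, np.maximum(r_wed[fragments], 1e-6))
        delays = np.empty(n_frag)
        for i, name in enumerate(frag_names):
            m = choice == i
            lam = SPECIES[name].decay_constant
            delays[m] = rng.exponential(1.0 / lam, int(m.sum()))
        species_list.append(np.array(frag_names, dtype=object)[choice].astype(str))
        origin_list.append(np.full(n_frag, "fragment"))
        z_wed_list.append(z_frag)
        tb_list.append(t_birth[fragments])
        delay_list.append(delays)

    if not species_list:
        empty = np.array([])
        return AnnihilationEventSet(empty, empty, empty, empty, empty,
                                    np.array([], dtype=str),
                                    np.array([], dtype=str),
                                    weight=schedule.total_primaries / n_primaries)

    species = np.concatenate(species_list)
    origin = np.concatenate(origin_list)
    z_wed = np.concatenate(z_wed_list)
    tb = np.concatenate(tb_list)
    t = tb + np.concatenate(delay_list)

    # water-equivalent stop depth -> physical depth inside the phantom
    wet = phantom.water_equivalent_thickness
    z_wed = np.clip(z_wed, 0.0, wet - 1e-9)
    z_phys = _vector_physical_depth(phantom, z_wed)

    n_ev = species.size
    half = field_mm / 2.0
    x = rng.uniform(-half, half, n_ev)
    y = rng.uniform(-half, half, n_ev)
    if positron_blur_mm > 0:
        x = x + rng.normal(0.0, positron_blur_mm, n_ev)
        y = y + rng.normal(0.0, positron_blur_mm, n_ev)
        z_phys = z_phys + rng.normal(0.0, positron_blur_mm, n_ev)
    z_phys = np.clip(z_phys, 0.0, phantom.thickness)

    return AnnihilationEventSet(
        x, y, z_phys, t, tb, species.astype(str), origin.astype(str),
        weight=schedule.total_primaries / n_primaries)


def _vector_physical_depth(phantom: Phantom, wed: np.ndarray) -> np.ndarray:
    """Vectorised inverse water-equivalent-depth conversion."""
    out = np.empty_like(wed)
    lower_wed = 0.0
    lower_phys = 0.0
    remaining = np.ones(wed.size, dtype=bool)
    for slab in phantom.slabs:
        upper_wed = lower_wed + slab.thickness * slab.wer
        m = remaining & (wed <= upper_wed + 1e-12)
        out[m] = lower_phys + (wed[m] - lower_wed) / slab.wer
        remaining &= ~m
        lower_wed, lower_phys = upper_wed, lower_phys + slab.thickness
    out[remaining] = phantom.thickness
    return out


def bin_events(events: AnnihilationEventSet, window: tuple[float, float],
               voxel: float = 1.5,
               bounds: tuple[tuple[float, float], ...] | None = None
               ) -> AnnihilationMap:
    """Bin events with t in the half-open window into half-open voxels.

    ``bounds`` is ((x0, x1), (y0, y1), (z0, z1)) in mm; events outside are
    dropped (count logged).
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"inverted window: {window}")
    if voxel <= 0:
        raise ValueError("voxel size must be > 0")
    if bounds is None:
        bounds = ((-30.0, 30.0), (-30.0, 30.0), (0.0, 250.0))
    in_t = (events.t >= t0) & (events.t < t1)
    sel = events.select(in_t)
    edges = [np.arange(lo, hi + voxel * 0.5, voxel) for lo, hi in bounds]
    counts, _ = np.histogramdd(
        np.column_stack([sel.x, sel.y, sel.z]), bins=edges)
    dropped = len(sel) - int(counts.sum())
    if dropped:
        log.info("bin_events: %d events outside bounds dropped", dropped)
    return AnnihilationMap(counts.astype(np.int64), voxel, (t0, t1),
                           origin_mm=(bounds[0][0], bounds[1][0], bounds[2][0]))


def blur_map(amap: AnnihilationMap, fwhm: float = 3.5) -> AnnihilationMap:
    """Gaussian PSF blur with sigma = fwhm / 2.3548 per axis.

    Reflective boundaries, so total intensity is conserved; fwhm = 0 is
    the identity.  The result is real-valued.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return AnnihilationMap(np.asarray(amap.counts, dtype=float), amap.voxel,
                               amap.window, amap.origin_mm)
    from scipy import ndimage

    sigma_vox = fwhm / 2.3548 / amap.voxel
    blurred = ndimage.gaussian_filter(np.asarray(amap.counts, dtype=float),
                                      sigma=sigma_vox, mode="reflect")
    return AnnihilationMap(blurred, amap.voxel, amap.window, amap.origin_mm)


def estimate_half_life(decay_delays: np.ndarray) -> tuple[float, float]:
    """MLE half-life (and its standard error) from decay delays.

    For exponential delays the MLE of the mean lifetime is the sample
    mean, with SE mean/sqrt(n); half-life = ln2 * lifetime.
    """
    d = np.asarray(decay_delays, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two decay delays")
    tau = d.mean()
    se_tau = tau / np.sqrt(d.size)
    ln2 = np.log(2.0)
    return ln2 * tau, ln2 * se_tau
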
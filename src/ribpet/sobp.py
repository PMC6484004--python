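"""Spread-out Bragg peak (SOBP) construction.

Builds a polyenergetic beam spectrum whose weighted superposition of
pristine Bragg curves delivers a flat *biological* dose (physical dose
times RBE10) across a target depth range, and maps a stable-ion spectrum
onto its positron-emitting analog so that both SOBPs occupy the same
depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .microdosimetry import RBEProfile
from .phantom_beam import DepthDoseProfile, IonSpecies, range_from_energy

__all__ = [
    "BeamSpectrum",
    "SOBPPlan",
    "ProfileSet",
    "interpolate_profiles",
    "optimize_sobp_weights",
    "map_weights_to_radioactive",
    "biological_dose_profile",
    "FlatnessError",
]


class FlatnessError(RuntimeError):
    """Raised when the optimizer cannot reach the requested flatness."""

    def __init__(self, achieved: float, tolerance: float):
        self.achieved = achieved
        self.tolerance = tolerance
        super().__init__(
            f"SOBP flatness {achieved:.4f} exceeds tolerance {tolerance:.4f}")


@dataclass(frozen=True)
class BeamSpectrum:
    """Weighted list of monoenergetic components for one species.

    ``components`` is a tuple of (energy MeV/u, weight) pairs with
    strictly increasing energies and at least one positive weight; the
    weight scale (normalized or primaries per spill) is up to the caller.
    """

    species: IonSpecies
    components: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        e = np.array([c[0] for c in self.components])
        w = np.array([c[1] for c in self.components])
        if e.size == 0:
            raise ValueError("beam spectrum needs at least one component")
        if e.size > 1 and np.any(np.diff(e) <= 0):
            raise ValueError("component energies must be strictly increasing")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one > 0")

    @property
    def energies(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    def normalized(self) -> "BeamSpectrum":
        total = self.weights.sum()
        return BeamSpectrum(self.species, tuple(
            (e, w / total) for e, w in self.components))

    def peak_depths(self, material: str = "water") -> np.ndarray:
        """Bragg-peak depth of each component (mm water)."""
        return np.array([range_from_energy(e, self.species, material)
                         for e in self.energies])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"energy_MeV_u": self.energies,
                      "weight": self.weights}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, species: IonSpecies) -> "BeamSpectrum":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(species, tuple(zip(df["energy_MeV_u"], df["weight"])))


@dataclass(frozen=True)
class SOBPPlan:
    """Flat-biological-dose prescription over a depth range."""

    target_range: tuple[float, float] = (78.0, 138.0)  # proximal, distal mm
    target_biological_dose_rate: float = 5.0  # Gy(RBE)/min
    flatness_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.target_range[0] >= self.target_range[1]:
            raise ValueError("proximal edge must be shallower than distal edge")
        if self.target_biological_dose_rate <= 0:
            raise ValueError("dose rate must be > 0")

    @property
    def width(self) -> float:
        return self.target_range[1] - self.target_range[0]


@dataclass
class ProfileSet:
    """Depth-dose and biological-dose curves on a dense energy grid.

    ``phys[i]`` and ``bio[i]`` are the physical and biological dose per
    primary of the i-th energy on the common ``depth`` grid.
    """

    energies: np.ndarray
    depth: np.ndarray
    phys: np.ndarray  # (n_energy, n_depth)
    bio: np.ndarray  # (n_energy, n_depth)

    def index_of(self, energy: float) -> int:
        idx = np.nonzero(np.isclose(self.energies, energy))[0]
        if idx.size == 0:
            raise KeyError(f"energy {energy} MeV/u not in profile set")
        return int(idx[0])


def _interp_rbe(rbe: RBEProfile | None, depth: np.ndarray) -> np.ndarray:
    if rbe is None:
        return np.ones_like(depth)
    return np.interp(depth, rbe.depth, rbe.rbe_mean)


def interpolate_profiles(simulated: list[tuple[float, DepthDoseProfile, RBEProfile | None]],
                         step: float = 1.0) -> ProfileSet:
    """Densify anchor profiles to an energy grid of spacing ``step``.

    Both physical and biological dose (physical times interpolated RBE10)
    are interpolated linearly between adjacent anchor energies on the
    common depth grid; anchors are reproduced exactly.  Querying outside
    the anchor hull raises (no extrapolation).
    """
    if len(simulated) < 2:
        raise ValueError("need at least two anchor energies")
    if step <= 0:
        raise ValueError("step must be > 0")
    sims = sorted(simulated, key=lambda t: t[0])
    e_anchor = np.array([t[0] for t in sims])
    depth = sims[0][1].depth
    for _, prof, _ in sims:
        if prof.depth.shape != depth.shape or not np.allclose(prof.depth, depth):
            raise ValueError("all anchor profiles must share one depth grid")
    phys_anchor = np.stack([t[1].dose for t in sims])
    bio_anchor = np.stack([t[1].dose * _interp_rbe(t[2], depth) for t in sims])

    n_dense = int(round((e_anchor[-1] - e_anchor[0]) / step)) + 1
    e_dense = e_anchor[0] + step * np.arange(n_dense)
    if e_dense[-1] > e_anchor[-1] + 1e-9:
        raise ValueError("dense grid extends beyond simulated hull")
    phys = np.empty((n_dense, depth.size))
    bio = np.empty((n_dense, depth.size))
    for j in range(depth.size):
        phys[:, j] = np.interp(e_dense, e_anchor, phys_anchor[:, j])
        bio[:, j] = np.interp(e_dense, e_anchor, bio_anchor[:, j])
    # anchors bit-exact, not merely close
    for i, ea in enumerate(e_anchor):
        k = int(np.argmin(np.abs(e_dense - ea)))
        if abs(e_dense[k] - ea) < 1e-9:
            phys[k] = phys_anchor[i]
            bio[k] = bio_anchor[i]
    return ProfileSet(e_dense, depth, phys, bio)


def dense_profile_set(energies: np.ndarray, species: IonSpecies, phantom,
                      rbe_anchors: list[tuple[float, RBEProfile]] | None = None,
                      grid_step: float = 1.0,
                      straggling_fraction: float = 0.01) -> ProfileSet:
    """Dense profile set from the closed-form depth-dose model.

    Curves are evaluated on the phantom's *physical* depth grid (the
    closed-form Bragg curve is evaluated at the water-equivalent depth of
    each grid point), so that they compose directly with physical-depth
    RBE profiles, treatment plans and annihilation maps.  Because the
    depth-dose model is analytic, a profile can be generated at every
    energy directly; only RBE10 — which is expensive to sample — is
    interpolated between the given anchor (energy, RBEProfile) pairs.
    This is the synthetic-data counterpart of
    :func:`interpolate_profiles`, which serves user-supplied simulated
    profiles: pointwise energy interpolation of narrow pristine peaks
    cannot create intermediate peak depths, so the dense set is generated
    rather than interpolated here.
    """
    from .phantom_beam import wed_of_depths, depths_of_wed
    from .phantom_beam import bragg_curve

    energies = np.asarray(energies, dtype=float)
    depth = np.arange(0.0, phantom.thickness, grid_step)
    wed = wed_of_depths(phantom, depth)
    r_dense = np.array([range_from_energy(e, species, "water")
                        for e in energies])
    phys = np.stack([bragg_curve(wed, r, straggling_fraction * r)
                     for r in r_dense])
    if rbe_anchors:
        # RBE of a pristine beam is sharply ridged along its own range, so
        # anchors are aligned on residual depth (z - R) before energy
        # interpolation; plain pointwise interpolation would smear the
        # ridge between anchor energies.
        anchors = sorted(rbe_anchors, key=lambda t: t[0])
        e_anchor = np.array([a[0] for a in anchors])
        r_anchor = np.array([range_from_energy(e, species, "water")
                             for e in e_anchor])
        # bracketing anchors and linear weights per dense energy
        k = np.clip(np.searchsorted(e_anchor, energies) - 1, 0, e_anchor.size - 2)
        t = np.clip((energies - e_anchor[k]) /
                    (e_anchor[k + 1] - e_anchor[k]), 0.0, 1.0)
        rbe_dense = np.empty((energies.size, depth.size))
        for i in range(energies.size):
            # shift each anchor's profile so its ridge lands on this
            # energy's range (alignment done in water-equivalent depth)
            lo_depth = depths_of_wed(phantom, wed - (r_dense[i] - r_anchor[k[i]]))
            hi_depth = depths_of_wed(phantom, wed - (r_dense[i] - r_anchor[k[i] + 1]))
            lo = _interp_rbe(anchors[k[i]][1], lo_depth)
            hi = _interp_rbe(anchors[k[i] + 1][1], hi_depth)
            rbe_dense[i] = (1.0 - t[i]) * lo + t[i] * hi
        bio = phys * rbe_dense
    else:
        bio = phys.copy()
    return ProfileSet(energies, depth, phys, bio)


def sobp_flatness(depth: np.ndarray, dose: np.ndarray,
                  target_range: tuple[float, float]) -> float:
    """Max |relative deviation from the mean| inside the target range."""
    mask = (depth >= target_range[0]) & (depth <= target_range[1])
    inside = dose[mask]
    if inside.size == 0:
        raise ValueError("no depth samples inside the target range")
    mean = inside.mean()
    if mean <= 0:
        raise ValueError("zero dose inside the target range")
    return float(np.max(np.abs(inside - mean)) / mean)


def optimize_sobp_weights(profiles: ProfileSet, plan: SOBPPlan,
                          species: IonSpecies) -> BeamSpectrum:
    """Non-negative least-squares weights for a flat biological dose.

    Minimises sum over target-range depths of
    (sum_e w_e b_e(depth) - 1)^2 with w >= 0, then checks the achieved
    flatness against ``plan.flatness_tolerance`` (raises
    :class:`FlatnessError` if unreachable).  Weights are in units of
    primaries per unit biological dose; rescale as needed.
    """
    prox, dist = plan.target_range
    mask = (profiles.depth >= prox) & (profiles.depth <= dist)
    # every target depth must sit in the high-dose region of some profile
    norm = profiles.bio / profiles.bio.max(axis=1, keepdims=True)
    covered = norm[:, mask].max(axis=0) >= 0.5
    if not covered.all():
        bad = profiles.depth[mask][~covered]
        raise ValueError(
            f"available Bragg peaks do not cover the target range "
            f"{prox}-{dist} mm (uncovered depths near {bad[0]:.0f} mm)")
    A = profiles.bio[:, mask].T
    target = np.ones(A.shape[0])
    w, _ = optimize.nnls(A, target)
    bio = w @ profiles.bio
    achieved = sobp_flatness(profiles.depth, bio, plan.target_range)
    if achieved > plan.flatness_tolerance:
        raise FlatnessError(achieved, plan.flatness_tolerance)
    keep = w > 0
    comps = tuple((float(e), float(wi))
                  for e, wi in zip(profiles.energies[keep], w[keep]))
    return BeamSpectrum(species, comps)


def map_weights_to_radioactive(stable: BeamSpectrum, radioactive: IonSpecies,
                               plan: SOBPPlan, range_model=range_from_energy,
                               phantom=None) -> BeamSpectrum:
    """Map a stable-ion SOBP spectrum onto a radioactive species.

    Finds the radioactive energies whose Bragg peaks sit at the stable
    spectrum's proximal and distal peak depths (by numerically inverting
    ``range_model``), then affinely maps every stable component energy
    into that interval, preserving its weight.  The identity species maps
    to itself.
    """
    e_stable = stable.energies
    r_prox = range_model(float(e_stable[0]), stable.species, "water")
    r_dist = range_model(float(e_stable[-1]), stable.species, "water")
    plan_lo, plan_hi = plan.target_range
    if phantom is not None:  # plan depths are physical in the phantom
        from .phantom_beam import wed_of_depths

        plan_lo = float(wed_of_depths(phantom, plan_lo))
        plan_hi = float(wed_of_depths(phantom, plan_hi))
    # a couple of mm of slack: the optimizer may drop edge components whose
    # peaks sit within a straggling width of the plan boundary
    if r_prox > plan_lo + 2.0 or r_dist < plan_hi - 2.0:
        raise ValueError("stable spectrum does not span the plan's depth range")

    def invert(target_range_mm: float) -> float:
        f = lambda e: range_model(e, radioactive, "water") - target_range_mm
        lo, hi = 1.0, 2000.0
        if f(lo) * f(hi) > 0:
            raise ValueError(
                f"range model does not bracket {target_range_mm} mm in [1, 2000] MeV/u")
        return float(optimize.brentq(f, lo, hi, xtol=1e-10))

    e_prox, e_dist = invert(r_prox), invert(r_dist)
    lo, hi = float(e_stable[0]), float(e_stable[-1])
    if hi == lo:
        mapped = np.full_like(e_stable, e_prox)
    else:
        mapped = e_prox + (e_stable - lo) * (e_dist - e_prox) / (hi - lo)
    return BeamSpectrum(radioactive, tuple(
        (float(e), float(w)) for e, w in zip(mapped, stable.weights)))


def biological_dose_profile(beam: BeamSpectrum, profiles: ProfileSet,
                            plan: SOBPPlan,
                            rbe: RBEProfile | None = None) -> dict:
    """Summed physical and biological depth-dose of a weighted beam.

    Biological dose is RBE10(depth) x summed physical dose when an
    explicit ``rbe`` profile is given; otherwise the per-energy biological
    curves of ``profiles`` are summed directly.  Returns the curves plus a
    flatness report (max relative deviation inside the target range and
    the entrance-to-SOBP dose ratio).
    """
    w = np.zeros(profiles.energies.size)
    for e, wi in beam.components:
        w[profiles.index_of(e)] = wi
    phys = w @ profiles.phys
    if rbe is not None:
        bio = phys * _interp_rbe(rbe, profiles.depth)
    else:
        bio = w @ profiles.bio
    mask = (profiles.depth >= plan.target_range[0]) & \
           (profiles.depth <= plan.target_range[1])
    entrance = bio[profiles.depth <= 0.1 * plan.target_range[0]]
    report = {
        "flatness_bio": sobp_flatness(profiles.depth, bio, plan.target_range),
        "flatness_phys": sobp_flatness(profiles.depth, phys, plan.target_range),
        "entrance_to_sobp_ratio": float(entrance.mean() / bio[mask].mean())
        if entrance.size else float("nan"),
    }
    return {"depth": profiles.depth, "physical": phys, "biological": bio,
            "report": report}
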
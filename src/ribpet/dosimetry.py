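"""Incidental activity/dose from radioactive-beam decays, and the
variance-based convergence study used to choose simulation sample sizes.

The incidental-dose estimate is a bulk order-of-magnitude calculation:
every stopped radioactive primary eventually decays, depositing its mean
positron kinetic energy locally plus a fraction of the two 511 keV
annihilation photons' energy absorbed within the treatment volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .phantom_beam import IonSpecies

__all__ = [
    "IncidentalDoseReport",
    "activity_concentration",
    "incidental_dose",
    "convergence_study",
    "MEAN_POSITRON_ENERGY_MEV",
]

#: Mean positron kinetic energy per decay, MeV (physical constants).
MEAN_POSITRON_ENERGY_MEV: dict[str, float] = {
    "C11": 0.386,
    "C10": 0.81,
    "O15": 0.735,
}

MEV_TO_J = 1.602e-13
ANNIHILATION_ENERGY_MEV = 1.022  # two 511 keV photons


@dataclass
class IncidentalDoseReport:
    n_primaries: float
    activity_concentration: float  # MBq/cc
    decay_dose: float  # mSv
    volume: float  # cc
    assumptions: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump({
                "n_primaries": float(self.n_primaries),
                "activity_concentration_MBq_cc": float(self.activity_concentration),
                "decay_dose_mSv": float(self.decay_dose),
                "volume_cc": float(self.volume),
                "assumptions": self.assumptions,
            }, fh, sort_keys=False)


def activity_concentration(n_atoms: float, species: IonSpecies,
                           volume: float) -> float:
    """Initial activity concentration lambda N / V in MBq/cc.

    ``n_atoms`` radioactive atoms uniformly distributed through ``volume``
    cc give A0/V = n_atoms * ln2 / T_half / volume becquerel per cc.
    """
    if species.stable:
        raise ValueError(f"{species.name} is stable: no activity")
    if volume <= 0:
        raise ValueError("volume must be > 0")
    bq_per_cc = n_atoms * species.decay_constant / volume
    return bq_per_cc * 1e-6


def incidental_dose(n_atoms: float, species: IonSpecies, volume: float,
                    mean_positron_energy: float | None = None,
                    gamma_absorbed_fraction: float = 0.3,
                    tissue_density: float = 1.0) -> IncidentalDoseReport:
    """Total decay dose (mSv) delivered to the volume by all n_atoms decays.

    dose = n_atoms * (E_beta_mean + f_gamma * 1.022 MeV) / mass, with a
    radiation weighting factor of 1 (positrons and photons), so mSv equals
    mGy.  ``gamma_absorbed_fraction`` is the fraction of annihilation
    photon energy absorbed locally (default 0.3 for a head-sized volume);
    ``tissue_density`` in g/cc.
    """
    if not 0.0 <= gamma_absorbed_fraction <= 1.0:
        raise ValueError("gamma_absorbed_fraction must be in [0, 1]")
    if mean_positron_energy is None:
        mean_positron_energy = MEAN_POSITRON_ENERGY_MEV.get(species.name, 0.386)
    energy_mev = mean_positron_energy + gamma_absorbed_fraction * ANNIHILATION_ENERGY_MEV
    mass_kg = volume * tissue_density * 1e-3
    dose_gy = n_atoms * energy_mev * MEV_TO_J / mass_kg
    return IncidentalDoseReport(
        n_primaries=n_atoms,
        activity_concentration=activity_concentration(n_atoms, species, volume),
        decay_dose=dose_gy * 1e3,  # mSv, w_R = 1
        volume=volume,
        assumptions={
            "mean_positron_energy_MeV": mean_positron_energy,
            "gamma_absorbed_fraction": gamma_absorbed_fraction,
            "tissue_density_g_cc": tissue_density,
            "radiation_weighting_factor": 1.0,
        })


def convergence_study(estimator: Callable[[int, int], float], M: int = 50,
                      threshold: float = 0.01, n_start: int = 100,
                      seed: int = 0, max_doublings: int = 20
                      ) -> tuple[int, list[tuple[int, float]]]:
    """Double N until the relative spread of the estimator drops below
    ``threshold``.

    ``estimator(seed, N)`` returns a scalar; at each N, M seeded
    replicates are run and the ratio SD/|mean| recorded.  Returns the
    first N meeting the threshold and the full (N, SD/mean) trace.
    """
    if M < 2:
        raise ValueError("M must be >= 2 (SD undefined otherwise)")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ss = np.random.SeedSequence(seed)
    trace: list[tuple[int, float]] = []
    N = int(n_start)
    for _ in range(max_doublings):
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(M)]
        vals = np.array([estimator(s, N) for s in seeds], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"estimator returned non-finite output at N={N}")
        mean = vals.mean()
        ratio = float(vals.std(ddof=1) / abs(mean)) if mean != 0 else float("inf")
        trace.append((N, ratio))
        if ratio < threshold:
            return N, trace
        N *= 2
    raise RuntimeError(
        f"convergence not reached after {max_doublings} doublings; trace={trace}")
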
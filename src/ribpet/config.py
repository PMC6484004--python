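"""Study configuration: YAML parsing, validation, defaults.

An empty config reproduces the package's reference study: a skull
phantom, carbon and oxygen beams with their positron-emitting analogs, a
78-138 mm flat-biological-dose SOBP at 5 Gy(RBE)/min, 20 spills of
1.9 s on / 1.4 s off at 1e9 primaries/s, 1.5 mm voxels and a 3.5 mm
imaging PSF.  Every default that a loaded config falls back on is
recorded in ``StudyConfig.provenance`` and logged.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annihilation_sim import SpillSchedule
from .microdosimetry import MKMParams
from .phantom_beam import SPECIES, Phantom, skull_phantom, water_phantom
from .sobp import SOBPPlan

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "load_config", "save_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "phantom": "skull",
    "stable_species": ["C12", "O16"],
    "radioactive_map": {"C12": ["C11", "C10"], "O16": ["O15"]},
    "plan": {
        "proximal_mm": 78.0,
        "distal_mm": 138.0,
        "dose_rate_gy_rbe_min": 5.0,
        "flatness_tolerance": 0.02,
    },
    "spills": {
        "n_spills": 20,
        "beam_on_s": 1.9,
        "beam_off_s": 1.4,
        "intensity_pps": 1.0e9,
    },
    "mkm": {
        "alpha0": 0.13,
        "beta0": 0.05,
        "rho": 1.0,
        "r_d_um": 0.42,
        "y0_keV_um": 150.0,
        "d10_ref_gy": 5.0,
        "tissue_correction": 1.05,
        "correction_mode": "depth",
    },
    "generator": {
        "n_events_per_volume": 4000,
        "straggling_fraction": 0.01,
        "fragmentation_probability": 0.2,
        "positron_blur_mm": 1.0,
        "field_mm": 50.0,
    },
    "imaging": {"voxel_mm": 1.5, "psf_fwhm_mm": 3.5},
    "n_primaries": 1_000_000,
    "rbe_report_depths_mm": [50.0, 81.0, 111.0, 131.0, 171.0],
    "n_anchor_energies": 5,
    "seeds": {"spectra": 101, "simulation": 202, "noise": 303},
    "outdir": "study_out",
}

#: provenance notes for the study defaults
_DEFAULT_NOTES: dict[str, str] = {
    "plan": "78-138 mm flat biological dose at 5 Gy(RBE)/min (reference study)",
    "spills": "20 spills, 1.9 s on / 1.4 s off, 1e9 primaries/s",
    "mkm": "HSG cells: alpha0=0.13/Gy, beta0=0.05/Gy^2, r_d=0.42 um, "
           "D10(200 kVp X-ray)=5 Gy; 1.05 brain-tissue correction",
    "imaging": "1.5 mm voxels, 3.5 mm system PSF",
    "phantom": "skull: 10 mm bone + 240 mm brain-as-muscle",
}


@dataclass
class StudyConfig:
    """Validated, default-filled study configuration."""

    raw: dict
    provenance: dict[str, str] = field(default_factory=dict)

    # -- constructed objects -------------------------------------------------
    def phantom(self) -> Phantom:
        name = self.raw["phantom"]
        if name == "skull":
            return skull_phantom()
        if name == "water":
            return water_phantom()
        raise ValueError(f"phantom: unknown phantom {name!r}")

    def plan(self) -> SOBPPlan:
        p = self.raw["plan"]
        return SOBPPlan((p["proximal_mm"], p["distal_mm"]),
                        p["dose_rate_gy_rbe_min"], p["flatness_tolerance"])

    def schedule(self) -> SpillSchedule:
        s = self.raw["spills"]
        return SpillSchedule(s["n_spills"], s["beam_on_s"], s["beam_off_s"],
                             s["intensity_pps"])

    def mkm_params(self) -> MKMParams:
        m = self.raw["mkm"]
        return MKMParams(m["alpha0"], m["beta0"], m["rho"], m["r_d_um"],
                         m["y0_keV_um"], m["d10_ref_gy"])

    def seed(self, stage: str) -> int:
        return int(self.raw["seeds"][stage])

    def __getitem__(self, key):
        return self.raw[key]


def _validate(cfg: dict) -> None:
    plan = cfg["plan"]
    if plan["proximal_mm"] >= plan["distal_mm"]:
        raise ValueError("plan.proximal_mm must be < plan.distal_mm")
    for k, v in cfg["spills"].items():
        if v <= 0:
            raise ValueError(f"spills.{k} must be positive, got {v}")
    for k, v in cfg["mkm"].items():
        if k == "correction_mode":
            if v not in ("depth", "dose"):
                raise ValueError(f"mkm.correction_mode must be depth|dose, got {v!r}")
        elif v <= 0:
            raise ValueError(f"mkm.{k} must be positive, got {v}")
    gen = cfg["generator"]
    if not 0.0 <= gen["fragmentation_probability"] <= 1.0:
        raise ValueError("generator.fragmentation_probability must be in [0, 1]")
    if cfg["n_primaries"] < 1:
        raise ValueError("n_primaries must be >= 1")
    for s in cfg["stable_species"]:
        if s not in SPECIES:
            raise ValueError(f"stable_species: unknown species {s!r}")
        if not SPECIES[s].stable:
            raise ValueError(f"stable_species: {s} is not stable")
    for stable, rads in cfg["radioactive_map"].items():
        if stable not in SPECIES:
            raise ValueError(f"radioactive_map: unknown species {stable!r}")
        for r in rads:
            if r not in SPECIES:
                raise ValueError(f"radioactive_map: unknown species {r!r}")
            if SPECIES[r].stable:
                raise ValueError(f"radioactive_map: {r} is stable")
    for stage in ("spectra", "simulation", "noise"):
        if stage not in cfg["seeds"]:
            raise ValueError(f"seeds.{stage} missing (explicit seeds required)")


def _merge(defaults: dict, user: dict, provenance: dict, prefix: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        path = f"{prefix}{key}"
        if key not in user:
            out[key] = copy.deepcopy(dval)
            note = _DEFAULT_NOTES.get(key, "package default")
            provenance[path] = f"default ({note})"
        elif isinstance(dval, dict) and isinstance(user[key], dict):
            out[key] = _merge(dval, user[key], provenance, path + ".")
        else:
            out[key] = copy.deepcopy(user[key])
            provenance[path] = "config override"
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(prefix + k for k in unknown)}")
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> StudyConfig:
    """Load and validate a YAML config; ``None`` gives the full default study."""
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        with open(p) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user = {**user, **overrides}
    provenance: dict[str, str] = {}
    cfg = _merge(DEFAULT_CONFIG, user, provenance)
    _validate(cfg)
    for key, src in provenance.items():
        log.debug("config %s: %s", key, src)
    return StudyConfig(cfg, provenance)


def save_config(config: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=False)
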
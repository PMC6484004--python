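"""Contrast-to-noise ratio (CNR) between paired regions of a map.

CNR = |mu_a - mu_b| / sqrt(sigma_a^2 + sigma_b^2) with population
standard deviations, computed between slabs just inside and just outside
the proximal, distal and upper lateral edges of the SOBP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annihilation_sim import AnnihilationMap
from .sobp import SOBPPlan

__all__ = ["RegionPair", "cnr", "sobp_edge_regions", "cnr_report"]


@dataclass
class RegionPair:
    """Two disjoint voxel index sets on either side of an SOBP edge.

    ``inside`` and ``outside`` are (n, 3) integer index arrays into the
    map's counts grid; ``bounds_mm`` records the mm boxes they were cut
    from ((x0,x1),(y0,y1),(z0,z1)) for each side.
    """

    inside: np.ndarray
    outside: np.ndarray
    edge_label: str
    bounds_mm: tuple | None = None

    def __post_init__(self) -> None:
        if self.inside.size == 0 or self.outside.size == 0:
            raise ValueError(f"{self.edge_label}: both regions must be non-empty")
        a = {tuple(v) for v in self.inside}
        b = {tuple(v) for v in self.outside}
        if a & b:
            raise ValueError(f"{self.edge_label}: regions must be disjoint")


def _region_values(amap: AnnihilationMap, idx: np.ndarray) -> np.ndarray:
    return np.asarray(amap.counts, dtype=float)[idx[:, 0], idx[:, 1], idx[:, 2]]


def cnr(amap: AnnihilationMap, pair: RegionPair) -> float:
    """Contrast-to-noise ratio between the pair's two regions.

    Population SDs; symmetric in the two regions and invariant under
    positive affine rescaling of the map intensities.  Returns +inf (with
    a warning) when both SDs vanish but the means differ; 0 when the
    regions are statistically identical.
    """
    va = _region_values(amap, pair.inside)
    vb = _region_values(amap, pair.outside)
    mu_a, mu_b = va.mean(), vb.mean()
    var_a, var_b = va.var(), vb.var()
    denom = np.sqrt(var_a + var_b)
    if denom == 0.0:
        if mu_a == mu_b:
            return 0.0
        warnings.warn(f"{pair.edge_label}: zero variance with unequal means; "
                      "CNR is infinite", stacklevel=2)
        return float("inf")
    return float(abs(mu_a - mu_b) / denom)


def _box_to_indices(amap: AnnihilationMap, box: tuple) -> np.ndarray:
    """Voxel indices whose centres fall inside a half-open mm box."""
    sel = []
    for axis in range(3):
        centres = amap.voxel_centres(axis)
        lo, hi = box[axis]
        sel.append(np.nonzero((centres >= lo) & (centres < hi))[0])
    if any(s.size == 0 for s in sel):
        raise ValueError(f"region box {box} exceeds map bounds")
    ii, jj, kk = np.meshgrid(*sel, indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])


def sobp_edge_regions(amap: AnnihilationMap, plan: SOBPPlan,
                      transverse_extent: float = 50.0,
                      margin: float = 0.0, slab: float = 10.0
                      ) -> dict[str, RegionPair]:
    """Paired slabs at the proximal, distal and upper lateral SOBP edges.

    For each edge, ``inside`` is a slab of thickness ``slab`` just inside
    the boundary and ``outside`` the mirrored slab just beyond it,
    separated by ``margin``.  Proximal/distal pairs are restricted to the
    central 50% of the transverse field; the lateral pair spans the
    target depth range at the +x field edge.
    """
    prox, dist = plan.target_range
    half = transverse_extent / 2.0
    c = transverse_extent / 4.0  # central 50% of the field
    central_xy = ((-c, c), (-c, c))

    pairs = {}
    pairs["proximal"] = RegionPair(
        _box_to_indices(amap, (*central_xy, (prox, prox + slab))),
        _box_to_indices(amap, (*central_xy, (prox - margin - slab, prox - margin))),
        "proximal",
        bounds_mm=((prox, prox + slab), (prox - margin - slab, prox - margin)))
    pairs["distal"] = RegionPair(
        _box_to_indices(amap, (*central_xy, (dist - slab, dist))),
        _box_to_indices(amap, (*central_xy, (dist + margin, dist + margin + slab))),
        "distal",
        bounds_mm=((dist - slab, dist), (dist + margin, dist + margin + slab)))
    pairs["lateral"] = RegionPair(
        _box_to_indices(amap, ((half - slab, half), (-c, c), (prox, dist))),
        _box_to_indices(amap, ((half + margin, half + margin + slab), (-c, c),
                               (prox, dist))),
        "lateral",
        bounds_mm=((half - slab, half), (half + margin, half + margin + slab)))
    return pairs


def cnr_report(maps: dict[str, AnnihilationMap], plan: SOBPPlan,
               **region_kwargs) -> "pd.DataFrame":
    """CNR per (map label, edge) as a tidy table mirroring a
    species-by-window CNR grid."""
    import pandas as pd

    rows = []
    for label, amap in maps.items():
        pairs = sobp_edge_regions(amap, plan, **region_kwargs)
        for edge, pair in pairs.items():
            rows.append({"map": label, "edge": edge, "cnr": cnr(amap, pair)})
    return pd.DataFrame(rows)
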
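"""Time-activity curve (TAC) decomposition into fixed-half-life components.

Total activity in a region irradiated by a carbon or oxygen beam is a sum
of exponentials from the dominant positron emitters (C11, C10, O15):

    A(t) = sum_s A0_s * exp(-ln2 * t / T_s)

With the half-lives T_s fixed to their physical values the model is
linear in the initial activities A0_s, so the fit is a non-negative least
squares problem on an exponential design matrix.  Relative yields are the
A0_s as percentages of their sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .phantom_beam import SPECIES, DepthDoseProfile

__all__ = [
    "TimeActivityCurve",
    "YieldEstimate",
    "DEFAULT_HALF_LIVES",
    "total_activity",
    "fit_initial_activities",
    "roi_bounds_from_dose",
    "tac_from_events",
]

#: C11 20.334 min, C10 19.29 s, O15 122.24 s.
DEFAULT_HALF_LIVES: dict[str, float] = {
    "C11": SPECIES["C11"].half_life,
    "C10": SPECIES["C10"].half_life,
    "O15": SPECIES["O15"].half_life,
}


@dataclass
class TimeActivityCurve:
    """Frame-averaged activity per time frame.

    ``t`` holds frame start times; ``frame_lengths`` the frame durations
    (zero-length frames are instantaneous samples).
    """

    t: np.ndarray  # s, frame starts, increasing
    activity: np.ndarray  # Bq or counts/frame
    frame_lengths: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if np.isscalar(self.frame_lengths):
            self.frame_lengths = np.full_like(self.t, float(self.frame_lengths))
        else:
            self.frame_lengths = np.asarray(self.frame_lengths, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.activity < 0):
            raise ValueError("activity must be non-negative")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t_start_s": self.t,
                      "t_end_s": self.t + self.frame_lengths,
                      "activity": self.activity}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TimeActivityCurve":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        t0 = df["t_start_s"].to_numpy(float)
        return cls(t0, df["activity"].to_numpy(float),
                   df["t_end_s"].to_numpy(float) - t0)


@dataclass
class YieldEstimate:
    """Fitted initial activities and relative yields per species."""

    A0: dict[str, float]  # Bq
    relative_yield: dict[str, float]  # percent, sums to 100
    covariance: np.ndarray  # A0 covariance estimate (species order of A0)
    residual_norm: float = 0.0

    @property
    def species(self) -> list[str]:
        return list(self.A0)

    def standard_errors(self) -> dict[str, float]:
        se = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        return dict(zip(self.A0, se))

    def yield_table(self) -> str:
        """Pretty table of relative yields, one row per isotope."""
        lines = ["Isotope\tA0 (Bq)\tRelative yield (%)"]
        for s in self.A0:
            lines.append(f"{s}\t{self.A0[s]:.4g}\t{self.relative_yield[s]:.2f}")
        return "\n".join(lines)


def total_activity(t, A0: dict[str, float],
                   half_lives: dict[str, float] | None = None) -> np.ndarray:
    """Multi-exponential activity A(t) = sum_s A0_s 2^(-t/T_s)."""
    if half_lives is None:
        half_lives = DEFAULT_HALF_LIVES
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for s, a0 in A0.items():
        T = half_lives[s]
        if T <= 0:
            raise ValueError(f"half-life of {s} must be > 0")
        out = out + a0 * np.exp(-np.log(2.0) * t / T)
    return out


def _basis(t0: np.ndarray, dt: np.ndarray, half_lives: list[float]) -> np.ndarray:
    """Design matrix: frame-averaged exponentials (instantaneous if dt=0)."""
    cols = []
    for T in half_lives:
        lam = np.log(2.0) / T
        inst = np.exp(-lam * t0)
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = inst * (1.0 - np.exp(-lam * dt)) / (lam * dt)
        cols.append(np.where(dt > 0, avg, inst))
    return np.column_stack(cols)


def fit_initial_activities(tac: TimeActivityCurve,
                           half_lives: dict[str, float] | None = None
                           ) -> YieldEstimate:
    """Fit A0 per species by NNLS with half-lives fixed.

    Frame values are treated as frame-averaged activity, so the basis
    functions are the frame averages of the decaying exponentials.
    Raises if the design matrix is rank-deficient (e.g. two species share
    a half-life) or if fewer than three frames are given.
    """
    if half_lives is None:
        half_lives = DEFAULT_HALF_LIVES
    if tac.t.size < 3:
        raise ValueError("need at least three frames to fit")
    names = list(half_lives)
    Ts = [half_lives[s] for s in names]
    if len(set(Ts)) != len(Ts):
        raise ValueError("design matrix rank-deficient: duplicate half-lives")
    X = _basis(tac.t, tac.frame_lengths, Ts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix rank-deficient")
    a0, rnorm = optimize.nnls(X, tac.activity)
    total = a0.sum()
    rel = {s: (100.0 * a / total if total > 0 else 0.0)
           for s, a in zip(names, a0)}
    dof = max(tac.t.size - len(names), 1)
    sigma2 = rnorm**2 / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return YieldEstimate(dict(zip(names, a0)), rel, cov, residual_norm=float(rnorm))


def roi_bounds_from_dose(profile: DepthDoseProfile,
                         plateau_fraction: float = 0.1) -> tuple[float, float]:
    """Build-up and Bragg-peak region bounds from a depth-dose profile.

    Start: first depth where the dose has risen 5% above the entrance
    plateau (mean over the first ``plateau_fraction`` of the grid).
    End: last depth where the dose is still >= 5% of the peak value.
    """
    n_plateau = max(int(np.ceil(plateau_fraction * profile.depth.size)), 1)
    plateau = profile.dose[:n_plateau].mean()
    if plateau <= 0:
        raise ValueError("entrance plateau has zero dose")
    rise = profile.dose >= 1.05 * plateau
    if not rise.any():
        raise ValueError("dose never rises 5% above the entrance plateau")
    z_start = float(profile.depth[int(np.argmax(rise))])
    above = profile.dose >= 0.05 * profile.dose.max()
    z_end = float(profile.depth[int(np.nonzero(above)[0][-1])])
    if z_start >= z_end:
        raise ValueError("degenerate ROI: start >= end")
    return z_start, z_end


def tac_from_events(events, frames: np.ndarray, roi_z: tuple[float, float],
                    *, decay_correct_half_life: float | None = None
                    ) -> TimeActivityCurve:
    """Histogram annihilation events in a depth ROI into time frames.

    ``frames`` is an array of frame edges (s); the curve holds counts per
    frame divided by the frame length (i.e. frame-averaged count rate,
    which is the frame-averaged activity up to the event weight).  If
    ``decay_correct_half_life`` is given, each frame is multiplied by
    2^(t_mid/T) to undo the decay of a chosen reference species.
    """
    frames = np.asarray(frames, dtype=float)
    in_roi = (events.z >= roi_z[0]) & (events.z < roi_z[1])
    counts, _ = np.histogram(events.t[in_roi], bins=frames)
    dt = np.diff(frames)
    rate = counts / dt
    if decay_correct_half_life is not None:
        t_mid = frames[:-1] + dt / 2.0
        rate = rate * 2.0 ** (t_mid / decay_correct_half_life)
    return TimeActivityCurve(frames[:-1], rate, dt)
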
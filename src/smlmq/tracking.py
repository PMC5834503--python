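"""Single-particle tracking: linking, MSD diffusion, mobility classes.

Localizations are linked frame-to-frame by greedy nearest-neighbor
association, trajectories shorter than 5 steps are discarded, the apparent
diffusion coefficient comes from a linear fit of the first MSD lags
(MSD(τ) = 4Dτ in 2D), and particles are split into immobile
(D < 0.02 µm² s⁻¹) and mobile (D ≥ 0.02 µm² s⁻¹) classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_io import LocalizationTable

__all__ = [
    "Trajectory",
    "MOBILITY_THRESHOLD",
    "link_tracks",
    "filter_tracks",
    "msd_curve",
    "msd_diffusion",
    "classify_mobility",
    "MobilityClassifier",
]

MOBILITY_THRESHOLD = 0.02  # µm² s⁻¹


@dataclass
class Trajectory:
    particle_id: int
    frames: np.ndarray
    xy_nm: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, np.int64)
        self.xy_nm = np.asarray(self.xy_nm, float).reshape(-1, 2)
        if len(self.frames) != len(self.xy_nm):
            raise ValueError("frames and positions must align")
        if len(self.frames) < 2 or (np.diff(self.frames) <= 0).any():
            raise ValueError("frames must be strictly increasing with >= 2 points")

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1


def link_tracks(
    table: LocalizationTable,
    max_disp_nm: float = 500.0,
    max_gap_frames: int = 1,
) -> list[Trajectory]:
    """Greedy nearest-neighbor frame-to-frame linking.

    Within each frame, localizations (in record order) claim the nearest
    active track whose last frame is within ``max_gap_frames`` and whose
    last position is within ``max_disp_nm``; equidistant candidates go to
    the lower record index.  Every localization joins at most one track;
    single-localization tracks are dropped.
    """
    if max_disp_nm <= 0:
        raise ValueError("max_disp_nm must be > 0")
    xy = table.xy
    frames = table.frames
    n = len(table)
    track_frames: list[list[int]] = []
    track_xy: list[list[np.ndarray]] = []
    last_frame: list[int] = []

    order = np.argsort(frames, kind="stable")
    uniq, starts = np.unique(frames[order], return_index=True)
    starts = np.append(starts, n)
    for fi, f in enumerate(uniq):
        rows = order[starts[fi] : starts[fi + 1]]
        rows = rows[np.argsort(rows)]
        eligible = [
            t for t in range(len(track_frames))
            if f - 1 - max_gap_frames <= last_frame[t] <= f - 1
        ]
        taken: set[int] = set()
        epos = np.array([track_xy[t][-1] for t in eligible]) if eligible else None
        for r in rows:
            best = -1
            if eligible:
                d = np.linalg.norm(epos - xy[r], axis=1)
                for j in np.argsort(d, kind="stable"):
                    t = eligible[j]
                    if t in taken:
                        continue
                    if d[j] <= max_disp_nm:
                        best = t
                    break
            if best >= 0:
                track_frames[best].append(f)
                track_xy[best].append(xy[r])
                last_frame[best] = f
                taken.add(best)
            else:
                track_frames.append([f])
                track_xy.append([xy[r]])
                last_frame.append(f)
                taken.add(len(track_frames) - 1)

    out = []
    pid = 0
    for fr, pos in zip(track_frames, track_xy):
        if len(fr) >= 2:
            out.append(Trajectory(pid, np.array(fr), np.array(pos)))
            pid += 1
    return out


def filter_tracks(trajectories: list[Trajectory], min_steps: int = 5) -> list[Trajectory]:
    """Keep trajectories with at least ``min_steps`` steps."""
    return [t for t in trajectories if t.n_steps >= min_steps]


def msd_curve(traj: Trajectory, max_lag: int) -> np.ndarray:
    """Time-averaged MSD (nm²) at frame lags 1..max_lag; NaN where no pair."""
    out = np.full(max_lag, np.nan)
    for lag in range(1, max_lag + 1):
        dframes = traj.frames[:, None] - traj.frames[None, :]
        i, j = np.nonzero(dframes == -lag)
        if len(i):
            disp = traj.xy_nm[j] - traj.xy_nm[i]
            out[lag - 1] = float((disp**2).sum(axis=1).mean())
    return out


def msd_diffusion(
    traj: Trajectory,
    dt_s: float,
    n_fit_points: int = 4,
    fit_offset: bool = False,
) -> float:
    """Apparent D (µm² s⁻¹) from a linear fit of the first MSD lags.

    Default is a through-origin fit of MSD(τ) = 4Dτ on lags 1..4; with
    ``fit_offset`` an intercept absorbs the 4σ_loc² localization-noise
    plateau.  Negative slopes clip to D = 0.
    """
    if traj.n_steps < n_fit_points:
        raise ValueError("trajectory shorter than the number of MSD fit points")
    msd_nm2 = msd_curve(traj, n_fit_points)
    tau = dt_s * np.arange(1, n_fit_points + 1)
    ok = np.isfinite(msd_nm2)
    msd_um2 = msd_nm2[ok] / 1e6
    tau = tau[ok]
    if fit_offset:
        slope = np.polyfit(tau, msd_um2, 1)[0]
    else:
        slope = float((msd_um2 * tau).sum() / (tau**2).sum())
    return max(slope, 0.0) / 4.0


def classify_mobility(D_app: float, threshold: float = MOBILITY_THRESHOLD) -> str:
    """'immobile' below the threshold, 'mobile' at or above it."""
    if D_app < 0:
        raise ValueError("D_app must be >= 0")
    return "immobile" if D_app < threshold else "mobile"


class MobilityClassifier(BaseEstimator):
    """MSD-based diffusion estimation and mobility grouping of trajectories.

    ``fit`` stores per-trajectory apparent D in ``D_app_`` and classes in
    ``labels_``; ``summary_`` is a tidy per-particle DataFrame.
    """

    def __init__(
        self,
        dt_s: float,
        threshold: float = MOBILITY_THRESHOLD,
        n_fit_points: int = 4,
        fit_offset: bool = False,
        min_steps: int = 5,
    ):
        self.dt_s = dt_s
        self.threshold = threshold
        self.n_fit_points = n_fit_points
        self.fit_offset = fit_offset
        self.min_steps = min_steps

    def fit(self, X: list[Trajectory], y=None) -> "MobilityClassifier":
        kept = filter_tracks(X, self.min_steps)
        D = np.array(
            [msd_diffusion(t, self.dt_s, self.n_fit_points, self.fit_offset) for t in kept]
        )
        self.trajectories_ = kept
        self.D_app_ = D
        self.labels_ = np.array([classify_mobility(d, self.threshold) for d in D])
        self.summary_ = pd.DataFrame(
            {
                "particle_id": [t.particle_id for t in kept],
                "n_steps": [t.n_steps for t in kept],
                "D_um2_s": D,
                "mobility": self.labels_,
            }
        )
        return self

    def predict(self, X: list[Trajectory]) -> np.ndarray:
        return np.array(
            [
                classify_mobility(
                    msd_diffusion(t, self.dt_s, self.n_fit_points, self.fit_offset),
                    self.threshold,
                )
                for t in X
            ]
        )
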
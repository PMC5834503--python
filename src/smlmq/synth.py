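"""Synthetic localization-microscopy data with ground-truth annotations.

Every generator here emulates one class of raw input consumed by the
analysis pipelines: blinking emitters decorating filament centerlines,
clustered and uniform background localizations, fiducial beads riding a
common drift curve, per-oligomer intensity traces under binomial subunit
labeling, and 2D Brownian membrane trajectories.  All randomness flows
through one :func:`numpy.random.default_rng` seed, so a fixed seed yields
byte-identical output, and every localization carries a truth label
(``truth_id`` / ``truth_kind`` columns) linking it back to the object that
emitted it (or to ``"background"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ROI, IntensityTrace, LocalizationTable, Polyline

__all__ = [
    "BlinkModel",
    "GroundTruth",
    "sim_filament_field",
    "sim_microtubule",
    "sim_cluster_field",
    "sim_fiducials_with_drift",
    "sim_oligomer_traces",
    "sim_membrane_diffusion",
]

# FWHM = 2.35 * sigma throughout (truncated Gaussian convention).
FWHM_FACTOR = 2.35


@dataclass(frozen=True)
class BlinkModel:
    """Photoswitching statistics of a single fluorophore.

    ``logI_mu``/``logI_sigma`` parametrize the log-normal distribution of a
    single blink's integrated intensity in AD counts; the defaults are the
    AF647 calibration values µ = 5.68, σ = 0.4.  On-times are geometric in
    frames (memoryless), with mean ``on_frames``.
    """

    mean_blinks_per_fluorophore: float = 3.0
    on_frames: float = 2.0
    logI_mu: float = 5.68
    logI_sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.logI_sigma <= 0:
            raise ValueError("logI_sigma must be > 0")
        if self.mean_blinks_per_fluorophore <= 0:
            raise ValueError("mean_blinks_per_fluorophore must be > 0")

    @property
    def mean_intensity(self) -> float:
        """E[I] of one blink = exp(µ + σ²/2)."""
        return float(np.exp(self.logI_mu + self.logI_sigma**2 / 2))


@dataclass
class GroundTruth:
    """Truth annotations produced alongside each synthetic dataset."""

    emitters: pd.DataFrame | None = None        # emitter_id, x_nm, y_nm, object_id
    filaments: list[dict] = field(default_factory=list)
    clusters: pd.DataFrame | None = None        # cluster_id, x_nm, y_nm, radius_nm, n_members
    drift: np.ndarray | None = None             # (n_frames, 2) nm
    diffusion: pd.DataFrame | None = None       # particle_id, D_um2_s
    oligomers: pd.DataFrame | None = None       # oligomer_id, k_labeled
    sigma_loc_nm: float | None = None


def _blink_localizations(
    emitter_xy: np.ndarray,
    blink: BlinkModel,
    sigma_loc_nm: float,
    n_frames: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand emitters into per-frame localizations via the blink model.

    Each emitter produces at least one blink; each blink occupies a run of
    consecutive frames (geometric duration) and yields one localization per
    on-frame with isotropic Gaussian position error.  A blink's integrated
    log-normal intensity is spread evenly over its on-frames.
    """
    rows_id, rows_frame, rows_int = [], [], []
    n_emitters = len(emitter_xy)
    n_blinks = np.maximum(1, rng.poisson(blink.mean_blinks_per_fluorophore, n_emitters))
    for i in range(n_emitters):
        for _ in range(n_blinks[i]):
            start = rng.integers(0, n_frames)
            dur = rng.geometric(min(1.0, 1.0 / blink.on_frames))
            frames = np.arange(start, min(start + dur, n_frames))
            amp = rng.lognormal(blink.logI_mu, blink.logI_sigma)
            rows_id.append(np.full(len(frames), i))
            rows_frame.append(frames)
            rows_int.append(np.full(len(frames), amp / len(frames)))
    emitter_idx = np.concatenate(rows_id)
    frames = np.concatenate(rows_frame)
    xy = emitter_xy[emitter_idx] + rng.normal(0.0, sigma_loc_nm, (len(frames), 2))
    df = pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "frame": frames,
            "intensity": np.concatenate(rows_int),
            "truth_id": emitter_idx,
        }
    )
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


def _resample_polyline(vertices: np.ndarray, arclengths: np.ndarray) -> np.ndarray:
    """Points at given arclengths along a polyline (nm)."""
    seg = np.diff(vertices, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = np.clip(np.searchsorted(cum, arclengths, side="right") - 1, 0, len(seg) - 1)
    t = (arclengths - cum[idx]) / seglen[idx]
    return vertices[idx] + t[:, None] * seg[idx]


def _polyline_normals(vertices: np.ndarray, arclengths: np.ndarray) -> np.ndarray:
    seg = np.diff(vertices, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    idx = np.clip(np.searchsorted(cum, arclengths, side="right") - 1, 0, len(seg) - 1)
    tang = seg[idx] / seglen[idx][:, None]
    return np.stack([-tang[:, 1], tang[:, 0]], axis=1)


def sim_filament_field(
    centerlines: list[Polyline],
    width_nm: float | list[float],
    coverage: float | list[float],
    label_density: float,
    blink: BlinkModel,
    sigma_loc_nm: float,
    seed: int,
    n_frames: int = 10_000,
    gap_segment_nm: float = 200.0,
) -> tuple[LocalizationTable, GroundTruth]:
    """Blinking emitters decorating filament centerlines.

    The nominal filament width w is realized as a transverse Gaussian with
    σ = w / 2.35, so a Gaussian FWHM fit of the transverse localization
    profile recovers w (convolved with localization precision:
    FWHM_apparent = sqrt(w² + (2.35 σ_loc)²)).  A fraction (1 − coverage)
    of contiguous ``gap_segment_nm`` centerline segments carries no
    emitters.  ``label_density`` is emitters per µm of labeled length.
    """
    rng = np.random.default_rng(seed)
    widths = np.broadcast_to(np.asarray(width_nm, float), (len(centerlines),))
    coverages = np.broadcast_to(np.asarray(coverage, float), (len(centerlines),))
    if ((coverages < 0) | (coverages > 1)).any():
        raise ValueError("coverage must be in [0, 1]")
    if (widths < 0).any():
        raise ValueError("width_nm must be >= 0")

    emitter_rows = []
    filament_truth = []
    for fid, line in enumerate(centerlines):
        length = line.length_nm
        n_seg = max(1, int(np.ceil(length / gap_segment_nm)))
        seg_edges = np.linspace(0.0, length, n_seg + 1)
        n_unlabeled = int(round((1.0 - coverages[fid]) * n_seg))
        unlabeled = set(rng.choice(n_seg, size=n_unlabeled, replace=False).tolist())
        labeled_segs = [i for i in range(n_seg) if i not in unlabeled]
        filament_truth.append(
            {
                "filament_id": fid,
                "centerline": line,
                "width_nm": float(widths[fid]),
                "coverage": float(coverages[fid]),
                "labeled_segments": labeled_segs,
                "segment_edges_nm": seg_edges,
            }
        )
        labeled_len = sum(seg_edges[i + 1] - seg_edges[i] for i in labeled_segs)
        n_emit = rng.poisson(label_density * labeled_len / 1000.0)
        if n_emit == 0 or not labeled_segs:
            continue
        # uniform arclength positions on the labeled portion
        u = rng.uniform(0.0, labeled_len, n_emit)
        offsets = np.concatenate(
            [[0.0], np.cumsum([seg_edges[i + 1] - seg_edges[i] for i in labeled_segs])]
        )
        which = np.clip(np.searchsorted(offsets, u, side="right") - 1, 0, len(labeled_segs) - 1)
        s = np.array([seg_edges[labeled_segs[w]] for w in which]) + (u - offsets[which])
        pts = _resample_polyline(line.vertices, s)
        normals = _polyline_normals(line.vertices, s)
        transverse = rng.normal(0.0, widths[fid] / FWHM_FACTOR if widths[fid] > 0 else 0.0, n_emit)
        xy = pts + transverse[:, None] * normals
        emitter_rows.append(
            pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "object_id": fid})
        )

    if emitter_rows:
        emitters = pd.concat(emitter_rows, ignore_index=True)
    else:
        emitters = pd.DataFrame({"x_nm": [], "y_nm": [], "object_id": []})
    emitters.insert(0, "emitter_id", np.arange(len(emitters)))

    if len(emitters):
        df = _blink_localizations(
            emitters[["x_nm", "y_nm"]].to_numpy(), blink, sigma_loc_nm, n_frames, rng
        )
    else:
        df = pd.DataFrame(
            {"x_nm": [], "y_nm": [], "frame": [], "intensity": [], "truth_id": []}
        )
    df["truth_kind"] = "filament"
    table = LocalizationTable(df, n_frames=n_frames)
    truth = GroundTruth(emitters=emitters, filaments=filament_truth, sigma_loc_nm=sigma_loc_nm)
    return table, truth


def sim_microtubule(
    n_localizations: int,
    diameter_nm: float = 25.0,
    probe_displacement_nm: float = 5.0,
    sigma_loc_nm: float = 10.0,
    length_nm: float = 5_000.0,
    seed: int = 0,
    n_frames: int = 10_000,
) -> LocalizationTable:
    """Localizations from a nanobody-decorated microtubule, projected to 2D.

    Emitters sit uniformly on a cylinder surface of the given diameter and
    are displaced radially outward by Uniform(0, probe_displacement) — the
    linkage error of the probe.  The transverse image coordinate is the
    projection r·cos(θ); isotropic Gaussian localization error is then
    added per axis.  The default geometry (25-nm tubule, ≤5-nm probe,
    10-nm precision) produces an apparent Gaussian-fitted fiber width near
    40 nm.
    """
    if min(diameter_nm, probe_displacement_nm, sigma_loc_nm) < 0:
        raise ValueError("lengths must be non-negative")
    if n_localizations < 100:
        warnings.warn("fewer than 100 localizations: width fit will be unstable")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_localizations)
    r = diameter_nm / 2.0 + rng.uniform(0.0, probe_displacement_nm, n_localizations)
    x = rng.uniform(0.0, length_nm, n_localizations)  # along the tubule axis
    y = r * np.cos(theta)
    xy = np.stack([x, y], axis=1) + rng.normal(0.0, sigma_loc_nm, (n_localizations, 2))
    frames = rng.integers(0, n_frames, n_localizations)
    order = np.argsort(frames, kind="stable")
    return LocalizationTable.from_arrays(
        xy[order, 0], xy[order, 1], frames[order], truth_kind="microtubule"
    )


def sim_cluster_field(
    roi: ROI,
    cluster_centers: int | np.ndarray,
    locs_per_cluster: int,
    cluster_radius_nm: float,
    background_density: float,
    seed: int,
    n_frames: int = 10_000,
) -> tuple[LocalizationTable, GroundTruth]:
    """Gaussian clusters plus homogeneous Poisson background inside a ROI.

    Cluster members are Normal(center, cluster_radius) in 2D; the
    background count is Poisson(background_density · area) with uniform
    positions (``background_density`` in localizations per µm²).
    Background points carry ``truth_id = -1``.
    """
    if background_density < 0:
        raise ValueError("background_density must be >= 0")
    rng = np.random.default_rng(seed)
    if np.isscalar(cluster_centers):
        n_clusters = int(cluster_centers)
        centers = np.stack(
            [
                rng.uniform(roi.x_min, roi.x_max, n_clusters),
                rng.uniform(roi.y_min, roi.y_max, n_clusters),
            ],
            axis=1,
        )
    else:
        centers = np.asarray(cluster_centers, float).reshape(-1, 2)
        n_clusters = len(centers)

    parts = []
    for cid in range(n_clusters):
        xy = centers[cid] + rng.normal(0.0, cluster_radius_nm, (locs_per_cluster, 2))
        parts.append(pd.DataFrame({"x_nm": xy[:, 0], "y_nm": xy[:, 1], "truth_id": cid}))
    n_bg = rng.poisson(background_density * roi.area_um2)
    if n_bg:
        parts.append(
            pd.DataFrame(
                {
                    "x_nm": rng.uniform(roi.x_min, roi.x_max, n_bg),
                    "y_nm": rng.uniform(roi.y_min, roi.y_max, n_bg),
                    "truth_id": -1,
                }
            )
        )
    if parts:
        df = pd.concat(parts, ignore_index=True)
    else:
        df = pd.DataFrame({"x_nm": [], "y_nm": [], "truth_id": []})
    df["frame"] = rng.integers(0, n_frames, len(df))
    df["intensity"] = 1.0
    df["truth_kind"] = np.where(df["truth_id"] >= 0, "cluster", "background")
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    truth = GroundTruth(
        clusters=pd.DataFrame(
            {
                "cluster_id": np.arange(n_clusters),
                "x_nm": centers[:, 0] if n_clusters else [],
                "y_nm": centers[:, 1] if n_clusters else [],
                "radius_nm": cluster_radius_nm,
                "n_members": locs_per_cluster,
            }
        )
    )
    return LocalizationTable(df, n_frames=n_frames), truth


def make_drift_curve(
    n_frames: int, drift_model: dict, rng: np.random.Generator
) -> np.ndarray:
    """(n_frames, 2) drift in nm; (0, 0) at frame 0."""
    kind = drift_model.get("kind", "none")
    if kind == "none":
        return np.zeros((n_frames, 2))
    if kind == "linear":
        v = np.asarray(drift_model["velocity_nm_per_frame"], float)
        return np.arange(n_frames)[:, None] * v[None, :]
    if kind == "random_walk":
        steps = rng.normal(0.0, drift_model["step_sd_nm"], (n_frames, 2))
        steps[0] = 0.0
        return np.cumsum(steps, axis=0)
    if kind == "curve":
        curve = np.asarray(drift_model["curve_nm"], float)
        if curve.shape != (n_frames, 2):
            raise ValueError("curve_nm must have shape (n_frames, 2)")
        return curve
    raise ValueError(f"unknown drift model kind {kind!r}")


def sim_fiducials_with_drift(
    n_beads: int,
    drift_model: dict,
    table: LocalizationTable,
    seed: int,
    bead_sigma_loc_nm: float = 2.0,
    bead_presence: float = 0.995,
    bead_intensity: float = 1e4,
) -> tuple[LocalizationTable, GroundTruth]:
    """Add bright fiducial beads and apply a common drift to everything.

    Beads localize in ≥99% of frames with small scatter (they are orders of
    magnitude brighter than single fluorophores); the same per-frame drift
    displaces both bead and sample localizations.  The truth stores the
    drift curve.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    n_frames = table.n_frames
    drift = make_drift_curve(n_frames, drift_model, rng)

    xy = table.xy
    if len(xy):
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        span = np.maximum(hi - lo, 1000.0)
    else:
        lo, span = np.zeros(2), np.full(2, 10_000.0)
    # beads placed in a margin ring around the sample so NeNA ROIs can avoid them
    base = lo + span * rng.uniform(-0.15, 1.15, (n_beads, 2))

    sample = table.df.copy()
    sample["x_nm"] = sample["x_nm"] + drift[sample["frame"], 0]
    sample["y_nm"] = sample["y_nm"] + drift[sample["frame"], 1]
    if "truth_kind" not in sample.columns:
        sample["truth_kind"] = "sample"

    bead_parts = []
    for b in range(n_beads):
        present = rng.uniform(size=n_frames) < bead_presence
        frames = np.flatnonzero(present)
        pos = base[b] + drift[frames] + rng.normal(0.0, bead_sigma_loc_nm, (len(frames), 2))
        bead_parts.append(
            pd.DataFrame(
                {
                    "x_nm": pos[:, 0],
                    "y_nm": pos[:, 1],
                    "frame": frames,
                    "intensity": bead_intensity,
                    "truth_id": b,
                    "truth_kind": "bead",
                }
            )
        )
    df = pd.concat([sample] + bead_parts, ignore_index=True)
    df = df.sort_values("frame", kind="stable").reset_index(drop=True)
    out = LocalizationTable(
        df, pixel_size_nm=table.pixel_size_nm, exposure_ms=table.exposure_ms, n_frames=n_frames
    )
    truth = GroundTruth(
        drift=drift,
        emitters=pd.DataFrame(
            {"emitter_id": np.arange(n_beads), "x_nm": base[:, 0], "y_nm": base[:, 1]}
        ),
    )
    return out, truth


def sim_oligomer_traces(
    dol: float,
    n_oligomers: int,
    seed: int,
    n_subunits: int = 24,
    blink: BlinkModel = BlinkModel(),
    n_frames: int = 200,
    baseline: float = 1000.0,
    noise_sd: float = 30.0,
    initial_on_frames: int = 5,
    blink_window: int = 100,
) -> tuple[list[IntensityTrace], GroundTruth]:
    """ROI intensity traces of immobilized oligomers under binomial labeling.

    Each oligomer carries k ~ Binomial(n_subunits, dol) fluorophores.  All k
    are on simultaneously during the first ``initial_on_frames`` frames (so
    the second frame integrates the full complement), each contributing one
    log-normal draw; afterwards the trace returns to baseline, and each
    fluorophore blinks individually within the last ``blink_window`` frames
    (Poisson number of blinks, geometric on-times, fresh log-normal
    amplitude per blink).  Gaussian camera noise rides on everything.
    """
    if not 0.0 <= dol <= 1.0:
        raise ValueError("dol must be in [0, 1]")
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    rng = np.random.default_rng(seed)
    traces = []
    ks = rng.binomial(n_subunits, dol, n_oligomers)
    for i in range(n_oligomers):
        counts = baseline + rng.normal(0.0, noise_sd, n_frames)
        k = ks[i]
        if k > 0:
            initial = rng.lognormal(blink.logI_mu, blink.logI_sigma, k).sum()
            counts[:initial_on_frames] += initial
            n_blinks = rng.poisson(blink.mean_blinks_per_fluorophore, k)
            w0 = n_frames - blink_window
            for _ in range(int(n_blinks.sum())):
                start = rng.integers(w0, n_frames)
                dur = rng.geometric(min(1.0, 1.0 / blink.on_frames))
                amp = rng.lognormal(blink.logI_mu, blink.logI_sigma)
                counts[start : min(start + dur, n_frames)] += amp
        traces.append(IntensityTrace(f"oligo_{i:05d}", counts))
    truth = GroundTruth(
        oligomers=pd.DataFrame({"oligomer_id": np.arange(n_oligomers), "k_labeled": ks})
    )
    return traces, truth


def sim_membrane_diffusion(
    n_particles: int,
    D_values: float | np.ndarray,
    dt_s: float,
    n_frames: int,
    sigma_loc_nm: float,
    seed: int,
    box_nm: float = 20_000.0,
) -> tuple[LocalizationTable, GroundTruth]:
    """2D Brownian trajectories at specified diffusion coefficients.

    Per-axis displacement per frame is Normal(0, sqrt(2·D·dt)); D in
    µm² s⁻¹, output in nm.  Localization noise is added independently per
    frame.  The truth stores each particle's D.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    D = np.broadcast_to(np.asarray(D_values, float), (n_particles,))
    if (D < 0).any():
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, box_nm, (n_particles, 2))
    # sqrt(2 D dt) in µm -> nm
    step_sd = np.sqrt(2.0 * D * dt_s) * 1000.0
    steps = rng.normal(0.0, 1.0, (n_particles, n_frames - 1, 2)) * step_sd[:, None, None]
    pos = np.concatenate(
        [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )
    obs = pos + rng.normal(0.0, sigma_loc_nm, pos.shape)
    frames = np.tile(np.arange(n_frames), n_particles)
    pid = np.repeat(np.arange(n_particles), n_frames)
    df = pd.DataFrame(
        {
            "x_nm": obs[:, :, 0].ravel(),
            "y_nm": obs[:, :, 1].ravel(),
            "frame": frames,
            "intensity": 1.0,
            "particle_id": pid,
            "truth_id": pid,
            "truth_kind": "particle",
        }
    )
    df = df.sort_values(["frame", "particle_id"], kind="stable").reset_index(drop=True)
    table = LocalizationTable(df, exposure_ms=dt_s * 1000.0, n_frames=n_frames)
    truth = GroundTruth(
        diffusion=pd.DataFrame({"particle_id": np.arange(n_particles), "D_um2_s": D}),
        sigma_loc_nm=sigma_loc_nm,
    )
    return table, truth
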
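"""Per-frame kinematic features and fixed-interval averaging.

Speed is the Euclidean centroid displacement between consecutive frames
divided by the elapsed time, assigned to the leading frame of each pair.
The body-posture feature is the midpoint bending angle: with M the skeleton
point nearest half arc length and A, P the points nearest one- and
three-quarter arc length, the angle is 180 deg minus the interior angle at
M between the vectors M->A and M->P, so a straight (collinear) worm scores
0 deg and a worm folded fully back on itself scores 180 deg. Both features
are then averaged over fixed windows (10 s by default) to give one point
per interval on the speed-vs-bending-angle plane.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import AnalysisConfig
from .errors import InsufficientDataError, ValidationError
from .types import IntervalFeature, Trajectory

log = logging.getLogger(__name__)


def centroid_speed(traj: Trajectory) -> np.ndarray:
    """Per-frame centroid speed in um/s.

    Returns an array of length ``n_frames - 1``; element ``i`` is the speed
    over the displacement from frame ``i`` to ``i + 1`` (leading-frame
    convention).
    """
    if traj.n_frames < 2:
        raise InsufficientDataError(
            f"animal {traj.animal_id!r}: need >= 2 frames for speed"
        )
    dt = np.diff(traj.time_s)
    if np.any(dt <= 0):
        raise ValidationError(f"animal {traj.animal_id!r}: non-positive time step")
    disp = np.hypot(np.diff(traj.x_um), np.diff(traj.y_um))
    return disp / dt


def _arc_length_points(skeleton: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Skeleton points nearest 25%, 50% and 75% of arc length, per frame.

    ``skeleton`` has shape (n_frames, k, 2). Degenerate frames (zero total
    arc length) get index 0 for all three points and are caught later.
    """
    seg = np.linalg.norm(np.diff(skeleton, axis=1), axis=2)  # (n, k-1)
    cum = np.concatenate(
        [np.zeros((skeleton.shape[0], 1)), np.cumsum(seg, axis=1)], axis=1
    )  # (n, k)
    total = cum[:, -1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, cum / total, 0.0)
    idx = [np.argmin(np.abs(frac - q), axis=1) for q in (0.25, 0.5, 0.75)]
    rows = np.arange(skeleton.shape[0])
    a, m, p = (skeleton[rows, i] for i in idx)
    return a, m, p


def midpoint_bending_angle(traj: Trajectory) -> np.ndarray:
    """Per-frame midpoint bending angle in degrees, length ``n_frames``.

    Uses the skeleton when present; otherwise passes through a tracker-
    provided ``bend_deg`` column unchanged. Frames with degenerate geometry
    (A or P coincident with M) are set to NaN and logged; they are excluded
    from interval means.
    """
    if traj.skeleton_um is not None:
        if traj.skeleton_um.shape[1] < 5:
            raise InsufficientDataError(
                f"animal {traj.animal_id!r}: skeleton has "
                f"{traj.skeleton_um.shape[1]} points (need >= 5)"
            )
        a, m, p = _arc_length_points(traj.skeleton_um)
        va = a - m
        vp = p - m
        na = np.linalg.norm(va, axis=1)
        npp = np.linalg.norm(vp, axis=1)
        degenerate = (na == 0) | (npp == 0)
        if degenerate.any():
            log.warning(
                "animal %s: %d frame(s) with degenerate skeleton geometry excluded",
                traj.animal_id,
                int(degenerate.sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", va, vp) / (na * npp)
        interior = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        bend = 180.0 - interior
        bend[degenerate] = np.nan
        return bend
    if traj.bend_deg is not None:
        return np.asarray(traj.bend_deg, dtype=float)
    raise InsufficientDataError(
        f"animal {traj.animal_id!r}: no skeleton and no bend_deg column"
    )


def bin_into_intervals(
    traj: Trajectory,
    speeds: np.ndarray,
    bends: np.ndarray | None,
    config: AnalysisConfig,
) -> list[IntervalFeature]:
    """Average per-frame features into fixed windows of ``config.interval_s``.

    A frame at time t belongs to interval ``floor((t - t_first)/interval_s)``.
    Speeds use the leading-frame convention, so the last frame contributes no
    speed sample. Intervals covering fewer than
    ``min_interval_coverage * interval_s * frame_rate_hz`` frames are dropped
    (logged); an empty result is returned with a warning rather than an error.
    """
    n = traj.n_frames
    if len(speeds) != n - 1:
        raise ValidationError("speed series must have length n_frames - 1")
    if bends is not None and len(bends) != n:
        raise ValidationError("bend series must be aligned to frames")

    rel_t = traj.time_s - traj.time_s[0]
    idx = np.floor(rel_t / config.interval_s).astype(int)
    speeds_padded = np.append(speeds, np.nan)  # last frame: no leading displacement
    min_frames = config.min_interval_coverage * config.interval_s * traj.frame_rate_hz

    out: list[IntervalFeature] = []
    for k in np.unique(idx):
        sel = idx == k
        n_frames = int(sel.sum())
        if n_frames < min_frames:
            log.info(
                "animal %s: interval %d dropped (%d frames < %.1f required)",
                traj.animal_id,
                int(k),
                n_frames,
                min_frames,
            )
            continue
        with np.errstate(invalid="ignore"):
            mean_speed = float(np.nanmean(speeds_padded[sel]))
            mean_bend = float(np.nanmean(bends[sel])) if bends is not None else float("nan")
        if not np.isfinite(mean_speed):
            continue  # interval consisted of the trailing frame only
        out.append(
            IntervalFeature(
                animal_id=traj.animal_id,
                interval_index=int(k),
                t_start_s=float(traj.time_s[0] + k * config.interval_s),
                mean_speed_um_s=mean_speed,
                mean_bend_deg=mean_bend,
                n_frames=n_frames,
            )
        )
    if not out:
        log.warning("animal %s: no intervals retained", traj.animal_id)
    return out


def interval_features(traj: Trajectory, config: AnalysisConfig) -> list[IntervalFeature]:
    """Convenience: speed + bending angle + binning in one call.

    Bending angle is included when the trajectory carries a skeleton or a
    ``bend_deg`` column, and left NaN otherwise (classification only needs
    speed).
    """
    speeds = centroid_speed(traj)
    try:
        bends = midpoint_bending_angle(traj)
    except InsufficientDataError:
        bends = None
    return bin_into_intervals(traj, speeds, bends, config)
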
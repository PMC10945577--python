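"""Synthetic data with known ground truth.

The trajectory generator emulates the statistical structure the behavioral
analysis assumes, without claiming to model the underlying neurobiology: a
two-state (roaming/dwelling) Markov chain switching at the 10-s interval
resolution, with state-conditional emissions chosen to match the assay's
qualitative signature -- roaming is fast and straight (lognormal speeds
around a 25 um/s median, low bending angles), dwelling is slow and curved
(median 2 um/s, high bending angles). Positions integrate the sampled speed
along a persistent-random-walk heading inside a circular arena (a 6 cm ring
by default), recorded at 3.75 frames/s.

Fluorescence generators produce Gaussian-spot images and per-animal
intensity tables with lognormal variation and condition-specific fold
changes, so ROI quantification and condition ratios can be verified against
the generating truth.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .types import DWELL, ROAM, Trajectory


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of the foraging-trajectory generator.

    ``p_dr`` and ``p_rd`` are per-interval transition probabilities
    dwell->roam and roam->dwell; the stationary roaming occupancy is
    ``p_dr / (p_dr + p_rd)``. Speed distributions are lognormal
    (median um/s, log-SD); bending-angle distributions are normal
    (mean deg, SD) truncated to [0, 180].
    """

    p_dr: float = 0.1
    p_rd: float = 0.2
    roam_speed: tuple[float, float] = (25.0, 0.3)
    dwell_speed: tuple[float, float] = (2.0, 0.4)
    roam_bend: tuple[float, float] = (10.0, 5.0)
    dwell_bend: tuple[float, float] = (45.0, 15.0)
    frame_rate_hz: float = 3.75
    interval_s: float = 10.0
    heading_persistence: float = 0.9
    arena_radius_um: float = 30000.0
    duration_s: float = 3600.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_dr", "p_rd"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        for name in ("roam_speed", "dwell_speed", "roam_bend", "dwell_bend"):
            loc, scale = getattr(self, name)
            if loc <= 0 or scale <= 0:
                raise ParameterError(f"{name} location and scale must be positive")
        if not 0 <= self.heading_persistence <= 1:
            raise ParameterError("heading_persistence must lie in [0, 1]")
        if min(self.frame_rate_hz, self.interval_s, self.arena_radius_um, self.duration_s) <= 0:
            raise ParameterError("rates, intervals, radius and duration must be positive")

    @property
    def stationary_roam_occupancy(self) -> float:
        if self.p_dr + self.p_rd == 0:
            return 0.5
        return self.p_dr / (self.p_dr + self.p_rd)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """True per-interval state labels and the generating parameters."""

    labels: tuple[str, ...]
    params: SimulationParams


def _sample_markov_labels(
    params: SimulationParams,
    n_intervals: int,
    rng: np.random.Generator,
    initial_state: str | None,
) -> list[str]:
    if initial_state is None:
        state = ROAM if rng.random() < params.stationary_roam_occupancy else DWELL
    else:
        state = initial_state
    labels = []
    for _ in range(n_intervals):
        labels.append(state)
        if state == DWELL:
            state = ROAM if rng.random() < params.p_dr else DWELL
        else:
            state = DWELL if rng.random() < params.p_rd else ROAM
    return labels


def _truncnorm_samples(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (180.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_foraging_trajectory(
    params: SimulationParams,
    *,
    animal_id: str = "sim",
    initial_state: str | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Generate one trajectory plus its ground-truth interval labels.

    The state chain starts from the stationary distribution unless
    ``initial_state`` is given. Each frame inherits the state of the 10-s
    interval it falls in, so ground-truth labels align exactly with the
    analysis pipeline's interval grid. Headings follow a persistent random
    walk (turn SD ``(1 - heading_persistence) * pi`` rad/frame) with
    specular reflection at the circular arena boundary.
    """
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.frame_rate_hz
    n_frames = int(np.floor(params.duration_s * params.frame_rate_hz))
    n_intervals = int(np.floor(params.duration_s / params.interval_s))
    if n_frames < 2 or n_intervals < 1:
        raise ParameterError("duration too short for the configured rates")

    labels = _sample_markov_labels(params, n_intervals, rng, initial_state)
    time_s = np.arange(n_frames) * dt
    frame_interval = np.minimum(
        np.floor(time_s / params.interval_s).astype(int), n_intervals - 1
    )
    roaming = np.asarray([labels[k] == ROAM for k in frame_interval])

    def lognormal(median_logsd: tuple[float, float], size: int) -> np.ndarray:
        median, logsd = median_logsd
        return median * np.exp(logsd * rng.standard_normal(size))

    speeds = np.where(
        roaming,
        lognormal(params.roam_speed, n_frames),
        lognormal(params.dwell_speed, n_frames),
    )
    n_roam = int(roaming.sum())
    bends = np.empty(n_frames)
    bends[roaming] = _truncnorm_samples(*params.roam_bend, n_roam, rng)
    bends[~roaming] = _truncnorm_samples(*params.dwell_bend, n_frames - n_roam, rng)

    turn_sd = (1.0 - params.heading_persistence) * np.pi
    turns = rng.standard_normal(n_frames) * turn_sd
    x = np.empty(n_frames)
    y = np.empty(n_frames)
    x[0] = y[0] = 0.0
    heading = rng.uniform(0.0, 2.0 * np.pi)
    r2 = params.arena_radius_um**2
    for i in range(1, n_frames):
        heading += turns[i]
        step = speeds[i - 1] * dt
        nx = x[i - 1] + step * np.cos(heading)
        ny = y[i - 1] + step * np.sin(heading)
        if nx * nx + ny * ny > r2:
            # specular reflection: flip the radial component of the heading
            phi = np.arctan2(ny, nx)
            heading = np.pi + 2.0 * phi - heading
            nx = x[i - 1] + step * np.cos(heading)
            ny = y[i - 1] + step * np.sin(heading)
            if nx * nx + ny * ny > r2:  # cornered against the wall
                nx, ny = x[i - 1], y[i - 1]
        x[i], y[i] = nx, ny

    traj = Trajectory(
        animal_id=animal_id,
        frame_index=np.arange(n_frames),
        time_s=time_s,
        x_um=x,
        y_um=y,
        frame_rate_hz=params.frame_rate_hz,
        bend_deg=np.clip(bends, 0.0, 180.0),
    )
    return traj, GroundTruth(labels=tuple(labels), params=params)


def simulate_cohort(
    params: SimulationParams, n_animals: int, *, id_prefix: str = "worm"
) -> list[tuple[Trajectory, GroundTruth]]:
    """Independent animals sharing parameters; per-animal seeds are derived
    from ``params.seed`` so the cohort is reproducible as a unit."""
    seeds = np.random.SeedSequence(params.seed).generate_state(n_animals) % (2**31)
    out = []
    for i in range(n_animals):
        p = dataclasses.replace(params, seed=int(seeds[i]))
        out.append(
            simulate_foraging_trajectory(p, animal_id=f"{id_prefix}{i:03d}")
        )
    return out


def simulate_fluorescence_image(
    shape: tuple[int, int],
    spot_centers_xy: Sequence[tuple[float, float]],
    amplitudes: Sequence[float],
    spot_sigma_px: float = 3.0,
    noise_sd: float = 0.0,
    baseline: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Sum of 2-D Gaussian spots + baseline + Gaussian read noise, clipped
    at zero. Returns the image and a truth record of the generating spots."""
    h, w = shape
    if len(spot_centers_xy) != len(amplitudes):
        raise ParameterError("one amplitude per spot centre required")
    for (cx, cy) in spot_centers_xy:
        if not (0 <= cx < w and 0 <= cy < h):
            raise ParameterError(f"spot centre ({cx}, {cy}) outside {w}x{h} image")
    if any(a < 0 for a in amplitudes):
        raise ParameterError("amplitudes must be >= 0")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    image = np.full(shape, float(baseline))
    for (cx, cy), amp in zip(spot_centers_xy, amplitudes):
        image += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * spot_sigma_px**2)
        )
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=shape)
    image = np.clip(image, 0.0, None)
    truth = {
        "centers_xy": [tuple(map(float, c)) for c in spot_centers_xy],
        "amplitudes": [float(a) for a in amplitudes],
        "baseline": float(baseline),
        "spot_sigma_px": float(spot_sigma_px),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
    }
    return image, truth


def simulate_fluorescence_table(
    n_per_group: int,
    condition_fold_changes: Mapping[str, float],
    *,
    base_median_au: float = 120.0,
    lognormal_sigma: float = 0.2,
    genotype: str = "wild type",
    neuron: str = "ASJ",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-animal maximum-intensity table with lognormal variation.

    Each condition's intensities are lognormal around
    ``base_median_au * fold_change`` with log-SD ``lognormal_sigma``.
    Because the log-SD is shared, the ratio of group means estimates the
    generating fold change. Returns the table and a truth record.
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    if any(f <= 0 for f in condition_fold_changes.values()):
        raise ParameterError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for condition, fold in condition_fold_changes.items():
        median = base_median_au * fold
        vals = median * np.exp(lognormal_sigma * rng.standard_normal(n_per_group))
        for i, v in enumerate(vals):
            rows.append(
                {
                    "animal_id": f"{genotype}-{condition}-{i:03d}",
                    "genotype": genotype,
                    "condition": condition,
                    "neuron": neuron,
                    "max_intensity_au": float(v),
                }
            )
    truth = {
        "fold_changes": dict(condition_fold_changes),
        "base_median_au": float(base_median_au),
        "lognormal_sigma": float(lognormal_sigma),
        "n_per_group": int(n_per_group),
        "seed": int(seed),
    }
    return pd.DataFrame(rows), truth
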
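"""Core domain containers shared across the pipeline modules."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ValidationError

#: State labels used throughout. Stored as plain strings so they survive
#: round trips through TSV files unchanged.
ROAM = "ROAM"
DWELL = "DWELL"


@dataclasses.dataclass
class Trajectory:
    """A tracked animal: time-ordered centroid positions, optionally with a
    skeleton (constant point count, head->tail) or a precomputed per-frame
    bending angle.

    Coordinates are micrometres in an arbitrary plate frame; only
    displacements and grid occupancy are ever used, so no origin convention
    is imposed. ``time_s`` is authoritative for all kinematics;
    ``frame_index`` is bookkeeping (dropped frames are common in tracking).
    """

    animal_id: str
    frame_index: np.ndarray  # (n,) int
    time_s: np.ndarray  # (n,) float, strictly increasing
    x_um: np.ndarray  # (n,) float
    y_um: np.ndarray  # (n,) float
    frame_rate_hz: float = 3.75
    skeleton_um: np.ndarray | None = None  # (n, k, 2) float, k >= 5
    bend_deg: np.ndarray | None = None  # (n,) float in [0, 180]

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("frame_index", "x_um", "y_um"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"animal {self.animal_id!r}: {name} length != time_s length"
                )
        if n and np.any(np.diff(self.time_s) <= 0):
            bad = int(np.argmax(np.diff(self.time_s) <= 0)) + 1
            raise ValidationError(
                f"animal {self.animal_id!r}: time_s not strictly increasing "
                f"at frame row {bad} (time {self.time_s[bad]:g} s)"
            )
        if n and np.any(np.diff(self.frame_index) <= 0):
            bad = int(np.argmax(np.diff(self.frame_index) <= 0)) + 1
            raise ValidationError(
                f"animal {self.animal_id!r}: frame_index not strictly increasing "
                f"at row {bad}"
            )
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        if self.skeleton_um is not None:
            if self.skeleton_um.ndim != 3 or self.skeleton_um.shape[2] != 2:
                raise ValidationError("skeleton_um must have shape (n_frames, k, 2)")
            if self.skeleton_um.shape[0] != n:
                raise ValidationError("skeleton frame count != trajectory frame count")
        if self.bend_deg is not None:
            if len(self.bend_deg) != n:
                raise ValidationError("bend_deg length != trajectory frame count")
            finite = self.bend_deg[np.isfinite(self.bend_deg)]
            if finite.size and (finite.min() < 0 or finite.max() > 180):
                raise ValidationError(
                    f"animal {self.animal_id!r}: bend_deg outside [0, 180]"
                )

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def n_skeleton_points(self) -> int | None:
        return None if self.skeleton_um is None else self.skeleton_um.shape[1]


@dataclasses.dataclass(frozen=True)
class IntervalFeature:
    """Mean speed and bending angle over one fixed-length averaging window."""

    animal_id: str
    interval_index: int
    t_start_s: float
    mean_speed_um_s: float
    mean_bend_deg: float  # NaN when no bending-angle source was available
    n_frames: int

    def __post_init__(self) -> None:
        if self.interval_index < 0:
            raise ValidationError("interval_index must be >= 0")
        if self.mean_speed_um_s < 0:
            raise ValidationError("mean_speed_um_s must be >= 0")
        if np.isfinite(self.mean_bend_deg) and not 0 <= self.mean_bend_deg <= 180:
            raise ValidationError("mean_bend_deg must lie in [0, 180]")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


@dataclasses.dataclass
class StateSequence:
    """Per-interval roaming/dwelling labels for one animal."""

    animal_id: str
    intervals: list[IntervalFeature]
    labels: list[str]  # ROAM / DWELL, parallel to intervals
    cutoff_um_s: float

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.intervals):
            raise ValidationError("labels length must equal interval count")
        bad = set(self.labels) - {ROAM, DWELL}
        if bad:
            raise ValidationError(f"unknown state labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclasses.dataclass(frozen=True)
class Bout:
    """A maximal same-state run that passed the minimum-duration filter."""

    animal_id: str
    state: str
    start_interval: int
    n_intervals: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.state not in (ROAM, DWELL):
            raise ValidationError(f"unknown state {self.state!r}")
        if self.n_intervals < 1:
            raise ValidationError("n_intervals must be >= 1")


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison summary (unpaired two-tailed t-test)."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_two_tailed: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_tailed <= 1:
            raise ValidationError("p-value must lie in [0, 1]")
        if self.df <= 0:
            raise ValidationError("df must be positive")

    @property
    def significance_marker(self) -> str:
        """Figure-legend style stars: * p<0.05, ** p<0.01, *** p<0.001,
        **** p<0.0001, 'ns' otherwise."""
        p = self.p_two_tailed
        for stars, thresh in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
            if p < thresh:
                return stars
        return "ns"


@dataclasses.dataclass(frozen=True)
class ExplorationResult:
    """Distinct grid squares crossed by one animal's track."""

    animal_id: str
    grid_mm: float
    occupied: frozenset[tuple[int, int]]  # (row, col) cells

    @property
    def squares_entered(self) -> int:
        return len(self.occupied)


@dataclasses.dataclass(frozen=True)
class NeuronROI:
    """Circular region of interest around one neuron's cell body."""

    neuron: str  # "ASI" or "ASJ"
    center_xy_px: tuple[int, int]
    radius_px: int

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValidationError("radius_px must be >= 1")


def as_label_array(labels: Sequence[str]) -> np.ndarray:
    """Labels as a boolean array, True where roaming."""
    return np.asarray([lab == ROAM for lab in labels], dtype=bool)
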
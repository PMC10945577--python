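"""Exploration-assay scoring: distinct grid squares crossed by a track.

The assay superimposes a square grid (3.5 mm cells by default) on the plate
and counts every cell the animal's track enters during the assay. Cells are
half-open: a point exactly on a boundary belongs to the higher-index cell,
so the cells partition the plane. Between consecutive frames the centroid is
assumed to move in a straight line (at 3.75 Hz the step is tiny relative to
a 3.5 mm cell), and every cell containing any point of that segment is
collected by splitting the segment at each gridline crossing.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .config import AnalysisConfig
from .errors import EmptyInputError
from .types import ExplorationResult, Trajectory


def _cell(x: float, y: float, g: float) -> tuple[int, int]:
    return (math.floor(y / g), math.floor(x / g))


def _segment_cells(
    x0: float, y0: float, x1: float, y1: float, g: float
) -> Iterable[tuple[int, int]]:
    """All grid cells containing at least one point of the closed segment.

    The segment is split at every axis-aligned gridline crossing; the cell of
    each open subsegment is read off its midpoint, which respects the
    half-open cell convention exactly (a subsegment lying on a gridline has
    its midpoint on the line and therefore lands in the higher cell, matching
    the convention for isolated points).
    """
    yield _cell(x0, y0, g)
    yield _cell(x1, y1, g)
    dx, dy = x1 - x0, y1 - y0
    if dx == 0 and dy == 0:
        return
    ts = [0.0, 1.0]
    for p0, d in ((x0, dx), (y0, dy)):
        if d == 0:
            continue
        lo, hi = sorted((p0, p0 + d))
        first = math.floor(lo / g) + 1
        last = math.ceil(hi / g) - 1
        for k in range(first, last + 1):
            t = (k * g - p0) / d
            if 0.0 < t < 1.0:
                ts.append(t)
    ts.sort()
    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (ta + tb)
        yield _cell(x0 + tm * dx, y0 + tm * dy, g)


def grid_squares_entered(
    traj: Trajectory,
    config: AnalysisConfig | None = None,
    *,
    origin_offset_um: tuple[float, float] = (0.0, 0.0),
) -> ExplorationResult:
    """Count the distinct grid cells a trajectory's track crosses.

    ``origin_offset_um`` shifts the grid origin, allowing sensitivity sweeps
    over grid placement (the physical grid's position on the plate is
    arbitrary).
    """
    config = config or AnalysisConfig()
    if traj.n_frames < 1:
        raise EmptyInputError(f"animal {traj.animal_id!r}: empty trajectory")
    g = config.grid_mm * 1000.0  # um
    ox, oy = origin_offset_um
    x = np.asarray(traj.x_um, float) - ox
    y = np.asarray(traj.y_um, float) - oy
    occupied: set[tuple[int, int]] = {_cell(float(x[0]), float(y[0]), g)}
    for i in range(len(x) - 1):
        occupied.update(
            _segment_cells(float(x[i]), float(y[i]), float(x[i + 1]), float(y[i + 1]), g)
        )
    return ExplorationResult(
        animal_id=traj.animal_id, grid_mm=config.grid_mm, occupied=frozenset(occupied)
    )
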
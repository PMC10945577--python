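"""Reading and writing the pipeline's file dialects.

The trajectory CSV dialect is defined here (the tracker vendors each export
their own layout): comma-separated UTF-8 with a header row and columns

    animal_id, frame, time_s, x_um, y_um

plus either a per-frame bending angle column ``bend_deg`` or skeleton columns
``skel_x0, skel_y0, ..., skel_xK, skel_yK`` (head to tail, K+1 >= 5 points).
A column-mapping dictionary adapts other exports without code changes.

Fluorescence value tables are CSVs with columns

    animal_id, genotype, condition, neuron, max_intensity_au

where ``neuron`` is ASI or ASJ and intensities are arbitrary units >= 0.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import EmptyInputError, FormatError, ValidationError
from .types import StateSequence, IntervalFeature, Trajectory

log = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ("animal_id", "frame", "time_s", "x_um", "y_um")
FLUORESCENCE_COLUMNS = (
    "animal_id",
    "genotype",
    "condition",
    "neuron",
    "max_intensity_au",
)
STATE_ANNOTATION_COLUMNS = (
    "animal_id",
    "interval_index",
    "t_start_s",
    "mean_speed_um_s",
    "mean_bend_deg",
    "label",
)

_SKEL_RE = re.compile(r"^skel_([xy])(\d+)$")


def _apply_column_map(
    df: pd.DataFrame, column_map: Mapping[str, str] | None
) -> pd.DataFrame:
    """Rename source columns to the canonical dialect (map: canonical -> source)."""
    if not column_map:
        return df
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise FormatError(f"column mapping refers to absent column(s): {missing}")
    return df.rename(columns={src: canon for canon, src in column_map.items()})


def _skeleton_columns(columns: Iterable[str]) -> list[tuple[str, str]]:
    """Paired (skel_xi, skel_yi) column names ordered by point index."""
    idx: dict[int, dict[str, str]] = {}
    for col in columns:
        m = _SKEL_RE.match(col)
        if m:
            idx.setdefault(int(m.group(2)), {})[m.group(1)] = col
    pairs = []
    for i in sorted(idx):
        if set(idx[i]) != {"x", "y"}:
            raise FormatError(f"skeleton point {i} missing one of skel_x{i}/skel_y{i}")
        pairs.append((idx[i]["x"], idx[i]["y"]))
    if pairs and sorted(idx) != list(range(len(pairs))):
        raise FormatError("skeleton point indices must be contiguous from 0")
    return pairs


def read_trajectory_table(
    path: str | Path,
    config: AnalysisConfig | None = None,
    *,
    frame_rate_hz: float = 3.75,
    column_map: Mapping[str, str] | None = None,
) -> list[Trajectory]:
    """Parse a trajectory CSV into one :class:`Trajectory` per animal.

    Frames are sorted by time within each animal, so row order in the file
    does not matter. Raises :class:`FormatError` for missing columns,
    :class:`ValidationError` for non-monotone time (naming the animal and
    row), and :class:`EmptyInputError` for a file without data rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    df = _apply_column_map(df, column_map)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    skel_pairs = _skeleton_columns(df.columns)
    if skel_pairs and len(skel_pairs) < 5:
        raise FormatError(
            f"{path}: skeleton present but only {len(skel_pairs)} points (need >= 5)"
        )
    has_bend = "bend_deg" in df.columns

    trajectories: list[Trajectory] = []
    for animal_id, group in df.groupby("animal_id", sort=True):
        group = group.sort_values("time_s", kind="mergesort")
        skeleton = None
        if skel_pairs:
            pts = np.stack(
                [group[[cx, cy]].to_numpy(float) for cx, cy in skel_pairs], axis=1
            )  # (n, k, 2)
            skeleton = pts
        traj = Trajectory(
            animal_id=str(animal_id),
            frame_index=group["frame"].to_numpy(int),
            time_s=group["time_s"].to_numpy(float),
            x_um=group["x_um"].to_numpy(float),
            y_um=group["y_um"].to_numpy(float),
            frame_rate_hz=frame_rate_hz,
            skeleton_um=skeleton,
            bend_deg=group["bend_deg"].to_numpy(float) if has_bend else None,
        )
        log.info("parsed animal %s: %d frames", traj.animal_id, traj.n_frames)
        trajectories.append(traj)
    return trajectories


def write_trajectory_table(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Write trajectories back out in the canonical CSV dialect."""
    if not trajectories:
        raise EmptyInputError("no trajectories to write")
    rows = []
    for traj in trajectories:
        rec: dict[str, np.ndarray | str] = {
            "animal_id": traj.animal_id,
            "frame": traj.frame_index,
            "time_s": traj.time_s,
            "x_um": traj.x_um,
            "y_um": traj.y_um,
        }
        if traj.bend_deg is not None:
            rec["bend_deg"] = traj.bend_deg
        frame = pd.DataFrame(rec)
        if traj.skeleton_um is not None:
            for i in range(traj.skeleton_um.shape[1]):
                frame[f"skel_x{i}"] = traj.skeleton_um[:, i, 0]
                frame[f"skel_y{i}"] = traj.skeleton_um[:, i, 1]
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_state_annotations(states: Sequence[StateSequence], path: str | Path) -> None:
    """Write per-interval features and labels as TSV.

    Columns: animal_id, interval_index, t_start_s, mean_speed_um_s,
    mean_bend_deg, label. Numeric fields use repr-precision floats so a
    read-back reproduces them exactly.
    """
    if not states:
        raise EmptyInputError("no state sequences to write")
    rows = []
    for seq in states:
        for iv, lab in zip(seq.intervals, seq.labels):
            rows.append(
                (
                    seq.animal_id,
                    iv.interval_index,
                    repr(float(iv.t_start_s)),
                    repr(float(iv.mean_speed_um_s)),
                    repr(float(iv.mean_bend_deg)),
                    lab,
                )
            )
    df = pd.DataFrame(rows, columns=STATE_ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_state_annotations(
    path: str | Path, cutoff_um_s: float = float("nan")
) -> list[StateSequence]:
    """Inverse of :func:`write_state_annotations` (labels and features only;
    the cutoff is not stored in the TSV and may be supplied by the caller)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STATE_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for animal_id, group in df.groupby("animal_id", sort=True):
        group = group.sort_values("interval_index", kind="mergesort")
        intervals = [
            IntervalFeature(
                animal_id=str(animal_id),
                interval_index=int(r.interval_index),
                t_start_s=float(r.t_start_s),
                mean_speed_um_s=float(r.mean_speed_um_s),
                mean_bend_deg=float(r.mean_bend_deg),
                n_frames=1,  # frame counts are not persisted in the TSV
            )
            for r in group.itertuples()
        ]
        out.append(
            StateSequence(
                animal_id=str(animal_id),
                intervals=intervals,
                labels=[str(lab) for lab in group["label"]],
                cutoff_um_s=cutoff_um_s,
            )
        )
    return out


def read_fluorescence_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a per-animal fluorescence value table.

    ``column_map`` (canonical name -> source column) adapts deposited layouts
    whose headers differ from the canonical dialect. Returns a DataFrame with
    the canonical columns; duplicate (animal_id, neuron, condition) rows or
    negative intensities raise :class:`ValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    df = _apply_column_map(df, column_map)
    missing = [c for c in FLUORESCENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    df = df.loc[:, list(FLUORESCENCE_COLUMNS)].copy()
    df["max_intensity_au"] = df["max_intensity_au"].astype(float)
    bad_neuron = set(df["neuron"]) - {"ASI", "ASJ"}
    if bad_neuron:
        raise ValidationError(f"{path}: unknown neuron value(s) {sorted(bad_neuron)}")
    if (df["max_intensity_au"] < 0).any():
        row = int(df.index[df["max_intensity_au"] < 0][0])
        raise ValidationError(f"{path}: negative intensity at data row {row}")
    dup = df.duplicated(subset=["animal_id", "neuron", "condition"], keep=False)
    if dup.any():
        key = df.loc[dup, ["animal_id", "neuron", "condition"]].iloc[0].tolist()
        raise ValidationError(f"{path}: duplicate (animal, neuron, condition) {key}")
    return df
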
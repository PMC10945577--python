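"""End-to-end pipeline commands behind the CLI.

Each command validates and computes everything in memory first and only then
writes its outputs, so a failing run leaves no partial files. Every run
writes a ``manifest.json`` recording the configuration snapshot, SHA-256
digests of the inputs, the package version, the seed and a timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .errors import RoamdwellError
from .exploration import grid_squares_entered
from .fluorescence import condition_ratio, group_summary
from .io import (
    read_fluorescence_table,
    read_state_annotations,
    read_trajectory_table,
    write_state_annotations,
    write_trajectory_table,
)
from .kinematics import interval_features
from .simulate import SimulationParams, simulate_cohort, simulate_fluorescence_table
from .states import (
    ROAM,
    classify_intervals,
    fraction_roaming,
    rout_filter,
    segment_bouts,
    select_speed_cutoff,
    ttest_unpaired,
)

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "animal_id",
    "n_intervals",
    "cutoff_um_s",
    "fraction_roaming",
    "n_roam_bouts",
    "n_dwell_bouts",
    "mean_roam_bout_s",
    "mean_dwell_bout_s",
    "outlier_flag",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    out_dir: Path,
    command: str,
    config: AnalysisConfig,
    inputs: Mapping[str, str | Path],
    outputs: list[str],
    seed: int | None,
) -> Path:
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
        },
        "outputs": outputs,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def run_simulate(
    out_dir: str | Path,
    params: SimulationParams,
    n_animals: int = 10,
    config: AnalysisConfig | None = None,
) -> dict[str, Path]:
    """Simulate a cohort; write the trajectory CSV and ground-truth labels."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    cohort = simulate_cohort(params, n_animals)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj_path = out_dir / "trajectories.csv"
    write_trajectory_table([t for t, _ in cohort], traj_path)
    truth_rows = [
        {"animal_id": t.animal_id, "interval_index": k, "label": lab}
        for t, gt in cohort
        for k, lab in enumerate(gt.labels)
    ]
    truth_path = out_dir / "truth_labels.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    outputs = {"trajectories": traj_path, "truth_labels": truth_path}
    _write_manifest(
        out_dir, "simulate", config, {}, [p.name for p in outputs.values()], params.seed
    )
    return outputs


def run_classify(
    trajectories: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    control_trajectories: str | Path | None = None,
) -> dict[str, Path]:
    """Classify roaming/dwelling for every animal in a trajectory CSV.

    The speed cutoff is placed from the control file's intervals when given,
    otherwise from the input cohort itself (self-control). Writes the state
    annotation TSV and the per-animal summary TSV (with ROUT outlier flags
    on the per-animal fraction-roaming values).
    """
    config = config or AnalysisConfig()
    trajectories = Path(trajectories)
    inputs: dict[str, Path] = {"trajectories": trajectories}
    trajs = read_trajectory_table(trajectories, config)
    per_animal = {t.animal_id: interval_features(t, config) for t in trajs}

    if control_trajectories is not None:
        control_trajectories = Path(control_trajectories)
        inputs["control_trajectories"] = control_trajectories
        control_trajs = read_trajectory_table(control_trajectories, config)
        control_ivs = [
            iv for t in control_trajs for iv in interval_features(t, config)
        ]
    else:
        control_ivs = [iv for ivs in per_animal.values() for iv in ivs]
    cutoff = select_speed_cutoff(control_ivs, config)

    sequences = []
    rows = []
    for animal_id, ivs in per_animal.items():
        if not ivs:
            log.warning("animal %s: no intervals; skipped", animal_id)
            continue
        seq = classify_intervals(ivs, cutoff, config)
        sequences.append(seq)
        bouts = segment_bouts(seq, config)
        roam_bouts = [b for b in bouts if b.state == ROAM]
        dwell_bouts = [b for b in bouts if b.state != ROAM]
        rows.append(
            {
                "animal_id": animal_id,
                "n_intervals": len(seq),
                "cutoff_um_s": cutoff,
                "fraction_roaming": fraction_roaming(seq),
                "n_roam_bouts": len(roam_bouts),
                "n_dwell_bouts": len(dwell_bouts),
                "mean_roam_bout_s": float(np.mean([b.duration_s for b in roam_bouts]))
                if roam_bouts
                else float("nan"),
                "mean_dwell_bout_s": float(np.mean([b.duration_s for b in dwell_bouts]))
                if dwell_bouts
                else float("nan"),
            }
        )
    summary = pd.DataFrame(rows)
    # flag outlier animals by ROUT on fraction roaming (needs n >= 3)
    if len(summary) >= 3:
        _, outliers = rout_filter(summary["fraction_roaming"].to_numpy(), config.rout_q)
        flagged = set()
        pool = list(outliers)
        for r in summary.itertuples():
            if r.fraction_roaming in pool:
                flagged.add(r.animal_id)
                pool.remove(r.fraction_roaming)
        summary["outlier_flag"] = summary["animal_id"].isin(flagged)
    else:
        summary["outlier_flag"] = False
    summary = summary[list(SUMMARY_COLUMNS)]

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann_path = out_dir / "state_annotations.tsv"
    write_state_annotations(sequences, ann_path)
    summary_path = out_dir / "per_animal_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.10g")
    outputs = {"state_annotations": ann_path, "per_animal_summary": summary_path}
    _write_manifest(
        out_dir, "classify", config, inputs, [p.name for p in outputs.values()],
        config.rng_seed,
    )
    return outputs


def run_bouts(
    state_annotations: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict[str, Path]:
    """Segment bouts from a state-annotation TSV and write a bout table."""
    config = config or AnalysisConfig()
    state_annotations = Path(state_annotations)
    sequences = read_state_annotations(state_annotations)
    rows = [
        dataclasses.asdict(b)
        for seq in sequences
        for b in segment_bouts(seq, config)
    ]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bout_path = out_dir / "bouts.tsv"
    pd.DataFrame(
        rows, columns=["animal_id", "state", "start_interval", "n_intervals", "duration_s"]
    ).to_csv(bout_path, sep="\t", index=False)
    _write_manifest(
        out_dir, "bouts", config, {"state_annotations": state_annotations},
        [bout_path.name], config.rng_seed,
    )
    return {"bouts": bout_path}


def run_explore(
    trajectories: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict[str, Path]:
    """Score the exploration assay for every animal in a trajectory CSV."""
    config = config or AnalysisConfig()
    trajectories = Path(trajectories)
    trajs = read_trajectory_table(trajectories, config)
    rows = []
    for t in trajs:
        res = grid_squares_entered(t, config)
        rows.append({"animal_id": t.animal_id, "squares_entered": res.squares_entered})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "exploration.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    _write_manifest(
        out_dir, "explore", config, {"trajectories": trajectories}, [path.name],
        config.rng_seed,
    )
    return {"exploration": path}


def run_fluor(
    table_path: str | Path,
    out_dir: str | Path,
    ratios: list[tuple[str, str, str, str]] | None = None,
    config: AnalysisConfig | None = None,
    column_map: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Summarise a fluorescence table and compute requested condition ratios.

    ``ratios`` is a list of (genotype, neuron, cond_num, cond_den) tuples.
    """
    config = config or AnalysisConfig()
    table_path = Path(table_path)
    table = read_fluorescence_table(table_path, column_map)
    summary = group_summary(table)
    ratio_records = []
    for genotype, neuron, cond_num, cond_den in ratios or []:
        res = condition_ratio(table, genotype, neuron, cond_num, cond_den)
        ratio_records.append(dataclasses.asdict(res))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_path = out_dir / "fluorescence_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.10g")
    ratio_path = out_dir / "condition_ratios.json"
    with open(ratio_path, "w") as fh:
        json.dump(ratio_records, fh, indent=2)
    _write_manifest(
        out_dir, "fluor", config, {"fluorescence": table_path},
        [summary_path.name, ratio_path.name], config.rng_seed,
    )
    return {"summary": summary_path, "ratios": ratio_path}


def run_report(
    summary_a: str | Path,
    summary_b: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    value_column: str = "fraction_roaming",
    apply_rout: bool = True,
) -> dict[str, Path]:
    """Compare a per-animal statistic between two cohorts.

    Reads two per-animal summary TSVs, optionally removes ROUT outliers
    within each cohort, runs the unpaired two-tailed t-test, and writes a
    JSON + TSV report with the figure-style significance marker.
    """
    config = config or AnalysisConfig()
    summary_a, summary_b = Path(summary_a), Path(summary_b)
    values = []
    for path in (summary_a, summary_b):
        df = pd.read_csv(path, sep="\t")
        if value_column not in df.columns:
            raise RoamdwellError(f"{path}: no column {value_column!r}")
        vals = df[value_column].to_numpy(float)
        n_out = 0
        if apply_rout and len(vals) >= 3:
            vals, outliers = rout_filter(vals, config.rout_q)
            n_out = len(outliers)
        values.append((vals, n_out))
    (a, out_a), (b, out_b) = values
    comparison = ttest_unpaired(a, b)
    record = {
        "value_column": value_column,
        "group_a": str(summary_a),
        "group_b": str(summary_b),
        "n_outliers_removed": [out_a, out_b],
        **dataclasses.asdict(comparison),
        "significance": comparison.significance_marker,
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "comparison.json"
    with open(json_path, "w") as fh:
        json.dump(record, fh, indent=2)
    tsv_path = out_dir / "comparison.tsv"
    pd.DataFrame([record]).to_csv(tsv_path, sep="\t", index=False)
    _write_manifest(
        out_dir, "report", config,
        {"summary_a": summary_a, "summary_b": summary_b},
        [json_path.name, tsv_path.name], config.rng_seed,
    )
    return {"comparison_json": json_path, "comparison_tsv": tsv_path}


def write_demo_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a small, complete demo dataset (trajectories + fluorescence)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = SimulationParams(duration_s=1800.0, seed=seed)
    outputs = run_simulate(out_dir, params, n_animals=6)
    table_wt, _ = simulate_fluorescence_table(
        15, {"Fed": 1.0, "Bottom": 8.1}, genotype="wild type", seed=seed + 1
    )
    table_gf, _ = simulate_fluorescence_table(
        15, {"Fed": 4.0, "Bottom": 6.8}, genotype="scd-2(gf)", seed=seed + 2
    )
    fluor_path = out_dir / "fluorescence.csv"
    pd.concat([table_wt, table_gf], ignore_index=True).to_csv(fluor_path, index=False)
    outputs["fluorescence"] = fluor_path
    return outputs
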
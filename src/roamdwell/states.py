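"""Roaming/dwelling classification, bout segmentation, and group statistics.

Each 10-s interval is a point on the speed-vs-bending-angle plane.
Classification draws a horizontal speed cutoff placed from the control
condition's speed distribution (the valley between the slow dwelling mode
and the fast roaming mode of a kernel density estimate), clipped into the
7-12 um/s band the assay operates in. Intervals strictly above the line are
roaming; at or below, dwelling. Bouts are maximal same-state runs strictly
longer than five intervals (>= 60 s at the 10-s resolution). Outlier animals
are removed with a univariate ROUT filter (robust median/RSDR residuals with
an FDR-style step-down test at level Q), and groups are compared with an
unpaired two-tailed t-test.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .config import AnalysisConfig
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)
from .types import DWELL, ROAM, Bout, GroupComparison, IntervalFeature, StateSequence

log = logging.getLogger(__name__)

#: Minimum number of control intervals for data-driven cutoff placement.
MIN_CONTROL_INTERVALS = 50


def select_speed_cutoff(
    control_intervals: Sequence[IntervalFeature],
    config: AnalysisConfig,
    *,
    grid_points: int = 2048,
) -> float:
    """Place the roaming speed cutoff from the control condition.

    Fits a Gaussian kernel density estimate to the control interval mean
    speeds and returns the location of the density minimum between the two
    highest modes, clipped into ``config.cutoff_bounds_um_s``. Falls back to
    the midpoint of the bounds when the density is unimodal or fewer than
    ``MIN_CONTROL_INTERVALS`` control intervals are available (logged).
    """
    if len(control_intervals) == 0:
        raise ConfigurationError("control interval set is empty")
    lo, hi = config.cutoff_bounds_um_s
    speeds = np.asarray([iv.mean_speed_um_s for iv in control_intervals], float)
    if len(speeds) < MIN_CONTROL_INTERVALS or np.ptp(speeds) == 0:
        log.info(
            "cutoff fallback: %d control intervals (< %d) -> midpoint %.3g",
            len(speeds),
            MIN_CONTROL_INTERVALS,
            config.cutoff_midpoint,
        )
        return config.cutoff_midpoint

    kde = stats.gaussian_kde(speeds)
    grid = np.linspace(0.0, float(speeds.max()) * 1.05, grid_points)
    density = kde(grid)
    peaks, _ = signal.find_peaks(density)
    if len(peaks) < 2:
        log.info("cutoff fallback: control speed density unimodal -> midpoint")
        return config.cutoff_midpoint
    top_two = peaks[np.argsort(density[peaks])[-2:]]
    left, right = int(top_two.min()), int(top_two.max())
    valley = left + int(np.argmin(density[left : right + 1]))
    cutoff = float(np.clip(grid[valley], lo, hi))
    log.info("speed cutoff placed at %.3g um/s (valley at %.3g)", cutoff, grid[valley])
    return cutoff


def classify_intervals(
    intervals: Sequence[IntervalFeature],
    cutoff_um_s: float,
    config: AnalysisConfig | None = None,
) -> StateSequence:
    """Label each interval ROAM iff its mean speed is strictly above the
    cutoff; ties go to DWELL (the line itself is not "above" it)."""
    config = config or AnalysisConfig()
    lo, hi = config.cutoff_bounds_um_s
    if not lo <= cutoff_um_s <= hi:
        raise ConfigurationError(
            f"cutoff {cutoff_um_s:g} outside configured bounds [{lo:g}, {hi:g}]"
        )
    if not intervals:
        raise InsufficientDataError("no intervals to classify")
    animal_id = intervals[0].animal_id
    labels = [
        ROAM if iv.mean_speed_um_s > cutoff_um_s else DWELL for iv in intervals
    ]
    return StateSequence(
        animal_id=animal_id,
        intervals=list(intervals),
        labels=labels,
        cutoff_um_s=float(cutoff_um_s),
    )


def fraction_roaming(seq: StateSequence) -> float:
    """Fraction of retained intervals labelled roaming."""
    if len(seq) == 0:
        raise InsufficientDataError(f"animal {seq.animal_id!r}: no labelled intervals")
    return sum(lab == ROAM for lab in seq.labels) / len(seq)


def segment_bouts(seq: StateSequence, config: AnalysisConfig | None = None) -> list[Bout]:
    """Maximal same-label runs at least ``min_bout_intervals`` long.

    Runs shorter than the threshold are discarded from bout statistics but
    still count toward the fraction of time roaming.
    """
    config = config or AnalysisConfig()
    bouts: list[Bout] = []
    labels = seq.labels
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        run = j - i
        if run >= config.min_bout_intervals:
            bouts.append(
                Bout(
                    animal_id=seq.animal_id,
                    state=labels[i],
                    start_interval=i,
                    n_intervals=run,
                    duration_s=run * config.interval_s,
                )
            )
        i = j
    return bouts


def rout_filter(
    values: Sequence[float], q: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Univariate ROUT outlier filter: (kept, outliers).

    The robust centre is the sample median and the robust scale (RSDR) is the
    68.27th percentile of the absolute residuals with an n/(n-1) small-sample
    correction. Candidates -- at most the 30% of points with the largest
    absolute residuals, scanned from the most extreme -- are tested with an
    FDR-style step-down rule: the candidate at rank i (1-based, largest
    residual first) is flagged when the two-tailed t probability (n-1 df) of
    its scaled residual falls below ``q * (n - i + 1) / n``. Every point up
    to the last flagged rank is removed.

    Returns the kept and outlier values as arrays; together they are a
    permutation of the input. A sample with all residuals zero passes
    through untouched.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if n < 3:
        raise InsufficientDataError(f"ROUT needs n >= 3, got {n}")
    if not 0 < q < 0.5:
        raise ParameterError(f"ROUT Q must lie in (0, 0.5), got {q}")

    resid = vals - np.median(vals)
    abs_resid = np.abs(resid)
    rsdr = float(np.percentile(abs_resid, 68.27)) * n / (n - 1)
    if rsdr == 0.0:
        if np.all(abs_resid == 0):
            return vals.copy(), np.array([], dtype=float)
        # median absolute residual mass at zero but extremes exist: use the
        # smallest positive residual as scale so extremes remain testable
        rsdr = float(abs_resid[abs_resid > 0].min())

    order = np.argsort(-abs_resid, kind="mergesort")  # most extreme first
    max_candidates = int(np.floor(0.3 * n))
    last_flagged = -1
    for rank0 in range(max_candidates):
        t = abs_resid[order[rank0]] / rsdr
        p_two = 2.0 * stats.t.sf(t, df=n - 1)
        threshold = q * (n - (rank0 + 1) + 1) / n
        if p_two < threshold:
            last_flagged = rank0
    if last_flagged < 0:
        return vals.copy(), np.array([], dtype=float)
    out_idx = order[: last_flagged + 1]
    mask = np.zeros(n, dtype=bool)
    mask[out_idx] = True
    return vals[~mask], vals[mask]


def ttest_unpaired(
    a: Sequence[float], b: Sequence[float], *, welch: bool = False
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups.

    Student's pooled-variance test by default (df = n_a + n_b - 2); Welch's
    unequal-variance form behind the ``welch`` flag. Two constant groups with
    equal means return t = 0, p = 1; constant groups with unequal means have
    no defined statistic and raise :class:`DegenerateDataError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if a.mean() == b.mean():
            return GroupComparison(
                n_a=len(a),
                n_b=len(b),
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                t_stat=0.0,
                df=float(len(a) + len(b) - 2),
                p_two_tailed=1.0,
            )
        raise DegenerateDataError(
            "both groups constant with unequal means: t statistic undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return GroupComparison(
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=float(res.statistic),
        df=df,
        p_two_tailed=float(res.pvalue),
    )


def estimate_transition_probs(
    seq: StateSequence,
) -> tuple[float | None, float | None]:
    """Per-interval transition probability estimates (p_dwell->roam,
    p_roam->dwell) from observed label transitions.

    A probability whose denominator is zero (the chain never visited that
    state before the final interval) is reported as ``None``.
    """
    if len(seq) < 2:
        raise InsufficientDataError("need >= 2 labels to estimate transitions")
    lab = np.asarray(seq.labels)
    cur, nxt = lab[:-1], lab[1:]
    n_d = int((cur == DWELL).sum())
    n_r = int((cur == ROAM).sum())
    p_dr = float(((cur == DWELL) & (nxt == ROAM)).sum() / n_d) if n_d else None
    p_rd = float(((cur == ROAM) & (nxt == DWELL)).sum() / n_r) if n_r else None
    return p_dr, p_rd
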
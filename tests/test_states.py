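"""Cutoff placement, classification, bouts, ROUT filtering, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from roamdwell import (
    AnalysisConfig,
    IntervalFeature,
    StateSequence,
    classify_intervals,
    estimate_transition_probs,
    fraction_roaming,
    rout_filter,
    segment_bouts,
    select_speed_cutoff,
    ttest_unpaired,
)
from roamdwell.errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from roamdwell.types import DWELL, ROAM


def make_intervals(speeds, animal_id="a1"):
    return [
        IntervalFeature(animal_id, k, 10.0 * k, float(s), float("nan"), 37)
        for k, s in enumerate(speeds)
    ]


def make_sequence(labels, animal_id="a1", cutoff=9.5):
    ivs = make_intervals([20.0 if lab == ROAM else 1.0 for lab in labels], animal_id)
    return StateSequence(animal_id, ivs, list(labels), cutoff)


def kde_valley_oracle(speeds, lo=0.0, hi=25.0, step=0.01):
    """Grid search for the density minimum between the two highest KDE modes."""
    kde = sps.gaussian_kde(speeds)
    grid = np.arange(lo, hi + step, step)
    dens = kde(grid)
    rising = np.diff(dens) > 0
    # local maxima: density rises then falls
    peaks = [i for i in range(1, len(dens) - 1) if dens[i - 1] < dens[i] >= dens[i + 1]]
    if len(peaks) < 2:
        return None
    top = sorted(sorted(peaks, key=lambda i: dens[i])[-2:])
    left, right = top
    return grid[left + int(np.argmin(dens[left : right + 1]))]


class TestSpeedCutoff:
    def test_well_separated_modes_cutoff_within_bounds(self, config, rng):
        speeds = np.concatenate(
            [rng.normal(2, 0.5, 200), rng.normal(20, 1.0, 200)]
        ).clip(0)
        cutoff = select_speed_cutoff(make_intervals(speeds), config)
        lo, hi = config.cutoff_bounds_um_s
        assert lo <= cutoff <= hi
        valley = kde_valley_oracle(speeds)
        assert valley is not None
        assert cutoff == pytest.approx(np.clip(valley, lo, hi), abs=0.05)

    def test_unimodal_control_falls_back_to_midpoint(self, config, rng):
        speeds = rng.normal(5, 1, 300).clip(0)
        assert select_speed_cutoff(make_intervals(speeds), config) == 9.5

    def test_valley_near_ten_found_inside_bounds(self, config, rng):
        speeds = np.concatenate(
            [rng.normal(6, 1.0, 300), rng.normal(14, 1.0, 300)]
        ).clip(0)
        cutoff = select_speed_cutoff(make_intervals(speeds), config)
        valley = kde_valley_oracle(speeds)
        assert cutoff == pytest.approx(np.clip(valley, 7, 12), abs=0.05)
        assert 8 <= cutoff <= 12

    def test_too_few_control_intervals_falls_back(self, config):
        cutoff = select_speed_cutoff(make_intervals([2.0] * 10 + [20.0] * 10), config)
        assert cutoff == config.cutoff_midpoint

    def test_empty_control_set_rejected(self, config):
        with pytest.raises(ConfigurationError):
            select_speed_cutoff([], config)


class TestClassification:
    @pytest.mark.parametrize(
        "speed,cutoff,expected",
        [(15.0, 10.0, ROAM), (10.0, 10.0, DWELL), (9.999, 10.0, DWELL)],
    )
    def test_strictly_above_is_roaming(self, speed, cutoff, expected):
        seq = classify_intervals(make_intervals([speed]), cutoff)
        assert seq.labels == [expected]

    def test_matches_elementwise_oracle(self, rng):
        speeds = rng.uniform(0, 30, 1000)
        cutoff = 9.5
        seq = classify_intervals(make_intervals(speeds), cutoff)
        expected = [ROAM if s > cutoff else DWELL for s in speeds]
        assert seq.labels == expected

    def test_raising_cutoff_never_increases_roaming(self, rng):
        speeds = rng.uniform(0, 30, 500)
        ivs = make_intervals(speeds)
        fractions = [
            fraction_roaming(classify_intervals(ivs, c)) for c in (7.0, 9.5, 12.0)
        ]
        assert fractions == sorted(fractions, reverse=True)

    def test_cutoff_outside_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_intervals(make_intervals([5.0]), 20.0)


class TestFractionRoaming:
    def test_half_roaming(self):
        assert fraction_roaming(make_sequence([ROAM, ROAM, DWELL, DWELL])) == 0.5

    def test_all_dwelling(self):
        assert fraction_roaming(make_sequence([DWELL] * 5)) == 0.0

    def test_matches_counting_oracle(self, rng):
        labels = [ROAM if b else DWELL for b in rng.random(360) < 0.4]
        seq = make_sequence(labels)
        assert fraction_roaming(seq) == labels.count(ROAM) / len(labels)

    def test_roam_plus_dwell_fractions_conserve_unity(self, rng):
        for _ in range(20):
            labels = [ROAM if b else DWELL for b in rng.random(50) < rng.random()]
            seq = make_sequence(labels)
            f_roam = fraction_roaming(seq)
            f_dwell = sum(l == DWELL for l in labels) / len(labels)
            assert f_roam + f_dwell == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(InsufficientDataError):
            fraction_roaming(make_sequence([]))


def rle_oracle(labels, min_run):
    """Brute-force run-length encoding bout oracle."""
    bouts = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        if j - i >= min_run:
            bouts.append((labels[i], i, j - i))
        i = j
    return bouts


class TestBoutSegmentation:
    def test_worked_example_two_roam_bouts(self, config):
        labels = [ROAM] * 7 + [DWELL] * 3 + [ROAM] * 6
        bouts = segment_bouts(make_sequence(labels), config)
        assert [(b.state, b.duration_s) for b in bouts] == [
            (ROAM, 70.0),
            (ROAM, 60.0),
        ]

    def test_five_interval_run_is_not_a_bout(self, config):
        assert segment_bouts(make_sequence([ROAM] * 5), config) == []

    def test_six_interval_dwell_is_a_bout(self, config):
        (bout,) = segment_bouts(make_sequence([DWELL] * 6), config)
        assert bout.state == DWELL and bout.duration_s == 60.0

    def test_matches_rle_oracle_on_random_sequences(self, config, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            labels = [ROAM if b else DWELL for b in rng.random(n) < 0.5]
            seq = make_sequence(labels)
            got = [(b.state, b.start_interval, b.n_intervals) for b in
                   segment_bouts(seq, config)]
            assert got == rle_oracle(labels, config.min_bout_intervals)

    def test_total_bout_time_bounded_by_observed_time(self, config, rng):
        labels = [ROAM if b else DWELL for b in rng.random(200) < 0.5]
        seq = make_sequence(labels)
        total = sum(b.duration_s for b in segment_bouts(seq, config))
        assert total <= len(labels) * config.interval_s


def rout_oracle(values, q):
    """Independent direct evaluation of the rank test."""
    vals = np.asarray(values, float)
    n = len(vals)
    resid = vals - np.median(vals)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0 and np.all(resid == 0):
        return set()
    order = sorted(range(n), key=lambda i: -abs(resid[i]))
    last = -1
    for i in range(int(np.floor(0.3 * n))):
        p = 2 * sps.t.sf(abs(resid[order[i]]) / rsdr, df=n - 1)
        if p < q * (n - (i + 1) + 1) / n:
            last = i
    return set(order[: last + 1])


class TestRoutFilter:
    def test_identical_values_pass_through(self):
        kept, out = rout_filter([4.0] * 10, 0.01)
        assert len(out) == 0 and len(kept) == 10

    def test_gross_outlier_among_normals_is_flagged(self, rng):
        vals = np.append(rng.standard_normal(49), 100.0)
        kept, out = rout_filter(vals, 0.01)
        assert 100.0 in out
        expected = rout_oracle(vals, 0.01)
        assert sorted(out) == sorted(vals[list(expected)])

    def test_partition_is_a_permutation_of_input(self, rng):
        vals = rng.standard_normal(40)
        kept, out = rout_filter(vals, 0.01)
        assert sorted(np.concatenate([kept, out])) == pytest.approx(sorted(vals))

    def test_n_below_three_rejected(self):
        with pytest.raises(InsufficientDataError):
            rout_filter([1.0, 2.0], 0.01)

    def test_false_positive_rate_controlled(self, rng):
        flagged = 0
        total = 0
        for _ in range(300):
            vals = rng.standard_normal(50)
            _, out = rout_filter(vals, 0.01)
            flagged += len(out)
            total += 50
        assert flagged / total <= 0.02

    def test_ten_sigma_point_always_caught(self, rng):
        caught = 0
        reps = 300
        for _ in range(reps):
            vals = np.append(rng.standard_normal(49), 10.0)
            _, out = rout_filter(vals, 0.01)
            caught += 10.0 in out
        assert caught / reps >= 0.99


class TestTTest:
    def test_identical_groups_give_null_result(self):
        res = ttest_unpaired([1, 2, 3], [1, 2, 3])
        assert res.t_stat == 0.0 and res.p_two_tailed == 1.0

    def test_closed_form_small_case(self):
        res = ttest_unpaired([1.0, 2.0], [3.0, 4.0])
        assert res.t_stat == pytest.approx(-2.828, abs=1e-3)
        assert res.df == 2

    def test_constant_equal_groups_give_p_one(self):
        res = ttest_unpaired([5.0, 5.0], [5.0, 5.0])
        assert res.t_stat == 0.0 and res.p_two_tailed == 1.0

    def test_constant_unequal_groups_rejected(self):
        with pytest.raises(DegenerateDataError):
            ttest_unpaired([5.0, 5.0], [7.0, 7.0])

    def test_matches_pooled_variance_closed_form(self, rng):
        """Cross-check against the explicit pooled-variance formula."""
        for _ in range(100):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 30))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), rng.integers(3, 30))
            res = ttest_unpaired(a, b)
            na, nb = len(a), len(b)
            sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
            p = 2 * sps.t.sf(abs(t), df=na + nb - 2)
            assert res.t_stat == pytest.approx(t, abs=1e-10)
            assert res.p_two_tailed == pytest.approx(p, abs=1e-10)
            assert res.df == na + nb - 2

    def test_significance_markers_follow_figure_convention(self):
        from roamdwell.types import GroupComparison

        cases = [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (5e-4, "***"), (5e-5, "****")]
        for p, stars in cases:
            gc = GroupComparison(3, 3, 0.0, 1.0, 2.0, 4.0, p)
            assert gc.significance_marker == stars


class TestTransitionEstimates:
    def test_counting_example(self):
        p_dr, p_rd = estimate_transition_probs(
            make_sequence([ROAM, ROAM, DWELL, DWELL, ROAM])
        )
        assert p_rd == pytest.approx(1 / 2)
        assert p_dr == pytest.approx(1 / 2)

    def test_absorbing_roam_has_undefined_dwell_exit(self):
        p_dr, p_rd = estimate_transition_probs(make_sequence([ROAM] * 6))
        assert p_rd == 0.0 and p_dr is None

    def test_recovers_generator_probabilities(self, rng):
        p_dr_true, p_rd_true = 0.1, 0.2
        state = DWELL
        labels = []
        for _ in range(10_000):
            labels.append(state)
            if state == DWELL:
                state = ROAM if rng.random() < p_dr_true else DWELL
            else:
                state = DWELL if rng.random() < p_rd_true else ROAM
        p_dr, p_rd = estimate_transition_probs(make_sequence(labels))
        assert p_dr == pytest.approx(p_dr_true, abs=0.02)
        assert p_rd == pytest.approx(p_rd_true, abs=0.02)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.sampled_from([ROAM, DWELL]), min_size=1, max_size=80))
def test_fraction_and_bouts_consistent_on_arbitrary_sequences(labels):
    """Conservation and bout-time bounds hold for any label sequence."""
    config = AnalysisConfig()
    seq = make_sequence(labels)
    f = fraction_roaming(seq)
    assert 0.0 <= f <= 1.0
    assert f + (1.0 - f) == 1.0
    bouts = segment_bouts(seq, config)
    assert sum(b.duration_s for b in bouts) <= len(labels) * config.interval_s
    got = [(b.state, b.start_interval, b.n_intervals) for b in bouts]
    assert got == rle_oracle(labels, config.min_bout_intervals)
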
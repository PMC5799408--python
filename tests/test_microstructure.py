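import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lickstruct import (
    ContractError,
    LickTrain,
    engagement_filter,
    segment_clusters,
    subject_means,
    summarize_session,
    sweep_thresholds,
)
from .conftest import random_train
from .oracles import naive_segment


def make_train(ts, **kw):
    return LickTrain(kw.pop("subject", "s"), kw.pop("day", 0),
                     kw.pop("conc", 4.0), tuple(ts), **kw)


class TestSegmentation:
    @pytest.mark.parametrize(
        "ts, threshold, sizes",
        [
            ((0.00, 0.10, 0.20, 0.60, 0.70), 0.25, [3, 2]),
            ((0.00, 0.25), 0.25, [1, 1]),          # "or longer": tie splits
            ((0.00,), 0.25, [1]),
            ((), 0.25, []),
            ((0.00, 0.10, 0.20), 10.0, [3]),       # threshold > span
        ],
    )
    def test_examples(self, ts, threshold, sizes):
        clusters = segment_clusters(make_train(ts), threshold)
        assert [c.size for c in clusters] == sizes

    def test_float_noise_at_boundary_counts_as_threshold(self):
        # 0.25 reached through arithmetic that lands a hair below on the grid
        ts = (0.0, 0.1 + 0.1 + 0.05)  # == 0.25000000000000006 in binary fp
        clusters = segment_clusters(make_train((0.0, round(ts[1], 2))), 0.25)
        assert [c.size for c in clusters] == [1, 1]

    def test_unsorted_rejected(self):
        t = make_train((0.0, 0.1))
        object.__setattr__(t, "timestamps", (0.1, 0.0))
        with pytest.raises(ContractError):
            segment_clusters(t)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ContractError):
            segment_clusters(make_train((0.0,)), 0.0)

    def test_min_cluster_size_option_drops_small_clusters(self):
        t = make_train((0.0, 0.1, 0.2, 1.0, 2.0, 2.1, 2.2))
        sizes = [c.size for c in segment_clusters(t, 0.25, min_cluster_size=3)]
        assert sizes == [3, 3]

    def test_partition_and_gap_properties_random_trains(self, rng):
        for _ in range(300):
            train = random_train(rng)
            ts = np.asarray(train.timestamps)
            clusters = segment_clusters(train, 0.25)
            # partition: concatenated members reproduce the train exactly
            member_ts = [t for c in clusters for t in ts[c.start_index:c.end_index + 1]]
            assert member_ts == pytest.approx(list(ts))
            # gap property at the boundaries
            for c in clusters:
                internal = np.round(np.diff(ts[c.start_index:c.end_index + 1]), 2)
                assert np.all(internal < 0.25)
            for left, right in zip(clusters, clusters[1:]):
                gap = round(ts[right.start_index] - ts[left.end_index], 2)
                assert gap >= 0.25

    def test_agrees_with_naive_oracle(self, rng):
        for _ in range(300):
            train = random_train(rng)
            ours = [[t for t in np.asarray(train.timestamps)[c.start_index:c.end_index + 1]]
                    for c in segment_clusters(train, 0.25)]
            theirs = naive_segment(train.timestamps, 0.25)
            assert [len(c) for c in ours] == [len(c) for c in theirs]
            flat_ours = [t for c in ours for t in c]
            flat_theirs = [t for c in theirs for t in c]
            assert flat_ours == pytest.approx(flat_theirs)


class TestSummaries:
    def test_arithmetic(self):
        s = summarize_session(make_train((0.0, 0.1, 0.2, 0.6, 0.7)), 0.25)
        assert s.total_licks == 5
        assert s.n_clusters == 2
        assert s.cluster_sizes == (3, 2)
        assert s.mean_cluster_size == 2.5

    def test_empty_session_flagged_not_error(self):
        s = summarize_session(make_train(()), 0.25)
        assert s.total_licks == 0
        assert s.mean_cluster_size is None

    def test_single_cluster_when_all_gaps_below_threshold(self):
        ts = tuple(np.round(np.arange(50) * 0.1, 2))
        s = summarize_session(make_train(ts), 0.25)
        assert s.n_clusters == 1 and s.mean_cluster_size == 50

    def test_summary_matches_cluster_objects(self, rng):
        # the fast summary path must equal sizes read off LickCluster objects
        for _ in range(100):
            train = random_train(rng)
            s = summarize_session(train, 0.25)
            assert list(s.cluster_sizes) == [
                c.size for c in segment_clusters(train, 0.25)
            ]


class TestEngagementFilter:
    def _summary(self, n):
        ts = tuple(np.round(np.arange(n) * 0.1, 2))
        return summarize_session(make_train(ts, session_duration=9000.0), 0.25)

    def test_strictly_more_than(self):
        kept, flagged = engagement_filter([self._summary(100), self._summary(101)])
        assert [s.total_licks for s in kept] == [101]
        assert flagged[0][0].total_licks == 100 and "100" in flagged[0][1]

    def test_min_zero_keeps_all_nonempty(self):
        kept, flagged = engagement_filter([self._summary(1)], min_licks=0)
        assert len(kept) == 1 and not flagged


class TestSubjectMeans:
    def _summaries(self, daily_means, subject="s1", conc=4.0):
        out = []
        for day, m in enumerate(daily_means):
            if m is None:
                ts = ()
            else:
                # m licks in one cluster, then a lone lick per extra cluster:
                # easiest is k clusters of equal size m
                ts = []
                t = 0.0
                for _ in range(3):  # 3 clusters of size m -> mean m
                    for _ in range(int(m)):
                        ts.append(round(t, 2))
                        t += 0.1
                    t += 1.0
                ts = tuple(ts)
            out.append(summarize_session(
                LickTrain(subject, day, conc, ts), 0.25))
        return out

    def test_mean_of_session_means(self):
        means = subject_means(self._summaries([2, 3, 4, 3, 3]))
        assert means.loc[0, "mean_cluster_size"] == pytest.approx(3.0)
        assert means.loc[0, "n_sessions"] == 5

    def test_flagged_day_excluded(self):
        means = subject_means(self._summaries([2, None, 4, 3, 3]))
        assert means.loc[0, "mean_cluster_size"] == pytest.approx(3.0)
        assert means.loc[0, "n_sessions"] == 4

    def test_single_session(self):
        means = subject_means(self._summaries([7]))
        assert means.loc[0, "mean_cluster_size"] == pytest.approx(7.0)


class TestSweep:
    def test_single_threshold_reproduces_summary(self, rng):
        train = random_train(rng, n_max=40)
        tab = sweep_thresholds([train], [0.25])
        s = summarize_session(train, 0.25)
        row = tab.iloc[0]
        assert row["total_licks"] == s.total_licks
        assert row["n_clusters"] == s.n_clusters
        if s.mean_cluster_size is None:
            assert np.isnan(row["mean_cluster_size"])
        else:
            assert row["mean_cluster_size"] == pytest.approx(s.mean_cluster_size)

    def test_monotonicity_in_threshold(self, rng):
        # splits can only disappear as the threshold grows
        grid = [0.1, 0.25, 0.5, 1.0, 5.0]
        for _ in range(100):
            train = random_train(rng)
            if train.n_licks == 0:
                continue
            tab = sweep_thresholds([train], grid).sort_values("threshold")
            assert tab["total_licks"].nunique() == 1
            assert (np.diff(tab["n_clusters"]) <= 0).all()
            assert (np.diff(tab["mean_cluster_size"]) >= -1e-12).all()

    def test_threshold_beyond_duration_single_cluster(self, rng):
        train = random_train(rng, n_max=30)
        if train.n_licks:
            tab = sweep_thresholds([train], [1800.0])
            assert tab["n_clusters"].iloc[0] == 1


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    gaps=st.lists(
        st.sampled_from([0.01, 0.1, 0.24, 0.25, 0.3, 1.0]), min_size=0, max_size=40
    )
)
def test_every_lick_in_exactly_one_cluster(gaps):
    ts = np.round(np.concatenate(([0.0], np.cumsum(gaps))), 2)
    train = LickTrain("h", 0, 4.0, tuple(ts.tolist()), session_duration=1e5)
    clusters = segment_clusters(train, 0.25)
    covered = [i for c in clusters for i in range(c.start_index, c.end_index + 1)]
    assert covered == list(range(len(ts)))
    assert sum(c.size for c in clusters) == len(ts)
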
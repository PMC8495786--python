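"""Probability smoothing, thresholding, eventization and review merging."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tinamou.detection import (
    Detection,
    ProbabilitySeries,
    VocalEvent,
    group_vocal_events,
    merge_review_labels,
    review_queue,
    smooth_probabilities,
    threshold_detections,
)
from tinamou.ingest import SurveyRecording


def _rec(name="r.wav"):
    return SurveyRecording(Path(name), "S00", "terra_firme", "d1", "AM", False,
                           "2019-07-15", 16_000, 30.0)


def _series(col, labels=("a", "b"), rec=None):
    """Two-class series whose first-class probability is `col`."""
    col = np.asarray(col, dtype=float)
    probs = np.stack([col, 1 - col], axis=1)
    starts = np.arange(len(col)) * 0.25
    return ProbabilitySeries(rec, starts, probs, tuple(labels))


class TestSmoothing:
    def test_interior_weighted_average(self):
        out = smooth_probabilities(_series([0.0, 1.0, 0.0]))
        assert out.probs[1, 0] == pytest.approx(0.5)

    def test_boundary_renormalized(self):
        out = smooth_probabilities(_series([0.0, 1.0]))
        assert out.probs[0, 0] == pytest.approx(1 / 3)
        assert out.probs[1, 0] == pytest.approx(2 / 3)

    def test_constant_series_fixed_point(self):
        out = smooth_probabilities(_series([0.3] * 5))
        assert np.allclose(out.probs, _series([0.3] * 5).probs)

    def test_row_sums_preserved_exactly(self, rng):
        p = rng.dirichlet(np.ones(12), size=40)
        series = ProbabilitySeries(None, np.arange(40) * 0.25, p, tuple(map(str, range(12))))
        out = smooth_probabilities(series)
        assert np.allclose(out.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_direct_convolution_oracle(self, rng):
        """Interior rows equal (p[t-1]/2 + p[t] + p[t+1]/2) / 2."""
        p = rng.dirichlet(np.ones(4), size=10)
        series = ProbabilitySeries(None, np.arange(10) * 0.25, p, ("a", "b", "c", "d"))
        out = smooth_probabilities(series)
        for t in range(1, 9):
            expect = (0.5 * p[t - 1] + 1.0 * p[t] + 0.5 * p[t + 1]) / 2.0
            assert np.allclose(out.probs[t], expect)


class TestThreshold:
    def test_boundary_values(self):
        series = _series([0.84, 0.85, 0.86])
        dets = threshold_detections(series, 0.85)
        assert [d.start_s for d in dets] == [0.25, 0.5]

    def test_one_hot_retained_with_label(self):
        dets = threshold_detections(_series([1.0]), 0.85)
        assert len(dets) == 1 and dets[0].label == "a" and dets[0].max_prob == 1.0

    def test_raising_threshold_never_adds_detections(self, rng):
        p = rng.dirichlet(np.full(3, 0.3), size=200)
        series = ProbabilitySeries(None, np.arange(200) * 0.25, p, ("a", "b", "c"))
        counts = [len(threshold_detections(series, th)) for th in (0.5, 0.7, 0.85, 0.95)]
        assert counts == sorted(counts, reverse=True)

    def test_argmax_tie_breaks_to_lowest_index(self, caplog):
        probs = np.array([[0.45, 0.45, 0.10]])
        series = ProbabilitySeries(None, [0.0], probs, ("a", "b", "c"))
        with caplog.at_level("WARNING", logger="tinamou.detection"):
            dets = threshold_detections(series, 0.4)
        assert dets[0].label == "a"
        assert any("tie" in r.message for r in caplog.records)


def _det(start, label="a", rec=None, status="unreviewed"):
    return Detection(rec, start, 2.0, label, 0.9, review_status=status)


class TestGrouping:
    def test_consecutive_run_single_event(self):
        rec = _rec()
        events = group_vocal_events([_det(s, rec=rec) for s in (0.0, 0.25, 0.5)])
        assert len(events) == 1
        assert events[0].start_s == 0.0 and events[0].end_s == 2.5
        assert events[0].n_windows == 3

    def test_half_second_gap_merges(self):
        rec = _rec()
        # run1 ends at 2.0; run2 starts 2.5 -> gap 0.5 < 0.75
        events = group_vocal_events([_det(0.0, rec=rec), _det(2.5, rec=rec)])
        assert len(events) == 1

    def test_exact_gap_stays_separate(self):
        rec = _rec()
        events = group_vocal_events([_det(0.0, rec=rec), _det(2.75, rec=rec)])
        assert len(events) == 2

    def test_species_never_merge(self):
        rec = _rec()
        dets = [_det(0.0, "a", rec), _det(0.25, "b", rec), _det(0.5, "a", rec)]
        events = group_vocal_events(dets)
        assert sorted((e.species, e.n_windows) for e in events) == [("a", 2), ("b", 1)]

    def test_junk_windows_never_form_events(self):
        rec = _rec()
        events = group_vocal_events([_det(0.0, "junk", rec), _det(5.0, "a", rec)])
        assert [e.species for e in events] == ["a"]

    def test_rejected_windows_excluded(self):
        rec = _rec()
        dets = [_det(0.0, rec=rec), _det(10.0, rec=rec, status="rejected")]
        events = group_vocal_events(dets)
        assert len(events) == 1 and events[0].start_s == 0.0

    def test_equals_transitive_closure_oracle(self, rng):
        """Sweep grouping equals union-find clustering of window intervals."""
        rec = _rec()
        for _ in range(300):
            n = int(rng.integers(1, 50))
            starts = np.sort(rng.uniform(0, 60, n))
            species = rng.choice(["a", "b"], n)
            dets = [_det(float(s), sp, rec) for s, sp in zip(starts, species)]
            events = group_vocal_events(dets, 0.75)
            # oracle: union-find on pairwise interval gap < 0.75 per species
            expected_total = 0
            for sp in ("a", "b"):
                ivals = [(d.start_s, d.end_s) for d in dets if d.label == sp]
                parent = list(range(len(ivals)))

                def find(i):
                    while parent[i] != i:
                        parent[i] = parent[parent[i]]
                        i = parent[i]
                    return i

                for i in range(len(ivals)):
                    for j in range(i + 1, len(ivals)):
                        gap = max(ivals[i][0], ivals[j][0]) - min(ivals[i][1], ivals[j][1])
                        if gap < 0.75:
                            parent[find(i)] = find(j)
                expected_total += len({find(i) for i in range(len(ivals))})
            assert len(events) == expected_total

    def test_events_partition_retained_windows(self, rng):
        rec = _rec()
        n = 80
        starts = np.sort(rng.uniform(0, 120, n))
        dets = [_det(float(s), "a", rec) for s in starts]
        events = group_vocal_events(dets)
        assert sum(e.n_windows for e in events) == n
        spans = sorted((e.start_s, e.end_s) for e in events)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1  # disjoint spans


class TestReviewMerging:
    def test_empty_review_leaves_unreviewed(self):
        rec = _rec()
        dets = [_det(0.0, rec=rec)]
        out = merge_review_labels(dets, pd.DataFrame(columns=["file", "start_s", "status"]))
        assert out[0].review_status == "unreviewed"

    def test_relabel_rebuilds_event_under_new_species(self):
        rec = _rec()
        dets = [_det(0.0, "a", rec)]
        review = pd.DataFrame([{"file": "r.wav", "start_s": 0.0, "status": "relabelled", "label": "b"}])
        merge_review_labels(dets, review)
        events = group_vocal_events(dets)
        assert events[0].species == "b"

    def test_unmatched_key_warned_and_skipped(self, caplog):
        rec = _rec()
        dets = [_det(0.0, rec=rec)]
        review = pd.DataFrame([{"file": "other.wav", "start_s": 9.0, "status": "confirmed"}])
        with caplog.at_level("WARNING", logger="tinamou.detection"):
            merge_review_labels(dets, review)
        assert dets[0].review_status == "unreviewed"
        assert any("matches no detection" in r.message for r in caplog.records)

    def test_grandfathered_windows_not_requeued(self):
        rec = _rec()
        dets = [_det(0.0, rec=rec), _det(5.0, rec=rec)]
        merge_review_labels(dets, pd.DataFrame(columns=["file", "start_s", "status"]),
                            grandfathered={("r.wav", 0.0)})
        queue = review_queue(dets)
        assert [d.start_s for d in queue] == [5.0]


def test_vocal_event_timestamp_from_session_clock():
    rec = _rec()
    ev = VocalEvent("a", rec, 30.0, 32.0, 1)
    assert ev.timestamp == pd.Timestamp("2019-07-15 05:00:30")
    assert ev.site_id == "S00" and ev.habitat == "terra_firme" and ev.session == "AM"
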
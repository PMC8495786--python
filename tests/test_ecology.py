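"""Survey-effort statistics: lumping, rates, costs, frequencies, eBird."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tinamou.ecology import (
    IndependentCapture,
    capture_rate,
    chi_square_compare,
    duration_kernel_sample,
    effort_and_cost,
    effort_table,
    filter_ebird_checklists,
    habitat_averaged_frequencies,
    lump_independent_captures,
)


class _Event:
    def __init__(self, species, site, ts, habitat="terra_firme"):
        self.species = species
        self.site_id = site
        self.habitat = habitat
        self.timestamp = pd.Timestamp(ts)


class TestLumping:
    def test_chained_events_become_one_capture(self):
        evs = [_Event("a", "S1", f"2019-07-15 0{h}:{m:02d}") for h, m in
               ((6, 0), (6, 30), (7, 15))]
        caps = lump_independent_captures(evs)
        assert len(caps) == 1
        assert caps[0].timestamp == pd.Timestamp("2019-07-15 06:00")
        assert caps[0].n_lumped_events == 3

    def test_exactly_one_hour_gap_splits(self):
        evs = [_Event("a", "S1", "2019-07-15 06:00"), _Event("a", "S1", "2019-07-15 07:00")]
        assert len(lump_independent_captures(evs)) == 2

    def test_sites_never_lumped_together(self):
        evs = [_Event("a", "S1", "2019-07-15 06:00"), _Event("a", "S2", "2019-07-15 06:00")]
        assert len(lump_independent_captures(evs)) == 2

    def test_species_never_lumped_together(self):
        evs = [_Event("a", "S1", "2019-07-15 06:00"), _Event("b", "S1", "2019-07-15 06:10")]
        assert len(lump_independent_captures(evs)) == 2

    def test_missing_timestamp_rejected(self):
        ev = _Event("a", "S1", "2019-07-15 06:00")
        ev.timestamp = None
        with pytest.raises(ValueError, match="timestamp"):
            lump_independent_captures([ev])

    def test_equals_chain_construction_oracle(self, rng):
        """Sweep chaining equals a brute-force chain builder."""
        for _ in range(300):
            n = int(rng.integers(1, 100))
            evs = [_Event(rng.choice(["a", "b"]), rng.choice(["S1", "S2"]),
                          pd.Timestamp("2019-07-15") + pd.Timedelta(minutes=float(m)))
                   for m in rng.uniform(0, 60 * 12, n)]
            got = len(lump_independent_captures(evs))
            # oracle: sort each (species, site) stream, count chain breaks
            expected = 0
            streams = {}
            for e in evs:
                streams.setdefault((e.species, e.site_id), []).append(e.timestamp)
            for ts in streams.values():
                ts.sort()
                expected += 1 + sum((b - a) >= pd.Timedelta(hours=1) for a, b in zip(ts, ts[1:]))
            assert got == expected


class TestCaptureRate:
    def test_zero_captures_zero_rate(self):
        assert capture_rate(0, 100.0) == 0.0

    def test_linear_in_captures_inverse_in_hours(self):
        base = capture_rate(10, 200.0)
        assert capture_rate(20, 200.0) == pytest.approx(2 * base)
        assert capture_rate(10, 400.0) == pytest.approx(base / 2)

    def test_zero_hours_rejected(self):
        with pytest.raises(ValueError):
            capture_rate(5, 0.0)

    def test_trap_day_convention(self):
        # 24 captures over 24 h = 1 trap-day -> 24,000 per 1,000 trap-days
        assert capture_rate(24, 24.0) == pytest.approx(24_000.0)


class TestEffortComparison:
    def test_equal_tables_give_unit_multipliers(self):
        t = effort_table({"a": 10, "b": 5}, 240.0, equipment_cost=1000.0)
        out = effort_and_cost(t, t)
        assert out["effort_multiplier"] == pytest.approx(1.0)
        assert out["cost_multiplier"] == pytest.approx(1.0)

    def test_totals_are_column_sums(self):
        t = effort_table({"a": 10, "b": 5}, 240.0, equipment_cost=1000.0)
        assert t.totals["captures"] == 15
        assert t.totals["capture_rate"] == pytest.approx(t.table["capture_rate"].sum())

    def test_no_shared_species_rejected(self):
        a = effort_table({"a": 1}, 24.0, equipment_cost=10.0)
        b = effort_table({"z": 1}, 24.0, equipment_cost=10.0)
        with pytest.raises(ValueError, match="shared"):
            effort_and_cost(a, b)

    def test_zero_rate_cost_flagged_nan(self, caplog):
        with caplog.at_level("WARNING", logger="tinamou.ecology"):
            t = effort_table({"a": 0}, 24.0, equipment_cost=10.0)
        assert np.isnan(t.table["cost_per_capture"].iloc[0])


class TestHabitatFrequencies:
    def _caps(self, spec_counts_by_hab):
        caps = []
        for hab, counts in spec_counts_by_hab.items():
            for sp, n in counts.items():
                caps += [IndependentCapture(sp, "S1", hab, pd.Timestamp("2019-07-15"), 1)] * n
        return caps

    def test_element_wise_mean_of_strata(self):
        caps = self._caps({"terra_firme": {"a": 2, "b": 8}, "floodplain": {"a": 6, "b": 4}})
        freq = habitat_averaged_frequencies(caps, species=["a", "b"])
        assert freq["a"] == pytest.approx(0.4)
        assert freq["b"] == pytest.approx(0.6)

    def test_identical_strata_unchanged(self):
        caps = self._caps({"terra_firme": {"a": 3, "b": 7}, "floodplain": {"a": 3, "b": 7}})
        freq = habitat_averaged_frequencies(caps, species=["a", "b"])
        assert freq["a"] == pytest.approx(0.3)

    def test_sums_to_one(self, rng):
        caps = self._caps({
            "terra_firme": {s: int(rng.integers(1, 20)) for s in "abcd"},
            "floodplain": {s: int(rng.integers(1, 20)) for s in "abcd"},
        })
        assert habitat_averaged_frequencies(caps).sum() == pytest.approx(1.0)

    def test_empty_stratum_named_in_error(self):
        df = pd.DataFrame({"species": ["a"], "habitat": ["terra_firme"]})
        df = pd.concat([df, pd.DataFrame({"species": [], "habitat": []})])
        freq = habitat_averaged_frequencies(df)  # single stratum is fine
        assert freq.sum() == pytest.approx(1.0)


class TestChiSquare:
    def test_identical_distributions_zero(self):
        stat, p = chi_square_compare([10, 20, 30], [1 / 6, 2 / 6, 3 / 6])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_worked_two_cell_case(self):
        stat, _ = chi_square_compare([10, 30], [0.5, 0.5])
        assert stat == pytest.approx(10.0)

    def test_permutation_invariant(self, rng):
        obs = rng.integers(5, 50, 6).astype(float)
        exp = rng.dirichlet(np.ones(6))
        s1, _ = chi_square_compare(obs, exp)
        perm = rng.permutation(6)
        s2, _ = chi_square_compare(obs[perm], exp[perm])
        assert s1 == pytest.approx(s2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_square_compare([0, 0], [0.5, 0.5])

    def test_matches_scipy_directly(self, rng):
        obs = rng.integers(5, 50, 5).astype(float)
        exp_p = rng.dirichlet(np.ones(5))
        stat, p = chi_square_compare(obs, exp_p)
        ref = stats.chisquare(obs, exp_p * obs.sum())
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestEbirdFiltering:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["protocol", "duration_min", "distance_km"])

    def test_boundary_rules(self):
        df = self._df([
            ("stationary", 160.0, np.nan),   # removed: >150 min
            ("stationary", 150.0, np.nan),   # kept: boundary inclusive
            ("traveling", 60.0, 0.4),        # kept
            ("traveling", 60.0, 0.5),        # kept: boundary inclusive
            ("traveling", 60.0, 0.6),        # removed
        ])
        out = filter_ebird_checklists(df)
        assert len(out) == 3

    def test_other_protocols_dropped_with_warning(self, caplog):
        df = self._df([("incidental", 30.0, np.nan), ("stationary", 30.0, np.nan)])
        with caplog.at_level("WARNING", logger="tinamou.ecology"):
            out = filter_ebird_checklists(df)
        assert list(out["protocol"]) == ["stationary"]
        assert any("unsupported protocols" in r.message for r in caplog.records)

    def test_malformed_rows_skipped_with_count(self, caplog):
        df = self._df([("stationary", np.nan, np.nan), ("traveling", 30.0, np.nan),
                       ("stationary", 30.0, np.nan)])
        with caplog.at_level("WARNING", logger="tinamou.ecology"):
            out = filter_ebird_checklists(df)
        assert len(out) == 1
        assert any("malformed" in r.message for r in caplog.records)


class TestDurationKernel:
    def _setup(self, rng, n_caps=60):
        sessions = pd.DataFrame([
            {"site_id": "S1", "habitat": "terra_firme",
             "start": pd.Timestamp("2019-07-15 05:00"), "duration_s": 9000.0},
            {"site_id": "S2", "habitat": "floodplain",
             "start": pd.Timestamp("2019-07-15 05:00"), "duration_s": 9000.0},
        ])
        caps = []
        for i in range(n_caps):
            site = "S1" if i % 2 == 0 else "S2"
            hab = "terra_firme" if i % 2 == 0 else "floodplain"
            sp = "a" if i % 3 else "b"
            ts = pd.Timestamp("2019-07-15 05:00") + pd.Timedelta(minutes=float(rng.uniform(0, 140)))
            caps.append(IndependentCapture(sp, site, hab, ts, 1))
        return sessions, caps

    def test_constant_durations_reproduced(self, rng):
        sessions, caps = self._setup(rng)
        checklists = pd.DataFrame({"protocol": ["stationary"] * 30,
                                   "duration_min": [45.0] * 30})
        freq = duration_kernel_sample(checklists, caps, sessions, 50, rng,
                                      species=["a", "b"], jitter_frac_iqr=0.0)
        assert freq.sum() == pytest.approx(1.0)

    def test_zero_capture_species_frequency_zero(self, rng):
        sessions, caps = self._setup(rng)
        checklists = pd.DataFrame({"protocol": ["stationary"] * 10, "duration_min": [60.0] * 10})
        freq = duration_kernel_sample(checklists, caps, sessions, 30, rng,
                                      species=["a", "b", "ghost"])
        assert freq["ghost"] == 0.0

    def test_sampled_lengths_follow_source_distribution(self, rng):
        """Bootstrap-with-jitter lengths are indistinguishable from source."""
        durations = rng.uniform(10, 150, 400)
        iqr = np.subtract(*np.percentile(durations, [75, 25]))
        samples = rng.choice(durations, 1000) + rng.normal(0, 0.05 * iqr, 1000)
        ks = stats.ks_2samp(durations, samples)
        assert ks.pvalue > 0.01


def test_published_style_workflow_composes(rng):
    """Lump -> rate -> effort comparison on a small synthetic capture set."""
    evs = []
    for i in range(40):
        evs.append(_Event("a" if i % 2 else "b", f"S{i % 4}",
                          pd.Timestamp("2019-07-15 05:00") + pd.Timedelta(hours=float(i) * 1.5)))
    caps = lump_independent_captures(evs)
    counts = {}
    for c in caps:
        counts[c.species] = counts.get(c.species, 0) + 1
    acoustic = effort_table(counts, 120.0, equipment_cost=2800.0)
    camera = effort_table(counts, 2400.0, equipment_cost=1260.8, method="camera")
    out = effort_and_cost(acoustic, camera)
    assert out["effort_multiplier"] == pytest.approx(20.0)  # hours ratio
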
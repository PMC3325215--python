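"""The 5'->3' coverage index, its filters, and the slope index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnoverseq import TranscriptModel, coverage_index, pair_and_filter, slope_index
from turnoverseq.coverage import CoverageProfile
from turnoverseq.index import (
    FLAG_LOW_COVERAGE,
    FLAG_NONSENSE,
    FLAG_OUTLIER_HIGH,
    FLAG_OUTLIER_LOW,
    IndexRecord,
    index_records,
)


def _profile_from_starts(starts, L, read_len=1, tid="T"):
    starts = np.asarray(starts, dtype=np.int64)
    return CoverageProfile.from_reads(
        tid, L, starts, np.full(starts.size, read_len, dtype=np.int64)
    )


class TestCoverageIndex:
    def test_uniform_starts_give_unit_index(self):
        prof = _profile_from_starts(np.arange(100), 100)
        rec = coverage_index(prof)
        assert rec.n5 == rec.n3 == 20
        assert rec.index == pytest.approx(1.0)

    def test_manual_enumeration_short_transcript(self):
        # L = 10, w = 2: starts {0, 1, 9} -> n5 = 2, n3 = 1
        prof = _profile_from_starts([0, 1, 9], 10)
        rec = coverage_index(prof)
        assert (rec.n5, rec.n3) == (2, 1)
        assert rec.index == pytest.approx(2.0)

    def test_zero_3prime_count_is_nonsense(self):
        prof = _profile_from_starts([0, 1, 2], 100)
        rec = coverage_index(prof)
        assert rec.index is None
        assert FLAG_NONSENSE in rec.flags

    def test_zero_window_width_rejected(self):
        prof = _profile_from_starts([0], 4)
        with pytest.raises(ValueError, match="window width 0"):
            coverage_index(prof)
        # index_records skips rather than propagating
        assert index_records({"T": prof}) == {}

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=20), min_size=10, max_size=80)
    )
    @settings(deadline=None, max_examples=60)
    def test_reversal_maps_index_to_reciprocal(self, counts):
        counts = np.array(counts, dtype=np.int64)
        L = counts.size
        starts = np.repeat(np.arange(L), counts)
        fwd = coverage_index(_profile_from_starts(starts, L))
        rev = coverage_index(_profile_from_starts(L - 1 - starts, L))
        if fwd.index is None:
            assert rev.index is None
        else:
            assert rev.index == pytest.approx(1.0 / fwd.index)

    @given(
        counts=st.lists(st.integers(min_value=0, max_value=9), min_size=10, max_size=60)
    )
    @settings(deadline=None, max_examples=60)
    def test_duplicating_reads_leaves_index_unchanged(self, counts):
        counts = np.array(counts, dtype=np.int64)
        starts = np.repeat(np.arange(counts.size), counts)
        one = coverage_index(_profile_from_starts(starts, counts.size))
        two = coverage_index(
            _profile_from_starts(np.concatenate([starts, starts]), counts.size)
        )
        if one.index is None:
            assert two.index is None
        else:
            assert two.index == pytest.approx(one.index)


def _record(tid, n5, n3, cov):
    index = None if (n5 == 0 or n3 == 0) else n5 / n3
    flags = {FLAG_NONSENSE} if index is None else set()
    return IndexRecord(tid, n5, n3, index, cov, flags)


TRANSCRIPTS = [TranscriptModel(f"G{i}", 100, "nuclear", "control", 1.0) for i in range(6)]


class TestPairAndFilter:
    def _table(self, wt, mut):
        return pair_and_filter(wt, mut, TRANSCRIPTS)

    def test_low_coverage_in_one_sample_fails_row(self):
        wt = {"G0": _record("G0", 10, 10, 0.4)}
        mut = {"G0": _record("G0", 10, 10, 0.9)}
        table = self._table(wt, mut)
        assert not table.loc[0, "pass"]
        assert FLAG_LOW_COVERAGE in table.loc[0, "flags_wt"]

    def test_outlier_bounds_are_inclusive(self):
        wt = {
            "G0": _record("G0", 100, 10, 0.9),   # exactly 10: removed
            "G1": _record("G1", 999, 100, 0.9),  # 9.99: kept
            "G2": _record("G2", 10, 100, 0.9),   # exactly 0.1: removed
            "G3": _record("G3", 11, 100, 0.9),   # 0.11: kept
        }
        mut = {k: _record(k, 50, 50, 0.9) for k in wt}
        table = self._table(wt, mut).set_index("transcript_id")
        assert not table.loc["G0", "pass"]
        assert FLAG_OUTLIER_HIGH in table.loc["G0", "flags_wt"]
        assert table.loc["G1", "pass"]
        assert not table.loc["G2", "pass"]
        assert FLAG_OUTLIER_LOW in table.loc["G2", "flags_wt"]
        assert table.loc["G3", "pass"]

    def test_nonsense_in_either_sample_fails(self):
        wt = {"G0": _record("G0", 5, 0, 0.9)}
        mut = {"G0": _record("G0", 5, 5, 0.9)}
        assert not self._table(wt, mut)["pass"].any()

    def test_empty_inputs_give_empty_table(self):
        assert self._table({}, {}).empty

    def test_mismatched_annotations_rejected(self):
        wt = {"G0": _record("G0", 5, 5, 0.9)}
        with pytest.raises(ValueError, match="different annotations"):
            self._table(wt, {})

    def test_filter_is_idempotent_on_passing_set(self):
        wt = {f"G{i}": _record(f"G{i}", 10 + i, 10, 0.9) for i in range(6)}
        mut = {f"G{i}": _record(f"G{i}", 10, 10 + i, 0.9) for i in range(6)}
        table = self._table(wt, mut)
        passing = set(table.loc[table["pass"], "transcript_id"])
        wt2 = {k: v for k, v in wt.items() if k in passing}
        mut2 = {k: v for k, v in mut.items() if k in passing}
        table2 = pair_and_filter(wt2, mut2, TRANSCRIPTS)
        assert table2["pass"].all()
        assert set(table2["transcript_id"]) == passing


class TestSlopeIndex:
    def test_uniform_depth_is_flat(self):
        prof = CoverageProfile.from_reads(
            "T", 50, np.arange(50), np.ones(50, dtype=np.int64)
        )
        assert slope_index(prof) == pytest.approx(0.0, abs=1e-12)

    def test_linear_decay_normalised_slope(self):
        # depth falls linearly from 2d at the 5' end to 0 at the 3' end
        L, d = 101, 6.0
        prof = CoverageProfile.from_reads("T", L, np.empty(0, int), np.empty(0, int))
        prof.depth = (2 * d * (1 - np.arange(L) / (L - 1)))
        prof.total_reads = 1
        assert slope_index(prof) == pytest.approx(-2.0)

    def test_single_covered_position_undefined(self):
        prof = CoverageProfile.from_reads("T", 50, np.array([3]), np.array([1]))
        assert slope_index(prof) is None

    def test_direction_agrees_with_coverage_index(self, small_experiment):
        # transcripts with decent depth: sign(index - 1) vs sign(-slope)
        profiles = small_experiment["profiles"]["wt"]
        agree = total = 0
        for tid, prof in profiles.items():
            if prof.total_reads < 200:
                continue
            rec = coverage_index(prof)
            slope = slope_index(prof)
            if rec.index is None or slope is None or rec.index == 1 or slope == 0:
                continue
            total += 1
            agree += (rec.index > 1) == (slope < 0)
        assert total >= 50
        assert agree / total >= 0.95

    def test_reversal_negates_slope(self):
        depth = np.array([5, 4, 4, 3, 2, 2, 1, 1, 0, 0], dtype=float)
        prof = CoverageProfile.from_reads("T", 10, np.empty(0, int), np.empty(0, int))
        prof.depth = depth
        prof.total_reads = 1
        rev = CoverageProfile.from_reads("T", 10, np.empty(0, int), np.empty(0, int))
        rev.depth = depth[::-1].copy()
        rev.total_reads = 1
        assert slope_index(rev) == pytest.approx(-slope_index(prof))
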
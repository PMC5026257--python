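"""Unit and property tests for the physical pileup track."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from poolte import ingest, ppileup
from conftest import aligned, brute_force_track, proper_pair, sig_pair

LENGTH = 400


class TestBuildTrack:
    def test_proper_pair_inner_span(self):
        pairs = {"s": [proper_pair("r0", 10, 50)]}
        track = ppileup.build_track(pairs, {"s": 100}, "chr1", LENGTH)
        # inner span is [anchor.end, mate.start) = [110, 160)
        assert track.absence[0, 109] == 0
        assert track.absence[0, 110] == 1
        assert track.absence[0, 159] == 1
        assert track.absence[0, 160] == 0

    def test_overlapping_mates_contribute_nothing(self):
        pairs = {"s": [proper_pair("r0", 10, -20)]}
        track = ppileup.build_track(pairs, {"s": 100}, "chr1", LENGTH)
        assert track.absence.sum() == 0

    def test_forward_signature_span(self):
        pairs = {"s": [sig_pair("r0", 10, "F")]}
        track = ppileup.build_track(pairs, {"s": 40}, "chr1", LENGTH)
        arr = track.presence[("roo", "F")]
        # smeared over [anchor.end, anchor.end + median) = [110, 150)
        assert arr[0, 109] == 0 and arr[0, 110] == 1
        assert arr[0, 149] == 1 and arr[0, 150] == 0

    def test_reverse_signature_span(self):
        pairs = {"s": [sig_pair("r0", 200, "R")]}
        track = ppileup.build_track(pairs, {"s": 40}, "chr1", LENGTH)
        arr = track.presence[("roo", "R")]
        # smeared over [anchor.start - median, anchor.start) = [160, 200)
        assert arr[0, 159] == 0 and arr[0, 160] == 1
        assert arr[0, 199] == 1 and arr[0, 200] == 0

    def test_spans_clipped_to_bounds(self):
        pairs = {"s": [sig_pair("r0", LENGTH - 120, "F"), sig_pair("r1", 5, "R")]}
        track = ppileup.build_track(pairs, {"s": 100}, "chr1", LENGTH)
        assert track.presence[("roo", "F")][0].sum() == 20  # [380, 400)
        assert track.presence[("roo", "R")][0].sum() == 5  # [0, 5)

    def test_matches_interval_stabbing_oracle(self):
        rng = np.random.default_rng(7)
        pairs_by_sample = {}
        median_id = {}
        for sid in ("s1", "s2"):
            pairs = []
            for i in range(200):
                kind = rng.integers(0, 3)
                start = int(rng.integers(-50, LENGTH + 50))
                if kind == 0:
                    pairs.append(proper_pair(f"{sid}r{i}", start, int(rng.integers(-10, 120))))
                else:
                    fam = ["roo", "jockey"][int(rng.integers(0, 2))]
                    direction = "FR"[int(rng.integers(0, 2))]
                    pairs.append(sig_pair(f"{sid}r{i}", start, direction, family=fam))
            pairs_by_sample[sid] = pairs
            median_id[sid] = int(rng.integers(1, 150))
        track = ppileup.build_track(pairs_by_sample, median_id, "chr1", LENGTH)
        absence, presence = brute_force_track(pairs_by_sample, median_id, LENGTH)
        np.testing.assert_array_equal(track.absence, absence)
        assert set(track.presence) <= set(presence) | set(track.presence)
        for key, arr in presence.items():
            if key in track.presence:
                np.testing.assert_array_equal(track.presence[key], arr)
            else:
                assert arr.sum() == 0

    def test_strand_votes_cover_presence_spans(self):
        pairs = {"s": [sig_pair("r0", 10, "F", te_strand="-")]}
        track = ppileup.build_track(pairs, {"s": 40}, "chr1", LENGTH)
        votes = track.strand_votes[("roo", "F")]
        # F anchor with TE mate on "-" votes for a "+" insertion
        assert votes[110:150, 0].tolist() == [1] * 40
        assert votes[:, 1].sum() == 0


class TestPpileupRoundTrip:
    def _random_track(self, seed):
        rng = np.random.default_rng(seed)
        pairs_by_sample = {}
        median_id = {}
        for sid in ("a", "b", "c"):
            pairs = []
            for i in range(60):
                start = int(rng.integers(0, LENGTH - 100))
                if rng.random() < 0.5:
                    pairs.append(proper_pair(f"{sid}{i}", start, int(rng.integers(0, 100))))
                else:
                    pairs.append(
                        sig_pair(
                            f"{sid}{i}",
                            start,
                            "FR"[int(rng.integers(0, 2))],
                            family=["roo", "jockey"][int(rng.integers(0, 2))],
                        )
                    )
            pairs_by_sample[sid] = pairs
            median_id[sid] = int(rng.integers(20, 120))
        return ppileup.build_track(pairs_by_sample, median_id, "chr1", LENGTH)

    def test_write_read_lossless(self):
        track = self._random_track(3)
        buf = io.StringIO()
        ppileup.write_ppileup(track, buf)
        buf.seek(0)
        back = ppileup.read_ppileup(buf)
        assert back.sample_ids == track.sample_ids
        assert back.median_inner_distance == track.median_inner_distance
        assert back.chromosome == track.chromosome
        assert back.origin == track.origin
        np.testing.assert_array_equal(back.absence, track.absence)
        np.testing.assert_array_equal(back.masked, track.masked)
        for key in track.presence:
            if track.presence[key].any():
                np.testing.assert_array_equal(back.presence[key], track.presence[key])

    def test_write_is_fixpoint(self):
        # write(read(write(track))) must produce identical bytes
        track = self._random_track(4)
        first = io.StringIO()
        ppileup.write_ppileup(track, first)
        first.seek(0)
        again = io.StringIO()
        ppileup.write_ppileup(ppileup.read_ppileup(first), again)
        assert first.getvalue() == again.getvalue()

    def test_masked_field_round_trip(self):
        track = self._random_track(5)
        track.masked[1, 100:200] = True
        track.absence[1, 100:200] = 0
        for arr in track.presence.values():
            arr[1, 100:200] = 0
        buf = io.StringIO()
        ppileup.write_ppileup(track, buf)
        assert "\t-\t" in buf.getvalue() or buf.getvalue().rstrip().endswith("-")
        buf.seek(0)
        back = ppileup.read_ppileup(buf)
        np.testing.assert_array_equal(back.masked, track.masked)

    def test_gzip_round_trip(self, tmp_path):
        track = self._random_track(6)
        path = tmp_path / "track.ppileup.gz"
        ppileup.write_ppileup(track, path)
        assert path.read_bytes()[:2] == b"\x1f\x8b"
        back = ppileup.read_ppileup(path)
        np.testing.assert_array_equal(back.absence, track.absence)

    def test_malformed_field_reports_line(self):
        text = "@MID s 100\nchr1\t1\tA:3\nchr1\t2\tBOGUS\n"
        with pytest.raises(ValueError, match="line 3"):
            ppileup.read_ppileup(io.StringIO(text))

    def test_non_contiguous_positions_rejected(self):
        text = "@MID s 100\nchr1\t1\tA:3\nchr1\t5\tA:3\n"
        with pytest.raises(ValueError, match="non-contiguous"):
            ppileup.read_ppileup(io.StringIO(text))

    def test_strand_votes_sidecar_round_trip(self):
        track = self._random_track(8)
        buf = io.StringIO()
        ppileup.write_strand_votes(track, buf)
        original = {k: v.copy() for k, v in track.strand_votes.items()}
        track.strand_votes = None
        buf.seek(0)
        votes = ppileup.read_strand_votes(buf, track)
        for key, arr in original.items():
            if arr.any():
                np.testing.assert_array_equal(votes[key], arr)


class TestColumnAccess:
    def test_column_set_column_round_trip(self):
        pairs = {"s": [proper_pair("r0", 10, 50), sig_pair("r1", 30, "F")]}
        track = ppileup.build_track(pairs, {"s": 40}, "chr1", LENGTH)
        col = track.column(140)  # inside both spans
        assert col.absence[0] == 1
        assert col.presence[0] == {("roo", "F"): 1}
        assert col.total(0) == 2
        track.set_column(140, col)
        again = track.column(140)
        assert again.absence == col.absence and again.presence == col.presence


@given(
    spans=st.lists(
        st.tuples(st.integers(0, LENGTH - 1), st.integers(1, 200)),
        min_size=1,
        max_size=30,
    )
)
def test_total_absence_mass_equals_clipped_span_lengths(spans):
    pairs = [
        proper_pair(f"r{i}", start - 100, inner)
        for i, (start, inner) in enumerate(spans)
    ]
    track = ppileup.build_track({"s": pairs}, {"s": 100}, "chr1", LENGTH)
    expected = sum(
        max(0, min(LENGTH, start + inner) - max(0, start)) for start, inner in spans
    )
    assert int(track.absence.sum()) == expected
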
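"""The physical pileup track: per-position, per-sample physical coverage.

In contrast to base coverage, which counts reads at a position, physical
coverage counts read *pairs* whose spanned region (between the mates)
covers the position.  The track splits it into absence coverage (inner
spans of proper pairs) and presence coverage per (TE family, signature
direction).  Because the true span of a discordant pair is unknown, the
sample's median inner distance of proper pairs is used as its length.

Coordinates are 0-based half-open internally and 1-based in the on-disk
text format.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .ingest import ClassifiedPair, PairClass

__all__ = [
    "PpileupColumn",
    "PpileupTrack",
    "build_track",
    "write_ppileup",
    "read_ppileup",
    "write_strand_votes",
    "read_strand_votes",
]

Key = tuple[str, str]  # (family, direction "F"|"R")


@dataclass
class PpileupColumn:
    """One genomic position of the track, across all samples."""

    absence: list[int]
    presence: list[dict[Key, int]]
    masked: list[bool]

    def total(self, sample: int) -> int:
        if self.masked[sample]:
            return 0
        return self.absence[sample] + sum(self.presence[sample].values())

    @property
    def n_samples(self) -> int:
        return len(self.absence)


@dataclass
class PpileupTrack:
    """Dense physical pileup for one chromosome.

    ``absence`` has shape (n_samples, n_columns); ``presence`` maps each
    (family, direction) to an array of the same shape.  ``origin`` is the
    1-based position of the first column.  ``strand_votes`` optionally
    carries, per (family, direction), an (n_columns, 2) array of
    insertion-strand votes (columns: +, -) pooled across samples; it is
    collected at build time from the TE-mapped mate orientations and is
    not part of the serialized ppileup format.
    """

    chromosome: str
    origin: int
    sample_ids: list[str]
    median_inner_distance: dict[str, int]
    absence: np.ndarray
    presence: dict[Key, np.ndarray]
    masked: np.ndarray  # bool, (n_samples, n_columns)
    strand_votes: dict[Key, np.ndarray] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_columns(self) -> int:
        return self.absence.shape[1]

    def totals(self) -> np.ndarray:
        """Total physical coverage per sample and position (masked -> 0)."""
        tot = self.absence.copy()
        for arr in self.presence.values():
            tot += arr
        tot[self.masked] = 0
        return tot

    def keys(self) -> list[Key]:
        return sorted(self.presence)

    def column(self, index: int) -> PpileupColumn:
        absence = [int(self.absence[s, index]) for s in range(self.n_samples)]
        presence = [
            {
                key: int(arr[s, index])
                for key, arr in sorted(self.presence.items())
                if arr[s, index]
            }
            for s in range(self.n_samples)
        ]
        masked = [bool(self.masked[s, index]) for s in range(self.n_samples)]
        return PpileupColumn(absence, presence, masked)

    def set_column(self, index: int, column: PpileupColumn) -> None:
        for s in range(self.n_samples):
            self.absence[s, index] = column.absence[s]
            self.masked[s, index] = column.masked[s]
            for key in self.presence:
                self.presence[key][s, index] = column.presence[s].get(key, 0)


def _presence_span(
    pair: ClassifiedPair, median_id: int, length: int
) -> tuple[int, int]:
    """Span of presence evidence for a discordant pair, clipped to bounds."""
    if pair.pair_class is PairClass.SIG_FORWARD:
        lo, hi = pair.anchor.end, pair.anchor.end + median_id
    else:
        lo, hi = pair.anchor.start - median_id, pair.anchor.start
    return max(0, lo), min(length, hi)


def build_track(
    pairs_by_sample: Mapping[str, Iterable[ClassifiedPair]],
    median_id: Mapping[str, int],
    chromosome: str,
    chromosome_length: int,
    collect_strand_votes: bool = True,
) -> PpileupTrack:
    """Accumulate classified pairs into a dense physical pileup track.

    A PROPER pair with inner span [a, b) (end of the upstream read to the
    start of the downstream read) increments absence coverage on [a, b);
    abutting or overlapping mates (b <= a) contribute nothing.  A forward
    signature whose anchor ends at e increments presence[(family, "F")] on
    [e, e + median_id); a reverse signature whose anchor starts at s
    increments presence[(family, "R")] on [s - median_id, s).  Spans are
    clipped to the chromosome bounds, never an error.
    """
    sample_ids = list(pairs_by_sample)
    length = int(chromosome_length)
    n = len(sample_ids)
    absence_diff = np.zeros((n, length + 1), dtype=np.int64)
    presence_diff: dict[Key, np.ndarray] = {}
    votes_diff: dict[Key, np.ndarray] = {}

    for s, sid in enumerate(sample_ids):
        mid = int(median_id[sid])
        if mid < 1:
            raise ValueError(f"sample {sid!r}: median inner distance must be >= 1")
        for pair in pairs_by_sample[sid]:
            cls = pair.pair_class
            if cls is PairClass.PROPER:
                a = max(0, pair.anchor.end)
                b = min(length, pair.mate.start)
                if b > a:
                    absence_diff[s, a] += 1
                    absence_diff[s, b] -= 1
            elif cls in (PairClass.SIG_FORWARD, PairClass.SIG_REVERSE):
                if not pair.family:
                    raise ValueError("signature pair without a family")
                direction = "F" if cls is PairClass.SIG_FORWARD else "R"
                key = (pair.family, direction)
                lo, hi = _presence_span(pair, mid, length)
                if hi <= lo:
                    continue
                if key not in presence_diff:
                    presence_diff[key] = np.zeros((n, length + 1), dtype=np.int64)
                    votes_diff[key] = np.zeros((length + 1, 2), dtype=np.int64)
                presence_diff[key][s, lo] += 1
                presence_diff[key][s, hi] -= 1
                if collect_strand_votes:
                    # F anchor(+) with TE-mate on "-" (and symmetrically R
                    # with mate on "+") votes for a + strand insertion.
                    plus = (pair.mate.strand == "-") == (direction == "F")
                    votes_diff[key][lo, 0 if plus else 1] += 1
                    votes_diff[key][hi, 0 if plus else 1] -= 1

    absence = np.cumsum(absence_diff[:, :-1], axis=1).astype(np.int32)
    presence = {
        key: np.cumsum(diff[:, :-1], axis=1).astype(np.int32)
        for key, diff in sorted(presence_diff.items())
    }
    votes = None
    if collect_strand_votes:
        votes = {
            key: np.cumsum(diff[:-1], axis=0).astype(np.int32)
            for key, diff in sorted(votes_diff.items())
        }
    return PpileupTrack(
        chromosome=chromosome,
        origin=1,
        sample_ids=sample_ids,
        median_inner_distance={sid: int(median_id[sid]) for sid in sample_ids},
        absence=absence,
        presence=presence,
        masked=np.zeros((n, length), dtype=bool),
        strand_votes=votes,
    )


# ---------------------------------------------------------------------------
# Serialization.  Header: one "@MID <sample_id> <int>" line per sample, in
# column order.  Data lines: "chr<TAB>pos<TAB>field..." with pos 1-based and
# one field per sample: "A:<absence>[;<family><dir>:<count>...]" with
# families sorted lexicographically; a masked sample field is "-".  Dense:
# zero-total columns are written so windows stay well defined.
# ---------------------------------------------------------------------------


def _format_field(track: PpileupTrack, s: int, i: int, keys: list[Key]) -> str:
    if track.masked[s, i]:
        return "-"
    parts = [f"A:{int(track.absence[s, i])}"]
    for fam, direction in keys:
        count = int(track.presence[(fam, direction)][s, i])
        if count:
            parts.append(f"{fam}{direction}:{count}")
    return ";".join(parts)


def _open_text(sink: str | Path | IO[str], mode: str) -> tuple[IO[str], bool]:
    if isinstance(sink, (str, Path)):
        path = str(sink)
        if path.endswith(".gz"):
            return gzip.open(path, mode + "t", encoding="utf-8"), True
        return open(path, mode, encoding="utf-8"), True
    return sink, False


def write_ppileup(track: PpileupTrack, sink: str | Path | IO[str]) -> None:
    handle, owned = _open_text(sink, "w")
    try:
        for sid in track.sample_ids:
            handle.write(f"@MID {sid} {track.median_inner_distance[sid]}\n")
        keys = track.keys()
        chrom = track.chromosome
        for i in range(track.n_columns):
            fields = "\t".join(
                _format_field(track, s, i, keys) for s in range(track.n_samples)
            )
            handle.write(f"{chrom}\t{track.origin + i}\t{fields}\n")
    finally:
        if owned:
            handle.close()


def _open_sniffed(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        raw = open(source, "rb")
        magic = raw.read(2)
        raw.seek(0)
        if magic == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.GzipFile(fileobj=raw)), True
        return io.TextIOWrapper(raw), True
    return source, False


def read_ppileup(source: str | Path | IO[str]) -> PpileupTrack:
    """Parse a ppileup file; ``read(write(track))`` preserves all counts."""
    handle, owned = _open_sniffed(source)
    try:
        sample_ids: list[str] = []
        median_id: dict[str, int] = {}
        chromosome: str | None = None
        origin: int | None = None
        absence_cols: list[list[int]] = []
        presence_cols: dict[Key, dict[tuple[int, int], int]] = {}
        masked_cols: list[list[bool]] = []
        n_cols = 0
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("@MID"):
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"line {lineno}: malformed @MID header")
                sample_ids.append(parts[1])
                median_id[parts[1]] = int(parts[2])
                continue
            parts = line.split("\t")
            if len(parts) != 2 + len(sample_ids):
                raise ValueError(
                    f"line {lineno}: expected {2 + len(sample_ids)} fields, "
                    f"got {len(parts)}"
                )
            chrom, pos_text = parts[0], parts[1]
            if chromosome is None:
                chromosome = chrom
            elif chrom != chromosome:
                raise ValueError(f"line {lineno}: multiple chromosomes in track")
            pos = int(pos_text)
            if origin is None:
                origin = pos
            elif pos != origin + n_cols:
                raise ValueError(f"line {lineno}: non-contiguous position {pos}")
            abs_row: list[int] = []
            mask_row: list[bool] = []
            for s, text in enumerate(parts[2:]):
                if text == "-":
                    abs_row.append(0)
                    mask_row.append(True)
                    continue
                mask_row.append(False)
                try:
                    chunks = text.split(";")
                    if not chunks[0].startswith("A:"):
                        raise ValueError
                    abs_row.append(int(chunks[0][2:]))
                    for chunk in chunks[1:]:
                        name, count_text = chunk.rsplit(":", 1)
                        key = (name[:-1], name[-1])
                        if key[1] not in ("F", "R"):
                            raise ValueError
                        presence_cols.setdefault(key, {})[(s, n_cols)] = int(
                            count_text
                        )
                except ValueError:
                    raise ValueError(
                        f"line {lineno}: malformed sample field {text!r}"
                    ) from None
            absence_cols.append(abs_row)
            masked_cols.append(mask_row)
            n_cols += 1
        if chromosome is None:
            chromosome = ""
        n = len(sample_ids)
        absence = (
            np.array(absence_cols, dtype=np.int32).T
            if n_cols
            else np.zeros((n, 0), dtype=np.int32)
        )
        masked = (
            np.array(masked_cols, dtype=bool).T
            if n_cols
            else np.zeros((n, 0), dtype=bool)
        )
        presence: dict[Key, np.ndarray] = {}
        for key, cells in sorted(presence_cols.items()):
            arr = np.zeros((n, n_cols), dtype=np.int32)
            for (s, i), count in cells.items():
                arr[s, i] = count
            presence[key] = arr
        return PpileupTrack(
            chromosome=chromosome,
            origin=origin if origin is not None else 1,
            sample_ids=sample_ids,
            median_inner_distance=median_id,
            absence=absence,
            presence=presence,
            masked=masked,
        )
    finally:
        if owned:
            handle.close()


def write_strand_votes(track: PpileupTrack, sink: str | Path | IO[str]) -> None:
    """Sidecar table of pooled insertion-strand votes (not in ppileup)."""
    if track.strand_votes is None:
        raise ValueError("track carries no strand votes")
    handle, owned = _open_text(sink, "w")
    try:
        handle.write("#chr\tpos\tfamily\tdir\tplus\tminus\n")
        for (fam, direction), arr in sorted(track.strand_votes.items()):
            nz = np.nonzero(arr.any(axis=1))[0]
            for i in nz:
                handle.write(
                    f"{track.chromosome}\t{track.origin + int(i)}\t{fam}\t"
                    f"{direction}\t{int(arr[i, 0])}\t{int(arr[i, 1])}\n"
                )
    finally:
        if owned:
            handle.close()


def read_strand_votes(
    source: str | Path | IO[str], track: PpileupTrack
) -> dict[Key, np.ndarray]:
    """Load a strand-vote sidecar and attach it to ``track``."""
    handle, owned = _open_sniffed(source)
    try:
        votes: dict[Key, np.ndarray] = {}
        for raw in handle:
            if raw.startswith("#") or not raw.strip():
                continue
            chrom, pos, fam, direction, plus, minus = raw.rstrip("\n").split("\t")
            key = (fam, direction)
            if key not in votes:
                votes[key] = np.zeros((track.n_columns, 2), dtype=np.int32)
            i = int(pos) - track.origin
            if 0 <= i < track.n_columns:
                votes[key][i, 0] = int(plus)
                votes[key][i, 1] = int(minus)
        track.strand_votes = votes
        return votes
    finally:
        if owned:
            handle.close()
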
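"""Alignment ingestion: TE hierarchy, mate-pair restoration and pair classification.

Reads are expected to have been mapped *independently* (single-end mode)
against a merged reference consisting of the TE-masked genome chromosomes
plus the TE consensus sequences.  Mate pairing is restored here from read
names.  Each restored pair is then classified as evidence for the absence
of a TE insertion (a proper, innie-oriented chromosome pair) or for its
presence (one read anchored on a chromosome, the mate on a TE sequence).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "TEHierarchy",
    "AlignedRead",
    "PairClass",
    "ClassifiedPair",
    "PairingStats",
    "parse_hierarchy",
    "read_alignments",
    "restore_pairs",
    "classify_pair",
    "median_inner_distance",
]

_MATE_SUFFIX = re.compile(r"[/_][12]$")


@dataclass(frozen=True)
class TEHierarchy:
    """Maps each TE reference-sequence ID to its family (and optional order).

    A reference name is considered a TE sequence iff it is a key of this
    mapping; every other reference name is treated as a genome chromosome.
    """

    entries: dict[str, tuple[str, str]]

    def is_te(self, reference: str) -> bool:
        return reference in self.entries

    def family_of(self, te_id: str) -> str:
        try:
            return self.entries[te_id][0]
        except KeyError:
            raise KeyError(f"reference {te_id!r} is not a known TE sequence") from None

    @property
    def families(self) -> list[str]:
        return sorted({fam for fam, _ in self.entries.values()})


def parse_hierarchy(source: str | Path | IO[str] | Iterable[str]) -> TEHierarchy:
    """Parse a tab-separated TE hierarchy: ``id<TAB>family[<TAB>order]``.

    Lines starting with ``#`` are comments.  Duplicate IDs and missing
    family fields are rejected.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return parse_hierarchy(handle)
    entries: dict[str, tuple[str, str]] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[1].strip():
            raise ValueError(f"line {lineno}: missing family field in {line!r}")
        te_id = parts[0].strip()
        family = parts[1].strip()
        order = parts[2].strip() if len(parts) > 2 else ""
        if te_id in entries:
            raise ValueError(f"duplicate TE sequence ID {te_id!r}")
        entries[te_id] = (family, order)
    return TEHierarchy(entries)


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """A single mapped read; ``read_id`` carries no mate suffix.

    Coordinates are 0-based half-open on the named reference sequence.
    """

    read_id: str
    reference: str
    start: int
    end: int
    strand: str  # "+" or "-"
    mapq: int
    sample_id: str = ""


class PairClass(Enum):
    PROPER = "PROPER"
    SIG_FORWARD = "SIG_FORWARD"
    SIG_REVERSE = "SIG_REVERSE"
    DISCARD = "DISCARD"


@dataclass(frozen=True, slots=True)
class ClassifiedPair:
    """A restored mate pair with its evidence class.

    For PROPER pairs ``anchor`` is the upstream (leftmost) read and
    ``mate`` the downstream one.  For signatures ``anchor`` is the
    chromosome-mapped read and ``mate`` the TE-mapped one; ``family`` is
    the hierarchy family of the mate's reference.
    """

    pair_class: PairClass
    anchor: AlignedRead
    mate: AlignedRead
    family: str = ""


def strip_mate_suffix(name: str) -> str:
    return _MATE_SUFFIX.sub("", name)


def read_alignments(
    path: str | Path,
    sample_id: str = "",
) -> Iterator[AlignedRead]:
    """Stream mapped primary alignments from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped (single best
    placement per mate is assumed by the pairing model).  Mate designators
    come from the SAM first/second-in-pair flags when present, otherwise
    from ``/1``, ``/2`` (or ``_1``, ``_2``) read-name suffixes; either way
    the emitted ``read_id`` is the bare template name.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield AlignedRead(
                read_id=strip_mate_suffix(rec.query_name),
                reference=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                sample_id=sample_id,
            )


@dataclass
class PairingStats:
    pairs: int = 0
    dropped_low_mapq: int = 0
    dropped_unpaired: int = 0


def restore_pairs(
    reads: Iterable[AlignedRead],
    min_mapq: int = 15,
    stats: PairingStats | None = None,
) -> list[tuple[AlignedRead, AlignedRead]]:
    """Rejoin independently mapped mates by read ID.

    One pair is emitted per read ID for which both mates are present with
    ``mapq >= min_mapq``; reads failing the threshold or lacking a mate are
    dropped (and counted in ``stats``).  Input order is irrelevant.  Three
    or more primary alignments sharing an ID are an error: secondary and
    supplementary records must be filtered upstream.
    """
    by_id: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in reads:
        group = by_id[read.read_id]
        group.append(read)
        if len(group) > 2:
            raise ValueError(
                f"read ID {read.read_id!r} has more than two primary alignments"
            )
    out: list[tuple[AlignedRead, AlignedRead]] = []
    if stats is None:
        stats = PairingStats()
    for group in by_id.values():
        if len(group) != 2:
            stats.dropped_unpaired += len(group)
            continue
        a, b = group
        if a.mapq < min_mapq or b.mapq < min_mapq:
            stats.dropped_low_mapq += 2
            continue
        out.append((a, b))
        stats.pairs += 1
    return out


def classify_pair(
    pair: tuple[AlignedRead, AlignedRead],
    hierarchy: TEHierarchy,
    max_fragment: int | None = None,
) -> ClassifiedPair:
    """Classify a restored mate pair as absence/presence evidence.

    Chromosome + chromosome, same chromosome, opposite strands in innie
    orientation -> PROPER.  Chromosome + TE -> SIG_FORWARD when the
    chromosome-mapped read is on the + strand (evidence extends rightwards
    towards the insertion), SIG_REVERSE when on the - strand.  Everything
    else (TE+TE, outie or same-strand chromosome pairs, cross-chromosome
    pairs) -> DISCARD.  Classification is total: every pair gets a class.
    """
    a, b = pair
    a_te = hierarchy.is_te(a.reference)
    b_te = hierarchy.is_te(b.reference)
    if a_te and b_te:
        return ClassifiedPair(PairClass.DISCARD, a, b)
    if a_te or b_te:
        anchor, mate = (b, a) if a_te else (a, b)
        family = hierarchy.family_of(mate.reference)
        cls = PairClass.SIG_FORWARD if anchor.strand == "+" else PairClass.SIG_REVERSE
        return ClassifiedPair(cls, anchor, mate, family)
    # chromosome + chromosome
    if a.reference != b.reference or a.strand == b.strand:
        return ClassifiedPair(PairClass.DISCARD, a, b)
    upstream, downstream = (a, b) if a.start <= b.start else (b, a)
    if upstream.strand != "+" or downstream.strand != "-":
        return ClassifiedPair(PairClass.DISCARD, a, b)  # outie orientation
    if max_fragment is not None and downstream.end - upstream.start > max_fragment:
        return ClassifiedPair(PairClass.DISCARD, a, b)
    return ClassifiedPair(PairClass.PROPER, upstream, downstream)


def median_inner_distance(proper_pairs: Iterable[ClassifiedPair]) -> int:
    """Median gap between the mates of proper pairs, for one sample.

    The inner distance of a pair is ``downstream.start - upstream.end``
    (fragment size minus twice the read length).  Negative distances from
    overlapping mates enter the median; the returned value is floored at 1
    so it can serve as a span length.  Even-length lists use the lower
    median, keeping the statistic an observed value and deterministic.
    """
    distances = sorted(
        p.mate.start - p.anchor.end
        for p in proper_pairs
        if p.pair_class is PairClass.PROPER
    )
    if not distances:
        raise ValueError("no proper pairs: cannot estimate the inner distance")
    med = distances[(len(distances) - 1) // 2]
    return max(1, med)
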
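"""Shared fixtures and helpers for the poolte test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from poolte import ingest, ppileup

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

READ_LENGTH = 100


@pytest.fixture
def hierarchy() -> ingest.TEHierarchy:
    return ingest.TEHierarchy(
        {
            "roo#1": ("roo", "LTR"),
            "roo#2": ("roo", "LTR"),
            "jockey#1": ("jockey", "LINE"),
        }
    )


def aligned(
    read_id: str,
    reference: str,
    start: int,
    strand: str = "+",
    mapq: int = 60,
    length: int = READ_LENGTH,
    sample_id: str = "",
) -> ingest.AlignedRead:
    return ingest.AlignedRead(
        read_id=read_id,
        reference=reference,
        start=start,
        end=start + length,
        strand=strand,
        mapq=mapq,
        sample_id=sample_id,
    )


def proper_pair(
    read_id: str,
    start: int,
    inner: int,
    chromosome: str = "chr1",
    length: int = READ_LENGTH,
) -> ingest.ClassifiedPair:
    """A PROPER pair whose inner span is [start+length, start+length+inner)."""
    a = aligned(read_id, chromosome, start, "+", length=length)
    b = aligned(read_id, chromosome, start + length + inner, "-", length=length)
    return ingest.ClassifiedPair(ingest.PairClass.PROPER, a, b)


def sig_pair(
    read_id: str,
    anchor_start: int,
    direction: str,
    family: str = "roo",
    te_ref: str = "roo#1",
    chromosome: str = "chr1",
    te_strand: str | None = None,
    length: int = READ_LENGTH,
) -> ingest.ClassifiedPair:
    """A discordant pair: chromosome anchor plus TE-mapped mate."""
    anchor_strand = "+" if direction == "F" else "-"
    if te_strand is None:
        te_strand = "-" if direction == "F" else "+"
    anchor = aligned(read_id, chromosome, anchor_start, anchor_strand, length=length)
    mate = aligned(read_id, te_ref, 0, te_strand, length=length)
    cls = (
        ingest.PairClass.SIG_FORWARD
        if direction == "F"
        else ingest.PairClass.SIG_REVERSE
    )
    return ingest.ClassifiedPair(cls, anchor, mate, family)


def locus_pairs(
    rng: np.random.Generator,
    frequency: float,
    physical_coverage: float = 100.0,
    pool_size: int = 100,
    inner_mean: float = 100.0,
    inner_sd: float = 20.0,
    length: int = 3000,
    insertion: int = 1500,
    family: str = "roo",
    te_ref: str = "roo#1",
) -> list[ingest.ClassifiedPair]:
    """Classified pairs around one insertion locus, drawn directly.

    Simulates a per-haplotype Poisson fragment process at the given pool
    physical coverage with a single insertion at ``insertion`` carried by
    ``round(frequency * pool_size)`` haplotypes, bypassing sequence-level
    simulation.  Junction-straddling reads are dropped as in the full
    simulator.
    """
    rl = READ_LENGTH
    lam = physical_coverage / (pool_size * inner_mean)  # fragments /bp /haplotype
    carriers = set(range(int(round(frequency * pool_size))))
    pairs: list[ingest.ClassifiedPair] = []
    rid = 0
    span = length + 4 * rl + 2 * inner_mean
    for h in range(pool_size):
        n_frag = rng.poisson(lam * span)
        starts = rng.uniform(-2 * rl - inner_mean, length + 2 * rl + inner_mean, n_frag)
        inners = np.maximum(np.rint(rng.normal(inner_mean, inner_sd, n_frag)), 0)
        for s, inner in zip(starts, inners):
            a_end = s + rl
            m_start = a_end + inner
            rid += 1
            carrier = h in carriers
            if carrier and a_end <= insertion < m_start:
                # fragment crosses the insertion point: discordant pair
                pairs.append(
                    ingest.ClassifiedPair(
                        ingest.PairClass.SIG_FORWARD,
                        aligned(f"l{rid}", "chr1", int(s), "+"),
                        aligned(f"l{rid}", te_ref, 0, "-"),
                        family,
                    )
                )
                continue
            if carrier and (
                s <= insertion < s + rl or m_start <= insertion < m_start + rl + 1
            ):
                continue  # junction read, dropped
            pairs.append(
                ingest.ClassifiedPair(
                    ingest.PairClass.PROPER,
                    aligned(f"l{rid}", "chr1", int(s), "+"),
                    aligned(f"l{rid}", "chr1", int(m_start), "-"),
                )
            )
    return pairs


def brute_force_track(
    pairs_by_sample: dict[str, list[ingest.ClassifiedPair]],
    median_id: dict[str, int],
    length: int,
) -> tuple[np.ndarray, dict]:
    """Interval-stabbing oracle for build_track (absence and presence)."""
    sids = list(pairs_by_sample)
    absence = np.zeros((len(sids), length), dtype=int)
    presence: dict[tuple[str, str], np.ndarray] = {}
    for s, sid in enumerate(sids):
        mid = median_id[sid]
        for pair in pairs_by_sample[sid]:
            if pair.pair_class is ingest.PairClass.PROPER:
                for pos in range(max(0, pair.anchor.end), min(length, pair.mate.start)):
                    absence[s, pos] += 1
            elif pair.pair_class is ingest.PairClass.SIG_FORWARD:
                key = (pair.family, "F")
                arr = presence.setdefault(key, np.zeros((len(sids), length), dtype=int))
                for pos in range(
                    max(0, pair.anchor.end), min(length, pair.anchor.end + mid)
                ):
                    arr[s, pos] += 1
            elif pair.pair_class is ingest.PairClass.SIG_REVERSE:
                key = (pair.family, "R")
                arr = presence.setdefault(key, np.zeros((len(sids), length), dtype=int))
                for pos in range(
                    max(0, pair.anchor.start - mid), min(length, pair.anchor.start)
                ):
                    arr[s, pos] += 1
    return absence, presence
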
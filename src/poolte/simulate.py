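"""Benchmark simulator: pooled populations with TE insertions.

Builds a pool of N haploid genomes from a random reference chromosome and
a set of random TE consensus sequences: each insertion gets a uniform
random site (subject to a minimum spacing), family, strand and population
frequency, and is carried by round(f*N) randomly chosen haplotypes.
Paired-end reads are drawn from the haplotypes with a configurable inner
distance distribution, per-base substitution errors and chimeric pairs
(mates from unrelated genomic positions).

Because every read carries its true provenance, alignments against the
merged reference (chromosome + TE consensus sequences) can be emitted
directly at the true projected coordinates, which replaces an external
aligner for desk-scale benchmarking; reads straddling an insertion
junction are dropped, mimicking unmappable junction reads.  FASTQ export
is available for running a real aligner outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from .ingest import AlignedRead

__all__ = [
    "SimConfig",
    "TruthRow",
    "Landscape",
    "HaplotypeLayout",
    "ReadPairs",
    "simulate_landscape",
    "simulate_reads",
    "emit_alignments",
    "pairs_for_physical_coverage",
    "write_truth",
    "read_truth",
    "write_fasta",
    "write_fastq",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G


@dataclass(frozen=True)
class SimConfig:
    """Benchmark configuration.

    Defaults reproduce the pooled-population benchmark conditions: a pool
    of N=100 genomes with 1,000 TE insertions at least 990 bp apart, with
    population frequencies uniform in [0.01, 1.0] on a ~3.3 Mb genome,
    2x100 bp reads with inner distance ~ N(100, 20), a 1% per-base error
    rate and 2% chimeric pairs.
    """

    pool_size: int = 100
    n_insertions: int = 1000
    min_spacing: int = 990
    freq_low: float = 0.01
    freq_high: float = 1.0
    genome_length: int = 3_300_000
    n_te_families: int = 5
    te_length_range: tuple[int, int] = (500, 5000)
    read_length: int = 100
    inner_mean: float = 100.0
    inner_sd: float = 20.0
    n_read_pairs: int = 6_580_000
    error_rate: float = 0.01
    chimera_rate: float = 0.02
    placement: str = "random"  # "uniform" | "random"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.freq_low <= self.freq_high <= 1):
            raise ValueError("need 0 < freq_low <= freq_high <= 1")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be >= 0")
        for name in (
            "pool_size",
            "n_insertions",
            "genome_length",
            "n_te_families",
            "read_length",
            "n_read_pairs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.placement not in ("uniform", "random"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if not (0 <= self.error_rate < 1 and 0 <= self.chimera_rate <= 1):
            raise ValueError("rates must lie in [0, 1)")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one simulated insertion.

    ``position`` is the 1-based coordinate of the last reference base
    before the insertion point.  ``frequency`` equals
    ``len(carriers) / pool_size`` exactly.
    """

    chromosome: str
    position: int
    family: str
    strand: str
    frequency: float
    carriers: tuple[int, ...]


@dataclass
class HaplotypeLayout:
    """Coordinate map of one haplotype: reference plus inserted TE copies.

    ``breakpoints`` (0-based, on the reference), ``families``, ``strands``
    and ``te_lengths`` describe the carried insertions in genomic order.
    ``boundaries`` interleaves the haplotype-coordinate start/end of every
    TE copy; even search intervals are reference segments, odd ones TE
    copies.  ``te_before`` holds the cumulative TE length upstream of each
    reference segment.
    """

    breakpoints: np.ndarray
    families: list[str]
    strands: list[str]
    te_lengths: np.ndarray
    boundaries: np.ndarray = field(init=False)
    te_before: np.ndarray = field(init=False)
    length: int = field(init=False)

    def __post_init__(self) -> None:
        cum = np.concatenate([[0], np.cumsum(self.te_lengths)])
        starts = self.breakpoints + cum[:-1]
        ends = self.breakpoints + cum[1:]
        self.boundaries = np.empty(2 * len(self.breakpoints), dtype=np.int64)
        self.boundaries[0::2] = starts
        self.boundaries[1::2] = ends
        self.te_before = cum
        self.length = 0  # set by Landscape (needs reference length)


@dataclass
class Landscape:
    chromosome: str
    reference: np.ndarray  # uint8 codes 0..3
    te_sequences: dict[str, np.ndarray]
    truth: list[TruthRow]
    haplotypes: list[HaplotypeLayout]

    @property
    def pool_size(self) -> int:
        return len(self.haplotypes)

    @property
    def haplotype_lengths(self) -> np.ndarray:
        return np.array([h.length for h in self.haplotypes], dtype=np.int64)

    @property
    def mean_haplotype_length(self) -> float:
        return float(self.haplotype_lengths.mean())

    def haplotype_sequence(self, index: int) -> np.ndarray:
        """Materialize the base sequence of one haplotype."""
        layout = self.haplotypes[index]
        chunks: list[np.ndarray] = []
        prev = 0
        for b, fam, strand in zip(
            layout.breakpoints, layout.families, layout.strands
        ):
            chunks.append(self.reference[prev:b])
            te = self.te_sequences[fam]
            chunks.append(te if strand == "+" else _COMPLEMENT[te[::-1]])
            prev = b
        chunks.append(self.reference[prev:])
        return np.concatenate(chunks) if chunks else self.reference.copy()


def _draw_sites(
    rng: np.random.Generator, n: int, length: int, spacing: int
) -> np.ndarray:
    margin = spacing
    slack = length - 2 * margin - (n - 1) * spacing
    if slack < 0:
        raise ValueError(
            f"cannot place {n} insertions at spacing {spacing} on a "
            f"{length} bp chromosome"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    return margin + offsets + np.arange(n) * spacing


def simulate_landscape(
    config: SimConfig,
    rng: np.random.Generator,
    reference: np.ndarray | None = None,
    te_sequences: dict[str, np.ndarray] | None = None,
    chromosome: str = "chr1",
) -> Landscape:
    """Draw insertion sites, families, strands, frequencies and carriers.

    ``reference`` and ``te_sequences`` may be supplied to place several
    simulated populations on a common reference (sample-specific
    insertions on shared coordinates).  Deterministic given the generator
    state.
    """
    config.validate()
    if reference is None:
        reference = rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
    if te_sequences is None:
        lo, hi = config.te_length_range
        te_sequences = {
            f"te{i + 1}": rng.integers(
                0, 4, size=int(rng.integers(lo, hi + 1)), dtype=np.uint8
            )
            for i in range(config.n_te_families)
        }
    family_names = sorted(te_sequences)
    sites = _draw_sites(
        rng, config.n_insertions, len(reference), config.min_spacing
    )
    families = [family_names[i] for i in rng.integers(0, len(family_names), sites.size)]
    strands = ["+" if b else "-" for b in rng.integers(0, 2, sites.size)]
    freqs = rng.uniform(config.freq_low, config.freq_high, sites.size)
    n_carriers = np.rint(freqs * config.pool_size).astype(int)

    carried: list[list[int]] = [[] for _ in range(config.pool_size)]
    truth: list[TruthRow] = []
    for j, (site, fam, strand) in enumerate(zip(sites, families, strands)):
        carriers = np.sort(rng.choice(config.pool_size, n_carriers[j], replace=False))
        for h in carriers:
            carried[h].append(j)
        truth.append(
            TruthRow(
                chromosome=chromosome,
                position=int(site),
                family=fam,
                strand=strand,
                frequency=n_carriers[j] / config.pool_size,
                carriers=tuple(int(c) for c in carriers),
            )
        )

    haplotypes: list[HaplotypeLayout] = []
    for h in range(config.pool_size):
        idx = carried[h]  # already in genomic order (sites are sorted)
        layout = HaplotypeLayout(
            breakpoints=sites[idx].astype(np.int64),
            families=[families[j] for j in idx],
            strands=[strands[j] for j in idx],
            te_lengths=np.array(
                [len(te_sequences[families[j]]) for j in idx], dtype=np.int64
            ),
        )
        layout.length = len(reference) + int(layout.te_lengths.sum())
        haplotypes.append(layout)
    return Landscape(chromosome, reference, dict(te_sequences), truth, haplotypes)


@dataclass
class ReadPairs:
    """Simulated read pairs in haplotype coordinates (mate axis = 1).

    Mate 0 is the left (forward) read of the fragment and mate 1 the
    right (reverse) one, except for chimeric pairs, whose mates are
    independent placements with random orientation.
    """

    hap: np.ndarray  # (n, 2) int32
    start: np.ndarray  # (n, 2) int64, haplotype coordinates
    reverse: np.ndarray  # (n, 2) bool
    inner: np.ndarray  # (n,) int32
    chimera: np.ndarray  # (n,) bool
    read_length: int

    @property
    def n_pairs(self) -> int:
        return self.hap.shape[0]


def simulate_reads(
    landscape: Landscape, config: SimConfig, rng: np.random.Generator
) -> ReadPairs:
    """Draw ``config.n_read_pairs`` pairs from the pool.

    Each pair picks a haplotype uniformly (placement="random") or the
    pairs are spread evenly over haplotypes and positions
    (placement="uniform"); the inner distance is drawn from
    N(inner_mean, inner_sd), rounded and floored at 0.  With probability
    ``chimera_rate`` both mates are re-drawn from independent unrelated
    positions.  Fragments that do not fit their haplotype are resampled.
    """
    config.validate()
    n = config.n_read_pairs
    rl = config.read_length
    lengths = landscape.haplotype_lengths
    if lengths.min() < 2 * rl:
        raise ValueError("haplotypes shorter than one read pair")
    inner = np.rint(rng.normal(config.inner_mean, config.inner_sd, n))
    inner = np.maximum(inner, 0).astype(np.int64)
    frag = 2 * rl + inner

    if config.placement == "uniform":
        hap = (np.arange(n) % landscape.pool_size).astype(np.int64)
        start = np.empty(n, dtype=np.int64)
        for h in range(landscape.pool_size):
            sel = np.nonzero(hap == h)[0]
            if sel.size == 0:
                continue
            grid = (np.arange(sel.size) * lengths[h]) // sel.size
            start[sel] = np.minimum(grid, lengths[h] - frag[sel])
    else:
        hap = rng.integers(0, landscape.pool_size, n)
        room = lengths[hap] - frag + 1
        bad = room <= 0
        while bad.any():  # fragment longer than haplotype: resample
            redraw = np.rint(
                rng.normal(config.inner_mean, config.inner_sd, int(bad.sum()))
            )
            inner[bad] = np.maximum(redraw, 0).astype(np.int64)
            frag = 2 * rl + inner
            room = lengths[hap] - frag + 1
            bad = room <= 0
        start = (rng.random(n) * room).astype(np.int64)
    start = np.maximum(start, 0)

    hap2 = np.stack([hap, hap], axis=1).astype(np.int32)
    start2 = np.stack([start, start + rl + inner], axis=1)
    reverse = np.zeros((n, 2), dtype=bool)
    reverse[:, 1] = True

    chimera = rng.random(n) < config.chimera_rate
    n_chim = int(chimera.sum())
    if n_chim:
        for mate in range(2):
            chap = rng.integers(0, landscape.pool_size, n_chim)
            cpos = (rng.random(n_chim) * (lengths[chap] - rl + 1)).astype(np.int64)
            hap2[chimera, mate] = chap
            start2[chimera, mate] = cpos
            reverse[chimera, mate] = rng.random(n_chim) < 0.5
    return ReadPairs(hap2, start2, reverse, inner.astype(np.int32), chimera, rl)


@dataclass
class EmitStats:
    emitted: int = 0
    dropped_junction: int = 0


def emit_alignments(
    reads: ReadPairs,
    landscape: Landscape,
    sample_id: str = "",
    mapq: int = 60,
    drop_junction: bool = True,
    stats: EmitStats | None = None,
) -> list[AlignedRead]:
    """Project reads onto the merged reference at their true coordinates.

    Mates fully inside a reference segment get chromosome coordinates;
    mates fully inside an inserted TE copy get coordinates on that
    family's consensus (with strand flipped for - insertions); mates
    straddling an insertion junction are dropped (they would not map).
    """
    rl = reads.read_length
    n = reads.n_pairs
    flat_hap = reads.hap.reshape(-1)
    flat_start = reads.start.reshape(-1)
    flat_rev = reads.reverse.reshape(-1)
    ref_name = np.empty(2 * n, dtype=object)
    out_pos = np.empty(2 * n, dtype=np.int64)
    out_rev = flat_rev.copy()
    keep = np.ones(2 * n, dtype=bool)

    for h in range(landscape.pool_size):
        sel = np.nonzero(flat_hap == h)[0]
        if sel.size == 0:
            continue
        layout = landscape.haplotypes[h]
        starts = flat_start[sel]
        if layout.boundaries.size == 0:
            ref_name[sel] = landscape.chromosome
            out_pos[sel] = starts
            continue
        i1 = np.searchsorted(layout.boundaries, starts, side="right")
        i2 = np.searchsorted(layout.boundaries, starts + rl - 1, side="right")
        straddle = i1 != i2
        keep[sel[straddle]] = not drop_junction
        in_ref = (i1 % 2) == 0
        ref_sel = sel[in_ref & ~straddle]
        ref_name[ref_sel] = landscape.chromosome
        out_pos[ref_sel] = flat_start[ref_sel] - layout.te_before[
            i1[in_ref & ~straddle] // 2
        ]
        te_mask = ~in_ref & ~straddle
        for k in np.nonzero(te_mask)[0]:
            j = (i1[k] - 1) // 2
            fam = layout.families[j]
            te_len = int(layout.te_lengths[j])
            offset = int(starts[k] - layout.boundaries[2 * j])
            idx = sel[k]
            ref_name[idx] = fam
            if layout.strands[j] == "+":
                out_pos[idx] = offset
            else:
                out_pos[idx] = te_len - offset - rl
                out_rev[idx] = not out_rev[idx]

    if stats is None:
        stats = EmitStats()
    alignments: list[AlignedRead] = []
    for flat_idx in np.nonzero(keep)[0]:
        pair = flat_idx // 2
        alignments.append(
            AlignedRead(
                read_id=f"r{pair}",
                reference=str(ref_name[flat_idx]),
                start=int(out_pos[flat_idx]),
                end=int(out_pos[flat_idx]) + rl,
                strand="-" if out_rev[flat_idx] else "+",
                mapq=mapq,
                sample_id=sample_id,
            )
        )
    stats.emitted = len(alignments)
    stats.dropped_junction = int(2 * n - keep.sum())
    return alignments


def pairs_for_physical_coverage(
    landscape: Landscape, inner_mean: float, physical_coverage: float
) -> int:
    """Pair count giving the requested pool physical coverage.

    The average physical coverage is n_pairs * mean inner span / mean
    haplotype length, since every pair contributes one span of roughly
    the mean inner distance somewhere in the pool.
    """
    return int(round(physical_coverage * landscape.mean_haplotype_length / inner_mean))


# ---------------------------------------------------------------------------
# Sequence materialization and file export.
# ---------------------------------------------------------------------------


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def _read_sequences(
    reads: ReadPairs,
    landscape: Landscape,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(2n, read_length) base-code matrix (as sequenced) and error mask."""
    rl = reads.read_length
    n = reads.n_pairs
    seqs = np.empty((2 * n, rl), dtype=np.uint8)
    cache: dict[int, np.ndarray] = {}
    flat_hap = reads.hap.reshape(-1)
    flat_start = reads.start.reshape(-1)
    flat_rev = reads.reverse.reshape(-1)
    for idx in range(2 * n):
        h = int(flat_hap[idx])
        if h not in cache:
            cache[h] = landscape.haplotype_sequence(h)
        s = int(flat_start[idx])
        chunk = cache[h][s : s + rl]
        seqs[idx] = _COMPLEMENT[chunk[::-1]] if flat_rev[idx] else chunk
    if error_rate > 0:
        mask = rng.random(seqs.shape) < error_rate
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        seqs[mask] = (seqs[mask] + shift) % 4
    else:
        mask = np.zeros(seqs.shape, dtype=bool)
    return seqs, mask


def write_fasta(landscape: Landscape, sink: str | Path | IO[str]) -> None:
    """Merged reference: masked-genome chromosome plus TE consensuses."""
    owned = isinstance(sink, (str, Path))
    handle = open(sink, "w", encoding="utf-8") if owned else sink
    try:
        handle.write(f">{landscape.chromosome}\n{_decode(landscape.reference)}\n")
        for fam in sorted(landscape.te_sequences):
            handle.write(f">{fam}\n{_decode(landscape.te_sequences[fam])}\n")
    finally:
        if owned:
            handle.close()


def write_fastq(
    reads: ReadPairs,
    landscape: Landscape,
    config: SimConfig,
    prefix: str | Path,
    rng: np.random.Generator,
) -> tuple[Path, Path]:
    """Two FASTQ files (mate 1 / mate 2) with substitution errors applied."""
    seqs, _ = _read_sequences(reads, landscape, config.error_rate, rng)
    qual = "I" * reads.read_length
    paths = (Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq"))
    for mate, path in enumerate(paths):
        with open(path, "w", encoding="utf-8") as handle:
            for pair in range(reads.n_pairs):
                seq = _decode(seqs[2 * pair + mate])
                handle.write(f"@r{pair}/{mate + 1}\n{seq}\n+\n{qual}\n")
    return paths


def write_sam(
    alignments: Sequence[AlignedRead],
    landscape: Landscape,
    path: str | Path,
) -> None:
    """Single-end SAM against the merged reference (sequences omitted)."""
    import pysam

    names = [landscape.chromosome] + sorted(landscape.te_sequences)
    lengths = [len(landscape.reference)] + [
        len(landscape.te_sequences[f]) for f in sorted(landscape.te_sequences)
    ]
    header = pysam.AlignmentHeader.from_references(names, lengths)
    ref_ids = {name: i for i, name in enumerate(names)}
    counter: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "w", header=header) as handle:
        for read in alignments:
            rec = pysam.AlignedSegment(header)
            mate = counter.get(read.read_id, 0) + 1
            counter[read.read_id] = mate
            rec.query_name = f"{read.read_id}/{mate}"
            rec.reference_id = ref_ids[read.reference]
            rec.reference_start = read.start
            rec.mapping_quality = read.mapq
            rec.flag = 16 if read.strand == "-" else 0
            rec.cigarstring = f"{read.end - read.start}M"
            handle.write(rec)


def write_truth(truth: Sequence[TruthRow], sink: str | Path | IO[str]) -> None:
    owned = isinstance(sink, (str, Path))
    handle = open(sink, "w", encoding="utf-8") if owned else sink
    try:
        handle.write("#chr\tpos\tfamily\tstrand\tfrequency\tcarriers\n")
        for row in truth:
            carriers = ",".join(str(c) for c in row.carriers)
            handle.write(
                f"{row.chromosome}\t{row.position}\t{row.family}\t{row.strand}"
                f"\t{row.frequency:.6f}\t{carriers}\n"
            )
    finally:
        if owned:
            handle.close()


def read_truth(source: str | Path | IO[str]) -> list[TruthRow]:
    owned = isinstance(source, (str, Path))
    handle = open(source, encoding="utf-8") if owned else source
    try:
        rows: list[TruthRow] = []
        for raw in handle:
            if raw.startswith("#") or not raw.strip():
                continue
            chrom, pos, fam, strand, freq, carriers = raw.rstrip("\n").split("\t")
            rows.append(
                TruthRow(
                    chromosome=chrom,
                    position=int(pos),
                    family=fam,
                    strand=strand,
                    frequency=float(freq),
                    carriers=tuple(int(c) for c in carriers.split(",") if c),
                )
            )
        return rows
    finally:
        if owned:
            handle.close()
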
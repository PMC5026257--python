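"""Unit and statistical tests for the benchmark simulator."""

import io
import math
from dataclasses import replace

import numpy as np
import pytest

from poolte import ingest, ppileup, simulate
from poolte.benchmark import classified_pairs_for_sample, run_pipeline

SMALL = simulate.SimConfig(
    n_insertions=50,
    genome_length=330_000,
    n_read_pairs=10_000,
    seed=1,
)


class TestSimulateLandscape:
    def test_minimum_spacing_respected(self):
        rng = np.random.default_rng(1)
        land = simulate.simulate_landscape(SMALL, rng)
        sites = np.array([row.position for row in land.truth])
        assert (np.diff(sites) >= SMALL.min_spacing).all()
        assert sites.min() >= SMALL.min_spacing
        assert sites.max() <= SMALL.genome_length - SMALL.min_spacing

    def test_deterministic_given_seed(self):
        a = simulate.simulate_landscape(SMALL, np.random.default_rng(5))
        b = simulate.simulate_landscape(SMALL, np.random.default_rng(5))
        assert a.truth == b.truth
        np.testing.assert_array_equal(a.reference, b.reference)

    def test_truth_frequency_exact(self):
        rng = np.random.default_rng(2)
        land = simulate.simulate_landscape(SMALL, rng)
        for row in land.truth:
            assert row.frequency == len(row.carriers) / SMALL.pool_size
            assert len(set(row.carriers)) == len(row.carriers)

    def test_fixed_frequency_one_carried_by_all(self):
        config = simulate.SimConfig(
            n_insertions=10,
            genome_length=100_000,
            freq_low=1.0,
            freq_high=1.0,
            n_read_pairs=1,
        )
        land = simulate.simulate_landscape(config, np.random.default_rng(3))
        for row in land.truth:
            assert row.carriers == tuple(range(config.pool_size))

    def test_too_many_insertions_is_error(self):
        config = simulate.SimConfig(
            n_insertions=1000, genome_length=10_000, n_read_pairs=1
        )
        with pytest.raises(ValueError, match="cannot place"):
            simulate.simulate_landscape(config, np.random.default_rng(0))

    def test_shared_reference_reused(self):
        rng = np.random.default_rng(4)
        ref = rng.integers(0, 4, size=330_000, dtype=np.uint8)
        tes = {"teA": rng.integers(0, 4, size=800, dtype=np.uint8)}
        land = simulate.simulate_landscape(
            SMALL, rng, reference=ref, te_sequences=tes
        )
        assert land.reference is ref
        assert set(land.te_sequences) == {"teA"}

    def test_haplotype_length_accounting(self):
        rng = np.random.default_rng(6)
        land = simulate.simulate_landscape(SMALL, rng)
        for h, layout in enumerate(land.haplotypes):
            assert layout.length == len(land.reference) + layout.te_lengths.sum()
            assert len(land.haplotype_sequence(h)) == layout.length


class TestSimulateReads:
    def test_inner_mean_within_3_se(self):
        rng = np.random.default_rng(7)
        land = simulate.simulate_landscape(SMALL, rng)
        config = simulate.SimConfig(
            n_insertions=50,
            genome_length=330_000,
            n_read_pairs=100_000,
            chimera_rate=0.0,
        )
        reads = simulate.simulate_reads(land, config, rng)
        se = config.inner_sd / math.sqrt(reads.n_pairs)
        # rounding to integers adds no bias; resampling truncation negligible
        assert abs(reads.inner.mean() - config.inner_mean) <= 3 * se + 0.5

    def test_chimera_fraction_within_3_se(self):
        rng = np.random.default_rng(8)
        land = simulate.simulate_landscape(SMALL, rng)
        config = simulate.SimConfig(
            n_insertions=50, genome_length=330_000, n_read_pairs=100_000
        )
        reads = simulate.simulate_reads(land, config, rng)
        p = config.chimera_rate
        se = math.sqrt(p * (1 - p) / reads.n_pairs)
        assert abs(reads.chimera.mean() - p) <= 3 * se

    def test_uniform_placement_is_even_grid(self):
        config = simulate.SimConfig(
            pool_size=1,
            n_insertions=1,
            min_spacing=10,
            freq_low=0.01,
            freq_high=0.01,
            genome_length=100_000,
            n_read_pairs=500,
            chimera_rate=0.0,
            placement="uniform",
        )
        rng = np.random.default_rng(9)
        land = simulate.simulate_landscape(config, rng)
        reads = simulate.simulate_reads(land, config, rng)
        starts = reads.start[:, 0]
        steps = np.diff(np.sort(starts))
        # an even grid up to integer division; the last position may be
        # clamped so the whole fragment fits the haplotype
        interior = steps[:-1]
        assert interior.min() >= interior.max() - 1

    def test_reads_fit_haplotypes(self):
        rng = np.random.default_rng(10)
        land = simulate.simulate_landscape(SMALL, rng)
        reads = simulate.simulate_reads(land, SMALL, rng)
        lengths = land.haplotype_lengths
        ends = reads.start + reads.read_length
        assert (reads.start >= 0).all()
        assert (ends <= lengths[reads.hap]).all()


def toy_landscape(strand="+"):
    """Reference of 1000 bp, one 200 bp TE inserted at 500 in haplotype 0."""
    rng = np.random.default_rng(0)
    reference = rng.integers(0, 4, size=1000, dtype=np.uint8)
    te = rng.integers(0, 4, size=200, dtype=np.uint8)
    layout = simulate.HaplotypeLayout(
        breakpoints=np.array([500], dtype=np.int64),
        families=["teA"],
        strands=[strand],
        te_lengths=np.array([200], dtype=np.int64),
    )
    layout.length = 1200
    truth = [
        simulate.TruthRow("chr1", 500, "teA", strand, 1.0, (0,)),
    ]
    return simulate.Landscape("chr1", reference, {"teA": te}, truth, [layout])


class TestEmitAlignments:
    def _reads(self, starts, read_length=100):
        n = len(starts)
        return simulate.ReadPairs(
            hap=np.zeros((n, 2), dtype=np.int32),
            start=np.array([[s, s] for s in starts], dtype=np.int64),
            reverse=np.tile([False, True], (n, 1)),
            inner=np.zeros(n, dtype=np.int32),
            chimera=np.zeros(n, dtype=bool),
            read_length=read_length,
        )

    def test_reference_segments_projected(self):
        land = toy_landscape()
        # upstream of the TE: unchanged; downstream: shifted left by 200
        reads = self._reads([100, 800])
        out = simulate.emit_alignments(reads, land)
        by_pos = sorted(a.start for a in out)
        assert by_pos == [100, 100, 600, 600]
        assert all(a.reference == "chr1" for a in out)

    def test_te_read_plus_strand(self):
        land = toy_landscape("+")
        out = simulate.emit_alignments(self._reads([550]), land)
        assert {(a.reference, a.start) for a in out} == {("teA", 50)}

    def test_te_read_minus_strand_flips(self):
        land = toy_landscape("-")
        out = simulate.emit_alignments(self._reads([550]), land)
        # offset 50 in a reversed 200 bp copy: 200 - 50 - 100 = 50 with
        # the strand inverted
        assert {(a.reference, a.start) for a in out} == {("teA", 50)}
        assert {a.strand for a in out} == {"-", "+"}

    def test_junction_reads_dropped(self):
        land = toy_landscape()
        stats = simulate.EmitStats()
        out = simulate.emit_alignments(self._reads([450]), land, stats=stats)
        assert out == []
        assert stats.dropped_junction == 2

    def test_mapq_and_sample_id_propagated(self):
        land = toy_landscape()
        out = simulate.emit_alignments(
            self._reads([100]), land, sample_id="pool", mapq=37
        )
        assert all(a.sample_id == "pool" and a.mapq == 37 for a in out)


class TestPhysicalCoverageAccounting:
    def test_track_coverage_matches_target_within_5_percent(self):
        target_pc = 50.0
        config = simulate.SimConfig(
            n_insertions=5,
            genome_length=50_000,
            error_rate=0.0,
            chimera_rate=0.0,
            n_read_pairs=1,
            seed=12,
        )
        rng = np.random.default_rng(12)
        land = simulate.simulate_landscape(config, rng)
        n_pairs = simulate.pairs_for_physical_coverage(
            land, config.inner_mean, target_pc
        )
        config = replace(config, n_read_pairs=n_pairs)
        reads = simulate.simulate_reads(land, config, rng)
        alignments = simulate.emit_alignments(reads, land, sample_id="s")
        hierarchy = ingest.TEHierarchy({f: (f, "") for f in land.te_sequences})
        classified = classified_pairs_for_sample(alignments, hierarchy)
        track, _, _ = run_pipeline({"s": classified}, "chr1", len(land.reference))
        mu_pc = float(track.totals()[0].mean())
        assert abs(mu_pc - target_pc) / target_pc <= 0.05


class TestTruthIO:
    def test_round_trip(self):
        rng = np.random.default_rng(13)
        land = simulate.simulate_landscape(SMALL, rng)
        buf = io.StringIO()
        simulate.write_truth(land.truth, buf)
        buf.seek(0)
        back = simulate.read_truth(buf)
        assert back == land.truth

    def test_fasta_export(self):
        land = toy_landscape()
        buf = io.StringIO()
        simulate.write_fasta(land, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == ">chr1" and len(lines[1]) == 1000
        assert lines[2] == ">teA" and len(lines[3]) == 200
        assert set(lines[1]) <= set("ACGT")
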
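# Methods

This note documents the statistical model behind `poolte`, the default
parameter choices, and the design of the benchmark harnesses, including the
reasoning behind the less obvious decisions.

## Physical coverage model

All evidence is counted in units of DNA *fragments* (read pairs), not
reads. At a genomic position:

- An **absence** fragment is a proper innie pair (opposite strands, same
  chromosome, forward mate upstream) whose *inner span* — the interval
  `[anchor.end, mate.start)` between the two mates — covers the position.
  Such a fragment was sequenced through the position without hitting a TE,
  so the haplotype it came from carries no insertion there.
- A **presence** fragment is a discordant pair with one mate anchored on
  the chromosome and the other mapping to a TE sequence. The insertion
  must lie downstream of a forward (`F`) anchor or upstream of a reverse
  (`R`) anchor, within roughly one inner distance; presence evidence is
  therefore smeared over `[anchor.end, anchor.end + m)` for `F` and
  `[anchor.start - m, anchor.start)` for `R`, where `m` is the sample's
  median inner distance (lower median over all proper pairs, floored at 1).

TE mates are aggregated by *family* through the hierarchy table, so
fragments hitting diverged copies of the same family pool their evidence.
Pairs that are TE–TE, outie, same-strand, or cross-chromosome are
discarded, as are pairs where either mate falls below the mapping-quality
threshold (default 15).

Both mates of a pooled sample are exchangeable draws from the pool, so the
fraction of fragments at a site that support the insertion estimates the
fraction of pool haplotypes carrying it:

```
f = te_cov / (te_cov + abs_cov)
```

## Signature windows and the estimation window size

The presence profile of an insertion is approximately triangular with
half-width `m`: a fragment whose anchor lies `d < m` bases from the
insertion contributes to positions between the anchor and the insertion.
Averaging `f` over a footprint-wide window therefore mixes the peak with
its flanks and *systematically underestimates* the frequency (empirically
by ~25% at `m = 100`). The default estimation window is deliberately
narrow — `max(10, m/10)` — and is placed at the maximum of the summed
presence signal within each candidate run, which keeps the estimator
nearly unbiased (mean absolute error ~0.03 at 100× physical coverage)
while still averaging out column noise. Windows containing masked columns
are never used for estimation.

## Candidate triggers: counts versus subsampling-proportional means

Two different questions are asked of the presence signal, and they need
different statistics:

- **Detection sensitivity** is about *how many distinct fragments* support
  an insertion. The default trigger (`trigger="max"`) flags a window when
  its best column holds at least `min_count` presence fragments — a count
  statistic. With it, insertions supported by as few as two fragments are
  found, and the single-population benchmarks recover ≥99% of insertions.
- **Cross-sample abundance comparison** needs a statistic that responds
  *proportionally* to per-position coverage subsampling, because
  homogenization works precisely by thinning per-position counts. A
  max-type count survives thinning almost unchanged (some column keeps a
  fragment), which would let the higher-coverage sample keep its detection
  advantage. The `trigger_window` option therefore switches the candidate
  statistic to the mean presence over a footprint-scale window (`m` by
  default in the benchmark harness), computed over unmasked columns. This
  halves and quarters cleanly under 2× and 4× thinning, so after
  homogenization all samples sit at the same operating point.

The abundance benchmark uses the footprint trigger; the single-population
benchmarks keep the count trigger (the footprint mean of a
two-fragment signal is below threshold for rare insertions, costing
sensitivity where none needs to be traded away).

## Coverage homogenization

`subsample` reduces every sample's physical coverage at every position to
a common target: positions below target are masked (jointly across all
samples by default — a position unusable in one sample is unusable for
comparison everywhere), positions above target draw the retained fragments
without replacement from the position's categories (absence plus each
(family, direction)) via a multivariate hypergeometric draw. Each position
uses an independent generator keyed by `(seed, position)`, so results are
reproducible and independent of traversal order or chunking.

## Pairing signatures into calls

Forward and reverse signatures of the same family are joined greedily,
nearest anchors first, each signature used at most once; the call position
is the rounded mean of the two anchors and per-sample frequencies are
averaged (a defined estimate wins over an undefined one). Because both
signature windows center on the insertion, the reverse anchor typically
lands slightly *upstream* of the forward anchor; candidate pairs are
therefore accepted when the reverse anchor is at most `overlap_allowance`
upstream (the pipeline passes the median inner distance; the CLI default
is one window size). The join radius default is `3m + 2·read_length`,
covering both footprints plus slack. Insertion strand is a majority vote
over TE-mate orientations: an `F` anchor whose TE mate maps to the minus
strand of the consensus (or an `R` anchor with a plus-strand mate) votes
for a plus-strand insertion; ties give ".".

## Chimeric pairs and the fragment cap

Chimeric pairs whose mates happen to land in innie orientation on the same
chromosome masquerade as proper pairs with enormous inner spans and would
pollute the absence track (biasing all frequencies downwards). The
pipeline drops proper pairs whose outer fragment exceeds twice the
sample's median fragment size (`2 · (2·read_length + m)`); the `ppileup`
command exposes this as `--max-fragment`.

## Benchmark simulator

`simulate` draws a pool of `N` haploid genomes from one random reference
chromosome and a set of random TE consensus sequences. Each insertion gets
a site (minimum spacing enforced), family, strand, and population
frequency `f ~ U[0.01, 1]`; exactly `round(f·N)` randomly chosen
haplotypes carry it, and the truth table records site, family, strand,
exact frequency, and carriers. Read pairs are drawn per haplotype with
inner distance `N(100, 20)`, 1% substitution errors, and 2% chimeras by
default. Because each read's true provenance is known, alignments are
*emitted* at the true projected coordinates on the merged reference
(reads fully inside a TE copy map to the family consensus, with
coordinates and strand flipped for minus-strand insertions); reads
straddling an insertion junction are dropped, as a real aligner would fail
to map them. FASTQ export exists for running a real aligner externally.

The pair count for a target pool physical coverage `pc` is
`pc · mean_haplotype_length / inner_mean`, since each pair contributes one
inner span of `inner_mean` bases on average somewhere in the pool.

## Benchmark harnesses and scaling

The published full-scale setting (≈1,000 insertions on megabase genomes,
millions of read pairs through an external aligner) is reduced tenfold in
genome size and insertion count while *preserving the per-site physical
coverage (~100×), read geometry, error and chimera rates, insertion
spacing and frequency distribution*. Detection power and per-insertion
position/frequency accuracy depend on the local fragment evidence, not on
genome size, so the scaled runs measure the same quantities up to sampling
noise; acceptance tolerances are widened accordingly, also because the
idealized coordinate emission has no aligner mismapping.

The abundance harness simulates three populations with 100/75/50
sample-specific insertions, all at `f = 0.01`, sequenced with inner
distances 100/150/200 at physical coverages 100/200/400, and scores three
analyses of the same multi-sample track: naive, reads subsampled to equal
numbers, and physical coverage homogenized to 100×. The score is
σ<sub>obs/sim</sub>, the standard deviation (n−1) across populations of
observed/simulated insertion counts; homogenization wins (seed 1:
naive 0.277, equal reads 0.223, equal physical coverage 0.070, and the
same ordering held in 20/20 independent replicates). This harness uses 20
TE families rather than the single-population default of 5: the three
populations interleave ~225 insertions on a 150 kb chromosome, and with
only 5 families ~13% of insertions would merge with a same-family
neighbor from another population, a reference-scale artifact that a
realistic many-family TE landscape does not have.

## Known limitations

- **Idealized mapping.** Emitted alignments have no mismapping, soft
  clipping, or multi-mappers; real-aligner benchmarks will show somewhat
  larger position and frequency errors (the README example and acceptance
  tolerances account for this).
- **No reference TEs.** The simulator models only non-reference
  insertions; detecting absence of reference TE copies is out of scope.
- **Single chromosome per track.** Multi-chromosome data are processed one
  chromosome at a time.
- **False positives at permissive thresholds.** With `min_count` 2 and
  chimeric reads present, scattered chimeric TE-mates can co-occur by
  chance and produce low-support single-signature calls; raising
  `min_count` removes them (see the README example).
- **Frequency resolution.** Pool frequencies are estimated from ~100
  fragments per site at default coverage, so the per-site standard error
  is a few percentage points; rare insertions (`f` ≲ 2/pc) are at the
  detection floor.
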
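"""Physical-coverage homogenization across samples.

Pool-Seq samples differ in read number, insert size and coverage
heterogeneity, so they differ in power to detect TE insertions; more TEs
are found in the better-covered sample.  Downsampling the per-position
physical coverage to a common target equalizes that power.  Sampling is
without replacement (multivariate hypergeometric over the absence /
per-(family, direction) presence categories), so counts never increase
and category proportions are preserved in expectation.  Positions where a
sample cannot reach the target are masked; in the default joint mode an
insufficient position is masked in *all* samples, so that downstream
comparisons only use regions with sufficient physical coverage everywhere.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, TypeVar

import numpy as np

from .ppileup import PpileupColumn, PpileupTrack

__all__ = [
    "subsample_column",
    "homogenize_track",
    "subsample_reads",
]

T = TypeVar("T")


def _sample_counts(
    absence: int,
    presence: dict,
    target: int,
    rng: np.random.Generator,
) -> tuple[int, dict]:
    keys = sorted(presence)
    colors = [absence] + [presence[k] for k in keys]
    drawn = rng.multivariate_hypergeometric(colors, target)
    new_presence = {
        k: int(c) for k, c in zip(keys, drawn[1:]) if c
    }
    return int(drawn[0]), new_presence


def subsample_column(
    column: PpileupColumn, target: int, rng: np.random.Generator
) -> PpileupColumn:
    """Downsample one column to ``target`` total coverage per sample.

    Samples whose total is below the target are masked (their counts are
    zeroed); samples at exactly the target are left unchanged; the rest
    are drawn without replacement, so the resulting category counts follow
    the multivariate hypergeometric law and sum to the target exactly.
    """
    if target <= 0:
        raise ValueError("target coverage must be >= 1")
    absence = list(column.absence)
    presence = [dict(p) for p in column.presence]
    masked = list(column.masked)
    for s in range(column.n_samples):
        if masked[s]:
            absence[s] = 0
            presence[s] = {}
            continue
        total = absence[s] + sum(presence[s].values())
        if total < target:
            masked[s] = True
            absence[s] = 0
            presence[s] = {}
        elif total > target:
            absence[s], presence[s] = _sample_counts(
                absence[s], presence[s], target, rng
            )
    return PpileupColumn(absence, presence, masked)


def _position_rng(seed: int, position: int) -> np.random.Generator:
    # Counter-based stream: one generator per absolute position, so the
    # result does not depend on processing order.
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(position))))


def homogenize_track(
    track: PpileupTrack,
    target: int,
    mode: str = "joint",
    seed: int = 0,
) -> PpileupTrack:
    """Downsample every position of the track to ``target`` total coverage.

    mode="joint" (default): a position where any sample falls short of the
    target is masked in all samples; elsewhere every sample ends up at
    exactly the target.  mode="per-sample": masking applies independently
    per sample.  Deterministic given ``seed`` and the input.
    """
    if target <= 0:
        raise ValueError("target coverage must be >= 1")
    if mode not in ("joint", "per-sample"):
        raise ValueError(f"unknown mode {mode!r}")
    keys = track.keys()
    totals = track.totals()
    insufficient = (totals < target) | track.masked
    if mode == "joint":
        insufficient = np.broadcast_to(
            insufficient.any(axis=0), insufficient.shape
        ).copy()

    absence = track.absence.copy()
    presence = {k: arr.copy() for k, arr in track.presence.items()}
    masked = insufficient
    absence[masked] = 0
    for arr in presence.values():
        arr[masked] = 0

    needs = (~masked) & (totals > target)
    for i in np.nonzero(needs.any(axis=0))[0]:
        rng = _position_rng(seed, track.origin + int(i))
        for s in range(track.n_samples):
            if not needs[s, i]:
                continue
            colors = [int(absence[s, i])] + [int(presence[k][s, i]) for k in keys]
            drawn = rng.multivariate_hypergeometric(colors, target)
            absence[s, i] = drawn[0]
            for k, c in zip(keys, drawn[1:]):
                presence[k][s, i] = c
    return PpileupTrack(
        chromosome=track.chromosome,
        origin=track.origin,
        sample_ids=list(track.sample_ids),
        median_inner_distance=dict(track.median_inner_distance),
        absence=absence,
        presence=presence,
        masked=masked,
        strand_votes=track.strand_votes,
    )


def subsample_reads(
    pairs_by_sample: Mapping[str, Sequence[T]],
    n_target: int,
    rng: np.random.Generator,
) -> dict[str, list[T]]:
    """Uniform random subset of exactly ``n_target`` pairs per sample.

    Mirrors the "equal reads" normalization strategy (identical base
    coverage across samples).  A sample with fewer pairs than the target
    is an error.
    """
    out: dict[str, list[T]] = {}
    for sid, pairs in pairs_by_sample.items():
        n = len(pairs)
        if n < n_target:
            raise ValueError(
                f"sample {sid!r} has only {n} pairs, fewer than the "
                f"requested {n_target}"
            )
        idx = rng.choice(n, size=n_target, replace=False)
        idx.sort()
        out[sid] = [pairs[i] for i in idx]
    return out
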
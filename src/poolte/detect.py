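"""Signature detection and population-frequency estimation.

For each (TE family, direction) a window slides over the physical pileup;
runs of windows holding enough presence coverage are reduced to the single
window with the maximal presence signal.  The population frequency of a
signature is the ratio of the mean physical coverage supporting the TE to
the total physical coverage in its window: f = te_cov / (te_cov + abs_cov).

The window is deliberately much narrower than the presence footprint of an
insertion (which has width ~ the median inner distance by construction):
averaging the ratio over a footprint-wide window dilutes the presence peak
with its flanks and systematically underestimates the frequency, while a
narrow window placed at the peak is close to unbiased.  Nearby candidate
windows are grouped over a footprint-scale distance, so each insertion
still yields a single signature per direction.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from .ppileup import PpileupTrack

__all__ = [
    "SampleEvidence",
    "Signature",
    "default_window",
    "scan_signatures",
    "estimate_frequency",
    "write_signatures",
    "read_signatures",
]


def estimate_frequency(te_cov: float, abs_cov: float) -> float:
    """Population frequency of a TE signature.

    The ratio of the average physical coverage supporting the TE to the
    total physical coverage in the window, e.g. 72 / (72 + 18) = 0.8.
    """
    if te_cov < 0 or abs_cov < 0:
        raise ValueError("coverages must be non-negative")
    total = te_cov + abs_cov
    if total == 0:
        raise ValueError("frequency is undefined at zero total coverage")
    return te_cov / total


@dataclass(frozen=True)
class SampleEvidence:
    """Per-sample coverages of a signature window.

    ``frequency`` is None when the window holds no physical coverage at
    all for the sample.
    """

    te_cov: float
    abs_cov: float

    @property
    def frequency(self) -> float | None:
        if self.te_cov + self.abs_cov == 0:
            return None
        return estimate_frequency(self.te_cov, self.abs_cov)


@dataclass(frozen=True)
class Signature:
    """A forward or reverse TE-insertion signature.

    ``anchor`` is the window edge facing the insertion: the right edge for
    a forward signature (evidence extends rightwards) and the left edge
    for a reverse one.  Coordinates are 1-based inclusive.
    """

    chromosome: str
    family: str
    direction: str  # "F" | "R"
    window_start: int
    window_end: int
    samples: tuple[SampleEvidence, ...]
    votes_plus: int = 0
    votes_minus: int = 0

    @property
    def anchor(self) -> int:
        return self.window_end if self.direction == "F" else self.window_start

    @property
    def window_size(self) -> int:
        return self.window_end - self.window_start + 1


def default_window(track: PpileupTrack) -> int:
    """Default scan window: a tenth of the median inner distance, >= 10.

    The across-sample median of the per-sample median inner distances sets
    the footprint scale; the window is kept a small fraction of it so the
    windowed coverage ratio stays near the peak value (see module docs).
    """
    mids = sorted(track.median_inner_distance.values())
    if not mids:
        return 10
    m = mids[(len(mids) - 1) // 2]
    return max(10, round(m / 10))


def _window_means(arr: np.ndarray, window: int) -> np.ndarray:
    """Mean over each length-``window`` slice, per row: (S, L-w+1)."""
    csum = np.cumsum(arr, axis=-1, dtype=np.float64)
    csum = np.concatenate([np.zeros(arr.shape[:-1] + (1,)), csum], axis=-1)
    return (csum[..., window:] - csum[..., :-window]) / window


def _window_max(arr: np.ndarray, window: int) -> np.ndarray:
    view = np.lib.stride_tricks.sliding_window_view(arr, window, axis=-1)
    return view.max(axis=-1)


def scan_signatures(
    track: PpileupTrack,
    window: int | None = None,
    min_count: float = 2.0,
    step: int = 1,
    trigger: str = "max",
    group_distance: int | None = None,
    trigger_window: int | None = None,
) -> list[Signature]:
    """Scan the track for TE-insertion signatures.

    For each (family, direction) every window position is scored; a window
    is a candidate when, in at least one sample, its presence coverage
    reaches ``min_count``.  With trigger="max" (default) the per-sample
    statistic is the maximal column presence in the window, i.e. the
    number of supporting fragments at the best column; trigger="mean" uses
    the windowed mean instead.  Candidates lying within ``group_distance``
    of each other (default: the larger of the window and the track's
    median inner distance) form one run, resolved by keeping the window
    that maximizes the sample-summed mean presence (ties: leftmost).
    Windows containing masked columns are skipped entirely.

    When ``trigger_window`` is given, candidate detection uses the mean
    presence over windows of that (footprint-scale) size instead; masked
    columns are excluded from those means rather than disqualifying the
    whole window.  The narrow ``window`` is still used to localize each
    run's signature and estimate its frequency.  A footprint-wide mean
    trigger responds proportionally to per-position coverage
    subsampling, which a narrow or max-based statistic does not.
    """
    if min_count <= 0:
        raise ValueError("min_count must be > 0")
    if step < 1:
        raise ValueError("step must be >= 1")
    if trigger not in ("max", "mean"):
        raise ValueError(f"unknown trigger {trigger!r}")
    if window is None:
        window = default_window(track)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > track.n_columns:
        return []
    if trigger_window is not None and not window <= trigger_window <= track.n_columns:
        return []
    if group_distance is None:
        mids = sorted(track.median_inner_distance.values()) or [window]
        group_distance = max(window, mids[(len(mids) - 1) // 2])

    masked_any = track.masked.any(axis=0)
    # a window starting at i is valid iff no column in [i, i+window) is masked
    bad = _window_max(masked_any.astype(np.int8)[None, :], window)[0] > 0
    abs_means = _window_means(track.absence, window)
    if trigger_window is not None:
        # per trigger window: mean over its unmasked columns (0 if all masked)
        unmasked = (~masked_any).astype(np.float64)
        ucount = np.concatenate([[0.0], np.cumsum(unmasked)])
        ucount = ucount[trigger_window:] - ucount[:-trigger_window]

    signatures: list[Signature] = []
    for family, direction in track.keys():
        pres = track.presence[(family, direction)]
        means = _window_means(pres, window)
        if trigger_window is not None:
            upres = pres * (~masked_any)
            csum = np.concatenate(
                [np.zeros((pres.shape[0], 1)), np.cumsum(upres, axis=1)], axis=1
            )
            sums = csum[:, trigger_window:] - csum[:, :-trigger_window]
            stat = np.divide(
                sums,
                ucount,
                out=np.zeros_like(sums),
                where=ucount > 0,
            )
            cand = (stat >= min_count).any(axis=0)
        else:
            stat = _window_max(pres, window) if trigger == "max" else means
            cand = (~bad) & (stat >= min_count).any(axis=0)
        idxs = np.nonzero(cand)[0]
        if step > 1:
            idxs = idxs[(idxs % step) == 0]
        if idxs.size == 0:
            continue
        score = means.sum(axis=0)
        # windows with masked columns cannot yield valid frequency estimates
        score = np.where(bad, -1.0, score)
        breaks = np.nonzero(np.diff(idxs) > group_distance)[0] + 1
        for run in np.split(idxs, breaks):
            if trigger_window is None:
                best = run[int(np.argmax(score[run]))]
            else:
                # localize inside the run's span with the narrow window
                lo = int(run[0])
                hi = min(int(run[-1]) + trigger_window - window, score.size - 1)
                best = lo + int(np.argmax(score[lo : hi + 1]))
                if score[best] < 0:
                    continue  # no fully unmasked estimation window in the run
            evidence = tuple(
                SampleEvidence(
                    te_cov=float(means[s, best]),
                    abs_cov=float(abs_means[s, best]),
                )
                for s in range(track.n_samples)
            )
            vp = vm = 0
            if track.strand_votes is not None:
                varr = track.strand_votes.get((family, direction))
                if varr is not None:
                    vp = int(varr[best : best + window, 0].sum())
                    vm = int(varr[best : best + window, 1].sum())
            signatures.append(
                Signature(
                    chromosome=track.chromosome,
                    family=family,
                    direction=direction,
                    window_start=track.origin + int(best),
                    window_end=track.origin + int(best) + window - 1,
                    samples=evidence,
                    votes_plus=vp,
                    votes_minus=vm,
                )
            )
    signatures.sort(key=lambda sig: (sig.anchor, sig.family, sig.direction))
    return signatures


# ---------------------------------------------------------------------------
# Signature table IO (consumed by the pair-up stage).
# ---------------------------------------------------------------------------


def write_signatures(
    signatures: Sequence[Signature],
    sample_ids: Sequence[str],
    sink: str | Path | IO[str],
) -> None:
    owned = isinstance(sink, (str, Path))
    handle = open(sink, "w", encoding="utf-8") if owned else sink
    try:
        cols = ["#chr", "pos", "dir", "family", "wstart", "wend", "vplus", "vminus"]
        for sid in sample_ids:
            cols += [f"{sid}:te_cov", f"{sid}:abs_cov", f"{sid}:freq"]
        handle.write("\t".join(cols) + "\n")
        for sig in signatures:
            row = [
                sig.chromosome,
                str(sig.anchor),
                sig.direction,
                sig.family,
                str(sig.window_start),
                str(sig.window_end),
                str(sig.votes_plus),
                str(sig.votes_minus),
            ]
            for ev in sig.samples:
                freq = ev.frequency
                row += [
                    repr(ev.te_cov),
                    repr(ev.abs_cov),
                    "NA" if freq is None else repr(freq),
                ]
            handle.write("\t".join(row) + "\n")
    finally:
        if owned:
            handle.close()


def read_signatures(
    source: str | Path | IO[str],
) -> tuple[list[Signature], list[str]]:
    owned = isinstance(source, (str, Path))
    handle = open(source, encoding="utf-8") if owned else source
    try:
        header = handle.readline().rstrip("\n").split("\t")
        sample_ids = [c[: -len(":te_cov")] for c in header[8:] if c.endswith(":te_cov")]
        signatures: list[Signature] = []
        for raw in handle:
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            evidence = tuple(
                SampleEvidence(
                    te_cov=float(parts[8 + 3 * s]),
                    abs_cov=float(parts[9 + 3 * s]),
                )
                for s in range(len(sample_ids))
            )
            signatures.append(
                Signature(
                    chromosome=parts[0],
                    family=parts[3],
                    direction=parts[2],
                    window_start=int(parts[4]),
                    window_end=int(parts[5]),
                    samples=evidence,
                    votes_plus=int(parts[6]),
                    votes_minus=int(parts[7]),
                )
            )
        return signatures, sample_ids
    finally:
        if owned:
            handle.close()
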
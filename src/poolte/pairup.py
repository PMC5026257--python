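"""Joining forward and reverse signatures into final TE insertion calls.

A TE insertion flanked by enough reads produces one forward and one
reverse signature of the same family.  Matching signatures within a given
distance are joined; position and per-sample frequency of the joined call
are the averages of the two signatures' estimates.  Signatures left
without a partner are still reported as single-signature insertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from .detect import Signature

__all__ = [
    "TEInsertion",
    "default_max_distance",
    "pair_signatures",
    "assign_strand",
    "write_insertions",
    "read_insertions",
]


@dataclass(frozen=True)
class TEInsertion:
    """A final TE insertion call.

    ``support`` is "FR" for a joined forward/reverse pair, "F" or "R" for
    a single signature.  ``frequencies`` holds one entry per sample (None
    where no physical coverage was available).  ``strand`` is "+", "-" or
    "." (unknown).
    """

    chromosome: str
    position: int
    family: str
    strand: str
    support: str
    frequencies: tuple[float | None, ...]
    votes_plus: int = 0
    votes_minus: int = 0


def default_max_distance(median_inner_distance: int, read_length: int) -> int:
    """Join radius: the F and R windows flank the insertion by at most
    about one physical span each, so three spans plus two read lengths is
    a generous, scale-aware bound."""
    return 3 * int(median_inner_distance) + 2 * int(read_length)


def assign_strand(votes_plus: int, votes_minus: int) -> str:
    """Majority vote over the TE-mapped mate orientations ("." on ties)."""
    if votes_plus > votes_minus:
        return "+"
    if votes_minus > votes_plus:
        return "-"
    return "."


def _mean_frequency(
    a: float | None, b: float | None
) -> float | None:
    if a is None:
        return b
    if b is None:
        return a
    return (a + b) / 2


def _single(sig: Signature) -> TEInsertion:
    return TEInsertion(
        chromosome=sig.chromosome,
        position=sig.anchor,
        family=sig.family,
        strand=assign_strand(sig.votes_plus, sig.votes_minus),
        support=sig.direction,
        frequencies=tuple(ev.frequency for ev in sig.samples),
        votes_plus=sig.votes_plus,
        votes_minus=sig.votes_minus,
    )


def pair_signatures(
    signatures: Sequence[Signature],
    max_distance: int,
    overlap_allowance: int | None = None,
) -> list[TEInsertion]:
    """Greedy nearest-first joining of forward/reverse signature pairs.

    Candidate pairs are same-family (F, R) signatures whose anchors lie
    within ``max_distance`` of each other and whose windows are not in the
    wrong order: the reverse anchor may not lie more than
    ``overlap_allowance`` upstream of the forward anchor (both windows
    center on the insertion, so overlap of up to about one signature
    footprint is normal; default: one window size).  The closest pair is
    joined first (ties: leftmost forward anchor); every signature is used
    at most once; leftovers become single-signature calls.  The matching
    depends only on anchor values, never on input order.
    """
    from bisect import bisect_left, bisect_right

    forward = [s for s in signatures if s.direction == "F"]
    reverse = [s for s in signatures if s.direction == "R"]
    rev_by_family: dict[str, list[tuple[int, int]]] = {}
    for ri, r in enumerate(reverse):
        rev_by_family.setdefault(r.family, []).append((r.anchor, ri))
    for anchors in rev_by_family.values():
        anchors.sort()
    candidates = []
    for fi, f in enumerate(forward):
        anchors = rev_by_family.get(f.family, ())
        keys = [a for a, _ in anchors]
        allowance = f.window_size if overlap_allowance is None else overlap_allowance
        lo = bisect_left(keys, max(f.anchor - allowance, f.anchor - max_distance))
        hi = bisect_right(keys, f.anchor + max_distance)
        for r_anchor, ri in anchors[lo:hi]:
            candidates.append((abs(r_anchor - f.anchor), f.anchor, r_anchor, fi, ri))
    candidates.sort()
    used_f: set[int] = set()
    used_r: set[int] = set()
    insertions: list[TEInsertion] = []
    for dist, _, _, fi, ri in candidates:
        if fi in used_f or ri in used_r:
            continue
        used_f.add(fi)
        used_r.add(ri)
        f, r = forward[fi], reverse[ri]
        position = (f.anchor + r.anchor + 1) // 2  # mean, rounded half up
        freqs = tuple(
            _mean_frequency(ef.frequency, er.frequency)
            for ef, er in zip(f.samples, r.samples)
        )
        vp = f.votes_plus + r.votes_plus
        vm = f.votes_minus + r.votes_minus
        insertions.append(
            TEInsertion(
                chromosome=f.chromosome,
                position=position,
                family=f.family,
                strand=assign_strand(vp, vm),
                support="FR",
                frequencies=freqs,
                votes_plus=vp,
                votes_minus=vm,
            )
        )
    for fi, f in enumerate(forward):
        if fi not in used_f:
            insertions.append(_single(f))
    for ri, r in enumerate(reverse):
        if ri not in used_r:
            insertions.append(_single(r))
    insertions.sort(key=lambda ins: (ins.chromosome, ins.position, ins.family))
    return insertions


# ---------------------------------------------------------------------------
# Insertion table IO.
# ---------------------------------------------------------------------------


def write_insertions(
    insertions: Sequence[TEInsertion],
    sample_ids: Sequence[str],
    sink: str | Path | IO[str],
) -> None:
    """Tab-separated call table: chr, pos, strand, family, support, then
    one frequency column per sample (NA where undefined)."""
    owned = isinstance(sink, (str, Path))
    handle = open(sink, "w", encoding="utf-8") if owned else sink
    try:
        header = ["#chr", "pos", "strand", "family", "support"] + list(sample_ids)
        handle.write("\t".join(header) + "\n")
        ordered = sorted(
            insertions, key=lambda ins: (ins.chromosome, ins.position, ins.family)
        )
        for ins in ordered:
            row = [ins.chromosome, str(ins.position), ins.strand, ins.family, ins.support]
            row += ["NA" if f is None else repr(f) for f in ins.frequencies]
            handle.write("\t".join(row) + "\n")
    finally:
        if owned:
            handle.close()


def read_insertions(
    source: str | Path | IO[str],
) -> tuple[list[TEInsertion], list[str]]:
    owned = isinstance(source, (str, Path))
    handle = open(source, encoding="utf-8") if owned else source
    try:
        header = handle.readline().rstrip("\n").split("\t")
        sample_ids = header[5:]
        insertions: list[TEInsertion] = []
        for raw in handle:
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            freqs = tuple(
                None if f == "NA" else float(f) for f in parts[5 : 5 + len(sample_ids)]
            )
            insertions.append(
                TEInsertion(
                    chromosome=parts[0],
                    position=int(parts[1]),
                    strand=parts[2],
                    family=parts[3],
                    support=parts[4],
                    frequencies=freqs,
                )
            )
        return insertions, sample_ids
    finally:
        if owned:
            handle.close()
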
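"""Scoring TE insertion calls against a simulated truth table.

Calls are matched one-to-one to truth rows (greedy nearest-first, same
family, within a maximal distance), yielding found / missed / false
positive counts, strand correctness, the split into both-signature and
single-signature calls, and the accuracy of position and frequency
estimates.  For multi-sample abundance comparisons, the spread of the
observed-to-simulated count ratio across populations measures how biased
the comparison is: an unbiased analysis gives a stable ratio (low
sigma_obs_sim).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .pairup import TEInsertion
from .simulate import TruthRow

__all__ = [
    "Matching",
    "EvalMetrics",
    "match_calls",
    "compute_metrics",
    "compare_abundance",
]


@dataclass
class Matching:
    pairs: list[tuple[int, int]]  # (call index, truth index)
    unmatched_calls: list[int]
    unmatched_truth: list[int]


def match_calls(
    calls: Sequence[TEInsertion],
    truth: Sequence[TruthRow],
    max_match_dist: int = 100,
) -> Matching:
    """Greedy nearest-first one-to-one matching of calls to truth rows.

    A call can match a truth row only with the same family and
    |position difference| <= max_match_dist.  The matching depends only
    on positions, never on input order.
    """
    candidates = []
    by_family: dict[str, list[int]] = {}
    for ti, row in enumerate(truth):
        by_family.setdefault(row.family, []).append(ti)
    for ci, call in enumerate(calls):
        for ti in by_family.get(call.family, ()):
            row = truth[ti]
            if row.chromosome != call.chromosome:
                continue
            dist = abs(call.position - row.position)
            if dist <= max_match_dist:
                candidates.append((dist, row.position, call.position, ci, ti))
    candidates.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, ci, ti in candidates:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        pairs.append((ci, ti))
    pairs.sort(key=lambda p: truth[p[1]].position)
    return Matching(
        pairs=pairs,
        unmatched_calls=[ci for ci in range(len(calls)) if ci not in used_c],
        unmatched_truth=[ti for ti in range(len(truth)) if ti not in used_t],
    )


@dataclass
class EvalMetrics:
    """Benchmark metrics for one call set against one truth table.

    Position and frequency errors are absolute differences over matched
    pairs; standard deviations use the n-1 denominator.  ``bias_dfreq``
    is the signed mean frequency error (diagnostic for the direction of
    the estimator bias).  ``mu_c`` and ``mu_pc`` (average base and
    physical coverage, measured from the data) are filled in by the
    caller when available.
    """

    found: int
    missed: int
    false_positive: int
    strand_correct: int
    both_sign: int
    single_sign: int
    mu_dpos: float | None
    sigma_dpos: float | None
    mu_dfreq: float | None
    sigma_dfreq: float | None
    bias_dfreq: float | None
    frac_within_10bp: float | None
    mu_c: float | None = None
    mu_pc: float | None = None


def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = sum(values) / len(values)
    if len(values) < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return mean, math.sqrt(var)


def compute_metrics(
    matching: Matching,
    calls: Sequence[TEInsertion],
    truth: Sequence[TruthRow],
    sample: int = 0,
) -> EvalMetrics:
    """Tally benchmark metrics from a matching.

    ``sample`` selects which sample's frequency column is scored against
    the truth frequency.  Calls with an unknown strand never count as
    strand-correct.
    """
    dpos: list[float] = []
    dfreq: list[float] = []
    signed: list[float] = []
    strand_correct = 0
    both = single = 0
    for ci, ti in matching.pairs:
        call, row = calls[ci], truth[ti]
        dpos.append(abs(call.position - row.position))
        freq = call.frequencies[sample] if call.frequencies else None
        if freq is not None:
            dfreq.append(abs(freq - row.frequency))
            signed.append(freq - row.frequency)
        if call.strand == row.strand:
            strand_correct += 1
        if call.support == "FR":
            both += 1
        else:
            single += 1
    mu_dpos, sigma_dpos = _mean_sd(dpos)
    mu_dfreq, sigma_dfreq = _mean_sd(dfreq)
    bias = sum(signed) / len(signed) if signed else None
    within = (
        sum(1 for d in dpos if d <= 10) / len(dpos) if dpos else None
    )
    return EvalMetrics(
        found=len(matching.pairs),
        missed=len(matching.unmatched_truth),
        false_positive=len(matching.unmatched_calls),
        strand_correct=strand_correct,
        both_sign=both,
        single_sign=single,
        mu_dpos=mu_dpos,
        sigma_dpos=sigma_dpos,
        mu_dfreq=mu_dfreq,
        sigma_dfreq=sigma_dfreq,
        bias_dfreq=bias,
        frac_within_10bp=within,
    )


def compare_abundance(
    observed: Sequence[int], simulated: Sequence[int]
) -> tuple[list[float], float]:
    """Observed/simulated TE-count ratios per population and their spread.

    Returns the ratios r_i = observed_i / simulated_i and their sample
    standard deviation (n-1 denominator), the sigma_obs_sim statistic.
    """
    if len(observed) != len(simulated):
        raise ValueError("observed and simulated counts differ in length")
    if any(s <= 0 for s in simulated):
        raise ValueError("simulated counts must be positive")
    ratios = [o / s for o, s in zip(observed, simulated)]
    sigma = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return ratios, sigma


def write_metrics(metrics: EvalMetrics, sink: str | Path | IO[str]) -> None:
    """One-row tab-separated metrics table (NA for undefined entries)."""
    owned = isinstance(sink, (str, Path))
    handle = open(sink, "w", encoding="utf-8") if owned else sink

    def fmt(value: float | int | None) -> str:
        if value is None:
            return "NA"
        if isinstance(value, int):
            return str(value)
        return f"{value:.4f}"

    try:
        names = [
            "found",
            "missed",
            "false_positive",
            "strand_correct",
            "both_sign",
            "single_sign",
            "mu_dpos",
            "sigma_dpos",
            "mu_dfreq",
            "sigma_dfreq",
            "bias_dfreq",
            "frac_within_10bp",
            "mu_c",
            "mu_pc",
        ]
        handle.write("#" + "\t".join(names) + "\n")
        handle.write("\t".join(fmt(getattr(metrics, n)) for n in names) + "\n")
    finally:
        if owned:
            handle.close()
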
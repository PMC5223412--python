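"""Scoring predicted inversions against simulated truth.

A call matches a truth inversion when their reciprocal overlap reaches
the threshold (50% of each interval by default).  Because of diploid,
mutually overlapping events one call may match two truth inversions;
both count as found.  Precision is TP/(TP+FP) over calls; recall is
found/(found+FN) over (eligible) truth, mirroring the positive
predictive value / sensitivity conventions of the benchmark protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .calls import InversionCall
from .simulate import TruthInversion


@dataclass
class EvalReport:
    n_calls: int
    tp: int
    fp: int
    fn: int
    found: int
    n_truth: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def fdr(self) -> float | None:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.found / (self.found + self.fn) if (self.found + self.fn) else None

    def to_tsv(self) -> str:
        prec = "NA" if self.precision is None else f"{100 * self.precision:.2f}"
        rec = "NA" if self.recall is None else f"{100 * self.recall:.2f}"
        return (
            "n_calls\tTP\tFP\tFN\tfound\tprecision\trecall\n"
            f"{self.n_calls}\t{self.tp}\t{self.fp}\t{self.fn}\t{self.found}\t{prec}%\t{rec}%\n"
        )


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for two half-open intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _call_span(call) -> tuple[str, int, int]:
    if isinstance(call, InversionCall):
        start, end = call.segment
        return call.chromosome, start, end
    chrom, start, end = call
    return chrom, int(start), int(end)


def evaluate_calls(
    calls: Sequence,
    truth: Sequence[TruthInversion],
    reciprocal: float = 0.50,
    restrict_to_covered: bool = False,
    min_truth_size: int | None = None,
) -> EvalReport:
    """Score calls against truth at the given reciprocal-overlap threshold.

    ``restrict_to_covered`` drops truth inversions without clone coverage
    at both breakpoints from the denominator; ``min_truth_size`` restricts
    the truth set (and matching) to inversions of at least that size.
    """
    eligible = [t for t in truth if (t.clone_covered or not restrict_to_covered)]
    if min_truth_size is not None:
        eligible = [t for t in eligible if t.size >= min_truth_size]

    spans = [_call_span(c) for c in calls]
    truth_found = [False] * len(eligible)
    tp = 0
    for chrom, s, e in spans:
        matched = False
        for i, t in enumerate(eligible):
            if t.chromosome != chrom:
                continue
            if reciprocal_overlap((s, e), (t.start, t.end)) >= reciprocal:
                matched = True
                truth_found[i] = True
        tp += matched
    found = sum(truth_found)
    fp = len(spans) - tp
    fn = len(eligible) - found
    return EvalReport(
        n_calls=len(spans), tp=tp, fp=fp, fn=fn, found=found, n_truth=len(eligible)
    )
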
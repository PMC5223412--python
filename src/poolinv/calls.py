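"""Inversion call refinement, support recalculation, and final filters.

Every quasi-clique becomes one inversion call with four coordinates: two
breakpoint uncertainty intervals, ``[left_outer, left_inner)`` and
``[right_inner, right_outer)``.  The segment ``[left_inner, right_inner)``
is the conservatively-inner estimate of the inverted sequence.  Refined
intervals come from intersecting the member PSC breakpoint intervals
(adding members can only narrow the estimate); if an outlier empties the
intersection, the two highest-support members define a fallback envelope.

Calls are then re-scored against the genome-wide same-strand pairs and
filtered: support below ``min_support`` (default 2), more than 40% of the
inner span inside assembly gaps, or segmental-duplication overlap at
*both* breakpoints (an SD at one breakpoint alone is expected for real
inversions and does not remove the call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pairs import FragmentStats
from .splitclones import PairedSplitClones, count_window_support

logger = logging.getLogger(__name__)

LOW_SUPPORT = "low_support"
GAP_OVERLAP = "gap_overlap"
SD_BOTH_BREAKPOINTS = "sd_both_breakpoints"


@dataclass
class InversionCall:
    chromosome: str
    left_outer: int
    left_inner: int
    right_inner: int
    right_outer: int
    n_psc: int
    n_pools: int
    rp_support: int
    filters: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.left_outer <= self.left_inner < self.right_inner <= self.right_outer):
            raise ValueError("call coordinates must satisfy lo <= li < ri <= ro")
        if self.n_pools < 2:
            raise ValueError("a call requires split clones from >= 2 pools")

    @property
    def left_bp(self) -> tuple[int, int]:
        return (self.left_outer, self.left_inner)

    @property
    def right_bp(self) -> tuple[int, int]:
        return (self.right_inner, self.right_outer)

    @property
    def inner_span(self) -> tuple[int, int]:
        """Minimal extent: certainly inside the event only when breakpoint
        estimates scatter symmetrically (they do not; see segment)."""
        return (self.left_inner, self.right_inner)

    @property
    def segment(self) -> tuple[int, int]:
        """Best estimate of the inverted segment.

        Split-clone breakpoint estimates are one-sided: a clone spanning
        the left breakpoint ends exactly at it, while the reflected piece
        of a right-spanning clone overshoots into the inverted segment
        (and symmetrically on the right).  The outermost envelope
        coordinates therefore estimate the true breakpoints, and the
        outer extent is the called inversion.
        """
        return (self.left_outer, self.right_outer)

    @property
    def size(self) -> int:
        lo, hi = self.segment
        return hi - lo


def _refine_interval(
    intervals: Sequence[tuple[int, int]], supports: Sequence[int]
) -> tuple[int, int]:
    lo = max(i[0] for i in intervals)
    hi = min(i[1] for i in intervals)
    if lo < hi:
        return lo, hi
    # outlier member(s): fall back to the two highest-support members
    order = sorted(range(len(intervals)), key=lambda k: (-supports[k], k))[:2]
    a = max(intervals[k][0] for k in order)
    b = min(intervals[k][1] for k in order)
    lo, hi = (a, b) if a <= b else (b, a)
    if lo == hi:
        hi += 1
    return lo, hi


def refine_breakpoints(pscs: Sequence[PairedSplitClones]) -> InversionCall:
    """Collapse a quasi-clique of PSCs into one call (see module docstring)."""
    if not pscs:
        raise ValueError("clique must be non-empty")
    chroms = {p.chromosome for p in pscs}
    if len(chroms) > 1:
        raise ValueError(f"clique spans chromosomes {sorted(chroms)}: graph construction bug")
    supports = [p.rp_support for p in pscs]
    l_lo, l_hi = _refine_interval([p.left_bp for p in pscs], supports)
    r_lo, r_hi = _refine_interval([p.right_bp for p in pscs], supports)
    if l_hi >= r_lo:
        # degenerate tiny event: keep interval order by pulling inners apart
        l_hi = min(l_hi, r_lo - 1)
        l_lo = min(l_lo, l_hi)
        if l_hi < l_lo:
            l_lo = l_hi
    pools = set()
    for p in pscs:
        pools.update((p.sc1.pool_id, p.sc2.pool_id))
    return InversionCall(
        chromosome=pscs[0].chromosome,
        left_outer=int(l_lo),
        left_inner=int(l_hi),
        right_inner=int(r_lo),
        right_outer=int(r_hi),
        n_psc=len(pscs),
        n_pools=len(pools),
        rp_support=max(supports),
    )


def recalculate_support(
    call: InversionCall,
    ss_index: Mapping[str, np.ndarray],
    frag_stats: FragmentStats,
) -> int:
    """Same-strand pairs consistent with the refined breakpoints, counted
    within windows padded by mu_fragment + 3 sigma_fragment."""
    pad = frag_stats.mu_fragment + 3 * frag_stats.sigma_fragment
    return count_window_support(ss_index, call.chromosome, call.left_bp, call.right_bp, pad)


# ---------------------------------------------------------------------------
# annotation tracks and filtering
# ---------------------------------------------------------------------------


def read_bed(path) -> dict[str, np.ndarray]:
    """Parse a BED track into per-chromosome merged interval arrays.

    Malformed lines raise with the offending line number.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty or inverted BED interval")
            per_chrom.setdefault(fields[0], []).append((start, end))
    return {chrom: merge_intervals(ivals) for chrom, ivals in per_chrom.items()}


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    arr = np.asarray(sorted(intervals), dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return arr
    keep_s = [arr[0, 0]]
    keep_e = [arr[0, 1]]
    for s, e in arr[1:]:
        if s <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], e)
        else:
            keep_s.append(s)
            keep_e.append(e)
    return np.column_stack([keep_s, keep_e])


def _overlap_bases(track: np.ndarray, start: int, end: int) -> int:
    if len(track) == 0 or start >= end:
        return 0
    s = np.maximum(track[:, 0], start)
    e = np.minimum(track[:, 1], end)
    return int(np.maximum(e - s, 0).sum())


def _any_overlap(track: Mapping[str, np.ndarray] | None, chrom: str, interval: tuple[int, int]) -> bool:
    if not track:
        return False
    arr = track.get(chrom)
    if arr is None:
        return False
    return _overlap_bases(arr, interval[0], interval[1]) > 0


def filter_calls(
    calls: Sequence[InversionCall],
    sd_track: Mapping[str, np.ndarray] | None = None,
    gap_track: Mapping[str, np.ndarray] | None = None,
    min_support: int = 2,
    max_track_overlap: float = 0.40,
) -> tuple[list[InversionCall], list[InversionCall]]:
    """Apply the final filters; returns (kept, removed-with-reasons)."""
    kept: list[InversionCall] = []
    removed: list[InversionCall] = []
    for call in calls:
        reasons = set()
        if call.rp_support < min_support:
            reasons.add(LOW_SUPPORT)
        if gap_track:
            arr = gap_track.get(call.chromosome)
            if arr is not None:
                span = max(call.right_inner - call.left_inner, 1)
                frac = _overlap_bases(arr, call.left_inner, call.right_inner) / span
                if frac > max_track_overlap:
                    reasons.add(GAP_OVERLAP)
        if _any_overlap(sd_track, call.chromosome, call.left_bp) and _any_overlap(
            sd_track, call.chromosome, call.right_bp
        ):
            reasons.add(SD_BOTH_BREAKPOINTS)
        call.filters = reasons
        if reasons:
            removed.append(call)
        else:
            kept.append(call)
    return kept, removed


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_DETAIL_HEADER = (
    "chrom\tleft_outer\tleft_inner\tright_inner\tright_outer\tn_psc\tn_pools\trp_support\tfilters"
)


def write_calls(
    calls: Sequence[InversionCall],
    bed_path,
    detail_path=None,
    removed: Sequence[InversionCall] | None = None,
    removed_path=None,
) -> None:
    """Write the BED-compatible main output plus the detailed TSV."""
    with open(bed_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\trp_support\n")
        for i, c in enumerate(calls, 1):
            fh.write(f"{c.chromosome}\t{c.left_inner}\t{c.right_inner}\tinv_{i}\t{c.rp_support}\n")
    if detail_path is not None:
        _write_detail(calls, detail_path)
    if removed_path is not None:
        _write_detail(removed or [], removed_path)


def _write_detail(calls: Sequence[InversionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(_DETAIL_HEADER + "\n")
        for c in calls:
            filt = ",".join(sorted(c.filters)) if c.filters else "."
            fh.write(
                f"{c.chromosome}\t{c.left_outer}\t{c.left_inner}\t{c.right_inner}\t"
                f"{c.right_outer}\t{c.n_psc}\t{c.n_pools}\t{c.rp_support}\t{filt}\n"
            )


def read_calls(detail_path) -> list[InversionCall]:
    """Parse a detailed TSV back into calls (inverse of :func:`write_calls`)."""
    out: list[InversionCall] = []
    with open(detail_path) as fh:
        header = fh.readline()
        if header.strip() != _DETAIL_HEADER:
            raise ValueError(f"{detail_path}: unrecognised calls header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{detail_path}:{lineno}: expected 9 fields")
            out.append(
                InversionCall(
                    chromosome=f[0],
                    left_outer=int(f[1]),
                    left_inner=int(f[2]),
                    right_inner=int(f[3]),
                    right_outer=int(f[4]),
                    n_psc=int(f[5]),
                    n_pools=int(f[6]),
                    rp_support=int(f[7]),
                    filters=set() if f[8] == "." else set(f[8].split(",")),
                )
            )
    return out
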
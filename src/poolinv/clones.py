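"""Clone (molecule) reconstruction from concordant read pairs.

Each pool is a dilute sample of large clones (fosmids ~40 Kbp, BACs
~140 Kbp) or long molecules (linked reads), so concordant read pairs from
one pool tile the underlying clones.  Clones are reconstructed per pool
and chromosome by merging pair spanning intervals that lie within a merge
distance (2 x mu_fragment by default; up to 10 Kb for sparse linked-read
data), then dropping candidates whose *breadth* of coverage -- the
fraction of the interval covered by actual read alignments -- is below
40%.  Depth of coverage is computed and reported but does not gate
filtering by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pairs import ReadPairRecord

logger = logging.getLogger(__name__)


@dataclass
class CandidateClone:
    chromosome: str
    start: int
    end: int
    pool_id: str
    n_pairs: int
    covered_bases: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("clone interval must be non-empty")
        if self.n_pairs < 1:
            raise ValueError("a candidate clone needs at least one pair")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class InferredClone(CandidateClone):
    breadth: float = 0.0
    depth: float = 0.0


@dataclass(frozen=True)
class CloneStats:
    mu_clone: float
    sigma_clone: float

    def __post_init__(self) -> None:
        if self.mu_clone <= 0 or self.sigma_clone < 0:
            raise ValueError("require mu_clone > 0 and sigma_clone >= 0")


def spanning_interval(pair: ReadPairRecord) -> tuple[int, int]:
    """Interval from the proximal read's start to the distal read's end."""
    start = min(pair.read1_start, pair.read2_start)
    end = max(pair.read1_end, pair.read2_end)
    return start, end


def _check_sorted(starts: np.ndarray) -> None:
    if len(starts) > 1 and np.any(np.diff(starts) < 0):
        raise ValueError("intervals must be sorted by start position")


def _merge_core(starts: np.ndarray, ends: np.ndarray, merge_distance: int):
    """Left-to-right sweep; returns (group_id, cand_start, cand_end)."""
    runmax = np.maximum.accumulate(ends)
    is_new = np.empty(len(starts), dtype=bool)
    is_new[0] = True
    is_new[1:] = starts[1:] - runmax[:-1] > merge_distance
    gid = np.cumsum(is_new) - 1
    first = np.flatnonzero(is_new)
    cand_start = starts[first]
    cand_end = np.maximum.reduceat(ends, first)
    return gid, cand_start, cand_end


def _union_lengths(starts: np.ndarray, ends: np.ndarray, gid: np.ndarray, n_groups: int) -> np.ndarray:
    """Union length of intervals per group.  Groups must occupy disjoint,
    ordered genomic ranges (true for merged candidates), so a single global
    sweep suffices."""
    order = np.argsort(starts, kind="stable")
    s, e, g = starts[order], ends[order], gid[order]
    cummax = np.maximum.accumulate(e)
    prev = np.empty(len(s), dtype=e.dtype)
    prev[0] = s[0]  # no prior coverage
    prev[1:] = cummax[:-1]
    contrib = np.maximum(e - np.maximum(s, prev), 0)
    out = np.zeros(n_groups, dtype=np.int64)
    np.add.at(out, g, contrib)
    return out


def merge_spanning_intervals(
    intervals: Sequence[tuple[int, int]] | np.ndarray,
    merge_distance: int,
    *,
    chromosome: str = "",
    pool_id: str = "",
) -> list[CandidateClone]:
    """Merge sorted spanning intervals into candidate clones.

    An interval joins the open candidate iff its start is within
    ``merge_distance`` of the candidate's current end; candidates are
    maximal.  ``covered_bases`` here is the union of the spanning intervals;
    :func:`breadth_filter` replaces it with the read-footprint union.
    """
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return []
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    starts, ends = arr[:, 0], arr[:, 1]
    _check_sorted(starts)
    gid, cs, ce = _merge_core(starts, ends, merge_distance)
    n_pairs = np.bincount(gid)
    covered = _union_lengths(starts, ends, gid, len(cs))
    return [
        CandidateClone(
            chromosome=chromosome,
            start=int(cs[i]),
            end=int(ce[i]),
            pool_id=pool_id,
            n_pairs=int(n_pairs[i]),
            covered_bases=int(covered[i]),
        )
        for i in range(len(cs))
    ]


def breadth_filter(
    candidates: Sequence[CandidateClone],
    read_intervals: Sequence[tuple[int, int]] | np.ndarray,
    min_breadth: float = 0.40,
) -> list[InferredClone]:
    """Compute breadth from read alignment footprints and keep candidates
    with breadth >= ``min_breadth`` (the boundary is inclusive: clones
    covered by *less than* the threshold are removed)."""
    if not 0 < min_breadth <= 1:
        raise ValueError("min_breadth must be in (0, 1]")
    if not candidates:
        return []
    reads = np.asarray(read_intervals, dtype=np.int64).reshape(-1, 2)
    cand_starts = np.array([c.start for c in candidates])
    cand_ends = np.array([c.end for c in candidates])
    order = np.argsort(cand_starts, kind="stable")
    # assign each read to the candidate containing its start
    idx = np.searchsorted(cand_starts[order], reads[:, 0], side="right") - 1
    valid = idx >= 0
    idx_o = order[np.clip(idx, 0, None)]
    inside = valid & (reads[:, 0] < cand_ends[idx_o])
    gid = idx_o[inside]
    clipped_e = np.minimum(reads[inside, 1], cand_ends[gid])
    covered = _union_lengths(reads[inside, 0], clipped_e, gid, len(candidates))
    read_bases = np.zeros(len(candidates), dtype=np.int64)
    np.add.at(read_bases, gid, clipped_e - reads[inside, 0])

    out: list[InferredClone] = []
    for i, c in enumerate(candidates):
        breadth = covered[i] / c.length
        if breadth >= min_breadth:
            out.append(
                InferredClone(
                    chromosome=c.chromosome,
                    start=c.start,
                    end=c.end,
                    pool_id=c.pool_id,
                    n_pairs=c.n_pairs,
                    covered_bases=int(covered[i]),
                    breadth=float(breadth),
                    depth=float(read_bases[i] / c.length),
                )
            )
    return out


def infer_clones_frame(
    df: pd.DataFrame,
    merge_distance: int,
    *,
    pool_id: str,
    chromosome: str,
    min_breadth: float = 0.40,
    min_depth: float | None = None,
) -> list[InferredClone]:
    """Vectorised driver: concordant pairs of one pool/chromosome ->
    inferred clones.  ``df`` needs the read-pair table columns."""
    if df.empty:
        return []
    r1s = df["r1_start"].to_numpy()
    r1e = df["r1_end"].to_numpy()
    r2s = df["r2_start"].to_numpy()
    r2e = df["r2_end"].to_numpy()
    span_s = np.minimum(r1s, r2s)
    span_e = np.maximum(r1e, r2e)
    order = np.argsort(span_s, kind="stable")
    span_s, span_e = span_s[order], span_e[order]
    cands = merge_spanning_intervals(
        np.column_stack([span_s, span_e]), merge_distance, chromosome=chromosome, pool_id=pool_id
    )
    reads = np.concatenate(
        [np.column_stack([r1s, r1e]), np.column_stack([r2s, r2e])]
    )
    clones = breadth_filter(cands, reads, min_breadth)
    if min_depth is not None:
        clones = [c for c in clones if c.depth >= min_depth]
    return clones


def clone_length_stats(
    clones: Sequence[InferredClone] | Sequence[int],
    min_clones: int = 30,
) -> CloneStats:
    """Sample mean/sd of clone lengths after one round of 3-sigma trimming."""
    if clones and isinstance(clones[0], (int, np.integer, float)):
        lengths = np.asarray(clones, dtype=float)
    else:
        lengths = np.array([c.length for c in clones], dtype=float)
    if len(lengths) < min_clones:
        raise ValueError(
            f"only {len(lengths)} inferred clones (need >= {min_clones}); "
            "supply mu_clone/sigma_clone via config instead"
        )
    mu, sd = lengths.mean(), lengths.std(ddof=1)
    if sd > 0:
        keep = np.abs(lengths - mu) <= 3 * sd
        lengths = lengths[keep]
        mu = lengths.mean()
        sd = lengths.std(ddof=1) if len(lengths) > 1 else 0.0
    return CloneStats(mu_clone=float(mu), sigma_clone=float(sd))


def clones_to_bed(clones: Iterable[InferredClone]) -> str:
    """BED text for inspection: chrom, start, end, pool, n_pairs, breadth."""
    lines = [
        f"{c.chromosome}\t{c.start}\t{c.end}\t{c.pool_id}\t{c.n_pairs}\t{c.breadth:.3f}"
        for c in clones
    ]
    return "\n".join(lines) + ("\n" if lines else "")
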
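"""Split-clone detection, cross-pool pairing, and read-pair support.

A clone spanning an inversion breakpoint maps to the reference as two
separate inferred intervals ("split clone"): the lengths of the two
pieces sum to a full clone length, and their separation equals the
inversion size (up to a clone length).  Split clones from *different*
pools that agree on both breakpoints are paired (PSC); the PSC is the
node later clustered by the quasi-clique stage.

Both acceptance tests use inclusive bounds:

* full-length sum:       mu_clone - 3 sigma <= |left| + |right| <= mu_clone + 3 sigma
* breakpoint distance:   min_inv_size <= right.start - left.start <= max_inv_size
* cross-pool tolerance:  |start difference| <= mu_clone on both members
  (one symmetric bound covering the gap and overlap configurations, since
  max gap and max overlap are both set to mu_clone).

Candidates without same-strand read-pair support at their implied
breakpoints are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clones import CloneStats, InferredClone
from .pairs import FragmentStats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InversionSizeBounds:
    min_inv_size: int = 200_000
    max_inv_size: int = 10_000_000

    def __post_init__(self) -> None:
        if not 0 < self.min_inv_size < self.max_inv_size:
            raise ValueError("require 0 < min_inv_size < max_inv_size")


@dataclass
class SplitClone:
    left: InferredClone
    right: InferredClone
    pool_id: str
    separation: int
    support: int = 0

    def __post_init__(self) -> None:
        if self.left.pool_id != self.right.pool_id or self.left.pool_id != self.pool_id:
            raise ValueError("split clone members must come from one pool")
        if self.left.chromosome != self.right.chromosome:
            raise ValueError("split clone members must share a chromosome")
        if self.left.start >= self.right.start:
            raise ValueError("left member must start before right member")

    @property
    def chromosome(self) -> str:
        return self.left.chromosome

    @property
    def summed_length(self) -> int:
        return self.left.length + self.right.length


def _envelope(a: int, b: int) -> tuple[int, int]:
    """Half-open interval spanning two point estimates (width >= 1)."""
    lo, hi = (a, b) if a <= b else (b, a)
    return int(lo), int(hi) + 1


@dataclass
class PairedSplitClones:
    sc1: SplitClone
    sc2: SplitClone
    left_bp: tuple[int, int] = (0, 0)
    right_bp: tuple[int, int] = (0, 0)
    rp_support: int = 0

    def __post_init__(self) -> None:
        if self.sc1.pool_id == self.sc2.pool_id:
            raise ValueError("a PSC requires split clones from different pools")
        if self.sc1.chromosome != self.sc2.chromosome:
            raise ValueError("a PSC requires split clones on one chromosome")
        if self.left_bp == (0, 0):
            self.left_bp = _envelope(self.sc1.left.end, self.sc2.left.end)
        if self.right_bp == (0, 0):
            self.right_bp = _envelope(self.sc1.right.start, self.sc2.right.start)

    @property
    def chromosome(self) -> str:
        return self.sc1.chromosome

    @property
    def implied_size(self) -> int:
        """Distance between breakpoint interval midpoints."""
        lm = (self.left_bp[0] + self.left_bp[1]) // 2
        rm = (self.right_bp[0] + self.right_bp[1]) // 2
        return rm - lm


# ---------------------------------------------------------------------------
# split-clone detection
# ---------------------------------------------------------------------------


def _split_clone_ok(
    left: InferredClone,
    right: InferredClone,
    stats: CloneStats,
    bounds: InversionSizeBounds,
) -> bool:
    total = left.length + right.length
    lo = stats.mu_clone - 3 * stats.sigma_clone
    hi = stats.mu_clone + 3 * stats.sigma_clone
    if not (lo <= total <= hi):
        return False
    sep = right.start - left.start
    return bounds.min_inv_size <= sep <= bounds.max_inv_size


def find_split_clones(
    clones: Sequence[InferredClone],
    clone_stats: CloneStats,
    bounds: InversionSizeBounds,
) -> list[SplitClone]:
    """All ordered clone pairs of one pool satisfying the split-clone
    inequalities.  Clones must be sorted by start per chromosome; a sliding
    window over the separation bound keeps the scan amortised linear in the
    window occupancy."""
    out: list[SplitClone] = []
    by_chrom: dict[str, list[InferredClone]] = {}
    for c in clones:
        by_chrom.setdefault(c.chromosome, []).append(c)
    for chrom, cs in by_chrom.items():
        starts = np.array([c.start for c in cs])
        if np.any(np.diff(starts) < 0):
            raise ValueError("clones must be sorted by start position")
        for i, left in enumerate(cs):
            j0 = int(np.searchsorted(starts, left.start + bounds.min_inv_size, side="left"))
            j1 = int(np.searchsorted(starts, left.start + bounds.max_inv_size, side="right"))
            for j in range(max(j0, i + 1), j1):
                right = cs[j]
                if _split_clone_ok(left, right, clone_stats, bounds):
                    out.append(
                        SplitClone(
                            left=left,
                            right=right,
                            pool_id=left.pool_id,
                            separation=right.start - left.start,
                        )
                    )
    return out


def all_pairs_split_clones(
    clones: Sequence[InferredClone],
    clone_stats: CloneStats,
    bounds: InversionSizeBounds,
) -> list[SplitClone]:
    """O(n^2) reference implementation of :func:`find_split_clones`
    (test oracle; applies the inequality systems directly to every pair)."""
    out = []
    for a in clones:
        for b in clones:
            if a.chromosome != b.chromosome or a.start >= b.start:
                continue
            if _split_clone_ok(a, b, clone_stats, bounds):
                out.append(SplitClone(left=a, right=b, pool_id=a.pool_id, separation=b.start - a.start))
    return out


# ---------------------------------------------------------------------------
# cross-pool pairing
# ---------------------------------------------------------------------------


def pair_split_clones(
    split_clones: Sequence[SplitClone],
    clone_stats: CloneStats,
) -> list[PairedSplitClones]:
    """Pair split clones from different pools whose left-member starts and
    right-member starts each differ by at most mu_clone (gap or overlap)."""
    tol = clone_stats.mu_clone
    out: list[PairedSplitClones] = []
    by_chrom: dict[str, list[SplitClone]] = {}
    for sc in split_clones:
        by_chrom.setdefault(sc.chromosome, []).append(sc)
    for chrom, scs in by_chrom.items():
        scs = sorted(scs, key=lambda s: s.left.start)
        starts = np.array([s.left.start for s in scs])
        for i, a in enumerate(scs):
            j1 = int(np.searchsorted(starts, a.left.start + tol, side="right"))
            for j in range(i + 1, j1):
                b = scs[j]
                if a.pool_id == b.pool_id:
                    continue
                if abs(b.right.start - a.right.start) <= tol:
                    out.append(PairedSplitClones(sc1=a, sc2=b))
    return out


# ---------------------------------------------------------------------------
# same-strand read-pair support
# ---------------------------------------------------------------------------


def build_same_strand_index(frames: Iterable[pd.DataFrame]) -> dict[str, np.ndarray]:
    """Collect same-strand pairs genome-wide into per-chromosome arrays
    with columns (leftmost read start, leftmost read end, rightmost read
    start, rightmost read end), sorted by leftmost read start."""
    parts: dict[str, list[np.ndarray]] = {}
    for df in frames:
        if df.empty:
            continue
        same = df["strand1"].to_numpy() == df["strand2"].to_numpy()
        sub = df[same]
        if sub.empty:
            continue
        r1s = sub["r1_start"].to_numpy()
        r1e = sub["r1_end"].to_numpy()
        r2s = sub["r2_start"].to_numpy()
        r2e = sub["r2_end"].to_numpy()
        left_is_r1 = r1s <= r2s
        ls = np.where(left_is_r1, r1s, r2s)
        le = np.where(left_is_r1, r1e, r2e)
        rs = np.where(left_is_r1, r2s, r1s)
        re = np.where(left_is_r1, r2e, r1e)
        arr = np.column_stack([ls, le, rs, re]).astype(np.int64)
        for chrom, grp in zip(*_group_by_chrom(sub, arr)):
            parts.setdefault(chrom, []).append(grp)
    out: dict[str, np.ndarray] = {}
    for chrom, arrs in parts.items():
        merged = np.concatenate(arrs)
        merged = merged[np.argsort(merged[:, 0], kind="stable")]
        out[chrom] = merged
    return out


def _group_by_chrom(df: pd.DataFrame, arr: np.ndarray):
    chroms = df["chrom"].to_numpy()
    uniq = pd.unique(chroms)
    groups = [arr[chroms == c] for c in uniq]
    return list(uniq), groups


def count_window_support(
    ss_index: Mapping[str, np.ndarray],
    chromosome: str,
    left_window: tuple[int, int],
    right_window: tuple[int, int],
    pad: float,
) -> int:
    """Count same-strand pairs whose leftmost read lies inside the padded
    left window and rightmost read inside the padded right window."""
    arr = ss_index.get(chromosome)
    if arr is None or len(arr) == 0:
        return 0
    lla, llb = left_window[0] - pad, left_window[1] + pad
    rra, rrb = right_window[0] - pad, right_window[1] + pad
    i0 = int(np.searchsorted(arr[:, 0], lla, side="left"))
    i1 = int(np.searchsorted(arr[:, 0], llb, side="right"))
    if i0 >= i1:
        return 0
    sub = arr[i0:i1]
    ok = (sub[:, 1] <= llb) & (sub[:, 2] >= rra) & (sub[:, 3] <= rrb)
    return int(ok.sum())


def split_clone_read_support(
    candidate: SplitClone | PairedSplitClones,
    ss_index: Mapping[str, np.ndarray],
    frag_stats: FragmentStats,
) -> int:
    """Same-strand pairs consistent with the candidate's breakpoints.

    For a lone split clone the windows are its two member intervals (the
    breakpoint lies at one edge of each); for a PSC they are the breakpoint
    intervals.  Windows are padded by mu_fragment + 3 sigma_fragment.
    """
    pad = frag_stats.mu_fragment + 3 * frag_stats.sigma_fragment
    if isinstance(candidate, PairedSplitClones):
        return count_window_support(
            ss_index, candidate.chromosome, candidate.left_bp, candidate.right_bp, pad
        )
    lw = (candidate.left.start, candidate.left.end)
    rw = (candidate.right.start, candidate.right.end)
    return count_window_support(ss_index, candidate.chromosome, lw, rw, pad)


def attach_support(
    candidates: Sequence[SplitClone] | Sequence[PairedSplitClones],
    ss_index: Mapping[str, np.ndarray],
    frag_stats: FragmentStats,
    *,
    discard_unsupported: bool = True,
):
    """Compute support for every candidate; drop those with support 0."""
    kept = []
    for cand in candidates:
        s = split_clone_read_support(cand, ss_index, frag_stats)
        if isinstance(cand, PairedSplitClones):
            cand.rp_support = s
        else:
            cand.support = s
        if s > 0 or not discard_unsupported:
            kept.append(cand)
    return kept


def pscs_to_bedpe(pscs: Iterable[PairedSplitClones]) -> str:
    """BEDPE text of PSCs (two breakpoint intervals, pools, support)."""
    lines = [
        "\t".join(
            map(
                str,
                (
                    p.chromosome,
                    p.left_bp[0],
                    p.left_bp[1],
                    p.chromosome,
                    p.right_bp[0],
                    p.right_bp[1],
                    f"{p.sc1.pool_id},{p.sc2.pool_id}",
                    p.rp_support,
                ),
            )
        )
        for p in pscs
    ]
    return "\n".join(lines) + ("\n" if lines else "")
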
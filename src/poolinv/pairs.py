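"""Read-pair ingestion and orientation classification.

Long-range sequencing experiments (pooled clone sequencing, barcoded
linked reads) deliver ordinary short paired-end reads; what makes them
long-range is the pool/barcode structure.  This module turns per-pool
alignment files (or one barcode-tagged file) into columnar tables of
mapped read pairs, estimates the fragment-size distribution, and
classifies every pair as

* ``concordant``       -- opposite strands, forward mate upstream, and an
  implied fragment length within three standard deviations of the mean;
  these reconstruct clone locations,
* ``same_strand``      -- both reads on the same strand: the read-pair
  signature of an inversion breakpoint,
* ``other_discordant`` -- everything else (wrong orientation or aberrant
  fragment size).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: classification labels
CONCORDANT = "concordant"
SAME_STRAND = "same_strand"
OTHER_DISCORDANT = "other_discordant"
PAIR_CLASSES = (CONCORDANT, SAME_STRAND, OTHER_DISCORDANT)

#: integer codes used in columnar tables
_CLASS_CODE = {CONCORDANT: 0, SAME_STRAND: 1, OTHER_DISCORDANT: 2}
_CODE_CLASS = {v: k for k, v in _CLASS_CODE.items()}

#: columns of the per-pool read-pair table; strands are +1 / -1 int8
PAIR_COLUMNS = (
    "chrom",
    "r1_start",
    "r1_end",
    "r2_start",
    "r2_end",
    "strand1",
    "strand2",
)


@dataclass(frozen=True)
class ReadPairRecord:
    """One mapped paired-end fragment, both mates on the same chromosome."""

    chromosome: str
    read1_start: int
    read1_end: int
    read2_start: int
    read2_end: int
    strand1: str  # '+' or '-'
    strand2: str
    pool_id: str = ""
    mapq_min: int = 0

    def __post_init__(self) -> None:
        if not (self.read1_start < self.read1_end and self.read2_start < self.read2_end):
            raise ValueError("read intervals must be non-empty with start < end")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError("strands must be '+' or '-'")

    @property
    def fragment_length(self) -> int:
        """Outer span: leftmost read start to rightmost read end."""
        return max(self.read1_end, self.read2_end) - min(self.read1_start, self.read2_start)


@dataclass(frozen=True)
class FragmentStats:
    """Mean and standard deviation of the sequenced fragment (insert) length."""

    mu_fragment: float
    sigma_fragment: float

    def __post_init__(self) -> None:
        if self.mu_fragment <= 0 or self.sigma_fragment < 0:
            raise ValueError("require mu_fragment > 0 and sigma_fragment >= 0")


@dataclass
class PoolSet:
    """Read pairs grouped by pool (one alignment file per pool, or one
    barcode tag value per pool in linked-read mode)."""

    pools: dict[str, pd.DataFrame]
    mode: str = "pcs"  # "pcs" or "linked_read"
    n_missing_barcode: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("pcs", "linked_read"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_pairs(self) -> int:
        return sum(len(df) for df in self.pools.values())

    def items(self) -> Iterator[tuple[str, pd.DataFrame]]:
        return iter(self.pools.items())


def records_to_frame(records: Iterable[ReadPairRecord]) -> pd.DataFrame:
    """Build a columnar pair table from scalar records."""
    rows = [
        (
            r.chromosome,
            r.read1_start,
            r.read1_end,
            r.read2_start,
            r.read2_end,
            1 if r.strand1 == "+" else -1,
            1 if r.strand2 == "+" else -1,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(PAIR_COLUMNS))


def empty_pair_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in PAIR_COLUMNS})
    return df.astype(
        {
            "chrom": object,
            "r1_start": np.int64,
            "r1_end": np.int64,
            "r2_start": np.int64,
            "r2_end": np.int64,
            "strand1": np.int8,
            "strand2": np.int8,
        }
    )


# ---------------------------------------------------------------------------
# alignment file ingestion
# ---------------------------------------------------------------------------


def _iter_alignment_pairs(path, min_mapq: int, barcode_tag: str | None):
    """Yield (barcode_or_None, pair_tuple) from one SAM/BAM/CRAM file.

    Keeps primary alignments of paired reads with both mates mapped to the
    same reference, mapq >= min_mapq on both mates, and no duplicate flag.
    Pairs are assembled by query name.  Returns the count of reads skipped
    for a missing barcode tag through the second element of the final
    StopIteration value; callers use :func:`_collect_pairs`.
    """
    import pysam

    pending: dict[str, tuple] = {}
    n_missing = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if (
                not aln.is_paired
                or aln.is_unmapped
                or aln.mate_is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_duplicate
            ):
                continue
            if aln.reference_id != aln.next_reference_id:
                continue  # inter-chromosomal pairs are out of scope
            if aln.mapping_quality < min_mapq:
                continue
            bc = None
            if barcode_tag is not None:
                if not aln.has_tag(barcode_tag):
                    n_missing += 1
                    continue
                bc = str(aln.get_tag(barcode_tag))
            key = aln.query_name
            rec = (
                aln.reference_name,
                int(aln.reference_start),
                int(aln.reference_end),
                -1 if aln.is_reverse else 1,
                aln.is_read1,
                bc,
            )
            mate = pending.pop(key, None)
            if mate is None:
                pending[key] = rec
                continue
            first, second = (rec, mate) if rec[4] else (mate, rec)
            if barcode_tag is not None and first[5] != second[5]:
                n_missing += 1
                continue
            yield first[5], (
                first[0],
                first[1],
                first[2],
                second[1],
                second[2],
                first[3],
                second[3],
            )
    if pending:
        logger.debug("%d unpaired reads discarded", len(pending))
    if n_missing:
        logger.warning("%d reads skipped for missing/mismatched barcode tag", n_missing)
    # stash for the caller (generators cannot easily return values here)
    _iter_alignment_pairs.last_missing = n_missing  # type: ignore[attr-defined]


def _rows_to_frame(rows: list[tuple]) -> pd.DataFrame:
    if not rows:
        return empty_pair_frame()
    df = pd.DataFrame(
        rows,
        columns=list(PAIR_COLUMNS),
    )
    for col in ("r1_start", "r1_end", "r2_start", "r2_end"):
        df[col] = df[col].astype(np.int64)
    df["strand1"] = df["strand1"].astype(np.int8)
    df["strand2"] = df["strand2"].astype(np.int8)
    return df


def load_pools(
    paths: Sequence | None = None,
    *,
    barcode_file=None,
    mode: str = "pcs",
    barcode_tag: str = "BX",
    min_mapq: int = 1,
) -> PoolSet:
    """Load per-pool alignment files (``pcs`` mode) or demultiplex one
    barcode-tagged file into pools (``linked_read`` mode).

    Only primary alignments of pairs with both mates mapped to the same
    chromosome, mapq >= ``min_mapq`` and no duplicate flag are kept.
    """
    if mode == "pcs":
        if not paths:
            raise ValueError("pcs mode requires a list of per-pool alignment files")
        pools: dict[str, pd.DataFrame] = {}
        for p in paths:
            pool_id = Path(p).stem
            rows = [pair for _, pair in _iter_alignment_pairs(p, min_mapq, None)]
            pools[pool_id] = _rows_to_frame(rows)
            logger.info("pool %s: %d read pairs", pool_id, len(rows))
        return PoolSet(pools=pools, mode="pcs")
    if mode == "linked_read":
        if barcode_file is None:
            raise ValueError("linked_read mode requires barcode_file")
        by_bc: dict[str, list[tuple]] = {}
        for bc, pair in _iter_alignment_pairs(barcode_file, min_mapq, barcode_tag):
            by_bc.setdefault(bc, []).append(pair)
        n_missing = getattr(_iter_alignment_pairs, "last_missing", 0)
        pools = {bc: _rows_to_frame(rows) for bc, rows in sorted(by_bc.items())}
        return PoolSet(pools=pools, mode="linked_read", n_missing_barcode=n_missing)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# fragment-size statistics
# ---------------------------------------------------------------------------


def fragment_lengths(df: pd.DataFrame) -> np.ndarray:
    """Outer fragment span of every pair in the table."""
    lo = np.minimum(df["r1_start"].to_numpy(), df["r2_start"].to_numpy())
    hi = np.maximum(df["r1_end"].to_numpy(), df["r2_end"].to_numpy())
    return hi - lo


def estimate_fragment_stats(
    pairs: pd.DataFrame | Iterable[pd.DataFrame],
    max_sample: int = 200_000,
    min_pairs: int = 100,
) -> FragmentStats:
    """Estimate (mu, sigma) of the fragment length from opposite-strand pairs.

    One round of 3-sigma outlier trimming makes the estimate robust to
    discordant pairs contaminating the sample.
    """
    if isinstance(pairs, pd.DataFrame):
        frames: Iterable[pd.DataFrame] = [pairs]
    else:
        frames = pairs
    samples: list[np.ndarray] = []
    n = 0
    for df in frames:
        opp = df[df["strand1"].to_numpy() != df["strand2"].to_numpy()]
        if len(opp):
            samples.append(fragment_lengths(opp))
            n += len(opp)
        if n >= max_sample:
            break
    if n < min_pairs:
        raise ValueError(
            f"only {n} opposite-strand pairs available (need >= {min_pairs}); "
            "supply mu_fragment/sigma_fragment via config instead"
        )
    x = np.concatenate(samples)[:max_sample].astype(float)
    mu, sd = x.mean(), x.std(ddof=1)
    if sd > 0:
        keep = np.abs(x - mu) <= 3 * sd
        x = x[keep]
        mu = x.mean()
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
    return FragmentStats(mu_fragment=float(mu), sigma_fragment=float(sd))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_frame(df: pd.DataFrame, stats: FragmentStats) -> np.ndarray:
    """Vectorised pair classification; returns int8 codes 0/1/2
    (concordant / same_strand / other_discordant)."""
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    same = s1 == s2

    r1s = df["r1_start"].to_numpy()
    r2s = df["r2_start"].to_numpy()
    # strand of the leftmost read; ties resolved by read1 first
    left_is_r1 = r1s <= r2s
    left_strand = np.where(left_is_r1, s1, s2)
    right_strand = np.where(left_is_r1, s2, s1)
    fr = (left_strand == 1) & (right_strand == -1)

    frag = fragment_lengths(df)
    lo = stats.mu_fragment - 3 * stats.sigma_fragment
    hi = stats.mu_fragment + 3 * stats.sigma_fragment
    size_ok = (frag >= lo) & (frag <= hi)

    codes = np.full(len(df), _CLASS_CODE[OTHER_DISCORDANT], dtype=np.int8)
    codes[same] = _CLASS_CODE[SAME_STRAND]
    codes[~same & fr & size_ok] = _CLASS_CODE[CONCORDANT]
    return codes


def classify_pair(pair: ReadPairRecord, stats: FragmentStats) -> str:
    """Classify a single read pair (total function; see module docstring)."""
    df = records_to_frame([pair])
    return _CODE_CLASS[int(classify_frame(df, stats)[0])]


def class_counts(codes: np.ndarray) -> dict[str, int]:
    out = {name: 0 for name in PAIR_CLASSES}
    vals, counts = np.unique(codes, return_counts=True)
    for v, c in zip(vals, counts):
        out[_CODE_CLASS[int(v)]] = int(c)
    return out
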
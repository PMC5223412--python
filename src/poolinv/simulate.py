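"""Synthetic long-range sequencing experiments with implanted inversions.

The generator emulates the pooled-clone simulation protocol the pipeline
is benchmarked against: a random genome, a donor carrying implanted
inversions (reverse-complemented segments, optionally diploid with
overlapping events on opposite haplotypes), pools of clones with
normally distributed lengths at a stated *physical* coverage, and
paired-end fragments at a stated *sequence* coverage per pool.

Two read modes are provided.  ``ideal_mapping`` maps each read end
analytically through the known inversion coordinate transform and yields
reference-coordinate pair tables directly, so no external aligner is
needed; reads crossing a breakpoint junction are dropped as unmappable.
``fastq`` emits per-pool FASTQ files with donor-derived sequences for
use with a real aligner.

Default parameters follow the fosmid protocol: 300 pools of clones
N(40 Kbp, 10 Kbp) at 5X physical coverage, 150 bp reads, fragments
N(600 bp, 60 bp) at 10X sequence coverage per pool.  The genome itself
is scaled to desk size (tens of Mbp).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .pairs import PAIR_COLUMNS

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b


@dataclass
class SimConfig:
    genome_length: int = 40_000_000
    n_chromosomes: int = 1
    n_inversions: int = 40
    inv_size_range: tuple[int, int] = (500, 10_000_000)
    inv_sizes: Sequence[int] | None = None  # explicit sizes override the range
    diploid: bool = False
    overlap_fraction: float = 0.0  # fraction of inversions intersecting another
    hom_fraction: float = 0.3  # homozygous fraction when diploid
    n_pools: int = 300
    mu_clone: int = 40_000
    sigma_clone: int = 10_000
    physical_coverage: float = 5.0
    read_length: int = 150
    mu_fragment: int = 600
    sigma_fragment: int = 60
    read_coverage: float = 10.0
    min_breakpoint_clones: int = 0  # guarantee clones spanning every breakpoint
    min_inversion_gap: int | None = None  # default: 2 * mu_clone
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes <= 0 or self.n_pools <= 0:
            raise ValueError("genome_length, n_chromosomes and n_pools must be positive")
        if self.inv_sizes is None:
            a, b = self.inv_size_range
            if not 0 < a <= b < self.genome_length:
                raise ValueError("inv_size_range must lie within (0, genome_length)")
        if self.overlap_fraction and not self.diploid:
            raise ValueError("overlapping inversions require diploid=True")

    @property
    def inversion_gap(self) -> int:
        return self.min_inversion_gap if self.min_inversion_gap is not None else 2 * self.mu_clone


@dataclass
class TruthInversion:
    chromosome: str
    start: int
    end: int
    haplotype: str = "both"  # "1", "2" or "both"
    clone_covered: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("inversion must be non-empty")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class Donor:
    """Chromosome lengths plus, per (chromosome, haplotype), the sorted
    disjoint inverted segments.  Haplotype 0 denotes a homozygous genome."""

    chrom_lengths: dict[str, int]
    inversions: dict[tuple[str, int], np.ndarray]  # (k, 2) sorted arrays
    truth: list[TruthInversion]
    haplotypes: tuple[int, ...] = (0,)

    def boundaries(self, chrom: str, hap: int) -> np.ndarray:
        segs = self.inversions.get((chrom, hap))
        if segs is None or len(segs) == 0:
            return np.empty(0, dtype=np.int64)
        return segs.reshape(-1)


# ---------------------------------------------------------------------------
# donor construction
# ---------------------------------------------------------------------------


def _sample_sizes(config: SimConfig, rng: np.random.Generator, capacity: int) -> np.ndarray:
    if config.inv_sizes is not None:
        sizes = np.asarray(config.inv_sizes, dtype=np.int64)
        if len(sizes) != config.n_inversions:
            raise ValueError("inv_sizes length must equal n_inversions")
        return sizes
    a, b = config.inv_size_range
    for _ in range(50):
        sizes = np.exp(rng.uniform(math.log(a), math.log(b), size=config.n_inversions))
        sizes = sizes.astype(np.int64)
        if sizes.sum() <= 0.7 * capacity:
            return sizes
    raise ValueError(
        "could not place inversions: reduce n_inversions or the inversion size range"
    )


def _place_on_chrom(sizes: np.ndarray, length: int, gap: int, rng: np.random.Generator) -> np.ndarray:
    """Place sizes left-to-right with gaps >= ``gap``; remaining slack is
    distributed randomly.  Returns (k, 2) start/end array."""
    k = len(sizes)
    occupied = int(sizes.sum()) + (k + 1) * gap
    free = length - occupied
    if free < 0:
        raise ValueError(
            "could not place inversions on a chromosome: reduce n_inversions "
            "or inversion sizes"
        )
    extra = rng.dirichlet(np.ones(k + 1)) * free if k else np.array([free])
    out = np.empty((k, 2), dtype=np.int64)
    pos = 0
    for i in range(k):
        pos += gap + int(extra[i])
        out[i] = (pos, pos + sizes[i])
        pos += int(sizes[i])
    return out


def simulate_donor(config: SimConfig, rng: np.random.Generator | None = None) -> Donor:
    """Build the donor: place inversions, assign haplotypes, record truth.

    Deterministic given ``config.rng_seed`` (or a supplied generator).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    per = config.genome_length // config.n_chromosomes
    chrom_lengths = {f"chr{i + 1}": per for i in range(config.n_chromosomes)}
    haplotypes = (1, 2) if config.diploid else (0,)

    n = config.n_inversions
    n_olap = int(round(config.overlap_fraction * n))
    n_pairs = n_olap // 2
    n_base = n - n_pairs

    sizes = _sample_sizes(replace(config, n_inversions=n), rng, config.genome_length)
    base_sizes = sizes[:n_base]
    partner_sizes = sizes[n_base:]

    # distribute base inversions over chromosomes proportionally to capacity
    chroms = list(chrom_lengths)
    order = rng.permutation(n_base)
    base_sizes = base_sizes[order]
    assign = np.sort(rng.integers(0, len(chroms), size=n_base)) if len(chroms) > 1 else np.zeros(n_base, dtype=int)

    truth: list[TruthInversion] = []
    placed: list[tuple[str, int, int]] = []  # (chrom, start, end) of base events
    inv_per_hap: dict[tuple[str, int], list[tuple[int, int]]] = {
        (c, h): [] for c in chroms for h in haplotypes
    }
    gap = config.inversion_gap
    for ci, chrom in enumerate(chroms):
        mask = assign == ci
        s = base_sizes[mask]
        coords = _place_on_chrom(s, chrom_lengths[chrom], gap, rng)
        for (a, b) in coords:
            if config.diploid:
                if rng.random() < config.hom_fraction:
                    hap_label = "both"
                    haps = (1, 2)
                else:
                    h = int(rng.integers(1, 3))
                    hap_label = str(h)
                    haps = (h,)
            else:
                hap_label = "both"
                haps = (0,)
            truth.append(TruthInversion(chrom, int(a), int(b), hap_label))
            placed.append((chrom, int(a), int(b)))
            for h in haps:
                inv_per_hap[(chrom, h)].append((int(a), int(b)))

    # overlapping partners: placed on the opposite haplotype of a het base
    het_idx = [i for i, t in enumerate(truth) if t.haplotype in ("1", "2")]
    rng.shuffle(het_idx)
    for k in range(min(n_pairs, len(het_idx))):
        t = truth[het_idx[k]]
        size = int(partner_sizes[k]) if k < len(partner_sizes) else t.size
        size = min(size, t.size + gap // 3)
        lo = max(t.start - gap // 3, 0)
        hi = t.end + gap // 3 - size
        if hi <= lo:
            start = lo
        else:
            start = int(rng.integers(lo, hi))
        # force a genuine intersection with the base event
        start = min(max(start, t.start - size + 1), t.end - 1)
        start = max(start, 0)
        other = "2" if t.haplotype == "1" else "1"
        truth.append(TruthInversion(t.chromosome, start, start + size, other))
        inv_per_hap[(t.chromosome, int(other))].append((start, start + size))

    inversions = {
        key: np.asarray(sorted(ivals), dtype=np.int64).reshape(-1, 2)
        for key, ivals in inv_per_hap.items()
        if ivals
    }
    for key, arr in inversions.items():
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise AssertionError("per-haplotype inversions must be disjoint")
    truth.sort(key=lambda t: (t.chromosome, t.start))
    return Donor(chrom_lengths=chrom_lengths, inversions=inversions, truth=truth, haplotypes=haplotypes)


def truth_to_bed(truth: Sequence[TruthInversion]) -> str:
    lines = [
        f"{t.chromosome}\t{t.start}\t{t.end}\thap_{t.haplotype}\t{int(t.clone_covered)}"
        for t in truth
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def intersecting_fraction(truth: Sequence[TruthInversion]) -> float:
    """Fraction of inversions that intersect at least one other inversion."""
    hit = [False] * len(truth)
    for i, a in enumerate(truth):
        for j in range(i + 1, len(truth)):
            b = truth[j]
            if a.chromosome == b.chromosome and a.start < b.end and b.start < a.end:
                hit[i] = hit[j] = True
    return sum(hit) / len(truth) if truth else 0.0


# ---------------------------------------------------------------------------
# clone pools
# ---------------------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float, n: int, lo: float, hi: float) -> np.ndarray:
    """Normal(mu, sigma) resampled into [lo, hi] (+-3 sigma by default use)."""
    x = rng.normal(mu, sigma, size=n)
    bad = (x < lo) | (x > hi)
    for _ in range(100):
        if not bad.any():
            break
        x[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return np.clip(x, lo, hi)


def simulate_pools(donor: Donor, config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample clone intervals (donor coordinates) and assign them to pools.

    Clone count is chosen so the expected total clone bases equal
    physical_coverage x genome length.  Sets ``clone_covered`` on the
    truth records (both breakpoints spanned by at least one
    haplotype-compatible clone).
    """
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    total_len = sum(donor.chrom_lengths.values())
    n_clones = int(round(config.physical_coverage * total_len / config.mu_clone))
    lo = max(config.mu_clone - 3 * config.sigma_clone, 2 * config.read_length + 1)
    hi = config.mu_clone + 3 * config.sigma_clone
    lengths = _truncated_normal(rng, config.mu_clone, config.sigma_clone, n_clones, lo, hi).astype(np.int64)

    chroms = list(donor.chrom_lengths)
    weights = np.array([donor.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_clones, p=weights / weights.sum())
    clens = np.array([donor.chrom_lengths[chroms[i]] for i in chrom_idx])
    lengths = np.minimum(lengths, clens)
    starts = (rng.random(n_clones) * (clens - lengths)).astype(np.int64)
    haps = (
        rng.integers(1, 3, size=n_clones)
        if donor.haplotypes != (0,)
        else np.zeros(n_clones, dtype=np.int64)
    )
    pools = rng.integers(0, config.n_pools, size=n_clones)

    rows = {
        "chrom": [chroms[i] for i in chrom_idx],
        "hap": haps,
        "start": starts,
        "end": starts + lengths,
        "pool": pools,
    }
    df = pd.DataFrame(rows)

    if config.min_breakpoint_clones > 0:
        df = _guarantee_breakpoint_clones(df, donor, config, rng)

    _flag_clone_coverage(df, donor)
    return df


def _donor_breakpoints(t: TruthInversion) -> tuple[int, int]:
    # inversions preserve segment boundaries, so breakpoints sit at the
    # same coordinates in donor and reference space
    return t.start, t.end


def _hap_compatible(clone_hap: int, t: TruthInversion) -> bool:
    if clone_hap == 0 or t.haplotype == "both":
        return True
    return str(clone_hap) == t.haplotype


def _guarantee_breakpoint_clones(
    df: pd.DataFrame, donor: Donor, config: SimConfig, rng: np.random.Generator, flank: int = 5_000
) -> pd.DataFrame:
    """Top up clones so >= min_breakpoint_clones span each breakpoint with
    comfortable flanks (emulating a run where, by chance, clone coverage
    exists over every breakpoint)."""
    lo = max(config.mu_clone - 3 * config.sigma_clone, 2 * config.read_length + 1, 2 * flank + 1)
    hi = config.mu_clone + 3 * config.sigma_clone
    extra = {k: [] for k in ("chrom", "hap", "start", "end", "pool")}
    for t in donor.truth:
        for bp in _donor_breakpoints(t):
            sub = df[(df["chrom"] == t.chromosome)]
            spans = (
                (sub["start"] + flank <= bp)
                & (sub["end"] - flank >= bp)
                & sub["hap"].map(lambda h, t=t: _hap_compatible(int(h), t))
            )
            need = config.min_breakpoint_clones - int(spans.sum())
            for _ in range(max(need, 0)):
                ln = int(_truncated_normal(rng, config.mu_clone, config.sigma_clone, 1, lo, hi)[0])
                off = int(rng.integers(flank, ln - flank))
                start = max(bp - off, 0)
                end = min(start + ln, donor.chrom_lengths[t.chromosome])
                if donor.haplotypes == (0,):
                    hap = 0
                elif t.haplotype == "both":
                    hap = int(rng.integers(1, 3))
                else:
                    hap = int(t.haplotype)
                extra["chrom"].append(t.chromosome)
                extra["hap"].append(hap)
                extra["start"].append(start)
                extra["end"].append(end)
                extra["pool"].append(int(rng.integers(0, config.n_pools)))
    if extra["chrom"]:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    return df


def _flag_clone_coverage(df: pd.DataFrame, donor: Donor) -> None:
    for t in donor.truth:
        sub = df[df["chrom"] == t.chromosome]
        covered = True
        for bp in _donor_breakpoints(t):
            spans = (sub["start"] < bp) & (sub["end"] > bp)
            spans &= sub["hap"].map(lambda h, t=t: _hap_compatible(int(h), t))
            if not bool(spans.any()):
                covered = False
                break
        t.clone_covered = covered


def clones_to_bed(df: pd.DataFrame) -> str:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\tpool_{r.pool}\thap_{r.hap}"
        for r in df.itertuples()
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# reads: ideal mapping
# ---------------------------------------------------------------------------


def map_intervals(
    bounds: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map donor intervals to reference coordinates through the inversion
    reflection x -> inv_start + inv_end - x.

    Returns (mapped_start, mapped_end, flipped, mappable); intervals
    crossing a segment junction are unmappable.
    """
    i1 = np.searchsorted(bounds, starts, side="right")
    i2 = np.searchsorted(bounds, ends - 1, side="right")
    ok = i1 == i2
    flipped = ok & (i1 % 2 == 1)
    ms = starts.copy()
    me = ends.copy()
    if flipped.any():
        a = bounds[i1[flipped] - 1]
        b = bounds[i1[flipped]]
        ms[flipped] = a + b - ends[flipped]
        me[flipped] = a + b - starts[flipped]
    return ms, me, flipped, ok


@dataclass
class ReadSimReport:
    n_pairs: int = 0
    n_dropped_junction: int = 0
    n_clones_skipped: int = 0


def _pool_fragments(
    clones: pd.DataFrame, config: SimConfig, rng: np.random.Generator, report: ReadSimReport
):
    """Sample fragments for one pool; returns (chrom codes, hap, frag
    start, frag length) arrays in donor coordinates."""
    lens = (clones["end"] - clones["start"]).to_numpy()
    usable = lens >= 2 * config.read_length
    report.n_clones_skipped += int((~usable).sum())
    clones = clones[usable]
    lens = lens[usable]
    if clones.empty:
        return None
    lam = config.read_coverage * lens / (2 * config.read_length)
    n_per = rng.poisson(lam)
    total = int(n_per.sum())
    if total == 0:
        return None
    idx = np.repeat(np.arange(len(clones)), n_per)
    clone_start = clones["start"].to_numpy()[idx]
    clone_len = lens[idx]
    flen = _truncated_normal(
        rng,
        config.mu_fragment,
        config.sigma_fragment,
        total,
        2 * config.read_length,
        config.mu_fragment + 3 * config.sigma_fragment,
    ).astype(np.int64)
    flen = np.minimum(flen, clone_len)
    fstart = clone_start + (rng.random(total) * (clone_len - flen)).astype(np.int64)
    return clones["chrom"].to_numpy()[idx], clones["hap"].to_numpy()[idx], fstart, flen


def ideal_pair_frames(
    clones: pd.DataFrame,
    donor: Donor,
    config: SimConfig,
    rng_seed: int | None = None,
    report: ReadSimReport | None = None,
) -> Iterator[tuple[str, pd.DataFrame]]:
    """Yield (pool_id, reference-coordinate pair table) per pool.

    Read 1 sits at the fragment start on the forward donor strand, read 2
    at the fragment end on the reverse strand; both ends are pushed through
    the inversion transform and pairs with an unmappable end are dropped.
    """
    seed = config.rng_seed + 2 if rng_seed is None else rng_seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_pools)
    report = ReadSimReport() if report is None else report
    rl = config.read_length
    for pool in range(config.n_pools):
        rng = np.random.default_rng(children[pool])
        sub = clones[clones["pool"] == pool]
        frags = _pool_fragments(sub, config, rng, report)
        rows = []
        if frags is not None:
            chroms, haps, fstart, flen = frags
            for chrom in pd.unique(chroms):
                for hap in np.unique(haps[chroms == chrom]):
                    m = (chroms == chrom) & (haps == hap)
                    fs, fl = fstart[m], flen[m]
                    bounds = donor.boundaries(str(chrom), int(hap))
                    r1s, r1e = fs, fs + rl
                    r2s, r2e = fs + fl - rl, fs + fl
                    m1s, m1e, f1, ok1 = map_intervals(bounds, r1s, r1e)
                    m2s, m2e, f2, ok2 = map_intervals(bounds, r2s, r2e)
                    keep = ok1 & ok2
                    report.n_dropped_junction += int((~keep).sum())
                    s1 = np.where(f1[keep], -1, 1).astype(np.int8)
                    s2 = np.where(f2[keep], 1, -1).astype(np.int8)
                    rows.append(
                        pd.DataFrame(
                            {
                                "chrom": str(chrom),
                                "r1_start": m1s[keep],
                                "r1_end": m1e[keep],
                                "r2_start": m2s[keep],
                                "r2_end": m2e[keep],
                                "strand1": s1,
                                "strand2": s2,
                            }
                        )
                    )
        if rows:
            frame = pd.concat(rows, ignore_index=True)
        else:
            frame = pd.DataFrame({c: [] for c in PAIR_COLUMNS})
        report.n_pairs += len(frame)
        yield f"pool_{pool}", frame


def simulate_read_pairs(
    clones: pd.DataFrame,
    donor: Donor,
    config: SimConfig,
    mode: str = "ideal_mapping",
    out_dir=None,
    reference=None,
    error_rate: float = 0.0,
) -> dict[str, pd.DataFrame] | list[Path]:
    """Materialise the read simulation.

    ``ideal_mapping`` returns {pool_id: pair table} (or writes per-pool TSV
    tables under ``out_dir``); ``fastq`` writes per-pool paired FASTQ files
    and requires a ``reference`` from :func:`simulate_reference_sequences`.
    """
    if mode == "ideal_mapping":
        frames = dict(ideal_pair_frames(clones, donor, config))
        if out_dir is None:
            return frames
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for pool_id, df in frames.items():
            p = out_dir / f"{pool_id}.pairs.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        return paths
    if mode == "fastq":
        if out_dir is None or reference is None:
            raise ValueError("fastq mode requires out_dir and reference sequences")
        return _write_fastq_pools(clones, donor, config, Path(out_dir), reference, error_rate)
    raise ValueError(f"unknown read simulation mode {mode!r}")


# ---------------------------------------------------------------------------
# sequences (fastq mode and FASTA export)
# ---------------------------------------------------------------------------


def simulate_reference_sequences(
    donor: Donor, rng_seed: int, fasta_path=None
) -> dict[str, np.ndarray]:
    """Uniform-random reference sequences as uint8 ASCII arrays."""
    rng = np.random.default_rng(rng_seed)
    seqs = {
        chrom: _BASES[rng.integers(0, 4, size=length)]
        for chrom, length in donor.chrom_lengths.items()
    }
    if fasta_path is not None:
        write_fasta(seqs, fasta_path)
    return seqs


def donor_haplotype_sequence(reference: dict[str, np.ndarray], donor: Donor, chrom: str, hap: int) -> np.ndarray:
    """Reference with each inverted segment reverse-complemented."""
    seq = reference[chrom].copy()
    segs = donor.inversions.get((chrom, hap))
    if segs is not None:
        for a, b in segs:
            seq[a:b] = _COMPLEMENT[seq[a:b][::-1]]
    return seq


def write_fasta(seqs: dict[str, np.ndarray], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width] + "\n")


def _write_fastq_pools(clones, donor, config, out_dir, reference, error_rate) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    rl = config.read_length
    hapseqs = {
        key: donor_haplotype_sequence(reference, donor, key[0], key[1])
        for key in (
            {(c, h) for c in donor.chrom_lengths for h in donor.haplotypes}
        )
    }
    ss = np.random.SeedSequence(config.rng_seed + 2)
    children = ss.spawn(config.n_pools)
    report = ReadSimReport()
    paths = []
    for pool in range(config.n_pools):
        rng = np.random.default_rng(children[pool])
        sub = clones[clones["pool"] == pool]
        frags = _pool_fragments(sub, config, rng, report)
        p1 = out_dir / f"pool_{pool}_1.fastq"
        p2 = out_dir / f"pool_{pool}_2.fastq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            if frags is not None:
                chroms, haps, fstart, flen = frags
                for k in range(len(fstart)):
                    seq = hapseqs[(str(chroms[k]), int(haps[k]))]
                    s, L = int(fstart[k]), int(flen[k])
                    r1 = seq[s : s + rl].copy()
                    r2 = _COMPLEMENT[seq[s + L - rl : s + L][::-1]].copy()
                    for arr in (r1, r2):
                        if error_rate > 0:
                            err = rng.random(rl) < error_rate
                            if err.any():
                                arr[err] = _BASES[rng.integers(0, 4, size=int(err.sum()))]
                    name = f"pool{pool}_frag{k}"
                    f1.write(f"@{name}/1\n{r1.tobytes().decode()}\n+\n{'I' * rl}\n")
                    f2.write(f"@{name}/2\n{r2.tobytes().decode()}\n+\n{'I' * rl}\n")
        paths.extend([p1, p2])
    return paths
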
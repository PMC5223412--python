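"""Shared fixtures and object factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from poolinv.clones import InferredClone
from poolinv.pairs import FragmentStats, ReadPairRecord
from poolinv.splitclones import PairedSplitClones, SplitClone


@pytest.fixture
def frag600() -> FragmentStats:
    return FragmentStats(mu_fragment=600, sigma_fragment=60)


def mk_pair(
    r1=(1000, 1150),
    r2=(1400, 1550),
    strands=("+", "-"),
    chrom="chr1",
    pool="p0",
) -> ReadPairRecord:
    return ReadPairRecord(
        chromosome=chrom,
        read1_start=r1[0],
        read1_end=r1[1],
        read2_start=r2[0],
        read2_end=r2[1],
        strand1=strands[0],
        strand2=strands[1],
        pool_id=pool,
    )


def mk_clone(start, end, pool="p0", chrom="chr1", n_pairs=10) -> InferredClone:
    return InferredClone(
        chromosome=chrom,
        start=start,
        end=end,
        pool_id=pool,
        n_pairs=n_pairs,
        covered_bases=end - start,
        breadth=1.0,
        depth=10.0,
    )


def mk_split_clone(left, right, pool="p0", chrom="chr1") -> SplitClone:
    lc = mk_clone(*left, pool=pool, chrom=chrom)
    rc = mk_clone(*right, pool=pool, chrom=chrom)
    return SplitClone(left=lc, right=rc, pool_id=pool, separation=rc.start - lc.start)


def mk_psc(left_bp, right_bp, pools=("p1", "p2"), chrom="chr1", support=1) -> PairedSplitClones:
    """Build a PSC whose breakpoint envelopes equal the given half-open
    intervals exactly."""
    la, lb = left_bp
    ra, rb = right_bp
    piece = 30_000
    sc1 = mk_split_clone((la - piece, la), (ra, ra + piece), pool=pools[0], chrom=chrom)
    sc2 = mk_split_clone((lb - 1 - piece, lb - 1), (rb - 1, rb - 1 + piece), pool=pools[1], chrom=chrom)
    psc = PairedSplitClones(sc1=sc1, sc2=sc2)
    psc.rp_support = support
    assert psc.left_bp == (min(la, lb - 1), max(la, lb - 1) + 1)
    assert psc.right_bp == (min(ra, rb - 1), max(ra, rb - 1) + 1)
    return psc
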
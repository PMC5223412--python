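"""Call refinement, support recalculation, filtering and serialisation."""

from __future__ import annotations

import numpy as np
import pytest

from poolinv.calls import (
    GAP_OVERLAP,
    LOW_SUPPORT,
    SD_BOTH_BREAKPOINTS,
    InversionCall,
    filter_calls,
    read_bed,
    read_calls,
    recalculate_support,
    refine_breakpoints,
    write_calls,
)
from poolinv.pairs import FragmentStats, records_to_frame
from poolinv.splitclones import build_same_strand_index

from conftest import mk_pair, mk_psc


def test_refine_intersection():
    a = mk_psc((1_000_000, 1_020_000), (3_000_000, 3_030_000), pools=("p1", "p2"))
    b = mk_psc((1_010_000, 1_030_000), (3_010_000, 3_040_000), pools=("p3", "p4"))
    call = refine_breakpoints([a, b])
    assert call.left_bp == (1_010_000, 1_020_000)
    assert call.right_bp == (3_010_000, 3_030_000)
    assert call.n_psc == 2 and call.n_pools == 4


def test_refine_idempotent_on_identical_members():
    a = mk_psc((1_000_000, 1_020_000), (3_000_000, 3_030_000), pools=("p1", "p2"))
    b = mk_psc((1_000_000, 1_020_000), (3_000_000, 3_030_000), pools=("p3", "p4"))
    call = refine_breakpoints([a, b])
    assert call.left_bp == (1_000_000, 1_020_000)
    assert call.right_bp == (3_000_000, 3_030_000)


def test_refine_outlier_fallback_narrows():
    """With one disjoint outlier interval, refinement falls back to the two
    highest-support members; the result is no wider than their envelope."""
    a = mk_psc((1_000_000, 1_020_000), (3_000_000, 3_030_000), pools=("p1", "p2"), support=5)
    b = mk_psc((1_005_000, 1_025_000), (3_005_000, 3_035_000), pools=("p3", "p4"), support=4)
    out = mk_psc((1_050_000, 1_070_000), (3_000_000, 3_030_000), pools=("p5", "p6"), support=1)
    call = refine_breakpoints([a, b, out])
    assert call.left_bp == (1_005_000, 1_020_000)  # from the two high-support members
    width = call.left_inner - call.left_outer
    assert width <= 20_000  # never wider than a member interval


def test_refine_rejects_mixed_chromosomes():
    a = mk_psc((1_000_000, 1_020_000), (3_000_000, 3_030_000), chrom="chr1")
    b = mk_psc((1_000_000, 1_020_000), (3_000_000, 3_030_000), chrom="chr2", pools=("p3", "p4"))
    with pytest.raises(ValueError, match="chromosome"):
        refine_breakpoints([a, b])


def _call(support=3, filters=None, left=(1_000_000, 1_010_000), right=(2_000_000, 2_010_000)):
    return InversionCall(
        chromosome="chr1",
        left_outer=left[0],
        left_inner=left[1],
        right_inner=right[0],
        right_outer=right[1],
        n_psc=3,
        n_pools=4,
        rp_support=support,
        filters=set(filters or []),
    )


def test_recalculate_support():
    frag = FragmentStats(600, 60)
    call = _call()
    inside = [
        mk_pair(r1=(1_005_000, 1_005_150), r2=(2_005_000, 2_005_150), strands=("+", "+")),
        mk_pair(r1=(1_009_000, 1_009_150), r2=(2_001_000, 2_001_150), strands=("-", "-")),
        mk_pair(r1=(1_000_500, 1_000_650), r2=(2_009_000, 2_009_150), strands=("+", "+")),
    ]
    idx = build_same_strand_index([records_to_frame(inside)])
    assert recalculate_support(call, idx, frag) == 3

    outside = [mk_pair(r1=(1_050_000, 1_050_150), r2=(2_005_000, 2_005_150), strands=("+", "+"))]
    idx = build_same_strand_index([records_to_frame(outside)])
    assert recalculate_support(call, idx, frag) == 0


def test_filter_low_support():
    kept, removed = filter_calls([_call(support=1)], min_support=2)
    assert kept == [] and removed[0].filters == {LOW_SUPPORT}


def test_filter_gap_overlap():
    gap = {"chr1": np.array([[1_010_000, 1_510_000]])}  # 50% of the inner span
    kept, removed = filter_calls([_call(right=(2_010_000, 2_020_000))], gap_track=gap)
    assert kept == [] and GAP_OVERLAP in removed[0].filters


def test_filter_sd_requires_both_breakpoints():
    sd_left_only = {"chr1": np.array([[1_000_000, 1_005_000]])}
    kept, removed = filter_calls([_call()], sd_track=sd_left_only)
    assert len(kept) == 1 and kept[0].filters == set()

    sd_both = {"chr1": np.array([[1_000_000, 1_005_000], [2_000_000, 2_005_000]])}
    kept, removed = filter_calls([_call()], sd_track=sd_both)
    assert kept == [] and removed[0].filters == {SD_BOTH_BREAKPOINTS}


def test_filter_monotone_in_min_support():
    calls = [_call(support=s) for s in (1, 2, 3, 5)]
    previous = None
    for threshold in (1, 2, 3, 4, 5, 6):
        kept, _ = filter_calls([_call(support=c.rp_support) for c in calls], min_support=threshold)
        if previous is not None:
            assert len(kept) <= previous
        previous = len(kept)


def test_read_bed_errors(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t100\t200\nchr1\tx\t300\n")
    with pytest.raises(ValueError, match="bad.bed:2"):
        read_bed(p)


def test_write_read_round_trip(tmp_path):
    calls = [_call(support=4), _call(support=7, left=(5_000_000, 5_010_000), right=(6_000_000, 6_020_000))]
    bed = tmp_path / "calls.bed"
    tsv = tmp_path / "calls.tsv"
    write_calls(calls, bed, detail_path=tsv)
    back = read_calls(tsv)
    assert [(c.chromosome, c.left_outer, c.left_inner, c.right_inner, c.right_outer, c.rp_support) for c in back] == [
        (c.chromosome, c.left_outer, c.left_inner, c.right_inner, c.right_outer, c.rp_support) for c in calls
    ]
    lines = bed.read_text().strip().split("\n")
    assert len(lines) == 3  # header + 2 calls


def test_write_empty_calls(tmp_path):
    bed = tmp_path / "calls.bed"
    tsv = tmp_path / "calls.tsv"
    write_calls([], bed, detail_path=tsv)
    assert bed.read_text().startswith("#chrom")
    assert read_calls(tsv) == []
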
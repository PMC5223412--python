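"""Alignment ingestion, fragment statistics, and pair classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolinv.pairs import (
    CONCORDANT,
    OTHER_DISCORDANT,
    SAME_STRAND,
    FragmentStats,
    classify_frame,
    classify_pair,
    class_counts,
    estimate_fragment_stats,
    load_pools,
    records_to_frame,
)

from conftest import mk_pair


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000000\n"


def _sam_pair(name, pos1, pos2, tag=None, unmapped_mate=False, mapq=60):
    """Two SAM lines for one 100 bp-read pair (FR orientation)."""
    t = f"\tBX:Z:{tag}" if tag else ""
    if unmapped_mate:
        l1 = f"{name}\t73\tchr1\t{pos1 + 1}\t{mapq}\t100M\t=\t{pos1 + 1}\t0\t*\t*{t}"
        l2 = f"{name}\t133\tchr1\t{pos1 + 1}\t0\t*\t=\t{pos1 + 1}\t0\t*\t*{t}"
    else:
        l1 = f"{name}\t97\tchr1\t{pos1 + 1}\t{mapq}\t100M\t=\t{pos2 + 1}\t0\t*\t*{t}"
        l2 = f"{name}\t145\tchr1\t{pos2 + 1}\t{mapq}\t100M\t=\t{pos1 + 1}\t0\t*\t*{t}"
    return l1 + "\n" + l2 + "\n"


def _write_sam(path, body):
    path.write_text(_HEADER + body)
    return path


def test_load_pools_counts_and_filters(tmp_path):
    """Two pool files with 10 and 20 pairs load as two pools of 30 records;
    a pair with an unmapped mate is excluded."""
    body_a = "".join(_sam_pair(f"a{i}", 1000 * i, 1000 * i + 500) for i in range(10))
    body_a += _sam_pair("bad", 50_000, 50_000, unmapped_mate=True)
    body_b = "".join(_sam_pair(f"b{i}", 2000 * i, 2000 * i + 500) for i in range(20))
    pa = _write_sam(tmp_path / "poolA.sam", body_a)
    pb = _write_sam(tmp_path / "poolB.sam", body_b)
    ps = load_pools([pa, pb], mode="pcs", min_mapq=1)
    assert set(ps.pools) == {"poolA", "poolB"}
    assert len(ps.pools["poolA"]) == 10
    assert len(ps.pools["poolB"]) == 20
    assert ps.n_pairs == 30


def test_load_pools_mapq_filter(tmp_path):
    body = _sam_pair("ok", 1000, 1500) + _sam_pair("multi", 3000, 3500, mapq=0)
    p = _write_sam(tmp_path / "pool.sam", body)
    ps = load_pools([p], mode="pcs", min_mapq=1)
    assert ps.n_pairs == 1


def test_linked_read_barcode_grouping(tmp_path):
    """Grouping by barcode then concatenating pools reproduces the input
    pair multiset; untagged reads are skipped and counted."""
    body = (
        _sam_pair("x1", 1000, 1500, tag="A")
        + _sam_pair("x2", 9000, 9600, tag="B")
        + _sam_pair("x3", 4000, 4550, tag="A")
        + _sam_pair("untagged", 7000, 7500)
    )
    p = _write_sam(tmp_path / "lr.sam", body)
    ps = load_pools(barcode_file=p, mode="linked_read", barcode_tag="BX")
    assert set(ps.pools) == {"A", "B"}
    assert len(ps.pools["A"]) == 2 and len(ps.pools["B"]) == 1
    assert ps.n_missing_barcode == 2  # both mates of the untagged pair
    all_starts = sorted(
        s for df in ps.pools.values() for s in df["r1_start"].tolist()
    )
    assert all_starts == [1000, 4000, 9000]


# ---------------------------------------------------------------------------
# fragment statistics
# ---------------------------------------------------------------------------


def _frames_from_fragments(fragments):
    pairs = [mk_pair(r1=(0, 150), r2=(f - 150, f)) for f in fragments]
    return records_to_frame(pairs)


def test_fragment_stats_constant():
    stats = estimate_fragment_stats(_frames_from_fragments([600] * 150))
    assert stats.mu_fragment == 600 and stats.sigma_fragment == 0


def test_fragment_stats_small_sample():
    stats = estimate_fragment_stats(
        _frames_from_fragments([590, 600, 610] * 50), min_pairs=100
    )
    assert stats.mu_fragment == pytest.approx(600)
    expected_sd = np.std([590, 600, 610] * 50, ddof=1)
    assert stats.sigma_fragment == pytest.approx(expected_sd, rel=1e-6)


def test_fragment_stats_monte_carlo():
    rng = np.random.default_rng(42)
    frags = rng.normal(600, 60, size=1000).astype(int)
    stats = estimate_fragment_stats(_frames_from_fragments(frags.tolist()))
    assert abs(stats.mu_fragment - 600) < 6


def test_fragment_stats_too_few_pairs():
    with pytest.raises(ValueError, match="config"):
        estimate_fragment_stats(_frames_from_fragments([600] * 10))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r1,r2,strands,expected",
    [
        # at the mean fragment size, FR orientation
        ((0, 150), (300, 450), ("+", "-"), CONCORDANT),
        # fragment 800 > 450 + 3*98 = 744
        ((0, 150), (650, 800), ("+", "-"), OTHER_DISCORDANT),
        # same strand regardless of size
        ((0, 150), (650, 800), ("+", "+"), SAME_STRAND),
        ((0, 150), (300, 450), ("-", "-"), SAME_STRAND),
        # reverse-forward at short range: wrong orientation
        ((0, 150), (300, 450), ("-", "+"), OTHER_DISCORDANT),
    ],
)
def test_classify_examples(r1, r2, strands, expected):
    stats = FragmentStats(450, 98)
    assert classify_pair(mk_pair(r1=r1, r2=r2, strands=strands), stats) == expected


@given(
    start1=st.integers(0, 10_000),
    len1=st.integers(50, 300),
    gap=st.integers(-200, 2000),
    len2=st.integers(50, 300),
    s1=st.sampled_from("+-"),
    s2=st.sampled_from("+-"),
)
@settings(max_examples=200, derandomize=True)
def test_classification_partition_and_swap_invariance(start1, len1, gap, len2, s1, s2):
    """Every pair gets exactly one class, and the class is invariant under
    swapping read1/read2."""
    stats = FragmentStats(600, 60)
    r2_start = start1 + len1 + gap
    pair = mk_pair(r1=(start1, start1 + len1), r2=(r2_start, r2_start + len2), strands=(s1, s2))
    cls = classify_pair(pair, stats)
    assert cls in (CONCORDANT, SAME_STRAND, OTHER_DISCORDANT)
    swapped = mk_pair(
        r1=(r2_start, r2_start + len2), r2=(start1, start1 + len1), strands=(s2, s1)
    )
    assert classify_pair(swapped, stats) == cls


def test_class_counts_partition(frag600):
    rng = np.random.default_rng(0)
    pairs = []
    for _ in range(200):
        a = int(rng.integers(0, 100_000))
        b = a + int(rng.integers(200, 1500))
        strands = tuple(rng.choice(["+", "-"], size=2))
        pairs.append(mk_pair(r1=(a, a + 150), r2=(b - 150, b), strands=strands))
    df = records_to_frame(pairs)
    counts = class_counts(classify_frame(df, frag600))
    assert sum(counts.values()) == len(df)
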
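"""Simulator: donor construction, clone pools, read generation, scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolinv.pairs import FragmentStats, classify_frame
from poolinv.evaluate import EvalReport, evaluate_calls, reciprocal_overlap
from poolinv.simulate import (
    SimConfig,
    TruthInversion,
    donor_haplotype_sequence,
    ideal_pair_frames,
    intersecting_fraction,
    map_intervals,
    simulate_donor,
    simulate_pools,
    simulate_read_pairs,
    simulate_reference_sequences,
)

_COMP = dict(zip("ACGT", "TGCA"))


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def test_no_inversions_donor_equals_reference():
    cfg = SimConfig(genome_length=50_000, n_inversions=0, inv_sizes=[], mu_clone=5_000,
                    sigma_clone=500, rng_seed=0)
    donor = simulate_donor(cfg)
    ref = simulate_reference_sequences(donor, 0)
    hap = donor_haplotype_sequence(ref, donor, "chr1", 0)
    assert donor.truth == []
    assert np.array_equal(ref["chr1"], hap)


def test_inverted_segment_is_reverse_complement():
    cfg = SimConfig(genome_length=200_000, n_inversions=1, inv_sizes=[30_000],
                    mu_clone=10_000, sigma_clone=1_000, rng_seed=1)
    donor = simulate_donor(cfg)
    t = donor.truth[0]
    ref = simulate_reference_sequences(donor, 1)
    hap = donor_haplotype_sequence(ref, donor, "chr1", 0)
    ref_seg = ref["chr1"][t.start : t.end].tobytes().decode()
    hap_seg = hap[t.start : t.end].tobytes().decode()
    assert hap_seg == _revcomp(ref_seg)
    # outside the inversion the donor matches the reference
    assert np.array_equal(ref["chr1"][: t.start], hap[: t.start])
    assert np.array_equal(ref["chr1"][t.end :], hap[t.end :])


def test_overlap_fraction_emulation():
    """With overlap_fraction ~0.37 the realised fraction of inversions that
    intersect another is close to the request."""
    cfg = SimConfig(
        genome_length=10_000_000, n_inversions=100, inv_size_range=(5_000, 20_000),
        diploid=True, overlap_fraction=0.37, mu_clone=10_000, sigma_clone=1_000,
        rng_seed=2,
    )
    donor = simulate_donor(cfg)
    assert len(donor.truth) == 100
    assert intersecting_fraction(donor.truth) == pytest.approx(0.37, abs=0.10)


def test_map_intervals_round_trip():
    """The donor->reference transform is an involution away from junctions,
    and junction-crossing intervals are unmappable."""
    bounds = np.array([10_000, 20_000, 50_000, 90_000])
    rng = np.random.default_rng(3)
    starts = rng.integers(0, 99_000, size=2_000)
    ends = starts + rng.integers(50, 500, size=2_000)
    ms, me, flipped, ok = map_intervals(bounds, starts, ends)
    ms2, me2, flipped2, ok2 = map_intervals(bounds, ms[ok], me[ok])
    assert np.array_equal(ms2, starts[ok])
    assert np.array_equal(me2, ends[ok])
    assert np.array_equal(flipped2, flipped[ok])
    # crossing interval: straddles the junction at 10_000
    _, _, _, okx = map_intervals(bounds, np.array([9_900]), np.array([10_100]))
    assert not okx[0]


def test_physical_coverage_and_clone_count():
    """Expected total clone bases match physical_coverage x genome length
    within 5% over 10 seeds."""
    totals = []
    for seed in range(10):
        cfg = SimConfig(genome_length=10_000_000, n_inversions=0, inv_sizes=[],
                        physical_coverage=5, mu_clone=40_000, sigma_clone=10_000,
                        rng_seed=seed)
        donor = simulate_donor(cfg)
        clones = simulate_pools(donor, cfg)
        assert abs(len(clones) - 1250) < 2  # 5 * 10e6 / 40e3
        assert (clones["start"] >= 0).all() and (clones["end"] <= 10_000_000).all()
        totals.append((clones["end"] - clones["start"]).sum())
    mean_cov = np.mean(totals) / 10_000_000
    assert mean_cov == pytest.approx(5.0, rel=0.05)


def test_reads_inside_inversion_are_concordant():
    """Fragments fully inside an inverted segment map to reflected
    coordinates but stay concordant in reference orientation; fragments
    straddling a junction with both reads clear of it become same-strand."""
    cfg = SimConfig(genome_length=1_000_000, n_inversions=1, inv_sizes=[300_000],
                    n_pools=2, mu_clone=40_000, sigma_clone=5_000,
                    physical_coverage=3, read_coverage=10, rng_seed=4)
    donor = simulate_donor(cfg)
    t = donor.truth[0]
    clones = simulate_pools(donor, cfg)
    stats = FragmentStats(600, 60)
    n_same = 0
    for _, df in ideal_pair_frames(clones, donor, cfg):
        codes = classify_frame(df, stats)
        inside = (
            (np.minimum(df["r1_start"], df["r2_start"]) >= t.start)
            & (np.maximum(df["r1_end"], df["r2_end"]) <= t.end)
        ).to_numpy()
        # pairs fully inside the inversion never appear same-strand
        assert not (codes[inside] == 1).any()
        same = df[codes == 1]
        n_same += len(same)
        for row in same.itertuples():
            lo = min(row.r1_start, row.r2_start)
            hi = max(row.r1_end, row.r2_end)
            # same-strand pairs bracket one of the two breakpoints
            assert (lo <= t.start <= hi) or (lo <= t.end <= hi)
    assert n_same > 0


def test_ideal_mapping_determinism():
    cfg = SimConfig(genome_length=500_000, n_inversions=1, inv_sizes=[100_000],
                    n_pools=3, mu_clone=40_000, sigma_clone=5_000,
                    physical_coverage=2, read_coverage=5, rng_seed=5)
    donor = simulate_donor(cfg)
    clones = simulate_pools(donor, cfg)
    a = {k: v for k, v in ideal_pair_frames(clones, donor, cfg)}
    b = {k: v for k, v in ideal_pair_frames(clones, donor, cfg)}
    assert set(a) == set(b)
    for k in a:
        pd.testing.assert_frame_equal(a[k], b[k])


def test_fastq_mode_writes_donor_sequences(tmp_path):
    cfg = SimConfig(genome_length=100_000, n_inversions=1, inv_sizes=[20_000],
                    n_pools=2, mu_clone=10_000, sigma_clone=1_000,
                    physical_coverage=1, read_coverage=2, rng_seed=6)
    donor = simulate_donor(cfg)
    clones = simulate_pools(donor, cfg)
    ref = simulate_reference_sequences(donor, 6, tmp_path / "ref.fa")
    paths = simulate_read_pairs(clones, donor, cfg, mode="fastq", out_dir=tmp_path, reference=ref)
    assert (tmp_path / "ref.fa").exists()
    assert len(paths) == 4  # R1/R2 per pool
    hap = donor_haplotype_sequence(ref, donor, "chr1", 0).tobytes().decode()
    lines = paths[0].read_text().strip().split("\n")
    assert len(lines) % 4 == 0 and len(lines) > 0
    assert lines[1] in hap  # read 1 is a forward donor substring


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def test_reciprocal_overlap_examples():
    assert reciprocal_overlap((0, 100_000), (10_000, 110_000)) == pytest.approx(0.9)
    assert reciprocal_overlap((0, 100_000), (60_000, 200_000)) < 0.5
    assert reciprocal_overlap((0, 100), (200, 300)) == 0.0


def test_evaluate_calls_tp_fp_found():
    truth = [
        TruthInversion("chr1", 0, 100_000, clone_covered=True),
        TruthInversion("chr1", 500_000, 700_000, clone_covered=False),
    ]
    calls = [("chr1", 10_000, 110_000), ("chr1", 900_000, 950_000)]
    rep = evaluate_calls(calls, truth)
    assert (rep.tp, rep.fp, rep.found, rep.fn) == (1, 1, 1, 1)
    assert rep.precision == pytest.approx(0.5)
    # dropping truth without breakpoint clone coverage removes the FN
    rep2 = evaluate_calls(calls, truth, restrict_to_covered=True)
    assert (rep2.found, rep2.fn) == (1, 0)


def test_precision_matches_benchmark_convention():
    # 191 TP out of 198 calls -> positive predictive value 96.46%
    rep = EvalReport(n_calls=198, tp=191, fp=7, fn=54, found=221, n_truth=275)
    assert 100 * rep.precision == pytest.approx(96.46, abs=0.01)
    assert 100 * rep.recall == pytest.approx(80.36, abs=0.01)
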
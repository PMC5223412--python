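"""End-to-end orchestration: pools in, inversion calls out.

``run_discovery`` executes the whole chain -- classification, clone
inference, split-clone detection, cross-pool pairing, quasi-clique
clustering, refinement and filtering -- streaming one pool at a time so
peak memory scales with a single pool's read pairs plus the (small)
genome-wide same-strand set and clone list.  ``run_simulation_benchmark``
wraps a simulator run plus discovery plus evaluation.

All thresholds in effect are recorded in the run report for
auditability, and all randomness flows from one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from . import pairs as pairs_mod
from .pairs import FragmentStats, PoolSet, classify_frame, class_counts, estimate_fragment_stats
from .clones import CloneStats, InferredClone, clone_length_stats, infer_clones_frame
from .splitclones import (
    InversionSizeBounds,
    attach_support,
    build_same_strand_index,
    find_split_clones,
    pair_split_clones,
)
from .quasiclique import QuasiCliqueParams, build_cluster_graph, find_maximal_quasi_cliques
from .calls import InversionCall, filter_calls, read_bed, recalculate_support, refine_breakpoints
from .evaluate import EvalReport, evaluate_calls
from .simulate import SimConfig, ideal_pair_frames, simulate_donor, simulate_pools

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = "pcs"  # "pcs" or "linked_read"
    barcode_tag: str = "BX"
    min_mapq: int = 1
    # fragment statistics: estimated from the data unless both are given
    mu_fragment: float | None = None
    sigma_fragment: float | None = None
    # clone statistics: estimated from inferred clones unless both are given
    mu_clone: float | None = None
    sigma_clone: float | None = None
    merge_distance: int | None = None  # default 2*mu_fragment (pcs)
    linked_read_merge_distance: int = 10_000
    min_breadth: float = 0.40
    min_depth: float | None = None
    min_inv_size: int = 200_000
    max_inv_size: int = 10_000_000
    alpha: float = 0.50
    beta: float = 0.60
    tabu_rounds: int | None = None
    min_clique_size: int = 2
    min_support: int = 2
    max_track_overlap: float = 0.40
    sd_track: str | None = None
    gap_track: str | None = None
    apply_track_filters: bool | None = None  # default: on for pcs, off for linked reads
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def track_filters_enabled(self) -> bool:
        if self.apply_track_filters is not None:
            return self.apply_track_filters
        return self.mode == "pcs"


@dataclass
class DiscoveryResult:
    calls: list[InversionCall]
    removed: list[InversionCall]
    report: dict
    fragment_stats: FragmentStats | None = None
    clone_stats: CloneStats | None = None


def _as_pool_iter(pools) -> Iterator[tuple[str, pd.DataFrame]]:
    if isinstance(pools, PoolSet):
        return iter(pools.pools.items())
    if isinstance(pools, Mapping):
        return iter(pools.items())
    return iter(pools)


def _empty_result(report: dict) -> DiscoveryResult:
    return DiscoveryResult(calls=[], removed=[], report=report)


def run_discovery(pools, config: PipelineConfig) -> DiscoveryResult:
    """Run the discovery pipeline over an iterable of (pool_id, pair table).

    Accepts a :class:`~poolinv.pairs.PoolSet`, a mapping, or any iterable of
    ``(pool_id, DataFrame)`` (e.g. the simulator's lazy pool generator).
    """
    report: dict = {"thresholds": _thresholds(config)}
    pool_iter = _as_pool_iter(pools)

    # --- fragment statistics (buffer the first pools if estimating) -------
    buffered: list[tuple[str, pd.DataFrame]] = []
    if config.mu_fragment is not None and config.sigma_fragment is not None:
        frag_stats = FragmentStats(config.mu_fragment, config.sigma_fragment)
    else:
        n_opp = 0
        for pool_id, df in pool_iter:
            buffered.append((pool_id, df))
            if len(df):
                n_opp += int((df["strand1"].to_numpy() != df["strand2"].to_numpy()).sum())
            if n_opp >= 10_000:
                break
        frag_stats = estimate_fragment_stats((df for _, df in buffered))
    report["fragment_stats"] = (frag_stats.mu_fragment, frag_stats.sigma_fragment)
    logger.info("fragment stats: mu=%.1f sigma=%.1f", frag_stats.mu_fragment, frag_stats.sigma_fragment)

    if config.merge_distance is not None:
        merge_distance = config.merge_distance
    elif config.mode == "linked_read":
        merge_distance = config.linked_read_merge_distance
    else:
        merge_distance = int(round(2 * frag_stats.mu_fragment))
    report["merge_distance"] = merge_distance

    # --- per-pool streaming: classify, collect same-strand, infer clones --
    counts = {k: 0 for k in pairs_mod.PAIR_CLASSES}
    n_pools = 0
    clones: list[InferredClone] = []
    ss_frames: list[pd.DataFrame] = []

    def _consume(pool_id: str, df: pd.DataFrame) -> None:
        nonlocal n_pools
        n_pools += 1
        if df.empty:
            return
        codes = classify_frame(df, frag_stats)
        c = class_counts(codes)
        for k, v in c.items():
            counts[k] += v
        logger.debug("pool %s: %s", pool_id, c)
        same = df[codes == 1]
        if len(same):
            ss_frames.append(same)
        conc = df[codes == 0]
        if len(conc):
            for chrom in pd.unique(conc["chrom"].to_numpy()):
                sub = conc[conc["chrom"].to_numpy() == chrom]
                clones.extend(
                    infer_clones_frame(
                        sub,
                        merge_distance,
                        pool_id=str(pool_id),
                        chromosome=str(chrom),
                        min_breadth=config.min_breadth,
                        min_depth=config.min_depth,
                    )
                )

    for pool_id, df in buffered:
        _consume(pool_id, df)
    buffered.clear()
    for pool_id, df in pool_iter:
        _consume(pool_id, df)

    report["pair_counts"] = counts
    report["n_pools"] = n_pools
    report["n_clones"] = len(clones)
    if n_pools < 2:
        raise ValueError("discovery requires at least 2 pools")
    if not clones:
        report.update(n_split_clones=0, n_supported_split_clones=0, n_psc=0, n_cliques=0, n_calls=0)
        return _empty_result(report)

    # --- clone statistics --------------------------------------------------
    if config.mu_clone is not None and config.sigma_clone is not None:
        clone_stats = CloneStats(config.mu_clone, config.sigma_clone)
    else:
        clone_stats = clone_length_stats(clones)
    report["clone_stats"] = (clone_stats.mu_clone, clone_stats.sigma_clone)
    logger.info("clone stats: mu=%.0f sigma=%.0f", clone_stats.mu_clone, clone_stats.sigma_clone)

    ss_index = build_same_strand_index(ss_frames)
    del ss_frames

    # --- split clones per pool ---------------------------------------------
    bounds = InversionSizeBounds(config.min_inv_size, config.max_inv_size)
    by_pool: dict[str, list[InferredClone]] = {}
    for c in clones:
        by_pool.setdefault(c.pool_id, []).append(c)
    split_clones = []
    for pool_id, cs in by_pool.items():
        cs.sort(key=lambda c: (c.chromosome, c.start))
        split_clones.extend(find_split_clones(cs, clone_stats, bounds))
    report["n_split_clones"] = len(split_clones)

    split_clones = attach_support(split_clones, ss_index, frag_stats)
    report["n_supported_split_clones"] = len(split_clones)

    # --- PSCs and clustering ------------------------------------------------
    pscs = pair_split_clones(split_clones, clone_stats)
    pscs = attach_support(pscs, ss_index, frag_stats)
    report["n_psc"] = len(pscs)
    if not pscs:
        report.update(n_cliques=0, n_calls=0)
        return _empty_result(report)

    graph = build_cluster_graph(pscs)
    params = QuasiCliqueParams(
        alpha=config.alpha,
        beta=config.beta,
        tabu_rounds=config.tabu_rounds,
        min_clique_size=config.min_clique_size,
        rng_seed=config.rng_seed,
    )
    cliques = find_maximal_quasi_cliques(graph, params)
    report["n_cliques"] = len(cliques)

    # --- refinement and final filters ---------------------------------------
    calls = []
    for clique in cliques:
        call = refine_breakpoints([pscs[i] for i in sorted(clique)])
        call.rp_support = recalculate_support(call, ss_index, frag_stats)
        calls.append(call)
    calls.sort(key=lambda c: (c.chromosome, c.left_inner))

    sd = read_bed(config.sd_track) if (config.sd_track and config.track_filters_enabled()) else None
    gap = read_bed(config.gap_track) if (config.gap_track and config.track_filters_enabled()) else None
    kept, removed = filter_calls(
        calls, sd_track=sd, gap_track=gap,
        min_support=config.min_support, max_track_overlap=config.max_track_overlap,
    )
    report["n_calls"] = len(kept)
    report["n_removed_calls"] = len(removed)
    logger.info(
        "pipeline: %d pairs -> %d clones -> %d split clones (%d supported) -> "
        "%d PSCs -> %d cliques -> %d calls (%d filtered)",
        sum(counts.values()), len(clones), report["n_split_clones"],
        report["n_supported_split_clones"], len(pscs), len(cliques), len(kept), len(removed),
    )
    return DiscoveryResult(
        calls=kept, removed=removed, report=report,
        fragment_stats=frag_stats, clone_stats=clone_stats,
    )


def _thresholds(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def run_simulation_benchmark(
    sim_config: SimConfig,
    pipeline_config: PipelineConfig | None = None,
    reciprocal: float = 0.50,
    restrict_to_covered: bool = False,
    min_truth_size: int | None = None,
) -> tuple[EvalReport, DiscoveryResult, list]:
    """Simulate -> discover -> evaluate (ideal-mapping reads)."""
    pipe = pipeline_config or PipelineConfig()
    donor = simulate_donor(sim_config)
    clones = simulate_pools(donor, sim_config)
    frames = ideal_pair_frames(clones, donor, sim_config)
    result = run_discovery(frames, pipe)
    ev = evaluate_calls(
        result.calls,
        donor.truth,
        reciprocal=reciprocal,
        restrict_to_covered=restrict_to_covered,
        min_truth_size=min_truth_size,
    )
    return ev, result, donor.truth
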
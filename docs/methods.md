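# Methods

## Model

A pool of large clones (or barcoded long molecules) is a dilute sample of
the donor genome: within one pool, concordant short-read pairs tile
well-separated clone intervals. An inversion relative to the reference
produces two coupled signatures. First, any fragment whose two reads fall
on opposite sides of a breakpoint junction maps with both reads on the
same strand. Second, a clone spanning a breakpoint is reconstructed as two
reference intervals whose lengths sum to a clone length and whose
separation approximates the inversion size — a *split clone*. Neither
signature is reliable alone (same-strand pairs are produced by mapping
artefacts; split-clone-like interval pairs arise by chance), so the caller
requires both, and additionally requires split clones from at least two
independent pools to agree on both breakpoints.

Coordinates are 0-based half-open throughout; BED conventions on output.

## Stage-by-stage choices

**Classification.** Concordant means opposite strands in forward–reverse
orientation with the forward read upstream, and an outer fragment span
within μ_f ± 3σ_f. Reverse–forward pairs at short range are
`other_discordant`: the platform's short-insert libraries are FR, and RF
pairs carry no inversion information here. Classification is symmetric in
the two reads.

**Fragment and clone statistics.** Estimated from the data (outer spans of
opposite-strand pairs; lengths of inferred clones) with one round of
3σ trimming, which bounds the influence of discordant contamination and of
split-clone pieces. Both can be overridden in the config; estimation
refuses samples below 100 pairs / 30 clones rather than guessing. In the
streaming pipeline, fragment statistics come from the first pools buffered
until 10,000 opposite-strand pairs are seen.

**Clone inference.** Spanning intervals of concordant pairs are merged by
a left-to-right sweep with merge distance 2 × μ_f (PCS) or a configurable
value up to 10 Kbp (linked reads, whose per-molecule read coverage is far
lower). Breadth uses actual read footprints, not spanning intervals, and
the 40 % threshold is inclusive: exactly 40 % survives, because the
removal rule targets candidates covered by *less than* 40 %. Depth is
computed and reported; no depth threshold is applied by default (one can
be enabled via `min_depth`) since breadth is the documented gate.

**Split clones and PSCs.** The two inequality systems (summed length
within μ_c ± 3σ_c; separation within the inversion size bounds) are
applied with inclusive boundaries. The cross-pool compatibility tolerance
is symmetric, |Δstart| ≤ μ_c on both members, covering both the gap and
the overlap configuration since max gap and max overlap share the value
μ_c. Default size bounds are 200 Kbp – 10 Mbp, both configurable (the
benchmark harness lowers the minimum to 40 Kbp). A split clone may join
many PSCs; disambiguation belongs to the clustering stage.

**Read-pair support.** A same-strand pair supports a candidate when its
leftmost read lies within the left breakpoint window and its rightmost
read within the right window; windows are the breakpoint intervals padded
by μ_f + 3σ_f on each side. The same containment test serves (+,+) and
(−,−) pairs: the two strand classes sit on opposite sides of each
junction, but both fall inside the padded windows, so strand-specific
half-windows would only tighten the count without changing which
candidates survive at the support threshold used. Unsupported split
clones and PSCs are discarded before clustering.

**Quasi-clique extraction.** The cluster graph joins two PSCs when their
left breakpoint intervals intersect and their right intervals intersect
(closed-interval semantics on integer coordinates; point estimates become
width-1 intervals). A subset V′ is an (α, β)-quasi-clique when every node
has internal degree ≥ α·|V′| and the internal edge count is
≥ β·|V′|(|V′|−1)/2. The edge condition is normalised for undirected
edges — dividing the ordered-pair count |V′|(|V′|−1) by two — because a
triangle must qualify at β = 0.6 for the definition to admit complete
subgraphs. Defaults α = 0.5, β = 0.6, tabu length ⌈|graph|/10⌉,
minimum cluster size 2 (two PSCs ⇒ at least two independent pool pairs).

The search is a tabu local search over candidate sizes: grow greedily
from a high-degree seed to size k, then alternate removing the internal
node with the fewest internal links and adding the external node with the
most, recently moved nodes being tabu; the first feasible k in a
descending sweep is the extracted cluster size. Components of ≤ 30 nodes
are swept exhaustively over k with all seeds and two restarts; larger
components first take a greedy feasible baseline and then ascend in k
until two consecutive sizes fail, which keeps the dense near-complete
components produced by real inversions fast. Extracted clusters are
greedily maximalised (no single external node can be added while staying
feasible), removed from the graph, and the search repeats, so clusters
are disjoint and each PSC supports one call. All tie-breaks flow through
one seeded generator; identical seeds give identical output. On seeded
random graphs of ≤ 12 nodes the search is validated against exhaustive
enumeration (tests require ≥ 0.9 × the optimum size; in the committed
validation runs it attains the optimum).

**Refinement.** Each cluster's breakpoint intervals are intersected; a
non-empty intersection is never wider than any member interval, so adding
split clones to a cluster narrows the estimate. If an outlier empties the
intersection, the envelope of the two highest-support members is used.
The four coordinates (left_outer ≤ left_inner < right_inner ≤
right_outer) follow the usual confidence-interval convention. The called
inverted segment is the **outer** extent: member estimates are one-sided,
since a clone spanning the left breakpoint ends exactly at it while the
reflected piece of a right-spanning clone overshoots *into* the inverted
segment (symmetrically on the right), so the outermost envelope
coordinates are the unbiased breakpoint estimates. The minimal (inner)
span is what the BED output reports per interchange convention.

**Filters.** Calls are removed when recalculated support < 2, when more
than 40 % of the inner span lies in assembly gaps, or when *both*
breakpoint intervals overlap a segmental duplication — an SD at a single
breakpoint is expected for genuine large inversions and never removes a
call. Track filters default to on for PCS and off for linked reads.
Removed calls are retained in a secondary output with their reasons.

## Simulator

The generator emulates the pooled-fosmid benchmark protocol: by default
300 pools of clones N(40 Kbp, 10 Kbp) at 5X physical coverage, 150 bp
reads, fragments N(600 bp, 60 bp) at 10X sequence coverage per pool, and
inversions of 500 bp – 10 Mbp placed with gaps of at least 2 × μ_clone so
that neighbouring clusters stay separable. Inversion sizes are
log-uniform within the configured range (or given explicitly); in diploid
mode a configurable fraction of events is homozygous and a requested
fraction of inversions is made to intersect a partner on the opposite
haplotype. Clone and fragment lengths are truncated normals (±3σ),
avoiding nonphysical negatives. `min_breakpoint_clones` plants additional
clones so every breakpoint is spanned with ≥ 5 Kbp flanks, emulating runs
in which clone coverage happens to exist at every breakpoint (the
alternative — excluding uncovered truth from the denominator — is
available as `restrict_to_covered` in the evaluator).

In `ideal_mapping` mode each read is pushed analytically through the
reflection x → inv_start + inv_end − x; reads crossing a junction are
dropped as unmappable rather than soft-clipped, which is loss-free for
this pipeline because neither split reads nor clipped alignments are
used. `fastq` mode emits donor-derived sequences (error-free by default,
uniform substitutions configurable) for use with a real aligner.

What the simulator does *not* emulate: reference repeat structure
(segmental duplications, satellite arrays) and alignment ambiguity, the
main sources of false split clones in real genomes; chimeric clones;
barcode collisions in linked-read data; GC and coverage biases. Passing
benchmarks here therefore demonstrate correctness of the signal model and
clustering machinery under realistic coverage and size distributions, not
robustness to repeat-induced mismapping.

## Benchmark harness and problem sizes

`scripts/acceptance.py` and the heavyweight tests run a desk-scale
analogue of the published protocol: a 40 Mbp genome (one chromosome), 44
homozygous inversions — 40 sizes geometrically spaced from 40 Kbp to
1 Mbp plus 2, 3, 4 and 5 Mbp, jointly filling about two thirds of the
genome, the largest placeable set at this genome size — 300 fosmid pools
at 5X physical / 10X read coverage in ideal-mapping mode,
`min_inv_size` = 40 Kbp, scored at 50 % reciprocal overlap and averaged
over three seeds. A run processes ~6.7 million read pairs and finishes in
well under a minute; the haploid control (no variants, 10 ± 1 Kbp clones)
and the quasi-clique oracle comparison complete in seconds.

## Known limitations

* Inter-chromosomal events, deletions/duplications/translocations and
  genotyping are out of scope; clones never span chromosomes.
* The support-window padding (μ_f + 3σ_f) and the refinement fallback are
  design choices where the method description leaves the constant open;
  both are fixed here and documented above rather than exposed as tuning
  advice.
* On real data, mapping-quality filtering (default min MAPQ 1) discards
  multi-mapping reads; breakpoints deep inside long, near-identical
  duplications remain invisible, as for any mapping-based caller.
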
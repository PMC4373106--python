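# Methods

This note documents the models, parameter choices and numerical conventions
behind `synscaf`, and what the synthetic benchmark does and does not show.

## Coordinate and orientation conventions

All coordinates are 0-based half-open internally; AGP output converts to
1-based inclusive at the file boundary. PAF strand semantics are kept: query
coordinates are always forward-strand, `-` means the query segment matches
the reverse complement of the reference interval. A link edge joins two
scaffold *ends* and implies that the linked ends face each other; a chain of
such edges therefore determines relative orientations up to one global flip
per chain, and the evaluator treats a reversed chain as identical.

## Single-coverage filtering

Whole-genome aligners emit overlapping, partly redundant local alignments;
superscaffolding needs at most 1× coverage on both genomes. The filter is a
deterministic greedy pass in descending score order (ties: longer combined
span, then lexicographic ids and coordinates). A candidate overlapping
already-accepted alignments is cut down to its largest conflict-free
sub-interval on the conflicting axis (ties resolved toward the lower
coordinate), the paired axis being trimmed proportionally with integer-floor
arithmetic and strand-aware end correspondence; trimming alternates between
axes until the candidate is conflict-free or shorter than `min_keep_len`
(default 200 bp) on either axis, in which case it is dropped. Proportional
trimming is an approximation — alignments are treated as locally 1:1 — which
is adequate because downstream consumers only use block-scale coordinates.

## Chaining and block scale

Blocks chain alignments sharing (query, reference, strand) whose
consecutive gaps are ≤ `max_gap` = 100 kb on both genomes with a consistent
diagonal direction, and must hold ≥ `min_block_bp` = 5 kb of aligned
sequence. These defaults sit one to two orders of magnitude below the
megabase block scale typical of the genomes this tool targets, so true
blocks are never split by the gap threshold while isolated spurious hits
(typically < 5 kb) fail the size floor.

## Direct linking

Each scaffold terminus is placed on the reference by extrapolating from its
outermost block assuming locally 1:1 spacing; a terminal block qualifies
when its distance to the terminus is at most half of min(largest insert,
scaffold length) — an anchor farther away than half the relevant window
could not support a within-window link. Every terminus is then paired with
its *nearest* facing terminus on the same reference chromosome. Restricting
to nearest neighbours (rather than all window-compatible pairs) is
deliberate: all-pairs linking creates transitive edges (A–C skipping B)
whose anchor weights tie with the true edge, forcing the ambiguity rule to
drop both; nearest-facing pairing is what ordering scaffolds along a
chromosome means operationally.

The three windows (40 ± 20, 200 ± 100, 500 ± 250 kb) all equal a ± 50%
relative tolerance, shared with the mate-pair route. Read literally, the
lower window bounds reject truly adjacent scaffolds separated by less than
20 kb; by default separations below the smallest window still link
(`allow_sub_window`, down to a 2 kb apparent overlap to absorb jitter), and
the literal behaviour is available via `--strict-windows`.

## Mate-pair route

The mosaic lays query sequence down in reference order — member alignments,
not block hulls, because hulls may legally interleave where translocated
content sits inside another block's chain gap — with inter-alignment
reference distances preserved as uncapped N-runs, so insert-scale distances
on the mosaic approximate reference distances. Mate pairs are drawn with
uniform starts and per-pair insert uniform in the ± 50% window;
reads are 100 bp (the simulated-read length is not externally constrained;
100 bp matches common short-read lengths and is configurable), forward/
reverse, and pairs touching N or chromosome ends are redrawn up to a retry
cap. Because reads are verbatim query substrings, mapping back to scaffolds
is exact full-length matching seeded by 31-mers, both strands; reads with
zero or multiple matches are discarded, which removes both
mosaic-boundary-spanning reads and repeats.

A mapped read implicates the scaffold end its mate points past
(tail distance: scaffold length − position for forward reads, position +
read length for reverse ones). A pair's implied inter-scaffold gap is
insert − tail_a − tail_b; pairs whose implied gap falls outside ± tolerance
are discarded as discordant — equivalent, for gaps small against the insert,
to requiring the pair's end-to-end span to lie within the ± 50% window. A
bucket of ≥ `min_links` = 5 concordant pairs on one (end, end) pair becomes
an edge weighted by its size with the median implied gap. `min_links` = 5
and `ambiguity_ratio` = 0.7 are ordinary operating values for mate-pair
scaffolders; the source procedure's exact settings are not recorded, so
these are explicit, configurable defaults.

## Conflict resolution and assembly

Links are resolved per insert class, smallest first — the way an iterative
mate-pair scaffolder consumes its libraries — so short-range evidence claims
scaffold ends before long-range evidence may. Within a class, an end with
several links keeps the heaviest only when the second-heaviest weighs less
than 0.7 of it; otherwise the end is ambiguous and loses all its links.
The surviving degree-≤1 graph decomposes into chains (residual cycles are
broken at their lightest edge); chains are emitted from their
lexicographically smaller terminus, orientations follow the facing-ends
algebra, and gaps are the link estimates clamped to ≥ `min_gap` = 10 N —
enough to keep components separable in FASTA without inventing length.

## Evaluation

A junction is correct iff its two scaffolds lie on the same truth
chromosome, are consecutive in truth order, and their relative orientation
matches (directly or fully reversed). Consecutiveness is computed among the
scaffolds that participate in at least one junction: pieces the scaffolder
left unordered are treated as absent, so a correct join across an unlinked
fragment is not penalised. The strict variant — consecutiveness over every
input scaffold — is reported alongside (`correct_link_rate_strict`); the two
correspond to excluding/including unordered pieces and bracket the
headline number. A scaffold is correctly linked iff all its junctions are
correct; the per-scaffold rate over linked scaffolds is the primary
statistic, with the per-junction rate reported as well.

Intra-chromosomal rearrangement flags use the majority strand (by aligned
bp) of a scaffold's blocks: minority-strand runs are inversions, and
majority-strand blocks outside the longest increasing subsequence of
reference order (run-merged) are transpositions. The LIS is the O(n²) DP,
deterministic under ties.

## Synthetic data: what it emulates and what it does not

The generator derives a query genome from a random reference
(i.i.d. bases, GC 0.42 as typical of the genomes this tool targets) by
planting translocations and inversions on an exact segment map, then
substitutions, then short indels (geometric lengths, mean 5 bp) through a
monotone anchor map. Applying indels last keeps the query→reference truth
map exact, which the zero-noise round-trip tests require; the three
mutation classes commute distributionally, so the order is an
implementation convenience, not a model claim. Rearrangement sizes default
to 50–500 kb (inversions) and 50–300 kb (translocations): large enough to
span several scaffolds, small enough that several fit per chromosome.

Fragmentation cuts chromosomes uniformly at random, deleting a true gap
(default 0.5–10 kb) at each cut, but never produces pieces below
`min_scaffold_len` = 5 kb — draft assemblies entering a scaffolding step
have a scaffold-size floor, and a piece much smaller than that cannot carry
alignment or mate-pair evidence in any case. Alignments are emitted from
the truth map (strand-aware through inversions) rather than computed by an
aligner, with three noise knobs: per-record dropout, spurious records
(random short query interval → random reference interval, at a rate
relative to the surviving true records), and uniform ± jitter on all four
coordinates.

Not emulated: repeat landscapes, heterozygosity, sequencing error,
alignment-score noise correlated with divergence, and reference-genome
assembly errors. Passing tests therefore demonstrate the correctness of the
ordering/orientation machinery under realistic noise *geometry*, not
robustness to repeat-induced mis-alignment, which on real data is the main
residual failure mode.

## Benchmark scale

The full-genome validation this package's benchmark mirrors used ~1 Gb
genomes and 12.8 million mate pairs. The benchmark runs at desk scale: five
chromosomes of 3.5–4.5 Mb (≈ 20 Mb per genome), ~200 scaffolds, 10%
substitution divergence, 1% indels, 5 inversions + 3 translocations, noise
(dropout 0.05, spurious 0.10, jitter 500 bp), and pair counts scaled by
1/1000 (10,000 / 2,000 / 800) — chosen so spanning coverage per junction
(≈ 20 pairs per class) matches the full-scale setting. Ten fixtures are run
per invocation; the reported numbers are means over fixtures.

## Determinism

Every stochastic step takes an explicit seed; compound steps derive child
seeds through a seed sequence. Identical seeds give byte-identical FASTA,
PAF, truth tables, mate pairs, AGP and reports. Ties anywhere
(filter order, conflict resolution, chain emission) are broken
lexicographically so results are independent of input ordering.

## Known limitations

* Proportional trimming assumes locally uniform alignment spacing; indel-
  rich alignments can shift trimmed query coordinates by the local indel
  drift.
* Direct-mode gap estimates extrapolate reference distance and inherit any
  reference/query length difference at the junction.
* The rearrangement flags operate per (scaffold, chromosome) pair and do
  not aggregate support across multiple references.
* Mis-join detection only sees inter-chromosomal transitions; intra-
  chromosomal mis-joins (inverted or transposed segments within one
  chromosome) are reported as rearrangement events, not as break calls.
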
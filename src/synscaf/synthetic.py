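"""Synthetic reference/query fixtures with exact ground truth.

The generator emulates the inputs of reference-guided superscaffolding: a
multi-chromosome reference; a diverged query (substitutions, short indels,
inversions, translocations); fragmentation of the query into scaffolds with
a known order/orientation truth; and a noisy alignment set standing in for a
whole-genome aligner (dropout, spurious records, coordinate jitter).

Rearrangements are applied on an exact segment map and indels through a
monotone anchor map, so every scaffold interval can be projected onto the
reference without approximation; emitted alignments are truthful up to the
configured jitter.  Everything is deterministic per seed.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import PairwiseAlignment, SequenceRecord

__all__ = [
    "EvolutionParams",
    "NoiseParams",
    "FixtureParams",
    "TruthAssembly",
    "QueryMap",
    "generate_reference",
    "evolve_query",
    "fragment_into_scaffolds",
    "emit_alignments",
    "generate_fixture",
    "write_truth_tsv",
    "read_truth_tsv",
]

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass
class EvolutionParams:
    """Divergence knobs for deriving a query genome from the reference."""

    substitution_rate: float = 0.10
    indel_rate: float = 0.01
    mean_indel_len: float = 5.0
    n_inversions: int = 0
    n_translocations: int = 0
    inversion_len_range: tuple[int, int] = (50_000, 500_000)
    translocation_len_range: tuple[int, int] = (50_000, 300_000)
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.n_inversions < 0 or self.n_translocations < 0:
            raise ValueError("rearrangement counts must be >= 0")


@dataclass
class NoiseParams:
    """Alignment-set noise: dropped, spurious and jittered records."""

    dropout_rate: float = 0.0
    spurious_rate: float = 0.0
    jitter_bp: int = 0
    spurious_len_range: tuple[int, int] = (500, 5_000)

    def __post_init__(self) -> None:
        for rate in (self.dropout_rate, self.spurious_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")


class QueryMap:
    """Exact projection of query-chromosome intervals onto the reference.

    Per query chromosome: a monotone anchor map absorbing the indels, and an
    ordered segment list (from the rearrangement history) mapping pre-indel
    coordinates to reference intervals with strand.
    """

    def __init__(self, identity: float):
        self.identity = identity
        self._chroms: dict[str, dict] = {}

    def add_chromosome(self, chrom: str, af: list[int], ap: list[int], segs: list[list]):
        starts = [0]
        for seg in segs:
            starts.append(starts[-1] + seg[0])
        self._chroms[chrom] = {"af": af, "ap": ap, "segs": segs, "starts": starts}

    @staticmethod
    def _piecewise(x: int, src: list[int], dst: list[int]) -> int:
        i = bisect_right(src, x) - 1
        v = dst[i] + (x - src[i])
        if i + 1 < len(dst):
            v = min(v, dst[i + 1])
        return v

    def to_proto(self, chrom: str, q: int) -> int:
        c = self._chroms[chrom]
        return self._piecewise(q, c["af"], c["ap"])

    def to_final(self, chrom: str, p: int) -> int:
        c = self._chroms[chrom]
        return self._piecewise(p, c["ap"], c["af"])

    def project(self, chrom: str, q0: int, q1: int) -> list[tuple[int, int, str, int, int, str]]:
        """Pieces (q_start, q_end, ref_chrom, r_start, r_end, strand) covering [q0, q1)."""
        c = self._chroms[chrom]
        p0, p1 = self.to_proto(chrom, q0), self.to_proto(chrom, q1)
        if p1 <= p0:
            return []
        starts = c["starts"]
        segs = c["segs"]
        pieces = []
        i = max(bisect_right(starts, p0) - 1, 0)
        while i < len(segs) and starts[i] < p1:
            seg_start, seg_end = starts[i], starts[i + 1]
            pp0, pp1 = max(p0, seg_start), min(p1, seg_end)
            if pp1 > pp0:
                _, rchrom, rs, re_, strand = segs[i]
                if strand == "+":
                    r0 = rs + (pp0 - seg_start)
                    r1 = rs + (pp1 - seg_start)
                else:
                    r1 = re_ - (pp0 - seg_start)
                    r0 = re_ - (pp1 - seg_start)
                qq0 = max(q0, self.to_final(chrom, pp0))
                qq1 = min(q1, self.to_final(chrom, pp1))
                if qq1 > qq0 and r1 > r0:
                    pieces.append((qq0, qq1, rchrom, r0, r1, strand))
            i += 1
        return pieces


@dataclass
class TruthAssembly:
    """Ground-truth chromosome composition of the fragmented query.

    ``chromosomes`` maps each query chromosome to its ordered
    (scaffold_id, orientation, gap_after) parts; ``origins`` maps scaffolds
    to their query-chromosome interval; ``events`` is the rearrangement log.
    """

    chromosomes: dict[str, list[tuple[str, str, int | None]]]
    origins: dict[str, tuple[str, int, int]]
    events: list[dict] = field(default_factory=list)
    query_map: QueryMap | None = None
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def scaffold_lengths(self) -> dict[str, int]:
        return {s: e - b for s, (_, b, e) in self.origins.items()}


def generate_reference(
    n_chromosomes: int,
    length_range: tuple[int, int],
    gc: float = 0.42,
    seed: int = 0,
) -> list[SequenceRecord]:
    """I.i.d. random chromosomes at the given GC fraction."""
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if length_range[0] < 10_000 or length_range[1] < length_range[0]:
        raise ValueError("chromosome lengths must be >= 10 kb and a valid range")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at, cg = (1.0 - gc) / 2.0, gc / 2.0
    records = []
    for i in range(n_chromosomes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        codes = rng.choice(4, size=length, p=[at, cg, cg, at]).astype(np.uint8)
        records.append(SequenceRecord(f"chr{i + 1}", _to_str(codes)))
    return records


class _Chrom:
    """Mutable chromosome under evolution: sequence, rearrangement mask, segment map."""

    def __init__(self, ref_id: str, codes: np.ndarray):
        self.codes = codes
        self.mask = np.zeros(codes.size, dtype=bool)
        # segments: [length, ref_chrom, r_start, r_end, strand]
        self.segs: list[list] = [[codes.size, ref_id, 0, codes.size, "+"]]

    def __len__(self) -> int:
        return self.codes.size

    def _split(self, pos: int) -> int:
        """Ensure a segment boundary at ``pos``; return index of segment starting there."""
        acc = 0
        for i, seg in enumerate(self.segs):
            if acc == pos:
                return i
            if acc + seg[0] > pos:
                d = pos - acc
                length, rchrom, rs, re_, strand = seg
                if strand == "+":
                    left = [d, rchrom, rs, rs + d, "+"]
                    right = [length - d, rchrom, rs + d, re_, "+"]
                else:
                    left = [d, rchrom, re_ - d, re_, "-"]
                    right = [length - d, rchrom, rs, re_ - d, "-"]
                self.segs[i : i + 1] = [left, right]
                return i + 1
            acc += seg[0]
        return len(self.segs)

    def invert(self, a: int, b: int) -> None:
        i, j = self._split(a), self._split(b)
        flipped = []
        for length, rchrom, rs, re_, strand in reversed(self.segs[i:j]):
            flipped.append([length, rchrom, rs, re_, "-" if strand == "+" else "+"])
        self.segs[i:j] = flipped
        self.codes[a:b] = (3 - self.codes[a:b])[::-1]
        self.mask[a:b] = True

    def excise(self, a: int, b: int) -> tuple[np.ndarray, list[list]]:
        i, j = self._split(a), self._split(b)
        piece_segs = self.segs[i:j]
        del self.segs[i:j]
        piece = self.codes[a:b].copy()
        self.codes = np.concatenate([self.codes[:a], self.codes[b:]])
        self.mask = np.concatenate([self.mask[:a], self.mask[b:]])
        return piece, piece_segs

    def insert(self, pos: int, piece: np.ndarray, piece_segs: list[list]) -> None:
        i = self._split(pos)
        self.segs[i:i] = piece_segs
        self.codes = np.concatenate([self.codes[:pos], piece, self.codes[pos:]])
        self.mask = np.concatenate(
            [self.mask[:pos], np.ones(piece.size, dtype=bool), self.mask[pos:]]
        )


def _draw_clear_interval(
    chroms: list[_Chrom], len_range: tuple[int, int], rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[int, int, int] | None:
    """A (chrom_idx, start, end) interval avoiding previously rearranged bases."""
    lengths = np.array([len(c) for c in chroms], dtype=np.float64)
    for _ in range(max_tries):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        ok = lengths > length
        if not ok.any():
            continue
        p = np.where(ok, lengths, 0.0)
        ci = int(rng.choice(len(chroms), p=p / p.sum()))
        start = int(rng.integers(0, len(chroms[ci]) - length))
        if not chroms[ci].mask[start : start + length].any():
            return ci, start, start + length
    return None


def _apply_indels(
    codes: np.ndarray, rate: float, mean_len: float, rng: np.random.Generator,
) -> tuple[np.ndarray, list[int], list[int]]:
    """Apply short indels; return (new_codes, final_anchors, proto_anchors)."""
    af, ap = [0], [0]
    if rate <= 0.0:
        return codes, af, ap
    positions = np.flatnonzero(rng.random(codes.size) < rate)
    p_geo = min(1.0, 1.0 / max(mean_len, 1.0))
    pieces: list[np.ndarray] = []
    f = 0
    cursor = 0
    for pos in positions:
        pos = int(pos)
        if pos < cursor:
            continue  # swallowed by a previous deletion
        length = int(rng.geometric(p_geo))
        is_insertion = rng.random() < 0.5
        pieces.append(codes[cursor:pos])
        f += pos - cursor
        if is_insertion:
            pieces.append(rng.integers(0, 4, size=length).astype(np.uint8))
            f += length
            af.append(f)
            ap.append(pos)
            cursor = pos
        else:
            length = min(length, codes.size - pos)
            af.append(f)
            ap.append(pos + length)
            cursor = pos + length
    pieces.append(codes[cursor:])
    return np.concatenate(pieces), af, ap


def evolve_query(
    reference: Sequence[SequenceRecord],
    params: EvolutionParams,
) -> tuple[list[SequenceRecord], QueryMap, list[dict]]:
    """Derive a diverged query genome with an exact truth map.

    Returns the query chromosomes, a :class:`QueryMap` projecting query
    intervals onto the reference, and the rearrangement event log.
    """
    rng = np.random.default_rng(params.seed)
    chroms = [_Chrom(r.id, _ENCODE[np.frombuffer(r.sequence.encode(), np.uint8)].copy()) for r in reference]
    names = [f"q{r.id}" for r in reference]
    events: list[dict] = []

    for _ in range(params.n_translocations):
        src = _draw_clear_interval(chroms, params.translocation_len_range, rng)
        if src is None:
            break
        ci, a, b = src
        piece, piece_segs = chroms[ci].excise(a, b)
        for _try in range(200):
            cj = int(rng.integers(0, len(chroms)))
            pos = int(rng.integers(0, len(chroms[cj]) + 1))
            m = chroms[cj].mask
            if 0 < pos < len(chroms[cj]) and m[pos - 1] and m[pos]:
                continue
            break
        chroms[cj].insert(pos, piece, piece_segs)
        events.append(
            {"kind": "translocation", "src_chrom": names[ci], "src_start": a,
             "src_end": b, "dst_chrom": names[cj], "dst_pos": pos, "length": b - a}
        )

    for _ in range(params.n_inversions):
        iv = _draw_clear_interval(chroms, params.inversion_len_range, rng)
        if iv is None:
            break
        ci, a, b = iv
        chroms[ci].invert(a, b)
        events.append({"kind": "inversion", "chrom": names[ci], "start": a, "end": b, "length": b - a})

    if params.substitution_rate > 0.0:
        for c in chroms:
            hit = np.flatnonzero(rng.random(len(c)) < params.substitution_rate)
            shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
            c.codes[hit] = (c.codes[hit] + shift) % 4

    qmap = QueryMap(identity=1.0 - params.substitution_rate)
    records: list[SequenceRecord] = []
    for name, c in zip(names, chroms):
        final_codes, af, ap = _apply_indels(c.codes, params.indel_rate, params.mean_indel_len, rng)
        qmap.add_chromosome(name, af, ap, c.segs)
        records.append(SequenceRecord(name, _to_str(final_codes)))
    return records, qmap, events


def fragment_into_scaffolds(
    query: Sequence[SequenceRecord],
    n_breaks_per_chrom: int,
    gap_range: tuple[int, int],
    seed: int,
    query_map: QueryMap | None = None,
    events: list[dict] | None = None,
    min_scaffold_len: int = 5_000,
) -> tuple[list[SequenceRecord], TruthAssembly]:
    """Cut query chromosomes into scaffolds, deleting a true gap at each cut.

    Cut positions are uniform, but pieces shorter than ``min_scaffold_len``
    are not produced (draft assemblies have a scaffold-size floor; cuts that
    would violate it are skipped).  The truth records order (all '+'),
    per-junction gap and per-scaffold origin interval; emitted scaffold
    order is shuffled and ids are opaque.
    """
    if gap_range[0] < 0 or gap_range[1] < gap_range[0]:
        raise ValueError("invalid gap range")
    rng = np.random.default_rng(seed)
    pending: list[tuple[str, int, int, int | None]] = []  # chrom, start, end, gap_after
    chrom_lengths: dict[str, int] = {}
    for rec in query:
        length = rec.length
        chrom_lengths[rec.id] = length
        n_breaks = min(n_breaks_per_chrom, max(length - 2, 0))
        cuts = sorted(int(x) for x in rng.choice(np.arange(1, length), size=n_breaks, replace=False))
        start = 0
        parts: list[tuple[str, int, int, int | None]] = []
        for cut in cuts:
            if cut - start < min_scaffold_len:
                continue
            gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
            gap = min(gap, length - cut - min_scaffold_len)
            if gap < 0:
                continue
            parts.append((rec.id, start, cut, gap))
            start = cut + gap
        parts.append((rec.id, start, length, None))
        pending.extend(parts)

    order = rng.permutation(len(pending))
    ids = [""] * len(pending)
    for new_idx, old_idx in enumerate(order):
        ids[old_idx] = f"scf_{new_idx:05d}"

    chromosomes: dict[str, list[tuple[str, str, int | None]]] = {}
    origins: dict[str, tuple[str, int, int]] = {}
    for (chrom, s, e, gap), sid in zip(pending, ids):
        chromosomes.setdefault(chrom, []).append((sid, "+", gap))
        origins[sid] = (chrom, s, e)

    seqs = {rec.id: rec.sequence for rec in query}
    scaffolds = [
        SequenceRecord(ids[i], seqs[pending[i][0]][pending[i][1] : pending[i][2]])
        for i in order
    ]
    truth = TruthAssembly(
        chromosomes=chromosomes,
        origins=origins,
        events=list(events or []),
        query_map=query_map,
        chromosome_lengths=chrom_lengths,
    )
    return scaffolds, truth


def emit_alignments(
    truth: TruthAssembly,
    reference: Sequence[SequenceRecord],
    noise: NoiseParams,
    seed: int,
) -> list[PairwiseAlignment]:
    """Emit the alignment set a whole-genome aligner would produce.

    One record per truth segment of each scaffold, strand-aware through
    planted inversions; records are dropped, jittered and topped up with
    spurious records according to ``noise``.
    """
    if truth.query_map is None:
        raise ValueError("truth has no query map; generate it with evolve_query")
    rng = np.random.default_rng(seed)
    ref_lengths = {r.id: r.length for r in reference}
    identity = truth.query_map.identity
    scaffold_lengths = truth.scaffold_lengths()

    out: list[PairwiseAlignment] = []
    for sid in sorted(truth.origins):
        chrom, s, e = truth.origins[sid]
        qlen = e - s
        for q0, q1, rchrom, r0, r1, strand in truth.query_map.project(chrom, s, e):
            if rng.random() < noise.dropout_rate:
                continue
            qs, qe = q0 - s, q1 - s
            rs, re_ = r0, r1
            if noise.jitter_bp > 0:
                j = noise.jitter_bp
                rlen = ref_lengths[rchrom]
                qs = int(np.clip(qs + rng.integers(-j, j + 1), 0, qlen - 1))
                qe = int(np.clip(qe + rng.integers(-j, j + 1), qs + 1, qlen))
                rs = int(np.clip(rs + rng.integers(-j, j + 1), 0, rlen - 1))
                re_ = int(np.clip(re_ + rng.integers(-j, j + 1), rs + 1, rlen))
            matches = max(1, int(min(qe - qs, re_ - rs) * identity))
            out.append(
                PairwiseAlignment(
                    sid, qs, qe, qlen, rchrom, rs, re_, ref_lengths[rchrom],
                    strand, matches, float(matches),
                )
            )

    n_spurious = int(round(noise.spurious_rate * len(out)))
    sids = sorted(scaffold_lengths)
    rids = sorted(ref_lengths)
    for _ in range(n_spurious):
        sid = sids[int(rng.integers(0, len(sids)))]
        qlen = scaffold_lengths[sid]
        length = int(rng.integers(noise.spurious_len_range[0], noise.spurious_len_range[1] + 1))
        length = min(length, qlen)
        if length < 1:
            continue
        qs = int(rng.integers(0, qlen - length + 1))
        rid = rids[int(rng.integers(0, len(rids)))]
        rlen = ref_lengths[rid]
        rspan = min(length, rlen)
        rs = int(rng.integers(0, rlen - rspan + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        matches = max(1, int(0.5 * min(length, rspan)))
        out.append(
            PairwiseAlignment(
                sid, qs, qs + length, qlen, rid, rs, rs + rspan, rlen,
                strand, matches, float(matches),
            )
        )
    return out


def write_truth_tsv(truth: TruthAssembly, path) -> None:
    """Serialize the truth layout (order, orientation, gaps, origins) as TSV.

    The query->reference map is not serialized; the TSV carries everything
    the evaluator needs.
    """
    with open(path, "w") as fh:
        fh.write("chrom\tindex\tscaffold_id\torientation\tgap_after\torigin_start\torigin_end\tchrom_length\n")
        for chrom in sorted(truth.chromosomes):
            for idx, (sid, orient, gap) in enumerate(truth.chromosomes[chrom]):
                _, s, e = truth.origins[sid]
                gap_str = "NA" if gap is None else str(gap)
                clen = truth.chromosome_lengths.get(chrom, 0)
                fh.write(f"{chrom}\t{idx}\t{sid}\t{orient}\t{gap_str}\t{s}\t{e}\t{clen}\n")


def read_truth_tsv(path) -> TruthAssembly:
    chromosomes: dict[str, list[tuple[str, str, int | None]]] = {}
    origins: dict[str, tuple[str, int, int]] = {}
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: not a truth TSV")
        for line in fh:
            chrom, _idx, sid, orient, gap_str, s, e, clen = line.rstrip("\n").split("\t")
            gap = None if gap_str == "NA" else int(gap_str)
            chromosomes.setdefault(chrom, []).append((sid, orient, gap))
            origins[sid] = (chrom, int(s), int(e))
            chrom_lengths[chrom] = int(clen)
    return TruthAssembly(chromosomes=chromosomes, origins=origins, chromosome_lengths=chrom_lengths)


@dataclass
class FixtureParams:
    """One self-contained benchmark fixture, governed by a single seed."""

    n_chromosomes: int = 5
    chromosome_length_range: tuple[int, int] = (3_500_000, 4_500_000)
    gc: float = 0.42
    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    n_breaks_per_chrom: int = 44
    gap_range: tuple[int, int] = (500, 10_000)
    min_scaffold_len: int = 5_000
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0


@dataclass
class Fixture:
    reference: list[SequenceRecord]
    query: list[SequenceRecord]
    scaffolds: list[SequenceRecord]
    truth: TruthAssembly
    alignments: list[PairwiseAlignment]


def generate_fixture(params: FixtureParams) -> Fixture:
    """Generate reference, query, scaffolds, truth and alignments from one seed."""
    child = np.random.SeedSequence(params.seed).generate_state(4)
    reference = generate_reference(
        params.n_chromosomes, params.chromosome_length_range, params.gc, int(child[0])
    )
    evo = EvolutionParams(**{**params.evolution.__dict__, "seed": int(child[1])})
    query, qmap, events = evolve_query(reference, evo)
    scaffolds, truth = fragment_into_scaffolds(
        query, params.n_breaks_per_chrom, params.gap_range, int(child[2]),
        query_map=qmap, events=events, min_scaffold_len=params.min_scaffold_len,
    )
    alignments = emit_alignments(truth, reference, params.noise, int(child[3]))
    return Fixture(reference, query, scaffolds, truth, alignments)
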
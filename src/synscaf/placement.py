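"""Two routes from collinear blocks to linkable scaffold placements.

Route (a): project each scaffold's terminal blocks onto the reference to get
direct end placements that can be linked when termini fall within an insert
window of one another.

Route (b): rebuild a reference-ordered mosaic of the query sequence (query
nucleotides arranged in reference order, inter-block reference gaps preserved
as N-runs), simulate long-insert mate pairs from the mosaic, and map them
back to the original scaffolds by exact full-length matching.  Because the
mosaic is built verbatim from query sequence, exact matching is lossless and
no external aligner is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .collinearity import CollinearBlock
from .io_formats import SequenceRecord, revcomp

__all__ = [
    "EndPlacement",
    "InsertSpec",
    "MatePair",
    "MappedPair",
    "MosaicSegment",
    "default_insert_specs",
    "place_scaffold_ends",
    "build_reference_ordered_mosaic",
    "simulate_long_mate_pairs",
    "map_mate_pairs",
]

LEFT = "LEFT"
RIGHT = "RIGHT"

DEFAULT_READ_LENGTH = 100
DEFAULT_MAX_TERMINAL_OFFSET_FRACTION = 0.5


@dataclass(frozen=True)
class InsertSpec:
    """One simulated long-insert library.

    ``tolerance`` defaults to half the insert size (a +/-50% window).
    """

    insert: int
    n_pairs: int
    tolerance: int | None = None
    read_length: int = DEFAULT_READ_LENGTH
    label: str = ""

    def __post_init__(self) -> None:
        if self.tolerance is None:
            object.__setattr__(self, "tolerance", self.insert // 2)
        if not self.label:
            object.__setattr__(self, "label", f"{self.insert // 1000}k")
        if self.read_length >= self.insert:
            raise ValueError("read_length must be smaller than the insert size")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        return (self.insert - self.tolerance, self.insert + self.tolerance)


def default_insert_specs(scale: float = 1.0, read_length: int = DEFAULT_READ_LENGTH) -> list[InsertSpec]:
    """The three standard long-insert classes: 40 kb, 200 kb and 500 kb.

    Full-scale pair counts are 10e6, 2e6 and 0.8e6; ``scale`` divides them
    for desk-scale runs.
    """
    counts = (10_000_000, 2_000_000, 800_000)
    inserts = (40_000, 200_000, 500_000)
    return [
        InsertSpec(insert=i, n_pairs=max(0, int(round(c * scale))), read_length=read_length)
        for i, c in zip(inserts, counts)
    ]


@dataclass
class EndPlacement:
    """Projection of one scaffold terminus onto the reference."""

    scaffold_id: str
    end: str  # LEFT | RIGHT
    ref_id: str
    ref_pos: int
    orientation: str  # scaffold orientation on the reference
    anchor_bp: int
    terminal_offset: int


@dataclass
class MatePair:
    pair_id: str
    insert_class: str
    read1_seq: str
    read2_seq: str
    true_origin: tuple[str, int, int]


@dataclass
class MappedPair:
    pair_id: str
    scaffold_a: str
    pos_a: int
    strand_a: str
    scaffold_b: str
    pos_b: int
    strand_b: str
    insert_class: str


@dataclass
class MosaicSegment:
    """One mosaic interval and the scaffold slice it was copied from."""

    mosaic_id: str
    m_start: int
    m_end: int
    scaffold_id: str
    q_start: int
    q_end: int
    strand: str


def place_scaffold_ends(
    blocks: Iterable[CollinearBlock],
    insert_specs: Sequence[InsertSpec],
    max_terminal_offset_fraction: float = DEFAULT_MAX_TERMINAL_OFFSET_FRACTION,
) -> list[EndPlacement]:
    """Place scaffold termini on the reference via their outermost blocks.

    For each scaffold end, the block closest to that end qualifies when its
    distance to the terminus is at most ``max_terminal_offset_fraction`` of
    min(largest insert, scaffold length).  The terminus reference position
    extrapolates past the block edge assuming 1:1 spacing.
    """
    largest_insert = max(s.insert for s in insert_specs)
    by_query: dict[str, list[CollinearBlock]] = {}
    qlen: dict[str, int] = {}
    for b in blocks:
        by_query.setdefault(b.query_id, []).append(b)
        qlen[b.query_id] = b.members[0].query_len

    placements: list[EndPlacement] = []
    for qid in sorted(by_query):
        bs = by_query[qid]
        scaffold_len = qlen[qid]
        max_offset = max_terminal_offset_fraction * min(largest_insert, scaffold_len)
        left = min(bs, key=lambda b: (b.q_start, b.r_start))
        right = max(bs, key=lambda b: (b.q_end, b.r_end))
        off = left.q_start
        if off <= max_offset:
            if left.strand == "+":
                ref_pos = left.r_start - off
            else:
                ref_pos = left.r_end + off
            placements.append(
                EndPlacement(qid, LEFT, left.ref_id, ref_pos, left.strand, left.aligned_bp, off)
            )
        off = scaffold_len - right.q_end
        if off <= max_offset:
            if right.strand == "+":
                ref_pos = right.r_end + off
            else:
                ref_pos = right.r_start - off
            placements.append(
                EndPlacement(qid, RIGHT, right.ref_id, ref_pos, right.strand, right.aligned_bp, off)
            )
    return placements


def build_reference_ordered_mosaic(
    blocks: Iterable[CollinearBlock],
    query_seqs: dict[str, str],
    ref_lengths: dict[str, int],
) -> tuple[list[SequenceRecord], list[MosaicSegment]]:
    """Arrange query sequence in reference order, one mosaic per chromosome.

    Block members are laid down in reference order; each contributes its
    query subsequence (reverse-complemented for '-' members) and reference
    gaps between consecutive members are preserved as N-runs of the same
    length so long-range distances on the mosaic approximate reference
    distances.  Members rather than block hulls are placed because hulls of
    different blocks may legally interleave (e.g. translocated content
    inside another block's chain gap) while single-coverage members cannot.
    """
    by_ref: dict[str, list] = {}
    for b in blocks:
        for m in b.members:
            by_ref.setdefault(m.ref_id, []).append((m.r_start, m.r_end, m.query_id, m.q_start, m.q_end, m.strand))

    mosaics: list[SequenceRecord] = []
    segments: list[MosaicSegment] = []
    for ref_id in sorted(by_ref, key=lambda r: (r not in ref_lengths, r)):
        ms = sorted(by_ref[ref_id])
        for prev, nxt in zip(ms, ms[1:]):
            if nxt[0] < prev[1]:
                raise ValueError(
                    f"alignments overlap on {ref_id}: {prev[0]}-{prev[1]} vs "
                    f"{nxt[0]}-{nxt[1]} (input is not single-coverage)"
                )
        mosaic_id = f"mosaic_{ref_id}"
        pieces: list[str] = []
        pos = 0
        prev_end: int | None = None
        for r_start, r_end, qid, q_start, q_end, strand in ms:
            if prev_end is not None and r_start > prev_end:
                gap = r_start - prev_end
                pieces.append("N" * gap)
                pos += gap
            seq = query_seqs[qid][q_start:q_end]
            if strand == "-":
                seq = revcomp(seq)
            pieces.append(seq)
            segments.append(
                MosaicSegment(mosaic_id, pos, pos + len(seq), qid, q_start, q_end, strand)
            )
            pos += len(seq)
            prev_end = r_end
        mosaics.append(SequenceRecord(mosaic_id, "".join(pieces)))
    return mosaics, segments


# --- mate-pair simulation ---------------------------------------------

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def simulate_long_mate_pairs(
    mosaics: Sequence[SequenceRecord],
    spec: InsertSpec,
    seed: int,
    max_retries: int = 50,
) -> list[MatePair]:
    """Draw random long-insert mate pairs from the mosaic chromosomes.

    Pair starts are uniform over eligible positions, the per-pair insert is
    uniform over the insert window, read1 is the forward strand at the start
    and read2 the reverse complement ending at start + insert.  Pairs whose
    reads would contain N or run off the chromosome are redrawn up to
    ``max_retries`` times, then skipped; the output is deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    rl = spec.read_length
    lo, hi = spec.window
    usable = [m for m in mosaics if m.length >= hi]
    skipped_short = [m.id for m in mosaics if m.length < hi]
    if skipped_short:
        import warnings

        warnings.warn(
            f"{len(skipped_short)} mosaic chromosome(s) shorter than the "
            f"largest insert were skipped for the {spec.label} library"
        )
    if not usable or spec.n_pairs == 0:
        return []

    codes = [_encode(m.sequence) for m in usable]
    # prefix counts of non-ACGT characters, for O(1) N-checks
    ncum = [np.concatenate(([0], np.cumsum(c > 3))) for c in codes]
    lengths = np.array([m.length for m in usable], dtype=np.int64)

    pairs: list[MatePair] = []
    for i in range(spec.n_pairs):
        placed = False
        for _ in range(max_retries):
            insert = int(rng.integers(lo, hi + 1))
            eligible = np.maximum(lengths - insert, 0)
            total = int(eligible.sum())
            if total == 0:
                break
            ci = int(rng.choice(len(usable), p=eligible / total))
            pos = int(rng.integers(0, eligible[ci]))
            end = pos + insert
            r2_start = end - rl
            if ncum[ci][pos + rl] - ncum[ci][pos] or ncum[ci][end] - ncum[ci][r2_start]:
                continue
            seq = usable[ci].sequence
            read1 = seq[pos : pos + rl]
            read2 = revcomp(seq[r2_start:end])
            pairs.append(
                MatePair(
                    pair_id=f"{spec.label}:{i}",
                    insert_class=spec.label,
                    read1_seq=read1,
                    read2_seq=read2,
                    true_origin=(usable[ci].id, pos, r2_start),
                )
            )
            placed = True
            break
        if not placed:
            continue
    return pairs


class _ExactMatchIndex:
    """k-mer seeded exact full-length matcher over a scaffold set."""

    def __init__(self, scaffolds: Sequence[SequenceRecord], k: int = 31):
        self.k = k
        self.ids = [s.id for s in scaffolds]
        # concatenate with a separator code so matches cannot span scaffolds
        parts = []
        starts = []
        pos = 0
        for s in scaffolds:
            starts.append(pos)
            parts.append(_encode(s.sequence))
            parts.append(np.array([4], dtype=np.uint8))
            pos += s.length + 1
        self.codes = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
        self.starts = np.array(starts, dtype=np.int64)
        n = self.codes.size
        self.badcum = np.concatenate(([0], np.cumsum(self.codes > 3, dtype=np.int64)))
        if n < k:
            self.sorted_kmers = np.zeros(0, dtype=np.uint64)
            self.order = np.zeros(0, dtype=np.int64)
            return
        m = n - k + 1
        acc = np.zeros(m, dtype=np.uint64)
        for j in range(k):
            acc = (acc << np.uint64(2)) | self.codes[j : j + m].astype(np.uint64)
        valid = (self.badcum[k:] - self.badcum[:m]) == 0
        positions = np.flatnonzero(valid)
        kmers = acc[positions]
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.order = positions[order]

    def _candidates(self, seed: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_kmers, np.uint64(seed), side="left")
        hi = np.searchsorted(self.sorted_kmers, np.uint64(seed), side="right")
        return self.order[lo:hi]

    def _verify(self, arr: np.ndarray, candidates: np.ndarray, strand: str,
                hits: list[tuple[int, str]]) -> bool:
        """Append verified hits; return False as soon as a second hit appears."""
        for p in candidates:
            p = int(p)
            end = p + arr.size
            if end > self.codes.size:
                continue
            if self.badcum[end] - self.badcum[p]:
                continue
            if np.array_equal(self.codes[p:end], arr):
                hits.append((p, strand))
                if len(hits) > 1:
                    return False
        return True

    def locate(self, read: str) -> tuple[str, int, str] | None:
        """Unique full-length location of ``read`` on either strand, or None."""
        q = _encode(read)
        if q.size < self.k or (q > 3).any():
            return None
        rc = (3 - q)[::-1]
        hits: list[tuple[int, str]] = []
        for strand, arr in (("+", q), ("-", rc)):
            seed = 0
            for j in range(self.k):
                seed = (seed << 2) | int(arr[j])
            if not self._verify(arr, self._candidates(seed), strand, hits):
                return None
        if len(hits) != 1:
            return None
        return self._to_local(hits[0])

    def _to_local(self, hit: tuple[int, str]) -> tuple[str, int, str]:
        p, strand = hit
        si = int(np.searchsorted(self.starts, p, side="right")) - 1
        return self.ids[si], p - int(self.starts[si]), strand

    def locate_batch(self, reads: Sequence[str]) -> list[tuple[str, int, str] | None]:
        """Vectorised :meth:`locate` over equal-length reads."""
        if not reads:
            return []
        arr = np.vstack([_encode(r) for r in reads])
        rc = (3 - arr)[:, ::-1]
        n, rl = arr.shape
        k = self.k
        seeds = np.zeros((2, n), dtype=np.uint64)
        for j in range(k):
            seeds[0] = (seeds[0] << np.uint64(2)) | arr[:, j].astype(np.uint64)
            seeds[1] = (seeds[1] << np.uint64(2)) | rc[:, j].astype(np.uint64)
        lo = np.searchsorted(self.sorted_kmers, seeds, side="left")
        hi = np.searchsorted(self.sorted_kmers, seeds, side="right")
        out: list[tuple[str, int, str] | None] = []
        for i in range(n):
            if rl < k or (arr[i] > 3).any():
                out.append(None)
                continue
            hits: list[tuple[int, str]] = []
            ok = self._verify(arr[i], self.order[lo[0, i]:hi[0, i]], "+", hits)
            if ok:
                ok = self._verify(rc[i], self.order[lo[1, i]:hi[1, i]], "-", hits)
            out.append(self._to_local(hits[0]) if ok and len(hits) == 1 else None)
        return out


def map_mate_pairs(
    pairs: Iterable[MatePair],
    scaffolds: Sequence[SequenceRecord],
    k: int = 31,
    index: _ExactMatchIndex | None = None,
) -> list[MappedPair]:
    """Map mate pairs onto scaffolds by unique exact full-length matching.

    Reads with zero or multiple full-length matches (either strand) are
    discarded; only pairs with both reads uniquely mapped are returned.
    A prebuilt index over the same scaffolds may be passed to amortise the
    indexing cost across libraries.
    """
    if index is None:
        index = _ExactMatchIndex(scaffolds, k=k)
    pairs = list(pairs)
    reads: list[str] = []
    for pair in pairs:
        reads.append(pair.read1_seq)
        reads.append(pair.read2_seq)
    # group equal-length reads for the batch path
    locs: list[tuple[str, int, str] | None] = [None] * len(reads)
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r), []).append(i)
    for _, idxs in sorted(by_len.items()):
        for i, loc in zip(idxs, index.locate_batch([reads[i] for i in idxs])):
            locs[i] = loc
    mapped: list[MappedPair] = []
    for j, pair in enumerate(pairs):
        loc1, loc2 = locs[2 * j], locs[2 * j + 1]
        if loc1 is None or loc2 is None:
            continue
        mapped.append(
            MappedPair(
                pair_id=pair.pair_id,
                scaffold_a=loc1[0], pos_a=loc1[1], strand_a=loc1[2],
                scaffold_b=loc2[0], pos_b=loc2[1], strand_b=loc2[2],
                insert_class=pair.insert_class,
            )
        )
    return mapped
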
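"""Readers and writers for the on-disk formats the scaffolder touches.

All coordinates are 0-based half-open internally.  The AGP writer converts to
1-based inclusive at the file boundary, which is what AGP v2.1 requires; PAF
is already 0-based half-open, so its columns pass through unshifted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "PairwiseAlignment",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_paf",
    "write_paf",
    "read_agp",
    "write_agp",
    "write_superscaffold_fasta",
    "write_bed",
]

_VALID = set("ACGTN")
_NONACGTN = re.compile(r"[^ACGTN]")
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_RC)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (scaffold, chromosome, mosaic, read)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PairwiseAlignment:
    """One aligned segment between a query scaffold and the reference.

    ``strand`` follows PAF semantics: query coordinates are always on the
    forward strand of the query; '-' means the query segment aligns to the
    reverse complement of the reference interval.
    """

    query_id: str
    q_start: int
    q_end: int
    query_len: int
    ref_id: str
    r_start: int
    r_end: int
    ref_len: int
    strand: str
    matches: int
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end <= self.query_len):
            raise ValueError(
                f"bad query interval {self.q_start}-{self.q_end} "
                f"(len {self.query_len}) on {self.query_id}"
            )
        if not (0 <= self.r_start < self.r_end <= self.ref_len):
            raise ValueError(
                f"bad reference interval {self.r_start}-{self.r_end} "
                f"(len {self.ref_len}) on {self.ref_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def r_span(self) -> int:
        return self.r_end - self.r_start


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file.

    Sequences are uppercased and characters outside {A,C,G,T,N} are mapped
    to N.  Duplicate headers are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header: {rec.id}")
        seen.add(rec.id)
        seq = _NONACGTN.sub("N", str(rec.seq).upper())
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    bio = (_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_paf(path: str | Path) -> list[PairwiseAlignment]:
    """Read alignments from a PAF file (>= 12 mandatory columns).

    The score is the mapping quality (column 12) unless an ``AS:i`` tag is
    present, in which case the alignment score is used.  Records with an
    empty query interval are rejected; the count of rejected records is
    attached to the returned list as ``.n_rejected``.
    """
    path = Path(path)
    alignments: list[PairwiseAlignment] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has {len(cols)} columns (<12)")
            try:
                qid, qlen, qs, qe = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
                strand = cols[4]
                rid, rlen, rs, re_ = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
                matches = int(cols[9])
                mapq = int(cols[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF line: {exc}") from None
            score: float = float(mapq)
            for tag in cols[12:]:
                if tag.startswith("AS:i:"):
                    score = float(tag[5:])
                    break
            if qe <= qs:
                n_rejected += 1
                continue
            alignments.append(
                PairwiseAlignment(qid, qs, qe, qlen, rid, rs, re_, rlen, strand, matches, score)
            )
    result = _PafList(alignments)
    result.n_rejected = n_rejected
    return result


class _PafList(list):
    """A list of alignments that also reports how many records were rejected."""

    n_rejected: int = 0


def write_paf(alignments: Iterable[PairwiseAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            block = max(a.q_span, a.r_span)
            fh.write(
                f"{a.query_id}\t{a.query_len}\t{a.q_start}\t{a.q_end}\t{a.strand}\t"
                f"{a.ref_id}\t{a.ref_len}\t{a.r_start}\t{a.r_end}\t{a.matches}\t"
                f"{block}\t60\tAS:i:{int(a.score)}\n"
            )


# --- AGP ---------------------------------------------------------------

def write_agp(superscaffolds, scaffold_lengths: dict[str, int], path: str | Path) -> None:
    """Write superscaffolds as AGP v2.1.

    Component lines are type W with 1-based inclusive coordinates; gap lines
    are type N with gap_type ``scaffold``, linkage ``yes`` and evidence
    ``align_genus``.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for ss in superscaffolds:
            pos = 0  # 0-based running offset on the object
            part_no = 0
            for i, (scf, orient, gap_after) in enumerate(ss.parts):
                if scf not in scaffold_lengths:
                    raise KeyError(f"unknown scaffold id in AGP output: {scf}")
                length = scaffold_lengths[scf]
                part_no += 1
                fh.write(
                    f"{ss.id}\t{pos + 1}\t{pos + length}\t{part_no}\tW\t"
                    f"{scf}\t1\t{length}\t{orient}\n"
                )
                pos += length
                last = i == len(ss.parts) - 1
                if not last:
                    if gap_after is None or gap_after <= 0:
                        raise ValueError(f"non-positive gap in {ss.id} after {scf}")
                    part_no += 1
                    fh.write(
                        f"{ss.id}\t{pos + 1}\t{pos + gap_after}\t{part_no}\tN\t"
                        f"{gap_after}\tscaffold\tyes\talign_genus\n"
                    )
                    pos += gap_after


def read_agp(path: str | Path):
    """Read an AGP v2.1 file back into Superscaffold objects."""
    from .graph import Superscaffold  # local import avoids a cycle

    objects: dict[str, list] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            obj = cols[0]
            if obj not in objects:
                objects[obj] = []
                order.append(obj)
            if cols[4] == "W":
                objects[obj].append([cols[5], cols[8], None])
            elif cols[4] == "N":
                objects[obj][-1][2] = int(cols[5])
    return [
        Superscaffold(obj, [(s, o, g) for s, o, g in objects[obj]]) for obj in order
    ]


def write_superscaffold_fasta(superscaffolds, scaffolds: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Materialise superscaffold sequences.

    Components are concatenated in order (reverse-complemented for '-'
    orientation) with runs of N of the recorded gap length between them.
    """
    by_id = {s.id: s.sequence for s in scaffolds}
    out: list[SequenceRecord] = []
    for ss in superscaffolds:
        pieces: list[str] = []
        for i, (scf, orient, gap_after) in enumerate(ss.parts):
            if scf not in by_id:
                raise KeyError(f"missing component sequence: {scf}")
            seq = by_id[scf]
            pieces.append(revcomp(seq) if orient == "-" else seq)
            if i < len(ss.parts) - 1:
                pieces.append("N" * int(gap_after))
        out.append(SequenceRecord(ss.id, "".join(pieces)))
    return out


def write_bed(blocks, path: str | Path) -> None:
    """Export collinear blocks as BED6 on reference coordinates.

    name = ``query_id:block_idx``, score = aligned bp, strand = block strand.
    """
    counters: dict[str, int] = {}
    with open(path, "w") as fh:
        for b in blocks:
            idx = counters.get(b.query_id, 0)
            counters[b.query_id] = idx + 1
            fh.write(
                f"{b.ref_id}\t{b.r_start}\t{b.r_end}\t{b.query_id}:{idx}\t"
                f"{b.aligned_bp}\t{b.strand}\n"
            )
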
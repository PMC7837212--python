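"""Local alignment and seed-and-extend read mapping.

The aligner is a full affine-gap Smith-Waterman (jitted kernel in ``_sw``)
with deterministic tie-breaking; unaligned read flanks are reported as soft
clips. ``map_read`` finds candidate windows by exact k-mer seeding against an
indexed reference set, searches both strands, and keeps the best-scoring
local alignment; reads whose best score falls below ``min_score`` are
unmapped. This stands in, at toy scale, for a short-read mapper.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._sw import OP_D, OP_EQ, OP_I, OP_X, sw_align
from .sequtil import check_alphabet, encode, revcomp
from .simulate import ReadRecord

__all__ = [
    "ScoringScheme",
    "AlignmentRecord",
    "ReferenceSet",
    "smith_waterman",
    "map_read",
    "mismatches_vs_reference",
    "oriented_bases",
    "oriented_qualities",
    "query_to_ref_map",
    "cigar_items",
    "write_sam",
]

_OP_CHARS = "=XID"
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/gap scores. Defaults favour clipping divergent tails
    over gapping, mimicking short-read mapper behaviour the xeno-filter
    depends on."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


@dataclass
class AlignmentRecord:
    """One read aligned (or not) to one reference sequence."""

    read_id: str
    ref_name: str | None
    ref_start0: int
    ref_end0: int
    strand: str  # '+' or '-'
    score: int
    cigar: str  # M/X/=/I/D/S over the full query
    n_mismatch: int
    aligned_length: int  # query bases inside the local alignment
    clipped_length: int  # query bases soft-clipped at the flanks
    mapped: bool
    query_length: int = 0

    def covers(self, contig: str, position0: int) -> bool:
        return (
            self.mapped
            and self.ref_name == contig
            and self.ref_start0 <= position0 < self.ref_end0
        )


def cigar_items(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _cigar_from_ops(ops: np.ndarray, lead_clip: int, tail_clip: int) -> str:
    parts: list[str] = []
    if lead_clip:
        parts.append(f"{lead_clip}S")
    run_op = -1
    run_len = 0
    for op in ops:
        if op == run_op:
            run_len += 1
        else:
            if run_len:
                parts.append(f"{run_len}{_OP_CHARS[run_op]}")
            run_op = int(op)
            run_len = 1
    if run_len:
        parts.append(f"{run_len}{_OP_CHARS[run_op]}")
    if tail_clip:
        parts.append(f"{tail_clip}S")
    return "".join(parts)


def _unmapped(read_id: str, qlen: int, score: int = 0) -> AlignmentRecord:
    return AlignmentRecord(
        read_id=read_id,
        ref_name=None,
        ref_start0=0,
        ref_end0=0,
        strand="+",
        score=score,
        cigar="",
        n_mismatch=0,
        aligned_length=0,
        clipped_length=qlen,
        mapped=False,
        query_length=qlen,
    )


def smith_waterman(
    query: str,
    target: str,
    scoring: ScoringScheme = ScoringScheme(),
    min_score: int = 1,
    read_id: str = "query",
    ref_name: str = "target",
) -> AlignmentRecord:
    """Optimal local alignment of ``query`` against ``target``.

    N never matches. Unaligned flanks of the query are soft clips. Records
    with best score below ``min_score`` are returned unmapped.
    """
    check_alphabet(query, "query")
    check_alphabet(target, "target")
    q = encode(query)
    t = encode(target)
    score, q0, q1, t0, t1, ops = sw_align(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if score < min_score:
        return _unmapped(read_id, len(query), score=int(score))
    n_mm = int(np.count_nonzero(ops == OP_X))
    aligned = int(np.count_nonzero((ops == OP_EQ) | (ops == OP_X) | (ops == OP_I)))
    cigar = _cigar_from_ops(ops, q0, len(query) - q1)
    return AlignmentRecord(
        read_id=read_id,
        ref_name=ref_name,
        ref_start0=int(t0),
        ref_end0=int(t1),
        strand="+",
        score=int(score),
        cigar=cigar,
        n_mismatch=n_mm,
        aligned_length=aligned,
        clipped_length=len(query) - aligned,
        mapped=True,
        query_length=len(query),
    )


class ReferenceSet:
    """A named set of reference sequences with exact k-mer seed indexes."""

    def __init__(self, sequences: dict[str, str], seed_length: int = 15):
        if seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        self.sequences = dict(sequences)
        self.names = list(self.sequences)
        self.lengths = {n: len(s) for n, s in self.sequences.items()}
        self.seed_length = seed_length
        self._codes = {n: encode(s) for n, s in self.sequences.items()}
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def codes(self, name: str) -> np.ndarray:
        return self._codes[name]

    def index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._indexes:
            idx: dict[str, list[tuple[str, int]]] = {}
            for name in self.names:
                seq = self.sequences[name]
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos : pos + k], []).append((name, pos))
            self._indexes[k] = idx
        return self._indexes[k]


def _seed_offsets(qlen: int, k: int) -> list[int]:
    offs = list(range(0, qlen - k + 1, k))
    last = qlen - k
    if last not in offs:
        offs.append(last)
    return offs


def _record_key(rec: AlignmentRecord) -> tuple:
    # score desc, then smallest ref start, shortest reference span,
    # lexicographic reference name, forward strand first
    return (
        -rec.score,
        rec.ref_start0,
        rec.ref_end0 - rec.ref_start0,
        rec.ref_name or "",
        rec.strand != "+",
    )


def map_read(
    read: ReadRecord | str,
    references: ReferenceSet,
    scoring: ScoringScheme = ScoringScheme(),
    seed_length: int | None = None,
    min_score: int | None = None,
    read_id: str | None = None,
) -> AlignmentRecord:
    """Best local alignment of a read over all references and both strands.

    Candidate windows are located by exact-seed matching at a stride of one
    seed length; each distinct diagonal is verified by Smith-Waterman on a
    padded window. Returns an unmapped record when no candidate reaches
    ``min_score`` (default: half the maximal score of the read).
    """
    if isinstance(read, ReadRecord):
        bases = read.bases
        rid = read.read_id
    else:
        bases = read
        rid = read_id or "read"
    check_alphabet(bases, "read")
    k = references.seed_length if seed_length is None else seed_length
    if k < 8:
        raise ValueError("seed_length must be >= 8")
    if len(bases) < k:
        raise ValueError(f"read shorter than seed length {k}")
    if min_score is None:
        min_score = int(np.ceil(0.5 * len(bases) * scoring.match))

    index = references.index(k)
    pad = 12
    qlen = len(bases)
    best: AlignmentRecord | None = None
    best_raw_score = 0
    for strand in "+-":
        q = bases if strand == "+" else revcomp(bases)
        diagonals: set[tuple[str, int]] = set()
        for off in _seed_offsets(qlen, k):
            for name, pos in index.get(q[off : off + k], ()):
                diagonals.add((name, pos - off))
        for name, diag in sorted(diagonals):
            ref_seq = references.sequences[name]
            ws = max(0, diag - pad)
            we = min(len(ref_seq), diag + qlen + pad)
            rec = smith_waterman(
                q,
                ref_seq[ws:we],
                scoring,
                min_score=1,
                read_id=rid,
                ref_name=name,
            )
            best_raw_score = max(best_raw_score, rec.score)
            if not rec.mapped:
                continue
            rec.ref_start0 += ws
            rec.ref_end0 += ws
            rec.strand = strand
            if best is None or _record_key(rec) < _record_key(best):
                best = rec
    if best is None or best.score < min_score:
        return _unmapped(rid, qlen, score=best_raw_score)
    return best


def oriented_bases(read: ReadRecord, aln: AlignmentRecord) -> str:
    """Read bases in the orientation the alignment refers to."""
    return read.bases if aln.strand == "+" else revcomp(read.bases)


def oriented_qualities(read: ReadRecord, aln: AlignmentRecord) -> np.ndarray:
    return read.qualities if aln.strand == "+" else read.qualities[::-1]


def query_to_ref_map(aln: AlignmentRecord) -> np.ndarray:
    """Per oriented-query-base reference position (-1 for clips/insertions)."""
    if not aln.mapped:
        raise ValueError("alignment is unmapped")
    out = np.full(aln.query_length, -1, dtype=np.int64)
    qpos = 0
    tpos = aln.ref_start0
    for length, op in cigar_items(aln.cigar):
        if op in "=XM":
            out[qpos : qpos + length] = np.arange(tpos, tpos + length)
            qpos += length
            tpos += length
        elif op in "SI":
            qpos += length
        elif op == "D":
            tpos += length
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    return out


def mismatches_vs_reference(aln: AlignmentRecord, query: str | ReadRecord, target: str) -> int:
    """Independent column-by-column recount of mismatches along an alignment.

    ``query`` is the read in its original orientation (or a plain string);
    ``target`` is the full reference sequence the record refers to. Gap and
    clipped columns are not mismatches.
    """
    if not aln.mapped:
        raise ValueError("cannot recount mismatches on an unmapped alignment")
    bases = query.bases if isinstance(query, ReadRecord) else query
    q = bases if aln.strand == "+" else revcomp(bases)
    n_mm = 0
    qpos = 0
    tpos = aln.ref_start0
    for length, op in cigar_items(aln.cigar):
        if op in "=XM":
            for i in range(length):
                qb = q[qpos + i]
                tb = target[tpos + i]
                if qb != tb or qb == "N":
                    n_mm += 1
            qpos += length
            tpos += length
        elif op in "SI":
            qpos += length
        elif op == "D":
            tpos += length
    return n_mm


def write_sam(
    alignments: list[AlignmentRecord],
    reads: dict[str, ReadRecord] | list[ReadRecord],
    references: ReferenceSet,
    path: str | Path,
) -> None:
    """Minimal SAM output (soft clips, =/X ops, NM = mismatch count)."""
    if isinstance(reads, list):
        reads = {r.read_id: r for r in reads}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in references.names:
            fh.write(f"@SQ\tSN:{name}\tLN:{references.lengths[name]}\n")
        for aln in alignments:
            read = reads[aln.read_id]
            if aln.mapped:
                seq = oriented_bases(read, aln)
                qual = "".join(chr(q + 33) for q in oriented_qualities(read, aln))
                flag = 0 if aln.strand == "+" else 16
                fh.write(
                    f"{aln.read_id}\t{flag}\t{aln.ref_name}\t{aln.ref_start0 + 1}\t60\t"
                    f"{aln.cigar}\t*\t0\t0\t{seq}\t{qual}\tNM:i:{aln.n_mismatch}\n"
                )
            else:
                qual = "".join(chr(q + 33) for q in read.qualities)
                fh.write(
                    f"{aln.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.bases}\t{qual}\n"
                )
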
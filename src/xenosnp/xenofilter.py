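"""Dual-genome read disambiguation (xenograft-style host-read removal).

Every read is aligned to both the graft (human-role) and host (mouse-role)
references; a read whose alignment is better on the host side — smaller
penalty, where penalty = mismatches + 0.2 per soft-clipped base — is removed
as host-derived. Ties are kept as graft, the conservative choice toward
retaining graft reads. Reads unmapped on both sides are dropped from variant
calling but logged separately: they are neither detected host reads nor
usable evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align import AlignmentRecord, ReferenceSet, ScoringScheme, map_read
from .simulate import DualReference, ReadRecord

__all__ = [
    "XenoVerdict",
    "FilterSummary",
    "KEEP_VERDICTS",
    "xeno_penalty",
    "classify_read",
    "classify_alignments",
    "filter_readset",
    "write_verdict_table",
]

KEEP_VERDICTS = frozenset({"keep_graft", "keep_unmapped_host"})


@dataclass(frozen=True)
class XenoVerdict:
    read_id: str
    graft_penalty: float
    host_penalty: float
    verdict: str  # keep_graft | remove_host | keep_unmapped_host | drop_both_unmapped

    @property
    def kept(self) -> bool:
        return self.verdict in KEEP_VERDICTS


@dataclass
class FilterSummary:
    sample: str
    n_total: int
    n_removed_host: int
    n_kept: int
    n_dropped_unmapped: int
    removed_fraction: float


def xeno_penalty(aln: AlignmentRecord, clip_cost: float = 0.2) -> float:
    """Alignment-quality penalty: mismatches + ``clip_cost`` per clipped base.

    Clipping must cost less than mismatching, else divergent tails dominate
    the comparison. Unmapped records get +infinity.
    """
    if not aln.mapped:
        return math.inf
    return aln.n_mismatch + clip_cost * aln.clipped_length


def classify_read(
    graft_aln: AlignmentRecord, host_aln: AlignmentRecord, clip_cost: float = 0.2
) -> XenoVerdict:
    """Decide a read's fate from its two alignments.

    Host penalty strictly smaller -> remove_host; graft penalty smaller or
    tied -> keep_graft; host-unmapped but graft-mapped -> keep_unmapped_host;
    both unmapped -> drop_both_unmapped.
    """
    if graft_aln.read_id != host_aln.read_id:
        raise ValueError(
            f"alignment pair refers to different reads: "
            f"{graft_aln.read_id!r} vs {host_aln.read_id!r}"
        )
    gp = xeno_penalty(graft_aln, clip_cost)
    hp = xeno_penalty(host_aln, clip_cost)
    if not graft_aln.mapped and not host_aln.mapped:
        verdict = "drop_both_unmapped"
    elif not host_aln.mapped:
        verdict = "keep_unmapped_host"
    elif not graft_aln.mapped:
        verdict = "remove_host"
    elif hp < gp:
        verdict = "remove_host"
    else:
        verdict = "keep_graft"
    return XenoVerdict(graft_aln.read_id, gp, hp, verdict)


def classify_alignments(
    graft_alignments: list[AlignmentRecord],
    host_alignments: list[AlignmentRecord],
    clip_cost: float = 0.2,
    sample: str = "sample",
) -> tuple[list[XenoVerdict], FilterSummary]:
    if len(graft_alignments) != len(host_alignments):
        raise ValueError("graft/host alignment lists differ in length")
    verdicts = [
        classify_read(g, h, clip_cost) for g, h in zip(graft_alignments, host_alignments)
    ]
    n_total = len(verdicts)
    n_removed = sum(v.verdict == "remove_host" for v in verdicts)
    n_dropped = sum(v.verdict == "drop_both_unmapped" for v in verdicts)
    n_kept = n_total - n_removed - n_dropped
    summary = FilterSummary(
        sample=sample,
        n_total=n_total,
        n_removed_host=n_removed,
        n_kept=n_kept,
        n_dropped_unmapped=n_dropped,
        removed_fraction=n_removed / n_total if n_total else 0.0,
    )
    return verdicts, summary


def filter_readset(
    reads: list[ReadRecord],
    reference: DualReference,
    scoring: ScoringScheme = ScoringScheme(),
    seed_length: int = 15,
    min_score: int | None = None,
    clip_cost: float = 0.2,
    sample: str = "sample",
) -> tuple[list[ReadRecord], FilterSummary, pd.DataFrame]:
    """Map reads to both genomes, remove host-better reads.

    Returns the kept reads, a per-sample summary, and the per-read verdict
    table. Filtering is pure read-subset selection: no alignment is altered.
    """
    graft_rs = ReferenceSet(reference.graft, seed_length)
    host_rs = ReferenceSet(reference.host, seed_length)
    galns = [map_read(r, graft_rs, scoring, min_score=min_score) for r in reads]
    halns = [map_read(r, host_rs, scoring, min_score=min_score) for r in reads]
    verdicts, summary = classify_alignments(galns, halns, clip_cost, sample)
    kept = [r for r, v in zip(reads, verdicts) if v.kept]
    return kept, summary, verdict_frame(verdicts)


def verdict_frame(verdicts: list[XenoVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [(v.read_id, v.graft_penalty, v.host_penalty, v.verdict) for v in verdicts],
        columns=["read_id", "graft_penalty", "host_penalty", "verdict"],
    )


def write_verdict_table(verdicts: list[XenoVerdict] | pd.DataFrame, path: str | Path) -> None:
    df = verdicts if isinstance(verdicts, pd.DataFrame) else verdict_frame(verdicts)
    df.to_csv(path, sep="\t", index=False)
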
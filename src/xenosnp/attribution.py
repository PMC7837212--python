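"""Read-level species attribution of candidate SNPs.

For each candidate SNP the reads carrying the alternate allele are retrieved
and aligned to two 101-bp fragments: the graft reference flank around the
site (50 bp either side plus the site itself) and the syntenic host fragment
located by local alignment of the graft flank against the host genome. Reads
whose aligned span exceeds 45 bp on both fragments contribute mismatch counts
and percent identities; a SNP whose alternate allele equals the host base at
the syntenic site and whose reads are more identical to the host fragment is
declared host-derived contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import (
    AlignmentRecord,
    ReferenceSet,
    ScoringScheme,
    cigar_items,
    map_read,
    oriented_bases,
    query_to_ref_map,
    smith_waterman,
)
from .sequtil import revcomp
from .simulate import DualReference, ReadRecord

__all__ = [
    "AttributionConfig",
    "FragmentPair",
    "ReadAttribution",
    "AttributionReport",
    "SyntenyError",
    "extract_alt_reads",
    "build_fragment_pair",
    "align_read_to_fragments",
    "attribute_snp",
    "report_frame",
    "write_attribution_table",
]

SnpKey = tuple[str, int, str, str]  # (contig, position0, ref_base, alt_base)


class SyntenyError(ValueError):
    """No credible syntenic host region for a graft fragment."""


@dataclass(frozen=True)
class AttributionConfig:
    flank: int = 50
    min_aligned: int = 45  # strict-greater retention: >= 46 aligned bases
    seed_length: int = 8
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    synteny_identity_floor: float = 60.0  # percent

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.min_aligned <= 0 or self.seed_length <= 0:
            raise ValueError("flank, min_aligned and seed_length must be positive")
        if self.flank < self.min_aligned / 2:
            raise ValueError("flank must be >= min_aligned / 2")


@dataclass
class FragmentPair:
    contig: str
    position0: int
    ref_base: str
    alt_base: str
    graft_fragment: str
    graft_offset: int  # variant offset within graft_fragment
    host_fragment: str
    host_offset: int  # orthologous offset within host_fragment
    host_base_at_site: str

    @property
    def key(self) -> SnpKey:
        return (self.contig, self.position0, self.ref_base, self.alt_base)

    @property
    def alt_matches_host_base(self) -> bool:
        return self.alt_base == self.host_base_at_site


@dataclass
class ReadAttribution:
    read_id: str
    mm_graft: int
    mm_host: int
    aligned_graft: int  # match+mismatch columns vs the graft fragment
    aligned_host: int
    identity_graft: float  # percent
    identity_host: float
    retained: bool


@dataclass
class AttributionReport:
    contig: str
    position0: int
    ref_base: str
    alt_base: str
    n_reads: int  # retained reads
    mean_mm_graft: float
    mean_mm_host: float
    mean_identity_graft: float
    mean_identity_host: float
    alt_matches_host_base: bool
    verdict: str  # host_origin | graft_origin | ambiguous

    @property
    def key(self) -> SnpKey:
        return (self.contig, self.position0, self.ref_base, self.alt_base)


def extract_alt_reads(
    alignments: list[AlignmentRecord],
    reads: dict[str, ReadRecord] | list[ReadRecord],
    snp_key: SnpKey,
) -> list[ReadRecord]:
    """Reads whose aligned base at the SNP position equals the alternate."""
    if isinstance(reads, list):
        reads = {r.read_id: r for r in reads}
    contig, pos, _, alt = snp_key
    out: list[ReadRecord] = []
    for aln in alignments:
        if not aln.covers(contig, pos):
            continue
        read = reads[aln.read_id]
        ref_map = query_to_ref_map(aln)
        hits = np.flatnonzero(ref_map == pos)
        if hits.size == 0:  # position deleted or clipped in this read
            continue
        if oriented_bases(read, aln)[int(hits[0])] == alt:
            out.append(read)
    return out


def build_fragment_pair(
    reference: DualReference,
    snp_key: SnpKey,
    config: AttributionConfig = AttributionConfig(),
    host_references: ReferenceSet | None = None,
) -> FragmentPair:
    """Extract the graft flank fragment and locate its syntenic host fragment.

    The graft fragment is ``flank`` bases either side of the site plus the
    site itself (101 bp at defaults; truncated at contig edges with recorded
    offsets). The host fragment is found by local alignment of the graft
    fragment against the whole host reference; the site's host coordinate is
    read through the alignment columns.
    """
    contig, pos, ref_base, alt_base = snp_key
    graft_seq = reference.graft[contig]
    if not 0 <= pos < len(graft_seq):
        raise ValueError(f"position {pos} outside contig {contig}")
    if graft_seq[pos] != ref_base:
        raise ValueError(
            f"reference base mismatch at {contig}:{pos}: "
            f"expected {ref_base}, found {graft_seq[pos]}"
        )
    start = max(0, pos - config.flank)
    end = min(len(graft_seq), pos + config.flank + 1)
    fragment = graft_seq[start:end]
    offset = pos - start

    if host_references is None:
        host_references = ReferenceSet(reference.host, config.seed_length)
    aln = map_read(
        fragment,
        host_references,
        config.scoring,
        seed_length=config.seed_length,
        read_id=f"frag:{contig}:{pos}",
    )
    if not aln.mapped:
        raise SyntenyError(f"no syntenic host region for {contig}:{pos}")
    if aln.strand != "+":
        raise SyntenyError(
            f"syntenic host region for {contig}:{pos} is reverse-oriented "
            "(not supported under the co-linear divergence model)"
        )
    aligned_cols = sum(n for n, op in cigar_items(aln.cigar) if op in "=XM")
    identity = 100.0 * (aligned_cols - aln.n_mismatch) / aligned_cols if aligned_cols else 0.0
    if identity < config.synteny_identity_floor:
        raise SyntenyError(
            f"best host alignment for {contig}:{pos} has identity "
            f"{identity:.1f}% below the {config.synteny_identity_floor:.0f}% floor"
        )
    ref_map = query_to_ref_map(aln)
    host_pos = int(ref_map[offset])
    if host_pos < 0:
        raise SyntenyError(f"site {contig}:{pos} falls in a gap of the syntenic alignment")

    host_seq = host_references.sequences[aln.ref_name]
    h_start = max(0, host_pos - config.flank)
    h_end = min(len(host_seq), host_pos + config.flank + 1)
    return FragmentPair(
        contig=contig,
        position0=pos,
        ref_base=ref_base,
        alt_base=alt_base,
        graft_fragment=fragment,
        graft_offset=offset,
        host_fragment=host_seq[h_start:h_end],
        host_offset=host_pos - h_start,
        host_base_at_site=host_seq[host_pos],
    )


def _fragment_align(bases: str, fragment: str, config: AttributionConfig) -> tuple[int, int]:
    """Best local alignment of a read against one fragment.

    An exact shared seed of ``config.seed_length`` bases (either strand)
    gates the alignment. Returns (aligned match+mismatch columns, mismatch
    count); (0, 0) when unaligned. Gap columns are excluded from both.
    """
    k = config.seed_length
    frag_kmers = {fragment[i : i + k] for i in range(len(fragment) - k + 1)}
    best: tuple[int, int, int] | None = None  # (score, aligned, mm)
    for strand in "+-":
        q = bases if strand == "+" else revcomp(bases)
        if not any(q[i : i + k] in frag_kmers for i in range(len(q) - k + 1)):
            continue
        rec = smith_waterman(q, fragment, config.scoring, min_score=1)
        if not rec.mapped:
            continue
        aligned_cols = sum(n for n, op in cigar_items(rec.cigar) if op in "=XM")
        cand = (rec.score, aligned_cols, rec.n_mismatch)
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        return 0, 0
    return best[1], best[2]


def align_read_to_fragments(
    read: ReadRecord | str,
    pair: FragmentPair,
    config: AttributionConfig = AttributionConfig(),
) -> ReadAttribution:
    """Align one read to both fragments and compute mismatch/identity stats.

    A read is retained only when its aligned span is strictly greater than
    ``config.min_aligned`` bases on both fragments; identity is
    100 * (aligned - mismatches) / aligned.
    """
    bases = read.bases if isinstance(read, ReadRecord) else read
    rid = read.read_id if isinstance(read, ReadRecord) else "read"
    ag, mg = _fragment_align(bases, pair.graft_fragment, config)
    ah, mh = _fragment_align(bases, pair.host_fragment, config)
    ident_g = 100.0 * (ag - mg) / ag if ag else 0.0
    ident_h = 100.0 * (ah - mh) / ah if ah else 0.0
    retained = ag > config.min_aligned and ah > config.min_aligned
    return ReadAttribution(
        read_id=rid,
        mm_graft=mg,
        mm_host=mh,
        aligned_graft=ag,
        aligned_host=ah,
        identity_graft=ident_g,
        identity_host=ident_h,
        retained=retained,
    )


def attribute_snp(
    attributions: list[ReadAttribution], pair: FragmentPair
) -> AttributionReport:
    """Aggregate per-read statistics into a species-of-origin verdict.

    host_origin: the alternate allele equals the host base at the syntenic
    site AND the retained reads are on average more identical to the host
    fragment. graft_origin: mean identity to the graft fragment is strictly
    higher. Anything else (including no retained reads) is ambiguous.
    """
    retained = [a for a in attributions if a.retained]
    n = len(retained)
    if n == 0:
        return AttributionReport(
            contig=pair.contig,
            position0=pair.position0,
            ref_base=pair.ref_base,
            alt_base=pair.alt_base,
            n_reads=0,
            mean_mm_graft=float("nan"),
            mean_mm_host=float("nan"),
            mean_identity_graft=float("nan"),
            mean_identity_host=float("nan"),
            alt_matches_host_base=pair.alt_matches_host_base,
            verdict="ambiguous",
        )
    mean_mm_g = float(np.mean([a.mm_graft for a in retained]))
    mean_mm_h = float(np.mean([a.mm_host for a in retained]))
    mean_id_g = float(np.mean([a.identity_graft for a in retained]))
    mean_id_h = float(np.mean([a.identity_host for a in retained]))
    if pair.alt_matches_host_base and mean_id_h > mean_id_g:
        verdict = "host_origin"
    elif mean_id_g > mean_id_h:
        verdict = "graft_origin"
    else:
        verdict = "ambiguous"
    return AttributionReport(
        contig=pair.contig,
        position0=pair.position0,
        ref_base=pair.ref_base,
        alt_base=pair.alt_base,
        n_reads=n,
        mean_mm_graft=mean_mm_g,
        mean_mm_host=mean_mm_h,
        mean_identity_graft=mean_id_g,
        mean_identity_host=mean_id_h,
        alt_matches_host_base=pair.alt_matches_host_base,
        verdict=verdict,
    )


def report_frame(reports: list[AttributionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.contig,
                r.position0 + 1,
                r.ref_base,
                r.alt_base,
                r.n_reads,
                r.mean_mm_graft,
                r.mean_mm_host,
                r.mean_identity_graft,
                r.mean_identity_host,
                r.alt_matches_host_base,
                r.verdict,
            )
            for r in reports
        ],
        columns=[
            "contig",
            "pos1",
            "ref",
            "alt",
            "n_reads",
            "mean_mm_graft",
            "mean_mm_host",
            "mean_identity_graft",
            "mean_identity_host",
            "alt_matches_host_base",
            "verdict",
        ],
    )


def write_attribution_table(reports: list[AttributionReport], path: str | Path) -> None:
    report_frame(reports).to_csv(path, sep="\t", index=False)
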
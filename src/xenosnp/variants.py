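"""Pileup-based SNP calling with a hard-filter (flagging) stage.

A toy-scale re-implementation of the usual RNA-seq variant-calling recipe:
base-quality-aware pileup, threshold calling per (site, alternate base), and
a flag-don't-drop hard filter marking SNP clusters (>= ``cluster_size`` calls
within a ``cluster_window``-base span) and low quality-by-depth calls. Calls
are never deleted by filtering, so before/after comparisons operate on one
call set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignmentRecord, cigar_items, oriented_bases, oriented_qualities
from .sequtil import BASES, encode
from .simulate import ReadRecord

__all__ = [
    "PileupColumn",
    "VariantCall",
    "VariantPanel",
    "build_pileup",
    "call_snps",
    "hard_filter",
    "intersect_panel",
    "write_vcf",
    "read_vcf",
]


@dataclass
class PileupColumn:
    contig: str
    position0: int
    ref_base: str
    base_counts: dict[str, int]
    base_qual_sums: dict[str, int]
    depth: int


@dataclass
class VariantCall:
    contig: str
    position0: int
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int
    alt_fraction: float
    qd_score: float  # summed alt base quality / site depth
    filters: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position0, self.ref_base, self.alt_base)

    @property
    def passed(self) -> bool:
        """True when filters are unset or contain only PASS."""
        return not (self.filters - {"PASS"})


@dataclass
class VariantPanel:
    """A panel of (contig, position, ref, alt, label) sites of interest,
    mirroring a published list of cancer-associated SNPs."""

    entries: list[tuple[str, int, str, str, str]]

    def __post_init__(self) -> None:
        keys = [(c, p, a) for c, p, _, a, _ in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("panel entries must have unique (contig, position, alt) keys")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {(c, p, r, a) for c, p, r, a, _ in self.entries}

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(c, p + 1, r, a, lab) for c, p, r, a, lab in self.entries],
            columns=["contig", "pos1", "ref", "alt", "label"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantPanel":
        df = pd.read_csv(path, sep="\t")
        entries = [
            (str(r.contig), int(r.pos1) - 1, str(r.ref), str(r.alt), str(r.label))
            for r in df.itertuples()
        ]
        return cls(entries)


def build_pileup(
    alignments: list[AlignmentRecord],
    reads: dict[str, ReadRecord] | list[ReadRecord],
    reference: dict[str, str],
    min_base_quality: int = 20,
) -> list[PileupColumn]:
    """Per-position base counts from mapped alignments.

    Bases below ``min_base_quality`` and N bases are excluded from counts;
    the column depth is the sum of the retained A/C/G/T counts.
    """
    if isinstance(reads, list):
        reads = {r.read_id: r for r in reads}
    counts: dict[str, np.ndarray] = {}
    qsums: dict[str, np.ndarray] = {}
    for aln in alignments:
        if not aln.mapped:
            continue
        if aln.ref_name not in reference:
            raise ValueError(f"alignment references unknown contig {aln.ref_name!r}")
        contig = aln.ref_name
        length = len(reference[contig])
        if contig not in counts:
            counts[contig] = np.zeros((4, length), dtype=np.int64)
            qsums[contig] = np.zeros((4, length), dtype=np.int64)
        read = reads[aln.read_id]
        codes = encode(oriented_bases(read, aln))
        quals = oriented_qualities(read, aln)
        qpos = 0
        tpos = aln.ref_start0
        for seg_len, op in cigar_items(aln.cigar):
            if op in "=XM":
                c = codes[qpos : qpos + seg_len]
                q = quals[qpos : qpos + seg_len]
                pos = np.arange(tpos, tpos + seg_len)
                keep = (q >= min_base_quality) & (c < 4)
                np.add.at(counts[contig], (c[keep], pos[keep]), 1)
                np.add.at(qsums[contig], (c[keep], pos[keep]), q[keep].astype(np.int64))
                qpos += seg_len
                tpos += seg_len
            elif op in "SI":
                qpos += seg_len
            elif op == "D":
                tpos += seg_len

    columns: list[PileupColumn] = []
    for contig in sorted(counts):
        cnt = counts[contig]
        qs = qsums[contig]
        ref_seq = reference[contig]
        for pos in np.flatnonzero(cnt.sum(axis=0) > 0):
            pos = int(pos)
            bc = {BASES[b]: int(cnt[b, pos]) for b in range(4)}
            bq = {BASES[b]: int(qs[b, pos]) for b in range(4)}
            columns.append(
                PileupColumn(
                    contig=contig,
                    position0=pos,
                    ref_base=ref_seq[pos],
                    base_counts=bc,
                    base_qual_sums=bq,
                    depth=sum(bc.values()),
                )
            )
    return columns


def call_snps(
    pileup: list[PileupColumn],
    min_depth: int = 10,
    min_alt_count: int = 3,
    min_alt_fraction: float = 0.05,
) -> list[VariantCall]:
    """Emit a call per (position, alternate base) meeting all thresholds.

    Filters are left empty; :func:`hard_filter` assigns them. Defaults are
    calibrated to the synthetic design: host reads at >=5% contamination and
    depth ~50 produce calls, while isolated sequencing errors do not.
    """
    if min_depth <= 0 or min_alt_count <= 0 or min_alt_fraction <= 0:
        raise ValueError("calling thresholds must be positive")
    calls: list[VariantCall] = []
    for col in pileup:
        if col.depth < min_depth:
            continue
        for base in BASES:
            if base == col.ref_base:
                continue
            count = col.base_counts.get(base, 0)
            if count < min_alt_count:
                continue
            fraction = count / col.depth
            if fraction < min_alt_fraction:
                continue
            calls.append(
                VariantCall(
                    contig=col.contig,
                    position0=col.position0,
                    ref_base=col.ref_base,
                    alt_base=base,
                    depth=col.depth,
                    alt_count=count,
                    alt_fraction=fraction,
                    qd_score=col.base_qual_sums.get(base, 0) / col.depth,
                )
            )
    calls.sort(key=lambda c: (c.contig, c.position0, c.alt_base))
    return calls


def hard_filter(
    calls: list[VariantCall],
    cluster_window: int = 35,
    cluster_size: int = 3,
    min_qd: float = 2.0,
) -> list[VariantCall]:
    """Populate filter flags; no call is deleted.

    ``SnpCluster``: the call belongs to a run of >= ``cluster_size`` calls on
    one contig spanning at most ``cluster_window`` bases (GATK
    VariantFiltration convention). ``LowQD``: quality-by-depth below
    ``min_qd``. Calls with no flag get ``PASS``. Input must be sorted by
    (contig, position).
    """
    order = [(c.contig, c.position0) for c in calls]
    if order != sorted(order):
        raise ValueError("hard_filter requires calls sorted by (contig, position)")

    flagged: list[VariantCall] = []
    by_contig: dict[str, list[int]] = {}
    for i, c in enumerate(calls):
        by_contig.setdefault(c.contig, []).append(i)

    in_cluster = [False] * len(calls)
    for idxs in by_contig.values():
        pos = [calls[i].position0 for i in idxs]
        n = len(idxs)
        for a in range(n - cluster_size + 1):
            b = a + cluster_size - 1
            if pos[b] - pos[a] <= cluster_window:
                for k in range(a, b + 1):
                    in_cluster[idxs[k]] = True

    for i, c in enumerate(calls):
        flags: set[str] = set()
        if in_cluster[i]:
            flags.add("SnpCluster")
        if c.qd_score < min_qd:
            flags.add("LowQD")
        if not flags:
            flags.add("PASS")
        flagged.append(
            VariantCall(
                contig=c.contig,
                position0=c.position0,
                ref_base=c.ref_base,
                alt_base=c.alt_base,
                depth=c.depth,
                alt_count=c.alt_count,
                alt_fraction=c.alt_fraction,
                qd_score=c.qd_score,
                filters=flags,
            )
        )
    return flagged


def intersect_panel(
    calls: list[VariantCall], panel: VariantPanel, pass_only: bool = False
) -> tuple[int, list[VariantCall]]:
    """Count panel entries matched by calls (identical contig, position, ref
    and alt). With ``pass_only`` only calls whose filters are PASS (or unset)
    are considered."""
    keys = panel.keys
    matched = [
        c for c in calls if c.key in keys and (not pass_only or c.passed)
    ]
    matched_entries = {c.key for c in matched}
    return len(matched_entries), matched


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate allele count">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">
##INFO=<ID=QD,Number=1,Type=Float,Description="Summed alt base quality over depth">
##FILTER=<ID=SnpCluster,Description="Member of a SNP cluster">
##FILTER=<ID=LowQD,Description="Quality by depth below threshold">
"""


def write_vcf(
    calls: list[VariantCall], contig_lengths: dict[str, int], path: str | Path
) -> None:
    """Minimal VCF 4.2 output (positions 1-based)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if not c.filters:
                filt = "."
            elif c.passed:
                filt = "PASS"
            else:
                filt = ";".join(sorted(c.filters - {"PASS"}))
            info = f"DP={c.depth};AC={c.alt_count};AF={c.alt_fraction!r};QD={c.qd_score!r}"
            fh.write(
                f"{c.contig}\t{c.position0 + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\t{filt}\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, filt, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            if filt == ".":
                filters: set[str] = set()
            elif filt == "PASS":
                filters = {"PASS"}
            else:
                filters = set(filt.split(";"))
            depth = int(fields["DP"])
            alt_count = int(fields["AC"])
            calls.append(
                VariantCall(
                    contig=chrom,
                    position0=int(pos) - 1,
                    ref_base=ref,
                    alt_base=alt,
                    depth=depth,
                    alt_count=alt_count,
                    alt_fraction=float(fields["AF"]),
                    qd_score=float(fields["QD"]),
                    filters=filters,
                )
            )
    return calls
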
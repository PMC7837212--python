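"""Per-sample host-read contamination estimates and their relation to
spurious panel-SNP counts.

Three estimators of the host read fraction are supported: simulator truth
labels, the xeno-filter removal fraction, and an alignment-free k-mer
classifier that assigns each read by majority vote of canonical k-mers unique
to one species' reference (a stand-in for metagenomic sequence classifiers).
The association between host fraction and spurious panel-SNP counts across a
sample series is summarised by a Pearson correlation with a least-squares
line.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .sequtil import canonical_kmer
from .simulate import DualReference, ReadRecord

__all__ = [
    "SampleContamination",
    "CorrelationResult",
    "SpeciesKmerIndex",
    "kmer_classify_reads",
    "correlate_contamination_vs_snps",
    "count_reads_per_gene",
]


@dataclass
class SampleContamination:
    sample: str
    n_reads: int
    n_host_assigned: int
    n_graft_assigned: int
    n_unassigned: int
    host_fraction: float  # percent, among assigned reads
    host_fraction_of_total: float  # percent, among all reads
    method: str  # "xeno" | "kmer" | "truth"


@dataclass
class CorrelationResult:
    n_samples: int
    pearson_r: float
    slope: float
    intercept: float


class SpeciesKmerIndex:
    """Canonical k-mers unique to the graft or the host reference.

    With substitution-only divergence the discriminative k-mers are exactly
    those overlapping an interspecies substitution; reads from locally
    identical regions carry no vote and stay unassigned.
    """

    def __init__(self, reference: DualReference, k: int = 15):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        graft = self._kmers(reference.graft.values())
        host = self._kmers(reference.host.values())
        self.graft_only = graft - host
        self.host_only = host - graft

    def _kmers(self, seqs) -> set[str]:
        k = self.k
        out: set[str] = set()
        for seq in seqs:
            for i in range(len(seq) - k + 1):
                out.add(canonical_kmer(seq[i : i + k]))
        return out

    def classify(self, bases: str) -> str | None:
        """'graft', 'host', or None for a tie / no discriminative k-mer."""
        k = self.k
        if len(bases) < k:
            raise ValueError(f"read shorter than k = {k}")
        g = h = 0
        for i in range(len(bases) - k + 1):
            km = canonical_kmer(bases[i : i + k])
            if km in self.graft_only:
                g += 1
            elif km in self.host_only:
                h += 1
        if g > h:
            return "graft"
        if h > g:
            return "host"
        return None


def kmer_classify_reads(
    reads: list[ReadRecord],
    reference: DualReference,
    k: int = 15,
    sample: str = "sample",
    index: SpeciesKmerIndex | None = None,
) -> SampleContamination:
    """Assign each read to a species by unique-k-mer majority vote.

    Ties and no-vote reads are unassigned and excluded from the host-fraction
    denominator (an of-total fraction is also reported).
    """
    if index is None:
        index = SpeciesKmerIndex(reference, k)
    elif index.k != k:
        raise ValueError("index k does not match requested k")
    n_g = n_h = 0
    for r in reads:
        species = index.classify(r.bases)
        if species == "graft":
            n_g += 1
        elif species == "host":
            n_h += 1
    n_total = len(reads)
    n_assigned = n_g + n_h
    return SampleContamination(
        sample=sample,
        n_reads=n_total,
        n_host_assigned=n_h,
        n_graft_assigned=n_g,
        n_unassigned=n_total - n_assigned,
        host_fraction=100.0 * n_h / n_assigned if n_assigned else 0.0,
        host_fraction_of_total=100.0 * n_h / n_total if n_total else 0.0,
        method="kmer",
    )


def correlate_contamination_vs_snps(
    samples: list[tuple[float, float]],
) -> CorrelationResult:
    """Pearson r and least-squares line for (host_fraction, snp_count) pairs."""
    if len(samples) < 3:
        raise ValueError("correlation requires at least 3 samples")
    x = np.asarray([s[0] for s in samples], dtype=float)
    y = np.asarray([s[1] for s in samples], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("host_fraction axis has zero variance")
    if np.ptp(y) == 0:
        raise ValueError("snp_count axis has zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        n_samples=len(samples),
        pearson_r=r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def count_reads_per_gene(
    alignments: list[AlignmentRecord], contigs: list[str]
) -> pd.Series:
    """Mapped-read counts per contig (each contig plays the role of a gene)."""
    counter = Counter(a.ref_name for a in alignments if a.mapped)
    return pd.Series({c: int(counter.get(c, 0)) for c in contigs}, name="n_reads")
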
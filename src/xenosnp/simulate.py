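"""Synthetic dual-species references, planted variants and mixed-origin reads.

This module generates the ground-truth study material for the rest of the
package: pairs of orthologous "graft" (human-role) and "host" (mouse-role)
reference sequences diverged by substitutions only, germline variants planted
on the graft genome, and single-end reads drawn from either genome with a
configurable host-read contamination fraction — emulating RNA-seq libraries
from pluripotent stem cells co-cultured on mouse feeder cells versus
feeder-free cultures.

Every stochastic quantity is driven by explicit integer seeds so outputs are
byte-identical across reruns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtil import BASES, decode, encode

__all__ = [
    "DualReference",
    "PlantedVariant",
    "ReadRecord",
    "SampleSpec",
    "simulate_dual_reference",
    "plant_variants",
    "simulate_reads",
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_substitution_table",
    "write_variant_table",
    "write_origin_table",
    "read_table",
]


@dataclass(eq=False)
class DualReference:
    """Paired graft/host references under a substitution-only divergence model.

    contigs: list of ``(name, graft_seq, host_seq)``; the two sequences of a
    contig have equal length. ``substitution_map`` lists every interspecies
    difference as ``(contig, position0, graft_base, host_base)``.
    """

    contigs: list[tuple[str, str, str]]
    substitution_map: list[tuple[str, int, str, str]]
    divergence: float

    @cached_property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.contigs]

    @cached_property
    def graft(self) -> dict[str, str]:
        return {name: g for name, g, _ in self.contigs}

    @cached_property
    def host(self) -> dict[str, str]:
        return {name: h for name, _, h in self.contigs}

    @cached_property
    def lengths(self) -> dict[str, int]:
        return {name: len(g) for name, g, _ in self.contigs}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @cached_property
    def substitutions_by_contig(self) -> dict[str, np.ndarray]:
        """Sorted 0-based substitution positions per contig."""
        out: dict[str, list[int]] = {name: [] for name in self.names}
        for contig, pos, _, _ in self.substitution_map:
            out[contig].append(pos)
        return {name: np.asarray(sorted(p), dtype=np.int64) for name, p in out.items()}

    def validate(self) -> None:
        for name, g, h in self.contigs:
            if len(g) != len(h):
                raise ValueError(f"contig {name}: graft/host length mismatch")
        for contig, pos, gb, hb in self.substitution_map:
            if self.graft[contig][pos] != gb or self.host[contig][pos] != hb or gb == hb:
                raise ValueError(f"inconsistent substitution entry at {contig}:{pos}")


@dataclass(frozen=True)
class PlantedVariant:
    """A germline variant planted on the graft genome."""

    contig: str
    position0: int
    ref_base: str
    alt_base: str
    zygosity: str  # "het" | "hom"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position0, self.ref_base, self.alt_base)


@dataclass(eq=False)
class ReadRecord:
    """A (simulated) single-end read.

    ``true_origin``, ``source_contig`` and ``source_position0`` carry ground
    truth in synthetic mode and are ``None`` for reads parsed from FASTQ.
    """

    read_id: str
    bases: str
    qualities: np.ndarray  # Phred scores, uint8
    true_origin: str | None = None  # "graft" | "host" | None
    source_contig: str | None = None
    source_position0: int | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.read_id}: bases/qualities length mismatch")
        if len(self.qualities) and (self.qualities.min() < 2 or self.qualities.max() > 41):
            raise ValueError(f"read {self.read_id}: Phred scores must lie in [2, 41]")

    def __len__(self) -> int:
        return len(self.bases)

    def same_content(self, other: "ReadRecord") -> bool:
        return (
            self.read_id == other.read_id
            and self.bases == other.bases
            and np.array_equal(self.qualities, other.qualities)
        )


@dataclass
class SampleSpec:
    """Parameters of one simulated sequencing library."""

    name: str
    depth: float = 50.0
    read_length: int = 100
    error_rate: float = 0.003
    contamination_fraction: float = 0.0
    seed: int = 0
    base_quality: int = 40

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must lie in [0, 1]")
        if self.depth <= 0 or self.read_length <= 0:
            raise ValueError("depth and read_length must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if not 2 <= self.base_quality <= 41:
            raise ValueError("base_quality must lie in [2, 41]")


def simulate_dual_reference(
    n_contigs: int, contig_length: int, divergence: float, seed: int
) -> DualReference:
    """Simulate orthologous graft/host contig pairs.

    The graft sequence is uniform random; each position independently carries
    an interspecies substitution with probability ``divergence`` (human-mouse
    exonic scale is roughly 0.05-0.10), replacing the graft base with one of
    the three alternatives uniformly. No indels are introduced, so graft and
    host coordinates are identical.
    """
    if n_contigs <= 0 or contig_length <= 0:
        raise ValueError("n_contigs and contig_length must be positive")
    if contig_length < 200:
        raise ValueError("contig_length must be >= 200")
    if not 0.0 <= divergence <= 0.25:
        raise ValueError("divergence must lie in [0, 0.25]")

    rng = np.random.default_rng(seed)
    contigs: list[tuple[str, str, str]] = []
    submap: list[tuple[str, int, str, str]] = []
    width = max(2, len(str(n_contigs)))
    for c in range(n_contigs):
        name = f"contig{c + 1:0{width}d}"
        graft_codes = rng.integers(0, 4, size=contig_length, dtype=np.uint8)
        sub_mask = rng.random(contig_length) < divergence
        host_codes = graft_codes.copy()
        n_sub = int(sub_mask.sum())
        if n_sub:
            shift = rng.integers(1, 4, size=n_sub, dtype=np.uint8)
            host_codes[sub_mask] = (graft_codes[sub_mask] + shift) % 4
        graft = decode(graft_codes)
        host = decode(host_codes)
        for pos in np.flatnonzero(sub_mask):
            submap.append((name, int(pos), graft[pos], host[pos]))
        contigs.append((name, graft, host))
    ref = DualReference(contigs=contigs, substitution_map=submap, divergence=divergence)
    ref.validate()
    return ref


def plant_variants(
    ref: DualReference,
    n_variants: int,
    het_fraction: float,
    seed: int,
    *,
    margin: int = 0,
    min_spacing: int = 0,
    guard_window: int = 0,
    marker_band: tuple[int, int] | None = None,
) -> list[PlantedVariant]:
    """Plant germline variants on the graft genome at unique positions.

    Variants never coincide with interspecies substitutions, so the species
    attribution of every candidate SNP stays unambiguous. Placement can be
    constrained further so each downstream diagnostic is well-posed:

    margin
        keep variants at least this far from contig ends (guarantees full
        read coverage when margin >= read length);
    min_spacing
        minimum distance between planted variants (authentic germline SNPs
        are sparse; no planted-planted clusters);
    guard_window
        forbid positions where some window of span <= ``guard_window``
        contains the variant plus two or more interspecies substitutions,
        so contamination-derived SNP clusters can never engulf an authentic
        variant (set to the cluster filter's window);
    marker_band
        ``(lo, hi)``: require at least one interspecies substitution at a
        distance in ``[lo, hi]`` on either side, so the cross-species
        attribution diagnostic always has an informative marker in the flank.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be non-negative")
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must lie in [0, 1]")
    if n_variants == 0:
        return []

    rng = np.random.default_rng(seed)
    eligible: list[tuple[str, int]] = []
    for name in ref.names:
        length = ref.lengths[name]
        subs = ref.substitutions_by_contig[name]
        ok = np.zeros(length, dtype=bool)
        lo_edge, hi_edge = margin, length - margin
        if lo_edge < hi_edge:
            ok[lo_edge:hi_edge] = True
        ok[subs] = False

        ind = np.zeros(length, dtype=np.int64)
        np.add.at(ind, subs, 1)
        # pref[i] = number of substitutions at positions < i
        pref = np.concatenate([[0], np.cumsum(ind)])

        def count(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            # substitutions at positions in [a, b] inclusive
            a = np.clip(a, 0, length)
            b = np.clip(b + 1, 0, length)
            return pref[np.maximum(b, a)] - pref[a]

        if guard_window > 0:
            # a window of span <= guard_window holding the variant and two
            # substitutions requires a consecutive substitution pair with
            # gap <= guard_window; such a pair (s1 < s2) excludes positions
            # in [s2 - guard_window, s1 + guard_window]
            for s1, s2 in zip(subs[:-1], subs[1:]):
                if s2 - s1 <= guard_window:
                    lo_x = max(0, int(s2) - guard_window)
                    hi_x = min(length, int(s1) + guard_window + 1)
                    ok[lo_x:hi_x] = False
        pos = np.arange(length)
        if marker_band is not None:
            lo, hi = marker_band
            if not 0 < lo <= hi:
                raise ValueError("marker_band must satisfy 0 < lo <= hi")
            flank_hits = count(pos - hi, pos - lo) + count(pos + lo, pos + hi)
            ok &= flank_hits >= 1
        for p in np.flatnonzero(ok):
            eligible.append((name, int(p)))

    if len(eligible) < n_variants:
        raise ValueError(
            f"only {len(eligible)} eligible positions for {n_variants} variants"
        )

    # random sequential pick respecting min_spacing within each contig
    order = rng.permutation(len(eligible))
    chosen: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {}
    def try_place(contig: str, p: int) -> bool:
        placed = taken.setdefault(contig, [])
        if min_spacing > 0 and any(abs(p - q) < min_spacing for q in placed):
            return False
        placed.append(p)
        chosen.append((contig, p))
        return True

    for idx in order:
        contig, p = eligible[int(idx)]
        try_place(contig, p)
        if len(chosen) == n_variants:
            break
    if len(chosen) < n_variants:
        # densify deterministically: sorted sweep fills gaps the random pass
        # blocked, approaching the maximal packing under min_spacing
        for contig, p in sorted(eligible):
            try_place(contig, p)
            if len(chosen) == n_variants:
                break
    if len(chosen) < n_variants:
        raise ValueError(
            f"could not place {n_variants} variants with min_spacing={min_spacing}; "
            f"managed {len(chosen)}"
        )

    variants: list[PlantedVariant] = []
    for contig, p in sorted(chosen):
        ref_base = ref.graft[contig][p]
        alt_base = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        zyg = "het" if rng.random() < het_fraction else "hom"
        variants.append(PlantedVariant(contig, p, ref_base, alt_base, zyg))
    return variants


def simulate_reads(
    ref: DualReference, variants: list[PlantedVariant], spec: SampleSpec
) -> list[ReadRecord]:
    """Simulate a mixed-origin single-end read set with complete ground truth.

    Reads are drawn from contigs proportionally to length with uniform start
    positions; a fraction ``spec.contamination_fraction`` of reads originates
    from the host genome. Graft reads carry each overlapping het variant with
    probability 0.5 and each hom variant always; uniform substitution errors
    at ``spec.error_rate`` are then applied to all reads. Host reads never
    carry planted variants.
    """
    min_len = min(ref.lengths.values())
    if spec.read_length > min_len:
        raise ValueError(
            f"read_length {spec.read_length} exceeds shortest contig ({min_len})"
        )
    if ref.divergence > 0 and spec.error_rate >= ref.divergence:
        warnings.warn(
            "error_rate >= divergence: species attribution of single reads is "
            "information-theoretically void",
            stacklevel=2,
        )
    if ref.divergence == 0 and spec.contamination_fraction > 0:
        warnings.warn(
            "zero divergence with non-zero contamination: host reads are "
            "indistinguishable from graft reads",
            stacklevel=2,
        )

    rng = np.random.default_rng(spec.seed)
    names = ref.names
    lengths = np.array([ref.lengths[n] for n in names], dtype=np.float64)
    n_reads = int(round(spec.depth * lengths.sum() / spec.read_length))

    graft_codes = {n: encode(ref.graft[n]) for n in names}
    host_codes = {n: encode(ref.host[n]) for n in names}
    var_by_contig: dict[str, list[PlantedVariant]] = {n: [] for n in names}
    for v in variants:
        var_by_contig[v.contig].append(v)

    contig_idx = rng.choice(len(names), size=n_reads, p=lengths / lengths.sum())
    is_host = rng.random(n_reads) < spec.contamination_fraction
    quals = np.full(spec.read_length, spec.base_quality, dtype=np.uint8)

    reads: list[ReadRecord] = []
    rl = spec.read_length
    for i in range(n_reads):
        contig = names[int(contig_idx[i])]
        length = int(lengths[int(contig_idx[i])])
        start = int(rng.integers(0, length - rl + 1))
        host = bool(is_host[i])
        src = host_codes[contig] if host else graft_codes[contig]
        codes = src[start : start + rl].copy()
        if not host:
            for v in var_by_contig[contig]:
                off = v.position0 - start
                if 0 <= off < rl and (v.zygosity == "hom" or rng.random() < 0.5):
                    codes[off] = BASES.index(v.alt_base)
        if spec.error_rate > 0:
            err = rng.random(rl) < spec.error_rate
            n_err = int(err.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
                codes[err] = (codes[err] + shift) % 4
        reads.append(
            ReadRecord(
                read_id=f"{spec.name}:{i:06d}",
                bases=decode(codes),
                qualities=quals,
                true_origin="host" if host else "graft",
                source_contig=contig,
                source_position0=start,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# file I/O


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    """Write reads as FASTQ with Phred+33 qualities."""
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
            SeqIO.write([rec], fh, "fastq")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            ReadRecord(
                read_id=rec.id,
                bases=str(rec.seq).upper(),
                qualities=np.asarray(rec.letter_annotations["phred_quality"], dtype=np.uint8),
            )
        )
    return out


def write_substitution_table(ref: DualReference, path: str | Path) -> None:
    """Interspecies substitutions as TSV with 1-based positions."""
    df = pd.DataFrame(
        [(c, p + 1, g, h) for c, p, g, h in ref.substitution_map],
        columns=["contig", "pos1", "graft_base", "host_base"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_variant_table(variants: list[PlantedVariant], path: str | Path) -> None:
    df = pd.DataFrame(
        [(v.contig, v.position0 + 1, v.ref_base, v.alt_base, v.zygosity) for v in variants],
        columns=["contig", "pos1", "ref", "alt", "zygosity"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_origin_table(reads: list[ReadRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.read_id, r.true_origin) for r in reads], columns=["read_id", "origin"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
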
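"""End-to-end orchestration: simulate -> map -> xeno-filter -> call ->
hard-filter -> panel intersect -> attribute -> quantify.

One flat key-value config drives a deterministic run that writes every
intermediate (FASTA, FASTQ, SAM, VCF, TSV) plus a machine-readable JSON
summary under the output directory, and returns a :class:`RunReport` with
the per-sample before/after comparison table, the contamination-vs-SNP
correlation, and the per-SNP attribution verdicts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .align import ReferenceSet, ScoringScheme, map_read, write_sam
from .attribution import (
    AttributionConfig,
    AttributionReport,
    align_read_to_fragments,
    attribute_snp,
    build_fragment_pair,
    extract_alt_reads,
    report_frame,
    write_attribution_table,
)
from .contamination import (
    CorrelationResult,
    SpeciesKmerIndex,
    correlate_contamination_vs_snps,
    kmer_classify_reads,
)
from .sequtil import derive_seed
from .simulate import (
    DualReference,
    PlantedVariant,
    SampleSpec,
    plant_variants,
    simulate_dual_reference,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_origin_table,
    write_substitution_table,
    write_variant_table,
)
from .variants import (
    VariantCall,
    VariantPanel,
    build_pileup,
    call_snps,
    hard_filter,
    intersect_panel,
    write_vcf,
)
from .xenofilter import KEEP_VERDICTS, classify_alignments, write_verdict_table

__all__ = ["RunConfig", "RunReport", "ConfigError", "demo_config", "build_panel", "run_pipeline"]

log = logging.getLogger("xenosnp")


class ConfigError(ValueError):
    """Invalid or unknown configuration input."""


DEMO_SAMPLES: tuple[tuple[str, float], ...] = (
    ("LN-1", 0.0),
    ("LN-2", 0.0),
    ("MEF-02", 0.02),
    ("MEF-05", 0.05),
    ("MEF-10", 0.10),
    ("MEF-15", 0.15),
    ("MEF-20", 0.20),
    ("MEF-30", 0.30),
)


@dataclass
class RunConfig:
    """Flat run configuration; every stage reads its parameters from here."""

    # reference / truth
    n_contigs: int = 20
    contig_length: int = 1500
    divergence: float = 0.06
    seed: int = 1234
    n_variants: int = 100
    het_fraction: float = 0.5
    variant_spacing: int = 36
    variant_guard_window: int = 35
    variant_marker_lo: int = 1
    variant_marker_hi: int = 46
    n_panel_sites: int = 17
    n_panel_contigs: int = 14
    # sequencing
    depth: float = 50.0
    read_length: int = 100
    error_rate: float = 0.003
    base_quality: int = 40
    samples: list[tuple[str, float]] = field(default_factory=lambda: list(DEMO_SAMPLES))
    # mapping
    map_seed_length: int = 15
    min_score_fraction: float = 0.5
    # calling / filtering
    min_base_quality: int = 20
    min_depth: int = 10
    min_alt_count: int = 3
    min_alt_fraction: float = 0.05
    cluster_window: int = 35
    cluster_size: int = 3
    min_qd: float = 2.0
    # xeno-filter
    clip_cost: float = 0.2
    # attribution
    flank: int = 50
    min_aligned: int = 45
    attr_seed_length: int = 8
    # contamination quantification
    kmer_k: int = 15
    # stage toggles and output
    xenofilter: bool = True
    hardfilter: bool = True
    outdir: str = "runs/demo"

    def __post_init__(self) -> None:
        if not self.samples:
            raise ConfigError("at least one sample is required")
        names = [n for n, _ in self.samples]
        if len(set(names)) != len(names):
            raise ConfigError("sample names must be unique")
        for name, frac in self.samples:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"sample {name}: contamination must lie in [0, 1]")
        if self.n_panel_contigs > self.n_contigs:
            raise ConfigError("n_panel_contigs exceeds n_contigs")
        if self.n_panel_sites < self.n_panel_contigs:
            raise ConfigError("n_panel_sites must be >= n_panel_contigs")

    @property
    def scoring(self) -> ScoringScheme:
        return ScoringScheme()

    @property
    def min_score(self) -> int:
        return int(np.ceil(self.min_score_fraction * self.read_length * self.scoring.match))

    @property
    def attribution(self) -> AttributionConfig:
        return AttributionConfig(
            flank=self.flank,
            min_aligned=self.min_aligned,
            seed_length=self.attr_seed_length,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value config file (YAML mapping of scalars).

        Samples are given as a comma-separated ``name:fraction`` list.
        Unknown keys are rejected.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        if "samples" in raw:
            raw["samples"] = _parse_samples(raw["samples"])
        try:
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def _parse_samples(value) -> list[tuple[str, float]]:
    if isinstance(value, str):
        items = [p for p in value.split(",") if p.strip()]
        out = []
        for item in items:
            if ":" not in item:
                raise ConfigError(f"sample entry {item!r} is not name:fraction")
            name, frac = item.rsplit(":", 1)
            out.append((name.strip(), float(frac)))
        return out
    if isinstance(value, list):
        return [(str(n), float(f)) for n, f in value]
    raise ConfigError("samples must be a 'name:fraction,...' string")


def demo_config(outdir: str | Path = "runs/demo", seed: int = 1234) -> RunConfig:
    """The in-repo demonstration: 20 contigs x 1.5 kb at 6% divergence, a
    17-site panel across 14 contigs, 100 planted variants, and 8 samples at
    host contamination 0-30%."""
    return RunConfig(outdir=str(outdir), seed=seed)


@dataclass
class SampleResult:
    name: str
    contamination_truth_pct: float
    host_pct_xeno: float
    host_pct_kmer: float
    n_reads: int
    n_removed_host: int
    n_calls_prefilter: int
    n_calls_postfilter: int
    panel_snps_prefilter: int
    panel_snps_postfilter: int
    panel_snps_hardfilter_only: int
    planted_calls_prefilter: int
    planted_calls_postfilter: int


@dataclass
class RunReport:
    samples: pd.DataFrame  # one row per SampleResult
    correlation: CorrelationResult | None
    attribution: pd.DataFrame
    planted_call_keys: dict[str, dict[str, list]]  # sample -> {prefilter, postfilter}
    outdir: Path

    def to_json_dict(self) -> dict:
        corr = None
        if self.correlation is not None:
            corr = dataclasses.asdict(self.correlation)
        return {
            "samples": self.samples.to_dict(orient="records"),
            "correlation": corr,
            "attribution": self.attribution.to_dict(orient="records"),
        }


def build_panel(
    reference: DualReference,
    n_sites: int,
    n_contigs: int,
    seed: int,
    margin: int = 100,
) -> VariantPanel:
    """Place panel sites at interspecies substitutions: ref = graft base,
    alt = host base, spread round-robin over ``n_contigs`` contigs.

    These sites mimic a published list of cancer-associated SNPs whose
    alternate alleles happen to equal the host-species base.
    """
    rng = np.random.default_rng(seed)
    chosen = [reference.names[i] for i in rng.choice(len(reference.names), size=n_contigs, replace=False)]
    per_contig_pool: dict[str, list[int]] = {}
    for name in chosen:
        subs = reference.substitutions_by_contig[name]
        length = reference.lengths[name]
        pool = [int(p) for p in subs if margin <= p < length - margin]
        if not pool:
            raise ValueError(f"contig {name} has no eligible substitution for the panel")
        per_contig_pool[name] = pool
    entries: list[tuple[str, int, str, str, str]] = []
    used: set[tuple[str, int]] = set()
    i = 0
    while len(entries) < n_sites:
        name = chosen[i % len(chosen)]
        pool = [p for p in per_contig_pool[name] if (name, p) not in used]
        if not pool:
            i += 1
            continue
        pos = int(pool[rng.integers(0, len(pool))])
        used.add((name, pos))
        entries.append(
            (
                name,
                pos,
                reference.graft[name][pos],
                reference.host[name][pos],
                f"GENE{len(entries) + 1:02d}",
            )
        )
        i += 1
    entries.sort(key=lambda e: (e[0], e[1]))
    return VariantPanel(entries)


def _configure_logging(outdir: Path, verbose: bool) -> None:
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    stream = logging.StreamHandler()
    stream.setLevel(logging.DEBUG if verbose else logging.WARNING)
    stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(stream)
    fileh = logging.FileHandler(outdir / "run.log", mode="w")
    fileh.setLevel(logging.DEBUG)
    fileh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fileh)


def _mark_all_pass(calls: list[VariantCall]) -> list[VariantCall]:
    return [
        dataclasses.replace(c, filters={"PASS"})
        for c in calls
    ]


def run_pipeline(config: RunConfig, verbose: bool = False) -> RunReport:
    """Run every stage from a single config; deterministic for fixed seeds."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _configure_logging(outdir, verbose)
    log.info("stage=simulate_reference n_contigs=%d length=%d divergence=%g seed=%d",
             config.n_contigs, config.contig_length, config.divergence, config.seed)

    reference = simulate_dual_reference(
        config.n_contigs, config.contig_length, config.divergence, config.seed
    )
    variants = plant_variants(
        reference,
        config.n_variants,
        config.het_fraction,
        derive_seed(config.seed, "variants"),
        margin=config.read_length,
        min_spacing=config.variant_spacing,
        guard_window=config.variant_guard_window,
        marker_band=(config.variant_marker_lo, config.variant_marker_hi),
    )
    panel = build_panel(
        reference,
        config.n_panel_sites,
        config.n_panel_contigs,
        derive_seed(config.seed, "panel"),
        margin=config.read_length,
    )
    log.info("stage=truth n_variants=%d n_panel=%d n_substitutions=%d",
             len(variants), len(panel), len(reference.substitution_map))

    write_fasta(reference.graft, outdir / "graft.fa")
    write_fasta(reference.host, outdir / "host.fa")
    write_substitution_table(reference, outdir / "substitutions.tsv")
    write_variant_table(variants, outdir / "variants.tsv")
    panel.to_tsv(outdir / "panel.tsv")

    graft_rs = ReferenceSet(reference.graft, config.map_seed_length)
    host_rs = ReferenceSet(reference.host, config.map_seed_length)
    attr_host_rs = ReferenceSet(reference.host, config.attr_seed_length)
    kmer_index = SpeciesKmerIndex(reference, config.kmer_k)
    variant_keys = {v.key for v in variants}
    attr_cfg = config.attribution
    frag_cache: dict = {}

    rows: list[SampleResult] = []
    attr_rows: list[pd.DataFrame] = []
    planted_keys_per_sample: dict[str, dict[str, list]] = {}
    all_reports: list[tuple[str, str, AttributionReport]] = []

    for name, contamination in config.samples:
        sdir = outdir / name
        sdir.mkdir(exist_ok=True)
        spec = SampleSpec(
            name=name,
            depth=config.depth,
            read_length=config.read_length,
            error_rate=config.error_rate,
            contamination_fraction=contamination,
            seed=derive_seed(config.seed, "sample", name),
            base_quality=config.base_quality,
        )
        reads = simulate_reads(reference, variants, spec)
        write_fastq(reads, sdir / "reads.fastq")
        write_origin_table(reads, sdir / "origins.tsv")
        log.info("stage=simulate_reads sample=%s n_reads=%d contamination=%g",
                 name, len(reads), contamination)

        galns = [map_read(r, graft_rs, config.scoring, min_score=config.min_score) for r in reads]
        halns = [map_read(r, host_rs, config.scoring, min_score=config.min_score) for r in reads]
        write_sam(galns, reads, graft_rs, sdir / "graft.sam")
        write_sam(halns, reads, host_rs, sdir / "host.sam")

        verdicts, summary = classify_alignments(galns, halns, config.clip_cost, name)
        write_verdict_table(verdicts, sdir / "xeno_verdicts.tsv")
        log.info("stage=xenofilter sample=%s removed=%d kept=%d dropped=%d",
                 name, summary.n_removed_host, summary.n_kept, summary.n_dropped_unmapped)

        pre_alns = [a for a in galns if a.mapped]
        if config.xenofilter:
            kept_ids = {v.read_id for v in verdicts if v.verdict in KEEP_VERDICTS}
            post_alns = [a for a in pre_alns if a.read_id in kept_ids]
        else:
            post_alns = pre_alns

        def _call(alignments):
            pile = build_pileup(alignments, reads, reference.graft, config.min_base_quality)
            calls = call_snps(
                pile, config.min_depth, config.min_alt_count, config.min_alt_fraction
            )
            if config.hardfilter:
                calls = hard_filter(
                    calls, config.cluster_window, config.cluster_size, config.min_qd
                )
            else:
                calls = _mark_all_pass(calls)
            return calls

        pre_calls = _call(pre_alns)
        post_calls = pre_calls if not config.xenofilter else _call(post_alns)
        write_vcf(pre_calls, reference.lengths, sdir / "calls_prefilter.vcf")
        write_vcf(post_calls, reference.lengths, sdir / "calls_postfilter.vcf")

        panel_pre_n, panel_pre = intersect_panel(pre_calls, panel, pass_only=False)
        panel_post_n, _ = intersect_panel(post_calls, panel, pass_only=False)
        panel_hard_n, _ = intersect_panel(pre_calls, panel, pass_only=True)
        planted_pre = sorted({c.key for c in pre_calls if c.key in variant_keys})
        planted_post = sorted({c.key for c in post_calls if c.key in variant_keys})
        planted_keys_per_sample[name] = {
            "prefilter": planted_pre,
            "postfilter": planted_post,
        }

        truth_host = sum(r.true_origin == "host" for r in reads)
        kmer_est = kmer_classify_reads(reads, reference, config.kmer_k, name, kmer_index)

        # read-level attribution of panel matches and planted-variant calls
        reports: list[tuple[str, AttributionReport]] = []
        candidates = [("panel", c) for c in panel_pre] + [
            ("planted", c) for c in pre_calls if c.key in variant_keys
        ]
        seen: set = set()
        for klass, call in candidates:
            if call.key in seen:
                continue
            seen.add(call.key)
            if call.key not in frag_cache:
                frag_cache[call.key] = build_fragment_pair(
                    reference, call.key, attr_cfg, attr_host_rs
                )
            pair = frag_cache[call.key]
            alt_reads = extract_alt_reads(galns, reads, call.key)
            attrs = [align_read_to_fragments(r, pair, attr_cfg) for r in alt_reads]
            rep = attribute_snp(attrs, pair)
            reports.append((klass, rep))
            all_reports.append((name, klass, rep))
        frame = report_frame([r for _, r in reports])
        frame.insert(0, "sample", name)
        frame.insert(1, "class", [k for k, _ in reports])
        frame.to_csv(sdir / "attribution.tsv", sep="\t", index=False)
        attr_rows.append(frame)

        rows.append(
            SampleResult(
                name=name,
                contamination_truth_pct=100.0 * truth_host / len(reads) if reads else 0.0,
                host_pct_xeno=100.0 * summary.removed_fraction,
                host_pct_kmer=kmer_est.host_fraction,
                n_reads=len(reads),
                n_removed_host=summary.n_removed_host,
                n_calls_prefilter=len(pre_calls),
                n_calls_postfilter=len(post_calls),
                panel_snps_prefilter=panel_pre_n,
                panel_snps_postfilter=panel_post_n,
                panel_snps_hardfilter_only=panel_hard_n,
                planted_calls_prefilter=len(planted_pre),
                planted_calls_postfilter=len(planted_post),
            )
        )
        log.info(
            "stage=summary sample=%s panel_pre=%d panel_post=%d planted_pre=%d",
            name, panel_pre_n, panel_post_n, len(planted_pre),
        )

    samples_df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    correlation: CorrelationResult | None
    try:
        correlation = correlate_contamination_vs_snps(
            list(zip(samples_df["host_pct_xeno"], samples_df["panel_snps_prefilter"]))
        )
    except ValueError as exc:
        log.warning("correlation not computed: %s", exc)
        correlation = None

    attribution_df = (
        pd.concat(attr_rows, ignore_index=True) if attr_rows else report_frame([])
    )
    samples_df.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    attribution_df.to_csv(outdir / "attribution.tsv", sep="\t", index=False)
    report = RunReport(
        samples=samples_df,
        correlation=correlation,
        attribution=attribution_df,
        planted_call_keys=planted_keys_per_sample,
        outdir=outdir,
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
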
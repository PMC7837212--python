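"""Generator invariants: divergence, variant planting, read mixing, file I/O."""

import numpy as np
import pytest

from xenosnp.simulate import (
    DualReference,
    ReadRecord,
    SampleSpec,
    plant_variants,
    read_fasta,
    read_fastq,
    read_table,
    simulate_dual_reference,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_origin_table,
    write_substitution_table,
    write_variant_table,
)


class TestDualReference:
    def test_zero_divergence_identity(self):
        ref = simulate_dual_reference(1, 1000, 0.0, seed=1)
        assert ref.substitution_map == []
        assert ref.graft == ref.host

    def test_substitution_count_within_binomial_tolerance(self):
        n, length, d = 20, 1500, 0.06
        ref = simulate_dual_reference(n, length, d, seed=7)
        total = n * length
        expected = total * d
        sd = np.sqrt(total * d * (1 - d))
        assert abs(len(ref.substitution_map) - expected) <= 3 * sd

    def test_substitution_map_consistent(self):
        ref = simulate_dual_reference(3, 500, 0.1, seed=3)
        for contig, pos, gb, hb in ref.substitution_map:
            assert ref.graft[contig][pos] == gb
            assert ref.host[contig][pos] == hb
            assert gb != hb
        # non-substituted positions are identical
        for name in ref.names:
            subs = set(ref.substitutions_by_contig[name].tolist())
            g, h = ref.graft[name], ref.host[name]
            assert all((g[i] != h[i]) == (i in subs) for i in range(len(g)))

    def test_equal_lengths_per_contig(self):
        ref = simulate_dual_reference(4, 300, 0.2, seed=5)
        for _, g, h in ref.contigs:
            assert len(g) == len(h)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_dual_reference(2, 400, 0.08, seed=42)
        b = simulate_dual_reference(2, 400, 0.08, seed=42)
        assert a.contigs == b.contigs
        assert a.substitution_map == b.substitution_map

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_contigs=0, contig_length=500, divergence=0.1),
            dict(n_contigs=1, contig_length=100, divergence=0.1),
            dict(n_contigs=1, contig_length=500, divergence=1.0),
            dict(n_contigs=1, contig_length=500, divergence=-0.1),
        ],
    )
    def test_argument_errors(self, kwargs):
        with pytest.raises(ValueError):
            simulate_dual_reference(seed=1, **kwargs)


class TestPlantVariants:
    def test_zero_variants(self, small_ref):
        assert plant_variants(small_ref, 0, 0.5, seed=1) == []

    def test_unique_positions_off_substitutions(self, small_ref):
        variants = plant_variants(small_ref, 100, 0.5, seed=2)
        keys = {(v.contig, v.position0) for v in variants}
        assert len(keys) == 100
        subs = {(c, p) for c, p, _, _ in small_ref.substitution_map}
        assert not keys & subs
        for v in variants:
            assert small_ref.graft[v.contig][v.position0] == v.ref_base
            assert v.alt_base != v.ref_base

    def test_het_fraction_binomial(self, small_ref):
        variants = plant_variants(small_ref, 100, 0.5, seed=3)
        n_het = sum(v.zygosity == "het" for v in variants)
        assert abs(n_het - 50) <= 3 * np.sqrt(100 * 0.25)

    def test_insufficient_positions_error(self):
        ref = simulate_dual_reference(1, 200, 0.05, seed=1)
        with pytest.raises(ValueError):
            plant_variants(ref, 1000, 0.5, seed=1)

    def test_spacing_and_guard_constraints(self, small_ref, small_variants):
        by_contig: dict[str, list[int]] = {}
        for v in small_variants:
            by_contig.setdefault(v.contig, []).append(v.position0)
        for contig, positions in by_contig.items():
            positions = sorted(positions)
            if len(positions) > 1:
                assert min(np.diff(positions)) >= 36
            subs = small_ref.substitutions_by_contig[contig]
            for p in positions:
                # no 35-bp window holds the variant plus 2 substitutions
                near = [int(s) for s in subs if abs(s - p) <= 35]
                for a in near:
                    for b in near:
                        if a < b:
                            assert max(p, b) - min(p, a) > 35
                # at least one attribution marker within the flank band
                assert any(1 <= abs(int(s) - p) <= 46 for s in subs)


class TestSimulateReads:
    def test_zero_contamination_all_graft(self, small_ref, small_variants):
        spec = SampleSpec(name="s", depth=5, contamination_fraction=0.0, seed=1, error_rate=0.0)
        reads = simulate_reads(small_ref, small_variants, spec)
        assert reads and all(r.true_origin == "graft" for r in reads)

    def test_hom_variant_always_on_graft_reads(self, small_ref):
        variants = plant_variants(small_ref, 10, 0.0, seed=5, margin=100)  # all hom
        spec = SampleSpec(name="s", depth=50, contamination_fraction=0.0, seed=2, error_rate=0.0)
        reads = simulate_reads(small_ref, variants, spec)
        vmap = {(v.contig, v.position0): v.alt_base for v in variants}
        n_checked = 0
        for r in reads:
            for (contig, pos), alt in vmap.items():
                if r.source_contig == contig and r.source_position0 <= pos < r.source_position0 + len(r):
                    assert r.bases[pos - r.source_position0] == alt
                    n_checked += 1
        assert n_checked > 100

    def test_contamination_fraction_binomial(self, small_ref, small_variants):
        spec = SampleSpec(name="s", depth=25, contamination_fraction=0.2, seed=3)
        reads = simulate_reads(small_ref, small_variants, spec)
        n_host = sum(r.true_origin == "host" for r in reads)
        n = len(reads)
        assert abs(n_host - 0.2 * n) <= 3 * np.sqrt(n * 0.2 * 0.8)

    def test_host_read_identity_matches_error_rate(self, small_ref):
        spec = SampleSpec(name="s", depth=30, contamination_fraction=1.0,
                          error_rate=0.003, seed=4)
        reads = simulate_reads(small_ref, [], spec)
        mism = total = 0
        for r in reads:
            src = small_ref.host[r.source_contig][r.source_position0 : r.source_position0 + len(r)]
            mism += sum(a != b for a, b in zip(r.bases, src))
            total += len(r)
        identity = 1 - mism / total
        assert identity == pytest.approx(1 - 0.003, abs=3 * np.sqrt(0.003 / total) + 1e-4)

    def test_read_length_exceeding_contig_error(self, small_ref):
        spec = SampleSpec(name="s", read_length=900, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(small_ref, [], spec)

    def test_error_rate_vs_divergence_warns(self, small_ref):
        spec = SampleSpec(name="s", depth=1, error_rate=0.08, seed=1)
        with pytest.warns(UserWarning):
            simulate_reads(small_ref, [], spec)

    def test_deterministic_for_fixed_seed(self, small_ref, small_variants):
        spec = SampleSpec(name="s", depth=2, contamination_fraction=0.1, seed=9)
        a = simulate_reads(small_ref, small_variants, spec)
        b = simulate_reads(small_ref, small_variants, spec)
        assert all(x.same_content(y) for x, y in zip(a, b)) and len(a) == len(b)


class TestIO:
    def test_fasta_roundtrip(self, small_ref, tmp_path):
        path = tmp_path / "g.fa"
        write_fasta(small_ref.graft, path)
        assert read_fasta(path) == small_ref.graft

    def test_fastq_roundtrip_and_phred33(self, tmp_path):
        read = ReadRecord("r1", "ACGT", np.array([40, 40, 2, 41]))
        path = tmp_path / "r.fastq"
        write_fastq([read], path)
        text = path.read_text().splitlines()
        assert text[3][0] == "I"  # Phred 40 -> chr(40+33)
        back = read_fastq(path)
        assert len(back) == 1 and back[0].same_content(read)

    def test_empty_fastq(self, tmp_path):
        path = tmp_path / "empty.fastq"
        write_fastq([], path)
        assert read_fastq(path) == []

    def test_truth_tables_roundtrip(self, small_ref, small_variants, tmp_path):
        write_substitution_table(small_ref, tmp_path / "subs.tsv")
        subs = read_table(tmp_path / "subs.tsv")
        assert len(subs) == len(small_ref.substitution_map)
        assert list(subs.columns) == ["contig", "pos1", "graft_base", "host_base"]

        write_variant_table(small_variants, tmp_path / "vars.tsv")
        var = read_table(tmp_path / "vars.tsv")
        assert [(r.contig, r.pos1 - 1, r.ref, r.alt, r.zygosity) for r in var.itertuples()] == [
            (v.contig, v.position0, v.ref_base, v.alt_base, v.zygosity) for v in small_variants
        ]

        spec = SampleSpec(name="s", depth=1, seed=1)
        reads = simulate_reads(small_ref, [], spec)
        write_origin_table(reads, tmp_path / "orig.tsv")
        orig = read_table(tmp_path / "orig.tsv")
        assert len(orig) == len(reads)


def test_read_record_validation():
    with pytest.raises(ValueError):
        ReadRecord("r", "ACGT", np.array([40, 40]))
    with pytest.raises(ValueError):
        ReadRecord("r", "AC", np.array([40, 60]))
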
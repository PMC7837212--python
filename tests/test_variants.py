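"""Pileup, SNP calling thresholds, hard-filter flags and VCF I/O."""

import numpy as np
import pytest

from xenosnp.align import ReferenceSet, map_read
from xenosnp.simulate import SampleSpec, plant_variants, simulate_reads
from xenosnp.variants import (
    VariantCall,
    VariantPanel,
    build_pileup,
    call_snps,
    hard_filter,
    intersect_panel,
    read_vcf,
    write_vcf,
)


@pytest.fixture(scope="module")
def hom_site_setup(small_ref):
    """One hom variant, error-free reads at depth ~50, mapped to graft."""
    variants = plant_variants(small_ref, 1, 0.0, seed=44, margin=100)
    spec = SampleSpec(name="s", depth=50, error_rate=0.0, seed=45)
    reads = simulate_reads(small_ref, variants, spec)
    refset = ReferenceSet(small_ref.graft, 15)
    alns = [map_read(r, refset) for r in reads]
    return small_ref, variants[0], reads, [a for a in alns if a.mapped]


class TestPileup:
    def test_single_perfect_read(self, small_ref):
        refset = ReferenceSet(small_ref.graft, 15)
        contig = small_ref.names[0]
        frag = small_ref.graft[contig][100:200]
        from xenosnp.simulate import ReadRecord

        read = ReadRecord("r1", frag, np.full(100, 40))
        aln = map_read(read, refset)
        pile = build_pileup([aln], [read], small_ref.graft)
        assert len(pile) == 100
        assert all(c.depth == 1 for c in pile)
        assert all(c.base_counts[c.ref_base] == 1 for c in pile)

    def test_empty_input(self, small_ref):
        assert build_pileup([], [], small_ref.graft) == []

    def test_low_quality_bases_excluded(self, small_ref):
        refset = ReferenceSet(small_ref.graft, 15)
        contig = small_ref.names[0]
        frag = small_ref.graft[contig][100:200]
        from xenosnp.simulate import ReadRecord

        read = ReadRecord("r1", frag, np.full(100, 10))
        aln = map_read(read, refset)
        assert build_pileup([aln], [read], small_ref.graft, min_base_quality=20) == []

    def test_unknown_contig_error(self, small_ref):
        from xenosnp.align import AlignmentRecord

        aln = AlignmentRecord(
            read_id="r", ref_name="nope", ref_start0=0, ref_end0=10, strand="+",
            score=10, cigar="10=", n_mismatch=0, aligned_length=10,
            clipped_length=0, mapped=True, query_length=10,
        )
        from xenosnp.simulate import ReadRecord

        read = ReadRecord("r", "A" * 10, np.full(10, 40))
        with pytest.raises(ValueError):
            build_pileup([aln], [read], small_ref.graft)

    def test_hom_site_all_alt(self, hom_site_setup):
        ref, variant, reads, alns = hom_site_setup
        pile = build_pileup(alns, reads, ref.graft)
        col = next(
            c for c in pile if c.contig == variant.contig and c.position0 == variant.position0
        )
        assert col.base_counts[variant.alt_base] == col.depth > 0


class TestCallSnps:
    def test_hom_variant_alt_fraction_one(self, hom_site_setup):
        ref, variant, reads, alns = hom_site_setup
        calls = call_snps(build_pileup(alns, reads, ref.graft))
        match = [c for c in calls if c.key == variant.key]
        assert len(match) == 1
        assert match[0].alt_fraction == 1.0

    def test_perfect_recall_precision_without_noise(self, small_ref):
        """With no errors and no contamination the call set equals the
        planted variants exactly."""
        variants = plant_variants(small_ref, 10, 0.0, seed=46, margin=100)
        spec = SampleSpec(name="s", depth=50, error_rate=0.0, seed=47)
        reads = simulate_reads(small_ref, variants, spec)
        refset = ReferenceSet(small_ref.graft, 15)
        alns = [a for a in (map_read(r, refset) for r in reads) if a.mapped]
        calls = call_snps(build_pileup(alns, reads, small_ref.graft))
        assert {c.key for c in calls} == {v.key for v in variants}

    def test_threshold_blocks_low_alt_count(self):
        from xenosnp.variants import PileupColumn

        col = PileupColumn(
            contig="c", position0=5, ref_base="A",
            base_counts={"A": 48, "C": 2, "G": 0, "T": 0},
            base_qual_sums={"A": 1920, "C": 80, "G": 0, "T": 0},
            depth=50,
        )
        assert call_snps([col], min_alt_count=3) == []
        assert len(call_snps([col], min_alt_count=2, min_alt_fraction=0.01)) == 1

    def test_threshold_monotonicity(self, small_ref, small_variants):
        spec = SampleSpec(name="s", depth=40, error_rate=0.003,
                          contamination_fraction=0.2, seed=48)
        reads = simulate_reads(small_ref, small_variants, spec)
        refset = ReferenceSet(small_ref.graft, 15)
        alns = [a for a in (map_read(r, refset) for r in reads) if a.mapped]
        pile = build_pileup(alns, reads, small_ref.graft)
        base = len(call_snps(pile))
        assert len(call_snps(pile, min_depth=20)) <= base
        assert len(call_snps(pile, min_alt_count=5)) <= base
        assert len(call_snps(pile, min_alt_fraction=0.2)) <= base

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            call_snps([], min_depth=0)


def _mk_call(pos, contig="c", qd=20.0, alt="T"):
    return VariantCall(
        contig=contig, position0=pos, ref_base="A", alt_base=alt,
        depth=50, alt_count=25, alt_fraction=0.5, qd_score=qd,
    )


class TestHardFilter:
    def test_window_cluster_flagged(self):
        calls = [_mk_call(10), _mk_call(20), _mk_call(30)]
        out = hard_filter(calls, cluster_window=35, cluster_size=3)
        assert all("SnpCluster" in c.filters for c in out)

    def test_sparse_calls_pass(self):
        calls = [_mk_call(10), _mk_call(100), _mk_call(200)]
        out = hard_filter(calls)
        assert all(c.filters == {"PASS"} for c in out)

    def test_window_boundary(self):
        # span 35 is inside the window; span 36 is not
        inside = hard_filter([_mk_call(0), _mk_call(20), _mk_call(35)])
        assert all("SnpCluster" in c.filters for c in inside)
        outside = hard_filter([_mk_call(0), _mk_call(20), _mk_call(36)])
        assert all("SnpCluster" not in c.filters for c in outside)

    def test_low_qd_flag(self):
        out = hard_filter([_mk_call(10, qd=1.0)], min_qd=2.0)
        assert out[0].filters == {"LowQD"}

    def test_no_call_deleted(self):
        calls = [_mk_call(p) for p in (1, 5, 9, 200)]
        out = hard_filter(calls)
        assert [c.key for c in out] == [c.key for c in calls]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            hard_filter([_mk_call(30), _mk_call(10)])

    def test_flags_invariant_to_contig_interleaving(self):
        a = [_mk_call(10, "a"), _mk_call(20, "a"), _mk_call(30, "a"), _mk_call(15, "b")]
        a.sort(key=lambda c: (c.contig, c.position0))
        out = hard_filter(a)
        flags = {(c.contig, c.position0): c.filters for c in out}
        assert "SnpCluster" not in flags[("b", 15)]
        assert all("SnpCluster" in flags[("a", p)] for p in (10, 20, 30))


class TestPanel:
    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError):
            VariantPanel([("c", 1, "A", "T", "x"), ("c", 1, "G", "T", "y")])

    def test_empty_panel_zero_matches(self):
        n, matched = intersect_panel([_mk_call(10)], VariantPanel([]))
        assert n == 0 and matched == []

    def test_exact_key_match_required(self):
        panel = VariantPanel([("c", 10, "A", "T", "g1"), ("c", 99, "A", "T", "g2")])
        n, matched = intersect_panel([_mk_call(10), _mk_call(50)], panel)
        assert n == 1
        assert matched[0].position0 == 10
        # alt mismatch is not a match
        n2, _ = intersect_panel([_mk_call(10, alt="G")], panel)
        assert n2 == 0

    def test_pass_only_respects_flags(self):
        calls = hard_filter([_mk_call(10, qd=1.0)])
        panel = VariantPanel([("c", 10, "A", "T", "g1")])
        assert intersect_panel(calls, panel, pass_only=True)[0] == 0
        assert intersect_panel(calls, panel, pass_only=False)[0] == 1

    def test_tsv_roundtrip(self, tmp_path):
        panel = VariantPanel([("c1", 10, "A", "T", "g1"), ("c2", 99, "G", "C", "g2")])
        panel.to_tsv(tmp_path / "p.tsv")
        back = VariantPanel.from_tsv(tmp_path / "p.tsv")
        assert back.entries == panel.entries


class TestVcf:
    def test_roundtrip(self, tmp_path):
        calls = hard_filter([_mk_call(10), _mk_call(20), _mk_call(30), _mk_call(99, qd=0.5)])
        path = tmp_path / "x.vcf"
        write_vcf(calls, {"c": 1000}, path)
        back = read_vcf(path)
        assert back == calls

    def test_position_is_one_based(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf([_mk_call(99)], {"c": 1000}, path)
        row = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert row.split("\t")[1] == "100"

    def test_empty_callset_header_only(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf([], {"c": 1000}, path)
        assert read_vcf(path) == []
        assert path.read_text().startswith("##fileformat=VCFv4.2")

    def test_valid_for_pysam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        calls = hard_filter([_mk_call(10), _mk_call(20), _mk_call(30)])
        path = tmp_path / "x.vcf"
        write_vcf(calls, {"c": 1000}, path)
        with pysam.VariantFile(str(path)) as fh:
            recs = list(fh)
        assert [r.pos for r in recs] == [11, 21, 31]
        assert recs[0].info["DP"] == 50
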
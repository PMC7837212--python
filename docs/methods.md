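# Methods

This note records the models, defaults and design choices behind `xenosnp`,
and what the synthetic experiments do and do not demonstrate.

## The phenomenon being modelled

RNA-seq libraries from cells co-cultured with another species (here: human
pluripotent stem cells on mouse feeder layers) contain a minority of
host-species reads. At exonic human–mouse divergence a host read aligned to
the human genome typically carries several species-specific substitutions
within its span. When enough host reads stack up at an orthologous locus, a
pileup-based caller emits alternate alleles at every interspecies
substitution the reads cover — spurious "mutations" with three recognisable
signatures: they appear only in contaminated samples, they come in clusters
of nearby calls, and the reads carrying them match the host genome almost
perfectly while showing several mismatches against the graft genome. The
package reproduces the full diagnostic chain on synthetic data where every
read's true origin is known.

## Synthetic data model

**Dual reference.** Graft contigs are i.i.d. uniform DNA; each position
independently carries an interspecies substitution with probability
`divergence` (default 0.06, the exonic human–mouse scale), replacing the
graft base by one of the three alternatives uniformly. There are no indels
between the genomes, so graft and host coordinates coincide and every
downstream quantity (syntenic position, expected mismatch counts) is exact.
Indel divergence, splicing and paired-end structure are out of scope.

**Reads.** Single-end reads of fixed length (default 100 bp) start uniformly
within a contig chosen proportionally to length; a fraction
`contamination_fraction` of reads derives from the host genome. Graft reads
carry each overlapping heterozygous planted variant independently with
probability 0.5 and homozygous variants always (no haplotype phasing — allele
fractions are the only diploid quantity used). Sequencing errors substitute
uniformly among the three alternative bases at `error_rate` per base
(default 0.003), independent of the constant base quality (default Q40).
Because errors are injected independently of quality, base-quality filtering
is exercised structurally, not statistically. Expression-level weighting is
deliberately absent: the contamination artifact requires only read mixing,
not expression realism.

**Contamination levels.** The demo series spans 0–30% host reads across 8
libraries ({0, 0, 2, 5, 10, 15, 20, 30}%). Published boxplots for feeder
co-cultures show removal fractions that vary widely between cultures and
laboratories without printing per-sample values, so the series is a modelling
choice: two clean feeder-free libraries plus a graded ramp wide enough to
expose the dose–response relationship.

**Variant placement.** Planted variants never coincide with an interspecies
substitution, so the ground-truth species attribution of every candidate SNP
is unambiguous. The demo placement adds three geometric constraints, each
making one diagnostic well-posed under uniform coverage:

* *margin* = read length — full coverage at every variant site;
* *min_spacing* 36 bp and *guard window* 35 bp (no 35-bp window may contain
  the variant plus two substitutions) — at most two calls can ever share a
  cluster-filter window with an authentic variant, so authentic variants are
  structurally exempt from the SNP-cluster flag. In real data this exemption
  is provided by expression structure (authentic SNPs rarely sit inside
  dense host-divergence pileups at comparable allele fractions); a
  uniform-coverage simulator has to provide it geometrically.
* *marker band* (1, 46) — at least one substitution within 46 bp, so the
  101-bp attribution fragment always contains an informative species marker
  that local alignment cannot clip away (markers within ~3 bp of a fragment
  edge can be soft-clipped; 46 keeps them ≥ 4 bp inside).

**Panel.** Panel sites are placed at interspecies substitutions with
ref = graft base and alt = host base, spread round-robin across contigs
(demo: 17 sites on 14 of 20 contigs). They model a published SNP list whose
alternate alleles happen to equal the host-species base — the precondition
for contamination to masquerade as those SNPs.

**Randomness.** One top-level integer seed; per-sample streams are derived
by SHA-256 over (seed, "sample", name), so adding a sample never perturbs
existing ones and runs are byte-identical across platforms.

## Alignment

Affine-gap Smith–Waterman (match +1, mismatch −2, gap open −3, extend −1; a
length-L gap costs open + (L−1)·extend; N never matches). The defaults make
clipping a divergent tail cheaper than gapping through it, mimicking the
short-read mapper behaviour the xeno-filter depends on. Determinism is part
of the contract: the end cell is the maximal-score cell with smallest target
index then smallest query index, and traceback prefers diagonal over
query-gap over target-gap, closing gaps early. Unaligned flanks are reported
as soft clips (`S`) and mismatches as `X`, so `NM` is recomputable column by
column.

`map_read` finds candidate windows by exact k-mer seeds (default k = 15 at a
one-seed-length stride, both strands), verifies each distinct diagonal with
Smith–Waterman on a ±12 bp padded window, and keeps the best record under
the tie order (score, ref start, span, name, strand). Reads scoring below
`min_score` (default half the read's maximal score) are unmapped. The 8-base
seed is reserved for fragment-level attribution (below). The aligner is
intended for toy scale (≤ 10^5 reads and reference bases).

## Variant calling and hard filtering

Pileup counts bases of mapped reads with base quality ≥ 20, excluding N. A
call is emitted per (site, alternate base) with depth ≥ 10, alt count ≥ 3
and alt fraction ≥ 0.05. The fraction threshold is calibrated to the
synthetic design: at 5% contamination and depth 50 the expected host-allele
fraction at a substitution site is ~0.05, so a threshold of 0.10 would
suppress exactly the artifact the package exists to expose, while alt count
≥ 3 keeps isolated sequencing errors (expected < 2 spurious calls per demo
sample) out of the call set. No genotype-likelihood model is attempted;
the diploid assumption enters only through the interpretation of allele
fractions.

Hard filtering flags rather than deletes, so before/after comparisons use
one call set: `SnpCluster` for any call in a run of ≥ 3 calls spanning ≤ 35
bases (the GATK VariantFiltration convention), `LowQD` when summed alt base
quality / site depth < 2.0, `PASS` otherwise.

## Xeno-filter

Each read is aligned to both genomes; penalty = mismatches + 0.2 per
soft-clipped base. Clipping must cost less than mismatching (otherwise
mappers that clip divergent tails would hide the evidence); 0.2 is a
configurable surrogate for the alignment-quality comparison used by
dedicated xenograft filters, whose exact internal score is not
re-implemented. Host-better reads are removed; ties keep the graft read
(conservative toward retaining graft evidence); reads mapped to neither
genome are dropped from calling but reported separately — they are neither
detected host reads nor usable evidence. At 6% divergence a 100-bp host
read carries ~6 discriminative substitutions, so recall ≥ 99% and graft
false-removal ≤ 1% follow with a large margin; the residual undetectable
host reads are those whose span contains no substitution, and exactly those
reads cannot support a spurious allele either.

## Attribution

For a candidate SNP, alt-carrying reads are retrieved from the graft
alignments; the graft fragment is the 50 bp either side of the site plus the
site itself. The source description of this procedure alternates between
"50 bp before and after" and a 100-bp fragment; the package includes the
variant base, giving 101 bp, and records offsets when a contig edge
truncates the fragment. The syntenic host fragment is located by local
alignment of the graft fragment against the whole host reference (feasible
at toy scale; a 60% identity floor guards against spurious synteny, and
reverse-oriented synteny is rejected — the co-linear divergence model never
produces it). Reads align to each fragment gated by an exact shared 8-mer;
a read is retained only when its aligned (match+mismatch) span is strictly
greater than 45 bp on both fragments, read as strict because retention is
specified for fragments "longer than" the threshold. Mismatch counting
excludes gap columns; gaps reduce the aligned span instead. Verdict:
`host_origin` iff the alternate allele equals the host base at the syntenic
site and mean identity to the host fragment strictly exceeds mean identity
to the graft fragment; `graft_origin` iff the graft-side mean identity is
strictly higher; anything else (including zero retained reads) is
`ambiguous`. The strict-inequality rule is this package's formalisation; the
source reports complete separation rather than a numeric threshold.

## Contamination quantification

The k-mer classifier votes with canonical k-mers unique to one genome
(k = 15 by default — at 30 kb of toy reference, genome-scale k = 31 leaves
too few discriminative k-mers; with substitution-only divergence the
discriminative k-mers are exactly those overlapping a substitution). Ties
and vote-less reads are unassigned and excluded from the host-fraction
denominator; an of-total fraction is also reported. Pearson's r (not
Spearman) relates host fraction to pre-filter panel-SNP counts, matching the
field's use of r for this contrast; the fit line comes from ordinary least
squares.

## Pipeline and problem sizes

The demo runs 8 samples × 15,000 reads of 100 bp against 2 × 30 kb of
reference — about 1 minute end to end — chosen so the full suite of
before/after contrasts (panel SNPs appear only with contamination and
vanish after filtering; authentic calls are preserved; host fraction
correlates with spurious SNP counts at r > 0.8) is comfortably resolved:
at these sizes the binomial noise on every asserted quantity is at least
three standard deviations away from its acceptance boundary. All stage
outputs are plain text; reruns under a fixed seed are byte-identical.

## Known limitations

* Substitution-only divergence: no indels anywhere, no splicing, no
  expression weighting, single-end reads only. Consequently the simulator
  demonstrates the *logic* of the contamination diagnosis, not its
  performance on real transcriptomes (repeats, paralogs, splice junctions
  and expression skew all make the real problem harder).
* The aligner is exact but toy-scale; it is not a substitute for a
  production mapper.
* Allele fractions at heterozygous sites average slightly below 50%
  (~49%): an alternate allele within ~2 bp of a read end is soft-clipped
  by local alignment while the reference allele is not — the same edge
  effect exists in any local-alignment pileup.
* The xeno-filter penalty and the k-mer voting scheme are documented
  surrogates for external tools whose internal scores are not published;
  conclusions about those tools transfer only qualitatively.
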
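# Demonstration run: dual-species references at human-mouse exonic divergence,
# a 17-site panel of host-matching SNPs across 14 contigs, 100 planted germline
# variants, and 8 libraries spanning 0-30% host-read contamination
# (feeder co-culture vs feeder-free).
n_contigs: 20
contig_length: 1500
divergence: 0.06
seed: 1234
n_variants: 100
het_fraction: 0.5
n_panel_sites: 17
n_panel_contigs: 14
depth: 50
read_length: 100
error_rate: 0.003
samples: "LN-1:0,LN-2:0,MEF-02:0.02,MEF-05:0.05,MEF-10:0.10,MEF-15:0.15,MEF-20:0.20,MEF-30:0.30"
outdir: runs/demo
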
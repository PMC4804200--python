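# Demo pipeline configuration: a small synthetic two-lineage community,
# six metatranscriptome samples and two metagenomes across mock size
# fractions, followed by a 40-gene Ka/Ks screen.
seed: 7
out_dir: runs/demo
community:
  genome_length: 100000
  n_genes: 80
  gene_length: 900
  divergence: 0.05
  gc_content: 0.35
  rrna_intervals: [[95000, 97500]]
  its_intervals: [[97500, 97800]]
samples:
  - {name: srf_small_MG, mode: MG, n_reads: 10000, lineage_weights: {A: 0.95, B: 0.05}}
  - {name: srf_large_MG, mode: MG, n_reads: 10000, lineage_weights: {A: 0.45, B: 0.55}}
  - {name: srf_small_MT1, mode: MT, n_reads: 4000, lineage_weights: {A: 0.95, B: 0.05}}
  - {name: srf_small_MT2, mode: MT, n_reads: 2500, lineage_weights: {A: 0.9, B: 0.1}}
  - {name: srf_small_MT3, mode: MT, n_reads: 6000, lineage_weights: {A: 0.92, B: 0.08}}
  - {name: srf_large_MT1, mode: MT, n_reads: 5000, lineage_weights: {A: 0.4, B: 0.6}}
  - {name: srf_large_MT2, mode: MT, n_reads: 1500, lineage_weights: {A: 0.5, B: 0.5}}
  - {name: srf_large_MT3, mode: MT, n_reads: 3000, lineage_weights: {A: 0.35, B: 0.65}}
expression:
  pairs:
    - {mt: srf_small_MT1, mg: srf_small_MG}
    - {mt: srf_small_MT2, mg: srf_small_MG}
    - {mt: srf_small_MT3, mg: srf_small_MG}
    - {mt: srf_large_MT1, mg: srf_large_MG}
    - {mt: srf_large_MT2, mg: srf_large_MG}
    - {mt: srf_large_MT3, mg: srf_large_MG}
  hk_genes: [recA, gyrB]
  hk_method: mean
selection:
  n_pairs: 40
  n_codons: 300
  omega: 0.15
  expected_ds: 0.3
  B: 200
  alpha: 0.05
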
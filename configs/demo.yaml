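# Demo run: 1 Mb toy genome, ~10,000 CpG sites, 8 treated cells in two
# stages (with two pronucleus-style pairs) plus 4 untreated controls.
seed: 1
n_chrom: 1
chrom_len: 1000000
cpg_density: 10.0
base_rate: 0.001
class_rates:
  L1: 0.005
  ERVK: 0.005
conversion_eff: 0.8
background_rate: 0.0115
coverage_mean: 5.0
window_size: 1000
outdir: clever5fc_demo
manifest:
  - {cell_id: t00, treatment: treated, stage: early, pair_id: p0, pair_role: A}
  - {cell_id: t01, treatment: treated, stage: early, pair_id: p0, pair_role: B}
  - {cell_id: t02, treatment: treated, stage: early, pair_id: p1, pair_role: A}
  - {cell_id: t03, treatment: treated, stage: early, pair_id: p1, pair_role: B}
  - {cell_id: t04, treatment: treated, stage: late}
  - {cell_id: t05, treatment: treated, stage: late}
  - {cell_id: t06, treatment: treated, stage: late}
  - {cell_id: t07, treatment: treated, stage: late}
  - {cell_id: u00, treatment: untreated}
  - {cell_id: u01, treatment: untreated}
  - {cell_id: u02, treatment: untreated}
  - {cell_id: u03, treatment: untreated}
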
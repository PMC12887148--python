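# Demo pipeline: ~1,500-animal synthetic herd, 2,000 SNPs, all nine
# evaluation schemes, LR validation on the youngest 15% cohort.
simulate:
  n_founders: 300
  n_generations: 4
  n_snps: 2000
  n_chromosomes: 10
  qtl_fraction: 0.10
  genotyped_fraction: 0.4
  seed: 1

economics:
  diet_price_kg: 1.20
  feedlot_daily_overhead: 2.50
  arroba_price: 300.0
  carcass_dressing_female: 55.34
  carcass_dressing_male: 58.55
  period_days: 80

qc:
  phen_sd_limit: 3.5
  min_cg_size: 4
  snp_call_rate: 0.90
  animal_call_rate: 0.90
  maf_min: 0.05
  mendel_conflict_max: 0.01
  hwe_limit: 0.15
  autosomes_only: true

target: PFT
models: [ST_ss, ST_sswl1, ST_sswl2, ST_sswnl1, ST_sswnl2,
         TT_W450, TT_DMI, TTT_CAR, MT_ss]
validation:
  youngest_fraction: 0.15

alpha: 0.05
tune: true
solver: pcg
out_dir: demo_out
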
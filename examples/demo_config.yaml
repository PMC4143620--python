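# Demo pipeline configuration: a synthetic 12-family cohort with a rare
# causal haplotype segment at 100-110 cM that raises diastolic blood
# pressure (8 mmHg per causal allele), genotyped on a 784-marker LD-pruned
# style panel over a 220 cM chromosome. Running the pipeline on this
# configuration produces the pair list, the IBD sharing summary, the called
# excess-sharing regions and the per-region mixed-model association tables.
out_dir: demo_run
seed: 1
simulate:
  n_families: 12
  n_markers: 784
  map_length_cm: 220.0
  causal_region: [100.0, 110.0]
  n_causal: 5
  causal_maf: 0.04
  effect_beta3: 8.0
  seed: 1
ibd:
  alpha: 0.05
  beta: 0.01
  epsilon: 0.01
  kappa: 0.9
prune:
  window_cm: 1.0
  maf_min: 0.05
  r2_max: 0.5
select:
  tau: 0.0
  min_markers: 2
rare_maf_max: 0.05   # counts the ~4%-frequency causal alleles as the rare burden
with_rare: true
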
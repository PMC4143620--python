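"""Run the full IBD-to-association pipeline on the bundled demo cohort.

Simulates the demo configuration (12 families, a causal haplotype segment
at 100-110 cM raising DBP by 8 mmHg per allele), infers pairwise IBD for
all unrelated case-case/case-control pairs, calls regions of excess
case-case sharing, and tests each region in the longitudinal mixed model.
"""

from pathlib import Path

import pandas as pd

from ibdassoc.pipeline import PipelineConfig, run_pipeline

here = Path(__file__).resolve().parent
cfg = PipelineConfig.from_yaml(here / "demo_config.yaml")
cfg.out_dir = "scratch/demo_run"

out = run_pipeline(cfg)
print(f"run directory: {out}\n")

summary = pd.read_csv(out / "ibd_summary.tsv", sep="\t")
print("IBD sharing by pair group (proportions of markers, lengths in cM):")
print(summary.to_string(index=False), "\n")

regions = pd.read_csv(out / "regions.tsv", sep="\t")
print(f"{len(regions)} region(s) with excess case-case sharing:")
print(regions.to_string(index=False), "\n")

assoc = pd.read_csv(out / "association.tsv", sep="\t")
cols = ["region_id", "dataset", "p_beta2", "p_beta3", "p_joint", "p_beta2_only"]
print("association results (DOS = dosages, WGS = hard calls):")
print(assoc[cols].to_string(index=False))
print("\nThe causal region lies at 100-110 cM; a region overlapping it with "
      "a small joint p-value reproduces the intended discovery.")
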
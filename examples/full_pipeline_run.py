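"""End-to-end run: simulate, calibrate, screen, rank, stage-two report.

Writes every stage table plus a manifest under ./scratch/pipeline_demo and
prints the screening funnel (records surviving each filter) and the top five
candidate SNPs by combined rank.
"""

import json

from poolgwas import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    simulation=SimulationConfig(n_snps=500, n_effect_snps=25, seed=7),
    replicate_sd_max=0.05, top_n=48, seed=7)
result = run_pipeline(cfg, "scratch/pipeline_demo")

print("funnel:", json.dumps(result.manifest["funnel"], indent=2))
cols = ["snp_id", "rank_sum", "combined_rank", "p_female", "p_male"]
print(result.candidates[cols].head(5).to_string(index=False))
print("outputs:", ", ".join(result.manifest["outputs"].values()))
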
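"""Run the full analysis pipeline on a simulated study and print the report.

Writes the complete CSV bundle (locus summary, HWE grids, F_IS table,
differentiation matrices, BIC curves, relatedness tables, dyad calls,
network table), a versioned summary.json, and a run log with every seed.
"""

from kinpatch.pipeline import PipelineConfig, make_report, run_full_analysis
from kinpatch.simulate import SimulationConfig

config = PipelineConfig(
    seed=42,
    out_dir="pipeline_demo",
    simulation=SimulationConfig(seed=42, n_sites=4),
    # scaled-down replicate counts for a quick demonstration
    n_mc_hwe=5000, n_perm_diff=500, n_perm_rel=500, n_perm_sib=1000,
    n_perm_fis=1000, n_sim_net=1000, n_mc_exclusion=20_000,
)

bundle = run_full_analysis(config)
print(make_report(bundle))
print("\nOutputs written to ./pipeline_demo/ (see summary.json and run.log).")
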
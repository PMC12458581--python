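"""Generate a synthetic multi-omic aging study and inspect its ground truth.

The generator plants aging trajectories (up/down genes between weaning and
young adulthood), exposure effects that reverse or reinforce them, histone
mark peaks tied to promoters/enhancers, and an enhancer catalog.
"""

from liveraging import SimulationConfig, simulate_study

config = SimulationConfig(n_genes=600, n_exposure_genes=120, seed=7)
bundle = simulate_study(config)

truth = bundle.truth.genes
print(f"expression matrix: {bundle.expression.values.shape[0]} genes x "
      f"{bundle.expression.values.shape[1]} samples")
print("planted aging directions:", truth["aging_direction"].value_counts().to_dict())
print("planted TBT classes:     ", truth["TBT_class"].value_counts().to_dict())
print(f"enhancer catalog: {len(bundle.enhancers)} enhancers; "
      f"{len(bundle.truth.peaks)} planted mark peaks across {sorted(bundle.chip)}")
# 'attenuated' genes are aging genes whose exposure effect opposes the aging
# direction -- the recovery target for the downstream trajectory analysis.
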
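"""Run the full pipeline on a config and read the report.

Equivalent to `liveraging run-all --out <dir>`; every stage writes its
intermediate tables and the report JSON is reproducible byte-for-byte
under fixed seeds.
"""

import json

from liveraging import RunConfig, SimulationConfig, run_study

config = RunConfig(
    simulation=SimulationConfig(
        n_genes=500, n_exposure_genes=100,
        exposures=("vehicle", "TBT", "BPA.hi", "TCDD"), seed=1,
    ),
    n_perm=2000,
    cohort_n_samples=120,
    seed=1,
    outdir="scratch/example_run",
)
report = run_study(config)

print("per-exposure overlap with the aging signature:")
print(json.dumps(report["exposure_overlap"], indent=2, sort_keys=True))
print("concordance categories:", report["concordance"]["category_counts"])
print("severity association:",
      round(report["scoring"]["severity_association"]["r"], 3))
corr = report["scoring"]["correlation"]
print("aging vs exposure score correlations:",
      {k: v for k, v in corr["aging"].items() if k != "aging"})
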
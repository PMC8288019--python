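"""Generate the six-individual demo cohort and run the whole analysis.

Writes VCF/BEDGRAPH/BED inputs with known truth to ``demo_data/``, then
runs filtering, sex classification, heterozygosity, both ROH callers, the
length spectrum, gene-set excess and the permutation tests, leaving a
report and per-individual tracks under ``demo_data/results/``.

Equivalent shell form:
    rohscape demo --outdir demo_data --seed 0
    rohscape run --config demo_data/demo_config.yaml
"""
import pandas as pd

from rohscape import RunConfig, make_demo_dataset, run_pipeline

cfg_path = make_demo_dataset("demo_data", seed=0)
report = run_pipeline(RunConfig.from_yaml(cfg_path))

cols = ["individual", "het_rate_snps_per_mb", "f_roh_window", "f_roh_scan50",
        "long_roh_fraction", "mhc_like_excess", "or_like_p_deficiency"]
pd.set_option("display.width", 160)
print(report[cols].to_string(index=False))
print("\nEach row is one simulated genome: heterozygosity spans the planted "
      "12-459 SNPs/Mb range, F_ROH tracks the planted inbreeding, and the "
      "clustered gene family that avoids ROH shows small deficiency "
      "p-values where power allows.")
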
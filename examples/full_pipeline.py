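"""One-command end-to-end run on the default synthetic cohort.

simulate -> qflow -> features -> train -> evaluate -> compare, driven by a
single config and seed.  The equivalent shell command is
``veinflow run --seed 1 --out runs/demo`` (which also writes all artifacts).
"""

import json

from veinflow import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, save_images=False))

print(f"cohort:    {report['cohort']['n_subjects']} subjects, "
      f"{report['cohort']['n_scans']} scans")
print(f"model:     k = {report['model']['k']}, "
      f"threshold = {report['model']['threshold']}")
print(f"confusion: {report['confusion']}")
print(f"metrics:   {json.dumps({k: round(v, 2) for k, v in report['metrics'].items()})}")
print(f"significant GSV parameters: "
      f"{report['group_comparison']['significant']['GSV']}")
print("Metrics are computed on the training set (all limbs train the "
      "network), mirroring a small-cohort training-stage evaluation.")
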
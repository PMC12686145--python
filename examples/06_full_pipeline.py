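"""Run the whole pipeline on the packaged demo configuration.

Simulates cohorts and tissue sections, runs the model search, partitions
the winner's model genes into an up/down signature, scores every sample,
runs the spatial proximity stage, and writes the evaluation reports.
"""

import json

from cafsig.pipeline import demo_config, run_pipeline

outdir = run_pipeline(demo_config(), outdir="scratch/demo_run")
print(f"artifacts in {outdir}:")
for p in sorted(outdir.iterdir()):
    print(f"  {p.name}")

evaluation = json.loads((outdir / "evaluation.json").read_text())
print(f"\nexternal AUC of the winning model: {evaluation['external_auc']}")
print(f"accuracy at the Youden threshold:  {evaluation['accuracy']}")
# Rerunning with the same configuration reproduces every artifact
# byte-for-byte; the manifest records the config hash and seed.
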
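"""Run the complete reproducible pipeline from one YAML-able config.

simulate -> receptive fields -> tonotopy -> latency shifts -> MI -> sync,
writing every table as TSV plus a summary JSON.  Rerunning with the same
config reproduces every output byte-for-byte.
"""

import json

from notchcode import RunConfig, run_pipeline

config = RunConfig(seed=0, n_neurons=40, fm_reps=20, outdir="scratch/demo_run")
config.to_yaml("scratch/demo_config.yaml")

summary = run_pipeline(config)
print(json.dumps(summary["headline"], indent=2))
print(f"\ntables written to {config.outdir}/")
# The headline block reports the three population-level effects: the
# notch-induced FSL shift (significant, while counts are not), the MI
# medians per code, and the synchrony block increases.
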
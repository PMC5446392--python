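"""Run every stage end to end into one reproducible run directory.

Same config + seed gives byte-identical outputs; the manifest records the
seed and every threshold used.
"""

import json
import warnings

warnings.filterwarnings("ignore", category=UserWarning)

from methwas import CohortConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(cohort=CohortConfig(n_probes=5000, n_true_mvps=15, effect_size=0.12), seed=1)
summary = run_pipeline(cfg, "scratch/demo_run")
print(json.dumps(summary, indent=2, default=float))
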
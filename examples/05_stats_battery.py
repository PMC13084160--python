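"""The inferential battery on a three-condition experiment.

Emulates the translation-inhibitor design: scenes with planted
colocalization 0.8 (elongation blocked, ribosomes frozen on transcripts),
0.6 (untreated) and 0.3 (ribosomes dissociated), measured per cell, then
compared with Kruskal-Wallis followed by Dunn's test with Bonferroni
correction.
"""

import json

import numpy as np

from ncfish.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    scenario="aso", seed=2, n_cells=10,
    condition_coloc={"chx_like": 0.8, "untreated": 0.6, "puro_like": 0.3},
    scene={
        "image_shape": (512, 512),
        "soma_radius_um": 3.0,
        "neurite_specs": [(7.0, 1.4, 30.0), (6.0, 1.2, 200.0)],
        "n_spots_per_channel": {"rna": 60, "ribosome": 60},
        "mito_specs": [10, 1.5, 0.4],
    },
)
bundle = run_pipeline(cfg)

means = bundle["per_cell"].groupby("condition")["fraction"].mean()
print("mean estimated colocalization per condition:")
print(means.to_string(float_format="%.3f"))
print(f"\nKruskal-Wallis: H = {bundle['kruskal_H']:.2f}, "
      f"p = {bundle['kruskal_p']:.2e}")
print("\nDunn post hoc (Bonferroni):")
print(bundle["posthoc"].to_string(index=False))
print("\nfull stats record:")
print(json.dumps(bundle["stats"], indent=1, default=str))
# The battery should find the freeze > untreated > dissociate ordering
# with the drug-vs-untreated contrasts significant — the signature of
# translation-dependent colocalization.
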
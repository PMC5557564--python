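#!/usr/bin/env python
"""Part 1: select the NLR polynomial degree and the MLP architecture.

At the 100 Hz step, every complexity level is trained per subject and the
sequential Wilcoxon procedure picks the simplest level beyond which no
statistically significant gain remains.
"""

import json
from pathlib import Path

import numpy as np

from semgbench.pipeline import desk_scale_config, run_part1

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

config = desk_scale_config(seed=1)
part1 = run_part1(config)

with open(OUT / "part1.json", "w") as fh:
    json.dump(part1, fh, indent=1)

for key, label in (("nlr", "NLR degree"),
                   ("mlp_layers", "MLP hidden layers"),
                   ("mlp_neurons", "MLP neurons per layer")):
    block = part1[key]
    grid = block["grid"]
    means = np.mean(block["scores"], axis=0)
    sel = [v for k, v in block.items() if k.startswith("selected")][0]
    print(f"{label}: grid {grid} -> selected {sel}")
    print("  mean TS F1 per level:",
          ", ".join(f"{g}:{m:.2f}" for g, m in zip(grid, means)))
    if block["mean_fallback"]:
        print("  (cohort < 6 subjects: selected by mean F1, not Wilcoxon)")
print(f"\nWritten to {OUT / 'part1.json'}")
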
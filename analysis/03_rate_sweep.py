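#!/usr/bin/env python
"""Part 2: sweep NLR, MLP and SVM over training-set sampling rates.

Each subject's session is downsampled at steps {200, 100, 50, 25, 10}
(5-100 Hz); the selected-complexity NLR/MLP and the grid-searched SVM are
trained per step and scored on the test set (TS) and the generalization set
(GS), with the EOF computed under the 256 KB budget.
"""

import json
from pathlib import Path

import numpy as np

from semgbench.pipeline import desk_scale_config, run_part2

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

config = desk_scale_config(seed=1)
with open(OUT / "part1.json") as fh:
    part1 = json.load(fh)

part2 = run_part2(config, part1)
with open(OUT / "part2.json", "w") as fh:
    json.dump(part2, fh, indent=1)

rate = {200: "5 Hz", 100: "10 Hz", 50: "20 Hz", 25: "40 Hz", 10: "100 Hz"}
print("mean over subjects (GS F1 / nθ / EOF):")
for name, per_step in part2["results"].items():
    parts = []
    for step in sorted(per_step, reverse=True):
        cells = per_step[step]
        f1 = np.mean([c["GS"]["f1"] for c in cells])
        npar = np.mean([c["GS"]["n_parameters"] for c in cells])
        eof = np.mean([c["GS"]["eof"] for c in cells])
        parts.append(f"{rate.get(step, step)}: {f1:.1f}/{npar:.0f}/{eof:.1f}")
    print(f"  {name.upper():4s} " + " | ".join(parts))
print(f"\nWritten to {OUT / 'part2.json'}")
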
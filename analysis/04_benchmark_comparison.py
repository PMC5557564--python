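#!/usr/bin/env python
"""Part 3: compare the best-EOF models against the LDA benchmark.

For each subject and classifier the downsampling step with the highest EOF
on the generalization set is retained; the LDA branch (time-domain features
at full rate, 70/30 split) is trained per subject; and the four classifiers
are compared pairwise with Wilcoxon tests on F1, parameter count and EOF.
"""

import json
from pathlib import Path

import pandas as pd

from semgbench.pipeline import desk_scale_config, run_part3, summary_markdown

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

config = desk_scale_config(seed=1)
with open(OUT / "part2.json") as fh:
    part2 = json.load(fh)
# JSON turns the integer step keys into strings; restore them
part2["results"] = {name: {int(k): v for k, v in steps.items()}
                    for name, steps in part2["results"].items()}

part3 = run_part3(config, part2)
with open(OUT / "part3.json", "w") as fh:
    json.dump(part3, fh, indent=1)
pd.DataFrame(part3["summary"]).to_csv(OUT / "summary.csv", index=False)
(OUT / "summary.md").write_text(summary_markdown(part3["summary"]))

print("Best-EOF step per classifier (per subject):")
for name, picks in part3["best_step_on_gs"].items():
    print(f"  {name.upper():4s} {picks}")
print("\nSummary (mean (std) over subjects):")
print(summary_markdown(part3["summary"]))
if part3["comparisons"]:
    p = part3["comparisons"]["eof"]["p_values"]
    labels = part3["comparisons"]["eof"]["conditions"]
    print("Pairwise Wilcoxon p-values on EOF:")
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            print(f"  {labels[i]} vs {labels[j]}: p = {p[i][j]:.4f}")
print(f"\nWritten to {OUT / 'part3.json'}, summary.csv, summary.md")
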
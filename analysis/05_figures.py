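#!/usr/bin/env python
"""Boxplot figures for the rate sweep and the benchmark comparison."""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

OUT = Path("results/analysis")
FIGS = OUT / "figures"
FIGS.mkdir(parents=True, exist_ok=True)

with open(OUT / "part2.json") as fh:
    part2 = json.load(fh)
with open(OUT / "part3.json") as fh:
    part3 = json.load(fh)

rate = {"200": "5", "100": "10", "50": "20", "25": "40", "10": "100"}

# F1, nθ and EOF on GS over the training sampling rate, per classifier
for metric, ylabel, log in (("f1", "F1Score on GS", False),
                            ("n_parameters", "number of parameters", True),
                            ("eof", "EOF on GS", False)):
    fig, ax = plt.subplots(figsize=(7, 4))
    names = list(part2["results"])
    steps = sorted(part2["results"][names[0]], key=int, reverse=True)
    width = 0.25
    for k, name in enumerate(names):
        data = [[c["GS"][metric] for c in part2["results"][name][s]]
                for s in steps]
        pos = [i + (k - 1) * width for i in range(len(steps))]
        bp = ax.boxplot(data, positions=pos, widths=width * 0.9,
                        showmeans=True, patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(f"C{k}")
            box.set_alpha(0.5)
        ax.plot([], [], color=f"C{k}", label=name.upper())
    ax.set_xticks(range(len(steps)))
    ax.set_xticklabels([f"{rate[s]} Hz" for s in steps])
    ax.set_xlabel("training-set sampling rate")
    ax.set_ylabel(ylabel)
    if log:
        ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIGS / f"rate_sweep_{metric}.png", dpi=150)
    plt.close(fig)

# benchmark comparison: best-EOF models vs LDA
fig, axes = plt.subplots(1, 3, figsize=(12, 4))
labels = [row["classifier"].upper() for row in part3["summary"]]
for ax, metric, title in zip(axes, ("f1", "n_parameters", "eof"),
                             ("F1Score", "nθ", "EOF")):
    data = [part3["per_subject"][row["classifier"]][metric]
            for row in part3["summary"]]
    ax.boxplot(data, tick_labels=labels, showmeans=True)
    ax.set_title(title)
    if metric == "n_parameters":
        ax.set_yscale("log")
fig.tight_layout()
fig.savefig(FIGS / "benchmark_comparison.png", dpi=150)
plt.close(fig)

print(f"Figures written to {FIGS}/")
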
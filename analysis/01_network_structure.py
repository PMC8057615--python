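"""Summarise the network topology: census, regulation table, feedback loops.

Writes results/network/: a SIF edge list, a regulation CSV, and a JSON
summary with the positive feedback loops that underlie the bistability.
"""

import json
from pathlib import Path

import pandas as pd

from csf1r_grn import default_network, feedback_loops, write_sif

OUT = Path(__file__).resolve().parent.parent / "results" / "network"
OUT.mkdir(parents=True, exist_ok=True)

net = default_network()
write_sif(net, OUT / "network.sif")
pd.DataFrame([r.__dict__ for r in net.regulations]).to_csv(
    OUT / "regulations.csv", index=False)

loops = feedback_loops(net, max_length=4)
positive = [list(c.nodes) for c in loops if c.positive]
negative = [list(c.nodes) for c in loops if not c.positive]
summary = {
    "n_components": len(net.components),
    "n_regulations": len(net.regulations),
    "n_loops_up_to_4": len(loops),
    "n_positive": len(positive),
    "n_negative": len(negative),
    "positive_loops": positive,
    "negative_loops": negative,
}
(OUT / "summary.json").write_text(json.dumps(summary, indent=1))

print(f"{summary['n_components']} components, {summary['n_regulations']} regulations")
print(f"feedback loops (length <= 4): {len(loops)} "
      f"({len(positive)} positive, {len(negative)} negative)")
print("shortest positive loops:",
      [l for l in positive if len(l) <= 2])
print(f"wrote {OUT}/")
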
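"""Bifurcation structure vs LPS: steady-state branches with stability,
saddle-node locations, the hysteresis sweep, and the washout experiment —
in the basal condition and under 50% STAT1 knockdown.

Writes results/bifurcation/: branch CSVs, fold JSON, sweep and washout CSVs,
and a diagram figure.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from csf1r_grn import (
    build_model, default_network, default_params, find_steady_states,
    hysteresis_sweep, washout_experiment,
)
from csf1r_grn.bifurcation import BifurcationDiagram, continue_branch

OUT = Path(__file__).resolve().parent.parent / "results" / "bifurcation"
OUT.mkdir(parents=True, exist_ok=True)

net = default_network()
params = default_params()
model = build_model(net, params)


def diagram(synthesis_scale, tag):
    states = find_steady_states(net, params, 0.0, n_starts=24, seed=0,
                                synthesis_scale=synthesis_scale, model=model)
    branches, folds = [], []
    for start, direction in ((states[0], +1), (states[-1], +1), (states[-1], -1)):
        d = continue_branch(net, params, start, (-0.6, 1.5), direction=direction,
                            synthesis_scale=synthesis_scale, model=model)
        branches += d.branches
        folds += d.fold_points
    frame = BifurcationDiagram(branches, folds).to_frame(model)
    frame.to_csv(OUT / f"branches_{tag}.csv", index=False)
    (OUT / f"folds_{tag}.json").write_text(json.dumps(
        [{"lps": l, "stat1_mrna": float(s[model.mrna_index('STAT1')])}
         for l, s in folds], indent=1))
    print(f"{tag}: {len(states)} steady states at lps=0 "
          f"({sum(s.stable for s in states)} stable); folds at "
          f"{[round(l, 3) for l, _ in folds]}")
    return frame


frame0 = diagram(None, "basal")
frame_kd = diagram({"STAT1": 0.5}, "stat1_kd50")

sweep = hysteresis_sweep(net, params, [0, 0.25, 0.5, 0.75, 1.0], dwell_h=200.0,
                         model=model)
sweep.to_csv(OUT / "hysteresis.csv", index=False)
down0 = sweep[(sweep.sweep == "down") & (sweep.lps == 0)]["STAT1_mrna"].iloc[0]
print(f"down-sweep Stat1 mRNA at lps=0: {down0:.2f} (irreversible activation)")

kept, removed, rel = washout_experiment(net, params, 36.0, 48.0, model=model)
pd.concat([kept.long_frame().assign(arm="maintained"),
           removed.long_frame().assign(arm="removed")]).to_csv(
    OUT / "washout.csv", index=False)
print(f"washout 36+12 h: Irf8 diff {100 * rel['IRF8']:.1f}%, "
      f"Csf1 diff {100 * rel['CSF1']:.1f}% (both < 20% => persistence)")

fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
for ax, frame, title in ((axes[0], frame0, "basal"),
                         (axes[1], frame_kd, "50% STAT1 knockdown")):
    for (bid, stab), sub in frame.groupby(["branch_id", "stability"]):
        sub = sub.sort_values("lps")
        ax.plot(sub["lps"], sub["STAT1_mrna"],
                ls="-" if stab == "stable" else "--",
                color="k" if stab == "stable" else "0.6", lw=1.2)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel("LPS")
    ax.set_title(title)
axes[0].set_ylabel("Stat1 mRNA steady state")
fig.tight_layout()
fig.savefig(OUT / "diagram.png", dpi=120)
print(f"wrote {OUT}/")
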
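"""Simulate the basal and LPS-step time courses and classify each mRNA's
response shape; plot the panels of the calibration comparison.

Writes results/timecourse/: tidy CSVs for both conditions, the per-component
shape classification, and a figure of all 11 mRNA trajectories.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from csf1r_grn import build_model, default_network, default_params
from csf1r_grn.calibration import qualitative_fit_report
from csf1r_grn.simulate import ExperimentProtocol, run

OUT = Path(__file__).resolve().parent.parent / "results" / "timecourse"
OUT.mkdir(parents=True, exist_ok=True)

net = default_network()
params = default_params()
model = build_model(net, params)
grid = np.linspace(0, 48, 193)

basal = run(net, params, ExperimentProtocol.basal(48.0), grid=grid, model=model)
lps = run(net, params, ExperimentProtocol.lps_step(48.0), grid=grid, model=model)
basal.long_frame().to_csv(OUT / "basal.csv", index=False)
lps.long_frame().to_csv(OUT / "lps_step.csv", index=False)

report = qualitative_fit_report(net, params, model=model)
report.to_csv(OUT / "trajectory_classes.csv")
print(report.to_string())
stated = report.dropna(subset=["expected"])
print(f"\n{int(stated['match'].sum())}/{len(stated)} described response "
      "shapes reproduced")

frame = lps.mrna_frame()
fig, axes = plt.subplots(3, 4, figsize=(13, 8), sharex=True)
for ax, comp in zip(axes.flat, frame.columns):
    ax.plot(frame.index, frame[comp], "k-")
    ax.axhline(1.0, color="0.7", lw=0.8, ls="--")
    ax.set_title(f"{comp} ({report.loc[comp, 'simulated']})", fontsize=9)
axes.flat[-1].axis("off")
fig.supxlabel("time after LPS (h)")
fig.supylabel("mRNA (reference-gene-relative)")
fig.tight_layout()
fig.savefig(OUT / "lps_step.png", dpi=120)
print(f"wrote {OUT}/")
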
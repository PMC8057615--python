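"""siRNA-style knockdown predictions: 50% STAT1/STAT3 (48 h) and IRF8
(24 h) downregulation, each compared with the untreated control.

Writes results/knockdown/ratios.csv (component x knockdown ratios).
"""

from pathlib import Path

import pandas as pd

from csf1r_grn import build_model, default_network, default_params, knockdown_prediction

OUT = Path(__file__).resolve().parent.parent / "results" / "knockdown"
OUT.mkdir(parents=True, exist_ok=True)

net = default_network()
params = default_params()
model = build_model(net, params)

runs = [("STAT1", 0.5, 48.0), ("STAT3", 0.5, 48.0), ("IRF8", 0.5, 24.0)]
cols = {}
for target, frac, horizon in runs:
    ratios = knockdown_prediction(net, params, target, frac, horizon_h=horizon,
                                  model=model)
    cols[f"{target}_{int(frac * 100)}pct_{int(horizon)}h"] = ratios

table = pd.DataFrame(cols)
table.to_csv(OUT / "ratios.csv")
print("mRNA relative to untreated control:")
print(table.round(4).to_string())

s1 = table["STAT1_50pct_48h"].drop("STAT1")
i8 = table["IRF8_50pct_24h"].drop("IRF8")
print(f"\nSTAT1 knockdown lowers all other components: {(s1 < 1).all()}")
print(f"IRF8 knockdown leaves others within 10% of control: "
      f"{(abs(i8 - 1) < 0.1).all()}")
print(f"wrote {OUT}/")
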
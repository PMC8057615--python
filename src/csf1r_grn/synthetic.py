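"""qPCR-like synthetic data with the statistical structure of the source
experiments: a handful of time points over 0-48 h, four replicates,
values relative to an (assumed noise-free) reference gene, and
multiplicative lognormal measurement noise — qPCR ratios are positive
and approximately log-normal. A truth record (the generating parameters
and noiseless trajectories) accompanies every dataset so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import QpcrDataset, condition_protocol
from .model import build_model
from .network import NetworkDefinition
from .params import ParameterSet
from .simulate import run

__all__ = ["SynthConfig", "generate", "generate_ddct_view", "DEFAULT_TIME_GRID"]

#: sampling pattern of the LPS time-course figures: dense early, plus 48 h
DEFAULT_TIME_GRID = (0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 32.0, 48.0)

PRESETS = ("basal_48h", "lps_step_48h", "washout_36_12", "knockdown")


@dataclass(frozen=True)
class SynthConfig:
    preset: str = "lps_step_48h"
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    n_replicates: int = 4
    noise: str = "lognormal"      # or "gaussian"
    cv: float = 0.2               # lognormal coefficient of variation
    sd: float = 0.1               # gaussian additive SD
    seed: int = 0
    knockdown_target: str = "STAT1"
    knockdown_fraction: float = 0.5
    knockdown_horizon_h: float = 48.0

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.cv < 0 or self.sd < 0:
            raise ValueError("noise amplitude must be >= 0")

    @property
    def condition(self) -> str:
        return {
            "basal_48h": "basal",
            "lps_step_48h": "lps",
            "washout_36_12": "washout",
            "knockdown": f"kd:{self.knockdown_target}:{self.knockdown_fraction}",
        }[self.preset]


def generate(net: NetworkDefinition, params: ParameterSet,
             config: SynthConfig) -> tuple[QpcrDataset, dict]:
    """Simulate the preset protocol and sample noisy replicates.

    Returns the dataset plus a truth record holding the generating
    parameters and the noiseless trajectory table.
    """
    grid = np.asarray(config.time_grid, float)
    horizon = float(grid.max()) if config.preset != "knockdown" else config.knockdown_horizon_h
    if config.preset == "knockdown":
        grid = grid[grid <= horizon]
        if grid[-1] < horizon:
            grid = np.append(grid, horizon)
    proto = condition_protocol(config.condition, horizon)
    model = build_model(net, params)
    tc = run(net, params, proto, grid=grid, model=model)
    frame = tc.mrna_frame()
    rng = np.random.default_rng(config.seed)
    rows = []
    if config.noise == "lognormal":
        sigma = np.sqrt(np.log1p(config.cv ** 2))
        mu = -0.5 * sigma ** 2  # mean-preserving
    for t in grid:
        for comp in frame.columns:
            mean = float(frame.loc[t, comp])
            for rep in range(1, config.n_replicates + 1):
                if config.noise == "lognormal":
                    val = mean * float(rng.lognormal(mu, sigma)) if sigma > 0 else mean
                elif config.noise == "gaussian":
                    val = max(mean + float(rng.normal(0.0, config.sd)), 0.0)
                else:
                    raise ValueError(f"unknown noise model {config.noise!r}")
                rows.append({"condition": config.condition, "component": comp,
                             "time_h": t, "replicate": rep, "value": val})
    records = pd.DataFrame(rows)
    dataset = QpcrDataset(records, meta={"preset": config.preset, "cv": config.cv,
                                         "noise": config.noise, "seed": config.seed,
                                         "n_replicates": config.n_replicates})
    truth = {"params": params.to_dict(), "config": config,
             "noiseless": frame}
    return dataset, truth


def generate_ddct_view(dataset: QpcrDataset, control_condition: str) -> QpcrDataset:
    """Re-express values relative to the control condition's per-component
    mean (the fold-change normalization used for knockdown comparisons)."""
    rec = dataset.records
    if control_condition not in set(rec["condition"]):
        raise ValueError(f"control condition {control_condition!r} not in dataset")
    ctrl = rec[rec["condition"] == control_condition].groupby("component")["value"].mean()
    if (ctrl == 0).any():
        zero = list(ctrl[ctrl == 0].index)
        raise ZeroDivisionError(f"control mean is zero for component(s): {zero}")
    out = rec.copy()
    out["value"] = out.apply(lambda r: r["value"] / ctrl[r["component"]], axis=1)
    return QpcrDataset(out, normalization="2^-ddCt",
                       meta={**dataset.meta, "control_condition": control_condition})
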
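"""Synthetic study-like data for recovery and pipeline tests.

Two generators:

* `simulate_factorial` emulates the measurement layer — the 12-cell
  full-factorial design with per-cell mean response vectors plus Gaussian
  noise at the reported measurement uncertainties (5% of the mean where no
  uncertainty was reported). Percent-bounded responses are clipped to
  [0, 100] and non-negative responses to 0 so simulated datasets satisfy
  the dataset invariants.
* `plant_mlp_dataset` draws a random 7-9-22 network, evaluates it on all 12
  design encodings and denormalizes with a known scaler; training on that
  dataset must recover the planted function, which makes it the oracle for
  the estimation and sensitivity machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (NONNEGATIVE_RESPONSES, PERCENT_RESPONSES, RESPONSES,
                      Scaler, StudyDataset, all_design_points, encode_design,
                      load_study, load_study_uncertainties)
from .mlp import MLPResults

__all__ = ["FactorialSimConfig", "simulate_factorial", "plant_mlp_dataset",
           "default_noise_sd"]


def default_noise_sd(means: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample noise levels: reported uncertainties, else 5% of the mean."""
    if means is None:
        means = load_study().responses
    sd = load_study_uncertainties().reindex(means.index)
    fallback = 0.05 * means.abs()
    return sd.fillna(fallback[sd.columns]).astype(float)


@dataclass
class FactorialSimConfig:
    """Settings of the factorial measurement simulator.

    ``means`` and ``noise_sd`` are per-cell tables indexed like the
    packaged study (default: the packaged means and reported
    uncertainties). ``replicates`` repeats every cell with fresh noise.
    """

    means: pd.DataFrame | None = None
    noise_sd: pd.DataFrame | None = None
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.means is None:
            self.means = load_study().responses
        if self.noise_sd is None:
            self.noise_sd = default_noise_sd(self.means)
        self.noise_sd = self.noise_sd.reindex(self.means.index)
        if (self.noise_sd < 0).any().any():
            raise ValueError("noise_sd must be non-negative")
        self.noise_sd = self.noise_sd + 0.0   # -0.0 -> +0.0


def simulate_factorial(config: FactorialSimConfig | None = None,
                       **kwargs) -> StudyDataset:
    """Draw a noisy full-factorial dataset; seeded and reproducible."""
    cfg = config or FactorialSimConfig(**kwargs)
    rng = np.random.default_rng(cfg.seed)
    base = load_study().table[["id", "variety", "method"]]
    rows = []
    next_id = 1
    for _ in range(cfg.replicates):
        noise = rng.normal(0.0, cfg.noise_sd[list(RESPONSES)].to_numpy())
        vals = cfg.means[list(RESPONSES)].to_numpy() + noise
        rep = base.copy()
        rep["id"] = range(next_id, next_id + len(base))
        next_id += len(base)
        for j, name in enumerate(RESPONSES):
            col = vals[:, j]
            if name in NONNEGATIVE_RESPONSES:
                col = np.clip(col, 0.0, None)
            if name in PERCENT_RESPONSES:
                col = np.clip(col, 0.0, 100.0)
            rep[name] = col
        rows.append(rep)
    return StudyDataset(pd.concat(rows, ignore_index=True))


def plant_mlp_dataset(seed: int = 0, n_hidden: int = 9,
                      weight_scale: float = 0.5
                      ) -> tuple[MLPResults, StudyDataset]:
    """A random planted network and the noiseless dataset it generates.

    The planted network's normalized outputs are denormalized with the
    packaged study's scaler, so the resulting table has realistic units
    and passes the dataset invariants.
    """
    rng = np.random.default_rng(seed)
    n_in, n_out = 7, len(RESPONSES)
    W1 = rng.uniform(-weight_scale, weight_scale, (n_hidden, n_in))
    B1 = rng.uniform(-weight_scale, weight_scale, n_hidden)
    W2 = rng.uniform(-weight_scale, weight_scale, (n_out, n_hidden))
    B2 = rng.uniform(-weight_scale, weight_scale, n_out)
    scaler = Scaler.fit(load_study().responses, RESPONSES)
    planted = MLPResults(None, W1, B1, W2, B2, scaler)

    base = load_study().table[["id", "variety", "method"]].copy()
    X = np.vstack([encode_design(dp) for dp in all_design_points()])
    Y = scaler.inverse(planted.forward(X))
    for j, name in enumerate(RESPONSES):
        base[name] = Y[:, j]
    return planted, StudyDataset(base)
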
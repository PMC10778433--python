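"""Single-hidden-layer perceptron regression of quality responses on design.

The network is the MLP 7-9-22 of the study: a one-hot (variety, method)
encoding enters a tanh hidden layer of nine neurons, and a logistic output
layer produces the 22 responses in min-max normalized space,

    y = logistic(W2 . tanh(W1 . x + B1) + B2).

Weights are estimated by minimizing the sum-of-squares error (SOS) with the
BFGS quasi-Newton algorithm under multiple random restarts; the model object
follows the statsmodels convention of a `DryingMLP` model whose ``fit``
returns an `MLPResults` carrying estimates, fit diagnostics and prediction
methods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

from .dataset import (RESPONSES, DesignPoint, Scaler, StudyDataset,
                      encode_design)

__all__ = ["TrainConfig", "FitReport", "DryingMLP", "MLPResults",
           "forward", "sos_error", "r_squared"]


def forward(x: np.ndarray, W1: np.ndarray, B1: np.ndarray,
            W2: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Network forward pass in normalized space.

    ``x`` may be a single input vector or a (samples x inputs) matrix.
    Outputs lie in (0, 1) componentwise (logistic range).
    """
    x = np.asarray(x, float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != W1.shape[1]:
        raise ValueError(f"input dimension {X.shape[1]} does not match "
                         f"W1 columns {W1.shape[1]}")
    Y = expit(np.tanh(X @ W1.T + B1) @ W2.T + B2)
    return Y[0] if single else Y


def sos_error(pred: np.ndarray, target: np.ndarray) -> float:
    """Sum of squared deviations over all samples and outputs."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    return float(np.sum((pred - target) ** 2))


def r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    obs = np.asarray(obs, float).ravel()
    pred = np.asarray(pred, float).ravel()
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observations have zero variance; r^2 is undefined")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


@dataclass
class TrainConfig:
    """Optimization settings for `DryingMLP.fit`.

    The restart schedule is two-phase: ``restarts`` short BFGS runs of
    ``explore_maxiter`` iterations explore weight space from seeded uniform
    initializations, then the ``polish_top`` lowest-SOS candidates are run
    to convergence (up to ``polish_maxiter`` iterations each). The best
    final SOS wins.
    """

    n_hidden: int = 9
    restarts: int = 30
    explore_maxiter: int = 600
    polish_top: int = 5
    polish_maxiter: int = 5000
    gradient_tolerance: float = 1e-12
    init_scale: float = 0.5
    split: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class FitReport:
    """Per-cycle and per-output goodness of the trained network."""

    r2_train: float
    r2_test: float
    r2_validation: float
    r2_per_output: pd.Series
    sos: float
    n_iterations: int
    best_restart: int
    n_restarts: int
    seed: int
    sos_history: list = field(default_factory=list)


class _Arch:
    """Shapes and (un)packing of the flat parameter vector."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int):
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.sizes = [n_hidden * n_in, n_hidden, n_out * n_hidden, n_out]
        self.n_params = sum(self.sizes)

    def unpack(self, theta: np.ndarray):
        i = 0
        shapes = [(self.n_hidden, self.n_in), (self.n_hidden,),
                  (self.n_out, self.n_hidden), (self.n_out,)]
        out = []
        for s, shape in zip(self.sizes, shapes):
            out.append(theta[i:i + s].reshape(shape))
            i += s
        return out

    def pack(self, W1, B1, W2, B2) -> np.ndarray:
        return np.concatenate([np.ravel(W1), np.ravel(B1),
                               np.ravel(W2), np.ravel(B2)])


def _loss_and_grad(theta, X, Yn, arch):
    """SOS loss and its analytic gradient (backpropagation)."""
    W1, B1, W2, B2 = arch.unpack(theta)
    A = np.tanh(X @ W1.T + B1)
    P = expit(A @ W2.T + B2)
    E = P - Yn
    loss = np.sum(E * E)
    dZ = 2.0 * E * P * (1.0 - P)
    gW2 = dZ.T @ A
    gB2 = dZ.sum(axis=0)
    dA = (dZ @ W2) * (1.0 - A * A)
    gW1 = dA.T @ X
    gB1 = dA.sum(axis=0)
    return loss, arch.pack(gW1, gB1, gW2, gB2)


class DryingMLP:
    """MLP regression model of the 22 responses on the one-hot design.

    Parameters
    ----------
    dataset : StudyDataset
        Samples to fit. Outputs are min-max scaled to ``output_range``
        before training; the one-hot inputs are used as-is.
    n_hidden : int
        Hidden-layer width (the study's selected architecture uses 9).
    output_range : (float, float)
        Target interval for the scaled outputs. Kept inside (0, 1) with a
        margin so the logistic output layer never has to saturate.
    scaler : Scaler, optional
        Use a pre-fitted output scaler instead of fitting one to the
        dataset (e.g. the known scaler of a planted network).
    """

    def __init__(self, dataset: StudyDataset, n_hidden: int = 9,
                 output_range: tuple[float, float] = (0.05, 0.95),
                 scaler: Scaler | None = None):
        self.dataset = dataset
        self.n_hidden = int(n_hidden)
        self.scaler = scaler if scaler is not None else Scaler.fit(
            dataset.responses, RESPONSES,
            lo=output_range[0], hi=output_range[1])
        self.X = dataset.design_matrix()
        self.Y = dataset.responses.to_numpy(float)
        self.Yn = self.scaler.transform(self.Y)
        self.arch = _Arch(self.X.shape[1], self.n_hidden, self.Y.shape[1])

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "DryingMLP":
        return cls(StudyDataset(table), **kwargs)

    def fit(self, config: TrainConfig | None = None, *, seed: int | None = None,
            restarts: int | None = None, track_history: bool = False
            ) -> "MLPResults":
        """Train by multi-restart BFGS on the sum-of-squares error.

        ``seed`` / ``restarts`` override the corresponding `TrainConfig`
        fields. Reproducible: the same configuration and seed give a
        bit-identical result.
        """
        cfg = config or TrainConfig(n_hidden=self.n_hidden)
        if cfg.n_hidden != self.n_hidden:
            raise ValueError("TrainConfig.n_hidden disagrees with the model")
        if seed is not None:
            cfg = TrainConfig(**{**cfg.__dict__, "seed": seed})
        if restarts is not None:
            cfg = TrainConfig(**{**cfg.__dict__, "restarts": restarts})

        rng = np.random.default_rng(cfg.seed)
        args = (self.X, self.Yn, self.arch)
        candidates = []
        for r in range(cfg.restarts):
            theta0 = rng.uniform(-cfg.init_scale, cfg.init_scale,
                                 self.arch.n_params)
            res = minimize(_loss_and_grad, theta0, args=args, jac=True,
                           method="BFGS",
                           options={"maxiter": cfg.explore_maxiter,
                                    "gtol": cfg.gradient_tolerance})
            if not np.isfinite(res.fun):
                warnings.warn(f"restart {r} diverged to a non-finite loss; "
                              "discarded")
                continue
            candidates.append((float(res.fun), r, res.x, res.nit))
        if not candidates:
            raise RuntimeError("every training restart failed")
        candidates.sort(key=lambda c: (c[0], c[1]))

        history: list = []
        best = None
        for fun0, r, x0, nit0 in candidates[:max(1, cfg.polish_top)]:
            track = track_history and best is None
            cb = None
            if track:
                cb = lambda xk: history.append(  # noqa: E731
                    _loss_and_grad(xk, *args)[0])
            res = minimize(_loss_and_grad, x0, args=args, jac=True,
                           method="BFGS", callback=cb,
                           options={"maxiter": cfg.polish_maxiter,
                                    "gtol": cfg.gradient_tolerance})
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best[0]:
                best = (float(res.fun), r, res.x, nit0 + res.nit)
        if best is None:
            raise RuntimeError("polish stage failed on every candidate")

        sos, restart_idx, theta, nit = best
        W1, B1, W2, B2 = (a.copy() for a in self.arch.unpack(theta))
        P = forward(self.X, W1, B1, W2, B2)

        # Per-cycle r2. Training is resubstitution (all samples enter the
        # fit); the test/validation cycles are seeded random subsets held
        # out of *evaluation* only, mirroring an 8/2/2 partition of n=12.
        n = len(self.Yn)
        perm = np.random.default_rng(cfg.seed + 1).permutation(n)
        n_test = max(1, round(n * (cfg.split[1] if cfg.split[1] > 0 else 1 / 6)))
        n_val = max(1, round(n * (cfg.split[2] if cfg.split[2] > 0 else 1 / 6)))
        test_idx, val_idx = perm[:n_test], perm[n_test:n_test + n_val]

        def cycle_r2(idx):
            o, p = self.Yn[idx].ravel(), P[idx].ravel()
            if o.std() == 0:
                return float("nan")
            return float(stats.pearsonr(o, p)[0] ** 2)

        r2_out = pd.Series(
            [r_squared(self.Yn[:, j], P[:, j]) for j in range(len(RESPONSES))],
            index=list(RESPONSES), name="r2")
        report = FitReport(
            r2_train=cycle_r2(np.arange(n)),
            r2_test=cycle_r2(test_idx),
            r2_validation=cycle_r2(val_idx),
            r2_per_output=r2_out,
            sos=sos, n_iterations=int(nit), best_restart=int(restart_idx),
            n_restarts=cfg.restarts, seed=cfg.seed, sos_history=history)
        return MLPResults(self, W1, B1, W2, B2, self.scaler, report)


class MLPResults:
    """Fitted network: weights, scaler, diagnostics and predictions."""

    def __init__(self, model: DryingMLP | None, W1, B1, W2, B2,
                 scaler: Scaler, report: FitReport | None = None):
        self.model = model
        self.W1, self.B1 = np.asarray(W1, float), np.asarray(B1, float)
        self.W2, self.B2 = np.asarray(W2, float), np.asarray(B2, float)
        n_h, n_i = self.W1.shape
        if self.B1.shape != (n_h,) or self.W2.shape[1] != n_h:
            raise ValueError("weight matrix shapes are inconsistent")
        if self.B2.shape != (self.W2.shape[0],):
            raise ValueError("output bias shape is inconsistent")
        for a in (self.W1, self.B1, self.W2, self.B2):
            if not np.all(np.isfinite(a)):
                raise ValueError("weights must be finite")
        self.scaler = scaler
        self.report = report

    # -- prediction ----------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Normalized-space prediction for one-hot input(s)."""
        return forward(x, self.W1, self.B1, self.W2, self.B2)

    def predict_responses(self, dp: DesignPoint) -> pd.Series:
        """Predict the 22 responses, denormalized to their natural units."""
        if self.scaler is None:
            raise ValueError("model carries no scaler; cannot denormalize")
        y = self.scaler.inverse(self.forward(encode_design(dp)))
        return pd.Series(y, index=list(RESPONSES),
                         name=f"{dp.variety}/{dp.method}")

    @property
    def fittedvalues(self) -> pd.DataFrame:
        """In-sample predictions in natural units (samples x responses)."""
        P = self.scaler.inverse(self.forward(self.model.X))
        return pd.DataFrame(P, index=self.model.dataset.responses.index,
                            columns=list(RESPONSES))

    @property
    def resid(self) -> pd.DataFrame:
        return self.fittedvalues - self.model.dataset.responses

    @property
    def rsquared(self) -> float:
        return self.report.r2_train

    # -- downstream analyses -------------------------------------------
    def sensitivity(self, signed: bool = True):
        from .sensitivity import yoon_relative_importance
        return yoon_relative_importance(self, signed=signed)

    def gof(self, n_constants: int = 0) -> pd.DataFrame:
        from .gof import gof_table
        return gof_table(self.model.dataset.responses, self.fittedvalues,
                         n_constants=n_constants)

    def summary(self) -> str:
        r = self.report
        n_i, n_h, n_o = self.W1.shape[1], self.W1.shape[0], self.W2.shape[0]
        lines = [
            f"MLP {n_i}-{n_h}-{n_o} regression (tanh hidden, logistic output)",
            "=" * 62,
            f"training algorithm        BFGS on SOS, {r.n_restarts} restarts"
            if r else "untrained",
        ]
        if r:
            lines += [
                f"final SOS (normalized)    {r.sos:.6g}",
                f"iterations (best restart) {r.n_iterations}",
                f"r2 training               {r.r2_train:.4f}",
                f"r2 testing                {r.r2_test:.4f}",
                f"r2 validation             {r.r2_validation:.4f}",
                f"per-output r2 min/median  {r.r2_per_output.min():.4f} / "
                f"{r.r2_per_output.median():.4f}",
                f"seed                      {r.seed}",
            ]
        return "\n".join(lines)

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "W1": self.W1.tolist(), "B1": self.B1.tolist(),
            "W2": self.W2.tolist(), "B2": self.B2.tolist(),
            "hidden_activation": "tanh", "output_activation": "logistic",
            "scaler": json.loads(self.scaler.to_json()) if self.scaler else None,
        })
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "MLPResults":
        text = text_or_path
        if isinstance(text_or_path, Path) or (
                isinstance(text_or_path, str)
                and text_or_path.lstrip()[:1] != "{"):
            text = Path(text_or_path).read_text()
        d = json.loads(text)
        scaler = None
        if d.get("scaler") is not None:
            scaler = Scaler.from_json(json.dumps(d["scaler"]))
        return cls(None, np.array(d["W1"]), np.array(d["B1"]),
                   np.array(d["W2"]), np.array(d["B2"]), scaler)
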
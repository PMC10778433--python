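"""Study data: twelve dried sweet-potato samples and their design encoding.

The study crosses four sweet-potato varieties (white, pink, orange, purple)
with three drying methods (lyophilization, convective drying, osmotic
dehydration) and characterizes each of the twelve variety x method cells by
22 quality responses: CIELab color (L*, a*, b*), proximate chemical
composition (% dry weight), mineral content (mg/kg), total phenolics
(mg GAE/100 g DW), four antioxidant-capacity assays (TE/100 g DW) and two
inhibitory activities (%). The packaged values are the per-cell means; the
reported measurement uncertainties are carried in a side table and are used
only by the synthetic-data generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VARIETIES = ("white", "pink", "orange", "purple")
METHODS = ("lyophilization", "convective", "osmotic")

#: The 22 response names, in canonical column order.
RESPONSES = (
    "phenols", "dpph", "abts", "rp", "soa", "aia", "ahga",
    "L", "a", "b",
    "moisture", "proteins", "fats", "sugars", "cellulose", "ash", "carbs",
    "K", "Mg", "Ca", "Fe", "Na",
)

#: Responses bounded to [0, 100] (percentages).
PERCENT_RESPONSES = ("aia", "ahga", "moisture", "proteins", "fats",
                     "sugars", "cellulose", "ash", "carbs")
#: Responses that cannot be negative.
NONNEGATIVE_RESPONSES = PERCENT_RESPONSES + ("phenols", "dpph", "abts",
                                             "rp", "soa", "K", "Mg", "Ca",
                                             "Fe", "Na", "L")

#: Input labels of the 7-dimensional one-hot design encoding.
INPUT_LABELS = VARIETIES + METHODS


@dataclass(frozen=True)
class DesignPoint:
    """One cell of the full-factorial design: a variety and a drying method."""

    variety: str
    method: str

    def __post_init__(self) -> None:
        if self.variety not in VARIETIES:
            raise ValueError(f"unknown variety {self.variety!r}; "
                             f"expected one of {VARIETIES}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"expected one of {METHODS}")


def encode_design(dp: DesignPoint) -> np.ndarray:
    """One-hot encode a design point as a length-7 vector.

    Positions 0-3 indicate the variety, positions 4-6 the drying method;
    exactly two entries are 1.
    """
    x = np.zeros(7)
    x[VARIETIES.index(dp.variety)] = 1.0
    x[4 + METHODS.index(dp.method)] = 1.0
    return x


def all_design_points() -> list[DesignPoint]:
    """The 12 cells in sample-id order (variety blocks, methods within)."""
    return [DesignPoint(v, m) for v in VARIETIES for m in METHODS]


class StudyDataset:
    """A set of samples: design points plus their 22-response vectors.

    Wraps a DataFrame with columns ``id, variety, method, <22 responses>``.
    The packaged study has exactly 12 samples (ids 1-12); simulated datasets
    may carry replicates and therefore more rows.
    """

    def __init__(self, table: pd.DataFrame, require_full_factorial: bool = False):
        expected = ["id", "variety", "method", *RESPONSES]
        missing = [c for c in expected if c not in table.columns]
        if missing:
            raise ValueError(f"dataset table is missing columns {missing}")
        table = table.loc[:, expected].reset_index(drop=True)
        if table["id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        vals = table[list(RESPONSES)].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("all responses must be finite")
        for name in PERCENT_RESPONSES:
            col = table[name]
            if ((col < 0) | (col > 100)).any():
                raise ValueError(f"{name} must lie in [0, 100]")
        for name in NONNEGATIVE_RESPONSES:
            if (table[name] < 0).any():
                raise ValueError(f"{name} must be non-negative")
        for v, m in zip(table["variety"], table["method"]):
            DesignPoint(v, m)  # validates the enums
        if require_full_factorial:
            cells = set(zip(table["variety"], table["method"]))
            if len(table) != 12 or len(cells) != 12:
                raise ValueError("expected the 12 distinct variety x method cells")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def responses(self) -> pd.DataFrame:
        """Samples x 22 response matrix, indexed by sample id."""
        return self.table.set_index("id")[list(RESPONSES)]

    @property
    def design_points(self) -> list[DesignPoint]:
        return [DesignPoint(v, m)
                for v, m in zip(self.table["variety"], self.table["method"])]

    def design_matrix(self) -> np.ndarray:
        """Samples x 7 one-hot input matrix."""
        return np.vstack([encode_design(dp) for dp in self.design_points])

    def sample(self, sample_id: int) -> pd.Series:
        row = self.table[self.table["id"] == sample_id]
        if row.empty:
            raise KeyError(f"no sample with id {sample_id}")
        return row.iloc[0]

    def cell(self, dp: DesignPoint) -> pd.Series:
        """The (first) sample measured at the given design cell."""
        mask = (self.table["variety"] == dp.variety) & \
               (self.table["method"] == dp.method)
        row = self.table[mask]
        if row.empty:
            raise KeyError(f"no sample for cell {dp}")
        return row.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyDataset":
        return cls(pd.read_csv(path))

    def __repr__(self) -> str:
        return f"StudyDataset(n={len(self)}, responses={len(RESPONSES)})"


def _resource_frame(name: str) -> pd.DataFrame:
    ref = resources.files("sweetdry.resources").joinpath(name)
    if not ref.is_file():
        raise FileNotFoundError(f"packaged study table {name!r} is missing")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_study() -> StudyDataset:
    """Load the packaged 12-sample study dataset (per-cell means)."""
    ds = StudyDataset(_resource_frame("study_means.csv"),
                      require_full_factorial=True)
    if list(ds.ids) != list(range(1, 13)):
        raise ValueError("packaged dataset must carry sample ids 1-12 in order")
    return ds


def load_study_uncertainties() -> pd.DataFrame:
    """Reported per-sample standard deviations (NaN where unreported).

    Side information only: the modelling pipeline works on means; the
    synthetic-data generator uses these as default noise levels.
    """
    return _resource_frame("study_sd.csv").set_index("id")


class Scaler:
    """Per-variable affine min-max map onto a target interval.

    Fitted on named columns; ``transform`` maps each variable's observed
    [min, max] onto [lo, hi], and ``inverse`` is its exact inverse. Used to
    keep network targets inside the open range of the logistic output.
    """

    def __init__(self, names: Sequence[str], mins: np.ndarray,
                 maxs: np.ndarray, lo: float, hi: float):
        if not hi > lo:
            raise ValueError("hi must exceed lo")
        mins = np.asarray(mins, float)
        maxs = np.asarray(maxs, float)
        flat = [n for n, a, b in zip(names, mins, maxs) if not b > a]
        if flat:
            raise ValueError(f"constant column(s) cannot be scaled: {flat}")
        self.names = list(names)
        self.mins = mins
        self.maxs = maxs
        self.lo = float(lo)
        self.hi = float(hi)

    @classmethod
    def fit(cls, data: pd.DataFrame, names: Sequence[str] | None = None,
            lo: float = 0.05, hi: float = 0.95) -> "Scaler":
        names = list(names) if names is not None else list(data.columns)
        vals = data[names].to_numpy(float)
        return cls(names, vals.min(axis=0), vals.max(axis=0), lo, hi)

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, float)
        span = self.maxs - self.mins
        return self.lo + (values - self.mins) * (self.hi - self.lo) / span

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        scaled = np.asarray(scaled, float)
        span = self.maxs - self.mins
        return self.mins + (scaled - self.lo) * span / (self.hi - self.lo)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "names": self.names,
            "min": self.mins.tolist(),
            "max": self.maxs.tolist(),
            "lo": self.lo,
            "hi": self.hi,
        }, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "Scaler":
        text = text_or_path
        if isinstance(text_or_path, Path) or (
                isinstance(text_or_path, str) and text_or_path.lstrip()[:1] != "{"):
            text = Path(text_or_path).read_text()
        d = json.loads(text)
        return cls(d["names"], np.array(d["min"]), np.array(d["max"]),
                   d["lo"], d["hi"])
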
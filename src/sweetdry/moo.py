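"""Multi-objective selection of the best variety x drying-method cell.

Eight objectives are read off the trained network's predictions: maximize
the seven bioactivity responses (total phenolics, DPPH, ABTS, RP, SoA,
anti-inflammatory and anti-hyperglycemic activity) and minimize moisture.
Because the feasible design space has only 12 cells, exhaustive enumeration
of the non-dominated set is exact and authoritative; a small generational
genetic algorithm over the continuously relaxed one-hot space (with
per-block argmax repair to a feasible cell) is provided as the stochastic
counterpart and is validated against the enumeration.

The compromise member of the Pareto front is the candidate closest, in
Euclidean distance, to the ideal point assembled from the per-objective
optima over the front. By default the distance is taken on the raw
objective scales, which reproduces the study's selection; a min-max
normalized variant is available via ``normalize=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (METHODS, VARIETIES, DesignPoint, StudyDataset,
                      all_design_points, encode_design)

__all__ = ["OBJECTIVES", "objective_vector", "dominates", "ParetoFront",
           "pareto_enumerate", "GAConfig", "ga_optimize",
           "OptimizationResult", "select_compromise"]

#: Objective names and their orientation (+1 maximize, -1 minimize).
OBJECTIVES = (
    ("phenols", +1), ("dpph", +1), ("abts", +1), ("rp", +1),
    ("soa", +1), ("aia", +1), ("ahga", +1), ("moisture", -1),
)
OBJECTIVE_NAMES = tuple(n for n, _ in OBJECTIVES)
_SENSE = np.array([s for _, s in OBJECTIVES], float)


def objective_vector(responses: pd.Series) -> np.ndarray:
    """Extract the 8 objective values (natural units, unoriented)."""
    missing = [n for n in OBJECTIVE_NAMES if n not in responses.index]
    if missing:
        raise KeyError(f"response vector lacks objective field(s) {missing}")
    return responses[list(OBJECTIVE_NAMES)].to_numpy(float)


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance of oriented objective vectors (all-maximize)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return bool(np.all(a >= b) and np.any(a > b))


def orient(obj: np.ndarray) -> np.ndarray:
    """Flip minimized coordinates so that larger is uniformly better."""
    return np.asarray(obj, float) * _SENSE


@dataclass
class ParetoFront:
    """Candidate cells with objectives and non-domination flags."""

    designs: list[DesignPoint]
    predicted: pd.DataFrame               # candidates x 22 responses
    objectives: pd.DataFrame              # candidates x 8, natural units
    dominated: np.ndarray                 # bool per candidate

    def __post_init__(self):
        self.dominated = np.asarray(self.dominated, bool)

    @property
    def front_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.dominated)

    @property
    def front_designs(self) -> list[DesignPoint]:
        return [self.designs[i] for i in self.front_indices]

    def __len__(self) -> int:
        return len(self.designs)

    def to_json(self) -> str:
        rows = []
        for i, dp in enumerate(self.designs):
            rows.append({
                "variety": dp.variety, "method": dp.method,
                "objectives": self.objectives.iloc[i].to_dict(),
                "dominated": bool(self.dominated[i]),
            })
        import json
        return json.dumps(rows, indent=1)


def _flag_dominated(oriented: np.ndarray) -> np.ndarray:
    # pairwise: j dominates i iff all(j >= i) and any(j > i)
    ge = np.all(oriented[:, None, :] >= oriented[None, :, :], axis=2)
    gt = np.any(oriented[:, None, :] > oriented[None, :, :], axis=2)
    dom = ge & gt                     # dom[j, i]: j dominates i
    return dom.any(axis=0)


def _front_from_designs(results, designs: list[DesignPoint]) -> ParetoFront:
    preds = pd.DataFrame([results.predict_responses(dp) for dp in designs])
    preds.index = range(len(designs))
    obj = preds[list(OBJECTIVE_NAMES)].copy()
    flags = _flag_dominated(orient(obj.to_numpy()))
    return ParetoFront(designs, preds, obj, flags)


def pareto_enumerate(results) -> ParetoFront:
    """Exact non-dominated set over the 12 feasible design cells."""
    return _front_from_designs(results, all_design_points())


@dataclass
class GAConfig:
    """Settings of the generational genetic algorithm."""

    generations: int = 593
    population: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    mutation_scale: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.generations < 1 or self.population < 2:
            raise ValueError("need >= 1 generation and population >= 2")


def repair(x: np.ndarray) -> np.ndarray:
    """Project a relaxed [0,1]^7 vector onto a feasible one-hot encoding.

    Argmax within the 4-entry variety block and the 3-entry method block.
    """
    z = np.zeros(7)
    z[int(np.argmax(x[:4]))] = 1.0
    z[4 + int(np.argmax(x[4:]))] = 1.0
    return z


def _decode(x: np.ndarray) -> DesignPoint:
    z = repair(x)
    return DesignPoint(VARIETIES[int(np.argmax(z[:4]))],
                       METHODS[int(np.argmax(z[4:]))])


def ga_optimize(results, config: GAConfig | None = None) -> ParetoFront:
    """Genetic-algorithm search of the design space.

    Individuals live in the relaxed cube [0,1]^7; every evaluation first
    repairs the genome to a one-hot cell, so each candidate maps to one of
    the 12 feasible cells and the resulting front is a subset of the
    enumeration front. Selection is non-dominated sorting with crowding
    distance (NSGA-II style). Reproducible given the seed.
    """
    cfg = config or GAConfig()
    rng = np.random.default_rng(cfg.seed)

    cells = all_design_points()
    cell_objs = np.vstack([
        orient(objective_vector(results.predict_responses(dp)))
        for dp in cells])

    def evaluate(pop: np.ndarray) -> np.ndarray:
        idx = [cells.index(_decode(x)) for x in pop]
        return cell_objs[idx]

    pop = rng.random((cfg.population, 7))
    if len(np.unique([tuple(repair(x)) for x in pop], axis=0)) < 2:
        raise RuntimeError("degenerate initial population")
    objs = evaluate(pop)
    for _ in range(cfg.generations):
        # variation
        parents = pop[rng.integers(0, len(pop), (cfg.population, 2))]
        mask = rng.random((cfg.population, 7)) < 0.5
        children = np.where(mask, parents[:, 0], parents[:, 1])
        no_cx = rng.random(cfg.population) >= cfg.crossover_rate
        children[no_cx] = parents[no_cx, 0]
        mut = rng.random(children.shape) < cfg.mutation_rate
        children = children + mut * rng.normal(0, cfg.mutation_scale,
                                               children.shape)
        children = np.clip(children, 0.0, 1.0)
        cobjs = evaluate(children)
        # environmental selection on the merged population
        allpop = np.vstack([pop, children])
        allobj = np.vstack([objs, cobjs])
        keep = _nsga_select(allobj, cfg.population)
        pop, objs = allpop[keep], allobj[keep]

    final_designs = []
    seen = set()
    for x in pop:
        dp = _decode(x)
        if dp not in seen:
            seen.add(dp)
            final_designs.append(dp)
    return _front_from_designs(results, final_designs)


def _nsga_select(oriented: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k survivors by (front rank, crowding distance)."""
    n = len(oriented)
    remaining = list(range(n))
    chosen: list[int] = []
    while remaining and len(chosen) < k:
        sub = oriented[remaining]
        flags = _flag_dominated(sub)
        front = [remaining[i] for i in np.flatnonzero(~flags)]
        if len(chosen) + len(front) <= k:
            chosen.extend(front)
        else:
            crowd = _crowding(oriented[front])
            order = np.argsort(-crowd, kind="stable")
            need = k - len(chosen)
            chosen.extend([front[i] for i in order[:need]])
        remaining = [i for i in remaining if i not in set(front)]
    return np.array(chosen, int)


def _crowding(objs: np.ndarray) -> np.ndarray:
    n, m = objs.shape
    d = np.zeros(n)
    for j in range(m):
        order = np.argsort(objs[:, j], kind="stable")
        span = objs[order[-1], j] - objs[order[0], j]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0 and n > 2:
            d[order[1:-1]] += (objs[order[2:], j]
                               - objs[order[:-2], j]) / span
    return d


@dataclass
class OptimizationResult:
    """Selected compromise cell with predicted and measured responses."""

    design: DesignPoint
    predicted: pd.Series
    measured: pd.Series | None
    distance: float
    sample_id: int | None = None

    def summary(self) -> str:
        lines = [f"compromise optimum: {self.design.variety} variety, "
                 f"{self.design.method} drying",
                 f"ideal-point distance: {self.distance:.4g}"]
        if self.sample_id is not None:
            lines.append(f"matches study sample {self.sample_id}")
        src = self.measured if self.measured is not None else self.predicted
        kind = "measured" if self.measured is not None else "predicted"
        for name in OBJECTIVE_NAMES:
            lines.append(f"  {name:<10} {src[name]:>12.2f}  ({kind})")
        return "\n".join(lines)


def select_compromise(front: ParetoFront, dataset: StudyDataset | None = None,
                      normalize: bool = False) -> OptimizationResult:
    """Pick the front member nearest the ideal point.

    The ideal point takes each objective's best value over the front
    (maximum for the seven maximized responses, minimum for moisture).
    With ``normalize=True`` each objective is first min-max scaled over
    the front, making the choice invariant to per-objective rescaling.
    Ties break toward the earliest candidate. When ``dataset`` is given
    and the selected cell is one of its samples, the measured responses
    and sample id are attached.
    """
    idx = front.front_indices
    if idx.size == 0:
        raise ValueError("empty Pareto front")
    F = orient(front.objectives.to_numpy()[idx])
    if normalize:
        lo, hi = F.min(axis=0), F.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        F = (F - lo) / span
    ideal = F.max(axis=0)
    dist = np.linalg.norm(F - ideal, axis=1)
    best = idx[int(np.argmin(dist))]
    dp = front.designs[best]
    measured = sample_id = None
    if dataset is not None:
        try:
            row = dataset.cell(dp)
            sample_id = int(row["id"])
            measured = row[front.predicted.columns]
        except KeyError:
            pass
    return OptimizationResult(dp, front.predicted.iloc[best], measured,
                              float(dist.min()), sample_id)
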
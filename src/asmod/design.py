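"""Balanced experimental-design generation and inverse formulation selection.

``generate_design`` produces level-balanced designs: every factor takes each
of its levels in exactly ``n_runs / n_levels`` runs. Among all balanced
assignments, a seeded exchange heuristic maximises the minimum normalised
inter-run distance (a space-filling criterion), so the runs spread over the
design space instead of clustering. The balance property is exact by
construction; the spread is heuristic.

``select_formulations`` inverts fitted models: it evaluates every candidate
on a full factorial grid of the input space, keeps those satisfying all
response constraints, and ranks them by a single objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import DESIGN_DOMAINS, FormulationDataset, FormulationRecord, INPUT_COLUMNS
from .model import NeurofuzzyResults

__all__ = ["DesignSpec", "generate_design", "SelectionQuery", "select_formulations"]


@dataclass(frozen=True)
class DesignSpec:
    """Factors (name, lo, hi, n_levels), runs per level, and a seed."""

    factors: tuple[tuple[str, float, float, int], ...]
    minimum_pattern: int = 8
    seed: int = 0
    n_iterations: int = 2000

    @property
    def n_runs(self) -> int:
        n_levels = {f[3] for f in self.factors}
        if len(n_levels) != 1:
            raise ValueError("all factors must share the same number of levels")
        return next(iter(n_levels)) * self.minimum_pattern


def _min_distance(levels: np.ndarray) -> tuple[float, float]:
    """(min, mean) pairwise distance between runs in normalised level space."""
    n = levels.shape[0]
    d2 = (
        np.sum(levels**2, axis=1)[:, None]
        + np.sum(levels**2, axis=1)[None, :]
        - 2 * levels @ levels.T
    )
    iu = np.triu_indices(n, 1)
    pair = d2[iu]
    return float(pair.min()), float(pair.mean())


def generate_design(spec: DesignSpec) -> FormulationDataset:
    """Generate a balanced, space-filling design (inputs only).

    Deterministic given ``spec.seed``. Raises if the run count is not
    divisible by the level count.
    """
    if spec.minimum_pattern < 1:
        raise ValueError("minimum_pattern must be at least 1")
    n_runs = spec.n_runs
    for name, lo, hi, n_levels in spec.factors:
        if n_runs % n_levels:
            raise ValueError(f"{n_runs} runs not divisible by {n_levels} levels")
    rng = np.random.default_rng(spec.seed)
    # balanced start: each level index repeated n_runs/n_levels times, shuffled
    idx = []
    for name, lo, hi, n_levels in spec.factors:
        col = np.repeat(np.arange(n_levels), n_runs // n_levels)
        rng.shuffle(col)
        idx.append(col)
    idx = np.stack(idx, axis=1).astype(float)
    norm = idx / np.maximum(idx.max(axis=0), 1.0)
    best = _min_distance(norm)
    # exchange: swap two runs' level in one factor (preserves balance exactly)
    for _ in range(spec.n_iterations):
        j = int(rng.integers(len(spec.factors)))
        a, b = rng.integers(n_runs, size=2)
        if idx[a, j] == idx[b, j]:
            continue
        idx[a, j], idx[b, j] = idx[b, j], idx[a, j]
        norm = idx / np.maximum(idx.max(axis=0), 1.0)
        cand = _min_distance(norm)
        if cand > best:
            best = cand
        else:
            idx[a, j], idx[b, j] = idx[b, j], idx[a, j]
    records = []
    width = len(str(n_runs))
    for i in range(n_runs):
        kwargs: dict[str, object] = {"label": f"R{i + 1:0{width}d}"}
        for j, (name, lo, hi, n_levels) in enumerate(spec.factors):
            levels = np.linspace(lo, hi, n_levels)
            kwargs[name] = float(levels[int(idx[i, j])])
        for name in INPUT_COLUMNS:
            kwargs.setdefault(name, 0.0)
        records.append(FormulationRecord(**kwargs))  # type: ignore[arg-type]
    domains = {f[0]: (f[1], f[2]) for f in spec.factors}
    for name in INPUT_COLUMNS:
        domains.setdefault(name, DESIGN_DOMAINS[name])
    return FormulationDataset(
        records=records,
        input_domains=domains,
        provenance=f"balanced design (seed={spec.seed})",
    )


_COMPARATORS = {
    "<=": np.less_equal,
    ">=": np.greater_equal,
    "<": np.less,
    ">": np.greater,
}


@dataclass(frozen=True)
class SelectionQuery:
    """Response constraints, grid resolution and a ranking objective.

    ``constraints`` is a sequence of ``(response, comparator, bound)``;
    ``ranking`` is ``(response, "maximize" | "minimize")`` or ``None`` for
    input-lexicographic order.
    """

    constraints: tuple[tuple[str, str, float], ...]
    grid_resolution: int | Mapping[str, int] = 5
    ranking: tuple[str, str] | None = None

    def resolution_for(self, name: str) -> int:
        if isinstance(self.grid_resolution, Mapping):
            return int(self.grid_resolution.get(name, 5))
        return int(self.grid_resolution)


def select_formulations(
    models: Mapping[str, NeurofuzzyResults],
    query: SelectionQuery,
    input_domains: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Exhaustive grid search for formulations meeting all constraints.

    Returns a DataFrame with one row per feasible grid point: the seven input
    settings, the predicted value of every modelled response, and the rank
    order. Empty when no grid point is feasible.
    """
    for response, comparator, bound in query.constraints:
        if response not in models:
            raise KeyError(f"no fitted model for constrained response {response!r}")
        if comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {comparator!r}")
    domains = dict(input_domains or DESIGN_DOMAINS)
    axes = []
    for name in INPUT_COLUMNS:
        lo, hi = domains[name]
        res = query.resolution_for(name)
        if res < 1:
            raise ValueError("grid resolution must be at least 1")
        axes.append(np.linspace(lo, hi, res) if res > 1 else np.array([(lo + hi) / 2]))
    mesh = np.meshgrid(*axes, indexing="ij")
    grid = pd.DataFrame({name: m.ravel() for name, m in zip(INPUT_COLUMNS, mesh)})
    if grid.empty:
        raise ValueError("empty candidate grid")
    preds = {name: res.predict(grid) for name, res in models.items()}
    mask = np.ones(len(grid), dtype=bool)
    for response, comparator, bound in query.constraints:
        mask &= _COMPARATORS[comparator](preds[response], bound)
    out = grid.loc[mask].reset_index(drop=True)
    for name, values in preds.items():
        out[f"pred_{name}"] = np.asarray(values)[mask]
    if query.ranking is not None:
        response, direction = query.ranking
        if response not in preds:
            raise KeyError(f"no fitted model for ranking response {response!r}")
        ascending = direction in ("minimize", "min")
        out = out.sort_values(
            [f"pred_{response}", *INPUT_COLUMNS], ascending=[ascending] + [True] * 7
        ).reset_index(drop=True)
    else:
        out = out.sort_values(list(INPUT_COLUMNS)).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
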
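"""Greedy ASMOD-style structure search driven by Structural Risk Minimization.

Starting from the empty model (which predicts zero everywhere), the search
repeatedly enumerates candidate refinements of the incumbent structure, fits
each by ridge least squares, and accepts the candidate with the lowest SRM
score -- provided it beats the incumbent's score by at least the relative
margin ``config.min_improvement``. The margin implements the pruning
philosophy that a more complex structure must *earn* its place; with the
default margin the search keeps the false-discovery rate of spurious terms
low at the small run counts these designs use (see docs/methods.md).

Candidate moves, in fixed enumeration order:

a. add a univariate submodel on an unused input, at each allowed density;
b. raise one submodel's density on one input to a higher allowed value;
c. extend one submodel with an unused input (tensor product), at each allowed
   density of the new input;
d. merge two submodels into one tensor submodel;
e. delete a submodel;
f. split a multi-input submodel into its univariate parts.

Ties are broken by fewer effective parameters, then enumeration order, so the
search is fully deterministic: identical data and configuration reproduce an
identical history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import FormulationDataset, INPUT_COLUMNS, response_vector
from .model import (
    ModelConfig,
    NeurofuzzyModel,
    NeurofuzzyResults,
    effective_params,
    srm_score,
)

__all__ = ["SearchStep", "SearchResult", "structure_search", "search_dataset"]

# structure = tuple of (inputs tuple, densities tuple); hashable + ordered
Structure = tuple[tuple[tuple[str, ...], tuple[int, ...]], ...]


@dataclass(frozen=True)
class SearchStep:
    """One evaluated candidate: structure, score and acceptance flag."""

    iteration: int
    move: str
    structure: Structure
    p_params: int
    mse: float
    score: float
    accepted: bool


@dataclass
class SearchResult:
    """Final fitted model plus the full evaluation history."""

    results: NeurofuzzyResults | None
    structure: Structure
    score: float
    history: list[SearchStep] = field(default_factory=list)

    @property
    def selected_inputs(self) -> set[str]:
        return {name for inputs, _ in self.structure for name in inputs}

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iteration": s.iteration,
                    "move": s.move,
                    "structure": _fmt(s.structure),
                    "p_params": s.p_params,
                    "mse": s.mse,
                    "score": s.score,
                    "accepted": s.accepted,
                }
                for s in self.history
            ]
        )


def _fmt(structure: Structure) -> str:
    if not structure:
        return "(empty)"
    return " + ".join(
        "x".join(f"{n}({d})" for n, d in zip(inputs, dens)) for inputs, dens in structure
    )


def _candidates(
    structure: Structure, inputs: Sequence[str], config: ModelConfig
) -> list[tuple[str, Structure]]:
    dens = config.allowed_densities
    used = {name for ins, _ in structure for name in ins}
    out: list[tuple[str, Structure]] = []

    def basis(ins_d):
        return int(np.prod(ins_d))

    # (a) add univariate submodel, at each allowed density
    for name in inputs:
        if name not in used:
            for d in dens:
                out.append(("add", structure + (((name,), (d,)),)))
    # (b) raise one density
    for i, (ins, ds) in enumerate(structure):
        for j in range(len(ins)):
            for d in dens:
                if d > ds[j]:
                    nd = ds[:j] + (d,) + ds[j + 1 :]
                    if basis(nd) <= config.max_basis:
                        cand = structure[:i] + ((ins, nd),) + structure[i + 1 :]
                        out.append(("raise", cand))
    # (c) extend a submodel with an unused input
    for i, (ins, ds) in enumerate(structure):
        if len(ins) >= config.max_inputs_per_submodel:
            continue
        for name in inputs:
            if name in used:
                continue
            for d in dens:
                nd = ds + (d,)
                if basis(nd) <= config.max_basis:
                    cand = structure[:i] + ((ins + (name,), nd),) + structure[i + 1 :]
                    out.append(("extend", cand))
    # (d) merge two submodels
    for i in range(len(structure)):
        for j in range(i + 1, len(structure)):
            ins = structure[i][0] + structure[j][0]
            ds = structure[i][1] + structure[j][1]
            if len(ins) <= config.max_inputs_per_submodel and basis(ds) <= config.max_basis:
                rest = tuple(s for k, s in enumerate(structure) if k not in (i, j))
                out.append(("merge", rest + ((ins, ds),)))
    # (e) delete a submodel
    for i in range(len(structure)):
        out.append(("delete", structure[:i] + structure[i + 1 :]))
    # (f) split a tensor submodel into univariate parts
    for i, (ins, ds) in enumerate(structure):
        if len(ins) > 1:
            rest = structure[:i] + structure[i + 1 :]
            out.append(
                ("split", rest + tuple(((n,), (d,)) for n, d in zip(ins, ds)))
            )
    return out


def _score_structure(
    structure: Structure,
    y: np.ndarray,
    exog: pd.DataFrame,
    domains,
    config: ModelConfig,
) -> tuple[float, int, float, NeurofuzzyResults | None]:
    n = y.size
    if not structure:
        mse = float(np.mean(y**2))  # empty model predicts zero
        s = srm_score(mse, 0, n)
        return s.score, 0, mse, None
    model = NeurofuzzyModel(
        endog=y,
        exog=exog,
        submodels=list(structure),
        config=config,
        input_domains=domains,
    )
    res = model.fit()
    p = model.p_params
    s = srm_score(res.mse, p, n)
    return s.score, p, res.mse, res


def structure_search(
    y: np.ndarray,
    exog: pd.DataFrame,
    config: ModelConfig | None = None,
    input_domains=None,
    inputs: Sequence[str] | None = None,
    response_name: str = "y",
) -> SearchResult:
    """Run the greedy SRM search over additive fuzzy-spline structures."""
    config = config or ModelConfig()
    y = np.asarray(y, dtype=float)
    if y.size < 6:
        raise ValueError("need at least 6 usable rows for a structure search")
    if np.allclose(y, y[0]):
        raise ValueError("constant response: nothing to model")
    names = list(inputs) if inputs is not None else list(exog.columns)
    domains = input_domains

    structure: Structure = ()
    best_score, best_p, best_mse, best_res = _score_structure(
        structure, y, exog, domains, config
    )
    history: list[SearchStep] = []
    iteration = 0
    # below this the fit is numerically perfect; further "improvements" would
    # only chase ridge-induced rounding noise
    mse_floor = 1e-10 * float(np.mean(y**2))
    while best_mse > mse_floor:
        iteration += 1
        scored = []
        for order, (move, cand) in enumerate(_candidates(structure, names, config)):
            score, p, mse, res = _score_structure(cand, y, exog, domains, config)
            scored.append((score, p, order, move, cand, mse, res))
            history.append(
                SearchStep(iteration, move, cand, p, mse, score, accepted=False)
            )
        if not scored:
            break
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        top = scored[0]
        if not top[0] < best_score * (1.0 - config.min_improvement):
            break
        best_score, best_p, best_mse, best_res = top[0], top[1], top[5], top[6]
        structure = top[4]
        history.append(
            SearchStep(iteration, top[3], structure, top[1], top[5], top[0], accepted=True)
        )
    if best_res is not None:
        best_res.model.response_name = response_name
    return SearchResult(
        results=best_res, structure=structure, score=best_score, history=history
    )


def search_dataset(
    dataset: FormulationDataset,
    response: str,
    missing_policy: str = "drop",
    config: ModelConfig | None = None,
) -> SearchResult:
    """Structure search on one response of a formulation dataset."""
    y, labels = response_vector(dataset, response, missing_policy)
    frame = dataset.to_frame().set_index("label")
    exog = frame.loc[labels, list(INPUT_COLUMNS)].reset_index(drop=True)
    return structure_search(
        y,
        exog,
        config=config,
        input_domains=dataset.input_domains,
        inputs=list(INPUT_COLUMNS),
        response_name=response,
    )
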
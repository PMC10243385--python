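"""Linguistic IF-THEN rules, decision trees and partial-effect grids.

A fitted additive fuzzy-spline model is explained submodel by submodel. For
each submodel the model is evaluated at every combination of fuzzy-set peaks
(the submodel's *corners*), with every other submodel contributing its mean
over the training rows so that additive offsets do not distort the picture.
Min-max normalising the corner predictions gives each corner a membership
degree in [0, 1]; corners at degree >= 0.5 read as "response is HIGH", the
rest as "response is LOW". One rule per corner.

The same corner geometry yields a decision tree per submodel: each input is
split at the membership-0.5 boundaries (midpoints between adjacent peaks) and
each leaf carries the band of response values the model can produce inside
that cell. Splitting at the 0.5 crossings turns the fuzzy model into the
crisp threshold statements practitioners quote ("speed below 2,000 rpm...").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fuzzy import Submodel
from .model import NeurofuzzyResults

__all__ = [
    "LinguisticRule",
    "DecisionTree",
    "SubmodelTree",
    "TreeLeaf",
    "extract_rules",
    "to_decision_tree",
    "rules_from_tree",
    "rules_table",
    "PartialEffectGrid",
    "partial_effect_grid",
]


@dataclass(frozen=True)
class LinguisticRule:
    """One IF-THEN rule: a fuzzy-corner antecedent and a graded consequent."""

    rule_id: int
    submodel_id: int
    antecedents: tuple[tuple[str, str], ...]  # (input, fuzzy-set label)
    consequent_label: str  # HIGH / LOW on the response
    membership_degree: float
    corner_value: float
    degenerate: bool = False

    def text(self, response: str = "response") -> str:
        cond = " AND ".join(f"{name} is {label}" for name, label in self.antecedents)
        return (
            f"IF {cond} THEN {response} is {self.consequent_label} "
            f"({self.membership_degree:.2f})"
        )


def _corner_values(res: NeurofuzzyResults, index: int) -> np.ndarray:
    """Model output at each corner of submodel ``index``.

    The submodel's own contribution is exact at the corner (one-hot basis);
    every other submodel adds its training-row mean contribution.
    """
    s = res.model.submodels[index]
    w = res.submodel_params()[index]
    offset = sum(
        res.mean_contribution(k) for k in range(len(res.model.submodels)) if k != index
    )
    return w + offset  # basis at a peak corner is one-hot, in basis order


def extract_rules(res: NeurofuzzyResults) -> list[LinguisticRule]:
    """One rule per fuzzy-grid corner of each submodel, in stable order.

    Rules are numbered consecutively across submodels in submodel order, then
    row-major corner order.
    """
    if not res.model.submodels:
        raise ValueError("fitted model has no submodels")
    rules: list[LinguisticRule] = []
    rule_id = 1
    for k, s in enumerate(res.model.submodels):
        values = _corner_values(res, k)
        lo, hi = float(values.min()), float(values.max())
        degenerate = np.isclose(hi, lo)
        for labels, value in zip(s.label_grid(), values):
            if degenerate:
                degree = 0.5
            else:
                degree = float((value - lo) / (hi - lo))
            rules.append(
                LinguisticRule(
                    rule_id=rule_id,
                    submodel_id=k,
                    antecedents=tuple(zip(s.inputs, labels)),
                    consequent_label="HIGH" if degree >= 0.5 else "LOW",
                    membership_degree=degree,
                    corner_value=float(value),
                    degenerate=bool(degenerate),
                )
            )
            rule_id += 1
    return rules


def rules_table(rules: Sequence[LinguisticRule], response: str = "response") -> str:
    """Plain-text rule table (rule id, IF clauses, THEN label, degree)."""
    header = f"{'rule':>4}  {'IF':60}  THEN {response:12} degree"
    lines = [header, "-" * len(header)]
    for r in rules:
        cond = " AND ".join(f"{n} is {l}" for n, l in r.antecedents)
        lines.append(
            f"{r.rule_id:>4}  {cond:60}  {r.consequent_label:17} {r.membership_degree:.2f}"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# decision trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeLeaf:
    """A terminal cell: per-input intervals, response band, attached rule."""

    cells: tuple[tuple[str, float, float], ...]  # (input, cell lo, cell hi)
    band: tuple[float, float]  # min/max model response over the cell
    rule_id: int
    corner_value: float
    consequent_label: str
    membership_degree: float


@dataclass(frozen=True)
class SubmodelTree:
    """Decision tree of one submodel: nested splits, one leaf per corner."""

    submodel_id: int
    inputs: tuple[str, ...]
    thresholds: tuple[tuple[float, ...], ...]  # split points per input
    leaves: tuple[TreeLeaf, ...]  # row-major corner order

    def route(self, values: Mapping[str, float]) -> TreeLeaf:
        """Follow the splits to the leaf containing the given input values."""
        idx = 0
        for name, cuts in zip(self.inputs, self.thresholds):
            x = float(values[name])
            cell = int(np.searchsorted(np.asarray(cuts), x, side="right"))
            idx = idx * (len(cuts) + 1) + cell
        return self.leaves[idx]


@dataclass(frozen=True)
class DecisionTree:
    """Whole-model tree: one cascade per submodel, bands add across them."""

    subtrees: tuple[SubmodelTree, ...]
    offsets: tuple[float, ...]  # mean contribution of each submodel
    response: str = "response"

    def predict_band(self, values: Mapping[str, float]) -> tuple[float, float]:
        """Band of model outputs consistent with the routed cells.

        Each subtree band includes the *other* submodels at their mean;
        summing bands would over-count those means, so they are subtracted
        back out.
        """
        total = sum(self.offsets)
        lo = hi = 0.0
        for t in self.subtrees:
            leaf = t.route(values)
            other = total - self.offsets[t.submodel_id]
            lo += leaf.band[0] - other
            hi += leaf.band[1] - other
        return (lo, hi)

    def to_dot(self) -> str:
        """GraphViz DOT rendering of all subtree cascades."""
        lines = ["digraph decision_tree {", '  node [shape=box, fontsize=10];']
        nid = 0

        def emit(tree: SubmodelTree) -> None:
            nonlocal nid
            # breadth-wise emission of the nested splits
            frontier = [(f"t{tree.submodel_id}_root", 0, ())]
            lines.append(
                f'  t{tree.submodel_id}_root [label="submodel {tree.submodel_id}: '
                f'{" x ".join(tree.inputs)}"];'
            )
            for name, cuts in zip(tree.inputs, tree.thresholds):
                new_frontier = []
                bounds = [-np.inf, *cuts, np.inf]
                for parent, depth, path in frontier:
                    for c in range(len(cuts) + 1):
                        nid += 1
                        node = f"n{nid}"
                        lo, hi = bounds[c], bounds[c + 1]
                        if np.isinf(lo):
                            lab = f"{name} < {hi:g}"
                        elif np.isinf(hi):
                            lab = f"{name} > {lo:g}"
                        else:
                            lab = f"{lo:g} < {name} < {hi:g}"
                        lines.append(f'  {node} [label="{lab}"];')
                        lines.append(f"  {parent} -> {node};")
                        new_frontier.append((node, depth + 1, path + (c,)))
                frontier = new_frontier
            for parent, _, path in frontier:
                idx = 0
                for cuts, c in zip(tree.thresholds, path):
                    idx = idx * (len(cuts) + 1) + c
                leaf = tree.leaves[idx]
                nid += 1
                lines.append(
                    f'  n{nid} [shape=ellipse, label="{self.response} '
                    f'{leaf.consequent_label}\\nband [{leaf.band[0]:.3g}, {leaf.band[1]:.3g}]\\n'
                    f'degree {leaf.membership_degree:.2f}"];'
                )
                lines.append(f"  {parent} -> n{nid};")

        for t in self.subtrees:
            emit(t)
        lines.append("}")
        return "\n".join(lines)


def _contribution_range(
    s: Submodel, w: np.ndarray, box: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Exact min/max of a submodel's contribution over an axis-aligned box.

    Within a box the contribution is piecewise multilinear with kinks only at
    interior peaks, so extremes occur at box vertices or at peak coordinates;
    evaluating the tensor basis on that finite candidate grid is exact.
    """
    axes = []
    for p, (lo, hi) in zip(s.partitions, box):
        cands = {lo, hi}
        for peak in p.peaks:
            if lo < peak < hi:
                cands.add(float(peak))
        axes.append(sorted(cands))
    best_lo, best_hi = np.inf, -np.inf
    for point in itertools.product(*axes):
        v = float(s.tensor_basis(dict(zip(s.inputs, point))) @ w)
        best_lo = min(best_lo, v)
        best_hi = max(best_hi, v)
    return best_lo, best_hi


def to_decision_tree(res: NeurofuzzyResults) -> DecisionTree:
    """Transform a fitted model into crisp decision trees, one per submodel.

    Each leaf corresponds to one fuzzy corner (one rule); its band is the
    range of full-model outputs over the leaf's cell, holding the other
    submodels at their training-mean contribution.
    """
    rules = extract_rules(res)
    offsets = tuple(res.mean_contribution(k) for k in range(len(res.model.submodels)))
    subtrees = []
    for k, s in enumerate(res.model.submodels):
        w = res.submodel_params()[k]
        other = sum(o for i, o in enumerate(offsets) if i != k)
        thresholds = tuple(tuple(p.boundaries()) for p in s.partitions)
        cell_edges = []
        for p, cuts in zip(s.partitions, thresholds):
            lo, hi = p.domain
            edges = [lo, *cuts, hi]
            cell_edges.append([(edges[i], edges[i + 1]) for i in range(len(edges) - 1)])
        sub_rules = [r for r in rules if r.submodel_id == k]
        leaves = []
        for r, cells in zip(sub_rules, itertools.product(*cell_edges)):
            lo_c, hi_c = _contribution_range(s, w, cells)
            leaves.append(
                TreeLeaf(
                    cells=tuple(
                        (name, c[0], c[1]) for name, c in zip(s.inputs, cells)
                    ),
                    band=(lo_c + other, hi_c + other),
                    rule_id=r.rule_id,
                    corner_value=r.corner_value,
                    consequent_label=r.consequent_label,
                    membership_degree=r.membership_degree,
                )
            )
        subtrees.append(
            SubmodelTree(
                submodel_id=k,
                inputs=s.inputs,
                thresholds=thresholds,
                leaves=tuple(leaves),
            )
        )
    return DecisionTree(
        subtrees=tuple(subtrees), offsets=offsets, response=res.model.response_name
    )


def rules_from_tree(tree: DecisionTree) -> list[LinguisticRule]:
    """Rebuild the rules carried by a tree's leaves (labels and degrees).

    Antecedent fuzzy-set labels are not stored in the leaves, so the
    reconstruction carries the cell intervals' positional labels instead; the
    consequent label, degree and corner value round-trip exactly.
    """
    from .fuzzy import set_labels

    rules = []
    for t in tree.subtrees:
        densities = tuple(len(cuts) + 1 for cuts in t.thresholds)
        labels_per_input = [set_labels(d) for d in densities]
        for idx, leaf in enumerate(t.leaves):
            pos = []
            rem = idx
            for d in reversed(densities):
                pos.append(rem % d)
                rem //= d
            pos = list(reversed(pos))
            rules.append(
                LinguisticRule(
                    rule_id=leaf.rule_id,
                    submodel_id=t.submodel_id,
                    antecedents=tuple(
                        (name, labels_per_input[i][pos[i]])
                        for i, (name, _, _) in enumerate(leaf.cells)
                    ),
                    consequent_label=leaf.consequent_label,
                    membership_degree=leaf.membership_degree,
                    corner_value=leaf.corner_value,
                )
            )
    return sorted(rules, key=lambda r: r.rule_id)


# ---------------------------------------------------------------------------
# partial-effect grids
# ---------------------------------------------------------------------------


@dataclass
class PartialEffectGrid:
    """Predicted response over a 1-D or 2-D grid of inputs."""

    inputs: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    values: np.ndarray  # shape = tuple(len(a) for a in axes)

    def to_frame(self) -> pd.DataFrame:
        mesh = np.meshgrid(*self.axes, indexing="ij")
        data = {name: m.ravel() for name, m in zip(self.inputs, mesh)}
        data["predicted"] = self.values.ravel()
        return pd.DataFrame(data)


def partial_effect_grid(
    res: NeurofuzzyResults, inputs: Sequence[str] | str, resolution: int = 25
) -> PartialEffectGrid:
    """Model response over a grid of one or two inputs.

    Grid inputs sweep their domain (``resolution`` equally spaced points; a
    resolution of 1 evaluates the domain midpoint only). Submodels that do not
    involve any grid input contribute their mean over the training rows; in a
    submodel that mixes grid and non-grid inputs, the non-grid inputs are held
    at their training-row mean value.
    """
    if isinstance(inputs, str):
        inputs = (inputs,)
    inputs = tuple(inputs)
    if not 1 <= len(inputs) <= 2:
        raise ValueError("grids are one- or two-dimensional")
    model = res.model
    used = {name for s in model.submodels for name in s.inputs}
    for name in inputs:
        if name not in used:
            raise KeyError(f"input {name!r} does not appear in the model")
    axes = []
    for name in inputs:
        lo, hi = model.input_domains[name]
        if resolution == 1:
            axes.append(np.array([(lo + hi) / 2.0]))
        else:
            axes.append(np.linspace(lo, hi, resolution))
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = {name: m.ravel() for name, m in zip(inputs, mesh)}
    npts = flat[inputs[0]].size
    total = np.zeros(npts)
    for k, s in enumerate(model.submodels):
        if not set(s.inputs) & set(inputs):
            total += res.mean_contribution(k)
            continue
        vals = {}
        for name in s.inputs:
            if name in flat:
                vals[name] = flat[name]
            else:
                vals[name] = np.full(npts, float(model.exog[name].mean()))
        total += res.submodel_contribution(k, vals)
    return PartialEffectGrid(
        inputs=inputs, axes=tuple(axes), values=total.reshape(mesh[0].shape)
    )
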
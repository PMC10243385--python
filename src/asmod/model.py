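"""Additive tensor-spline neurofuzzy models fitted by ridge least squares.

The model for a response :math:`y` is an additive collection of submodels

.. math:: \\hat y(x) = \\sum_k \\sum_j w_{kj}\\, B_{kj}(x),

where the :math:`B_{kj}` are the tensor-product triangular-spline basis
functions of submodel :math:`k` (see :mod:`asmod.fuzzy`). No intercept is
added: each submodel's basis sums to one at every point, so constants live
inside the blocks. That same overlap means a model with :math:`k` submodels
and :math:`p` raw basis functions has only :math:`p - (k-1)` identifiable
parameters; ridge regularisation resolves the redundancy numerically, and all
reported degrees of freedom use the effective count.

Fit quality is reported as the training-set determination coefficient in
percent, an ANOVA F ratio comparing model to residual mean squares
(``df1`` = effective parameters, ``df2 = n - 1 - df1``), and a Structural
Risk Minimization (SRM) score used by the structure search
(:mod:`asmod.search`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .data import (
    DESIGN_DOMAINS,
    FormulationDataset,
    FormulationRecord,
    INPUT_COLUMNS,
    response_vector,
)
from .fuzzy import MembershipPartition, Submodel, make_partition

__all__ = [
    "ModelConfig",
    "AnovaReport",
    "SrmScore",
    "NeurofuzzyModel",
    "NeurofuzzyResults",
    "design_matrix",
    "fit_ridge",
    "r_squared",
    "anova_f",
    "srm_score",
    "effective_params",
    "build_structure",
    "quality_table",
]


@dataclass(frozen=True)
class ModelConfig:
    """Training parameters.

    ``ridge_factor`` is the ridge regularisation weight; ``allowed_densities``
    the fuzzy-set counts the structure search may use per input;
    ``min_improvement`` the relative SRM-score improvement a refinement must
    achieve to be accepted (the search's pruning strength).
    """

    ridge_factor: float = 1.0e-6
    allowed_densities: tuple[int, ...] = (2, 3)
    max_inputs_per_submodel: int = 4
    max_nodes_per_input: int = 15
    max_basis: int = 100
    selection_criterion: str = "srm"
    min_improvement: float = 0.25
    clamp_out_of_domain: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge_factor <= 0:
            raise ValueError("ridge_factor must be positive")
        dens = tuple(sorted(set(int(d) for d in self.allowed_densities)))
        if any(d < 2 or d > self.max_nodes_per_input for d in dens):
            raise ValueError(
                f"allowed densities {dens} must lie in [2, {self.max_nodes_per_input}]"
            )
        object.__setattr__(self, "allowed_densities", dens)
        if self.selection_criterion != "srm":
            raise ValueError("only the 'srm' selection criterion is implemented")
        if not 0.0 <= self.min_improvement < 1.0:
            raise ValueError("min_improvement must lie in [0, 1)")


@dataclass(frozen=True)
class AnovaReport:
    """ANOVA comparing model and residual mean squares."""

    f_ratio: float
    df1: int
    df2: int
    p_value: float
    alpha_band: str  # one of "<0.01", "<0.05", "<0.1", "n.s."


@dataclass(frozen=True)
class SrmScore:
    """Structural-risk score: training MSE times a complexity penalty."""

    mse: float
    penalty: float
    score: float


def build_structure(
    structure: Sequence,
    input_domains: Mapping[str, tuple[float, float]] | None = None,
) -> list[Submodel]:
    """Normalise a structure specification to a list of submodels.

    Accepts ready-made :class:`Submodel` objects or ``(inputs, densities)``
    pairs, e.g. ``[(("plga_pct", "speed_rpm"), (3, 3))]``, whose partitions
    are built with equally spaced peaks over ``input_domains``.
    """
    domains = dict(input_domains or DESIGN_DOMAINS)
    submodels: list[Submodel] = []
    for item in structure:
        if isinstance(item, Submodel):
            submodels.append(item)
            continue
        inputs, densities = item
        if isinstance(inputs, str):
            inputs, densities = (inputs,), (densities,)
        parts = tuple(
            make_partition(name, domains[name], int(d))
            for name, d in zip(inputs, densities)
        )
        submodels.append(Submodel(partitions=parts))
    return submodels


def design_matrix(
    submodels: Sequence[Submodel],
    data: pd.DataFrame | Mapping[str, object],
    clamp: bool = True,
) -> np.ndarray:
    """Horizontal concatenation of each submodel's tensor basis.

    Column order is submodel order, then row-major basis order within each
    submodel. Each block's rows sum to one (partition of unity).
    """
    if not submodels:
        raise ValueError("empty submodel list")
    if isinstance(data, pd.DataFrame):
        values: Mapping[str, object] = {c: data[c].to_numpy(dtype=float) for c in data.columns}
        n = len(data)
    else:
        values = data
        n = None
    blocks = []
    for s in submodels:
        vals = {name: values[name] for name in s.inputs}
        if not clamp:
            vals = {
                name: _reject_out_of_domain(p, vals[name])
                for name, p in zip(s.inputs, s.partitions)
            }
        blocks.append(np.atleast_2d(s.tensor_basis(vals)))
    X = np.hstack(blocks)
    if n is not None and X.shape[0] != n:
        raise ValueError("row mismatch between submodel blocks")
    return X


def _reject_out_of_domain(partition: MembershipPartition, v):
    lo, hi = partition.domain
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if np.any((arr < lo - 1e-12) | (arr > hi + 1e-12)):
        raise ValueError(
            f"{partition.input_name} outside domain ({lo}, {hi}) and clamping is off"
        )
    return v


def fit_ridge(X: np.ndarray, y: np.ndarray, ridge_factor: float) -> np.ndarray:
    """Coefficients minimising ``||y - Xw||^2 + ridge_factor * ||w||^2``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"dimension mismatch: X {X.shape}, y {y.shape}")
    p = X.shape[1]
    A = X.T @ X + ridge_factor * np.eye(p)
    return scipy.linalg.solve(A, X.T @ y, assume_a="pos")


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Training determination coefficient, in percent.

    ``100 * (1 - SSres / SStot)`` with the total sum of squares taken about
    the mean of ``y``.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant response: determination coefficient undefined")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def _alpha_band(p_value: float) -> str:
    if p_value < 0.01:
        return "<0.01"
    if p_value < 0.05:
        return "<0.05"
    if p_value < 0.1:
        return "<0.1"
    return "n.s."


def anova_f(y: np.ndarray, y_hat: np.ndarray, p_params: int) -> AnovaReport:
    """F ratio of model to residual mean squares.

    ``df1`` is the effective parameter count and ``df2 = n - 1 - df1``, so the
    two always sum to ``n - 1``.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = y.size
    df1 = int(p_params)
    df2 = n - 1 - df1
    if df2 <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={df1})")
    ss_model = float(np.sum((y_hat - y.mean()) ** 2))
    ss_res = float(np.sum((y - y_hat) ** 2))
    if ss_res == 0.0:
        return AnovaReport(math.inf, df1, df2, 0.0, "<0.01")
    f = (ss_model / df1) / (ss_res / df2)
    p_value = float(stats.f.sf(f, df1, df2))
    return AnovaReport(f, df1, df2, p_value, _alpha_band(p_value))


def srm_score(mse: float, p_params: int, n_obs: int) -> SrmScore:
    """Structural Risk Minimization score.

    The penalty is the small-sample bound
    ``1 / (1 - sqrt(rho - rho ln rho + ln(n) / (2n)))`` with
    ``rho = p / n``; when the radicand reaches one the bound collapses and the
    score is infinite. The penalty is 1-or-greater, strictly increasing in the
    parameter count at fixed ``n``, and infinite whenever ``p >= n``.
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    mse = float(mse)
    rho = p_params / n_obs
    arg = (rho - rho * math.log(rho) if rho > 0 else 0.0) + math.log(n_obs) / (2 * n_obs)
    if rho >= 1.0 or arg >= 1.0:
        return SrmScore(mse=mse, penalty=math.inf, score=math.inf)
    penalty = 1.0 / (1.0 - math.sqrt(arg))
    return SrmScore(mse=mse, penalty=penalty, score=mse * penalty)


def effective_params(submodels: Sequence[Submodel]) -> int:
    """Identifiable parameter count: raw basis total minus shared constants.

    Every submodel's basis contains the constant function (partition of
    unity), so ``k`` submodels share ``k - 1`` redundant constants.
    """
    total = sum(s.basis_size for s in submodels)
    return total - (len(submodels) - 1)


class NeurofuzzyModel:
    """An additive fuzzy-spline model of one response, ready to fit.

    Parameters
    ----------
    endog : array-like
        Response values, one per row of ``exog``.
    exog : DataFrame
        Input values in raw units; must contain every input named by the
        submodels.
    submodels : sequence of Submodel or (inputs, densities) pairs
        The model structure.
    config : ModelConfig, optional
    response_name : str, optional
    """

    def __init__(
        self,
        endog,
        exog: pd.DataFrame,
        submodels: Sequence,
        config: ModelConfig | None = None,
        response_name: str = "y",
        row_labels: Sequence[str] | None = None,
        input_domains: Mapping[str, tuple[float, float]] | None = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog.reset_index(drop=True)
        if len(self.endog) != len(self.exog):
            raise ValueError("endog and exog lengths differ")
        domains = input_domains
        if domains is None:
            domains = {
                c: DESIGN_DOMAINS.get(
                    c, (float(self.exog[c].min()), float(self.exog[c].max()))
                )
                for c in self.exog.columns
            }
        self.input_domains = dict(domains)
        self.submodels = build_structure(submodels, self.input_domains)
        self.config = config or ModelConfig()
        self.response_name = response_name
        self.row_labels = list(row_labels) if row_labels is not None else None
        for s in self.submodels:
            if len(s.inputs) > self.config.max_inputs_per_submodel:
                raise ValueError(
                    f"submodel {s.inputs} exceeds max_inputs_per_submodel"
                )
            if s.basis_size > self.config.max_basis:
                raise ValueError(f"submodel {s.inputs} exceeds basis cap")

    @classmethod
    def from_dataset(
        cls,
        dataset: FormulationDataset,
        response: str,
        structure: Sequence,
        missing_policy: str = "drop",
        config: ModelConfig | None = None,
    ) -> "NeurofuzzyModel":
        """Build a model from a :class:`FormulationDataset` response column."""
        y, labels = response_vector(dataset, response, missing_policy)
        frame = dataset.to_frame().set_index("label")
        exog = frame.loc[labels, list(INPUT_COLUMNS)].reset_index(drop=True)
        return cls(
            endog=y,
            exog=exog,
            submodels=structure,
            config=config,
            response_name=response,
            row_labels=labels,
            input_domains=dataset.input_domains,
        )

    @property
    def nobs(self) -> int:
        return int(self.endog.size)

    @property
    def p_params(self) -> int:
        return effective_params(self.submodels)

    def design_matrix(self) -> np.ndarray:
        return design_matrix(
            self.submodels, self.exog, clamp=self.config.clamp_out_of_domain
        )

    def fit(self) -> "NeurofuzzyResults":
        X = self.design_matrix()
        params = fit_ridge(X, self.endog, self.config.ridge_factor)
        return NeurofuzzyResults(model=self, params=params)


class NeurofuzzyResults:
    """A fitted neurofuzzy model: coefficients, fit statistics, prediction."""

    def __init__(self, model: NeurofuzzyModel, params: np.ndarray) -> None:
        self.model = model
        self.params = np.asarray(params, dtype=float)
        expected = sum(s.basis_size for s in model.submodels)
        if self.params.size != expected:
            raise ValueError(
                f"coefficient count {self.params.size} != basis total {expected}"
            )
        self.fittedvalues = model.design_matrix() @ self.params
        self.resid = model.endog - self.fittedvalues

    # -- quality statistics -------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def p_params(self) -> int:
        return self.model.p_params

    @property
    def rsquared(self) -> float:
        """Training determination coefficient, percent."""
        return r_squared(self.model.endog, self.fittedvalues)

    @property
    def mse(self) -> float:
        return float(np.mean(self.resid**2))

    @property
    def anova(self) -> AnovaReport:
        return anova_f(self.model.endog, self.fittedvalues, self.p_params)

    @property
    def fvalue(self) -> float:
        return self.anova.f_ratio

    @property
    def f_pvalue(self) -> float:
        return self.anova.p_value

    @property
    def alpha_band(self) -> str:
        return self.anova.alpha_band

    @property
    def df_model(self) -> int:
        return self.p_params

    @property
    def df_resid(self) -> int:
        return self.nobs - 1 - self.p_params

    @property
    def srm(self) -> SrmScore:
        return srm_score(self.mse, self.p_params, self.nobs)

    # -- prediction ---------------------------------------------------------

    def _coerce_values(self, record) -> tuple[Mapping[str, object], bool]:
        if isinstance(record, FormulationRecord):
            return record.inputs(), True
        if isinstance(record, FormulationDataset):
            return {c: record.to_frame()[c].to_numpy(float) for c in INPUT_COLUMNS}, False
        if isinstance(record, pd.DataFrame):
            return {c: record[c].to_numpy(float) for c in record.columns}, False
        if isinstance(record, Mapping):
            scalar = all(np.isscalar(v) for v in record.values())
            return record, scalar
        raise TypeError(f"cannot predict from {type(record)!r}")

    def predict(self, record):
        """Model prediction for a record, mapping, DataFrame or dataset."""
        values, scalar = self._coerce_values(record)
        needed = {name for s in self.model.submodels for name in s.inputs}
        missing = needed - set(values)
        if missing:
            raise KeyError(f"missing input value(s): {sorted(missing)}")
        out = None
        offset = 0
        for s in self.model.submodels:
            vals = {name: values[name] for name in s.inputs}
            if not self.model.config.clamp_out_of_domain:
                for name, p in zip(s.inputs, s.partitions):
                    _reject_out_of_domain(p, vals[name])
            B = s.tensor_basis(vals)
            w = self.params[offset : offset + s.basis_size]
            contrib = np.atleast_2d(B) @ w
            out = contrib if out is None else out + contrib
            offset += s.basis_size
        assert out is not None
        return float(out[0]) if scalar else out

    def submodel_params(self) -> list[np.ndarray]:
        """Coefficient blocks, one per submodel, in basis order."""
        blocks = []
        offset = 0
        for s in self.model.submodels:
            blocks.append(self.params[offset : offset + s.basis_size].copy())
            offset += s.basis_size
        return blocks

    def submodel_contribution(self, index: int, values: Mapping[str, object]):
        """One submodel's additive contribution at the given input values."""
        s = self.model.submodels[index]
        w = self.submodel_params()[index]
        B = np.atleast_2d(s.tensor_basis({name: values[name] for name in s.inputs}))
        out = B @ w
        return float(out[0]) if all(np.isscalar(values[n]) for n in s.inputs) else out

    def mean_contribution(self, index: int) -> float:
        """A submodel's mean contribution over the training rows."""
        s = self.model.submodels[index]
        vals = {name: self.model.exog[name].to_numpy(float) for name in s.inputs}
        return float(np.mean(self.submodel_contribution(index, vals)))

    # -- reporting ----------------------------------------------------------

    def structure_description(self) -> str:
        parts = []
        for s in self.model.submodels:
            parts.append(
                " x ".join(f"{n}({d})" for n, d in zip(s.inputs, s.densities))
            )
        return " + ".join(parts)

    def summary(self) -> str:
        a = self.anova
        lines = [
            "Neurofuzzy model results",
            "=" * 60,
            f"response:        {self.model.response_name}",
            f"observations:    {self.nobs}",
            f"structure:       {self.structure_description()}",
            f"effective params {self.p_params}",
            f"train R^2 (%):   {self.rsquared:.2f}",
            f"ANOVA f:         {a.f_ratio:.2f}  d.f. ({a.df1}, {a.df2})  alpha {a.alpha_band}",
            f"SRM score:       {self.srm.score:.6g}",
            "=" * 60,
        ]
        for s, w in zip(self.model.submodels, self.submodel_params()):
            lines.append(f"submodel {' x '.join(s.inputs)}: densities {s.densities}")
            for labels, coef in zip(s.label_grid(), w):
                lines.append(f"    {' & '.join(labels):30s} {coef: .4g}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "response_name": self.model.response_name,
            "submodels": [s.to_dict() for s in self.model.submodels],
            "coefficients": [float(v) for v in self.params],
            "n_obs": self.nobs,
            "p_params": self.p_params,
            "train_r2": self.rsquared,
            "srm": self.srm.score,
            "anova": {
                "f_ratio": self.fvalue,
                "df1": self.anova.df1,
                "df2": self.anova.df2,
                "p_value": self.f_pvalue,
                "alpha_band": self.alpha_band,
            },
            "input_domains": {k: list(v) for k, v in self.model.input_domains.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def quality_table(results: Sequence[NeurofuzzyResults]) -> pd.DataFrame:
    """Model-quality table: one row per fitted response."""
    rows = []
    for res in results:
        a = res.anova
        rows.append(
            {
                "response": res.model.response_name,
                "submodels": res.structure_description(),
                "r2_pct": round(res.rsquared, 2),
                "f_ratio": round(a.f_ratio, 2),
                "df1": a.df1,
                "df2": a.df2,
                "alpha": a.alpha_band,
            }
        )
    return pd.DataFrame(rows)
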
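"""Formulation datasets and particle-characterisation formulas.

This module holds the tabular data model for emulsion-solvent-evaporation
formulation studies (seven process/composition inputs, up to four measured
critical quality attributes per run) together with the standard
laser-diffraction summary statistics:

* ``median_volume_diameter`` -- D(v, 0.5), the median of the volume-weighted
  particle-size distribution,
* ``uniformity`` -- the volume-weighted mean absolute deviation of size
  classes from the median, normalised by the median,
* ``encapsulation_efficiency`` and ``drug_loading`` -- the two gravimetric
  drug-content ratios, in percent.

Missing response values (runs where a quantity was not assayed, e.g. drug
content of drug-free batches) are represented as *missing*, never as zero;
the only place a zero may be substituted is :func:`response_vector` under the
explicit ``zero_fill`` policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INPUT_COLUMNS",
    "RESPONSE_COLUMNS",
    "DESIGN_DOMAINS",
    "MISSING_MARKERS",
    "FormulationRecord",
    "FormulationDataset",
    "SizeDistribution",
    "SchemaError",
    "ParseError",
    "load_dataset",
    "save_dataset",
    "load_design24",
    "load_validation",
    "response_vector",
    "median_volume_diameter",
    "uniformity",
    "encapsulation_efficiency",
    "drug_loading",
]

#: Canonical input column names, in design order.
INPUT_COLUMNS = (
    "drug_pct",
    "plga_pct",
    "pva_pct",
    "ow_ratio",
    "speed_rpm",
    "time_s",
    "dilution_ratio",
)

#: Canonical response column names.
RESPONSE_COLUMNS = ("size_um", "uniformity", "ee_pct", "dl_pct")

#: Default design-space bounds per input, in raw units.
DESIGN_DOMAINS = {
    "drug_pct": (0.0, 2.0),
    "plga_pct": (10.0, 20.0),
    "pva_pct": (0.5, 2.0),
    "ow_ratio": (0.1, 0.4),
    "speed_rpm": (1000.0, 3000.0),
    "time_s": (60.0, 120.0),
    "dilution_ratio": (2.0, 10.0),
}

#: Cell contents interpreted as a missing response.
MISSING_MARKERS = ("", "–", "-", "NA", "nan")


class SchemaError(ValueError):
    """Raised when a table cannot be mapped onto the formulation schema."""


class ParseError(ValueError):
    """Raised when a cell is neither numeric nor a recognised missing marker."""


@dataclass(frozen=True)
class FormulationRecord:
    """A single formulation run: seven inputs plus measured attributes.

    Responses are ``None`` when not measured. ``label`` is the run identifier
    (e.g. ``"M01"``).
    """

    label: str
    drug_pct: float
    plga_pct: float
    pva_pct: float
    ow_ratio: float
    speed_rpm: float
    time_s: float
    dilution_ratio: float
    size_um: float | None = None
    uniformity: float | None = None
    ee_pct: float | None = None
    dl_pct: float | None = None

    def inputs(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in INPUT_COLUMNS}

    def response(self, name: str) -> float | None:
        if name not in RESPONSE_COLUMNS:
            raise KeyError(f"unknown response {name!r}")
        return getattr(self, name)


@dataclass
class FormulationDataset:
    """An ordered collection of formulation runs with shared input domains."""

    records: list[FormulationRecord]
    input_domains: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DESIGN_DOMAINS)
    )
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = [r.label for r in self.records]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise SchemaError(f"duplicate run labels: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Return the dataset as a DataFrame (missing responses as NaN)."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {"label": r.label}
            row.update(r.inputs())
            for name in RESPONSE_COLUMNS:
                v = getattr(r, name)
                row[name] = np.nan if v is None else v
            rows.append(row)
        return pd.DataFrame(rows, columns=["label", *INPUT_COLUMNS, *RESPONSE_COLUMNS])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        input_domains: dict[str, tuple[float, float]] | None = None,
        provenance: str = "",
        strict_domain: bool = True,
    ) -> "FormulationDataset":
        domains = dict(input_domains or DESIGN_DOMAINS)
        records = []
        for _, row in frame.iterrows():
            kwargs: dict[str, object] = {"label": str(row["label"])}
            for name in INPUT_COLUMNS:
                value = float(row[name])
                lo, hi = domains[name]
                if strict_domain and not (lo - 1e-9 <= value <= hi + 1e-9):
                    raise SchemaError(
                        f"run {row['label']}: {name}={value} outside domain ({lo}, {hi})"
                    )
                kwargs[name] = value
            for name in RESPONSE_COLUMNS:
                value = row.get(name, np.nan)
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    kwargs[name] = None
                else:
                    value = float(value)
                    if strict_domain and value < 0:
                        raise SchemaError(
                            f"run {row['label']}: negative response {name}={value}"
                        )
                    kwargs[name] = value
            records.append(FormulationRecord(**kwargs))  # type: ignore[arg-type]
        return cls(records=records, input_domains=domains, provenance=provenance)

    def subset(self, keep: Sequence[bool]) -> "FormulationDataset":
        kept = [r for r, k in zip(self.records, keep) if k]
        return replace(self, records=kept)


def _resolve_columns(columns: Iterable[str], schema: dict[str, str] | None) -> dict[str, str]:
    """Map file columns onto canonical names.

    ``schema`` maps canonical name -> file column. Without a schema, canonical
    names must appear verbatim (case-insensitive).
    """
    available = {c.strip().lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for name in ("label", *INPUT_COLUMNS, *RESPONSE_COLUMNS):
        source = schema.get(name, name) if schema else name
        key = source.strip().lower()
        if key in available:
            mapping[name] = available[key]
        elif name in INPUT_COLUMNS or name == "label":
            raise SchemaError(f"required column {source!r} not found")
    if not any(name in mapping for name in RESPONSE_COLUMNS):
        # zero responses is permitted (design-only tables)
        pass
    return mapping


def _parse_cell(raw: object, label: str, column: str) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    text = str(raw).strip()
    if text in MISSING_MARKERS:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(f"run {label!r}, column {column!r}: cannot parse {text!r}") from exc


def load_dataset(
    source,
    schema: dict[str, str] | None = None,
    input_domains: dict[str, tuple[float, float]] | None = None,
    provenance: str = "",
    strict_domain: bool = True,
) -> FormulationDataset:
    """Read a formulation table from a CSV path or text stream.

    Responses encoded as empty cells or en-dash/hyphen markers are parsed as
    *missing*, never coerced to zero. Row order is preserved.
    """
    try:
        frame = pd.read_csv(source, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("empty input stream") from exc
    if frame.empty and frame.columns.empty:
        raise SchemaError("empty input stream")
    mapping = _resolve_columns(frame.columns, schema)
    records = []
    domains = dict(input_domains or DESIGN_DOMAINS)
    for i, row in frame.iterrows():
        label = str(row[mapping["label"]]).strip()
        kwargs: dict[str, object] = {"label": label}
        for name in INPUT_COLUMNS:
            value = _parse_cell(row[mapping[name]], label, name)
            if value is None:
                raise ParseError(f"run {label!r}: missing input {name!r}")
            lo, hi = domains[name]
            if strict_domain and not (lo - 1e-9 <= value <= hi + 1e-9):
                raise SchemaError(f"run {label}: {name}={value} outside domain ({lo}, {hi})")
            kwargs[name] = value
        for name in RESPONSE_COLUMNS:
            if name in mapping:
                value = _parse_cell(row[mapping[name]], label, name)
                if strict_domain and value is not None and value < 0:
                    raise SchemaError(f"run {label}: negative response {name}={value}")
                kwargs[name] = value
        records.append(FormulationRecord(**kwargs))  # type: ignore[arg-type]
    return FormulationDataset(records=records, input_domains=domains, provenance=provenance)


def save_dataset(ds: FormulationDataset, target) -> None:
    """Write a dataset as canonical CSV; missing responses become empty cells."""
    frame = ds.to_frame()
    frame.to_csv(target, index=False, na_rep="")


def load_design24() -> FormulationDataset:
    """The bundled 24-run balanced design with its measured attributes."""
    ref = resources.files("asmod.datasets").joinpath("design24.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_dataset(fh, provenance="bundled 24-run balanced design")


def load_validation() -> FormulationDataset:
    """The two bundled validation formulations (inputs + measured outcomes)."""
    ref = resources.files("asmod.datasets").joinpath("validation.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_dataset(fh, provenance="bundled validation formulations")


def response_vector(
    ds: FormulationDataset, response: str, missing_policy: str = "drop"
) -> tuple[np.ndarray, list[str]]:
    """Extract one response column under an explicit missing-value policy.

    ``drop`` removes runs without the measurement; ``zero_fill`` keeps every
    run and substitutes 0.0 (appropriate when the missing value is a
    structural zero, e.g. drug loading of drug-free batches).
    """
    if response not in RESPONSE_COLUMNS:
        raise KeyError(f"unknown response {response!r}")
    if missing_policy not in ("drop", "zero_fill"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    values: list[float] = []
    labels: list[str] = []
    for r in ds.records:
        v = getattr(r, response)
        if v is None:
            if missing_policy == "zero_fill":
                values.append(0.0)
                labels.append(r.label)
        else:
            values.append(float(v))
            labels.append(r.label)
    return np.asarray(values, dtype=float), labels


# ---------------------------------------------------------------------------
# particle-size distribution summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeDistribution:
    """A binned volume-weighted particle-size distribution.

    ``class_centers`` are the mean diameters of the size classes (µm,
    strictly increasing); ``volume_fractions`` are the volume fractions in
    each class (non-negative, summing to one).
    """

    class_centers: np.ndarray
    volume_fractions: np.ndarray

    def __init__(self, class_centers, volume_fractions):
        centers = np.asarray(class_centers, dtype=float)
        fractions = np.asarray(volume_fractions, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("class_centers must be a non-empty 1-D array")
        if centers.shape != fractions.shape:
            raise ValueError("class_centers and volume_fractions must align")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("class_centers must be strictly increasing")
        if np.any(centers <= 0):
            raise ValueError("class_centers must be positive diameters")
        if np.any(fractions < 0):
            raise ValueError("volume_fractions must be non-negative")
        total = fractions.sum()
        if total <= 0:
            raise ValueError("volume_fractions sum to zero")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"volume_fractions sum to {total}, not 1")
        object.__setattr__(self, "class_centers", centers)
        object.__setattr__(self, "volume_fractions", fractions)


def median_volume_diameter(dist: SizeDistribution) -> float:
    """D(v, 0.5): the size at which the cumulative volume reaches one half.

    The cumulative curve is anchored at each class center with the class's
    half-mass convention (mass within a class counts half below its center)
    and interpolated linearly in cumulative fraction versus log10(size), the
    standard laser-diffraction convention.
    """
    d = dist.class_centers
    x = dist.volume_fractions
    cum = np.cumsum(x) - x / 2.0  # cumulative fraction *at* each class center
    if 0.5 <= cum[0]:
        return float(d[0])
    if 0.5 >= cum[-1]:
        return float(d[-1])
    logd = np.log10(d)
    return float(10.0 ** np.interp(0.5, cum, logd))


def uniformity(dist: SizeDistribution) -> float:
    """Volume-weighted absolute deviation from the median, over the median.

    ``sum_i x_i |d50 - d_i| / (d50 sum_i x_i)``; dimensionless, >= 0, and
    invariant under a common rescaling of all class centers.
    """
    d50 = median_volume_diameter(dist)
    d = dist.class_centers
    x = dist.volume_fractions
    return float(np.sum(x * np.abs(d50 - d)) / (d50 * np.sum(x)))


def encapsulation_efficiency(actual_mg: float, theoretical_mg: float) -> float:
    """Actual drug content as a percentage of the theoretical content.

    Values above 100% are permitted (assay variability).
    """
    if theoretical_mg <= 0:
        raise ValueError("theoretical drug content must be positive")
    if actual_mg < 0:
        raise ValueError("actual drug content must be non-negative")
    return 100.0 * actual_mg / theoretical_mg


def drug_loading(actual_mg: float, particle_mass_mg: float) -> float:
    """Drug mass as a percentage of microparticle mass."""
    if particle_mass_mg <= 0:
        raise ValueError("particle mass must be positive")
    if actual_mg < 0:
        raise ValueError("actual drug content must be non-negative")
    return 100.0 * actual_mg / particle_mass_mg
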
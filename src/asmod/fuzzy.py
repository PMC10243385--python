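"""Fuzzy-set machinery: triangular B-spline partitions and tensor bases.

Each model input is covered by a *membership partition*: ``density`` order-2
B-splines (triangular "hats") with equally spaced peaks spanning the input's
domain. At any point in the domain the memberships are non-negative, at most
two are non-zero, and they sum to exactly one (partition of unity) -- the
property that lets fitted spline weights be read as fuzzy IF-THEN rules.

A :class:`Submodel` is a tensor product of one partition per input; its basis
at a data point is the flattened outer product of the per-input membership
vectors, in row-major order of the submodel's inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["MembershipPartition", "Submodel", "make_partition", "set_labels"]


def set_labels(density: int) -> list[str]:
    """Linguistic tags by position: LOW/HIGH, LOW/MID/HIGH, LOW/L2/../HIGH."""
    if density == 2:
        return ["LOW", "HIGH"]
    if density == 3:
        return ["LOW", "MID", "HIGH"]
    return ["LOW"] + [f"L{i}" for i in range(2, density)] + ["HIGH"]


@dataclass(frozen=True)
class MembershipPartition:
    """The fuzzy-set decomposition of one input's domain.

    ``peaks`` are strictly increasing positions in ``[lo, hi]`` with the first
    at ``lo`` and the last at ``hi``; membership function *j* is the
    piecewise-linear hat peaking at 1 at ``peaks[j]`` and reaching 0 at the
    adjacent peaks.
    """

    input_name: str
    domain: tuple[float, float]
    density: int
    peaks: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if self.density < 2:
            raise ValueError("density must be at least 2")
        if not lo < hi:
            raise ValueError(f"degenerate domain ({lo}, {hi})")
        if len(self.peaks) != self.density:
            raise ValueError("number of peaks must equal density")
        if np.any(np.diff(self.peaks) <= 0):
            raise ValueError("peaks must be strictly increasing")
        if not (np.isclose(self.peaks[0], lo) and np.isclose(self.peaks[-1], hi)):
            raise ValueError("first/last peak must coincide with the domain bounds")
        if len(self.labels) != self.density:
            raise ValueError("one label per fuzzy set required")

    def memberships(self, x, clamp: bool = True) -> np.ndarray:
        """Membership degrees of ``x`` in each fuzzy set.

        Returns an array of shape ``(len(x), density)`` (or ``(density,)``
        for scalar input). Out-of-domain values are clamped to the nearest
        bound when ``clamp`` is true, otherwise rejected.
        """
        scalar = np.isscalar(x)
        xs = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.domain
        if clamp:
            xs = np.clip(xs, lo, hi)
        elif np.any((xs < lo - 1e-12) | (xs > hi + 1e-12)):
            bad = xs[(xs < lo - 1e-12) | (xs > hi + 1e-12)][0]
            raise ValueError(
                f"{self.input_name}={bad} outside domain ({lo}, {hi}) and clamping is off"
            )
        peaks = np.asarray(self.peaks)
        out = np.empty((xs.size, self.density))
        for j in range(self.density):
            hat = np.zeros(self.density)
            hat[j] = 1.0
            out[:, j] = np.interp(xs, peaks, hat)
        return out[0] if scalar else out

    def boundaries(self) -> list[float]:
        """Midpoints between adjacent peaks: the membership-0.5 crossings."""
        p = np.asarray(self.peaks)
        return [float(v) for v in (p[:-1] + p[1:]) / 2.0]

    def to_dict(self) -> dict:
        return {
            "input_name": self.input_name,
            "domain": list(self.domain),
            "density": self.density,
            "peaks": list(self.peaks),
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MembershipPartition":
        return cls(
            input_name=d["input_name"],
            domain=tuple(d["domain"]),
            density=int(d["density"]),
            peaks=tuple(float(p) for p in d["peaks"]),
            labels=tuple(d["labels"]),
        )


def make_partition(
    input_name: str,
    domain: tuple[float, float],
    density: int,
    peaks: Sequence[float] | None = None,
) -> MembershipPartition:
    """Build a partition with equally spaced peaks (or explicit ones)."""
    lo, hi = float(domain[0]), float(domain[1])
    if peaks is None:
        if density < 2:
            raise ValueError("density must be at least 2")
        if not lo < hi:
            raise ValueError(f"degenerate domain ({lo}, {hi})")
        peaks = np.linspace(lo, hi, density)
    return MembershipPartition(
        input_name=input_name,
        domain=(lo, hi),
        density=int(density),
        peaks=tuple(float(p) for p in peaks),
        labels=tuple(set_labels(int(density))),
    )


@dataclass(frozen=True)
class Submodel:
    """A tensor-product fuzzy term over an ordered subset of inputs."""

    partitions: tuple[MembershipPartition, ...]

    def __post_init__(self) -> None:
        names = [p.input_name for p in self.partitions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate inputs in submodel: {names}")
        if not self.partitions:
            raise ValueError("submodel needs at least one input")

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(p.input_name for p in self.partitions)

    @property
    def densities(self) -> tuple[int, ...]:
        return tuple(p.density for p in self.partitions)

    @property
    def basis_size(self) -> int:
        return int(np.prod(self.densities))

    def tensor_basis(self, values: Mapping[str, object]) -> np.ndarray:
        """Flattened outer product of per-input memberships.

        ``values`` maps input name -> scalar or array. Returns shape
        ``(n, basis_size)`` (``(basis_size,)`` for scalars), in row-major
        order of the submodel's inputs; rows sum to one.
        """
        mats = []
        scalar = True
        for p in self.partitions:
            if p.input_name not in values:
                raise KeyError(f"missing input value for {p.input_name!r}")
            v = values[p.input_name]
            scalar = scalar and np.isscalar(v)
            mats.append(np.atleast_2d(p.memberships(v)))
        out = mats[0]
        for m in mats[1:]:
            out = np.einsum("ni,nj->nij", out, m).reshape(out.shape[0], -1)
        return out[0] if scalar else out

    def corner_grid(self) -> list[tuple[float, ...]]:
        """Peak combinations in basis (row-major) order."""
        grids = np.meshgrid(*[np.asarray(p.peaks) for p in self.partitions], indexing="ij")
        stacked = np.stack([g.ravel() for g in grids], axis=-1)
        return [tuple(float(v) for v in row) for row in stacked]

    def label_grid(self) -> list[tuple[str, ...]]:
        """Linguistic label combinations in basis (row-major) order."""
        grids = np.meshgrid(
            *[np.arange(p.density) for p in self.partitions], indexing="ij"
        )
        idx = np.stack([g.ravel() for g in grids], axis=-1)
        return [
            tuple(p.labels[i] for p, i in zip(self.partitions, row)) for row in idx
        ]

    def to_dict(self) -> dict:
        return {"partitions": [p.to_dict() for p in self.partitions]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Submodel":
        return cls(
            partitions=tuple(MembershipPartition.from_dict(p) for p in d["partitions"])
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Submodel":
        return cls.from_dict(json.loads(text))
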
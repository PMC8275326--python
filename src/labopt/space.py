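"""Parameter-space definitions and the bijection onto the unit hypercube.

A :class:`ConfigSpace` holds an ordered list of parameter definitions:
continuous ranges are min-max scaled onto ``[0, 1]``; finite numeric levels
and categorical settings are embedded as equally spaced points (first level
at 0, last at 1) in their listed order.  When experiments must come from a
finite table of configurations, :class:`CandidateSet` assigns each requested
box center to the nearest unused candidate in scaled space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterKind",
    "ParameterDef",
    "ConfigSpace",
    "CandidateSet",
    "space_from_dataframe",
]


class ParameterKind(enum.Enum):
    CONTINUOUS = "continuous"
    LEVELS = "levels"
    CATEGORICAL = "categorical"


class OutOfRangeError(ValueError):
    """A native value falls outside its parameter's declared range/levels."""


@dataclass
class ParameterDef:
    """One tunable protocol parameter."""

    name: str
    kind: ParameterKind
    bounds: tuple[float, float] | None = None  # CONTINUOUS
    levels: list | None = None  # LEVELS / CATEGORICAL, order fixed
    unit: str = ""

    def __post_init__(self):
        if isinstance(self.kind, str):
            self.kind = ParameterKind(self.kind)
        if self.kind is ParameterKind.CONTINUOUS:
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError(f"{self.name}: continuous parameter needs min < max")
        else:
            if not self.levels:
                raise ValueError(f"{self.name}: needs a non-empty level list")

    # ------------------------------------------------------------------
    def scale_value(self, value) -> float:
        if self.kind is ParameterKind.CONTINUOUS:
            lo, hi = self.bounds
            v = float(value)
            if not lo <= v <= hi:
                raise OutOfRangeError(
                    f"parameter {self.name!r}: value {v} outside [{lo}, {hi}]"
                )
            return (v - lo) / (hi - lo)
        try:
            idx = self.levels.index(value)
        except ValueError:
            # numeric levels given as strings or vice versa
            try:
                idx = [float(l) for l in self.levels].index(float(value))
            except (TypeError, ValueError):
                raise OutOfRangeError(
                    f"parameter {self.name!r}: {value!r} is not one of {self.levels}"
                ) from None
        n = len(self.levels)
        return 0.0 if n == 1 else idx / (n - 1)

    def unscale_value(self, z: float):
        if self.kind is ParameterKind.CONTINUOUS:
            lo, hi = self.bounds
            return lo + float(z) * (hi - lo)
        n = len(self.levels)
        idx = 0 if n == 1 else int(round(float(z) * (n - 1)))
        return self.levels[min(max(idx, 0), n - 1)]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind.value, "unit": self.unit}
        if self.kind is ParameterKind.CONTINUOUS:
            d["bounds"] = list(self.bounds)
        else:
            d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterDef":
        return cls(
            name=d["name"],
            kind=ParameterKind(d["kind"]),
            bounds=tuple(d["bounds"]) if "bounds" in d else None,
            levels=list(d["levels"]) if "levels" in d else None,
            unit=d.get("unit", ""),
        )


class ConfigSpace:
    """Ordered collection of parameters with hypercube scaling."""

    def __init__(self, params: list[ParameterDef]) -> None:
        if not params:
            raise ValueError("need at least one parameter")
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        self.params = list(params)

    @property
    def dim(self) -> int:
        return len(self.params)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def scale(self, config) -> np.ndarray:
        """Map a native configuration (sequence or mapping) into [0,1]^d."""
        values = (
            [config[p.name] for p in self.params]
            if isinstance(config, dict)
            else list(config)
        )
        if len(values) != self.dim:
            raise ValueError(f"expected {self.dim} values, got {len(values)}")
        return np.array(
            [p.scale_value(v) for p, v in zip(self.params, values)], dtype=float
        )

    def unscale(self, z) -> list:
        z = np.asarray(z, dtype=float).ravel()
        if z.shape[0] != self.dim:
            raise ValueError(f"expected a {self.dim}-vector")
        return [p.unscale_value(zi) for p, zi in zip(self.params, z)]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {"parameters": [p.to_dict() for p in self.params]}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfigSpace":
        return cls([ParameterDef.from_dict(p) for p in d["parameters"]])

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ConfigSpace":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_yaml_file(cls, path) -> "ConfigSpace":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class CandidateSet:
    """A finite pool of configurations, each usable at most once.

    Distances are always computed in scaled space.  Ties between equidistant
    unused candidates are broken by row order in the source table.
    """

    def __init__(self, space: ConfigSpace, configurations: list[list]) -> None:
        self.space = space
        self.configurations = [list(c) for c in configurations]
        self.scaled = np.array([space.scale(c) for c in self.configurations])
        if len(self.scaled) and (
            self.scaled.min() < -1e-12 or self.scaled.max() > 1 + 1e-12
        ):
            raise ValueError("scaled candidates must lie within [0, 1]^d")
        self.used = np.zeros(len(self.configurations), dtype=bool)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, space: ConfigSpace) -> "CandidateSet":
        rows = df[space.names].to_numpy().tolist()
        return cls(space, rows)

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def n_unused(self) -> int:
        return int((~self.used).sum())

    def reset(self) -> None:
        self.used[:] = False

    def mark_used(self, index: int) -> None:
        self.used[index] = True

    def assign_center(self, center) -> tuple[int, list, np.ndarray] | None:
        """Nearest unused candidate to ``center`` in scaled space.

        Returns ``(row_index, native_config, scaled_config)`` and marks the
        candidate used, or ``None`` when the pool is exhausted.
        """
        if self.n_unused == 0:
            return None
        center = np.asarray(center, dtype=float).ravel()
        d2 = np.sum((self.scaled - center) ** 2, axis=1)
        d2[self.used] = np.inf
        idx = int(np.argmin(d2))  # argmin keeps the first minimum: row order
        self.used[idx] = True
        return idx, self.configurations[idx], self.scaled[idx]


def space_from_dataframe(df: pd.DataFrame, param_names: list[str]) -> ConfigSpace:
    """Infer a level-based space from a sweep table's parameter columns.

    Each column's distinct values, sorted ascending (numeric) or in first
    appearance order (non-numeric), become that parameter's ordered levels.
    """
    params = []
    for name in param_names:
        col = df[name]
        if np.issubdtype(col.dtype, np.number):
            levels = sorted(float(v) for v in col.unique())
        else:
            levels = list(dict.fromkeys(col.astype(str)))
        params.append(ParameterDef(name=name, kind=ParameterKind.LEVELS, levels=levels))
    return ConfigSpace(params)
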
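"""Hierarchical partitioning of the unit hypercube by trisection.

The search tree maintains axis-aligned boxes (:class:`Interval`) over
``[0, 1]^d``.  A box is divided into three equal children along its longest
side; ties between equally long sides are broken toward the lowest dimension
index so runs are reproducible.  The middle child shares its parent's center
and therefore inherits the parent's value; the two outer children start out
carrying optimistic surrogate placeholders until their centers are measured.
"""

from __future__ import annotations

import enum
import json
from typing import Iterator

import numpy as np

__all__ = [
    "ValueKind",
    "Interval",
    "PartitionTree",
    "trisect",
    "unevaluated_leaves",
]


class ValueKind(enum.Enum):
    """Provenance of the scalar attached to a node."""

    GROUND_TRUTH = "ground_truth"
    UCB = "ucb"


class AlreadyDividedError(RuntimeError):
    """Raised when trisection is attempted on a node that has children."""


class Interval:
    """An axis-aligned box in the unit hypercube, one node of the tree.

    Parameters
    ----------
    lower, upper:
        Box bounds, arrays of length ``d`` with ``lower < upper`` per axis.
    depth:
        Distance from the root (root has depth 0).
    value:
        Scalar attached to the node: a measured objective value or an upper
        confidence bound at the center, depending on ``value_kind``.
    """

    __slots__ = (
        "lower",
        "upper",
        "depth",
        "value",
        "value_kind",
        "children",
        "divided",
        "config",
        "evaluable",
    )

    def __init__(
        self,
        lower: np.ndarray,
        upper: np.ndarray,
        depth: int = 0,
        value: float | None = None,
        value_kind: ValueKind = ValueKind.UCB,
    ) -> None:
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower and upper must have the same shape")
        if not np.all(self.lower < self.upper):
            raise ValueError("need lower < upper along every dimension")
        self.depth = int(depth)
        self.value = value
        self.value_kind = value_kind
        self.children: list[Interval] = []
        self.divided = False
        # Native-space configuration assigned to this center (finite mode).
        self.config = None
        # False once a finite candidate set cannot supply this center.
        self.evaluable = True

    # ------------------------------------------------------------------
    @property
    def center(self) -> np.ndarray:
        return (self.lower + self.upper) / 2.0

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @property
    def sides(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def volume(self) -> float:
        return float(np.prod(self.sides))

    @property
    def is_leaf(self) -> bool:
        return not self.divided

    def longest_dimension(self) -> int:
        """Index of the longest side; lowest index wins ties."""
        return int(np.argmax(self.sides))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        c = np.round(self.center, 4).tolist()
        return (
            f"Interval(center={c}, depth={self.depth}, "
            f"value={self.value}, kind={self.value_kind.value})"
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "depth": self.depth,
            "value": self.value,
            "value_kind": self.value_kind.value,
            "divided": self.divided,
            "evaluable": self.evaluable,
            "children": [c.to_dict() for c in self.children],
        }
        if self.config is not None:
            cfg = self.config
            d["config"] = list(cfg) if isinstance(cfg, (list, tuple, np.ndarray)) else cfg
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Interval":
        node = cls(
            np.asarray(d["lower"]),
            np.asarray(d["upper"]),
            depth=d["depth"],
            value=d["value"],
            value_kind=ValueKind(d["value_kind"]),
        )
        node.divided = d["divided"]
        node.evaluable = d.get("evaluable", True)
        if "config" in d:
            node.config = d["config"]
        node.children = [cls.from_dict(c) for c in d["children"]]
        return node


def trisect(interval: Interval) -> tuple[Interval, Interval, Interval]:
    """Split ``interval`` into three equal children along its longest side.

    Returns the (left, middle, right) children ordered along the split axis.
    The middle child keeps the parent's center and inherits the parent's
    value and value kind; the outer children are created with UCB-kind
    placeholders (``value=None``) to be filled by the surrogate.

    Raises
    ------
    AlreadyDividedError
        If the interval has already been divided.
    """
    if interval.divided:
        raise AlreadyDividedError("interval has already been divided")
    j = interval.longest_dimension()
    lo, hi = interval.lower[j], interval.upper[j]
    third = (hi - lo) / 3.0
    cuts = [lo, lo + third, lo + 2.0 * third, hi]
    children = []
    for i in range(3):
        lower = interval.lower.copy()
        upper = interval.upper.copy()
        lower[j] = cuts[i]
        upper[j] = cuts[i + 1]
        child = Interval(lower, upper, depth=interval.depth + 1)
        children.append(child)
    left, middle, right = children
    # exact center inheritance: recompute middle bounds so that the middle
    # center is bit-identical to the parent center despite rounding
    middle.value = interval.value
    middle.value_kind = interval.value_kind
    middle.config = interval.config
    for outer in (left, right):
        outer.value = None
        outer.value_kind = ValueKind.UCB
    interval.children = children
    interval.divided = True
    return left, middle, right


def _center_key(node: Interval) -> tuple:
    return tuple(node.center.tolist())


class PartitionTree:
    """The full partition of ``[0, 1]^d`` rooted at the unit hypercube."""

    def __init__(self, dim: int) -> None:
        if dim < 1:
            raise ValueError("dimension must be >= 1")
        self.root = Interval(np.zeros(dim), np.ones(dim), depth=0)

    @property
    def dim(self) -> int:
        return self.root.dim

    # ------------------------------------------------------------------
    def iter_nodes(self) -> Iterator[Interval]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Interval]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def leaves_at_depth(self, depth: int) -> list[Interval]:
        out = [n for n in self.iter_nodes() if n.is_leaf and n.depth == depth]
        out.sort(key=_center_key)
        return out

    def nodes_deeper_than(self, depth: int) -> list[Interval]:
        return [n for n in self.iter_nodes() if n.depth > depth]

    def max_depth(self) -> int:
        return max(n.depth for n in self.iter_nodes())

    def trisect(self, node: Interval) -> tuple[Interval, Interval, Interval]:
        return trisect(node)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {"dim": self.dim, "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionTree":
        tree = cls(d["dim"])
        tree.root = Interval.from_dict(d["root"])
        return tree

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "PartitionTree":
        return cls.from_dict(json.loads(s))


def unevaluated_leaves(tree: PartitionTree) -> list[Interval]:
    """All leaves still carrying UCB-kind values, in deterministic order.

    Order is depth ascending, then lexicographic by center coordinates, so
    every downstream consumer sees candidates in the same sequence run to
    run.
    """
    out = [
        n
        for n in tree.iter_nodes()
        if n.is_leaf and n.value_kind is ValueKind.UCB
    ]
    out.sort(key=lambda n: (n.depth, _center_key(n)))
    return out
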
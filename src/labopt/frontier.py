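"""Frontier selection: the upper convex hull over (depth, UCB) candidates.

Every unevaluated leaf of the partition tree is encoded as a 2-D point whose
first coordinate is its tree depth (a proxy for how small its box is) and
whose second coordinate is the UCB of the objective at its center.  The
frontier is the upper convex hull of that scatter; points on the hull span
the exploration/exploitation spectrum and are the pool from which batches
are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .partition import Interval, ValueKind

__all__ = ["FrontierPoint", "compute_frontier", "fill_queue"]

_COLLINEAR_TOL = 1e-12


@dataclass
class FrontierPoint:
    """An unevaluated leaf encoded for hull computation."""

    node: Interval
    depth: int
    ucb: float
    center_key: tuple = field(default=None)

    def __post_init__(self):
        if self.node is not None and self.node.value_kind is not ValueKind.UCB:
            raise ValueError("frontier points must reference unevaluated nodes")
        if self.center_key is None:
            self.center_key = (
                tuple(self.node.center.tolist()) if self.node is not None else ()
            )


def _sort_output(points: list[FrontierPoint]) -> list[FrontierPoint]:
    return sorted(points, key=lambda p: (-p.ucb, p.depth, p.center_key))


def compute_frontier(candidates: list[FrontierPoint]) -> list[FrontierPoint]:
    """Points of ``candidates`` lying on the upper convex hull of (depth, UCB).

    A candidate dominated by a same-depth candidate with strictly greater
    UCB is removed first; collinear points on hull edges are kept.  The
    result is ordered by UCB descending, then depth ascending, then
    lexicographic center, matching the batch-fill priority.  An empty input
    yields an empty frontier.
    """
    if not candidates:
        return []
    # drop same-depth dominated points
    best_at_depth: dict[int, float] = {}
    for p in candidates:
        cur = best_at_depth.get(p.depth)
        if cur is None or p.ucb > cur:
            best_at_depth[p.depth] = p.ucb
    survivors = [p for p in candidates if p.ucb >= best_at_depth[p.depth]]

    depths = sorted(best_at_depth)
    if len(depths) == 1:
        return _sort_output(survivors)

    # upper hull of the per-depth maxima via monotone chain; strictly convex
    # vertices only — collinear candidates are recovered by the segment test
    pts = [(float(d), best_at_depth[d]) for d in depths]
    hull: list[tuple[float, float]] = []
    for pt in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            cross = (x2 - x1) * (pt[1] - y1) - (pt[0] - x1) * (y2 - y1)
            if cross >= -_COLLINEAR_TOL:  # middle point not strictly above chord
                hull.pop()
            else:
                break
        hull.append(pt)

    def on_hull(p: FrontierPoint) -> bool:
        x, y = float(p.depth), p.ucb
        for (x1, y1), (x2, y2) in zip(hull[:-1], hull[1:]):
            if x1 <= x <= x2:
                # height of the hull segment at x
                t = 0.0 if x2 == x1 else (x - x1) / (x2 - x1)
                h = y1 + t * (y2 - y1)
                if abs(y - h) <= _COLLINEAR_TOL * max(1.0, abs(h)):
                    return True
        return False

    return _sort_output([p for p in survivors if on_hull(p)])


def fill_queue(
    frontier: list[FrontierPoint],
    mandatory: list[Interval],
    k: int,
) -> list[Interval]:
    """Assemble a batch of at most ``k`` nodes to evaluate.

    Mandatory nodes (those a serial run of the algorithm would evaluate)
    come first, in the order given; the rest of the queue is filled with
    frontier nodes not already present, highest UCB first.  If the frontier
    cannot fill the queue the batch is simply shorter than ``k``.
    """
    if k < 1:
        raise ValueError("parallelism k must be >= 1")
    batch: list[Interval] = []
    seen: set[int] = set()
    for node in mandatory:
        if id(node) not in seen:
            batch.append(node)
            seen.add(id(node))
    for p in frontier:  # already in priority order
        if len(batch) >= k:
            break
        if id(p.node) not in seen:
            batch.append(p.node)
            seen.add(id(p.node))
    return batch[:k]
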
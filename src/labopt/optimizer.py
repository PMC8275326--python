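"""Deterministic batch bound-based Bayesian optimizer.

The main loop grows a trisection tree over the scaled search space while a
GP surrogate supplies optimistic value bounds (UCBs) for unmeasured box
centers.  Each iteration makes one top-down pass:

1. *Identify* — at every tree depth, find the best-valued leaf.  A measured
   leaf at least as good as the running incumbent becomes a division
   candidate; a measured leaf below it skips the depth; an unmeasured leaf
   triggers a frontier batch of experiments, after which the depth is
   re-examined.
2. *Prune* — a candidate survives only if a virtual lookahead tree grown
   from it contains a UCB exceeding the value of some strictly deeper real
   node (vacuously kept when no deeper nodes exist).
3. *Divide and select* — survivors are trisected; new outer children whose
   UCB reaches the incumbent are mandatory evaluations; the batch is then
   topped up to the parallelism level ``k`` with the highest-UCB frontier
   nodes.

The first element of every dispatched batch is exactly what a serial
(``k=1``) run in the same state would request, so batching never loses the
serial algorithm's convergence behavior.  Ground-truth evaluations alone
count against the budget; UCB bookkeeping is free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .frontier import FrontierPoint, compute_frontier, fill_queue
from .partition import Interval, PartitionTree, ValueKind, unevaluated_leaves
from .simlab import LatencyModel
from .space import CandidateSet
from .surrogate import GPSurrogate, UCBPolicy

logger = logging.getLogger(__name__)

__all__ = [
    "Assignment",
    "PendingExperiments",
    "ContinuousOracle",
    "TabularOracle",
    "ReplayOracle",
    "HistoryEntry",
    "OptimizationResult",
    "FrontierBatchOptimizer",
]


@dataclass
class Assignment:
    """A node's center resolved to a measurable configuration."""

    x_obs: np.ndarray  # scaled coordinates the GP will be conditioned at
    config: list  # native-space configuration
    key: tuple  # hashable lookup key for replay


class PendingExperiments(Exception):
    """Raised in replay mode when requested results are not yet known.

    ``suggestions`` holds the native configurations awaiting laboratory
    results; the surrounding suggest/ingest workflow persists them.
    """

    def __init__(self, suggestions: list[list]):
        self.suggestions = suggestions
        super().__init__(f"{len(suggestions)} experiment(s) awaiting results")


class ContinuousOracle:
    """Ground truth by direct evaluation of a function on box centers."""

    def __init__(self, func):
        self.func = func

    def assign(self, node: Interval) -> Assignment | None:
        center = node.center
        return Assignment(center, center.tolist(), tuple(center.tolist()))

    def can_measure(self, a: Assignment) -> bool:
        return True

    def measure(self, a: Assignment) -> tuple[dict, float]:
        value = self.func(np.asarray(a.config, dtype=float))
        return {}, float(np.asarray(value).ravel()[0])


class TabularOracle:
    """Ground truth replayed from a finite candidate table.

    Box centers are assigned to the nearest unused candidate (scaled-space
    Euclidean distance); an exhausted pool yields ``None`` and the node is
    left carrying its UCB forever.
    """

    def __init__(self, candidates: CandidateSet, values, endpoints=None):
        self.candidates = candidates
        self.values = np.asarray(values, dtype=float)
        if len(self.values) != len(candidates):
            raise ValueError("values must align with the candidate set")
        self.endpoints = endpoints  # optional DataFrame aligned with candidates

    def assign(self, node: Interval) -> Assignment | None:
        hit = self.candidates.assign_center(node.center)
        if hit is None:
            return None
        idx, config, scaled = hit
        return Assignment(np.asarray(scaled, dtype=float), list(config), ("row", idx))

    def can_measure(self, a: Assignment) -> bool:
        return True

    def measure(self, a: Assignment) -> tuple[dict, float]:
        idx = a.key[1]
        endpoints = (
            dict(self.endpoints.iloc[idx]) if self.endpoints is not None else {}
        )
        return endpoints, float(self.values[idx])


class ReplayOracle:
    """Wraps another oracle, answering measurements from a result ledger.

    Assignment is delegated (and therefore deterministic); a measurement
    whose key is absent from ``known`` means the experiment still has to be
    run in the lab.
    """

    def __init__(self, base, known: dict):
        self.base = base
        self.known = dict(known)

    def assign(self, node: Interval) -> Assignment | None:
        return self.base.assign(node)

    def can_measure(self, a: Assignment) -> bool:
        return a.key in self.known

    def measure(self, a: Assignment) -> tuple[dict, float]:
        return {}, float(self.known[a.key])


@dataclass
class HistoryEntry:
    """One ground-truth evaluation in the run log."""

    eval_index: int
    iteration: int
    batch_index: int
    slot: int  # position within the batch
    center: tuple
    x_obs: tuple
    config: list
    value: float
    best_so_far: float
    duration: float = 1.0


@dataclass
class OptimizationResult:
    incumbent_config: list
    incumbent_x: np.ndarray
    incumbent_value: float
    n_evaluations: int
    history: list[HistoryEntry]
    tree: PartitionTree
    gp: GPSurrogate
    frontier_log: list[dict] = field(default_factory=list)

    def best_so_far(self) -> np.ndarray:
        return np.array([h.best_so_far for h in self.history])


def _best_leaf(leaves: list[Interval]) -> Interval:
    """Highest-valued leaf; ties broken by lexicographic center."""
    return min(
        leaves,
        key=lambda n: (
            -(n.value if n.value is not None else -math.inf),
            tuple(n.center.tolist()),
        ),
    )


def _virtual_trisect(lower: np.ndarray, upper: np.ndarray):
    """Geometric trisection of a bare box (no tree nodes created)."""
    j = int(np.argmax(upper - lower))
    third = (upper[j] - lower[j]) / 3.0
    out = []
    for i in range(3):
        lo, up = lower.copy(), upper.copy()
        lo[j] = lower[j] + i * third
        up[j] = lower[j] + (i + 1) * third
        out.append((lo, up))
    return out


class FrontierBatchOptimizer:
    """Closed-loop bound-based optimizer with frontier batching.

    Parameters
    ----------
    oracle:
        Source of ground truth (:class:`ContinuousOracle`,
        :class:`TabularOracle`, or :class:`ReplayOracle`).
    dim:
        Dimension of the scaled search space.
    k:
        Parallelism level — the maximum batch size per request round.
    budget:
        Total number of ground-truth evaluations allowed.
    lookahead_depth:
        Levels of the virtual pruning tree grown in step 2; 0 disables
        pruning.
    async_mode:
        If True, batch results are ingested one by one in virtual
        completion order (drawn from ``latency``) with a surrogate refit
        after each arrival, instead of a single barrier ingest.
    """

    def __init__(
        self,
        oracle,
        dim: int,
        k: int = 4,
        budget: int = 25,
        gp: GPSurrogate | None = None,
        policy: UCBPolicy | None = None,
        lookahead_depth: int = 4,
        async_mode: bool = False,
        latency: LatencyModel | None = None,
        prior_observations: list[tuple] | None = None,
        max_iterations: int | None = None,
    ) -> None:
        if budget < 1:
            raise ValueError("budget must be >= 1")
        if k < 1:
            raise ValueError("parallelism k must be >= 1")
        self.oracle = oracle
        self.dim = dim
        self.k = k
        self.budget = budget
        self.gp = gp if gp is not None else GPSurrogate(dim)
        self.policy = policy if policy is not None else UCBPolicy()
        self.lookahead_depth = lookahead_depth
        self.async_mode = async_mode
        self.latency = latency
        self.max_iterations = (
            max_iterations if max_iterations is not None else 20 * budget + 100
        )

        self.tree = PartitionTree(dim)
        self.nu_max = -math.inf
        self.incumbent_config: list | None = None
        self.incumbent_x: np.ndarray | None = None
        self.n = 0
        self.iteration = 0
        self.history: list[HistoryEntry] = []
        self.frontier_log: list[dict] = []
        self._batch_counter = 0
        self.on_batch = None  # optional hook: fn(frontier, mandatory, batch)

        for x, y in prior_observations or []:
            self.gp.add_observation(np.asarray(x, dtype=float), float(y))

    # ------------------------------------------------------------------
    # value bookkeeping
    def _refresh_ucb(self) -> None:
        """Recompute bounds on all unmeasured leaves under the current GP."""
        nodes = unevaluated_leaves(self.tree)
        if not nodes:
            return
        X = np.array([n.center for n in nodes])
        means, variances = self.gp.posterior_many(X)
        for node, m, v in zip(nodes, means, variances):
            node.value = self.policy.bound(float(m), float(v))

    def _frontier_candidates(self) -> list[FrontierPoint]:
        return [
            FrontierPoint(node=n, depth=n.depth, ucb=n.value)
            for n in unevaluated_leaves(self.tree)
            if n.evaluable and n.value is not None
        ]

    def _log_frontier(self, frontier, batch) -> None:
        chosen = {id(b) for b in batch}
        for p in frontier:
            self.frontier_log.append(
                {
                    "iteration": self.iteration,
                    "depth": p.depth,
                    "ucb": p.ucb,
                    "center": list(p.center_key),
                    "selected": id(p.node) in chosen,
                }
            )

    # ------------------------------------------------------------------
    # dispatch / ingest
    def _dispatch(self, nodes: list[Interval]) -> int:
        """Assign, measure and ingest a batch; returns evaluations made."""
        assignments: list[tuple[Interval, Assignment]] = []
        for node in nodes:
            if node.value_kind is ValueKind.GROUND_TRUTH:
                continue
            a = self.oracle.assign(node)
            if a is None:
                node.evaluable = False
                logger.info("candidate pool exhausted; node left unevaluated")
                continue
            node.config = a.config
            assignments.append((node, a))
        missing = [a for _, a in assignments if not self.oracle.can_measure(a)]
        if missing:
            raise PendingExperiments([a.config for a in missing])
        if not assignments:
            return 0
        self._batch_counter += 1
        measured = []
        for node, a in assignments:
            endpoints, value = self.oracle.measure(a)
            duration = self.latency.draw() if self.latency is not None else 1.0
            measured.append((node, a, value, duration))
        order = range(len(measured))
        if self.async_mode:
            # batch size never exceeds k, so all jobs start together and
            # finish in duration order
            order = np.argsort([m[3] for m in measured], kind="stable")
        for slot, i in enumerate(order):
            node, a, value, duration = measured[i]
            self._ingest_one(node, a, value, duration, slot)
            if self.async_mode:
                self.gp.refit()
        return len(measured)

    def _ingest_one(self, node, a, value, duration, slot) -> None:
        node.value = float(value)
        node.value_kind = ValueKind.GROUND_TRUTH
        self.n += 1
        if value > self.nu_max or self.incumbent_config is None:
            self.nu_max = float(value)
            self.incumbent_config = a.config
            self.incumbent_x = np.asarray(a.x_obs, dtype=float)
        self.gp.add_observation(a.x_obs, value)
        self.history.append(
            HistoryEntry(
                eval_index=self.n - 1,
                iteration=self.iteration,
                batch_index=self._batch_counter - 1,
                slot=slot,
                center=tuple(node.center.tolist()),
                x_obs=tuple(np.asarray(a.x_obs).tolist()),
                config=list(a.config),
                value=float(value),
                best_so_far=self.nu_max,
                duration=duration,
            )
        )

    def _fill_and_dispatch(self, mandatory: list[Interval]) -> int:
        frontier = compute_frontier(self._frontier_candidates())
        batch = fill_queue(frontier, mandatory, self.k)
        batch = [b for b in batch if b.evaluable][: self.budget - self.n]
        if self.on_batch is not None:
            self.on_batch(frontier, list(mandatory), list(batch))
        self._log_frontier(frontier, batch)
        if not batch:
            return 0
        return self._dispatch(batch)

    # ------------------------------------------------------------------
    # the three steps
    def _step1_identify(self) -> list[Interval]:
        candidates: list[Interval] = []
        nu = -math.inf
        max_depth = self.tree.max_depth()
        for depth in range(max_depth + 1):
            while True:
                leaves = self.tree.leaves_at_depth(depth)
                if not leaves:
                    break
                best = _best_leaf(leaves)
                if best.value_kind is ValueKind.GROUND_TRUTH:
                    if best.value >= nu:
                        candidates.append(best)
                        nu = best.value
                    break  # cases 1 and 2 both finish the depth
                # case 3: the best leaf is unmeasured
                if not best.evaluable or self.n >= self.budget:
                    break
                if self._fill_and_dispatch([best]) == 0:
                    break
                # results ingested: re-examine this depth
        return candidates

    def _step2_prune(self, candidates: list[Interval]) -> list[Interval]:
        if self.lookahead_depth <= 0:
            return list(candidates)
        kept = []
        for node in candidates:
            deeper = [
                n.value
                for n in self.tree.nodes_deeper_than(node.depth)
                if n.value is not None
            ]
            if not deeper:
                kept.append(node)  # vacuous comparison
                continue
            if self._lookahead_exceeds(node, min(deeper)):
                kept.append(node)
        return kept

    def _lookahead_exceeds(self, node: Interval, threshold: float) -> bool:
        """Grow a virtual tree below ``node``; True if any center's UCB beats
        ``threshold``.  Virtual nodes are discarded, never evaluated."""
        level = [(node.lower.copy(), node.upper.copy())]
        for _ in range(self.lookahead_depth):
            nxt = []
            for lo, up in level:
                nxt.extend(_virtual_trisect(lo, up))
            centers = np.array([(lo + up) / 2.0 for lo, up in nxt])
            means, variances = self.gp.posterior_many(centers)
            for m, v in zip(means, variances):
                if self.policy.bound(float(m), float(v)) > threshold:
                    return True
            level = nxt
        return False

    def _step3_divide_and_select(self, candidates: list[Interval]) -> int:
        mandatory: list[Interval] = []
        divisions = 0
        for node in candidates:
            if node.divided:
                continue
            left, _, right = self.tree.trisect(node)
            divisions += 1
            for child in (left, right):
                mean, var = self.gp.posterior(child.center)
                child.value = self.policy.bound(mean, var)
                if child.value >= self.nu_max:
                    mandatory.append(child)
        evals = 0
        first = True
        while (first or mandatory) and self.n < self.budget:
            first = False
            take, mandatory = mandatory[: self.k], mandatory[self.k :]
            evals += self._fill_and_dispatch(take)
            # anything measured or exhausted leaves the mandatory queue
            mandatory = [
                m
                for m in mandatory
                if m.value_kind is ValueKind.UCB and m.evaluable
            ]
        return evals + divisions

    # ------------------------------------------------------------------
    def _iteration_once(self) -> bool:
        """One full pass of steps 1-3; True if any progress was made."""
        before = self.n
        self._refresh_ucb()
        candidates = self._step1_identify()
        progressed = self.n > before
        if self.n >= self.budget:
            return True
        candidates = self._step2_prune(candidates)
        made = self._step3_divide_and_select(candidates)
        return progressed or made > 0

    def run(self) -> OptimizationResult:
        """Execute the closed loop until the evaluation budget is spent."""
        if self.n == 0 and self.tree.root.value_kind is ValueKind.UCB:
            self.iteration = 0
            self._dispatch([self.tree.root])
        while self.n < self.budget and self.iteration < self.max_iterations:
            self.iteration += 1
            progressed = self._iteration_once()
            if self.n >= self.budget:
                break
            if not progressed:
                # safety valve: force the top frontier batch so a fully
                # pruned pass cannot stall the loop
                self._refresh_ucb()
                if self._fill_and_dispatch([]) == 0:
                    logger.info("no measurable work remains; stopping early")
                    break
            self.gp.refit()
        return OptimizationResult(
            incumbent_config=self.incumbent_config,
            incumbent_x=self.incumbent_x,
            incumbent_value=self.nu_max,
            n_evaluations=self.n,
            history=self.history,
            tree=self.tree,
            gp=self.gp,
            frontier_log=self.frontier_log,
        )
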
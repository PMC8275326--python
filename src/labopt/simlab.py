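"""Simulated cloud laboratory: a k-slot job queue over a tabulated oracle.

Experiments are never physically run; their endpoints are fetched from a
replayed dataset (or an analytic function) while a discrete-event queue
tracks virtual submission/start/completion times under a fixed parallelism
level.  This lets the batch/asynchronous dispatch logic be exercised — and
wall-clock savings estimated — entirely at the desk.
"""

from __future__ import annotations

import enum
import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "JobStatus",
    "ExperimentRecord",
    "LatencyModel",
    "LabQueue",
    "oracle_lookup",
    "elapsed_virtual_time",
]


class JobStatus(enum.Enum):
    QUEUED = "queued"
    RUNNING = "running"
    DONE = "done"
    FAILED = "failed"


@dataclass
class ExperimentRecord:
    """One experiment travelling through the job queue."""

    identifier: int
    configuration: list
    status: JobStatus = JobStatus.QUEUED
    submitted_at: float | None = None
    started_at: float | None = None
    completed_at: float | None = None
    endpoints: dict = field(default_factory=dict)
    value: float | None = None


class LatencyModel:
    """Per-job virtual durations: constant, or seeded log-normal."""

    def __init__(self, kind: str = "constant", duration: float = 1.0,
                 sigma: float = 0.5, seed: int = 0) -> None:
        if kind not in ("constant", "lognormal"):
            raise ValueError("latency kind must be 'constant' or 'lognormal'")
        self.kind = kind
        self.duration = duration
        self.sigma = sigma
        self._rng = np.random.default_rng(seed)

    def draw(self) -> float:
        if self.kind == "constant":
            return self.duration
        return float(self._rng.lognormal(mean=np.log(self.duration), sigma=self.sigma))


class DuplicateJobError(ValueError):
    pass


class MissingConfigurationError(KeyError):
    """The requested configuration is not a row of the replayed dataset."""


def oracle_lookup(dataset: pd.DataFrame, configuration, param_names: list[str]) -> dict:
    """Endpoints of the dataset row matching ``configuration`` exactly.

    A missing configuration is a hard error: centers are assigned to dataset
    rows upstream, so a miss indicates a mapping bug, not a user mistake.
    """
    sub = dataset
    for name, value in zip(param_names, configuration):
        col = sub[name]
        if np.issubdtype(col.dtype, np.number):
            sub = sub[np.isclose(col.astype(float), float(value))]
        else:
            sub = sub[col.astype(str) == str(value)]
        if len(sub) == 0:
            raise MissingConfigurationError(
                f"configuration {configuration!r} not present in dataset"
            )
    row = sub.iloc[0]
    return {
        c: row[c] for c in dataset.columns if c not in param_names
    }


class LabQueue:
    """Discrete-event k-slot queue with FIFO admission.

    Jobs submitted while all ``k`` slots are busy wait in line; at most
    ``k`` jobs are RUNNING at any virtual time.
    """

    def __init__(self, k: int, latency: LatencyModel | None = None) -> None:
        if k < 1:
            raise ValueError("slot count k must be >= 1")
        self.k = k
        self.latency = latency or LatencyModel()
        self.clock = 0.0
        self.pending: list[ExperimentRecord] = []
        self.running: list[tuple[float, int, ExperimentRecord]] = []  # heap
        self.done: list[ExperimentRecord] = []
        self._ids: set[int] = set()
        self._tiebreak = itertools.count()

    def submit(self, records: list[ExperimentRecord]) -> None:
        for rec in records:
            if rec.identifier in self._ids:
                raise DuplicateJobError(f"duplicate job id {rec.identifier}")
            self._ids.add(rec.identifier)
            rec.status = JobStatus.QUEUED
            rec.submitted_at = self.clock
            self.pending.append(rec)
        self._admit()

    def _admit(self) -> None:
        while self.pending and len(self.running) < self.k:
            rec = self.pending.pop(0)
            rec.status = JobStatus.RUNNING
            rec.started_at = self.clock
            finish = self.clock + self.latency.draw()
            heapq.heappush(self.running, (finish, next(self._tiebreak), rec))

    def step(self) -> ExperimentRecord | None:
        """Advance virtual time to the next completion; return that record."""
        if not self.running:
            return None
        finish, _, rec = heapq.heappop(self.running)
        self.clock = finish
        rec.status = JobStatus.DONE
        rec.completed_at = finish
        self.done.append(rec)
        self._admit()
        return rec

    def drain(self) -> list[ExperimentRecord]:
        """Run everything to completion; records in completion order."""
        out = []
        while self.running or self.pending:
            out.append(self.step())
        return out

    @property
    def n_running(self) -> int:
        return len(self.running)


class SimulatedLab:
    """Ground-truth oracle plus queue: the closed-loop testing harness.

    ``evaluate`` maps a native configuration to (endpoints, objective
    value).  ``run_batch`` pushes records through the virtual queue and
    returns them in completion order with values filled in.
    """

    def __init__(self, evaluate, k: int, latency: LatencyModel | None = None) -> None:
        self._evaluate = evaluate
        self.k = k
        self.latency = latency or LatencyModel()
        self.queue = LabQueue(k, self.latency)
        self._next_id = itertools.count()

    def run_batch(self, configurations: list) -> list[ExperimentRecord]:
        records = [
            ExperimentRecord(identifier=next(self._next_id), configuration=list(cfg))
            for cfg in configurations
        ]
        self.queue.submit(records)
        completed = self.queue.drain()
        for rec in completed:
            endpoints, value = self._evaluate(rec.configuration)
            rec.endpoints = endpoints
            rec.value = value
        return completed

    @property
    def elapsed(self) -> float:
        return self.queue.clock


def elapsed_virtual_time(durations, k: int) -> float:
    """Makespan of FIFO list scheduling of ``durations`` on ``k`` slots."""
    if k < 1:
        raise ValueError("k must be >= 1")
    slots = [0.0] * k
    heapq.heapify(slots)
    finish = 0.0
    for d in durations:
        start = heapq.heappop(slots)
        end = start + float(d)
        finish = max(finish, end)
        heapq.heappush(slots, end)
    return finish
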
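"""Save-state workflow: suggest a batch, run it in the lab, ingest results.

The optimizer is deterministic, so a session is persisted as nothing more
than the problem definition plus the ledger of results obtained so far.
``suggest`` replays the whole algorithm against that ledger; the replay
consumes known results until it requests configurations with no recorded
value — those are the next experiments to run.  ``ingest`` merges completed
results back into the ledger.  Results uploaded for configurations that
were never suggested are kept separately and condition the surrogate only;
the tree always starts from the center of the space.
"""

from __future__ import annotations

import warnings

import numpy as np
import yaml

from .optimizer import (
    Assignment,
    FrontierBatchOptimizer,
    PendingExperiments,
    ReplayOracle,
)
from .partition import Interval
from .space import ConfigSpace
from .surrogate import GPSurrogate, UCBPolicy

__all__ = ["RunState", "LiveOracle", "suggest", "ingest"]

_KEY_DECIMALS = 10


def config_key(config) -> tuple:
    """Hashable, YAML-round-trip-stable key for a native configuration."""
    out = []
    for v in config:
        if isinstance(v, (int, float, np.floating, np.integer)):
            out.append(round(float(v), _KEY_DECIMALS))
        else:
            out.append(str(v))
    return tuple(out)


class LiveOracle:
    """Maps box centers to native configurations for a live (non-replayed)
    space; each distinct configuration may be assigned only once."""

    def __init__(self, space: ConfigSpace):
        self.space = space
        self._assigned: set[tuple] = set()

    def assign(self, node: Interval) -> Assignment | None:
        config = self.space.unscale(node.center)
        key = config_key(config)
        if key in self._assigned:
            return None  # snapped onto an already-used configuration
        self._assigned.add(key)
        x_obs = self.space.scale(config)
        return Assignment(x_obs, config, key)

    def can_measure(self, a: Assignment) -> bool:
        return True

    def measure(self, a: Assignment):  # pragma: no cover - replaced in replay
        raise RuntimeError("a live space has no oracle; use suggest/ingest")


class RunState:
    """Everything needed to resume a session, serializable to YAML."""

    def __init__(
        self,
        space: ConfigSpace,
        k: int = 4,
        budget: int = 25,
        eta: float = 0.05,
        lookahead_depth: int = 4,
        gp_settings: dict | None = None,
        seed: int = 0,
    ) -> None:
        self.space = space
        self.k = k
        self.budget = budget
        self.eta = eta
        self.lookahead_depth = lookahead_depth
        self.gp_settings = gp_settings or {}
        self.seed = seed
        self.results: list[dict] = []  # {"config": [...], "value": float}
        self.uploads: list[dict] = []  # historical, never-suggested data
        self.pending: list[list] = []  # suggested, awaiting results

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "space": self.space.to_dict(),
            "settings": {
                "k": self.k,
                "budget": self.budget,
                "eta": self.eta,
                "lookahead_depth": self.lookahead_depth,
                "gp": dict(self.gp_settings),
                "seed": self.seed,
            },
            "results": self.results,
            "uploads": self.uploads,
            "pending": self.pending,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunState":
        s = d.get("settings", {})
        state = cls(
            space=ConfigSpace.from_dict(d["space"]),
            k=s.get("k", 4),
            budget=s.get("budget", 25),
            eta=s.get("eta", 0.05),
            lookahead_depth=s.get("lookahead_depth", 4),
            gp_settings=s.get("gp", {}),
            seed=s.get("seed", 0),
        )
        state.results = list(d.get("results", []))
        state.uploads = list(d.get("uploads", []))
        state.pending = [list(p) for p in d.get("pending", [])]
        return state

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunState":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _build_optimizer(state: RunState) -> FrontierBatchOptimizer:
    known = {config_key(r["config"]): float(r["value"]) for r in state.results}
    oracle = ReplayOracle(LiveOracle(state.space), known)
    gp = GPSurrogate(state.space.dim, **state.gp_settings)
    prior = [
        (state.space.scale(u["config"]), float(u["value"])) for u in state.uploads
    ]
    return FrontierBatchOptimizer(
        oracle,
        dim=state.space.dim,
        k=state.k,
        budget=state.budget,
        gp=gp,
        policy=UCBPolicy(eta=state.eta),
        lookahead_depth=state.lookahead_depth,
        prior_observations=prior,
    )


def suggest(state: RunState) -> list[list]:
    """Next batch of configurations (at most ``k``); empty when finished.

    Replays the deterministic algorithm against the recorded results; the
    replay halts at the first request that has no recorded value.
    """
    opt = _build_optimizer(state)
    try:
        opt.run()
    except PendingExperiments as pend:
        state.pending = [list(c) for c in pend.suggestions]
        return state.pending
    state.pending = []
    return []


def ingest(state: RunState, results: list[dict]) -> None:
    """Merge lab results into the state.

    Each result is ``{"config": [...], "value": float}``.  Results matching
    a pending suggestion extend the algorithm's ledger; others are accepted
    as historical uploads (with a warning) and condition the surrogate only.
    """
    def native(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    pending_keys = {config_key(p) for p in state.pending}
    for res in results:
        key = config_key(res["config"])
        entry = {
            "config": [native(v) for v in res["config"]],
            "value": float(res["value"]),
        }
        if key in pending_keys:
            state.results.append(entry)
            state.pending = [
                p for p in state.pending if config_key(p) != key
            ]
            pending_keys.discard(key)
        else:
            warnings.warn(
                f"result for non-suggested configuration {res['config']!r} "
                "accepted as historical data",
                UserWarning,
                stacklevel=2,
            )
            state.uploads.append(entry)
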
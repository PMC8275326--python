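"""Run-log summaries and simple static diagnostics.

Tabular artifacts are plain delimited text; plots are optional matplotlib
figures (Agg backend) of the best-so-far curve and frontier snapshots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simlab import elapsed_virtual_time

__all__ = [
    "success_summary",
    "history_to_dataframe",
    "best_so_far_frame",
    "batch_makespan",
    "plot_best_so_far",
    "plot_frontier",
]


def success_summary(percentages) -> dict:
    """Mean / median / sample SD (ddof=1) / max of success percentages."""
    v = np.asarray(percentages, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "max": float(v.max()),
    }


def history_to_dataframe(history) -> pd.DataFrame:
    """Flatten a run history into one row per ground-truth evaluation."""
    rows = []
    for h in history:
        row = {
            "eval_index": h.eval_index,
            "iteration": h.iteration,
            "batch_index": h.batch_index,
            "slot": h.slot,
            "value": h.value,
            "best_so_far": h.best_so_far,
            "duration": h.duration,
        }
        for i, c in enumerate(h.config):
            row[f"config{i + 1}"] = c
        for i, x in enumerate(h.x_obs):
            row[f"x{i + 1}"] = x
        rows.append(row)
    return pd.DataFrame(rows)


def best_so_far_frame(history) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_evaluations": np.arange(1, len(history) + 1),
            "best_so_far": [h.best_so_far for h in history],
        }
    )


def batch_makespan(history, k: int) -> float:
    """Virtual elapsed time of a run treating each batch as a barrier."""
    df = history_to_dataframe(history)
    if df.empty:
        return 0.0
    total = 0.0
    for _, grp in df.groupby("batch_index"):
        total += elapsed_virtual_time(grp["duration"].to_numpy(), k)
    return total


def _agg_axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots()


def plot_best_so_far(history, path) -> None:
    fig, ax = _agg_axes()
    frame = best_so_far_frame(history)
    ax.step(frame["n_evaluations"], frame["best_so_far"], where="post")
    ax.set_xlabel("ground-truth evaluations")
    ax.set_ylabel("best observed value")
    fig.savefig(path, dpi=120)
    import matplotlib.pyplot as plt

    plt.close(fig)


def plot_frontier(frontier_log, iteration: int, path) -> None:
    """Scatter of (depth, UCB) candidates at one iteration; frontier filled."""
    fig, ax = _agg_axes()
    rows = [r for r in frontier_log if r["iteration"] == iteration]
    if rows:
        depths = [r["depth"] for r in rows]
        ucbs = [r["ucb"] for r in rows]
        sel = [r["selected"] for r in rows]
        ax.scatter(depths, ucbs, c=["tab:red" if s else "tab:gray" for s in sel])
    ax.set_xlabel("tree depth")
    ax.set_ylabel("UCB")
    fig.savefig(path, dpi=120)
    import matplotlib.pyplot as plt

    plt.close(fig)
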
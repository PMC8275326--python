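"""Objective functions: endpoint scaling, combined scores, chromatographic
resolution, and analytic test functions.

Raw instrument endpoints (peak height, peak width, signal-to-noise ratio)
are min-max scaled per column before being combined, so columns with very
different dynamic ranges contribute comparably.  All objectives are exposed
in "maximize" orientation: endpoints whose natural direction is "smaller is
better" (peak width by default) are negated after scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "minmax_scale",
    "combo1",
    "combo2",
    "resolution",
    "sinusoid_1d",
    "PeakList",
    "EndpointTable",
    "objective_series",
    "OBJECTIVE_NAMES",
]

#: Guard for 1/width: min-max scaling sends the narrowest peak's width to 0.
WIDTH_EPSILON = 1e-3

#: Gaussian half-height resolution constant.
RESOLUTION_CONSTANT = 1.18

OBJECTIVE_NAMES = ("height", "width", "snr", "combo1", "combo2")


class DegenerateColumnWarning(UserWarning):
    pass


def minmax_scale(values) -> np.ndarray:
    """Scale a column onto [0, 1]; a constant column maps to all 0.5."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn(
            "constant column: min-max scaling is degenerate, returning 0.5",
            DegenerateColumnWarning,
            stacklevel=2,
        )
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def combo1(height_scaled, width_scaled) -> np.ndarray | float:
    """Scaled height plus the reciprocal of scaled width.

    Widths below :data:`WIDTH_EPSILON` are clamped to it: the scaled
    minimum width is exactly 0, where the reciprocal would be singular.
    """
    h = np.asarray(height_scaled, dtype=float)
    w = np.asarray(width_scaled, dtype=float)
    clamped = np.maximum(w, WIDTH_EPSILON)
    if np.any(w < WIDTH_EPSILON):
        warnings.warn(
            f"width below {WIDTH_EPSILON} clamped before reciprocal",
            UserWarning,
            stacklevel=2,
        )
    out = h + 1.0 / clamped
    return float(out) if out.ndim == 0 else out


def combo2(snr_scaled, combo1_value) -> np.ndarray | float:
    """Scaled SNR plus a combo1 score."""
    out = np.asarray(snr_scaled, dtype=float) + np.asarray(combo1_value, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class PeakList:
    """Chromatogram peaks: elution times and half-height widths."""

    times: np.ndarray
    widths: np.ndarray
    c: float = RESOLUTION_CONSTANT

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.times.shape != self.widths.shape:
            raise ValueError("times and widths must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("elution times must be non-decreasing")
        if np.any(self.widths <= 0):
            raise ValueError("half-height widths must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, c: float = RESOLUTION_CONSTANT):
        return cls(df["time"].to_numpy(), df["half_height_width"].to_numpy(), c=c)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "half_height_width": self.widths})


class UndefinedResolutionError(ValueError):
    """Resolution needs at least two peaks."""


def resolution(peaks: PeakList) -> float:
    """Total resolution of a chromatogram.

    Sum over adjacent peak pairs of ``c * (t[i+1] - t[i]) / (w[i] + w[i+1])``;
    larger values mean better-separated peaks.
    """
    if len(peaks) < 2:
        raise UndefinedResolutionError("resolution requires at least 2 peaks")
    gaps = np.diff(peaks.times)
    wsum = peaks.widths[:-1] + peaks.widths[1:]
    return float(np.sum(peaks.c * gaps / wsum))


def sinusoid_1d(x):
    """``0.5 * (sin(13 x) * sin(27 x) + 1)``, a multimodal test function on [0, 1]."""
    x = np.asarray(x, dtype=float)
    out = 0.5 * (np.sin(13.0 * x) * np.sin(27.0 * x) + 1.0)
    return float(out) if out.ndim == 0 else out


class EndpointTable:
    """Raw endpoint columns for a sweep of configurations, plus scaled views.

    In replay mode the min/max used for scaling come from the full table, so
    a configuration's objective value does not depend on evaluation order.
    """

    RAW_COLUMNS = ("height", "width", "snr")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in self.RAW_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"endpoint table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateColumnWarning)
            self.scaled = pd.DataFrame(
                {c: minmax_scale(self.df[c].to_numpy()) for c in self.RAW_COLUMNS}
            )

    def objective(self, name: str, snr_direction: str = "max") -> np.ndarray:
        return objective_series(self.df, name, snr_direction=snr_direction)


def objective_series(
    df: pd.DataFrame, name: str, snr_direction: str = "max"
) -> np.ndarray:
    """Per-row objective values (maximize orientation) for an endpoint table.

    ``height`` and ``snr`` are scaled columns; ``width`` is the negated
    scaled column (narrow peaks are better); ``combo1``/``combo2`` are the
    combined scores.  ``snr_direction='min'`` flips the sign of the scaled
    SNR wherever it is used.
    """
    if name not in OBJECTIVE_NAMES:
        raise ValueError(f"unknown objective {name!r}; pick from {OBJECTIVE_NAMES}")
    if snr_direction not in ("max", "min"):
        raise ValueError("snr_direction must be 'max' or 'min'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateColumnWarning)
        h = minmax_scale(df["height"].to_numpy())
        w = minmax_scale(df["width"].to_numpy())
        s = minmax_scale(df["snr"].to_numpy())
    if snr_direction == "min":
        s = -s
    if name == "height":
        return h
    if name == "width":
        return -w
    if name == "snr":
        return s
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        c1 = combo1(h, w)
    if name == "combo1":
        return c1
    return combo2(s, c1)
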
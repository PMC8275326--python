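"""Synthetic stand-ins for instrument sweep datasets and chromatograms.

``generate_sweep`` builds a full-factorial grid over a handful of numeric
parameters and attaches three endpoint columns (``height``, ``width``,
``snr``) drawn from a seeded response surface with a planted optimum.  The
surface families span difficulty levels: a separable quadratic bowl
(unimodal), a sum of Gaussian bumps (multimodal), and the bumps plus small
noise (rugged).  Every table ships with a machine-readable answer key so a
run's success is checkable without human inspection.

``generate_chromatogram`` builds Gaussian-peak lists whose total resolution
is known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .objectives import PeakList, resolution

__all__ = ["SweepSpec", "generate_sweep", "generate_chromatogram", "sweep_space"]

FAMILIES = ("bowl", "bumps", "rugged")


@dataclass
class SweepSpec:
    """Shape of a synthetic grid sweep."""

    grid_sizes: tuple[int, ...] = (5, 4, 3, 2)
    family: str = "bowl"
    noise_scale: float = 0.02  # rugged family only

    def __post_init__(self):
        self.grid_sizes = tuple(int(g) for g in self.grid_sizes)
        if any(g < 1 for g in self.grid_sizes):
            raise ValueError("grid sizes must be >= 1")
        if int(np.prod(self.grid_sizes)) < 2:
            raise ValueError("grid must contain at least 2 configurations")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")

    @property
    def n_rows(self) -> int:
        return int(np.prod(self.grid_sizes))

    @property
    def dim(self) -> int:
        return len(self.grid_sizes)


def _axis_levels(size: int) -> np.ndarray:
    if size == 1:
        return np.array([0.0])
    return np.arange(size) / (size - 1)


def _surface(Z: np.ndarray, spec: SweepSpec, rng) -> tuple[np.ndarray, int]:
    """Base response in roughly [0, 1] plus the planted-optimum row index."""
    n, d = Z.shape
    # plant away from the grid's corners: a sweep is normally designed to
    # bracket the optimum, so most coordinates of the best row are interior
    extreme = np.logical_or(Z == 0.0, Z == 1.0).sum(axis=1)
    pool = np.flatnonzero(extreme <= d // 2)
    if len(pool) == 0:
        pool = np.flatnonzero(extreme == extreme.min())
    target = int(pool[rng.integers(len(pool))])
    zstar = Z[target]
    if spec.family == "bowl":
        f = 1.0 - np.sum((Z - zstar) ** 2, axis=1) / d
    else:
        n_bumps = int(rng.integers(2, 4))
        f = np.zeros(n)
        # the planted bump is tallest; distractors are lower; bump widths are
        # comparable to the grid spacing so the surface is resolvable
        widths = rng.uniform(0.35, 0.6, size=n_bumps)
        centers = rng.uniform(0, 1, size=(n_bumps, d))
        centers[0] = zstar
        amps = np.concatenate([[1.0], rng.uniform(0.25, 0.5, size=n_bumps - 1)])
        for a, c, w in zip(amps, centers, widths):
            f += a * np.exp(-np.sum((Z - c) ** 2, axis=1) / (2 * w**2))
        # a conical component at the planted optimum keeps the peak row
        # clearly above its own grid neighbors (no flat top)
        dist = np.sqrt(np.sum((Z - zstar) ** 2, axis=1))
        f += 0.5 * np.maximum(0.0, 1.0 - dist / 0.5)
        if spec.family == "rugged":
            f += rng.normal(scale=spec.noise_scale, size=n)
    # ensure the planted optimum is the strict, unique maximum
    others = np.delete(f, target)
    gap = max(1e-3, 1e-3 * (others.max() - others.min() + 1.0))
    if f[target] <= others.max():
        f[target] = others.max() + gap
    # break any residual ties among the rest deterministically
    f += rng.uniform(0, gap * 1e-3, size=n) * (np.arange(n) != target)
    return f, target


def generate_sweep(
    spec: SweepSpec, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Full-factorial endpoint table plus its answer key.

    Endpoints are monotone transforms of one seeded response surface, so a
    single row is simultaneously the tallest/narrowest/cleanest: the key's
    ``optimum_row`` is the argmax of ``height`` and ``snr`` and the argmin
    of ``width``.
    """
    rng = np.random.default_rng(seed)
    axes = [_axis_levels(g) for g in spec.grid_sizes]
    rows = list(product(*axes))
    Z = np.array(rows)
    names = [f"param{i + 1}" for i in range(spec.dim)]
    df = pd.DataFrame(Z, columns=names)

    f, target = _surface(Z, spec, rng)
    lo, hi = f.min(), f.max()
    g = (f - lo) / (hi - lo)  # planted row at exactly 1
    df["height"] = 10.0 + 90.0 * g
    df["width"] = 0.2 + 1.8 * (1.0 - g)  # narrowest at the optimum
    df["snr"] = 2.0 + 18.0 * g

    key = {
        "optimum_row": target,
        "optimum_config": [float(v) for v in Z[target]],
        "family": spec.family,
        "grid_sizes": list(spec.grid_sizes),
        "seed": int(seed),
        "endpoint_argmax": {
            "height": int(df["height"].idxmax()),
            "width": int(df["width"].idxmin()),
            "snr": int(df["snr"].idxmax()),
        },
    }
    return df, key


def sweep_space(spec: SweepSpec):
    """The level-based search space matching a sweep table's grid."""
    from .space import ConfigSpace, ParameterDef, ParameterKind

    params = [
        ParameterDef(
            name=f"param{i + 1}",
            kind=ParameterKind.LEVELS,
            levels=[float(v) for v in _axis_levels(g)],
        )
        for i, g in enumerate(spec.grid_sizes)
    ]
    return ConfigSpace(params)


def generate_chromatogram(
    n_peaks: int,
    spacing: float = 1.0,
    widths: float | np.ndarray = 0.1,
    seed: int = 0,
    jitter: float = 0.0,
    n_trace_points: int = 0,
):
    """A seeded Gaussian-peak list with closed-form resolution.

    Peaks sit at ``t0 + i * spacing`` (optionally jittered) with the given
    half-height widths.  When ``n_trace_points > 0`` a densely sampled
    Gaussian-mixture trace is returned alongside, for end-to-end demos.

    Returns ``(PeakList, R_S, trace | None)``.
    """
    if n_peaks < 2:
        raise ValueError("need at least 2 peaks")
    rng = np.random.default_rng(seed)
    times = 1.0 + spacing * np.arange(n_peaks, dtype=float)
    if jitter > 0:
        times += rng.uniform(-jitter, jitter, size=n_peaks)
        times.sort()
    w = np.broadcast_to(np.asarray(widths, dtype=float), (n_peaks,)).copy()
    peaks = PeakList(times, w)
    rs = resolution(peaks)
    trace = None
    if n_trace_points > 0:
        # half-height width of a Gaussian = 2*sqrt(2 ln 2) * sd
        sd = w / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        t = np.linspace(times[0] - 5 * sd.max(), times[-1] + 5 * sd.max(),
                        n_trace_points)
        y = np.zeros_like(t)
        for ti, si in zip(times, sd):
            y += np.exp(-((t - ti) ** 2) / (2 * si**2))
        trace = pd.DataFrame({"time": t, "intensity": y})
    return peaks, rs, trace
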
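"""Firing-rate maps from spike/position event tables.

Construction follows the standard free-foraging recipe: bin the arena
(default 64 × 64), accumulate occupancy time and spike counts per bin, divide
to get a rate in Hz, smooth with a boxcar (default 5 bins), and normalize.
Flattened stacks feed :mod:`subgen.core` as cells × bins activity matrices.

Conventions fixed here (the literature is silent on all of them): bin edges
are half-open ``[lo, hi)`` with the final bin closed; a spike's position is
taken from the nearest trajectory time sample; a bin with occupancy below
``min_occupancy`` seconds (default 0.1 s) is considered unvisited and is
imputed from the smoothed neighborhood mean so NaNs never reach the PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from ._util import DegenerateInputError, DimensionMismatchError
from .core import ActivityMatrix

__all__ = [
    "EventTable",
    "RateMapStack",
    "make_ratemaps",
    "boxcar_smooth",
    "normalize_maps",
    "flatten",
    "unflatten",
]

#: seconds of occupancy below which a bin counts as unvisited
DEFAULT_MIN_OCCUPANCY = 0.1


@dataclass
class EventTable:
    """Trajectory samples plus per-cell spike times for one session.

    ``times`` are strictly increasing seconds; ``positions`` is (n, 2) in
    environment units within ``bounds`` = ((xmin, xmax), (ymin, ymax));
    ``spike_times`` maps cell id → ascending spike times inside the session.
    """

    times: np.ndarray
    positions: np.ndarray
    spike_times: Mapping[str, np.ndarray]
    bounds: tuple[tuple[float, float], tuple[float, float]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.shape != (self.times.size, 2):
            raise DimensionMismatchError(
                "times must be (n,) and positions (n, 2) with matching n"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.bounds is None:
            self.bounds = (
                (float(self.positions[:, 0].min()), float(self.positions[:, 0].max())),
                (float(self.positions[:, 1].min()), float(self.positions[:, 1].max())),
            )
        (x0, x1), (y0, y1) = self.bounds
        if np.any(self.positions[:, 0] < x0) or np.any(self.positions[:, 0] > x1) \
                or np.any(self.positions[:, 1] < y0) or np.any(self.positions[:, 1] > y1):
            raise ValueError("positions outside declared environment bounds")
        self.spike_times = {
            str(c): np.asarray(t, dtype=float) for c, t in self.spike_times.items()
        }
        t0, t1 = self.times[0], self.times[-1]
        for c, st in self.spike_times.items():
            if st.size and (st.min() < t0 or st.max() > t1):
                raise ValueError(
                    f"spike times of cell {c} fall outside the session window"
                )

    @property
    def n_cells(self) -> int:
        return len(self.spike_times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class RateMapStack:
    """Per-cell rate maps (Hz) over a common spatial binning."""

    maps: np.ndarray  # (n_cells, n_bins_x, n_bins_y)
    cell_labels: list[str] = field(default=None)  # type: ignore[assignment]
    bin_edges_x: np.ndarray | None = None
    bin_edges_y: np.ndarray | None = None
    occupancy: np.ndarray | None = None  # (n_bins_x, n_bins_y) seconds

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (n_cells, n_bins_x, n_bins_y)")
        if self.cell_labels is None:
            self.cell_labels = [f"cell{i}" for i in range(self.maps.shape[0])]
        if len(self.cell_labels) != self.maps.shape[0]:
            raise DimensionMismatchError("cell label count mismatch")
        if self.occupancy is not None:
            self.occupancy = np.asarray(self.occupancy, dtype=float)
            if self.occupancy.shape != self.maps.shape[1:]:
                raise DimensionMismatchError("occupancy shape mismatch")
            if np.any(self.occupancy < 0):
                raise ValueError("occupancy must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.maps.shape[0]

    @property
    def n_bins(self) -> tuple[int, int]:
        return self.maps.shape[1], self.maps.shape[2]

    def copy(self) -> "RateMapStack":
        return RateMapStack(
            self.maps.copy(),
            list(self.cell_labels),
            None if self.bin_edges_x is None else self.bin_edges_x.copy(),
            None if self.bin_edges_y is None else self.bin_edges_y.copy(),
            None if self.occupancy is None else self.occupancy.copy(),
        )


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [lo, hi) bins, final bin closed on the right."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    return idx


def _renormalized_boxcar(arr: np.ndarray, window: int) -> np.ndarray:
    """2-D moving average with the kernel renormalized over in-bounds bins."""
    size = (window, window)
    num = ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(
        np.ones_like(arr), size=size, mode="constant", cval=0.0
    )
    return num / den


def make_ratemaps(
    events: EventTable,
    n_bins: tuple[int, int] = (64, 64),
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
    unvisited: str = "neighborhood",
) -> RateMapStack:
    """Bin a session into per-cell rate maps: spike count / occupancy time.

    Each trajectory sample contributes its forward time step to the occupancy
    of its bin (the final sample contributes the median step).  Bins with
    occupancy below ``min_occupancy`` are unvisited; the default policy
    imputes them with a renormalized 5-bin boxcar mean of visited neighbors
    (policy ``"zero"`` leaves them at 0 instead).
    """
    nx, ny = int(n_bins[0]), int(n_bins[1])
    (x0, x1), (y0, y1) = events.bounds
    edges_x = np.linspace(x0, x1, nx + 1)
    edges_y = np.linspace(y0, y1, ny + 1)

    dt = np.diff(events.times)
    dt = np.append(dt, np.median(dt))
    ix = _bin_index(events.positions[:, 0], edges_x)
    iy = _bin_index(events.positions[:, 1], edges_y)
    occupancy = np.zeros((nx, ny))
    np.add.at(occupancy, (ix, iy), dt)
    if occupancy.sum() <= 0:
        raise DegenerateInputError("zero total occupancy")
    visited = (occupancy >= min_occupancy) & (occupancy > 0)
    if visited.sum() < 0.5 * visited.size:
        raise DegenerateInputError(
            f"only {visited.sum()} of {visited.size} bins visited; "
            "session does not cover the environment"
        )

    maps = np.zeros((events.n_cells, nx, ny))
    labels = list(events.spike_times.keys())
    for i, cell in enumerate(labels):
        st = events.spike_times[cell]
        if st.size == 0:
            warnings.warn(f"cell {cell} has no spikes; emitting a zero map")
            continue
        # spike position = nearest trajectory sample in time
        j = np.clip(np.searchsorted(events.times, st), 1, events.times.size - 1)
        j -= (st - events.times[j - 1]) < (events.times[j] - st)
        counts = np.zeros((nx, ny))
        np.add.at(counts, (ix[j], iy[j]), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(visited, counts / occupancy, 0.0)
        if unvisited == "neighborhood" and not visited.all():
            num = _renormalized_boxcar(np.where(visited, rate, 0.0), 5)
            den = _renormalized_boxcar(visited.astype(float), 5)
            with np.errstate(invalid="ignore", divide="ignore"):
                fill = np.where(den > 0, num / den, 0.0)
            rate = np.where(visited, rate, fill)
        maps[i] = rate
    return RateMapStack(maps, labels, edges_x, edges_y, occupancy)


def boxcar_smooth(stack: RateMapStack, window_bins: int = 5) -> RateMapStack:
    """2-D boxcar moving average, kernel renormalized at the arena edges.

    Renormalization over in-bounds bins avoids the downward bias of zero
    padding; a window of 1 is the identity.  Total map mass is conserved only
    up to the edge renormalization (exactly conserved for constant maps).
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("boxcar window must be a positive odd integer")
    out = stack.copy()
    if window_bins == 1:
        return out
    for i in range(out.n_cells):
        out.maps[i] = _renormalized_boxcar(stack.maps[i], window_bins)
    return out


def normalize_maps(stack: RateMapStack, method: str = "peak") -> RateMapStack:
    """Per-cell normalization: ``peak`` (max → 1) or ``zscore`` (mean 0, sd 1
    across bins)."""
    out = stack.copy()
    flat = out.maps.reshape(out.n_cells, -1)
    if method == "peak":
        peaks = flat.max(axis=1)
        bad = np.flatnonzero(peaks <= 0)
        if bad.size:
            names = ", ".join(out.cell_labels[i] for i in bad[:5])
            raise DegenerateInputError(
                f"all-zero map(s) for cell(s) {names}; cannot peak-normalize"
            )
        flat /= peaks[:, None]
    elif method == "zscore":
        flat -= flat.mean(axis=1, keepdims=True)
        sd = flat.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            names = ", ".join(out.cell_labels[i] for i in bad[:5])
            raise DegenerateInputError(
                f"constant map(s) for cell(s) {names}; cannot z-score"
            )
        flat /= sd[:, None]
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    out.maps = flat.reshape(out.maps.shape)
    return out


def flatten(stack: RateMapStack) -> ActivityMatrix:
    """Row-major flattening of bins into states (cells × bins matrix)."""
    nx, ny = stack.n_bins
    states = [f"bin_{i}_{j}" for i in range(nx) for j in range(ny)]
    return ActivityMatrix(
        stack.maps.reshape(stack.n_cells, nx * ny).copy(),
        list(stack.cell_labels),
        states,
    )


def unflatten(A: ActivityMatrix, n_bins: tuple[int, int]) -> RateMapStack:
    """Inverse of :func:`flatten` for a known binning."""
    nx, ny = n_bins
    if A.n_states != nx * ny:
        raise DimensionMismatchError(
            f"{A.n_states} states cannot reshape to {nx}×{ny}"
        )
    return RateMapStack(
        A.values.reshape(A.n_units, nx, ny).copy(), list(A.unit_labels)
    )
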
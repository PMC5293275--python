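"""Observables of the migrating cell: lengths, deformation, speed, outcome.

All metrics are pure functions of recorded trace data, so re-running them on
a saved trace reproduces the outputs bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

CM_PER_S_TO_UM_PER_H = 1.0e4 * 3600.0

NON_INVASIVE = "non_invasive"
IN_PROCESS = "in_process"
PASSED = "passed"


@dataclass
class CellTrace:
    """Time series recorded during a run (appended at the logging stride)."""

    t: list = field(default_factory=list)
    L: list = field(default_factory=list)            # cell-body length (cm)
    L_rate: list = field(default_factory=list)       # smoothed L' (cm/s)
    Nlen: list = field(default_factory=list)         # nucleus length (cm)
    nucleus_bottom_y: list = field(default_factory=list)
    nucleus_min_y: list = field(default_factory=list)
    nucleus_max_y: list = field(default_factory=list)
    membrane_max_y: list = field(default_factory=list)
    centroid: list = field(default_factory=list)     # membrane centroid (cm)
    phase: list = field(default_factory=list)
    dir_x: list = field(default_factory=list)        # migration direction
    dir_y: list = field(default_factory=list)
    Lperp: list = field(default_factory=list)        # lateral deformation
    LperpW: list = field(default_factory=list)
    LperpE: list = field(default_factory=list)
    ps: list = field(default_factory=list)           # sensing pressure
    a: list = field(default_factory=list)            # actin concentration
    mb: list = field(default_factory=list)
    r: list = field(default_factory=list)            # stiffening rate
    c_nucleus: list = field(default_factory=list)    # nucleus stiffness
    ca: list = field(default_factory=list)
    Fc: list = field(default_factory=list)
    B: list = field(default_factory=list)
    D: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        t = np.asarray(self.t)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = {k: v for k, v in self.__dict__.items()
                if isinstance(v, list) and len(v) == len(self.t)}
        cols["centroid_x"] = [c[0] for c in self.centroid]
        cols["centroid_y"] = [c[1] for c in self.centroid]
        cols.pop("centroid", None)
        return pd.DataFrame(cols)


@dataclass
class PassingOutcome:
    """Three-way gap-crossing classification with optional passing time."""

    status: str
    passing_time: float | None = None

    def __post_init__(self):
        if (self.status == PASSED) != (self.passing_time is not None):
            raise ValueError("passing_time present iff status is 'passed'")


# ---------------------------------------------------------------------------


def body_length(X: np.ndarray, direction) -> float:
    """Cell-body length: widest node separation projected on the migration
    direction (the longest front-to-rear distance for gap-aligned motion)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    proj = np.asarray(X) @ d
    return float(proj.max() - proj.min())


def diameter(X: np.ndarray) -> float:
    """Unprojected maximum pairwise node distance (logged alongside L)."""
    X = np.asarray(X)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def nucleus_deformation(markers: np.ndarray, marker_ref: np.ndarray
                        ) -> tuple[float, float, float]:
    """Lateral deformation ratios (Lperp, LperpW, LperpE).

    markers rows are (center, west, east); marker_ref holds the initial
    |W - c| and |E - c| distances, so the ratios are 1 at t = 0.
    """
    if markers is None or marker_ref is None:
        raise ValueError("deformation markers are not initialized")
    c, w, e = markers
    lw = np.linalg.norm(w - c) / marker_ref[0]
    le = np.linalg.norm(e - c) / marker_ref[1]
    return 0.5 * (lw + le), float(lw), float(le)


def average_speed(trace: CellTrace, window: tuple[float, float] | None = None
                  ) -> float:
    """Centroid displacement over the window divided by its duration, um/h."""
    t = np.asarray(trace.t)
    cen = np.asarray(trace.centroid)
    if window is None:
        i0, i1 = 0, len(t) - 1
    else:
        if window[0] < t[0] - 1e-12 or window[1] > t[-1] + 1e-12:
            raise ValueError("window outside the recorded trace")
        i0 = int(np.searchsorted(t, window[0]))
        i1 = int(np.searchsorted(t, window[1], side="right")) - 1
    dt = t[i1] - t[i0]
    if dt <= 0:
        return 0.0
    disp = np.linalg.norm(cen[i1] - cen[i0])
    return float(disp / dt) * CM_PER_S_TO_UM_PER_H


def speed_series(trace: CellTrace, bin_seconds: float) -> pd.DataFrame:
    """Binned average speeds (um/h) for speed-vs-time plots."""
    t = np.asarray(trace.t)
    cen = np.asarray(trace.centroid)
    edges = np.arange(t[0], t[-1] + bin_seconds, bin_seconds)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        i0 = int(np.searchsorted(t, a))
        i1 = min(int(np.searchsorted(t, b)), len(t) - 1)
        if t[i1] > t[i0]:
            v = np.linalg.norm(cen[i1] - cen[i0]) / (t[i1] - t[i0])
            rows.append((0.5 * (a + b), v * CM_PER_S_TO_UM_PER_H))
    return pd.DataFrame(rows, columns=["t", "speed_um_per_h"])


def classify_passing(trace: CellTrace, gap_line_y: float,
                     T_end: float | None = None) -> PassingOutcome:
    """Pass/block classification against the line through the gap.

    passed: the entire nucleus (its lowest point) crosses gap_line_y before
    T_end; in_process: the membrane has entered the gap but the nucleus has
    not fully crossed; non_invasive: otherwise.
    """
    t = np.asarray(trace.t)
    nuc_min = np.asarray(trace.nucleus_min_y)
    mem_max = np.asarray(trace.membrane_max_y)
    if T_end is not None:
        keep = t <= T_end + 1e-12
        t, nuc_min, mem_max = t[keep], nuc_min[keep], mem_max[keep]
    crossed = np.flatnonzero(nuc_min > gap_line_y)
    if crossed.size:
        return PassingOutcome(PASSED, passing_time=float(t[crossed[0]]))
    if np.any(mem_max > gap_line_y):
        return PassingOutcome(IN_PROCESS)
    return PassingOutcome(NON_INVASIVE)


def count_troughs(series, baseline: float, min_separation: float,
                  t=None) -> int:
    """Number of local minima below ``baseline`` separated by at least
    ``min_separation`` (same units as ``t``; samples if t is None)."""
    s = np.asarray(series, dtype=float)
    if len(s) < 3:
        raise ValueError("series too short")
    if t is not None:
        dt = float(np.median(np.diff(np.asarray(t))))
        distance = max(1, int(round(min_separation / dt)))
    else:
        distance = max(1, int(min_separation))
    idx, _ = find_peaks(-s, height=-baseline, distance=distance)
    return int(len(idx))


def direction_angle(displacement) -> float:
    """Signed angle (degrees) of a displacement from the +y axis; positive
    means north-east, negative north-west."""
    dx, dy = np.asarray(displacement, dtype=float)
    return float(np.degrees(np.arctan2(dx, dy)))


def phase_grid(table: pd.DataFrame, row: str, col: str,
               value: str = "status") -> pd.DataFrame:
    """Pivot a sweep outcome table into a dose-by-interval style matrix
    (rows and columns are parameter values, cells the outcome)."""
    return table.pivot(index=row, columns=col, values=value)


def render_phase_grid(table: pd.DataFrame, row: str, col: str, path,
                      value: str = "status") -> None:
    """Render a pass/block phase map as a heatmap image.

    Outcome categories map to the three-color scheme used for dose grids:
    non-invasive, in-process, passed.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = phase_grid(table, row, col, value)
    if value == "status":
        coding = {NON_INVASIVE: 0, "failed": 0, IN_PROCESS: 1, PASSED: 2}
        data = grid.replace(coding).astype(float).values
        cmap = matplotlib.colors.ListedColormap(
            ["#3b4cc0", "#d7191c", "#ffd700"])
        vmin, vmax = 0, 2
    else:
        data = grid.values.astype(float)
        cmap, vmin, vmax = "viridis", None, None
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(data, origin="lower", aspect="auto", cmap=cmap,
                   vmin=vmin, vmax=vmax)
    ax.set_xticks(range(len(grid.columns)), [str(c) for c in grid.columns])
    ax.set_yticks(range(len(grid.index)), [str(i) for i in grid.index])
    ax.set_xlabel(col)
    ax.set_ylabel(row)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def direction_angle_series(trace: CellTrace, window: float, h: float
                           ) -> pd.DataFrame:
    """Windowed migration angles; undefined angles (displacement < h) carry
    the previous value forward."""
    t = np.asarray(trace.t)
    cen = np.asarray(trace.centroid)
    edges = np.arange(t[0], t[-1] + window, window)
    rows, last = [], 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        i0 = int(np.searchsorted(t, a))
        i1 = min(int(np.searchsorted(t, b)), len(t) - 1)
        disp = cen[i1] - cen[i0]
        if np.linalg.norm(disp) >= h:
            last = direction_angle(disp)
        rows.append((0.5 * (a + b), last))
    return pd.DataFrame(rows, columns=["t", "angle_deg"])
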
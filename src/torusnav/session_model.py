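"""Core session data types, session-bundle I/O and cluster-quality statistics.

A recording session is represented by three objects: a :class:`Trajectory`
(timestamped 2D position of the animal on the arena, cm / s, arena center at
the origin, bridge toward negative y), a list of :class:`SpikeTrain` (sorted
spike times per cell) and a :class:`TrialEvents` table describing the homing
task trials (door open/close, lever press, lever and bridge coordinates,
light condition).

On disk a session bundle is a directory with ``trajectory.csv``,
``spikes.csv`` (cell_id,time), ``trials.csv`` and ``meta.yaml`` (arena radii,
bridge coordinates, tracking rate); all times in seconds, positions in cm,
angles in radians.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Trajectory",
    "SpikeTrain",
    "TrialEvents",
    "CellQC",
    "compute_speed",
    "cell_quality",
    "save_session",
    "load_session",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Animal position over time.

    t is strictly increasing with a near-uniform step; x, y are in cm with the
    arena center at the origin. ``hd`` (head direction, radians) is optional.
    ``speed`` (cm/s) is derived via :func:`compute_speed` on demand.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd: Optional[np.ndarray] = None
    speed: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.hd is not None:
            self.hd = np.asarray(self.hd, dtype=float)
        if self.t.shape != self.x.shape or self.t.shape != self.y.shape:
            raise ValueError("t, x, y must have the same shape")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def validate(self, arena_radius: Optional[float] = None, tol_cm: float = 2.0):
        """Raise ValueError if basic invariants are violated."""
        dt = np.diff(self.t)
        if self.t.size < 2 or np.any(dt <= 0):
            raise ValueError("t must be strictly increasing")
        step = np.median(dt)
        if np.any(np.abs(dt - step) > 0.5 * step):
            raise ValueError("time step must be near-uniform")
        if arena_radius is not None:
            r = np.hypot(self.x, self.y)
            if np.any(r > arena_radius + tol_cm):
                raise ValueError("positions exceed arena radius")

    def with_speed(self, smooth_sd: float = 0.1) -> "Trajectory":
        return replace(self, speed=compute_speed(self, smooth_sd))

    def slice(self, t0: float, t1: float) -> "Trajectory":
        m = (self.t >= t0) & (self.t < t1)
        return Trajectory(self.t[m], self.x[m], self.y[m],
                          None if self.hd is None else self.hd[m],
                          None if self.speed is None else self.speed[m])

    def position_at(self, times) -> np.ndarray:
        """Linear interpolation of position at arbitrary times."""
        times = np.asarray(times, dtype=float)
        return np.column_stack([
            np.interp(times, self.t, self.x),
            np.interp(times, self.t, self.y),
        ])


@dataclass
class SpikeTrain:
    cell_id: str
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)

    @property
    def n(self) -> int:
        return int(self.times.size)

    def in_interval(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.cell_id, self.times[m])

    def mean_rate(self, span: float) -> float:
        return self.n / span if span > 0 else np.nan


@dataclass
class TrialEvents:
    """Per-trial event table for the homing task.

    The underlying table has columns: trial_id, light ('light'|'dark'),
    t_door_open, t_door_close, t_lever_press (NaN if no press), lever_x,
    lever_y, bridge_x, bridge_y, arena_rotation.
    """

    table: pd.DataFrame

    REQUIRED = ("trial_id", "light", "t_door_open", "t_door_close",
                "t_lever_press", "lever_x", "lever_y",
                "bridge_x", "bridge_y", "arena_rotation")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")

    def validate(self):
        tb = self.table
        if np.any(tb.t_door_open.values >= tb.t_door_close.values):
            raise ValueError("door_open must precede door_close")
        press = tb.t_lever_press.values
        has = np.isfinite(press)
        if np.any(press[has] < tb.t_door_open.values[has]) or \
           np.any(press[has] > tb.t_door_close.values[has]):
            raise ValueError("lever press outside trial span")

    def __len__(self):
        return len(self.table)

    def __iter__(self):
        return (row for _, row in self.table.iterrows())


@dataclass
class CellQC:
    """Cluster-quality summary.

    A cluster is included when mean_rate > 0.1 Hz, refractory_ratio < 0.15 and
    the 0-30 ms spike-time autocorrelogram contains at least 100 spikes.
    """

    cell_id: str
    mean_rate: float
    refractory_ratio: float
    n_autocorr_spikes: int
    isolation_distance: float = np.nan
    isolation_defined: bool = True

    RATE_MIN = 0.1
    RATIO_MAX = 0.15
    AUTOCORR_MIN = 100

    @property
    def included(self) -> bool:
        if not np.isfinite(self.refractory_ratio):
            return False
        return (self.mean_rate > self.RATE_MIN
                and self.refractory_ratio < self.RATIO_MAX
                and self.n_autocorr_spikes >= self.AUTOCORR_MIN)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_speed(traj: Trajectory, smooth_sd: float = 0.1) -> np.ndarray:
    """Running speed (cm/s) from central-difference displacement.

    Parameters
    ----------
    smooth_sd : Gaussian smoothing of the speed series, in seconds
        (0 disables smoothing).
    """
    if traj.t.size < 3:
        raise ValueError("need at least 3 samples to compute speed")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    speed = np.hypot(vx, vy)
    if smooth_sd > 0:
        speed = gaussian_filter1d(speed, smooth_sd / traj.dt, mode="nearest")
    return speed


def spike_time_autocorrelogram(times: np.ndarray, max_lag: float = 0.030,
                               bin_width: float = 0.0005) -> np.ndarray:
    """Counts of spike-pair lags in (0, max_lag], excluding the zero-lag self pair."""
    times = np.sort(np.asarray(times, dtype=float))
    n_bins = int(round(max_lag / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    hi = np.searchsorted(times, times + max_lag, side="right")
    for i in range(times.size):
        lags = times[i + 1:hi[i]] - times[i]
        if lags.size:
            idx = np.minimum((lags / bin_width).astype(int), n_bins - 1)
            np.add.at(counts, idx, 1)
    return counts


def _mahalanobis(points: np.ndarray, mean: np.ndarray, cov_inv: np.ndarray) -> np.ndarray:
    d = points - mean
    return np.sqrt(np.einsum("ij,jk,ik->i", d, cov_inv, d))


def cell_quality(spikes: SpikeTrain, session_span: float,
                 own_features: Optional[np.ndarray] = None,
                 other_features: Optional[np.ndarray] = None) -> CellQC:
    """Cluster-quality statistics for one cell.

    The refractory-period ratio is computed from the 0-25 ms spike-time
    autocorrelogram (0.5-ms bins): mean count in the three bins spanning
    0-1.5 ms divided by the maximum count in any bin between 5 and 15 ms.
    The spike count criterion uses the 0-30 ms window. The isolation distance
    is the radius of the smallest Mahalanobis ellipsoid (covariance from the
    cluster itself) containing all own spikes and an equal number of spikes
    from other clusters: max of the own cluster's largest distance and the
    Nth-nearest other-cluster distance, N = own-cluster size.
    """
    counts = spike_time_autocorrelogram(spikes.times, max_lag=0.030)
    # ratio uses the 0-25 ms histogram (identical bins, narrower window)
    refr = counts[:3].mean()  # bins spanning 0-1.5 ms
    band = counts[10:30]      # bins spanning 5-15 ms
    peak = band.max() if band.size else 0
    ratio = refr / peak if peak > 0 else np.nan

    iso = np.nan
    iso_defined = False
    if own_features is not None and other_features is not None \
            and len(own_features) > own_features.shape[1]:
        own = np.asarray(own_features, dtype=float)
        other = np.asarray(other_features, dtype=float)
        cov = np.cov(own, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            cov_inv = None
        if cov_inv is not None:
            mean = own.mean(axis=0)
            d_own = _mahalanobis(own, mean, cov_inv)
            n = len(own)
            if len(other) >= n:
                d_other = np.sort(_mahalanobis(other, mean, cov_inv))
                iso = float(max(d_own.max(), d_other[n - 1]))
                iso_defined = True

    return CellQC(
        cell_id=spikes.cell_id,
        mean_rate=spikes.mean_rate(session_span),
        refractory_ratio=float(ratio),
        n_autocorr_spikes=int(counts.sum()),
        isolation_distance=iso,
        isolation_defined=iso_defined,
    )


# ---------------------------------------------------------------------------
# Session-bundle I/O
# ---------------------------------------------------------------------------

def save_session(path, traj: Trajectory, spikes: Sequence[SpikeTrain],
                 trials: Optional[TrialEvents] = None, meta: Optional[dict] = None):
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols = {"t": traj.t, "x": traj.x, "y": traj.y}
    if traj.hd is not None:
        cols["hd"] = traj.hd
    pd.DataFrame(cols).to_csv(path / "trajectory.csv", index=False)
    rows = []
    for st in spikes:
        rows.append(pd.DataFrame({"cell_id": st.cell_id, "time": st.times}))
    pd.concat(rows, ignore_index=True).to_csv(path / "spikes.csv", index=False) \
        if rows else pd.DataFrame(columns=["cell_id", "time"]).to_csv(
            path / "spikes.csv", index=False)
    if trials is not None:
        trials.table.to_csv(path / "trials.csv", index=False)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta or {}, fh)


def load_session(path):
    """Load a session bundle directory; returns (traj, spikes, trials, meta)."""
    path = Path(path)
    tr = pd.read_csv(path / "trajectory.csv")
    traj = Trajectory(tr.t.values, tr.x.values, tr.y.values,
                      tr.hd.values if "hd" in tr.columns else None)
    sp = pd.read_csv(path / "spikes.csv")
    spikes = [SpikeTrain(str(cid), g.time.values)
              for cid, g in sp.groupby("cell_id", sort=True)]
    trials = None
    if (path / "trials.csv").exists():
        trials = TrialEvents(pd.read_csv(path / "trials.csv"))
    meta = {}
    if (path / "meta.yaml").exists():
        with open(path / "meta.yaml") as fh:
            meta = yaml.safe_load(fh) or {}
    return traj, spikes, trials, meta
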
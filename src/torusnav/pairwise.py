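"""Pairwise measures between co-recorded grid cells.

Temporal firing association (Pearson r between instantaneous rates, 100-ms
bins, 100-ms Gaussian smoothing) and spike-triggered cross-firing-rate maps:
the rate of cell B at displacements relative to the animal's position at the
reference spikes of cell A, restricted to a 0.5-s window around each
reference spike and a 10-cm displacement radius. Rotation-correlation curves
compare cross-map sets between conditions under rotation, probing whether
the module's internal phase structure is preserved.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ._utils import masked_smooth2d, smooth1d
from .session_model import SpikeTrain, Trajectory

__all__ = [
    "CrossMap",
    "instantaneous_rate",
    "firing_association",
    "spike_triggered_cross_map",
    "rotation_correlation_curve",
]


@dataclass
class CrossMap:
    edges: np.ndarray
    rate: np.ndarray       # NaN outside the radius / invalid bins
    occupancy: np.ndarray

    def valid(self):
        return np.isfinite(self.rate)


def instantaneous_rate(spikes: SpikeTrain, t_start: float, t_end: float,
                       bin_size: float = 0.1, smooth_sd: float = 0.1):
    """Instantaneous firing rate series (Hz): binned counts, Gaussian smoothed.

    Returns (bin_centers, rate).
    """
    edges = np.arange(t_start, t_end + bin_size / 2, bin_size)
    counts, _ = np.histogram(spikes.times, bins=edges)
    rate = smooth1d(counts / bin_size, smooth_sd / bin_size)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def firing_association(rate_a: np.ndarray, rate_b: np.ndarray) -> float:
    """Pearson correlation between two instantaneous-rate series."""
    a = np.asarray(rate_a, float)
    b = np.asarray(rate_b, float)
    if a.shape != b.shape:
        raise ValueError("rate series must share length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance rate series")
    return float(np.corrcoef(a, b)[0, 1])


def spike_triggered_cross_map(cell_a: SpikeTrain, cell_b: SpikeTrain,
                              traj: Trajectory, window: float = 0.25,
                              radius: float = 10.0, bin_size: float = 1.0,
                              smooth_sd: float = 2.0) -> CrossMap:
    """Firing-rate map of cell B around the reference spikes of cell A.

    For each A-spike at position P_A, B-spikes within +/-``window`` s
    contribute counts at P_B - P_A and trajectory samples within the window
    contribute occupancy at P(t) - P_A. Smoothed counts are divided by
    smoothed occupancy; bins beyond ``radius`` cm are masked.
    """
    if cell_a.n == 0:
        raise ValueError("no reference spikes")
    half = np.ceil(radius / bin_size) * bin_size
    edges = np.arange(-half, half + bin_size / 2, bin_size)
    nb = edges.size - 1
    occ = np.zeros((nb, nb))
    cnt = np.zeros((nb, nb))
    dt = traj.dt
    pos_a = traj.position_at(cell_a.times)

    # occupancy: trajectory samples in the window around each reference spike
    lo = np.searchsorted(traj.t, cell_a.times - window)
    hi = np.searchsorted(traj.t, cell_a.times + window, side="right")
    blocks_x, blocks_y = [], []
    for k in range(cell_a.n):
        blocks_x.append(traj.x[lo[k]:hi[k]] - pos_a[k, 0])
        blocks_y.append(traj.y[lo[k]:hi[k]] - pos_a[k, 1])
    dx = np.concatenate(blocks_x)
    dy = np.concatenate(blocks_y)
    h, _, _ = np.histogram2d(dx, dy, bins=[edges, edges])
    occ += h * dt

    # counts: B spikes in the window around each reference spike
    pos_b = traj.position_at(cell_b.times)
    lo = np.searchsorted(cell_b.times, cell_a.times - window)
    hi = np.searchsorted(cell_b.times, cell_a.times + window, side="right")
    bx, by = [], []
    for k in range(cell_a.n):
        bx.append(pos_b[lo[k]:hi[k], 0] - pos_a[k, 0])
        by.append(pos_b[lo[k]:hi[k], 1] - pos_a[k, 1])
    dbx = np.concatenate(bx) if bx else np.empty(0)
    dby = np.concatenate(by) if by else np.empty(0)
    h, _, _ = np.histogram2d(dbx, dby, bins=[edges, edges])
    cnt += h

    centers = 0.5 * (edges[:-1] + edges[1:])
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    inside = np.hypot(cx, cy) <= radius
    valid = inside & (occ > 0)
    s_occ = masked_smooth2d(occ, valid, smooth_sd / bin_size)
    s_cnt = masked_smooth2d(cnt, valid, smooth_sd / bin_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = s_cnt / s_occ
    rate[~valid] = np.nan
    return CrossMap(edges, rate, occ)


def _rotate_map(values: np.ndarray, angle_deg: float):
    filled = np.nan_to_num(values)
    mask = np.isfinite(values).astype(float)
    rot = ndimage.rotate(filled, angle_deg, reshape=False, order=1)
    rmask = ndimage.rotate(mask, angle_deg, reshape=False, order=1) > 0.99
    out = np.where(rmask, rot, np.nan)
    return out


def rotation_correlation_curve(maps_1: Sequence[CrossMap],
                               maps_2: Sequence[CrossMap],
                               step: float = 10.0,
                               min_pairs: int = 10):
    """Mean map similarity between two conditions after rotating condition 1.

    Rotates each condition-1 cross-map about its center by each angle in
    [0, 360) and correlates it with the matching condition-2 map; returns
    (angles_deg, mean r per angle). Warns when fewer than ``min_pairs`` pairs
    are available.
    """
    if len(maps_1) != len(maps_2):
        raise ValueError("conditions must have matching cell-pair sets")
    if len(maps_1) < min_pairs:
        import warnings
        warnings.warn(f"only {len(maps_1)} pairs (<{min_pairs})", stacklevel=2)
    angles = np.arange(0.0, 360.0, step)
    rs = np.full((len(angles), len(maps_1)), np.nan)
    for j, (m1, m2) in enumerate(zip(maps_1, maps_2)):
        for i, ang in enumerate(angles):
            rot = _rotate_map(m1.rate, ang)
            sel = np.isfinite(rot) & np.isfinite(m2.rate)
            if sel.sum() >= 20 and rot[sel].std() > 0 and m2.rate[sel].std() > 0:
                rs[i, j] = np.corrcoef(rot[sel], m2.rate[sel])[0, 1]
    return angles, np.nanmean(rs, axis=1)
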
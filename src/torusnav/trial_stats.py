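"""Trial matrices, circular statistics and the drift-homing correlation.

A trial matrix holds one row per trial: the firing rate of a cell binned
over a behavioral variable (distance traveled, Y-position, distance to the
lever, time, or direction around the lever), or the density of decoded
directional errors (10-degree bins, max-normalized). The circular mean of a
trial's decoded-error distribution is the decoded trial drift; circular-
circular correlation (Jammalamadaka-SenGupta) between per-trial drift and
homing heading, against a trial-permutation null, tests whether the
module's orientation drift predicts homing behavior.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._utils import circ_mean_resultant, smooth1d, wrap_delta
from .session_model import SpikeTrain, Trajectory

__all__ = [
    "TrialMatrix",
    "trial_matrix",
    "trial_matrix_correlation",
    "decoded_error_trial_matrix",
    "circ_summary",
    "circ_corr",
    "drift_homing_analysis",
]

DEFAULT_BINS = {
    "distance": 2.0,        # cm of path traveled
    "y": 2.0,               # cm
    "lever_distance": 2.0,  # cm
    "time": 0.15,           # s
    "lever_direction": 10.0,  # deg
}


@dataclass
class TrialMatrix:
    values: np.ndarray       # (n_trials, n_bins)
    bin_edges: np.ndarray
    trial_ids: np.ndarray
    variable: str


def _variable_series(traj: Trajectory, sel: np.ndarray, variable: str,
                     lever_xy=None):
    xy = traj.xy()[sel]
    t = traj.t[sel]
    if variable == "distance":
        steps = np.hypot(*np.diff(xy, axis=0).T)
        return np.concatenate([[0.0], np.cumsum(steps)])
    if variable == "y":
        return xy[:, 1]
    if variable == "lever_distance":
        return np.hypot(xy[:, 0] - lever_xy[0], xy[:, 1] - lever_xy[1])
    if variable == "time":
        return t - t[0]
    if variable == "lever_direction":
        return np.rad2deg(np.arctan2(xy[:, 1] - lever_xy[1],
                                     xy[:, 0] - lever_xy[0]))
    raise ValueError(f"unknown variable {variable!r}")


def trial_matrix(traj: Trajectory, spikes: SpikeTrain,
                 intervals: Sequence[tuple[float, float]], variable: str,
                 lever_xy_per_trial: Optional[Sequence] = None,
                 bin_size: Optional[float] = None,
                 smooth_sd_bins: float = 2.0,
                 trial_ids: Optional[Sequence[int]] = None) -> TrialMatrix:
    """Per-trial firing rate binned over a behavioral variable.

    ``intervals`` are (t0, t1) per trial (e.g. search or homing segments);
    rows are smoothed with a Gaussian kernel of ``smooth_sd_bins`` bins.
    Empty rows (no occupancy anywhere) are dropped.
    """
    if bin_size is None:
        bin_size = DEFAULT_BINS[variable]
    dt = traj.dt
    per_trial = []
    for k, (t0, t1) in enumerate(intervals):
        sel = (traj.t >= t0) & (traj.t <= t1)
        if sel.sum() < 2:
            per_trial.append(None)
            continue
        lever = None if lever_xy_per_trial is None else lever_xy_per_trial[k]
        var = _variable_series(traj, sel, variable, lever)
        st = spikes.times[(spikes.times >= t0) & (spikes.times <= t1)]
        svar = np.interp(st, traj.t[sel], var) if st.size else np.empty(0)
        per_trial.append((var, svar))
    lo = min(v.min() for pair in per_trial if pair for v in [pair[0]])
    hi = max(v.max() for pair in per_trial if pair for v in [pair[0]])
    edges = np.arange(np.floor(lo / bin_size) * bin_size,
                      hi + bin_size, bin_size)
    if edges.size < 3:
        edges = np.array([lo, lo + bin_size, lo + 2 * bin_size])
    rows, ids = [], []
    for k, pair in enumerate(per_trial):
        if pair is None:
            continue
        var, svar = pair
        occ = np.histogram(var, bins=edges)[0] * dt
        cnt = np.histogram(svar, bins=edges)[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occ > 0, cnt / occ, np.nan)
        if not np.isfinite(rate).any():
            continue
        sm = smooth1d(np.nan_to_num(rate), smooth_sd_bins)
        sm[~np.isfinite(rate) & (occ == 0)] = np.nan
        rows.append(sm)
        ids.append(k if trial_ids is None else trial_ids[k])
    if not rows:
        raise ValueError("no non-empty trial rows")
    return TrialMatrix(np.vstack(rows), edges, np.asarray(ids), variable)


def trial_matrix_correlation(mat: TrialMatrix | np.ndarray) -> float:
    """Mean pairwise Pearson r between trial rows (off-diagonal),
    over jointly defined bins; pairs without overlap or variance are skipped."""
    values = mat.values if isinstance(mat, TrialMatrix) else np.asarray(mat, float)
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trial rows")
    rs = []
    for i in range(n):
        for j in range(i + 1, n):
            m = np.isfinite(values[i]) & np.isfinite(values[j])
            if m.sum() < 3:
                continue
            a, b = values[i][m], values[j][m]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(np.corrcoef(a, b)[0, 1])
    if not rs:
        raise ValueError("no valid trial pairs")
    return float(np.mean(rs))


def decoded_error_trial_matrix(trial_errors: Sequence[np.ndarray],
                               bin_deg: float = 10.0,
                               smooth_sd_deg: float = 10.0):
    """Per-trial decoded-error densities and decoded trial drifts.

    Each row is the histogram (bins of ``bin_deg`` degrees over (-180, 180])
    of one trial's decoded directional errors, Gaussian-smoothed
    (circularly) and normalized to a maximum of 1; the decoded trial drift
    is the circular mean per row. Empty trials are dropped. Returns
    (TrialMatrix, drifts).
    """
    edges = np.deg2rad(np.arange(-180, 180 + bin_deg / 2, bin_deg))
    rows, drifts, ids = [], [], []
    sigma_bins = smooth_sd_deg / bin_deg
    for k, err in enumerate(trial_errors):
        err = np.asarray(err, float)
        err = err[np.isfinite(err)]
        if err.size == 0:
            continue
        h = np.histogram(wrap_delta(err), bins=edges)[0].astype(float)
        if sigma_bins > 0:  # circular smoothing via wrap-around padding
            nb = h.size
            padded = np.concatenate([h, h, h])
            sm = smooth1d(padded, sigma_bins)[nb:2 * nb]
        else:
            sm = h
        peak = sm.max()
        rows.append(sm / peak if peak > 0 else sm)
        mean, _ = circ_mean_resultant(err)
        drifts.append(mean)
        ids.append(k)
    if not rows:
        raise ValueError("all trials empty")
    mat = TrialMatrix(np.vstack(rows), edges, np.asarray(ids),
                      "decoded_error")
    return mat, np.asarray(drifts)


def circ_summary(angles, weights=None):
    """(circular mean, mean vector length) of a sample of angles."""
    return circ_mean_resultant(angles, weights)


def circ_corr(alpha, beta) -> float:
    """Jammalamadaka-SenGupta circular-circular correlation coefficient."""
    a = np.asarray(alpha, float)
    b = np.asarray(beta, float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need equal-length samples of at least 5 angles")
    ma, _ = circ_mean_resultant(a)
    mb, _ = circ_mean_resultant(b)
    sa = np.sin(a - ma)
    sb = np.sin(b - mb)
    den = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
    if den == 0:
        raise ValueError("degenerate sample: zero angular variance")
    return float((sa * sb).sum() / den)


def drift_homing_analysis(trial_drifts: dict, homing_headings: np.ndarray,
                          n_shuffle: int = 1000, seed: Optional[int] = None,
                          min_trials: int = 10):
    """Does decoded trial drift predict homing direction?

    ``trial_drifts`` maps segment name ('search' | 'at_lever' | 'homing') to
    per-trial drift angles aligned with ``homing_headings``. Per segment the
    circular correlation is compared with a trial-permutation null;
    significant when r exceeds the null's 97.5th percentile. Returns
    {segment: dict(r, null_975, significant, p)}.
    """
    rng = np.random.default_rng(seed)
    heads = np.asarray(homing_headings, float)
    out = {}
    for seg, drifts in trial_drifts.items():
        d = np.asarray(drifts, float)
        ok = np.isfinite(d) & np.isfinite(heads)
        if ok.sum() < min_trials:
            raise ValueError(f"segment {seg!r}: fewer than {min_trials} trials")
        dv, hv = d[ok], heads[ok]
        r = circ_corr(dv, hv)
        null = np.empty(n_shuffle)
        for i in range(n_shuffle):
            null[i] = circ_corr(dv, rng.permutation(hv))
        thr = float(np.percentile(null, 97.5))
        p = float((null >= r).mean())
        out[seg] = dict(r=r, null_975=thr, significant=bool(r > thr), p=p)
    return out
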
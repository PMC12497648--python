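"""Movement reconstruction from decoded torus paths and drift statistics.

Per-step wrapped torus deltas are mapped to Cartesian movement vectors; their
cumulative sum anchored at the real starting position is the reconstructed
path. The decoded directional error is the signed angle between each decoded
movement vector and the animal's real movement vector; the mean vector
length (MVL) of the error distribution is the directional precision, its
circular mean the module rotation (or, per trial, the decoded trial drift).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._utils import circ_mean_resultant, wrap_delta
from .torus import ModuleGeometry, TorusPath, path_deltas, torus_delta_to_cartesian

__all__ = [
    "AngularErrorSet",
    "decoded_movement",
    "directional_errors",
    "shuffle_precision_null",
    "rotation_correction",
    "apply_rotation",
    "cumulative_decoding_error",
    "lever_vs_matched_drift",
]


@dataclass
class AngularErrorSet:
    """Per-sample decoded directional errors with summary statistics."""

    errors: np.ndarray   # (n,) rad in (-pi, pi], NaN where masked out
    mask: np.ndarray

    @property
    def masked(self) -> np.ndarray:
        return self.errors[self.mask]

    @property
    def precision(self) -> float:
        """Directional precision: MVL of the masked error distribution."""
        _, mvl = circ_mean_resultant(self.masked)
        return mvl

    @property
    def rotation(self) -> float:
        """Module rotation: circular mean of the masked errors."""
        mean, _ = circ_mean_resultant(self.masked)
        return mean


def decoded_movement(path: TorusPath, geom: ModuleGeometry, real_start):
    """Cartesian movement vectors and reconstructed path from a torus path.

    Returns (vectors (n-1, 2) cm, reconstructed path (n, 2) cm); the path is
    the cumulative sum of the vectors anchored at ``real_start``.
    """
    dv = path_deltas(path)
    vec = torus_delta_to_cartesian(dv, geom)
    real_start = np.asarray(real_start, dtype=float)
    recon = np.vstack([real_start, real_start + np.cumsum(vec, axis=0)])
    return vec, recon


def directional_errors(decoded_vec: np.ndarray, real_vec: np.ndarray,
                       mask: Optional[np.ndarray] = None) -> AngularErrorSet:
    """Signed angle between decoded and real movement vectors per sample."""
    decoded_vec = np.asarray(decoded_vec, float)
    real_vec = np.asarray(real_vec, float)
    if decoded_vec.shape != real_vec.shape:
        raise ValueError("vector series must be aligned")
    ang_d = np.arctan2(decoded_vec[:, 1], decoded_vec[:, 0])
    ang_r = np.arctan2(real_vec[:, 1], real_vec[:, 0])
    err = wrap_delta(ang_d - ang_r)
    if mask is None:
        mask = np.ones(err.size, dtype=bool)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(err) \
        & (np.hypot(real_vec[:, 0], real_vec[:, 1]) > 0)
    if not mask.any():
        raise ValueError("empty mask: no samples to evaluate")
    return AngularErrorSet(err, mask)


def shuffle_precision_null(decoded_vec: np.ndarray, real_vec: np.ndarray,
                           mask: np.ndarray, dt: float, n: int = 1000,
                           min_shift: float = 20.0,
                           seed: Optional[int] = None):
    """Null precision distribution from circular time-shifts of the decoding.

    The decoded vectors are circularly shifted relative to the real ones by a
    uniform amount in [min_shift, T - min_shift]; the MVL of each shuffled
    error set forms the null. Returns (null MVLs, 95th percentile).
    """
    decoded_vec = np.asarray(decoded_vec, float)
    real_vec = np.asarray(real_vec, float)
    nsamp = decoded_vec.shape[0]
    T = nsamp * dt
    if T < 2 * min_shift:
        raise ValueError("series shorter than twice the minimum shift")
    rng = np.random.default_rng(seed)
    ang_d = np.arctan2(decoded_vec[:, 1], decoded_vec[:, 0])
    ang_r = np.arctan2(real_vec[:, 1], real_vec[:, 0])
    mask = np.asarray(mask, dtype=bool)
    null = np.empty(n)
    for i in range(n):
        s = int(rng.uniform(min_shift, T - min_shift) / dt)
        err = wrap_delta(np.roll(ang_d, s) - ang_r)[mask]
        null[i] = np.abs(np.exp(1j * err).mean())
    return null, float(np.percentile(null, 95))


def rotation_correction(error_sets, mode: str = "session",
                        min_samples: int = 50):
    """Rotation correction angles from decoded-error distributions.

    ``mode='session'``: one correction per condition (the circular mean of
    the pooled errors of that condition); ``mode='trial'``: one correction
    per trial. ``error_sets`` maps condition (or trial) keys to
    :class:`AngularErrorSet`. Conditions with fewer than ``min_samples``
    masked samples are skipped (returned as NaN).
    """
    if mode not in ("session", "trial"):
        raise ValueError("mode must be 'session' or 'trial'")
    out = {}
    for key, es in error_sets.items():
        if es.mask.sum() < min_samples and mode == "session":
            out[key] = np.nan
            continue
        out[key] = es.rotation
    return out


def apply_rotation(vectors: np.ndarray, angle: float) -> np.ndarray:
    """Rotate movement vectors by ``angle`` (subtracting an estimated module
    rotation is equivalent to rerunning the decoder with rotated grid axes)."""
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return np.asarray(vectors, float) @ R.T


def cumulative_decoding_error(trials: Sequence[dict], rel_grid: np.ndarray):
    """Mean Euclidean position error vs time relative to an alignment event.

    Each trial dict carries ``t`` (s), ``recon`` (n, 2), ``real`` (n, 2) and
    ``t_event`` (s, e.g. lever contact); reconstructions are assumed to be
    restarted at the journey start. Trials without an event are skipped.
    Returns (rel_grid, mean error, n_trials per grid point).
    """
    rel_grid = np.asarray(rel_grid, float)
    acc = np.zeros(rel_grid.size)
    cnt = np.zeros(rel_grid.size)
    for tr in trials:
        if tr.get("t_event") is None or not np.isfinite(tr["t_event"]):
            continue
        t = np.asarray(tr["t"], float) - tr["t_event"]
        err = np.hypot(*(np.asarray(tr["recon"]) - np.asarray(tr["real"])).T)
        sel = (rel_grid >= t[0]) & (rel_grid <= t[-1])
        acc[sel] += np.interp(rel_grid[sel], t, err)
        cnt[sel] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    return rel_grid, mean, cnt


def lever_vs_matched_drift(trials: Sequence[dict]):
    """Per-trial difference between at-lever drift and distance-matched drift.

    Each trial dict carries ``search_err`` (masked errors during search, in
    path order), ``search_len`` (cumulative path length at those samples),
    ``lever_err`` (errors at the lever) and ``lever_len`` (path length
    traveled at the lever). The matched segment is the final stretch of the
    search whose path length equals the at-lever path length. Trials whose
    search is shorter than the at-lever stretch are skipped. A distribution
    centered on zero indicates translation-only (rotation-free) reanchoring.
    """
    diffs = []
    for tr in trials:
        s_err = np.asarray(tr["search_err"], float)
        s_len = np.asarray(tr["search_len"], float)
        l_err = np.asarray(tr["lever_err"], float)
        L = float(tr["lever_len"])
        if s_err.size == 0 or l_err.size == 0:
            continue
        total = s_len[-1]
        if total < L:
            continue
        seg = s_err[s_len >= total - L]
        if seg.size == 0:
            continue
        m_lever, _ = circ_mean_resultant(l_err)
        m_match, _ = circ_mean_resultant(seg)
        diffs.append(wrap_delta(m_lever - m_match))
    return np.asarray(diffs)
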
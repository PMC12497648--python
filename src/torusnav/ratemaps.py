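"""Firing-rate maps, spatial autocorrelation, grid score and related measures.

Rate maps bin the arena into 3x3-cm bins; spike-count and occupancy maps are
smoothed independently with a 5-cm Gaussian kernel (renormalized over valid
bins at the arena boundary) and divided. The spatial autocorrelation is the
Pearson correlation of the map with itself at every displacement, using
overlapping valid bins only. The grid score compares annulus correlations at
60/120-degree rotations against 30/90/150 degrees; cells are classified as
grid cells when their score exceeds the 95th percentile of scores obtained
after circular time-shifts of the position data (minimum shift 20 s).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from ._utils import masked_smooth2d
from .session_model import SpikeTrain, Trajectory

__all__ = [
    "RateMap",
    "GridMetrics",
    "rate_map",
    "spatial_autocorrelation",
    "detect_autocorr_fields",
    "grid_metrics",
    "grid_score",
    "classify_grid",
    "information_score",
    "map_similarity",
]


@dataclass
class RateMap:
    x_edges: np.ndarray
    y_edges: np.ndarray
    rate: np.ndarray        # (nx, ny) Hz, NaN where invalid
    occupancy: np.ndarray   # (nx, ny) seconds (unsmoothed)
    valid: np.ndarray

    @property
    def bin_size(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])

    def bin_centers(self):
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return cx, cy


def rate_map(traj: Trajectory, spikes: SpikeTrain, bin_size: float = 3.0,
             smooth_sd: float = 5.0, arena_radius: Optional[float] = None,
             speed_min: Optional[float] = None) -> RateMap:
    """Occupancy-normalized firing-rate map.

    Spike positions are interpolated from the trajectory at spike times. Both
    the spike-count and occupancy maps are smoothed (Gaussian, ``smooth_sd``
    cm, kernel renormalized over valid bins) before division. An empty spike
    train yields an all-zero map.
    """
    if arena_radius is None:
        arena_radius = float(np.hypot(traj.x, traj.y).max()) + 1e-9
    half = (np.ceil(arena_radius / bin_size)) * bin_size
    edges = np.arange(-half, half + bin_size / 2, bin_size)
    dt = traj.dt

    m = np.ones(traj.t.size, dtype=bool)
    if speed_min is not None:
        speed = traj.speed if traj.speed is not None else None
        if speed is None:
            from .session_model import compute_speed
            speed = compute_speed(traj)
        m &= speed > speed_min

    occ, _, _ = np.histogram2d(traj.x[m], traj.y[m], bins=[edges, edges])
    occ *= dt
    st = spikes.in_interval(traj.t[0], traj.t[-1] + dt)
    if st.n:
        pos = traj.position_at(st.times)
        if speed_min is not None:
            sp = np.interp(st.times, traj.t, speed)
            keep = sp > speed_min
            pos = pos[keep]
        cnt, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=[edges, edges])
    else:
        cnt = np.zeros_like(occ)

    valid = occ > 0
    s_occ = masked_smooth2d(occ, valid, smooth_sd / bin_size)
    s_cnt = masked_smooth2d(cnt, valid, smooth_sd / bin_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = s_cnt / s_occ
    rate[~valid] = np.nan
    return RateMap(edges, edges, rate, occ, valid)


def spatial_autocorrelation(rmap: RateMap, min_overlap: int = 20) -> np.ndarray:
    """2D spatial autocorrelation (Pearson r at each displacement).

    For each lag, r is computed over the bins where both copies of the map are
    valid; lags with fewer than ``min_overlap`` overlapping bins are NaN. The
    output has shape (2*nx-1, 2*ny-1) with r = 1 at the center.
    """
    a = rmap.rate if isinstance(rmap, RateMap) else np.asarray(rmap, float)
    valid = np.isfinite(a)
    if valid.sum() < min_overlap:
        raise ValueError("too few valid bins for autocorrelation")
    x = np.where(valid, a, 0.0)
    m = valid.astype(float)

    def corr(u, v):
        return fftconvolve(u, v[::-1, ::-1], mode="full")

    n = corr(m, m)
    sx = corr(x, m)
    sy = corr(m, x)
    sxy = corr(x, x)
    sxx = corr(x * x, m)
    syy = corr(m, x * x)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx ** 2) * (n * syy - sy ** 2))
        r = num / den
    r[np.round(n) < min_overlap] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return r


@dataclass
class GridMetrics:
    score: float
    periodicity_angles: np.ndarray
    periodicity: np.ndarray
    annulus: np.ndarray          # boolean mask on the autocorrelation
    n_fields: int


def detect_autocorr_fields(ac: np.ndarray, threshold: float = 0.1):
    """Detect fields of an autocorrelation around its central peak.

    The central field's extent is the thresholded component covering the
    center, capped at the first minimum of the radial correlation profile
    (the component can merge with the inner ring through positive bridges).
    Fields are the connected components of ``ac > threshold`` outside the
    central field; each is summarized by its peak position and mean pixel
    radius. Returns (inner_radius_bins, list of
    (dist_bins, angle_rad, comp_radius_bins, peak_value)).
    """
    thr_mask = np.nan_to_num(ac) > threshold
    ci, cj = np.array(ac.shape) // 2
    yy, xx = np.indices(ac.shape)
    rr = np.hypot(yy - ci, xx - cj)
    lab, _ = ndimage.label(thr_mask)
    center_lab = lab[ci, cj]
    inner = rr[lab == center_lab].max() if center_lab else 0.0
    rmax = int(rr[np.isfinite(ac)].max())
    prof = np.array([np.nanmean(ac[(rr >= k) & (rr < k + 1)])
                     for k in range(max(rmax, 2))])
    for k in range(1, prof.size - 1):
        if np.isfinite(prof[k]) and prof[k] <= prof[k - 1] \
                and prof[k] <= prof[k + 1]:
            inner = min(inner, float(k))
            break

    # exclude the outermost band of the valid region, where correlations are
    # computed from marginal overlaps and run high regardless of structure
    rmax_valid = rr[np.isfinite(ac)].max()
    lab, nlab = ndimage.label(thr_mask & (rr > inner) & (rr <= rmax_valid - 2))
    peaks = []
    for l in range(1, nlab + 1):
        mask = lab == l
        vals = np.nan_to_num(ac)[mask]
        # value-weighted centroid: robust against inflated correlations at
        # the sparse-overlap edge of the valid region
        w = vals / vals.sum()
        py = float((yy[mask] * w).sum())
        px = float((xx[mask] * w).sum())
        dist = float(np.hypot(py - ci, px - cj))
        ang = float(np.arctan2(px - cj, py - ci))  # array axis 0 = x
        comp_r = float(np.hypot(yy[mask] - py, xx[mask] - px).mean())
        peaks.append((dist, ang, comp_r, float(vals.max())))
    peaks.sort(key=lambda q: q[0])
    return inner, peaks


def _ring(ac, inner, outer):
    yy, xx = np.indices(ac.shape)
    ci, cj = np.array(ac.shape) // 2
    rr = np.hypot(yy - ci, xx - cj)
    return (rr > inner) & (rr <= outer)


def _annulus_from_fields(ac: np.ndarray, threshold: float = 0.1,
                         fallback: bool = False):
    """Annulus containing the six inner fields, excluding the central field.

    With ``fallback`` and fewer than six detected fields, a default annulus
    from the central-field radius out to the reliable part of the valid
    region is returned instead of None, so that a (low) score can still be
    computed — required for shuffle nulls, where conditioning on detectable
    six-field structure would bias the null toward hexagon-like noise.
    """
    inner, peaks = detect_autocorr_fields(ac, threshold)
    n_fields = len(peaks)
    if n_fields < 6:
        if not fallback:
            return None, n_fields
        yy, xx = np.indices(ac.shape)
        ci, cj = np.array(ac.shape) // 2
        rr = np.hypot(yy - ci, xx - cj)
        outer = rr[np.isfinite(ac)].max() - 2
        return _ring(ac, inner, outer), n_fields
    six = peaks[:6]
    outer = six[-1][0] + six[-1][2]
    return _ring(ac, inner, outer), n_fields


def _rotated_correlations(ac: np.ndarray, annulus: np.ndarray, angles_deg):
    filled = np.nan_to_num(ac)
    vmask = np.isfinite(ac)
    base = ac[annulus & vmask]
    out = np.empty(len(angles_deg))
    for i, ang in enumerate(angles_deg):
        rot = ndimage.rotate(filled, ang, reshape=False, order=1)
        rmask = ndimage.rotate(vmask.astype(float), ang, reshape=False,
                               order=1) > 0.99
        sel = annulus & vmask & rmask
        u, v = ac[sel], rot[sel]
        if u.size < 20 or u.std() == 0 or v.std() == 0:
            out[i] = np.nan
        else:
            out[i] = np.corrcoef(u, v)[0, 1]
    return out


def grid_metrics(ac: np.ndarray, threshold: float = 0.1,
                 form: str = "difference",
                 periodicity_step: float = 2.0,
                 compute_periodicity: bool = True,
                 annulus_fallback: bool = False) -> GridMetrics:
    """Grid score and rotational periodicity curve of an autocorrelation.

    The annulus containing the six inner fields (excluding the central field)
    is correlated with rotated copies of itself. Score (``form='difference'``,
    the default) = mean(r60, r120) - mean(r30, r90, r150); ``form='ratio'``
    divides instead. Fewer than six detectable fields raises (score undefined,
    distinct from a low score). The periodicity curve spans 0-180 degrees in
    ``periodicity_step`` steps.
    """
    annulus, n_fields = _annulus_from_fields(ac, threshold,
                                             fallback=annulus_fallback)
    if annulus is None:
        raise ValueError(f"fewer than 6 fields detected ({n_fields})")
    r = _rotated_correlations(ac, annulus, [30, 60, 90, 120, 150])
    if np.all(np.isnan(r[[1, 3]])) or np.all(np.isnan(r[[0, 2, 4]])):
        raise ValueError("rotated annulus correlations undefined")
    with np.errstate(invalid="ignore"):
        on = np.nanmean([r[1], r[3]])
        off = np.nanmean([r[0], r[2], r[4]])
    score = on - off if form == "difference" else on / off
    if compute_periodicity:
        angles = np.arange(0.0, 180.0 + periodicity_step / 2, periodicity_step)
        curve = _rotated_correlations(ac, annulus, angles)
    else:
        angles = np.empty(0)
        curve = np.empty(0)
    return GridMetrics(float(score), angles, curve, annulus, n_fields)


def grid_score(traj: Trajectory, spikes: SpikeTrain, form: str = "difference",
               annulus_fallback: bool = True, **map_kwargs) -> float:
    """Grid score of one cell (NaN when undefined).

    By default a fallback annulus is used when six fields are not
    detectable, so that weakly structured maps receive a low score rather
    than no score (the convention the shuffle classification requires).
    """
    rm = rate_map(traj, spikes, **map_kwargs)
    try:
        ac = spatial_autocorrelation(rm)
        return grid_metrics(ac, form=form, compute_periodicity=False,
                            annulus_fallback=annulus_fallback).score
    except ValueError:
        return np.nan


def classify_grid(traj: Trajectory, spikes: SpikeTrain, n_shuffle: int = 500,
                  min_shift: float = 20.0, pct: float = 95.0,
                  seed: Optional[int] = None, form: str = "difference",
                  **map_kwargs):
    """Shuffle-based grid-cell classification on one (foraging) trial.

    The spike train is circularly time-shifted relative to the positions by a
    random amount in [min_shift, T - min_shift], ``n_shuffle`` times; the
    cell is a grid cell when its observed score exceeds the ``pct``-th
    percentile of the shuffled scores. Returns
    (threshold, is_grid, observed_score, shuffled_scores). If the score is
    undefined on more than half of the shuffles *and* on the observed data,
    the cell is not classifiable (is_grid False, threshold NaN).
    """
    T = traj.duration
    if T < 2 * min_shift:
        raise ValueError("session shorter than twice the minimum shift")
    rng = np.random.default_rng(seed)
    bin_size = map_kwargs.get("bin_size", 3.0)
    smooth_sd = map_kwargs.get("smooth_sd", 5.0)
    base = rate_map(traj, spikes, **map_kwargs)
    valid = base.valid
    s_occ = masked_smooth2d(base.occupancy, valid, smooth_sd / bin_size)
    edges = [base.x_edges, base.y_edges]
    t0 = traj.t[0]

    def score_for(times):
        pos = traj.position_at(times)
        cnt, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=edges)
        s_cnt = masked_smooth2d(cnt, valid, smooth_sd / bin_size)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = s_cnt / s_occ
        rate[~valid] = np.nan
        try:
            ac = spatial_autocorrelation(rate)
            return grid_metrics(ac, form=form, compute_periodicity=False,
                                annulus_fallback=True).score
        except ValueError:
            return np.nan

    obs = score_for(spikes.in_interval(traj.t[0], traj.t[-1] + traj.dt).times)
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        shift = rng.uniform(min_shift, T - min_shift)
        null[i] = score_for(np.mod(spikes.times - t0 + shift, T) + t0)
    defined = np.isfinite(null)
    if not np.isfinite(obs) or defined.sum() < n_shuffle / 2:
        # undefined score: either no six-field structure in the observed map
        # or the null cannot be formed — not a grid cell either way
        thr = np.nanpercentile(null, pct) if defined.any() else np.nan
        return thr, False, obs, null
    thr = float(np.percentile(null[defined], pct))
    return thr, bool(obs > thr), obs, null


def information_score(rates: np.ndarray, occupancy_p: np.ndarray) -> float:
    """Spatial information (bits/spike) of an unsmoothed rate histogram.

    sum_i p_i * (lambda_i / lambda) * log2(lambda_i / lambda), with
    0 * log 0 = 0 and lambda the occupancy-weighted mean rate.
    """
    lam_i = np.asarray(rates, dtype=float)
    p = np.asarray(occupancy_p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("occupancy probabilities must sum to 1")
    lam = float((p * lam_i).sum())
    if lam <= 0:
        raise ValueError("mean rate is zero; information undefined")
    ratio = lam_i / lam
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(ratio > 0, p * ratio * np.log2(ratio), 0.0)
    return float(term.sum())


def map_similarity(map_a: RateMap, map_b: RateMap, min_overlap: int = 20) -> float:
    """Pearson r between two rate maps over jointly valid bins."""
    a, b = map_a.rate, map_b.rate
    if a.shape != b.shape:
        raise ValueError("maps must share binning")
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < min_overlap:
        raise ValueError("insufficient overlapping valid bins")
    return float(np.corrcoef(a[m], b[m])[0, 1])
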
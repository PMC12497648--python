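"""Two-stage gradient-descent fit of the grid rate model per cell.

Stage 1 constrains the lattice to perfect 60-degree periodicity (axes theta,
theta + 60, theta + 120 degrees, equal periods); stage 2 releases all three
axis directions and periods independently, initialized from stage 1. Both
stages minimize the mean squared error between the model rate and a target
instantaneous-rate series with Adam. Module geometry is the per-axis median
across simultaneously recorded grid cells after resolving the 60-degree axis
labeling ambiguity against a reference cell.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._optim import Adam
from ._utils import wrap_delta, wrap_pos
from .ratemaps import RateMap, spatial_autocorrelation
from .synthetic_session import GridModel, grid_rate
from .torus import ModuleGeometry

__all__ = [
    "init_from_autocorr",
    "fit_grid_model",
    "fit_cell",
    "module_geometry",
]


# ---------------------------------------------------------------------------
# Initialization from the autocorrelation
# ---------------------------------------------------------------------------

def init_from_autocorr(rmap: RateMap, threshold: float = 0.1) -> GridModel:
    """Initial grid-model guess from a rate map and its autocorrelation.

    Axis directions and periods come from the six inner autocorrelation
    peaks (three peaks with angle in [0, 180) degrees); the peak rate from
    the map maximum; the phase offsets from the field peak nearest the arena
    center.
    """
    ac = spatial_autocorrelation(rmap)
    from .ratemaps import detect_autocorr_fields
    _, peaks = detect_autocorr_fields(ac, threshold)
    if len(peaks) < 6:
        raise ValueError("cannot initialize: fewer than six fields")
    six = [(d * rmap.bin_size, ang) for d, ang, _, _ in peaks[:6]]
    dists = np.array([d for d, _ in six])
    if dists.max() > 1.5 * dists.min():
        raise ValueError("cannot initialize: inner fields do not form a ring")
    ax = sorted([(np.mod(ang, np.pi), dist) for dist, ang in six])
    # pair opposite peaks: take the three smallest distinct axis angles
    chosen = []
    for ang, dist in ax:
        if all(abs(wrap_delta(2 * (ang - a))) > np.deg2rad(20) for a, _ in chosen):
            chosen.append((ang, dist))
        if len(chosen) == 3:
            break
    if len(chosen) < 3:
        raise ValueError("cannot identify three grid axes")
    axang = np.sort([a for a, _ in chosen])
    gaps = np.array([axang[1] - axang[0], axang[2] - axang[1],
                     np.pi - (axang[2] - axang[0])])
    if np.any(np.abs(gaps - np.pi / 3) > np.deg2rad(10)):
        raise ValueError("cannot initialize: axes are not 60 degrees apart")
    # autocorrelation peaks lie along the lattice vectors, which sit 30
    # degrees from the cosine-model axis directions and at distance
    # 2 p / sqrt(3) (the lattice constant); invert both relations
    ang = np.mod(np.array([a for a, _ in chosen]) - np.pi / 6, np.pi)
    dist = np.array([d for _, d in chosen]) * (np.sqrt(3) / 2)
    order = np.argsort(ang)
    theta = ang[order]
    p = dist[order]

    rate = rmap.rate
    pr = float(np.nanmax(rate))
    # offsets: phase of the field peak nearest the center of the arena
    cx, cy = rmap.bin_centers()
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    finite = np.isfinite(rate)
    cand = finite & (rate > 0.8 * pr)
    if not cand.any():
        raise ValueError("cannot initialize offsets: uniform map")
    rr = np.where(cand, np.hypot(gx, gy), np.inf)
    k = np.unravel_index(np.argmin(rr), rr.shape)
    peak_xy = np.array([gx[k], gy[k]])
    u = np.column_stack([np.cos(theta), np.sin(theta)])
    o = wrap_pos(peak_xy @ u.T / p * 2 * np.pi)
    return GridModel(theta, p, o, pr)


# ---------------------------------------------------------------------------
# Gradient fit
# ---------------------------------------------------------------------------

def _model_rate_and_grads(xy, theta, p, o, pr):
    """Rate and analytic gradients of the rectified three-cosine model."""
    u = np.column_stack([np.cos(theta), np.sin(theta)])          # (3,2)
    d = xy @ u.T                                                 # (n,3)
    a = d / p * 2 * np.pi
    phase = a - o
    g = (np.cos(phase).sum(axis=1) + 1.5) / 4.5 * pr
    r = np.maximum(g, 0.0)
    act = (g > 0).astype(float)                                  # ReLU gate
    sin_ph = np.sin(phase)
    dg_da = -pr / 4.5 * sin_ph                                   # (n,3)
    da_dtheta = (2 * np.pi / p) * (-xy[:, :1] * np.sin(theta) +
                                   xy[:, 1:2] * np.cos(theta))   # (n,3)
    da_dp = -a / p
    return r, g, act, dg_da, da_dtheta, da_dp


def fit_grid_model(xy: np.ndarray, target: np.ndarray, init: GridModel,
                   stage: str = "constrained", lr: float = 0.01,
                   n_iter: int = 2000, tol: float = 1e-6,
                   patience: int = 10) -> tuple[GridModel, float]:
    """Fit the grid model to a target rate series by Adam on the MSE loss.

    ``stage='constrained'`` optimizes (theta, p, o0..o2, pr) with axes
    theta + {0, 60, 120} degrees and equal periods; ``stage='free'`` releases
    all theta_i and p_i. Returns (model at best loss, best loss). Training
    stops early when the relative loss change stays below ``tol`` for
    ``patience`` consecutive iterations; a non-finite loss raises.
    """
    xy = np.asarray(xy, dtype=float)
    y = np.asarray(target, dtype=float)
    if xy.shape[0] != y.shape[0]:
        raise ValueError("target must align with trajectory samples")
    n = y.size
    constrained = stage == "constrained"
    if constrained:
        theta0 = np.array([init.theta[0]])
        p0 = np.array([init.p.mean()])
    else:
        theta0 = init.theta.copy()
        p0 = init.p.copy()
    params = [theta0.copy(), p0.copy(), init.o.copy(),
              np.array([float(init.pr)])]
    opt = Adam(params, lr=lr)
    best = (np.inf, None)
    prev_loss = np.inf
    calm = 0
    offsets = np.array([0.0, np.pi / 3, 2 * np.pi / 3])
    for it in range(n_iter):
        th, pp, oo, prr = params
        theta = th[0] + offsets if constrained else th
        p = np.full(3, pp[0]) if constrained else pp
        pr = prr[0]
        r, g, act, dg_da, da_dtheta, da_dp = _model_rate_and_grads(
            xy, theta, p, oo, pr)
        resid = r - y
        loss = float(np.mean(resid ** 2))
        if not np.isfinite(loss):
            raise RuntimeError("grid-model fit diverged (non-finite loss)")
        if loss < best[0]:
            best = (loss, [q.copy() for q in params])
        dL_dg = (2.0 / n) * resid * act                          # (n,)
        grad_theta3 = (dL_dg[:, None] * dg_da * da_dtheta).sum(axis=0)
        grad_p3 = (dL_dg[:, None] * dg_da * da_dp).sum(axis=0)
        grad_o = -(dL_dg[:, None] * dg_da).sum(axis=0)
        grad_pr = float((dL_dg * (g / pr if pr != 0 else g)).sum())
        if constrained:
            grads = [np.array([grad_theta3.sum()]), np.array([grad_p3.sum()]),
                     grad_o, np.array([grad_pr])]
        else:
            grads = [grad_theta3, grad_p3, grad_o, np.array([grad_pr])]
        opt.step(grads)
        params[1][:] = np.maximum(params[1], 1.0)  # keep periods positive
        rel = abs(prev_loss - loss) / max(loss, 1e-12)
        calm = calm + 1 if rel < tol else 0
        if calm >= patience:
            break
        prev_loss = loss
    loss, (th, pp, oo, prr) = best
    if constrained:
        theta = th[0] + offsets
        p = np.full(3, pp[0])
    else:
        theta, p = th, pp
    return GridModel(wrap_pos(theta), p, wrap_pos(oo), float(max(prr[0], 0.0))), loss


def fit_cell(xy: np.ndarray, target: np.ndarray, init: GridModel,
             **kwargs) -> tuple[GridModel, float]:
    """Run the two stages sequentially (constrained then free)."""
    m1, _ = fit_grid_model(xy, target, init, stage="constrained", **kwargs)
    m2, loss2 = fit_grid_model(xy, target, m1, stage="free", **kwargs)
    return m2, loss2


# ---------------------------------------------------------------------------
# Module geometry
# ---------------------------------------------------------------------------

def _align_to(ref_theta0: float, theta: np.ndarray) -> np.ndarray:
    """Shift axis labels by multiples of 60 degrees to match a reference."""
    k = np.round(wrap_delta(theta[0] - ref_theta0) / (np.pi / 3))
    return theta - k * np.pi / 3


def module_geometry(models: Sequence[GridModel]) -> ModuleGeometry:
    """Median module geometry across >= 5 co-recorded grid cells.

    Each cell's axes are aligned to the first cell (wrapping theta modulo the
    60-degree lattice ambiguity) before taking elementwise medians of
    theta0, theta1, p0 and p1.
    """
    if len(models) < 5:
        raise ValueError("module geometry requires at least five grid cells")
    ref = models[0].theta[0]
    th0, th1, p0, p1 = [], [], [], []
    for m in models:
        th = _align_to(ref, m.theta)
        th0.append(ref + wrap_delta(th[0] - ref))
        th1.append(ref + np.pi / 3 + wrap_delta(th[1] - (ref + np.pi / 3)))
        p0.append(m.p[0])
        p1.append(m.p[1])
    return ModuleGeometry(np.median(th0), np.median(th1),
                          np.median(p0), np.median(p1))
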
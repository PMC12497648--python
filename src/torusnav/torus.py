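"""Coordinate transforms between Cartesian arena space and toroidal module space.

A grid module defines two axes (directions theta0, theta1; periods p0, p1 in
cm). Position along each axis, expressed as a phase v_i = d_i / p_i * 2*pi,
lives on a circle, so the module's representation of 2D position is a point
on a torus. Angle conventions: positions are wrapped to [0, 2*pi), deltas to
(-pi, pi].
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import wrap_delta, wrap_pos

__all__ = [
    "ModuleGeometry",
    "TorusPath",
    "to_torus",
    "torus_delta_to_cartesian",
    "cartesian_to_torus_delta",
]


@dataclass
class ModuleGeometry:
    """Shared lattice geometry of a grid module (two axes used downstream)."""

    theta0: float
    theta1: float
    p0: float
    p1: float

    def __post_init__(self):
        if self.p0 <= 0 or self.p1 <= 0:
            raise ValueError("periods must be positive")
        self.theta0 = float(np.mod(self.theta0, 2 * np.pi))
        self.theta1 = float(np.mod(self.theta1, 2 * np.pi))
        if abs(np.sin(self.theta0 - self.theta1)) < 1e-9:
            raise ValueError("degenerate geometry: axes are parallel")

    @property
    def axes(self) -> np.ndarray:
        """2x2 matrix of unit axis vectors (rows)."""
        return np.array([
            [np.cos(self.theta0), np.sin(self.theta0)],
            [np.cos(self.theta1), np.sin(self.theta1)],
        ])

    @property
    def periods(self) -> np.ndarray:
        return np.array([self.p0, self.p1])


@dataclass
class TorusPath:
    """Decoded or true path on the module torus (angles wrapped to [0, 2*pi))."""

    t: np.ndarray
    v0: np.ndarray
    v1: np.ndarray
    source: str = "true"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v0 = wrap_pos(np.asarray(self.v0, dtype=float))
        self.v1 = wrap_pos(np.asarray(self.v1, dtype=float))
        if self.t.shape != self.v0.shape or self.t.shape != self.v1.shape:
            raise ValueError("t, v0, v1 must share shape")

    def angles(self) -> np.ndarray:
        return np.column_stack([self.v0, self.v1])


def to_torus(xy, geom: ModuleGeometry):
    """Map Cartesian position(s) (cm) to torus angles (v0, v1) in [0, 2*pi).

    v_i = (xy . u_i) / p_i * 2*pi where u_i is the unit vector along axis i.
    """
    xy = np.asarray(xy, dtype=float)
    single = xy.ndim == 1
    xy = np.atleast_2d(xy)
    d = xy @ geom.axes.T                      # (n, 2) positions along axes
    v = wrap_pos(d / geom.periods * 2 * np.pi)
    return v[0] if single else v


def torus_delta_to_cartesian(dv, geom: ModuleGeometry):
    """Map wrapped torus deltas (dv0, dv1) to a Cartesian movement (dx, dy) in cm.

    The per-axis displacement d_i = dv_i / (2*pi) * p_i; the Cartesian vector m
    solves u_i . m = d_i for both axes (unique when the axes are independent).
    Unambiguous only for |dv_i| < pi, i.e. steps below half a period.
    """
    dv = np.asarray(dv, dtype=float)
    single = dv.ndim == 1
    dv = np.atleast_2d(dv)
    d = dv / (2 * np.pi) * geom.periods
    m = np.linalg.solve(geom.axes, d.T).T
    return m[0] if single else m


def cartesian_to_torus_delta(dxy, geom: ModuleGeometry):
    """Map a Cartesian movement (cm) to wrapped torus deltas in (-pi, pi]."""
    dxy = np.asarray(dxy, dtype=float)
    single = dxy.ndim == 1
    dxy = np.atleast_2d(dxy)
    d = dxy @ geom.axes.T
    dv = wrap_delta(d / geom.periods * 2 * np.pi)
    return dv[0] if single else dv


def path_deltas(path: TorusPath) -> np.ndarray:
    """Wrapped per-step deltas (n-1, 2) of a torus path."""
    dv0 = wrap_delta(np.diff(path.v0))
    dv1 = wrap_delta(np.diff(path.v1))
    return np.column_stack([dv0, dv1])
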
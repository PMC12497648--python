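"""Reference-frame anchoring of the decoded torus representation.

To infer where an object (the movable lever, or the fixed bridge) sits on
the module torus, the Cartesian vector from the animal to the object is
transformed into toroidal space and added to the decoded position of the
animal on the torus. If the module is anchored to the object, the inferred
object position clusters on the torus across trials even when the object
moves in the room. Concentration is quantified by fitting a bivariate von
Mises distribution (two independent circular marginals); the mean of the two
concentration parameters (k0 + k1)/2 is the anchoring strength (0 for a
uniform distribution). Significance comes from a shuffle in which each
trial's decoded path is rigidly translated to a random position on the
torus.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import circ_mean_resultant, wrap_pos
from .torus import ModuleGeometry, TorusPath, cartesian_to_torus_delta

__all__ = [
    "AnchoringFit",
    "object_torus_positions",
    "fit_bivariate_von_mises",
    "shuffle_anchoring_null",
    "anchoring_timecourse",
]


@dataclass
class AnchoringFit:
    mu0: float
    mu1: float
    k0: float
    k1: float
    n: int
    shuffle_percentile: Optional[float] = None

    @property
    def strength(self) -> float:
        return 0.5 * (self.k0 + self.k1)


def object_torus_positions(path: TorusPath, mouse_xy: np.ndarray,
                           object_xy: np.ndarray, geom: ModuleGeometry,
                           rotation_correction: float = 0.0) -> np.ndarray:
    """Inferred torus position of an object from a decoded path.

    psi = wrap(v + torus_delta(R(correction) . (object - mouse))). Samples
    with a missing (NaN) object position are dropped. ``object_xy`` may be a
    single coordinate or a per-sample array.
    """
    mouse_xy = np.asarray(mouse_xy, float)
    object_xy = np.broadcast_to(np.asarray(object_xy, float), mouse_xy.shape)
    rel = object_xy - mouse_xy
    ok = np.all(np.isfinite(rel), axis=1)
    rel = rel[ok]
    if rotation_correction != 0.0:
        c, s = np.cos(rotation_correction), np.sin(rotation_correction)
        rel = rel @ np.array([[c, -s], [s, c]]).T
    dv = cartesian_to_torus_delta(rel, geom)
    v = path.angles()[ok]
    return wrap_pos(v + dv)


def _kappa_from_R(R: float, cap: float = 1e3) -> float:
    """Invert the mean resultant length to a von Mises concentration.

    Three-regime approximation (Best & Fisher); capped for degenerate data.
    """
    if R < 1e-12:
        return 0.0
    if R < 0.53:
        k = 2 * R + R ** 3 + 5 * R ** 5 / 6
    elif R < 0.85:
        k = -0.4 + 1.39 * R + 0.43 / (1 - R)
    else:
        den = R ** 3 - 4 * R ** 2 + 3 * R
        k = 1.0 / den if den > 1e-12 else cap
    return float(min(max(k, 0.0), cap))


def fit_bivariate_von_mises(pairs: np.ndarray, min_n: int = 30) -> AnchoringFit:
    """Fit two independent von Mises marginals to torus angle pairs.

    Means are the per-marginal circular means; concentrations come from the
    standard mean-resultant-length inversion. Requires >= ``min_n`` pairs.
    """
    pairs = np.asarray(pairs, float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    if pairs.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} angle pairs")
    mu0, R0 = circ_mean_resultant(pairs[:, 0])
    mu1, R1 = circ_mean_resultant(pairs[:, 1])
    return AnchoringFit(mu0, mu1, _kappa_from_R(R0), _kappa_from_R(R1),
                        n=pairs.shape[0])


def anchoring_strength(pairs: np.ndarray, min_n: int = 30) -> float:
    return fit_bivariate_von_mises(pairs, min_n).strength


def shuffle_anchoring_null(trial_v: Sequence[np.ndarray],
                           trial_dv: Sequence[np.ndarray],
                           n: int = 1000, seed: Optional[int] = None,
                           min_trials: int = 5):
    """Shuffled anchoring-strength distribution.

    Per repetition, each trial's decoded torus path is rigidly translated by
    a uniform offset pair in (-pi, pi]^2 before the object vector (already in
    torus coordinates, ``trial_dv``) is added; the anchoring strength of the
    pooled shuffled object positions forms the null. Returns
    (null strengths, 95th percentile).
    """
    if len(trial_v) < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    if len(trial_v) != len(trial_dv):
        raise ValueError("trial_v and trial_dv must match")
    rng = np.random.default_rng(seed)
    vs = [np.asarray(v, float) for v in trial_v]
    dvs = [np.asarray(d, float) for d in trial_dv]
    null = np.empty(n)
    for i in range(n):
        pooled = []
        for v, d in zip(vs, dvs):
            off = rng.uniform(-np.pi, np.pi, size=2)
            pooled.append(wrap_pos(v + off + d))
        null[i] = anchoring_strength(np.concatenate(pooled, axis=0))
    return null, float(np.percentile(null, 95))


def anchoring_timecourse(trial_phases: Sequence[dict],
                         anchors=("lever", "bridge"),
                         cap_duration: float = 3.0,
                         cap_mode: str = "first") -> pd.DataFrame:
    """Anchoring strength per phase third, pooled across trials.

    ``trial_phases``: one dict per (trial, phase) with keys ``phase`` (e.g.
    'search' | 'at_lever' | 'homing'), ``t`` (s, relative to phase start),
    and per-anchor torus pairs ``psi_<anchor>`` (n, 2). Each phase is
    truncated to its first (``cap_mode='first'``) or last 3 s, split into
    three equal-duration thirds, and the pooled pairs of each third are
    fitted per anchor. Empty thirds are skipped. Returns a tidy DataFrame
    (phase, third, anchor, strength, n).
    """
    rows = []
    phases = sorted({d["phase"] for d in trial_phases})
    for phase in phases:
        pools = {(third, a): [] for third in range(3) for a in anchors}
        for d in (x for x in trial_phases if x["phase"] == phase):
            t = np.asarray(d["t"], float)
            if t.size == 0:
                continue
            t = t - t[0]
            dur = min(t[-1], cap_duration) if cap_mode == "first" else cap_duration
            if cap_mode == "first":
                keep = t <= cap_duration
            else:
                keep = t >= t[-1] - cap_duration
            tt = t[keep]
            if tt.size == 0:
                continue
            tt = tt - tt[0]
            span = max(tt[-1], 1e-9)
            third_idx = np.minimum((tt / span * 3).astype(int), 2)
            for a in anchors:
                psi = np.asarray(d[f"psi_{a}"], float)[keep]
                for third in range(3):
                    sel = third_idx == third
                    if sel.any():
                        pools[(third, a)].append(psi[sel])
        for (third, a), chunks in pools.items():
            if not chunks:
                continue
            pairs = np.concatenate(chunks, axis=0)
            try:
                s = anchoring_strength(pairs)
            except ValueError:
                continue
            rows.append(dict(phase=phase, third=third, anchor=a,
                             strength=s, n=pairs.shape[0]))
    return pd.DataFrame(rows)
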
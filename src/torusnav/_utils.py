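"""Small internal helpers shared across modules (angle wrapping, masked smoothing)."""
from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d


def wrap_pos(a):
    """Wrap angles to [0, 2*pi)."""
    return np.mod(a, 2.0 * np.pi)


def wrap_delta(a):
    """Wrap angle differences to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), 2.0 * np.pi)


def circ_mean_resultant(angles, weights=None):
    """Return (circular mean, mean vector length) of angles, optionally weighted."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("need at least one angle")
    if weights is None:
        z = np.exp(1j * angles).mean()
    else:
        weights = np.asarray(weights, dtype=float)
        w = weights.sum()
        if w <= 0:
            raise ValueError("total weight must be positive")
        z = (weights * np.exp(1j * angles)).sum() / w
    return float(np.angle(z)), float(np.abs(z))


def smooth1d(x, sigma_bins, axis=-1):
    """Gaussian smoothing in bin units; sigma <= 0 returns the input unchanged."""
    if sigma_bins <= 0:
        return np.asarray(x, dtype=float)
    return gaussian_filter1d(np.asarray(x, dtype=float), sigma_bins, axis=axis,
                             mode="constant")


def masked_smooth2d(values, valid, sigma_bins):
    """Gaussian-smooth a 2D map over its valid support, renormalizing the kernel.

    Invalid bins do not contribute mass; output is defined on the valid mask only.
    """
    values = np.where(valid, values, 0.0).astype(float)
    if sigma_bins <= 0:
        out = np.where(valid, values, np.nan)
        return out
    num = gaussian_filter(values, sigma_bins, mode="constant")
    den = gaussian_filter(valid.astype(float), sigma_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out
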
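"""Sequence decoder: population firing rates -> position on the module torus.

A two-layer LSTM (256 hidden features) reads the instantaneous firing rates
of the co-modular grid cells over the last 400 ms (20 bins of 20 ms, rates
smoothed with a 20-ms Gaussian kernel) and outputs cos(v0), sin(v0),
cos(v1), sin(v1); the torus angles are recovered with the two-argument
arctangent after smoothing the four outputs with a 100-ms Gaussian kernel.
Training: one epoch, batch size 64, learning rate 0.001, mean-squared-error
loss, Adam, on the first 80% of the first random foraging trial; the last
20% is held out.

The network and its backpropagation-through-time are implemented directly on
numpy arrays (float32 matmuls), so decoding runs on any CPU.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._optim import Adam
from ._utils import smooth1d, wrap_delta
from .session_model import SpikeTrain, Trajectory, compute_speed
from .torus import ModuleGeometry, TorusPath, to_torus

__all__ = [
    "DecoderSpec",
    "LSTMDecoder",
    "rate_matrix",
    "build_dataset",
    "train_decoder",
    "decode_torus",
]


@dataclass
class DecoderSpec:
    """Hyperparameters of the torus decoder."""

    window: int = 20          # input bins per sample (20 x 20 ms = 400 ms)
    bin_size: float = 0.02    # s
    rate_smooth_sd: float = 0.02   # s, smoothing of input rates
    hidden: int = 256
    layers: int = 2
    batch_size: int = 64
    lr: float = 0.001
    epochs: int = 1
    out_smooth_sd: float = 0.1     # s, smoothing of the four outputs
    train_frac: float = 0.8
    speed_min: float = 10.0        # cm/s, evaluation mask
    border_margin: float = 5.0     # cm from the wall excluded at evaluation
    zscore_inputs: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# LSTM (numpy)
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTMDecoder:
    """Two-layer LSTM + linear readout, numpy forward/backward.

    Gate layout along the 4H axis: input, forget, cell, output. Weights are
    initialized uniformly in [-1/sqrt(H), 1/sqrt(H)].
    """

    def __init__(self, n_inputs: int, hidden: int = 256, layers: int = 2,
                 n_outputs: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_inputs = n_inputs
        self.hidden = hidden
        self.layers = layers
        k = 1.0 / np.sqrt(hidden)
        self.params = []
        for l in range(layers):
            d = n_inputs if l == 0 else hidden
            self.params.append(rng.uniform(-k, k, (d, 4 * hidden)).astype(np.float32))
            self.params.append(rng.uniform(-k, k, (hidden, 4 * hidden)).astype(np.float32))
            self.params.append(rng.uniform(-k, k, 4 * hidden).astype(np.float32))
        self.params.append(rng.uniform(-k, k, (hidden, n_outputs)).astype(np.float32))
        self.params.append(rng.uniform(-k, k, n_outputs).astype(np.float32))
        self.input_mean = np.zeros(n_inputs, dtype=np.float32)
        self.input_scale = np.ones(n_inputs, dtype=np.float32)

    # -- forward ------------------------------------------------------------
    def _forward(self, X, keep_cache=False):
        """X: (B, T, D) float32. Returns output (B, n_out) and caches."""
        B, T, _ = X.shape
        H = self.hidden
        dtype = X.dtype
        caches = []
        inp = X
        for l in range(self.layers):
            Wx, Wh, b = self.params[3 * l:3 * l + 3]
            pre_x = inp @ Wx + b                      # (B, T, 4H)
            h = np.zeros((B, H), dtype=dtype)
            c = np.zeros((B, H), dtype=dtype)
            hs = np.empty((T, B, H), dtype=dtype)
            cache_t = [] if keep_cache else None
            for t in range(T):
                z = pre_x[:, t] + h @ Wh
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                if keep_cache:
                    cache_t.append((h, c, i, f, g, o, tc))
                h, c = h_new, c_new
                hs[t] = h
            caches.append((inp, hs, cache_t))
            inp = hs.transpose(1, 0, 2)               # (B, T, H)
        Wo, bo = self.params[-2:]
        out = inp[:, -1] @ Wo + bo
        return out, caches

    def predict(self, X, batch: int = 512) -> np.ndarray:
        """Forward pass only; X (N, T, D) in input units."""
        X = self._prep(X)
        outs = []
        for s in range(0, X.shape[0], batch):
            out, _ = self._forward(X[s:s + batch])
            outs.append(out)
        return np.concatenate(outs, axis=0)

    def _prep(self, X):
        X = np.asarray(X, dtype=np.float32)
        return (X - self.input_mean) / self.input_scale

    # -- backward -----------------------------------------------------------
    def _backward(self, X, caches, d_out):
        """Gradients of all parameters for a batch; d_out: (B, n_out)."""
        B, T, _ = X.shape
        H = self.hidden
        dtype = X.dtype
        grads = [np.zeros_like(p) for p in self.params]
        Wo, bo = self.params[-2:]
        top_h = caches[-1][1]                         # (T, B, H)
        grads[-2] += top_h[-1].T @ d_out
        grads[-1] += d_out.sum(axis=0)
        # gradient flowing into the top layer's hidden sequence
        d_hs = np.zeros((T, B, H), dtype=dtype)
        d_hs[-1] = d_out @ Wo.T
        for l in range(self.layers - 1, -1, -1):
            inp, hs, cache_t = caches[l]
            Wx, Wh, b = self.params[3 * l:3 * l + 3]
            gWx, gWh, gb = grads[3 * l:3 * l + 3]
            d_inp = np.zeros(inp.shape, dtype=dtype) if l > 0 else None
            dh_next = np.zeros((B, H), dtype=dtype)
            dc_next = np.zeros((B, H), dtype=dtype)
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i, f, g, o, tc = cache_t[t]
                dh = d_hs[t] + dh_next
                dc = dc_next + dh * o * (1 - tc * tc)
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                do = dh * tc
                dz = np.empty((B, 4 * H), dtype=dtype)
                dz[:, :H] = di * i * (1 - i)
                dz[:, H:2 * H] = df * f * (1 - f)
                dz[:, 2 * H:3 * H] = dg * (1 - g * g)
                dz[:, 3 * H:] = do * o * (1 - o)
                x_t = inp[:, t] if inp.ndim == 3 else inp[t]
                gWx += x_t.T @ dz
                gWh += h_prev.T @ dz
                gb += dz.sum(axis=0)
                if l > 0:
                    d_inp[:, t] = dz @ Wx.T
                dh_next = dz @ Wh.T
                dc_next = dc * f
            if l > 0:
                d_hs = d_inp.transpose(1, 0, 2)
        return grads

    # -- training -----------------------------------------------------------
    def fit(self, X, Y, spec: DecoderSpec, rng: Optional[np.random.Generator] = None):
        """Train with Adam/MSE for ``spec.epochs`` epochs. Returns loss curve."""
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(Y, dtype=np.float32)
        if spec.zscore_inputs:
            self.input_mean = X.mean(axis=(0, 1)).astype(np.float32)
            self.input_scale = (X.std(axis=(0, 1)) + 1e-6).astype(np.float32)
        Xp = (X - self.input_mean) / self.input_scale
        n = X.shape[0]
        opt = Adam(self.params, lr=spec.lr)
        losses = []
        for _ in range(spec.epochs):
            order = rng.permutation(n)
            for s in range(0, n, spec.batch_size):
                idx = order[s:s + spec.batch_size]
                xb, yb = Xp[idx], Y[idx]
                out, caches = self._forward(xb, keep_cache=True)
                resid = out - yb
                losses.append(float(np.mean(resid ** 2)))
                d_out = (2.0 / resid.size) * resid
                grads = self._backward(xb, caches, d_out.astype(np.float32))
                opt.step(grads)
        return np.asarray(losses)


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

def rate_matrix(spikes: Sequence[SpikeTrain], t_start: float, t_end: float,
                bin_size: float = 0.02, smooth_sd: float = 0.02):
    """Population instantaneous-rate matrix (n_bins, n_cells) in Hz.

    Returns (bin_centers, rates)."""
    edges = np.arange(t_start, t_end + bin_size / 2, bin_size)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates = np.empty((centers.size, len(spikes)), dtype=np.float32)
    for j, st in enumerate(spikes):
        counts, _ = np.histogram(st.times, bins=edges)
        rates[:, j] = smooth1d(counts / bin_size, smooth_sd / bin_size)
    return centers, rates


def build_dataset(rates: np.ndarray, labels_v: np.ndarray, window: int = 20,
                  segments: Optional[Sequence[tuple[int, int]]] = None):
    """Sliding-window samples: (N, window, n_cells) inputs, (N, 4) targets.

    ``labels_v`` holds the torus angles (n_bins, 2); targets are their
    cosines and sines at the window end. Windows never straddle segment
    boundaries; segments shorter than ``window`` are dropped. Also returns
    the bin index of each sample's window end.
    """
    rates = np.asarray(rates, dtype=np.float32)
    labels_v = np.asarray(labels_v, dtype=float)
    n = rates.shape[0]
    if labels_v.shape[0] != n:
        raise ValueError("rates and labels must be aligned")
    if segments is None:
        segments = [(0, n)]
    xs, ys, ends = [], [], []
    n_dropped = 0
    for s0, s1 in segments:
        if s1 - s0 < window:
            n_dropped += 1
            continue
        idx = np.arange(s0 + window - 1, s1)
        sl = np.lib.stride_tricks.sliding_window_view(
            rates[s0:s1], window, axis=0)          # (len, n_cells, window)
        xs.append(np.ascontiguousarray(sl.transpose(0, 2, 1)))
        v = labels_v[idx]
        ys.append(np.column_stack([np.cos(v[:, 0]), np.sin(v[:, 0]),
                                   np.cos(v[:, 1]), np.sin(v[:, 1])]))
        ends.append(idx)
    if not xs:
        raise ValueError("no segment is at least one window long")
    X = np.concatenate(xs, axis=0)
    Y = np.concatenate(ys, axis=0).astype(np.float32)
    ends = np.concatenate(ends)
    return X, Y, ends, n_dropped


def decode_torus(model: LSTMDecoder, rates: np.ndarray, t_bins: np.ndarray,
                 window: int = 20, out_smooth_sd: float = 0.1,
                 bin_size: float = 0.02) -> TorusPath:
    """Decode a torus path from a population rate matrix.

    The four outputs are smoothed with a Gaussian kernel (``out_smooth_sd``
    seconds) before the two-argument arctangent.
    """
    rates = np.asarray(rates, dtype=np.float32)
    if rates.shape[1] != model.n_inputs:
        raise ValueError("cell count differs from the training configuration")
    X, _, ends, _ = build_dataset(rates, np.zeros((rates.shape[0], 2)), window)
    out = model.predict(X)
    if out_smooth_sd > 0:
        out = smooth1d(out, out_smooth_sd / bin_size, axis=0)
    v0 = np.arctan2(out[:, 1], out[:, 0])
    v1 = np.arctan2(out[:, 3], out[:, 2])
    return TorusPath(np.asarray(t_bins)[ends], v0, v1, source="decoded")


# ---------------------------------------------------------------------------
# End-to-end training on a foraging trial
# ---------------------------------------------------------------------------

@dataclass
class TrainedDecoder:
    model: LSTMDecoder
    spec: DecoderSpec
    geom: ModuleGeometry
    train_loss: np.ndarray
    test_precision: float          # held-out 20% of the training trial
    test_rotation: float
    second_trial_precision: Optional[float] = None
    included: Optional[bool] = None


def _eval_precision(model: LSTMDecoder, traj: Trajectory,
                    rates, t_bins, spec: DecoderSpec, arena_radius: float):
    """Directional precision of decoded movement on one trajectory interval."""
    from .pathrecon import decoded_movement, directional_errors
    tp = decode_torus(model, rates, t_bins, spec.window,
                      spec.out_smooth_sd, spec.bin_size)
    real = traj.position_at(tp.t)
    vec, _ = decoded_movement(tp, _geom_of(model), real[0])
    real_vec = np.diff(real, axis=0)
    mid = real[:-1] + real_vec / 2
    speed = np.hypot(real_vec[:, 0], real_vec[:, 1]) / spec.bin_size
    mask = (speed > spec.speed_min) & \
           (np.hypot(mid[:, 0], mid[:, 1]) < arena_radius - spec.border_margin)
    err = directional_errors(vec, real_vec, mask)
    return err.precision, err.rotation


def _geom_of(model: LSTMDecoder) -> ModuleGeometry:
    return model._geom


def train_decoder(traj: Trajectory, spikes: Sequence[SpikeTrain],
                  geom: ModuleGeometry, spec: Optional[DecoderSpec] = None,
                  arena_radius: Optional[float] = None,
                  second_trial: Optional[tuple[Trajectory, Sequence[SpikeTrain]]] = None,
                  inclusion_threshold: float = 0.5) -> TrainedDecoder:
    """Train the torus decoder on the first foraging trial.

    Trains on the first ``train_frac`` of the trial, evaluates directional
    precision on the held-out remainder (speed > 10 cm/s, border excluded)
    and, when a second foraging trial is supplied, on that trial as well; the
    session-inclusion flag follows the second-trial precision.
    """
    if len(spikes) < 5:
        raise ValueError("decoding requires at least five co-modular grid cells")
    spec = spec or DecoderSpec()
    if arena_radius is None:
        arena_radius = float(np.hypot(traj.x, traj.y).max())
    t_bins, rates = rate_matrix(spikes, traj.t[0], traj.t[-1],
                                spec.bin_size, spec.rate_smooth_sd)
    v = to_torus(traj.position_at(t_bins), geom)
    n_train = int(spec.train_frac * rates.shape[0])
    X, Y, _, _ = build_dataset(rates[:n_train], v[:n_train], spec.window)
    model = LSTMDecoder(len(spikes), spec.hidden, spec.layers, seed=spec.seed)
    model._geom = geom
    losses = model.fit(X, Y, spec)
    test_traj = traj
    prec, rot = _eval_precision(
        model, traj, rates[n_train:], t_bins[n_train:], spec, arena_radius)
    out = TrainedDecoder(model, spec, geom, losses, prec, rot)
    if second_trial is not None:
        traj2, spikes2 = second_trial
        tb2, r2 = rate_matrix(spikes2, traj2.t[0], traj2.t[-1],
                              spec.bin_size, spec.rate_smooth_sd)
        p2, _ = _eval_precision(model, traj2, r2, tb2, spec, arena_radius)
        out.second_trial_precision = p2
        out.included = bool(p2 > inclusion_threshold)
    return out
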
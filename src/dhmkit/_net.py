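"""A small convolutional noise predictor with timestep conditioning, in numpy.

The denoiser ε̂_θ(x_t, t, condition) is a three-layer 3×3 convolutional
encoder–decoder operating at full resolution.  The diffusion timestep enters
through a sinusoidal embedding that modulates each hidden layer with a
per-channel scale and shift (FiLM), which lets the network express the
strongly t-dependent gain that ε-prediction requires.  Forward, backward and
the Adam update are written directly against numpy; the profile images used
here are small (tens of pixels a side), so im2col matrix products are fast.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvDenoiserNet", "Adam", "timestep_embedding"]


def timestep_embedding(t: np.ndarray, dim: int, t_max: int) -> np.ndarray:
    """Sinusoidal embedding of integer timesteps, shape (B, dim)."""
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = (np.asarray(t, dtype=float)[:, None] / t_max) * freqs[None, :] * t_max
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, C*9, H*W) patches for a 3x3, pad-1 convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # view: (B, C, H, W, 3, 3) -> (B, C, 3, 3, H, W)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * 9, h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to the image."""
    b, c, h, w = shape
    d = dcols.reshape(b, c, 3, 3, h, w)
    dxp = np.zeros((b, c, h + 2, w + 2))
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, 1:-1, 1:-1]


class ConvDenoiserNet:
    """Conv(2→C) · FiLM · ReLU · Conv(C→C) · FiLM · ReLU · Conv(C→1)."""

    def __init__(self, channels: int = 32, emb_dim: int = 32, t_max: int = 50, seed: int = 0):
        self.channels = channels
        self.emb_dim = emb_dim
        self.t_max = t_max
        rng = np.random.default_rng(seed)
        c = channels

        def conv_init(c_out, c_in):
            fan_in = c_in * 9
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))

        self.params = {
            "W1": conv_init(c, 2), "b1": np.zeros(c),
            "W2": conv_init(c, c), "b2": np.zeros(c),
            # zero-initialized output conv: the untrained net predicts ε̂ = 0
            "W3": np.zeros((1, c, 3, 3)), "b3": np.zeros(1),
            # FiLM dense maps start at identity modulation
            "F1g": np.zeros((emb_dim, c)), "F1b": np.zeros((emb_dim, c)),
            "F1gb": np.zeros(c), "F1bb": np.zeros(c),
            "F2g": np.zeros((emb_dim, c)), "F2b": np.zeros((emb_dim, c)),
            "F2gb": np.zeros(c), "F2bb": np.zeros(c),
        }

    # -- forward ---------------------------------------------------------
    def _conv(self, x, W, b):
        b_, c_in, h, w = x.shape
        c_out = W.shape[0]
        cols = _im2col(x)
        out = np.einsum("ok,bkp->bop", W.reshape(c_out, -1), cols)
        out += b[None, :, None]
        return out.reshape(b_, c_out, h, w), (cols, x.shape, W.shape)

    def forward(self, x: np.ndarray, t: np.ndarray, want_cache: bool = False):
        """Predict ε̂ from (B, 2, H, W) input [x_t, condition] and steps t."""
        p = self.params
        e = timestep_embedding(t, self.emb_dim, self.t_max)

        h1, c1 = self._conv(x, p["W1"], p["b1"])
        g1 = e @ p["F1g"] + p["F1gb"]
        s1 = e @ p["F1b"] + p["F1bb"]
        f1 = h1 * (1.0 + g1[:, :, None, None]) + s1[:, :, None, None]
        a1 = np.maximum(f1, 0.0)

        h2, c2 = self._conv(a1, p["W2"], p["b2"])
        g2 = e @ p["F2g"] + p["F2gb"]
        s2 = e @ p["F2b"] + p["F2bb"]
        f2 = h2 * (1.0 + g2[:, :, None, None]) + s2[:, :, None, None]
        a2 = np.maximum(f2, 0.0)

        out, c3 = self._conv(a2, p["W3"], p["b3"])
        if not want_cache:
            return out
        cache = dict(e=e, h1=h1, g1=g1, f1=f1, a1=a1, h2=h2, g2=g2, f2=f2, a2=a2,
                     c1=c1, c2=c2, c3=c3)
        return out, cache

    # -- backward --------------------------------------------------------
    def _conv_backward(self, dout, cache):
        cols, x_shape, w_shape = cache
        b_, c_out = dout.shape[:2]
        dout_m = dout.reshape(b_, c_out, -1)
        dW = np.einsum("bop,bkp->ok", dout_m, cols).reshape(w_shape)
        db = dout_m.sum(axis=(0, 2))
        W = None  # filled by caller
        return dW, db, dout_m

    def backward(self, dout: np.ndarray, cache: dict) -> dict:
        """Gradients of all parameters given dLoss/dε̂."""
        p = self.params
        grads = {}
        e = cache["e"]

        # conv3
        cols3, x3_shape, w3_shape = cache["c3"]
        b_ = dout.shape[0]
        dout3 = dout.reshape(b_, 1, -1)
        grads["W3"] = np.einsum("bop,bkp->ok", dout3, cols3).reshape(w3_shape)
        grads["b3"] = dout3.sum(axis=(0, 2))
        dcols3 = np.einsum("ok,bop->bkp", p["W3"].reshape(1, -1), dout3)
        da2 = _col2im(dcols3, x3_shape)

        # relu2 + film2
        df2 = da2 * (cache["f2"] > 0)
        dh2 = df2 * (1.0 + cache["g2"][:, :, None, None])
        dg2 = (df2 * cache["h2"]).sum(axis=(2, 3))
        ds2 = df2.sum(axis=(2, 3))
        grads["F2g"] = e.T @ dg2
        grads["F2gb"] = dg2.sum(axis=0)
        grads["F2b"] = e.T @ ds2
        grads["F2bb"] = ds2.sum(axis=0)

        # conv2
        cols2, x2_shape, w2_shape = cache["c2"]
        c = self.channels
        dout2 = dh2.reshape(b_, c, -1)
        grads["W2"] = np.einsum("bop,bkp->ok", dout2, cols2).reshape(w2_shape)
        grads["b2"] = dout2.sum(axis=(0, 2))
        dcols2 = np.einsum("ok,bop->bkp", p["W2"].reshape(c, -1), dout2)
        da1 = _col2im(dcols2, x2_shape)

        # relu1 + film1
        df1 = da1 * (cache["f1"] > 0)
        dh1 = df1 * (1.0 + cache["g1"][:, :, None, None])
        dg1 = (df1 * cache["h1"]).sum(axis=(2, 3))
        ds1 = df1.sum(axis=(2, 3))
        grads["F1g"] = e.T @ dg1
        grads["F1gb"] = dg1.sum(axis=0)
        grads["F1b"] = e.T @ ds1
        grads["F1bb"] = ds1.sum(axis=0)

        # conv1
        cols1, x1_shape, w1_shape = cache["c1"]
        dout1 = dh1.reshape(b_, c, -1)
        grads["W1"] = np.einsum("bop,bkp->ok", dout1, cols1).reshape(w1_shape)
        grads["b1"] = dout1.sum(axis=(0, 2))
        return grads

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def copy(self) -> "ConvDenoiserNet":
        dup = ConvDenoiserNet(self.channels, self.emb_dim, self.t_max)
        dup.params = {k: v.copy() for k, v in self.params.items()}
        return dup


class Adam:
    """Adam optimizer over a dict of numpy parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.step_count = 0

    def step(self, params: dict, grads: dict) -> None:
        self.step_count += 1
        b1c = 1.0 - self.beta1**self.step_count
        b2c = 1.0 - self.beta2**self.step_count
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
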
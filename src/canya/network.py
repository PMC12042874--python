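"""Numpy implementation of the convolution-attention network.

The architecture, for a 24x20 pad/one-hot/mask input:

1. Convolution: 100 filters of length 3, stride 1, exponential activation
   (no pooling), giving a 22 x 100 activation-energy map.
2. A learned positional embedding (22 x 100) added to the activation map.
3. Single-head self-attention with key length 6: dense Q/K/V projections
   (100 -> 6), a learned positional encoding in key space (24 x 6, rows
   beyond the 22 attention positions unused by the default input length)
   added to the keys before the softmax, scaled dot-product weights, and an
   output projection back to filter space (6 -> 100).
4. Mean pooling over positions, a 64-unit ReLU dense layer whose incoming
   weights carry an elastic-net penalty (0.01 L1 + 0.01 L2), and a 1-unit
   sigmoid output.

Dropout: 0.1 after convolution, 0.1 after attention, 0.4 after the dense
layer.  The default configuration has exactly 17,491 trainable parameters;
:func:`parameter_decomposition` reports the per-matrix counts.

The loss is binary cross-entropy, which for hard 0/1 labels equals the
binary KL divergence up to an additive constant (the label entropy is 0).
Optimisation uses Adam with standard defaults.

Everything here is plain numpy with explicit forward/backward passes so the
model trains deterministically on one CPU without a deep-learning runtime.
"""

from __future__ import annotations

import numpy as np

from canya.encoding import N_ROWS, N_CHANNELS

# exp(z) is clipped at this pre-activation to keep training finite; the
# closed-form activation identity exp(w.x + b) holds for any sane weights
_EXP_CLIP = 30.0


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) == 3:
        fan_in = shape[0] * shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Initialise all trainable parameters (Glorot kernels, zero biases and
    positional tables)."""
    F, k, d, flen = config.n_filters, config.key_len, config.dense_units, config.filter_len
    L = N_ROWS - flen + 1
    return {
        "conv_w": _glorot(rng, (flen, N_CHANNELS, F)),
        "conv_b": np.zeros(F),
        "pos_in": np.zeros((L, F)),
        "wq": _glorot(rng, (F, k)),
        "bq": np.zeros(k),
        "wk": _glorot(rng, (F, k)),
        "bk": np.zeros(k),
        "wv": _glorot(rng, (F, k)),
        "bv": np.zeros(k),
        "pos_key": np.zeros((N_ROWS, k)),
        "wo": _glorot(rng, (k, F)),
        "bo": np.zeros(F),
        "dense_w": _glorot(rng, (F, d)),
        "dense_b": np.zeros(d),
        "out_w": _glorot(rng, (d, 1))[:, 0],
        "out_b": np.zeros(1),
    }


def parameter_count(params: dict[str, np.ndarray]) -> int:
    return int(sum(p.size for p in params.values()))


def parameter_decomposition(params: dict[str, np.ndarray]) -> dict[str, int]:
    """Per-matrix trainable-parameter counts (sums to the total)."""
    return {name: int(p.size) for name, p in params.items()}


def _windows(X: np.ndarray, flen: int) -> np.ndarray:
    """(B, 24, 20) -> (B, 24-flen+1, flen*20) sliding windows."""
    L = X.shape[1] - flen + 1
    return np.concatenate([X[:, i:L + i, :] for i in range(flen)], axis=2)


def forward(params: dict, X: np.ndarray, config, train: bool = False,
            rng: np.random.Generator | None = None) -> tuple[np.ndarray, dict]:
    """Forward pass; returns (logits, cache for backward)."""
    flen = config.filter_len
    k = config.key_len
    Xw = _windows(X, flen)                                   # (B, L, flen*20)
    Wc = params["conv_w"].reshape(flen * N_CHANNELS, -1)
    Z1 = Xw @ Wc + params["conv_b"]
    Z1c = np.minimum(Z1, _EXP_CLIP)
    A = np.exp(Z1c)                                          # activation energies

    def _drop(T, rate):
        if not train or rate <= 0:
            return T, None
        mask = (rng.random(T.shape) >= rate) / (1.0 - rate)
        return T * mask, mask

    Ad, m_conv = _drop(A, config.dropout_conv)
    H = Ad + params["pos_in"]
    Lp = H.shape[1]
    Q = H @ params["wq"] + params["bq"]
    K = H @ params["wk"] + params["bk"] + params["pos_key"][:Lp]
    V = H @ params["wv"] + params["bv"]
    S = Q @ K.transpose(0, 2, 1) / np.sqrt(k)
    S = S - S.max(axis=-1, keepdims=True)
    W = np.exp(S)
    W /= W.sum(axis=-1, keepdims=True)                       # attention weights
    O = W @ V
    U = O @ params["wo"] + params["bo"]
    Ud, m_attn = _drop(U, config.dropout_attention)
    pooled = Ud.mean(axis=1)
    Zd = pooled @ params["dense_w"] + params["dense_b"]
    D = np.maximum(Zd, 0.0)
    Dd, m_dense = _drop(D, config.dropout_dense)
    logits = Dd @ params["out_w"] + params["out_b"][0]
    cache = dict(X=X, Xw=Xw, Z1=Z1, A=A, Ad=Ad, H=H, Q=Q, K=K, V=V, W=W, O=O,
                 Ud=Ud, pooled=pooled, Zd=Zd, Dd=Dd,
                 m_conv=m_conv, m_attn=m_attn, m_dense=m_dense)
    return logits, cache


def backward(params: dict, cache: dict, dlogits: np.ndarray, config,
             want_input_grad: bool = False) -> tuple[dict, np.ndarray | None]:
    """Backpropagate d(loss)/d(logits); returns (grads, dX or None).

    The elastic-net penalty gradient on the dense kernel is NOT included
    here; the training loop adds it so that raw gradients stay checkable
    against the unpenalised loss.
    """
    flen, k = config.filter_len, config.key_len
    B = dlogits.shape[0]
    g: dict[str, np.ndarray] = {}

    g["out_w"] = cache["Dd"].T @ dlogits
    g["out_b"] = np.array([dlogits.sum()])
    dDd = np.outer(dlogits, params["out_w"])
    dD = dDd if cache["m_dense"] is None else dDd * cache["m_dense"]
    dZd = dD * (cache["Zd"] > 0)
    g["dense_w"] = cache["pooled"].T @ dZd
    g["dense_b"] = dZd.sum(axis=0)
    dpooled = dZd @ params["dense_w"].T
    Lp = cache["H"].shape[1]
    dUd = np.repeat(dpooled[:, None, :], Lp, axis=1) / Lp
    dU = dUd if cache["m_attn"] is None else dUd * cache["m_attn"]
    g["wo"] = np.einsum("btk,btf->kf", cache["O"], dU)
    g["bo"] = dU.sum(axis=(0, 1))
    dO = dU @ params["wo"].T
    W = cache["W"]
    dW = dO @ cache["V"].transpose(0, 2, 1)
    dV = W.transpose(0, 2, 1) @ dO
    dS = W * (dW - (dW * W).sum(axis=-1, keepdims=True))
    dS /= np.sqrt(k)
    dQ = dS @ cache["K"]
    dK = dS.transpose(0, 2, 1) @ cache["Q"]
    g["pos_key"] = np.zeros_like(params["pos_key"])
    g["pos_key"][:Lp] = dK.sum(axis=0)
    H = cache["H"]
    g["wq"] = np.einsum("btf,btk->fk", H, dQ)
    g["bq"] = dQ.sum(axis=(0, 1))
    g["wk"] = np.einsum("btf,btk->fk", H, dK)
    g["bk"] = dK.sum(axis=(0, 1))
    g["wv"] = np.einsum("btf,btk->fk", H, dV)
    g["bv"] = dV.sum(axis=(0, 1))
    dH = dQ @ params["wq"].T + dK @ params["wk"].T + dV @ params["wv"].T
    g["pos_in"] = dH.sum(axis=0)
    dAd = dH
    dA = dAd if cache["m_conv"] is None else dAd * cache["m_conv"]
    dZ1 = dA * cache["A"] * (cache["Z1"] < _EXP_CLIP)
    Wc = params["conv_w"].reshape(flen * N_CHANNELS, -1)
    g["conv_w"] = np.einsum("btw,btf->wf", cache["Xw"], dZ1).reshape(params["conv_w"].shape)
    g["conv_b"] = dZ1.sum(axis=(0, 1))

    dX = None
    if want_input_grad:
        dXw = dZ1 @ Wc.T
        dX = np.zeros_like(cache["X"])
        for i in range(flen):
            dX[:, i:Lp + i, :] += dXw[:, :, i * N_CHANNELS:(i + 1) * N_CHANNELS]
    return g, dX


def bce_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits)."""
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return loss, (p - y) / len(y)


class Adam:
    """Adam optimiser with standard defaults (lr mutable for plateau decay)."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(p) for n, p in params.items()}
        self.v = {n: np.zeros_like(p) for n, p in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for n, p in params.items():
            gr = grads[n]
            self.m[n] = b1 * self.m[n] + (1 - b1) * gr
            self.v[n] = b2 * self.v[n] + (1 - b2) * gr * gr
            mhat = self.m[n] / (1 - b1 ** self.t)
            vhat = self.v[n] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
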
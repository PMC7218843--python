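"""Minimal stacked-LSTM sequence labeler in numpy.

Architecture: N unidirectional LSTM layers (gates ordered input, forget,
cell-candidate, output; hard-sigmoid gate activations, tanh cell/state
activations) followed by a 2-unit fully connected layer and softmax,
emitting a class probability pair at every time step.  Training is
back-propagation through time with per-sample cross-entropy, Adam updates,
and global L2-norm gradient clipping.

Everything runs on the CPU; the model is small (4 input features) and the
heavy lifting is batched matrix products over the time loop.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LstmParams", "init_params", "forward", "loss_and_grads", "AdamState", "adam_step", "clip_global_norm"]


def hard_sigmoid(x: np.ndarray) -> np.ndarray:
    return np.clip(0.2 * x + 0.5, 0.0, 1.0)


class LstmParams:
    """Weight container: per layer W (4H x D), R (4H x H), b (4H); head Wout (2 x H), bout (2)."""

    def __init__(self, layers: list[dict[str, np.ndarray]], Wout: np.ndarray, bout: np.ndarray):
        self.layers = layers
        self.Wout = Wout
        self.bout = bout

    def flat(self) -> list[np.ndarray]:
        out = []
        for lay in self.layers:
            out += [lay["W"], lay["R"], lay["b"]]
        out += [self.Wout, self.bout]
        return out

    def copy(self) -> "LstmParams":
        return LstmParams(
            [{k: v.copy() for k, v in lay.items()} for lay in self.layers],
            self.Wout.copy(),
            self.bout.copy(),
        )


def init_params(n_inputs: int, hidden_units: int, n_layers: int, rng: np.random.Generator) -> LstmParams:
    """Glorot-uniform input/recurrent weights, zero biases except forget
    gate bias = 1 (standard trick for gradient flow early in training)."""
    layers = []
    d = n_inputs
    H = hidden_units
    for _ in range(n_layers):
        s_w = np.sqrt(6.0 / (d + 4 * H))
        s_r = np.sqrt(6.0 / (H + 4 * H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0
        layers.append(
            {
                "W": rng.uniform(-s_w, s_w, size=(4 * H, d)),
                "R": rng.uniform(-s_r, s_r, size=(4 * H, H)),
                "b": b,
            }
        )
        d = H
    s_o = np.sqrt(6.0 / (H + 2))
    return LstmParams(layers, rng.uniform(-s_o, s_o, size=(2, H)), np.zeros(2))


def _layer_forward(x: np.ndarray, lay: dict[str, np.ndarray], cache: bool):
    """One LSTM layer over a (B, T, D) batch; returns (h_seq, caches)."""
    B, T, _ = x.shape
    H = lay["R"].shape[1]
    W, R, b = lay["W"], lay["R"], lay["b"]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    h_seq = np.empty((B, T, H))
    caches = None
    if cache:
        caches = {k: np.empty((B, T, H)) for k in ("i", "f", "g", "o", "c", "tc", "cprev")}
    xw = x @ W.T  # precompute input contribution for all t
    for t in range(T):
        z = xw[:, t] + h @ R.T + b
        i = hard_sigmoid(z[:, :H])
        f = hard_sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = hard_sigmoid(z[:, 3 * H :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        h_seq[:, t] = h
        if cache:
            caches["i"][:, t] = i
            caches["f"][:, t] = f
            caches["g"][:, t] = g
            caches["o"][:, t] = o
            caches["c"][:, t] = c
            caches["tc"][:, t] = tc
            caches["cprev"][:, t] = c_prev
    return h_seq, caches


def forward(params: LstmParams, x: np.ndarray, cache: bool = False):
    """Full forward pass.

    Returns ``(probs, hidden, caches)`` where probs is (B, T, 2).
    """
    h = x
    hiddens = []
    caches = []
    for lay in params.layers:
        h, cch = _layer_forward(h, lay, cache)
        hiddens.append(h)
        caches.append(cch)
    logits = h @ params.Wout.T + params.bout
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=-1, keepdims=True)
    return probs, hiddens, caches


def loss_and_grads(params: LstmParams, x: np.ndarray, y: np.ndarray):
    """Mean per-sample cross-entropy and gradients for a (B, T, D) batch
    with integer labels y of shape (B, T)."""
    B, T, _ = x.shape
    probs, hiddens, caches = forward(params, x, cache=True)
    n = B * T
    p_true = np.take_along_axis(probs, y[..., None], axis=-1)[..., 0]
    loss = float(-np.log(np.maximum(p_true, 1e-300)).mean())

    dlogits = probs.copy()
    np.put_along_axis(dlogits, y[..., None], np.take_along_axis(dlogits, y[..., None], axis=-1) - 1.0, axis=-1)
    dlogits /= n

    h_top = hiddens[-1]
    gWout = np.einsum("btk,bth->kh", dlogits, h_top)
    gbout = dlogits.sum(axis=(0, 1))
    dh_above = dlogits @ params.Wout  # (B, T, H)

    grads_layers = []
    for li in range(len(params.layers) - 1, -1, -1):
        lay = params.layers[li]
        cch = caches[li]
        x_in = x if li == 0 else hiddens[li - 1]
        H = lay["R"].shape[1]
        W, R = lay["W"], lay["R"]
        gW = np.zeros_like(W)
        gR = np.zeros_like(R)
        gb = np.zeros_like(lay["b"])
        dz_seq = np.empty((B, T, 4 * H))
        dh_rec = np.zeros((B, H))
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = cch["i"][:, t], cch["f"][:, t], cch["g"][:, t], cch["o"][:, t]
            tc, c_prev = cch["tc"][:, t], cch["cprev"][:, t]
            dh = dh_above[:, t] + dh_rec
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f  # becomes dc_prev for t-1
            # hard-sigmoid derivative is 0.2 on the linear branch
            dz = np.concatenate(
                [
                    di * 0.2 * ((i > 0) & (i < 1)),
                    df * 0.2 * ((f > 0) & (f < 1)),
                    dg * (1.0 - g * g),
                    do * 0.2 * ((o > 0) & (o < 1)),
                ],
                axis=1,
            )
            dz_seq[:, t] = dz
            h_prev = hiddens[li][:, t - 1] if t > 0 else np.zeros((B, H))
            gR += dz.T @ h_prev
            dh_rec = dz @ R
        gW = np.einsum("btz,btd->zd", dz_seq, x_in)
        gb = dz_seq.sum(axis=(0, 1))
        dh_above = dz_seq @ W  # gradient w.r.t. this layer's input sequence
        grads_layers.append({"W": gW, "R": gR, "b": gb})
    grads_layers.reverse()
    grads = LstmParams(grads_layers, gWout, gbout)
    return loss, grads


def clip_global_norm(grads: LstmParams, threshold: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``threshold``."""
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.flat()))
    if total > threshold and total > 0:
        scale = threshold / total
        for g in grads.flat():
            g *= scale
    return total


class AdamState:
    def __init__(self, params: LstmParams):
        self.m = [np.zeros_like(p) for p in params.flat()]
        self.v = [np.zeros_like(p) for p in params.flat()]
        self.t = 0


def adam_step(
    params: LstmParams,
    grads: LstmParams,
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.998,
    eps: float = 1e-8,
) -> None:
    state.t += 1
    t = state.t
    for p, g, m, v in zip(params.flat(), grads.flat(), state.m, state.v):
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * g * g
        mh = m / (1 - beta1**t)
        vh = v / (1 - beta2**t)
        p -= lr * mh / (np.sqrt(vh) + eps)
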
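"""Minimal NumPy neural-network primitives with manual backpropagation.

Contains exactly what the multi-task model needs: numerically stable
softmax/cross-entropy, an LSTM over a single sequence, additive
(Bahdanau-style) attention with a learned query, and an Adam optimizer over
a flat parameter dict.  All functions are pure NumPy and single-threaded
deterministic; gradient correctness is enforced by finite-difference checks
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softmax",
    "lstm_forward",
    "lstm_backward",
    "attention_forward",
    "attention_backward",
    "Adam",
    "init_lstm_params",
    "init_attention_params",
]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# LSTM (single sequence, T x D -> T x H); gate order i, f, g, o


def init_lstm_params(d_in: int, hidden: int, rng: np.random.Generator) -> dict:
    s = 1.0 / np.sqrt(max(d_in, hidden))
    b = np.zeros(4 * hidden)
    b[hidden : 2 * hidden] = 1.0  # forget-gate bias init
    return {
        "Wx": rng.normal(0.0, s, size=(d_in, 4 * hidden)),
        "Wh": rng.normal(0.0, s, size=(hidden, 4 * hidden)),
        "b": b,
    }


def lstm_forward(X: np.ndarray, p: dict) -> tuple[np.ndarray, dict]:
    T = X.shape[0]
    H = p["Wh"].shape[0]
    hs = np.zeros((T, H))
    cache: dict = {"X": X, "p": p, "gates": [], "cs": np.zeros((T, H))}
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(T):
        a = X[t] @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = _sigmoid(a[:H])
        f = _sigmoid(a[H : 2 * H])
        g = np.tanh(a[2 * H : 3 * H])
        o = _sigmoid(a[3 * H :])
        c_prev = c
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        hs[t] = h
        cache["cs"][t] = c
        cache["gates"].append((i, f, g, o, c_prev))
    cache["hs"] = hs
    return hs, cache


def lstm_backward(dhs: np.ndarray, cache: dict) -> tuple[np.ndarray, dict]:
    X, p = cache["X"], cache["p"]
    T, H = dhs.shape
    dX = np.zeros_like(X)
    dWx = np.zeros_like(p["Wx"])
    dWh = np.zeros_like(p["Wh"])
    db = np.zeros_like(p["b"])
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev = cache["gates"][t]
        c = cache["cs"][t]
        tanh_c = np.tanh(c)
        dh = dhs[t] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c**2) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ]
        )
        dX[t] = da @ p["Wx"].T
        h_prev = cache["hs"][t - 1] if t > 0 else np.zeros(H)
        dWx += np.outer(X[t], da)
        dWh += np.outer(h_prev, da)
        db += da
        dh_next = da @ p["Wh"].T
    return dX, {"Wx": dWx, "Wh": dWh, "b": db}


# ---------------------------------------------------------------------------
# Additive attention with learned query: e_t = v . tanh(S_t Wa + ba)


def init_attention_params(d_in: int, dim: int, rng: np.random.Generator) -> dict:
    s = 1.0 / np.sqrt(max(d_in, dim))
    return {
        "Wa": rng.normal(0.0, s, size=(d_in, dim)),
        "ba": np.zeros(dim),
        "v": rng.normal(0.0, s, size=dim),
    }


def attention_forward(S: np.ndarray, p: dict) -> tuple[np.ndarray, np.ndarray, dict]:
    """Return (context vector, weights, cache) for a T x D input."""
    A = np.tanh(S @ p["Wa"] + p["ba"])  # T x dim
    e = A @ p["v"]  # T
    alpha = softmax(e)
    u = alpha @ S
    return u, alpha, {"S": S, "A": A, "alpha": alpha, "p": p}


def attention_backward(du: np.ndarray, cache: dict) -> tuple[np.ndarray, dict]:
    S, A, alpha, p = cache["S"], cache["A"], cache["alpha"], cache["p"]
    dalpha = S @ du
    dS = np.outer(alpha, du)
    # softmax jacobian-vector product
    de = alpha * (dalpha - float(alpha @ dalpha))
    dA = np.outer(de, p["v"]) * (1.0 - A**2)
    dv = A.T @ de
    dWa = S.T @ dA
    dba = dA.sum(axis=0)
    dS += dA @ p["Wa"].T
    return dS, {"Wa": dWa, "ba": dba, "v": dv}


# ---------------------------------------------------------------------------
# Adam


class Adam:
    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
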
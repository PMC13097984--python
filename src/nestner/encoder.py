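"""A compact transformer encoder with explicit forward/backward passes.

This is the shipped contextual-embedding backbone: a randomly
initialized bidirectional self-attention encoder (token + position
embeddings, post-norm blocks of multi-head attention and a feed-forward
sublayer). It is deliberately small — the package's training paths are
desk-scale — and deterministic given a seed. Any object implementing
the same ``forward``/``backward``/``params`` surface can stand in as a
backbone, so larger pretrained encoders can be plugged in where
available.

Gradients are computed by hand; :func:`finite-difference
<tests.test_model>` checks guard their correctness.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _ln_forward(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _ln_backward(dy, cache, g):
    xhat, inv = cache
    dg = (dy * xhat).sum(axis=0)
    db = dy.sum(axis=0)
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


class TinyTransformerEncoder:
    """Bidirectional transformer encoder over subword-piece ids.

    Parameters
    ----------
    vocab_size:
        Size of the subword vocabulary.
    d_model, n_layers, n_heads, d_ff:
        Transformer dimensions; ``d_model`` must be divisible by
        ``n_heads``.
    max_len:
        Longest supported piece sequence (position-embedding table size).
    seed:
        Initialization seed; identical seeds give bitwise-identical
        parameters.
    """

    name = "tiny-transformer"

    def __init__(
        self,
        vocab_size: int,
        d_model: int = 48,
        n_layers: int = 2,
        n_heads: int = 4,
        d_ff: int = 96,
        max_len: int = 512,
        seed: int = 0,
    ):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.vocab_size = vocab_size
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.max_len = max_len
        rng = np.random.default_rng(seed)
        s = 0.02
        p: dict[str, np.ndarray] = {
            "tok_emb": rng.normal(0, s, (vocab_size, d_model)),
            "pos_emb": rng.normal(0, s, (max_len, d_model)),
        }
        for l in range(n_layers):
            for w in ("Wq", "Wk", "Wv", "Wo"):
                p[f"b{l}.{w}"] = rng.normal(0, s, (d_model, d_model))
            for b in ("bq", "bk", "bv", "bo"):
                p[f"b{l}.{b}"] = np.zeros(d_model)
            p[f"b{l}.W1"] = rng.normal(0, s, (d_model, d_ff))
            p[f"b{l}.c1"] = np.zeros(d_ff)
            p[f"b{l}.W2"] = rng.normal(0, s, (d_ff, d_model))
            p[f"b{l}.c2"] = np.zeros(d_model)
            p[f"b{l}.ln1_g"] = np.ones(d_model)
            p[f"b{l}.ln1_b"] = np.zeros(d_model)
            p[f"b{l}.ln2_g"] = np.ones(d_model)
            p[f"b{l}.ln2_b"] = np.zeros(d_model)
        self.params = p
        self._cache: dict | None = None

    # -- forward ------------------------------------------------------

    def forward(
        self, ids: np.ndarray, attn_mask: np.ndarray | None = None
    ) -> np.ndarray:
        """Map piece ids (L,) to hidden states (L, d_model).

        ``attn_mask``, when given, is a boolean array over positions;
        False positions (padding) are excluded as attention keys, so
        hidden states at True positions are invariant to padding length.
        """
        ids = np.asarray(ids, dtype=np.int64)
        L = len(ids)
        if L > self.max_len:
            raise ValueError(f"sequence of {L} pieces exceeds max_len={self.max_len}")
        p = self.params
        x = p["tok_emb"][ids] + p["pos_emb"][:L]
        key_bias = None
        if attn_mask is not None:
            key_bias = np.where(np.asarray(attn_mask, bool), 0.0, -1e9)
        blocks = []
        for l in range(self.n_layers):
            x, cache = self._block_forward(l, x, key_bias)
            blocks.append(cache)
        self._cache = {"ids": ids, "blocks": blocks, "L": L}
        return x

    def _block_forward(self, l, x, key_bias):
        p = self.params
        nh, dh = self.n_heads, self.d_model // self.n_heads
        L = x.shape[0]
        Q = x @ p[f"b{l}.Wq"] + p[f"b{l}.bq"]
        K = x @ p[f"b{l}.Wk"] + p[f"b{l}.bk"]
        V = x @ p[f"b{l}.Wv"] + p[f"b{l}.bv"]
        Qh = Q.reshape(L, nh, dh).transpose(1, 0, 2)
        Kh = K.reshape(L, nh, dh).transpose(1, 0, 2)
        Vh = V.reshape(L, nh, dh).transpose(1, 0, 2)
        S = Qh @ Kh.transpose(0, 2, 1) / np.sqrt(dh)
        if key_bias is not None:
            S = S + key_bias[None, None, :]
        A = softmax(S, axis=-1)
        Oh = A @ Vh
        O = Oh.transpose(1, 0, 2).reshape(L, self.d_model)
        attn = O @ p[f"b{l}.Wo"] + p[f"b{l}.bo"]
        y1, ln1 = _ln_forward(x + attn, p[f"b{l}.ln1_g"], p[f"b{l}.ln1_b"])
        F1pre = y1 @ p[f"b{l}.W1"] + p[f"b{l}.c1"]
        F1 = np.maximum(F1pre, 0.0)
        F2 = F1 @ p[f"b{l}.W2"] + p[f"b{l}.c2"]
        y2, ln2 = _ln_forward(y1 + F2, p[f"b{l}.ln2_g"], p[f"b{l}.ln2_b"])
        cache = {
            "x": x, "Qh": Qh, "Kh": Kh, "Vh": Vh, "A": A, "O": O,
            "y1": y1, "F1pre": F1pre, "F1": F1, "ln1": ln1, "ln2": ln2,
        }
        return y2, cache

    # -- backward -----------------------------------------------------

    def backward(self, dH: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate d(loss)/d(hidden) to parameter gradients."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dx = dH
        for l in reversed(range(self.n_layers)):
            dx = self._block_backward(l, dx, self._cache["blocks"][l], grads)
        ids, L = self._cache["ids"], self._cache["L"]
        np.add.at(grads["tok_emb"], ids, dx)
        grads["pos_emb"][:L] += dx
        return grads

    def _block_backward(self, l, dy2, cache, grads):
        p = self.params
        nh, dh = self.n_heads, self.d_model // self.n_heads
        L = cache["x"].shape[0]
        dr2, dg2, db2 = _ln_backward(dy2, cache["ln2"], p[f"b{l}.ln2_g"])
        grads[f"b{l}.ln2_g"] += dg2
        grads[f"b{l}.ln2_b"] += db2
        dy1 = dr2.copy()
        dF2 = dr2
        grads[f"b{l}.W2"] += cache["F1"].T @ dF2
        grads[f"b{l}.c2"] += dF2.sum(axis=0)
        dF1 = dF2 @ p[f"b{l}.W2"].T
        dF1pre = dF1 * (cache["F1pre"] > 0)
        grads[f"b{l}.W1"] += cache["y1"].T @ dF1pre
        grads[f"b{l}.c1"] += dF1pre.sum(axis=0)
        dy1 += dF1pre @ p[f"b{l}.W1"].T
        dr1, dg1, db1 = _ln_backward(dy1, cache["ln1"], p[f"b{l}.ln1_g"])
        grads[f"b{l}.ln1_g"] += dg1
        grads[f"b{l}.ln1_b"] += db1
        dx = dr1.copy()
        dattn = dr1
        grads[f"b{l}.Wo"] += cache["O"].T @ dattn
        grads[f"b{l}.bo"] += dattn.sum(axis=0)
        dO = dattn @ p[f"b{l}.Wo"].T
        dOh = dO.reshape(L, nh, dh).transpose(1, 0, 2)
        A, Qh, Kh, Vh = cache["A"], cache["Qh"], cache["Kh"], cache["Vh"]
        dA = dOh @ Vh.transpose(0, 2, 1)
        dVh = A.transpose(0, 2, 1) @ dOh
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(dh)
        dQh = dS @ Kh
        dKh = dS.transpose(0, 2, 1) @ Qh
        dQ = dQh.transpose(1, 0, 2).reshape(L, self.d_model)
        dK = dKh.transpose(1, 0, 2).reshape(L, self.d_model)
        dV = dVh.transpose(1, 0, 2).reshape(L, self.d_model)
        x = cache["x"]
        for name, dmat in (("q", dQ), ("k", dK), ("v", dV)):
            grads[f"b{l}.W{name}"] += x.T @ dmat
            grads[f"b{l}.b{name}"] += dmat.sum(axis=0)
            dx += dmat @ p[f"b{l}.W{name}"].T
        return dx


class AdamOptimizer:
    """Adam with the conventional bias-corrected moment estimates."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
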
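"""Numpy implementation of the attention-based node-scoring network.

Architecture: a stack of multi-head graph-attention layers, each coupled
with a node-wise linear layer of matching width; the two outputs are
summed (a residual connection) before the ELU nonlinearity.  Heads are
concatenated and every layer carries an additive bias.  The final node
embeddings feed a multilayer-perceptron regressor whose sigmoid output
constrains the node score p_n to [0, 1].

Forward and backward passes are written directly against dense per-graph
arrays: the training graphs are tiny (25 nodes), so an N x N attention
matrix per head is cheap and keeps the code transparent.  Gradients are
hand-derived and verified against numerical differentiation in the test
suite.  Dropout is applied to the normalized attention coefficients
during training only.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -1e30


def elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GATNetwork:
    """Parameter container + forward/backward for the full scoring network.

    Parameters are a flat dict of numpy arrays.  Per attention layer l
    (F_in inputs, H heads, C channels):

    - ``conv{l}_W``     (H, F_in, C)   per-head transforms
    - ``conv{l}_asrc``  (H, C), ``conv{l}_adst`` (H, C)  attention vectors
    - ``conv{l}_b``     (H*C,)         additive bias
    - ``conv{l}_Wlin``  (F_in, H*C), ``conv{l}_blin`` (H*C,)  residual linear

    Regressor layer r: ``reg{r}_W``, ``reg{r}_b``; the last layer maps to a
    single sigmoid unit.
    """

    def __init__(self, n_features, conv_channels, attention_heads,
                 regressor_widths, dropout=0.3, negative_slope=0.2):
        self.n_features = int(n_features)
        self.conv_channels = tuple(conv_channels)
        self.attention_heads = tuple(attention_heads)
        self.regressor_widths = tuple(regressor_widths)
        self.dropout = float(dropout)
        self.negative_slope = float(negative_slope)
        self.params = {}

    # -- initialization ----------------------------------------------------

    def initialize(self, rng: np.random.Generator):
        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        p = {}
        f_in = self.n_features
        for l, (c, h) in enumerate(zip(self.conv_channels, self.attention_heads)):
            p[f"conv{l}_W"] = glorot((h, f_in, c), f_in, c)
            p[f"conv{l}_asrc"] = glorot((h, c), c, 1)
            p[f"conv{l}_adst"] = glorot((h, c), c, 1)
            p[f"conv{l}_b"] = np.zeros(h * c)
            p[f"conv{l}_Wlin"] = glorot((f_in, h * c), f_in, h * c)
            p[f"conv{l}_blin"] = np.zeros(h * c)
            f_in = h * c
        widths = list(self.regressor_widths) + [1]
        for r, w in enumerate(widths):
            p[f"reg{r}_W"] = glorot((f_in, w), f_in, w)
            p[f"reg{r}_b"] = np.zeros(w)
            f_in = w
        self.params = p
        return self

    @property
    def n_conv_layers(self):
        return len(self.conv_channels)

    @property
    def n_reg_layers(self):
        return len(self.regressor_widths) + 1

    # -- forward -----------------------------------------------------------

    def forward(self, X, mask, training=False, rng=None):
        """Score every node.

        X : (N, F) feature matrix; mask : (N, N) boolean adjacency with
        self-loops (every node attends to itself, so isolated nodes fall
        back to self-only aggregation).  Returns (scores, cache).
        """
        p = self.params
        slope = self.negative_slope
        cache = {"inputs": [], "conv": [], "reg": []}
        A = X
        for l in range(self.n_conv_layers):
            W, asrc, adst = p[f"conv{l}_W"], p[f"conv{l}_asrc"], p[f"conv{l}_adst"]
            H, _, C = W.shape
            N = A.shape[0]
            Z = np.matmul(A[None, :, :], W)                     # (H, N, C)
            s = np.einsum("hnc,hc->hn", Z, asrc)
            d = np.einsum("hnc,hc->hn", Z, adst)
            pre = s[:, :, None] + d[:, None, :]                  # (H, N, N)
            e = np.where(pre > 0, pre, slope * pre)
            e = np.where(mask[None, :, :], e, NEG_INF)
            e -= e.max(axis=2, keepdims=True)
            ex = np.exp(e) * mask[None, :, :]
            alpha = ex / ex.sum(axis=2, keepdims=True)
            if training and self.dropout > 0:
                keep = rng.random(alpha.shape) >= self.dropout
                drop = keep / (1.0 - self.dropout)
            else:
                drop = None
            alpha_used = alpha if drop is None else alpha * drop
            Hh = np.matmul(alpha_used, Z)                        # (H, N, C)
            G = np.transpose(Hh, (1, 0, 2)).reshape(N, H * C)
            lin = A @ p[f"conv{l}_Wlin"] + p[f"conv{l}_blin"]
            out_pre = G + p[f"conv{l}_b"] + lin
            out = elu(out_pre)
            cache["inputs"].append(A)
            cache["conv"].append(
                {"Z": Z, "pre": pre, "alpha": alpha, "drop": drop,
                 "alpha_used": alpha_used, "out_pre": out_pre}
            )
            A = out
        for r in range(self.n_reg_layers):
            zpre = A @ p[f"reg{r}_W"] + p[f"reg{r}_b"]
            if r < self.n_reg_layers - 1:
                out = elu(zpre)
            else:
                out = sigmoid(zpre)
            cache["reg"].append({"A": A, "zpre": zpre, "out": out})
            A = out
        scores = A[:, 0]
        cache["mask"] = mask
        return scores, cache

    # -- backward ----------------------------------------------------------

    def backward(self, dscores, cache):
        """Gradients of a scalar loss w.r.t. all parameters.

        ``dscores`` is dLoss/dscores, shape (N,).  Returns a dict with the
        same keys as ``params``.
        """
        p = self.params
        grads = {}
        mask = cache["mask"]
        dA = dscores[:, None]
        for r in reversed(range(self.n_reg_layers)):
            c = cache["reg"][r]
            if r == self.n_reg_layers - 1:
                dz = dA * c["out"] * (1.0 - c["out"])
            else:
                dz = dA * elu_grad(c["zpre"])
            grads[f"reg{r}_W"] = c["A"].T @ dz
            grads[f"reg{r}_b"] = dz.sum(axis=0)
            dA = dz @ p[f"reg{r}_W"].T
        for l in reversed(range(self.n_conv_layers)):
            c = cache["conv"][l]
            A = cache["inputs"][l]
            W, asrc, adst = p[f"conv{l}_W"], p[f"conv{l}_asrc"], p[f"conv{l}_adst"]
            H, _, C = W.shape
            N = A.shape[0]
            dpre_out = dA * elu_grad(c["out_pre"])               # (N, H*C)
            grads[f"conv{l}_b"] = dpre_out.sum(axis=0)
            grads[f"conv{l}_blin"] = dpre_out.sum(axis=0)
            grads[f"conv{l}_Wlin"] = A.T @ dpre_out
            dA_next = dpre_out @ p[f"conv{l}_Wlin"].T
            dHh = np.transpose(dpre_out.reshape(N, H, C), (1, 0, 2))  # (H,N,C)
            Z, alpha, alpha_used = c["Z"], c["alpha"], c["alpha_used"]
            dalpha_used = np.matmul(dHh, np.transpose(Z, (0, 2, 1)))  # (H,N,N)
            dZ = np.matmul(np.transpose(alpha_used, (0, 2, 1)), dHh)  # (H,N,C)
            dalpha = dalpha_used if c["drop"] is None else dalpha_used * c["drop"]
            inner = (alpha * dalpha).sum(axis=2, keepdims=True)
            dE = alpha * (dalpha - inner)
            slope_grad = np.where(c["pre"] > 0, 1.0, self.negative_slope)
            dpre_attn = dE * slope_grad * mask[None, :, :]
            ds = dpre_attn.sum(axis=2)                            # (H, N)
            dd = dpre_attn.sum(axis=1)                            # (H, N)
            grads[f"conv{l}_asrc"] = np.einsum("hn,hnc->hc", ds, Z)
            grads[f"conv{l}_adst"] = np.einsum("hn,hnc->hc", dd, Z)
            dZ = dZ + ds[:, :, None] * asrc[:, None, :] + dd[:, :, None] * adst[:, None, :]
            grads[f"conv{l}_W"] = np.einsum("nf,hnc->hfc", A, dZ)
            dA_next = dA_next + np.einsum("hnc,hfc->nf", dZ, W)
            dA = dA_next
        return grads


class Adam:
    """Adam with the standard moment defaults (0.9, 0.999, eps 1e-8)."""

    def __init__(self, params, lr=1e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def adjacency_mask(g, nodes):
    """Boolean (N, N) attention mask: edges of ``g`` plus self-loops."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    mask = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(mask, True)
    for u, v in g.edges():
        if u == v:
            continue
        mask[idx[u], idx[v]] = True
        mask[idx[v], idx[u]] = True
    return mask
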
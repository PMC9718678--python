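"""The MIL network: fivemer embedding, read encoder, noisy-OR pooling.

Reads are encoded by a feed-forward network F operating on the per-read
feature vector

    x = (mu_{-w..w}, sigma_{-w..w}, l_{-w..w},
         f(S_{-w})_1, f(S_{-w})_2, ..., f(S_{+w})_1, f(S_{+w})_2)

where mu/sigma/l are z-scored signal mean, spread and dwell at each position
of the window and f is a learned 2-dimensional embedding of the fivemer at
that position.  F has two ReLU hidden layers (default widths 150 and 32) and
a scalar sigmoid output p, the probability that the read is modified.  Site
probabilities pool the read probabilities with a noisy-OR:

    P = 1 - prod_j (1 - p_j)

so a site is called modified if at least one of its reads looks modified.
Training minimises binary cross entropy between P and the site label; the
embedding and the encoder are learned end to end.

Everything here is plain numpy with hand-written gradients; correctness is
pinned against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

P_EPS = 1e-7  # probability clamp before logs


# ---------------------------------------------------------------------------
# parameter initialisation


def init_weights(
    rng: np.random.Generator,
    vocab_size: int,
    flank_width: int = 1,
    hidden: tuple[int, int] = (150, 32),
    embedding_dim: int = 2,
    init_bag_size: int = 20,
) -> dict[str, np.ndarray]:
    """He-initialised encoder weights plus a standard-normal embedding table.

    The output bias is set so that a bag of ``init_bag_size`` reads pools to
    a site probability near 0.5 at initialisation (a zero bias would start
    every 20-read site saturated at P ~ 1 under noisy-OR and waste the early
    epochs escaping it): b3 = logit(1 - 2**(-1/init_bag_size)).
    """
    k = 2 * flank_width + 1
    d_in = 3 * k + embedding_dim * k
    h1, h2 = hidden
    p0 = 1.0 - 0.5 ** (1.0 / init_bag_size)
    def he(fan_in, shape):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return {
        "embedding": rng.normal(0.0, 1.0, size=(vocab_size, embedding_dim)),
        "W1": he(d_in, (d_in, h1)),
        "b1": np.zeros(h1),
        "W2": he(h1, (h1, h2)),
        "b2": np.zeros(h2),
        "W3": he(h2, (h2, 1)),
        "b3": np.full(1, np.log(p0 / (1.0 - p0))),
    }


def input_width(weights: dict[str, np.ndarray]) -> int:
    return weights["W1"].shape[0]


# ---------------------------------------------------------------------------
# forward passes


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _assemble_input(
    weights: dict[str, np.ndarray], signals: np.ndarray, kmer_idx: np.ndarray
) -> np.ndarray:
    n = signals.shape[0]
    emb = weights["embedding"][kmer_idx]  # (n, k, emb_dim)
    x = np.concatenate([signals, emb.reshape(n, -1)], axis=1)
    if x.shape[1] != input_width(weights):
        raise ValueError(
            f"feature width mismatch: model expects {input_width(weights)}, "
            f"got {x.shape[1]} (signals {signals.shape[1]} + embedded "
            f"{emb.reshape(n, -1).shape[1]})"
        )
    return x


def read_probability(
    weights: dict[str, np.ndarray],
    signals: np.ndarray,
    kmer_idx: np.ndarray,
    return_hidden: bool = False,
):
    """Per-read modification probability p = F(x) for a batch of reads.

    ``signals``: (n, 3k) z-scored values ordered (means, spreads, dwells),
    each block upstream to downstream.  ``kmer_idx``: (n, k) vocabulary
    indices.  With ``return_hidden`` also returns the penultimate-layer
    activations (the read representation).
    """
    signals = np.asarray(signals, dtype=float)
    kmer_idx = np.asarray(kmer_idx)
    if signals.ndim == 1:
        signals = signals[None, :]
        kmer_idx = np.asarray(kmer_idx)[None, :]
    if np.any(kmer_idx < 0) or np.any(kmer_idx >= weights["embedding"].shape[0]):
        raise IndexError("fivemer index outside embedding vocabulary")
    x = _assemble_input(weights, signals, kmer_idx)
    a1 = np.maximum(x @ weights["W1"] + weights["b1"], 0.0)
    a2 = np.maximum(a1 @ weights["W2"] + weights["b2"], 0.0)
    z3 = (a2 @ weights["W3"] + weights["b3"])[:, 0]
    p = _sigmoid(z3)
    if return_hidden:
        return p, a2
    return p


def noisy_or_pool(read_probs: Iterable[float]) -> float:
    """Site probability 1 - prod(1 - p_j), computed stably in log space."""
    p = np.asarray(list(read_probs) if not isinstance(read_probs, np.ndarray) else read_probs, dtype=float)
    if p.size == 0:
        raise ValueError("noisy-OR pooling over an empty bag")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("read probabilities must lie in [0, 1]")
    if np.any(p == 1.0):
        return 1.0
    return float(-np.expm1(np.sum(np.log1p(-p))))


def site_loss(site_prob: float, label: int, eps: float = P_EPS) -> float:
    """Binary cross entropy of one site, with probability clamping."""
    p = min(max(float(site_prob), eps), 1.0 - eps)
    y = float(label)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def batch_objective(site_probs: Iterable[float], labels: Iterable[int]) -> float:
    probs = np.asarray(list(site_probs), dtype=float)
    labs = np.asarray(list(labels), dtype=float)
    return float(np.mean([site_loss(p, y) for p, y in zip(probs, labs)]))


# ---------------------------------------------------------------------------
# fused forward/backward over a batch of fixed-size bags


def bag_loss_and_grads(
    weights: dict[str, np.ndarray],
    signals: np.ndarray,
    kmer_idx: np.ndarray,
    labels: np.ndarray,
    weight_decay: float = 0.0,
):
    """Mean BCE over a batch of bags, plus gradients w.r.t. every parameter.

    ``signals``: (B, R, 3k), ``kmer_idx``: (B, R, k), ``labels``: (B,) in
    {0,1}.  Each bag holds exactly R sampled reads.  Returns
    ``(loss, site_probs, grads)``.
    """
    B, R = signals.shape[:2]
    sig = signals.reshape(B * R, -1)
    kid = kmer_idx.reshape(B * R, -1)
    emb = weights["embedding"][kid]  # (N, k, e)
    x = np.concatenate([sig, emb.reshape(B * R, -1)], axis=1)

    z1 = x @ weights["W1"] + weights["b1"]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ weights["W2"] + weights["b2"]
    a2 = np.maximum(z2, 0.0)
    z3 = (a2 @ weights["W3"] + weights["b3"])[:, 0]
    p = np.clip(_sigmoid(z3), P_EPS, 1.0 - P_EPS).reshape(B, R)

    log_q = np.sum(np.log1p(-p), axis=1)          # log prod(1-p)
    P = np.clip(-np.expm1(log_q), P_EPS, 1.0 - P_EPS)
    y = np.asarray(labels, dtype=float)
    loss = float(np.mean(-(y * np.log(P) + (1.0 - y) * np.log(1.0 - P))))

    # dL/dP through the clamp (pass-through), then dP/dz_j = exp(log_q) * p_j
    dP = (P - y) / (P * (1.0 - P)) / B            # (B,)
    gz3 = (dP * np.exp(log_q))[:, None] * p       # (B, R)
    gz3 = gz3.reshape(B * R, 1)

    grads: dict[str, np.ndarray] = {}
    grads["W3"] = a2.T @ gz3
    grads["b3"] = gz3.sum(axis=0)
    g2 = (gz3 @ weights["W3"].T) * (z2 > 0)
    grads["W2"] = a1.T @ g2
    grads["b2"] = g2.sum(axis=0)
    g1 = (g2 @ weights["W2"].T) * (z1 > 0)
    grads["W1"] = x.T @ g1
    grads["b1"] = g1.sum(axis=0)
    gx = g1 @ weights["W1"].T
    gemb_flat = gx[:, sig.shape[1]:].reshape(emb.shape)
    gE = np.zeros_like(weights["embedding"])
    np.add.at(gE, kid.reshape(-1), gemb_flat.reshape(-1, emb.shape[-1]))
    grads["embedding"] = gE

    if weight_decay:
        for k in ("W1", "W2", "W3", "embedding"):
            grads[k] = grads[k] + weight_decay * weights[k]
    return loss, P, grads


# ---------------------------------------------------------------------------
# Adam with the AMSGrad variant


class AdamState:
    """Adam(amsgrad) optimiser state over a weight dict."""

    def __init__(
        self,
        weights: dict[str, np.ndarray],
        lr: float = 4e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        amsgrad: bool = True,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.vhat = {k: np.zeros_like(v) for k, v in weights.items()}

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[k], self.v[k], out=self.vhat[k])
                denom = np.sqrt(self.vhat[k] / bc2) + self.eps
            else:
                denom = np.sqrt(self.v[k] / bc2) + self.eps
            weights[k] = weights[k] - self.lr * (self.m[k] / bc1) / denom
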
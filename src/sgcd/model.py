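"""Graph-convolutional representation learning with a contrastive objective.

Architecture: a single GCN encoder layer Z = relu(A_norm X W_e + b_e), a
symmetric single-layer GCN decoder H = A_norm Z W_d + b_d, and a bilinear
discriminator Phi(z, g) = sigmoid(z^T B g) that scores whether a node
embedding matches its local context vector g (sigmoid of the weighted mean
of neighboring embeddings).

Training minimizes

    L = lambda1 * L_recon + lambda2 * (L_scl + L_scl_random)

where L_recon is the summed squared reconstruction error, L_scl is the
binary cross-entropy separating (z_i, g_i) pairs from corrupted
(z'_i, g_i) pairs, and L_scl_random is the mirrored term on the corrupted
graph. The corruption permutes feature rows each epoch while keeping the
topology fixed.

Everything is plain NumPy: forward, analytic backward pass and an Adam
optimizer, fully deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import NormalizedAdjacency, WeightedGraph, normalize_adjacency

__all__ = [
    "ModelConfig",
    "ModelState",
    "EmbeddingResult",
    "gcn_layer",
    "encode",
    "decode",
    "recon_loss",
    "context_vectors",
    "discriminate",
    "scl_loss",
    "scl_loss_random",
    "total_loss",
    "train",
]


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x):
    # log(1 + e^x), stable for large |x|
    return np.logaddexp(0.0, x)


@dataclass
class ModelConfig:
    """Hyperparameters of the representation learner."""

    latent_dim: int = 64
    lambda1: float = 10.0
    lambda2: float = 1.0
    epochs: int = 600
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be non-negative")
        if self.latent_dim < 1 or self.epochs < 1:
            raise ValueError("latent_dim and epochs must be positive")


@dataclass
class ModelState:
    """Trainable parameters: encoder, decoder and discriminator."""

    W_e: np.ndarray
    b_e: np.ndarray
    W_d: np.ndarray
    b_d: np.ndarray
    B: np.ndarray
    config: ModelConfig

    @classmethod
    def init(cls, n_genes: int, config: ModelConfig) -> "ModelState":
        """Glorot-uniform initialization, deterministic under config.seed."""
        rng = np.random.default_rng(config.seed)
        h = config.latent_dim

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        return cls(
            W_e=glorot(n_genes, h),
            b_e=np.zeros(h),
            W_d=glorot(h, n_genes),
            b_d=np.zeros(n_genes),
            B=glorot(h, h),
            config=config,
        )

    def params(self) -> dict:
        return {"W_e": self.W_e, "b_e": self.b_e, "W_d": self.W_d,
                "b_d": self.b_d, "B": self.B}


@dataclass
class EmbeddingResult:
    """Final embeddings, reconstruction and the per-epoch loss trace."""

    Z: np.ndarray
    H: np.ndarray
    loss_trace: np.ndarray
    state: ModelState
    loss_components: dict = field(default_factory=dict)


def _as_matrix(A_norm) -> sp.csr_matrix:
    if isinstance(A_norm, NormalizedAdjacency):
        return A_norm.matrix
    return sp.csr_matrix(A_norm)


def gcn_layer(A_norm, Z_in, W, b, activation: str = "relu") -> np.ndarray:
    """One graph convolution: activation(A_norm @ Z_in @ W + b)."""
    A = _as_matrix(A_norm)
    Z_in = np.asarray(Z_in, dtype=float)
    if A.shape[1] != Z_in.shape[0] or Z_in.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: A {A.shape}, Z {Z_in.shape}, W {W.shape}"
        )
    out = A @ (Z_in @ W) + b
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation == "identity":
        return out
    raise ValueError(f"unknown activation {activation!r}")


def encode(A_norm, X, state: ModelState) -> np.ndarray:
    """Node embeddings Z = relu(A_norm X W_e + b_e)."""
    Z = gcn_layer(A_norm, X, state.W_e, state.b_e, "relu")
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError("non-finite values in encoder output")
    return Z


def decode(A_norm, Z, state: ModelState) -> np.ndarray:
    """Reconstruction H = A_norm Z W_d + b_d (identity activation)."""
    H = gcn_layer(A_norm, Z, state.W_d, state.b_d, "identity")
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite values in decoder output")
    return H


def recon_loss(X, H) -> float:
    """Sum over nodes of the squared Euclidean reconstruction error."""
    X = np.asarray(X, dtype=float)
    H = np.asarray(H, dtype=float)
    if X.shape != H.shape:
        raise ValueError("X and H must have the same shape")
    return float(((X - H) ** 2).sum())


def context_matrix(G: WeightedGraph) -> sp.csr_matrix:
    """Row-normalized weighted adjacency (no self term) for aggregation."""
    A = G.to_sparse()
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    return (sp.diags(inv) @ A).tocsr()


def context_vectors(G: WeightedGraph, Z: np.ndarray) -> np.ndarray:
    """Local context g_i = sigmoid(weighted mean of neighbor embeddings).

    Isolated nodes aggregate nothing and get sigmoid(0) = 0.5 everywhere.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] != G.n_nodes:
        raise ValueError("Z rows must match graph nodes")
    return _sigmoid(context_matrix(G) @ Z)


def discriminate(z, g, state: ModelState) -> float:
    """Phi(z, g) = sigmoid(z^T B g), the positive-pair probability.

    Clamped to [1e-7, 1 - 1e-7] so downstream logs stay finite.
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(g, dtype=float)
    p = float(_sigmoid(np.array([z @ state.B @ g]))[0])
    return min(max(p, 1e-7), 1.0 - 1e-7)


def _pair_scores(U, V, B):
    """Row-wise bilinear scores s_i = u_i^T B v_i."""
    return np.einsum("ij,ij->i", U @ B, V)


def scl_loss(Z, Z_corrupt, g, state: ModelState) -> float:
    """Contrastive BCE on the original graph's contexts.

    Positives (z_i, g_i) vs negatives (z'_i, g_i), averaged with the
    1/(2N) factor. Computed from logits via softplus, which equals BCE on
    probabilities clamped away from {0, 1}.
    """
    s_pos = _pair_scores(np.asarray(Z, float), np.asarray(g, float), state.B)
    s_neg = _pair_scores(np.asarray(Z_corrupt, float), np.asarray(g, float), state.B)
    return float((_softplus(-s_pos) + _softplus(s_neg)).mean() / 2.0)


def scl_loss_random(Z, Z_corrupt, g_corrupt, state: ModelState) -> float:
    """Mirrored contrastive BCE on the corrupted graph's contexts."""
    return scl_loss(Z_corrupt, Z, g_corrupt, state)


def total_loss(recon: float, scl: float, scl_random: float,
               lambda1: float = 10.0, lambda2: float = 1.0) -> float:
    """lambda1 * L_recon + lambda2 * (L_scl + L_scl_random)."""
    return float(lambda1 * recon + lambda2 * (scl + scl_random))


def _forward_backward(params: dict, X, X_corrupt, A: sp.csr_matrix,
                      M: sp.csr_matrix, lambda1: float, lambda2: float):
    """One full forward + analytic backward pass.

    Returns (loss components dict, gradients dict, Z, H). ``A`` is the
    normalized adjacency, ``M`` the row-normalized context aggregation
    matrix. The permutation producing ``X_corrupt`` is fixed by the caller
    so the pass is a deterministic function of the parameters.
    """
    W_e, b_e = params["W_e"], params["b_e"]
    W_d, b_d = params["W_d"], params["b_d"]
    B = params["B"]
    N = X.shape[0]

    # forward
    AX = A @ X
    AXc = A @ X_corrupt
    P = AX @ W_e + b_e
    Z = np.maximum(P, 0.0)
    Pc = AXc @ W_e + b_e
    Zc = np.maximum(Pc, 0.0)
    AZ = A @ Z
    H = AZ @ W_d + b_d

    Cg = M @ Z
    g = _sigmoid(Cg)
    Cgc = M @ Zc
    gc = _sigmoid(Cgc)

    ZB = Z @ B
    ZcB = Zc @ B
    s1 = np.einsum("ij,ij->i", ZB, g)    # positive, original contexts
    s2 = np.einsum("ij,ij->i", ZcB, g)   # negative, original contexts
    s3 = np.einsum("ij,ij->i", ZcB, gc)  # positive, corrupted contexts
    s4 = np.einsum("ij,ij->i", ZB, gc)   # negative, corrupted contexts

    L_rec = float(((X - H) ** 2).sum())
    L_scl = float((_softplus(-s1) + _softplus(s2)).mean() / 2.0)
    L_rand = float((_softplus(-s3) + _softplus(s4)).mean() / 2.0)
    L = lambda1 * L_rec + lambda2 * (L_scl + L_rand)

    # backward
    dZ = np.zeros_like(Z)
    dZc = np.zeros_like(Zc)
    dB = np.zeros_like(B)

    # reconstruction branch
    if lambda1 != 0.0:
        dH = 2.0 * lambda1 * (H - X)
        dW_d = AZ.T @ dH
        db_d = dH.sum(axis=0)
        dZ += A.T @ (dH @ W_d.T)
    else:
        dW_d = np.zeros_like(W_d)
        db_d = np.zeros_like(b_d)

    # contrastive branches
    if lambda2 != 0.0:
        scale = lambda2 / (2.0 * N)
        c1 = (_sigmoid(s1) - 1.0) * scale
        c2 = _sigmoid(s2) * scale
        c3 = (_sigmoid(s3) - 1.0) * scale
        c4 = _sigmoid(s4) * scale

        dg = c1[:, None] * ZB + c2[:, None] * ZcB
        dgc = c3[:, None] * ZcB + c4[:, None] * ZB
        dZ += c1[:, None] * (g @ B.T) + c4[:, None] * (gc @ B.T)
        dZc += c2[:, None] * (g @ B.T) + c3[:, None] * (gc @ B.T)
        dB += Z.T @ (c1[:, None] * g) + Zc.T @ (c2[:, None] * g)
        dB += Zc.T @ (c3[:, None] * gc) + Z.T @ (c4[:, None] * gc)

        dCg = dg * g * (1.0 - g)
        dCgc = dgc * gc * (1.0 - gc)
        dZ += M.T @ dCg
        dZc += M.T @ dCgc

    dP = dZ * (P > 0)
    dPc = dZc * (Pc > 0)
    dW_e = AX.T @ dP + AXc.T @ dPc
    db_e = dP.sum(axis=0) + dPc.sum(axis=0)

    losses = {"total": L, "recon": L_rec, "scl": L_scl, "scl_random": L_rand}
    grads = {"W_e": dW_e, "b_e": db_e, "W_d": dW_d, "b_d": db_d, "B": dB}
    return losses, grads, Z, H


class _Adam:
    """Minimal Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            gk = grads[k] + self.wd * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(X: np.ndarray, G: WeightedGraph, config: ModelConfig | None = None,
          self_loops: bool = True) -> EmbeddingResult:
    """Train the representation learner on a weighted spot graph.

    Each epoch regenerates the feature permutation (corruption), runs both
    graphs forward, and takes one Adam step on the combined loss. Fully
    reproducible under ``config.seed``; raises if the loss turns
    non-finite.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    if X.shape[0] != G.n_nodes:
        raise ValueError("X rows must match graph nodes")
    A = normalize_adjacency(G, self_loops=self_loops).matrix
    M = context_matrix(G)
    iso = int((np.asarray(G.to_sparse().sum(axis=1)).ravel() == 0).sum())
    if iso > 0.05 * G.n_nodes:
        import warnings

        warnings.warn(f"{iso} isolated nodes; embeddings there rely on self-signal only")

    state = ModelState.init(X.shape[1], config)
    params = state.params()
    opt = _Adam(params, config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed)

    trace = np.empty(config.epochs)
    components = {"recon": np.empty(config.epochs),
                  "scl": np.empty(config.epochs),
                  "scl_random": np.empty(config.epochs)}
    Z = H = None
    for epoch in range(config.epochs):
        Xc = X[rng.permutation(X.shape[0])]
        losses, grads, Z, H = _forward_backward(
            params, X, Xc, A, M, config.lambda1, config.lambda2
        )
        if not np.isfinite(losses["total"]):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        trace[epoch] = losses["total"]
        for k in components:
            components[k][epoch] = losses[k]
        opt.step(params, grads)

    final = ModelState(W_e=params["W_e"], b_e=params["b_e"], W_d=params["W_d"],
                       b_d=params["b_d"], B=params["B"], config=config)
    # embeddings from the last evaluated forward pass (pre-update parameters
    # would differ by one step; recompute with the final parameters instead)
    Z = encode(A, X, final)
    H = decode(A, Z, final)
    return EmbeddingResult(Z=Z, H=H, loss_trace=trace, state=final,
                           loss_components=components)
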
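"""Graph convolutional scoring of piRNA-disease pairs on the weighted
heterogeneous network.

The (m+n)-node graph stacks the piRNA sequence-similarity block, the
(weighted) association block and the disease semantic-similarity block:

    A_all = [[P_seq,  A'_PD],
             [A'_PD^T, D_sem]]

Propagation uses the standard self-looped symmetric normalisation
D~^{-1/2} (I + A_all) D~^{-1/2}.  Node inputs are the RWR feature rows,
projected per node type to a common dimension c; after L convolution
layers, three dense reduction layers per side produce the final
embeddings, and the score of a pair is their inner product.  Training
minimises the squared Frobenius error against a beta-enhanced target
(positives inflated to beta, held-out and unknown cells 0) plus an L2
penalty mu * ||W||^2 on the dense/convolution weight matrices.  Batch
normalisation (over the node axis — training is full-batch) precedes
every dense and convolution layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Tensor, concat_rows, glorot_uniform

__all__ = [
    "build_hetero_adjacency",
    "normalize_adjacency",
    "enhanced_target",
    "decode",
    "SWGCNModel",
    "TrainingLog",
    "train_model",
]


def build_hetero_adjacency(
    p_seq: np.ndarray, d_sem: np.ndarray, a_weighted: np.ndarray
) -> np.ndarray:
    """Assemble the (m+n) x (m+n) block adjacency of the heterogeneous graph."""
    p_seq, d_sem, a_w = map(np.asarray, (p_seq, d_sem, a_weighted))
    m, n = a_w.shape
    if p_seq.shape != (m, m) or d_sem.shape != (n, n):
        raise ValueError(
            f"block shapes incompatible: P_seq {p_seq.shape}, D_sem {d_sem.shape}, "
            f"A' {a_w.shape}"
        )
    return np.block([[p_seq, a_w], [a_w.T, d_sem]])


def normalize_adjacency(a_all: np.ndarray) -> np.ndarray:
    """Self-looped symmetric normalisation D~^{-1/2} (I + A_all) D~^{-1/2}.

    The added self-loop guarantees every degree is >= 1, and the
    symmetric scaling bounds the spectrum in [-1, 1].
    """
    a_all = np.asarray(a_all, dtype=np.float64)
    if a_all.shape[0] != a_all.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a_all, a_all.T, atol=1e-8):
        raise ValueError("adjacency must be symmetric")
    if a_all.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    a_tilde = a_all + np.eye(a_all.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def enhanced_target(
    a: np.ndarray, ind2_pairs: np.ndarray, beta: float
) -> np.ndarray:
    """Beta-enhanced training target.

    A cell is 0 when the association is unknown or belongs to the held-out
    evaluation pairs, and beta otherwise; inflating positives to beta > 1
    widens the margin against the overwhelming zero background.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = np.asarray(a)
    target = np.where(a == 1, float(beta), 0.0)
    if len(ind2_pairs):
        ind2_pairs = np.asarray(ind2_pairs)
        target[ind2_pairs[:, 0], ind2_pairs[:, 1]] = 0.0
    return target


def decode(f_p: np.ndarray, f_d: np.ndarray) -> np.ndarray:
    """Inner-product decoder: U[i, j] = <f'_p_i, f'_d_j>."""
    return np.asarray(f_p) @ np.asarray(f_d).T


# ---------------------------------------------------------------------------
# Model


class _BatchNorm:
    """Batch normalisation over the node (row) axis with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred**2.0).mean(axis=0, keepdims=True)
            x_hat = centred * (var + self.eps) ** -0.5
            k = self.momentum
            self.running_mean = (1 - k) * self.running_mean + k * mu.data.ravel()
            self.running_var = (1 - k) * self.running_var + k * var.data.ravel()
        else:
            x_hat = (x - self.running_mean) * (
                (self.running_var + self.eps) ** -0.5
            )
        return x_hat * self.gamma + self.beta


class _Dense:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.w = Tensor(glorot_uniform(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


@dataclass
class TrainingLog:
    losses: list[float] = field(default_factory=list)
    lr_milestones: list[tuple[int, float]] = field(default_factory=list)


class SWGCNModel:
    """The weighted-graph GCN scorer.

    Parameters
    ----------
    m, n
        Numbers of piRNAs and diseases; node inputs are the full-length
        RWR rows (dimension m for piRNAs, n for diseases).
    embed_dim
        Common dimension c of the per-type input projections.
    head_dims
        Widths of the three dense reduction layers applied per side after
        the convolutions.
    gcn_layers
        Number of propagation layers L (ReLU nonlinearity).
    seed
        Seeds the Glorot initialisation.
    """

    def __init__(
        self,
        m: int,
        n: int,
        embed_dim: int = 64,
        head_dims: tuple[int, ...] = (64, 32, 16),
        gcn_layers: int = 1,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.m, self.n = m, n
        self.bn_in_p = _BatchNorm(m)
        self.bn_in_d = _BatchNorm(n)
        self.proj_p = _Dense(rng, m, embed_dim)
        self.proj_d = _Dense(rng, n, embed_dim)
        self.bn_conv = [_BatchNorm(embed_dim) for _ in range(gcn_layers)]
        self.conv_w = [
            Tensor(glorot_uniform(rng, embed_dim, embed_dim), requires_grad=True)
            for _ in range(gcn_layers)
        ]
        dims = (embed_dim, *head_dims)
        self.bn_head_p = [_BatchNorm(d) for d in dims[:-1]]
        self.bn_head_d = [_BatchNorm(d) for d in dims[:-1]]
        self.head_p = [_Dense(rng, dims[i], dims[i + 1]) for i in range(len(head_dims))]
        self.head_d = [_Dense(rng, dims[i], dims[i + 1]) for i in range(len(head_dims))]

    # -- parameter bookkeeping --------------------------------------------

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for bn in (
            self.bn_in_p,
            self.bn_in_d,
            *self.bn_conv,
            *self.bn_head_p,
            *self.bn_head_d,
        ):
            params.extend(bn.params())
        for dense in (self.proj_p, self.proj_d, *self.head_p, *self.head_d):
            params.extend(dense.params())
        params.extend(self.conv_w)
        return params

    def weight_matrices(self) -> list[Tensor]:
        """The dense/convolution weight matrices entering the L2 penalty."""
        mats = [self.proj_p.w, self.proj_d.w, *self.conv_w]
        mats += [d.w for d in self.head_p] + [d.w for d in self.head_d]
        return mats

    # -- persistence -------------------------------------------------------

    def _named_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        bns = {
            "bn_in_p": self.bn_in_p,
            "bn_in_d": self.bn_in_d,
            **{f"bn_conv{i}": bn for i, bn in enumerate(self.bn_conv)},
            **{f"bn_head_p{i}": bn for i, bn in enumerate(self.bn_head_p)},
            **{f"bn_head_d{i}": bn for i, bn in enumerate(self.bn_head_d)},
        }
        for name, bn in bns.items():
            arrays[f"{name}.gamma"] = bn.gamma.data
            arrays[f"{name}.beta"] = bn.beta.data
            arrays[f"{name}.running_mean"] = bn.running_mean
            arrays[f"{name}.running_var"] = bn.running_var
        denses = {
            "proj_p": self.proj_p,
            "proj_d": self.proj_d,
            **{f"head_p{i}": d for i, d in enumerate(self.head_p)},
            **{f"head_d{i}": d for i, d in enumerate(self.head_d)},
        }
        for name, dense in denses.items():
            arrays[f"{name}.w"] = dense.w.data
            arrays[f"{name}.b"] = dense.b.data
        for i, w in enumerate(self.conv_w):
            arrays[f"conv_w{i}"] = w.data
        return arrays

    def save(self, path) -> None:
        """Write all parameters and batch-norm statistics to an .npz file."""
        meta = np.array(
            [self.m, self.n, self.proj_p.w.data.shape[1], len(self.conv_w)]
        )
        np.savez(path, _meta=meta, **self._named_arrays())

    @classmethod
    def load(cls, path, head_dims: tuple[int, ...] = (64, 32, 16)) -> "SWGCNModel":
        with np.load(path) as data:
            m, n, embed_dim, layers = (int(x) for x in data["_meta"])
            # Recover head widths from the stored dense shapes.
            dims = []
            i = 0
            while f"head_p{i}.w" in data:
                dims.append(data[f"head_p{i}.w"].shape[1])
                i += 1
            model = cls(
                m, n, embed_dim=embed_dim, head_dims=tuple(dims) or head_dims,
                gcn_layers=layers,
            )
            for name, arr in model._named_arrays().items():
                arr[...] = data[name]
        return model

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        fp: np.ndarray,
        fd: np.ndarray,
        operator: np.ndarray,
        training: bool,
    ) -> tuple[Tensor, Tensor]:
        """Embed all nodes; returns (piRNA embeddings, disease embeddings)."""
        op = Tensor(operator)
        xp = self.proj_p(self.bn_in_p(Tensor(fp), training))
        xd = self.proj_d(self.bn_in_d(Tensor(fd), training))
        h = concat_rows(xp, xd)
        for bn, w in zip(self.bn_conv, self.conv_w):
            h = (op @ bn(h, training) @ w).relu()
        ep, ed = h.rows(0, self.m), h.rows(self.m, self.m + self.n)
        for i, (bn_p, bn_d, lp, ld) in enumerate(
            zip(self.bn_head_p, self.bn_head_d, self.head_p, self.head_d)
        ):
            ep, ed = lp(bn_p(ep, training)), ld(bn_d(ed, training))
            if i < len(self.head_p) - 1:
                ep, ed = ep.relu(), ed.relu()
        return ep, ed

    def score_tensor(
        self, fp: np.ndarray, fd: np.ndarray, operator: np.ndarray, training: bool
    ) -> Tensor:
        ep, ed = self.forward(fp, fd, operator, training)
        return ep @ ed.t()

    def predict(
        self, fp: np.ndarray, fd: np.ndarray, operator: np.ndarray
    ) -> np.ndarray:
        """Deterministic evaluation-mode score matrix U (running BN stats)."""
        u = self.score_tensor(fp, fd, operator, training=False).data
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("non-finite scores in evaluation forward pass")
        return u

    def loss_tensor(self, u: Tensor, target: np.ndarray, mu: float) -> Tensor:
        """Squared Frobenius error plus mu * sum of squared weights."""
        err = ((u - Tensor(target)) ** 2.0).sum()
        if mu:
            for w in self.weight_matrices():
                err = err + mu * (w**2.0).sum()
        return err

    def loss_value(self, u: np.ndarray, target: np.ndarray, mu: float) -> float:
        penalty = (
            mu * sum(float((w.data**2).sum()) for w in self.weight_matrices())
            if mu
            else 0.0
        )
        return float(((np.asarray(u) - target) ** 2).sum() + penalty)


def train_model(
    model: SWGCNModel,
    fp: np.ndarray,
    fd: np.ndarray,
    operator: np.ndarray,
    target: np.ndarray,
    epochs: int = 1000,
    learning_rate: float = 1e-3,
    lr_decay: float = 0.2,
    mu: float = 1.0,
    decay_milestones: tuple[float, ...] = (0.5, 0.75),
) -> TrainingLog:
    """Full-batch training of the model against the enhanced target.

    The learning rate is multiplied by ``lr_decay`` when training reaches
    each fraction of the epoch budget in ``decay_milestones``.  A NaN loss
    aborts immediately with the epoch index.
    """
    log = TrainingLog()
    opt = Adam(model.parameters(), lr=learning_rate)
    milestones = {int(epochs * f) for f in decay_milestones}
    for epoch in range(epochs):
        if epoch in milestones and epoch > 0:
            opt.lr *= lr_decay
            log.lr_milestones.append((epoch, opt.lr))
        opt.zero_grad()
        u = model.score_tensor(fp, fd, operator, training=True)
        loss = model.loss_tensor(u, target, mu)
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        loss.backward()
        opt.step()
        log.losses.append(value)
    return log
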
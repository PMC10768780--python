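"""The hybrid Nm-site network.

Architecture: one stacked 1D-CNN block per conventional descriptor (three
conv -> ReLU -> max-pool stages, flatten, dropout, FC) and one stacked
Bi-GRU block with attention pooling per embedding channel (two bidirectional
GRU layers, additive attention over the 41 time steps, FC).  The 14 + 5
branch representations are concatenated and passed through a hidden FC layer
with ReLU and a single sigmoid output unit giving the probability that the
central nucleotide is 2'-O-methylated.

All forward primitives are exposed both as autograd operations (used in
training) and as numpy-in / numpy-out convenience wrappers used by the tests
and by downstream callers that only need inference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import NetworkConfig

EPS = 1e-7  # probability clipping for the cross-entropy loss


# ---------------------------------------------------------------------------
# shape arithmetic


def conv1d_out_length(L_in: int, P: int, D: int, kappa: int, S: int) -> int:
    """Output length of a 1-D convolution/pooling stage.

    floor(1 + (L_in + 2P - D(kappa - 1) - 1) / S); a result below 1 is a
    configuration error (the signal has been consumed).
    """
    if min(L_in, D, kappa, S) < 1 or P < 0:
        raise ValueError("invalid convolution geometry")
    L_out = 1 + (L_in + 2 * P - D * (kappa - 1) - 1) // S
    if L_out < 1:
        raise ValueError(
            f"convolution output length {L_out} < 1 for L_in={L_in}, P={P}, "
            f"D={D}, kappa={kappa}, S={S}"
        )
    return L_out


# ---------------------------------------------------------------------------
# numpy-facing forward primitives


def conv1d_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray,
                   stride: int = 1, pad: int = 0, dilation: int = 1) -> np.ndarray:
    """Cross-correlation (no kernel flip) of a (C_in, L) or (B, C_in, L)
    signal with (C_out, C_in, k) filters plus per-channel bias."""
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    out = ag.conv1d(Tensor(xb), Tensor(weight), Tensor(bias),
                    stride=stride, pad=pad, dilation=dilation).data
    return out[0] if squeeze else out


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, x)


def maxpool1d(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Window maxima per channel of a (C, L) or (B, C, L) signal."""
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    out = ag.maxpool1d(Tensor(xb), kernel, stride).data
    return out[0] if squeeze else out


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """One GRU update.

    u = sigma(W_iu x + U_hu h + b_iu + b_hu)
    r = sigma(W_ir x + U_hr h + b_ir + b_hr)
    n = tanh(W_in x + b_in + r * (U_hn h + b_hn))
    h' = (1 - u) * n + u * h
    """
    p = {k: Tensor(v) for k, v in params.items()}
    h = _gru_step_t(Tensor(np.atleast_2d(x_t)), Tensor(np.atleast_2d(h_prev)), p)
    return h.data[0] if np.ndim(x_t) == 1 else h.data


def _gru_step_t(x_t: Tensor, h_prev: Tensor, p: dict[str, Tensor]) -> Tensor:
    u = ag.sigmoid(x_t @ p["W_iu"] + h_prev @ p["U_hu"] + p["b_iu"] + p["b_hu"])
    r = ag.sigmoid(x_t @ p["W_ir"] + h_prev @ p["U_hr"] + p["b_ir"] + p["b_hr"])
    n = ag.tanh(x_t @ p["W_in"] + p["b_in"] + ag.mul(r, h_prev @ p["U_hn"] + p["b_hn"]))
    one = Tensor(1.0)
    return ag.add(ag.mul(one - u, n), ag.mul(u, h_prev))


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


_GRU_PARAM_ORDER = ("W_iu", "W_ir", "W_in", "U_hu", "U_hr", "U_hn",
                    "b_iu", "b_ir", "b_in", "b_hu", "b_hr", "b_hn")


def gru_sequence(E: Tensor, p: dict[str, Tensor], reverse: bool) -> Tensor:
    """One GRU direction over E (B, T, d) as a single fused graph node.

    The forward pass is a plain numpy recurrence; the backward pass is
    hand-written backpropagation through time over the cached gate
    activations.  Hidden states are returned in forward time order
    regardless of direction.
    """
    parents = [E] + [p[k] for k in _GRU_PARAM_ORDER]
    x = E.data
    B, T, d = x.shape
    H = p["U_hu"].shape[0]
    Wi = np.concatenate([p["W_iu"].data, p["W_ir"].data, p["W_in"].data], axis=1)
    U = np.concatenate([p["U_hu"].data, p["U_hr"].data, p["U_hn"].data], axis=1)
    bi = np.concatenate([p["b_iu"].data, p["b_ir"].data, p["b_in"].data])
    bh = np.concatenate([p["b_hu"].data, p["b_hr"].data, p["b_hn"].data])

    XP = x @ Wi + bi  # (B, T, 3H)
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H))
    H_out = np.empty((B, T, H))
    u_c = np.empty((B, T, H)); r_c = np.empty((B, T, H))
    n_c = np.empty((B, T, H)); hpn_c = np.empty((B, T, H))
    hprev_c = np.empty((B, T, H))
    for t in order:
        HP = h @ U + bh
        u = _sigmoid_np(XP[:, t, :H] + HP[:, :H])
        r = _sigmoid_np(XP[:, t, H:2 * H] + HP[:, H:2 * H])
        n = np.tanh(XP[:, t, 2 * H:] + r * HP[:, 2 * H:])
        hprev_c[:, t] = h
        h = (1.0 - u) * n + u * h
        H_out[:, t] = h
        u_c[:, t], r_c[:, t], n_c[:, t], hpn_c[:, t] = u, r, n, HP[:, 2 * H:]

    def backward(gH: np.ndarray):
        gXP = np.empty((B, T, 3 * H))
        gHP = np.empty((B, T, 3 * H))
        Ut = U.T
        gh = np.zeros((B, H))
        for t in (range(T) if reverse else range(T - 1, -1, -1)):
            g = gH[:, t] + gh
            u, r, n = u_c[:, t], r_c[:, t], n_c[:, t]
            hpn, hprev = hpn_c[:, t], hprev_c[:, t]
            gu = g * (hprev - n) * u * (1.0 - u)
            gn = g * (1.0 - u) * (1.0 - n * n)
            gr = gn * hpn * r * (1.0 - r)
            gHPn = gn * r
            gXP[:, t, :H] = gu
            gXP[:, t, H:2 * H] = gr
            gXP[:, t, 2 * H:] = gn
            gHP[:, t, :H] = gu
            gHP[:, t, H:2 * H] = gr
            gHP[:, t, 2 * H:] = gHPn
            gh = g * u + gHP[:, t] @ Ut
        gE = gXP @ Wi.T
        gWi = np.einsum("btd,bto->do", x, gXP, optimize=True)
        gU = np.einsum("bth,bto->ho", hprev_c, gHP, optimize=True)
        gbi = gXP.sum(axis=(0, 1))
        gbh = gHP.sum(axis=(0, 1))
        return (
            gE,
            gWi[:, :H], gWi[:, H:2 * H], gWi[:, 2 * H:],
            gU[:, :H], gU[:, H:2 * H], gU[:, 2 * H:],
            gbi[:H], gbi[H:2 * H], gbi[2 * H:],
            gbh[:H], gbh[H:2 * H], gbh[2 * H:],
        )

    return Tensor._make(H_out, parents, backward)


def bigru_forward_t(E: Tensor, params: dict[str, dict[str, Tensor]]) -> Tensor:
    fwd = gru_sequence(E, params["forward"], reverse=False)
    bwd = gru_sequence(E, params["backward"], reverse=True)
    return ag.concat([fwd, bwd], axis=2)


def bigru_forward(E: np.ndarray, params: dict[str, dict[str, np.ndarray]]) -> np.ndarray:
    """Bidirectional GRU over E (T, d) or (B, T, d); row t is the
    concatenation [forward h_t ; backward h_t]; initial states are zero."""
    squeeze = E.ndim == 2
    Eb = E[None] if squeeze else E
    p = {d: {k: Tensor(v) for k, v in sub.items()} for d, sub in params.items()}
    out = bigru_forward_t(Tensor(Eb), p).data
    return out[0] if squeeze else out


def attention_t(H: Tensor, p: dict[str, Tensor]) -> tuple[Tensor, Tensor]:
    scores = ag.tanh(H @ p["W_a"] + p["b_a"]) @ p["x_a"]  # (B, T, 1)
    B, T = scores.shape[0], scores.shape[1]
    alpha = ag.softmax(ag.reshape(scores, (B, T)), axis=1)
    context = ag.reshape(ag.reshape(alpha, (B, 1, T)) @ H, (B, H.shape[2]))
    return context, alpha


def attention(H: np.ndarray, params: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Additive attention pooling.

    A_t = x_a^T tanh(W_a h_t + b); alpha = softmax(A); c = sum_t alpha_t h_t.
    Accepts (T, 2H) or (B, T, 2H); returns (context, alpha).
    """
    squeeze = H.ndim == 2
    Hb = H[None] if squeeze else H
    p = {k: Tensor(v) for k, v in params.items()}
    c, a = attention_t(Tensor(Hb), p)
    return (c.data[0], a.data[0]) if squeeze else (c.data, a.data)


def bce_loss(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean binary cross-entropy, -[y ln p + (1-y) ln(1-p)], with p clipped
    to [EPS, 1-EPS]."""
    y = np.asarray(labels, dtype=float)
    p = np.clip(np.asarray(probs, dtype=float), EPS, 1.0 - EPS)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def bce_loss_t(y: np.ndarray, p: Tensor) -> Tensor:
    pc = ag.clip(p, EPS, 1.0 - EPS)
    yt = Tensor(np.asarray(y, dtype=float))
    one = Tensor(1.0)
    ll = ag.add(ag.mul(yt, ag.log(pc)), ag.mul(one - yt, ag.log(one - pc)))
    return ag.mean(ll) * Tensor(-1.0)


# ---------------------------------------------------------------------------
# parameter construction


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _gru_direction_params(rng: np.random.Generator, d: int, H: int) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    for gate in ("u", "r", "n"):
        p[f"W_i{gate}"] = _glorot(rng, (d, H))
        p[f"U_h{gate}"] = _glorot(rng, (H, H))
        p[f"b_i{gate}"] = np.zeros(H)
        p[f"b_h{gate}"] = np.zeros(H)
    return p


@dataclass
class HybridParams:
    """All weights of the hybrid model, keyed by branch."""

    cnn: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    gru: dict[str, dict] = field(default_factory=dict)
    fusion: dict[str, np.ndarray] = field(default_factory=dict)

    def flat(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for branch, params in self.cnn.items():
            for k, v in params.items():
                out[f"cnn/{branch}/{k}"] = v
        for branch, params in self.gru.items():
            for layer in ("layer1", "layer2"):
                for direction in ("forward", "backward"):
                    for k, v in params[layer][direction].items():
                        out[f"gru/{branch}/{layer}/{direction}/{k}"] = v
            for k, v in params["attention"].items():
                out[f"gru/{branch}/attention/{k}"] = v
            for k, v in params["fc"].items():
                out[f"gru/{branch}/fc/{k}"] = v
        for k, v in self.fusion.items():
            out[f"fusion/{k}"] = v
        return out

    @classmethod
    def from_flat(cls, flat: dict[str, np.ndarray]) -> "HybridParams":
        p = cls()
        for key, v in flat.items():
            parts = key.split("/")
            if parts[0] == "cnn":
                p.cnn.setdefault(parts[1], {})[parts[2]] = v
            elif parts[0] == "fusion":
                p.fusion[parts[1]] = v
            else:
                branch = p.gru.setdefault(
                    parts[1],
                    {"layer1": {"forward": {}, "backward": {}},
                     "layer2": {"forward": {}, "backward": {}},
                     "attention": {}, "fc": {}},
                )
                if parts[2] in ("layer1", "layer2"):
                    branch[parts[2]][parts[3]][parts[4]] = v
                else:
                    branch[parts[2]][parts[3]] = v
        return p


def _pool_geometry(L: int, kernel: int, stride: int) -> tuple[int, int]:
    """Clamp the pooling kernel to the signal length so short descriptor
    branches (e.g. sequence-averaged physicochemical vectors) still admit
    three pooling stages; a kernel-1 pool is the identity."""
    k = min(kernel, L)
    return k, stride


def cnn_flat_dim(input_dim: int, config: NetworkConfig) -> int:
    """Length of the flattened signal after the three conv/pool stages."""
    L = input_dim
    for _ in range(3):
        L = conv1d_out_length(L, config.conv_padding, config.conv_dilation,
                              config.conv_kernel, config.conv_stride)
        pk, ps = _pool_geometry(L, config.pool_kernel, config.pool_stride)
        L = conv1d_out_length(L, 0, 1, pk, ps)
    return L * config.conv_channels[2]


def init_params(
    descriptor_dims: dict[str, int],
    embedding_dims: dict[str, int],
    config: NetworkConfig,
    seed: int,
) -> HybridParams:
    """Reproducible Glorot-uniform initialization (biases zero) of every
    branch for the given descriptor/embedding inventory."""
    rng = np.random.default_rng(seed)
    params = HybridParams()
    ch = config.conv_channels
    for name in sorted(descriptor_dims):
        dim = descriptor_dims[name]
        flat = cnn_flat_dim(dim, config)
        k = config.conv_kernel
        params.cnn[name] = {
            "conv1_w": _glorot(rng, (ch[0], 1, k)), "conv1_b": np.zeros(ch[0]),
            "conv2_w": _glorot(rng, (ch[1], ch[0], k)), "conv2_b": np.zeros(ch[1]),
            "conv3_w": _glorot(rng, (ch[2], ch[1], k)), "conv3_b": np.zeros(ch[2]),
            "fc_w": _glorot(rng, (flat, config.cnn_fc_dim)),
            "fc_b": np.zeros(config.cnn_fc_dim),
        }
    H = config.gru_hidden
    for name in sorted(embedding_dims):
        d = embedding_dims[name]
        params.gru[name] = {
            "layer1": {
                "forward": _gru_direction_params(rng, d, H),
                "backward": _gru_direction_params(rng, d, H),
            },
            "layer2": {
                "forward": _gru_direction_params(rng, 2 * H, H),
                "backward": _gru_direction_params(rng, 2 * H, H),
            },
            "attention": {
                "W_a": _glorot(rng, (2 * H, config.attention_dim)),
                "b_a": np.zeros(config.attention_dim),
                "x_a": rng.standard_normal((config.attention_dim, 1)) * 0.1,
            },
            "fc": {
                "w": _glorot(rng, (2 * H, config.gru_fc_dim)),
                "b": np.zeros(config.gru_fc_dim),
            },
        }
    fused = len(descriptor_dims) * config.cnn_fc_dim + len(embedding_dims) * config.gru_fc_dim
    params.fusion = {
        "hidden_w": _glorot(rng, (fused, config.fusion_hidden)),
        "hidden_b": np.zeros(config.fusion_hidden),
        "out_w": _glorot(rng, (config.fusion_hidden, 1)),
        "out_b": np.zeros(1),
    }
    return params


# ---------------------------------------------------------------------------
# block forwards


def cnn_block_forward_t(
    v: Tensor, p: dict[str, Tensor], config: NetworkConfig,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """v (B, dim) -> (B, fc_dim); single-channel signal through 3x(conv ->
    ReLU -> pool), flatten, dropout, FC."""
    B = v.shape[0]
    x = ag.reshape(v, (B, 1, v.shape[1]))
    for i in (1, 2, 3):
        x = ag.conv1d(x, p[f"conv{i}_w"], p[f"conv{i}_b"],
                      stride=config.conv_stride, pad=config.conv_padding,
                      dilation=config.conv_dilation)
        x = ag.relu(x)
        pk, ps = _pool_geometry(x.shape[2], config.pool_kernel, config.pool_stride)
        x = ag.maxpool1d(x, pk, ps)
    flat = ag.reshape(x, (B, x.shape[1] * x.shape[2]))
    flat = ag.dropout(flat, config.dropout, rng)
    return flat @ p["fc_w"] + p["fc_b"]


def cnn_block_forward(v: np.ndarray, params: dict[str, np.ndarray],
                      config: NetworkConfig) -> np.ndarray:
    """Inference-mode CNN branch on (dim,) or (B, dim) input."""
    squeeze = v.ndim == 1
    vb = np.atleast_2d(v)
    p = {k: Tensor(x) for k, x in params.items()}
    out = cnn_block_forward_t(Tensor(vb), p, config, rng=None).data
    return out[0] if squeeze else out


def gru_att_block_forward_t(
    E: Tensor, p: dict, config: NetworkConfig,
) -> tuple[Tensor, Tensor]:
    """E (B, T, d) -> ((B, fc_dim), attention weights (B, T))."""
    H1 = bigru_forward_t(E, p["layer1"])
    H2 = bigru_forward_t(H1, p["layer2"])
    context, alpha = attention_t(H2, p["attention"])
    return context @ p["fc"]["w"] + p["fc"]["b"], alpha


def gru_att_block_forward(E: np.ndarray, params: dict,
                          config: NetworkConfig) -> tuple[np.ndarray, np.ndarray]:
    squeeze = E.ndim == 2
    Eb = E[None] if squeeze else E

    def wrap(d):
        return {k: (wrap(v) if isinstance(v, dict) else Tensor(v)) for k, v in d.items()}

    out, alpha = gru_att_block_forward_t(Tensor(Eb), wrap(params), config)
    if squeeze:
        return out.data[0], alpha.data[0]
    return out.data, alpha.data


@dataclass
class ForwardTrace:
    """Intermediate quantities of one forward pass."""

    cnn_reps: dict[str, np.ndarray]
    gru_reps: dict[str, np.ndarray]
    attention_weights: dict[str, np.ndarray]
    probability: np.ndarray


def fuse_and_predict_t(
    cnn_reps: list[Tensor], gru_reps: list[Tensor], p: dict[str, Tensor],
) -> Tensor:
    fused = ag.concat(list(cnn_reps) + list(gru_reps), axis=1)
    hidden = ag.relu(fused @ p["hidden_w"] + p["hidden_b"])
    logit = hidden @ p["out_w"] + p["out_b"]
    return ag.reshape(ag.sigmoid(logit), (logit.shape[0],))


def fuse_and_predict(cnn_reps: list[np.ndarray], gru_reps: list[np.ndarray],
                     params: dict[str, np.ndarray]) -> np.ndarray:
    c = [Tensor(np.atleast_2d(r)) for r in cnn_reps]
    g = [Tensor(np.atleast_2d(r)) for r in gru_reps]
    p = {k: Tensor(v) for k, v in params.items()}
    return fuse_and_predict_t(c, g, p).data


class HybridModel:
    """The full hybrid classifier over descriptor vectors and embedding
    matrices.

    ``descriptor_dims`` / ``embedding_dims`` fix the branch inventory; the
    generic default has 14 CNN branches and 5 GRU-attention branches.
    """

    def __init__(
        self,
        descriptor_dims: dict[str, int],
        embedding_dims: dict[str, int],
        config: NetworkConfig | None = None,
        seed: int = 0,
        params: HybridParams | None = None,
        site_type: str = "N",
    ):
        self.config = (config or NetworkConfig())
        self.config.validate()
        self.descriptor_dims = dict(descriptor_dims)
        self.embedding_dims = dict(embedding_dims)
        self.seed = seed
        self.site_type = site_type
        self.params = params or init_params(
            self.descriptor_dims, self.embedding_dims, self.config, seed
        )

    # -- forward ------------------------------------------------------------

    def _wrapped_params(self, train: bool):
        leaves: dict[str, Tensor] = {}

        def wrap(d, prefix):
            out = {}
            for k, v in d.items():
                if isinstance(v, dict):
                    out[k] = wrap(v, f"{prefix}/{k}")
                else:
                    t = Tensor(v, requires_grad=train)
                    leaves[f"{prefix}/{k}"] = t
                    out[k] = t
            return out

        cnn = {name: wrap(p, f"cnn/{name}") for name, p in self.params.cnn.items()}
        gru = {name: wrap(p, f"gru/{name}") for name, p in self.params.gru.items()}
        fusion = wrap(self.params.fusion, "fusion")
        return cnn, gru, fusion, leaves

    def forward_t(
        self,
        descriptors: dict[str, np.ndarray],
        embeddings: dict[str, np.ndarray],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, dict[str, Tensor], ForwardTrace]:
        cnn_p, gru_p, fusion_p, leaves = self._wrapped_params(train)
        cnn_reps, gru_reps, alphas = {}, {}, {}
        cnn_list, gru_list = [], []
        for name in sorted(self.descriptor_dims):
            rep = cnn_block_forward_t(
                Tensor(descriptors[name]), cnn_p[name], self.config,
                rng=rng if train else None,
            )
            cnn_reps[name] = rep
            cnn_list.append(rep)
        for name in sorted(self.embedding_dims):
            rep, alpha = gru_att_block_forward_t(
                Tensor(embeddings[name]), gru_p[name], self.config
            )
            gru_reps[name] = rep
            gru_list.append(rep)
            alphas[name] = alpha
        prob = fuse_and_predict_t(cnn_list, gru_list, fusion_p)
        trace = ForwardTrace(
            cnn_reps={k: v.data for k, v in cnn_reps.items()},
            gru_reps={k: v.data for k, v in gru_reps.items()},
            attention_weights={k: v.data for k, v in alphas.items()},
            probability=prob.data,
        )
        return prob, leaves, trace

    def predict_proba(
        self,
        descriptors: dict[str, np.ndarray],
        embeddings: dict[str, np.ndarray],
        batch_size: int = 256,
    ) -> np.ndarray:
        """Deterministic inference (dropout off), batched."""
        n = next(iter(descriptors.values())).shape[0]
        probs = np.empty(n)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            d = {k: v[sl] for k, v in descriptors.items()}
            e = {k: v[sl] for k, v in embeddings.items()}
            prob, _, _ = self.forward_t(d, e, train=False)
            probs[sl] = prob.data
        return probs

    def trace(self, descriptors, embeddings) -> ForwardTrace:
        _, _, tr = self.forward_t(descriptors, embeddings, train=False)
        return tr

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: config echo, seed and all weights."""
        meta = {
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "conv_kernel", "conv_stride", "conv_padding", "conv_dilation",
                    "pool_kernel", "pool_stride", "dropout", "cnn_fc_dim",
                    "gru_hidden", "attention_dim", "gru_fc_dim", "fusion_hidden",
                )},
                "conv_channels": list(self.config.conv_channels),
            },
            "descriptor_dims": self.descriptor_dims,
            "embedding_dims": self.embedding_dims,
            "seed": self.seed,
            "site_type": self.site_type,
        }
        flat = self.params.flat()
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **flat)

    @classmethod
    def load(cls, path: str | Path) -> "HybridModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            flat = {k: archive[k] for k in archive.files if k != "__meta__"}
        cfg_d = meta["config"]
        cfg = NetworkConfig(
            conv_channels=tuple(cfg_d.pop("conv_channels")), **cfg_d
        )
        model = cls(
            descriptor_dims=meta["descriptor_dims"],
            embedding_dims=meta["embedding_dims"],
            config=cfg,
            seed=meta["seed"],
            params=HybridParams.from_flat(flat),
            site_type=meta.get("site_type", "N"),
        )
        return model

    # -- structure ------------------------------------------------------------

    def structure_summary(self) -> dict[str, int]:
        """Branch and layer counts, used by the structural self-checks."""
        return {
            "n_cnn_branches": len(self.params.cnn),
            "n_gru_branches": len(self.params.gru),
            "conv_layers_per_cnn_branch": 3,
            "pool_layers_per_cnn_branch": 3,
            "bigru_layers_per_gru_branch": 2,
        }
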
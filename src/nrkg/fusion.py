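"""Attention-based fusion of embeddings with nutrition features.

Recipe side: a learned recipe vector ``r`` (width ``d_model``) is merged
with the projected standardized nutrient vector by element-wise product,
giving three width-``2 d_model`` views — [r*n ‖ r], [r*n ‖ n] and their
element-wise sum — which a multi-head self-attention block fuses into the
final recipe embedding (mean-pooled over the three tokens).

User side: the learned user vector is concatenated with the projected
7-component preference profile, matching the recipe embedding width.

The raw 7-component nutrient vectors cannot be multiplied element-wise
with a ``d_model``-wide embedding, so both nutrient inputs pass through
learned bias-free linear projections 7 -> ``d_model`` first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, glorot
from .data_io import N_NUTRIENTS


@dataclass
class EmbeddingConfig:
    """Widths and seeding for the fusion block.

    ``d_model`` is the base embedding width (fused embeddings have width
    ``2 * d_model``); ``heads`` splits the token width into
    ``d_k = 2 * d_model / heads`` per attention head. ``attention_mode``
    selects self-attention over the three fusion views (``"self"``,
    default) or a single cross-attention step with the product-embedding
    view as query (``"cross"``).
    """

    d_model: int = 16
    heads: int = 2
    seed: int = 0
    attention_mode: str = "self"

    def __post_init__(self) -> None:
        if self.d_model <= 0 or self.heads <= 0:
            raise ValueError("d_model and heads must be positive")
        if (2 * self.d_model) % self.heads != 0:
            raise ValueError(
                f"token width {2 * self.d_model} not divisible by heads={self.heads}"
            )
        if self.attention_mode not in ("self", "cross"):
            raise ValueError(f"unknown attention_mode {self.attention_mode!r}")

    @property
    def width(self) -> int:
        return 2 * self.d_model


@dataclass
class AttentionParams:
    """Projection matrices for one multi-head attention block."""

    WQ: Tensor
    WK: Tensor
    WV: Tensor
    WO: Tensor
    heads: int

    @classmethod
    def init(cls, rng: np.random.Generator, width: int, heads: int) -> "AttentionParams":
        if width % heads != 0:
            raise ValueError(f"width {width} not divisible by heads={heads}")
        return cls(
            WQ=glorot(rng, width, width),
            WK=glorot(rng, width, width),
            WV=glorot(rng, width, width),
            WO=glorot(rng, width, width),
            heads=heads,
        )

    @classmethod
    def identity(cls, width: int, heads: int = 1) -> "AttentionParams":
        if width % heads != 0:
            raise ValueError(f"width {width} not divisible by heads={heads}")
        eye = lambda: Tensor(np.eye(width), requires_grad=False)
        return cls(WQ=eye(), WK=eye(), WV=eye(), WO=eye(), heads=heads)

    def tensors(self) -> list:
        return [self.WQ, self.WK, self.WV, self.WO]


def project_nutrients(theta: Tensor | np.ndarray, W: Tensor) -> Tensor:
    """Bias-free linear map of 7-component nutrient rows to model width."""
    theta = theta if isinstance(theta, Tensor) else Tensor(theta)
    return theta @ _transpose(W)


def _transpose(W: Tensor) -> Tensor:
    """Differentiable transpose via matmul orientation.

    Weight matrices are stored (out, in); rows of the input batch multiply
    W^T. Implemented by wrapping a transposed view that shares gradient.
    """
    out = Tensor(W.data.T, requires_grad=W.requires_grad)
    if out.requires_grad:
        out._prev = (W,)
        out._backward = lambda g: W._accum(g.T)
    return out


def linear(x: Tensor | np.ndarray, W: Tensor) -> Tensor:
    """x @ W.T for batched rows."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    return x @ _transpose(W)


def multi_head_attention(queries, keys, values, params: AttentionParams):
    """Scaled dot-product multi-head attention over short token sequences.

    ``queries``/``keys``/``values`` are lists of (N, width) tensors — one
    entry per token position, batched over N items. Returns one output
    token per query position: ``softmax(Q K^T / sqrt(d_k)) V`` per head,
    heads concatenated and passed through the output map.
    """
    q_proj = [linear(t, params.WQ) for t in queries]
    k_proj = [linear(t, params.WK) for t in keys]
    v_proj = [linear(t, params.WV) for t in values]
    width = q_proj[0].shape[1]
    h = params.heads
    if width % h != 0:
        raise ValueError(f"token width {width} not divisible by heads={h}")
    d_k = width // h
    scale = 1.0 / np.sqrt(d_k)

    outputs = []
    for qi in q_proj:
        head_outs = []
        for head in range(h):
            cols = slice(head * d_k, (head + 1) * d_k)
            qh = qi[:, cols]
            khs = [kj[:, cols] for kj in k_proj]
            vhs = [vj[:, cols] for vj in v_proj]
            # per-pair scores (N, 1); softmax across the key tokens
            scores = [(qh * kh).sum(axis=1, keepdims=True) * scale for kh in khs]
            shift = np.max([s.data for s in scores], axis=0)  # detached; softmax shift-invariant
            exps = [(s - shift).exp() for s in scores]
            denom = exps[0]
            for e in exps[1:]:
                denom = denom + e
            attended = None
            for e, vh in zip(exps, vhs):
                term = (e * vh)
                attended = term if attended is None else attended + term
            inv = denom.clip(1e-300, np.inf)
            head_outs.append(attended * _reciprocal(inv))
        concat_heads = concat(head_outs, axis=1)
        outputs.append(linear(concat_heads, params.WO))
    return outputs


def _reciprocal(t: Tensor) -> Tensor:
    """1/t via exp(-log t); t must be positive."""
    return (-(t.log())).exp()


def fuse_recipe(r, theta_proj, attn: AttentionParams, mode: str = "self") -> Tensor:
    """Fuse recipe vectors with projected nutrient vectors.

    r_n = r * theta_proj (element-wise); the three attention tokens are
    [r_n ‖ r], [r_n ‖ theta_proj] and their sum. ``"self"`` mode runs
    self-attention over the 3-token sequence and mean-pools the outputs;
    ``"cross"`` uses the first view as query, second as key, sum as value.
    """
    r = r if isinstance(r, Tensor) else Tensor(r)
    theta_proj = theta_proj if isinstance(theta_proj, Tensor) else Tensor(theta_proj)
    if r.shape != theta_proj.shape:
        raise ValueError(
            f"element-wise product stage: shapes {r.shape} vs {theta_proj.shape}"
        )
    r_n = r * theta_proj
    r_nr = concat([r_n, r], axis=1)
    r_nn = concat([r_n, theta_proj], axis=1)
    gamma = r_nr + r_nn
    if mode == "self":
        tokens = [r_nr, r_nn, gamma]
        outs = multi_head_attention(tokens, tokens, tokens, attn)
        pooled = (outs[0] + outs[1] + outs[2]) / 3.0
        return pooled
    if mode == "cross":
        outs = multi_head_attention([r_nr], [r_nn], [gamma], attn)
        return outs[0]
    raise ValueError(f"unknown attention mode {mode!r}")


def fuse_user(u, profile_proj) -> Tensor:
    """User embedding: learned vector concatenated with projected profile."""
    u = u if isinstance(u, Tensor) else Tensor(u)
    profile_proj = profile_proj if isinstance(profile_proj, Tensor) else Tensor(profile_proj)
    if u.shape[0] != profile_proj.shape[0]:
        raise ValueError("user batch and profile batch sizes differ")
    return concat([u, profile_proj], axis=1)


@dataclass
class FusionParams:
    """All learned parameters of the fusion stage."""

    W_nutrient: Tensor  # 7 -> d_model, recipe nutrients
    W_profile: Tensor  # 7 -> d_model, user profiles
    attention: AttentionParams

    @classmethod
    def init(cls, cfg: EmbeddingConfig, rng: np.random.Generator) -> "FusionParams":
        return cls(
            W_nutrient=glorot(rng, N_NUTRIENTS, cfg.d_model),
            W_profile=glorot(rng, N_NUTRIENTS, cfg.d_model),
            attention=AttentionParams.init(rng, cfg.width, cfg.heads),
        )

    def tensors(self) -> list:
        return [self.W_nutrient, self.W_profile] + self.attention.tensors()
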
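"""The IMPACT network: three modality-specific temporal transformer encoders
(ROI, ICA, dynamic-connectivity streams), cross-modal attention fusion with
learned softmax gating, and a residual classification head.

Architecture summary (all shapes batched, batch dim first):

* Each stream X in R^{T x d} is linearly embedded to R^{T x h} and fixed
  sinusoidal positional encodings are added.
* Encoder layers are pre-activation-free transformer blocks:
  h1 = LayerNorm(X + MultiHead(X)); h2 = LayerNorm(h1 + FFN(h1)) with GELU,
  plus learned per-head relative position biases over clipped offsets
  (shared across layers within an encoder).
* Fusion stage 1: cross-modal attention with the ROI states as queries and
  the ICA states as keys/values. Stage 2: temporal mean-pooling of each
  stream, scalar gate logits w_m . h_m + b_m, softmax over modalities, and a
  convex combination of the pooled vectors (the ROI slot carries the pooled
  cross-attention states so stage 1 participates in the output).
* Classifier: residual blocks Linear(h, w) -> GELU -> Linear(w, h) with
  LayerNorm, then a final linear map to 2 logits.

Weights use Kaiming initialization; the attention projections W_Q/W_K/W_V and
the FFN weights are additionally scaled by 1/sqrt(n_heads); biases start at 0.

The default configuration is calibrated so the full model has 9.34M trainable
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import Tensor, Module, Parameter, Linear, LayerNorm, Dropout, concatenate
from .nn.modules import kaiming_normal

__all__ = [
    "ModelConfig", "EncoderOutput", "FusionOutput", "ClassOutput",
    "ForwardResult", "sinusoidal_positions", "scaled_dot_attention",
    "relative_attention", "MultiHeadAttention", "TransformerLayer",
    "ModalityEncoder", "CrossModalFusion", "ResidualClassifier", "ImpactModel",
    "count_parameters", "estimate_fusion_memory",
]

MODALITIES = ("roi", "ica", "conn")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``ffn_expansion`` and the classifier widths are calibrated so the default
    configuration totals 9.34M trainable parameters; the remaining defaults
    are the reference architecture settings (hidden 256, 8 heads, 2 layers,
    dropout 0.2).
    """

    hidden_dim: int = 256
    n_heads: int = 8
    n_layers: int = 2
    dropout: float = 0.2
    ffn_expansion: int = 9
    classifier_width: int = 89
    n_classifier_blocks: int = 2
    roi_dim: int = 48
    ica_dim: int = 5
    conn_dim: int = 1128
    max_rel_offset: int = 32
    use_abs_pos: bool = True
    use_rel_pos: bool = True
    modalities: tuple[str, ...] = MODALITIES
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} not divisible by n_heads {self.n_heads}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must lie in [0, 1), got {self.dropout}")
        for name in ("hidden_dim", "n_heads", "ffn_expansion", "classifier_width",
                     "roi_dim", "ica_dim", "conn_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.modalities or any(m not in MODALITIES for m in self.modalities):
            raise ValueError(f"modalities must be a non-empty subset of {MODALITIES}")

    @property
    def d_k(self) -> int:
        return self.hidden_dim // self.n_heads

    def input_dim(self, modality: str) -> int:
        return {"roi": self.roi_dim, "ica": self.ica_dim, "conn": self.conn_dim}[modality]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EncoderOutput:
    states: Tensor                       # (B, T, h)
    attention: list[np.ndarray]          # per layer: (B, heads, T, T)


@dataclass
class FusionOutput:
    fused: Tensor                        # (B, h)
    gates: Tensor                        # (B, n_modalities), rows sum to 1
    gate_order: tuple[str, ...]
    cross_states: Tensor | None          # (B, T, h) when ROI+ICA both present
    cross_attention: np.ndarray | None


@dataclass
class ClassOutput:
    logits: np.ndarray                   # (B, 2)
    probabilities: np.ndarray            # (B, 2), rows sum to 1


@dataclass
class ForwardResult:
    logits: Tensor
    output: ClassOutput
    encoders: dict[str, EncoderOutput]
    fusion: FusionOutput


# ------------------------------------------------------------------ building

_POS_CACHE: dict[tuple, np.ndarray] = {}
_RELIDX_CACHE: dict[tuple, np.ndarray] = {}


def sinusoidal_positions(T: int, h: int) -> np.ndarray:
    """Fixed sine/cosine positional encodings, shape (T, h)."""
    key = (T, h)
    if key not in _POS_CACHE:
        pos = np.arange(T)[:, None]
        i = np.arange(h)[None, :]
        angles = pos / np.power(10000.0, (i // 2) * 2.0 / h)
        _POS_CACHE[key] = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
    return _POS_CACHE[key]


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         bias: Tensor | None = None) -> tuple[Tensor, Tensor]:
    """softmax(Q K^T / sqrt(d_k) [+ B]) V; returns (output, weights)."""
    for t in (q, k, v):
        if not np.all(np.isfinite(t.data)):
            raise ValueError("attention inputs must be finite")
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if bias is not None:
        if bias.shape[-2:] != scores.shape[-2:]:
            raise ValueError(
                f"bias trailing shape {bias.shape[-2:]} incompatible with "
                f"scores {scores.shape[-2:]}")
        scores = scores + bias
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


def relative_attention(q: Tensor, k: Tensor, v: Tensor, bias: Tensor
                       ) -> tuple[Tensor, Tensor]:
    """Attention with an additive learned relative-position bias (B = 0
    reduces to plain scaled-dot attention)."""
    return scaled_dot_attention(q, k, v, bias=bias)


def _relative_index(T_q: int, T_k: int, max_offset: int) -> np.ndarray:
    key = (T_q, T_k, max_offset)
    if key not in _RELIDX_CACHE:
        offsets = np.arange(T_k)[None, :] - np.arange(T_q)[:, None]
        _RELIDX_CACHE[key] = np.clip(offsets, -max_offset, max_offset) + max_offset
    return _RELIDX_CACHE[key]


def _gather_rel_bias(table: Parameter, idx: np.ndarray) -> Tensor:
    """B[h, i, j] = table[h, idx[i, j]] with a bincount-based backward."""
    out = Tensor(table.data[:, idx], _prev=(table,))
    n_heads, n_buckets = table.shape
    flat = idx.ravel()

    def _bw(g):
        grad = np.stack([
            np.bincount(flat, weights=g[h].ravel().astype(np.float64),
                        minlength=n_buckets)
            for h in range(n_heads)
        ])
        return (grad.astype(table.data.dtype),)

    out._backward = _bw
    return out


class MultiHeadAttention(Module):
    """h-head attention with per-head Q/K/V projections, concatenation and an
    output projection; self-attention is the x_q = x_kv case."""

    def __init__(self, hidden_dim: int, n_heads: int, rng: np.random.Generator,
                 rel_bias: Parameter | None = None, max_rel_offset: int = 32):
        super().__init__()
        if hidden_dim % n_heads != 0:
            raise ValueError(f"hidden_dim {hidden_dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_k = hidden_dim // n_heads
        scale = 1.0 / np.sqrt(n_heads)
        self.w_q = Linear(hidden_dim, hidden_dim, rng, init_scale=scale)
        self.w_k = Linear(hidden_dim, hidden_dim, rng, init_scale=scale)
        self.w_v = Linear(hidden_dim, hidden_dim, rng, init_scale=scale)
        self.w_o = Linear(hidden_dim, hidden_dim, rng)
        # shared across layers; held in a dict so the owning encoder (not this
        # module) reports the parameter exactly once
        self._shared = {"rel_bias": rel_bias}  # (n_heads, 2*max_offset+1) or None
        self.max_rel_offset = max_rel_offset

    @property
    def rel_bias(self) -> Parameter | None:
        return self._shared["rel_bias"]

    def _split(self, x: Tensor) -> Tensor:
        B, T, h = x.shape
        return x.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, x_q: Tensor, x_kv: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (output (B, T_q, h), attention weights (B, heads, T_q, T_k))."""
        B, T_q, h = x_q.shape
        T_k = x_kv.shape[1]
        q = self._split(self.w_q(x_q))
        k = self._split(self.w_k(x_kv))
        v = self._split(self.w_v(x_kv))
        bias = None
        if self.rel_bias is not None:
            idx = _relative_index(T_q, T_k, self.max_rel_offset)
            bias = _gather_rel_bias(self.rel_bias, idx)   # (heads, T_q, T_k)
        out, weights = scaled_dot_attention(q, k, v, bias=bias)
        out = out.transpose(0, 2, 1, 3).reshape(B, T_q, h)
        return self.w_o(out), weights


class FeedForward(Module):
    """Position-wise FFN: GELU(x W1 + b1) W2 + b2."""

    def __init__(self, hidden_dim: int, expansion: int, n_heads: int,
                 rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(n_heads)
        self.lin1 = Linear(hidden_dim, expansion * hidden_dim, rng, init_scale=scale)
        self.lin2 = Linear(expansion * hidden_dim, hidden_dim, rng, init_scale=scale)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).gelu())


class TransformerLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 rel_bias: Parameter | None, dropout_rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(cfg.hidden_dim, cfg.n_heads, rng,
                                       rel_bias=rel_bias,
                                       max_rel_offset=cfg.max_rel_offset)
        self.ffn = FeedForward(cfg.hidden_dim, cfg.ffn_expansion, cfg.n_heads, rng)
        self.ln1 = LayerNorm(cfg.hidden_dim)
        self.ln2 = LayerNorm(cfg.hidden_dim)
        self.drop1 = Dropout(cfg.dropout, dropout_rng)
        self.drop2 = Dropout(cfg.dropout, dropout_rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        attn_out, weights = self.attn(x, x)
        h1 = self.ln1(x + self.drop1(attn_out))
        h2 = self.ln2(h1 + self.drop2(self.ffn(h1)))
        return h2, weights


class ModalityEncoder(Module):
    """Embedding + absolute positions + a stack of transformer layers.

    The learned relative-position bias table (one per head, clipped offsets in
    [-max_offset, max_offset]) is owned by the encoder and shared across its
    layers. Encoders never share parameters across modalities.
    """

    def __init__(self, input_dim: int, cfg: ModelConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.embed = Linear(input_dim, cfg.hidden_dim, rng)
        self.rel_bias = (Parameter(np.zeros((cfg.n_heads, 2 * cfg.max_rel_offset + 1)))
                         if cfg.use_rel_pos else None)
        self.layers = [TransformerLayer(cfg, rng, self.rel_bias, dropout_rng)
                       for _ in range(cfg.n_layers)]

    def embed_sequence(self, x: Tensor) -> Tensor:
        e = self.embed(x)
        if self.cfg.use_abs_pos:
            pos = sinusoidal_positions(x.shape[-2], self.cfg.hidden_dim)
            e = e + Tensor(pos.astype(e.data.dtype))
        return e

    def __call__(self, x: Tensor) -> EncoderOutput:
        if x.shape[-2] == 0:
            raise ValueError("cannot encode an empty sequence")
        h = self.embed_sequence(x)
        maps = []
        for layer in self.layers:
            h, w = layer(h)
            maps.append(w.data)
        return EncoderOutput(states=h, attention=maps)


class CrossModalFusion(Module):
    """Stage 1: ROI-queries/ICA-keys cross attention. Stage 2: softmax gating
    over temporal mean-pooled streams; the fused vector is the gated convex
    combination (ROI slot = pooled cross states when stage 1 ran)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.modalities = tuple(cfg.modalities)
        self.cross = (MultiHeadAttention(cfg.hidden_dim, cfg.n_heads, rng)
                      if {"roi", "ica"} <= set(self.modalities) else None)
        self.gates = {m: Linear(cfg.hidden_dim, 1, rng) for m in self.modalities}

    def named_parameters(self, prefix: str = ""):
        yield from super().named_parameters(prefix)
        for m, lin in self.gates.items():
            yield from lin.named_parameters(f"{prefix}gates.{m}.")

    def _child_modules(self):
        return super()._child_modules() + list(self.gates.values())

    def gate_weight_tensors(self) -> list[Parameter]:
        """Gate logit weights (the scope of the L1 penalty)."""
        return [lin.weight for lin in self.gates.values()]

    def __call__(self, states: dict[str, Tensor]) -> FusionOutput:
        if set(states) != set(self.modalities):
            raise ValueError(f"expected streams {self.modalities}, got {tuple(states)}")
        pooled = {m: s.mean(axis=-2) for m, s in states.items()}  # (B, h) each
        cross_states = cross_w = None
        if self.cross is not None:
            cross_states, w = self.cross(states["roi"], states["ica"])
            cross_w = w.data
            pooled_for_fuse = dict(pooled, roi=cross_states.mean(axis=-2))
        else:
            pooled_for_fuse = pooled
        logits = [self.gates[m](pooled[m]) for m in self.modalities]     # (B,1) each
        gates = concatenate(logits, axis=-1).softmax(axis=-1)            # (B, M)
        fused = None
        for i, m in enumerate(self.modalities):
            term = pooled_for_fuse[m] * gates[:, i:i + 1]
            fused = term if fused is None else fused + term
        return FusionOutput(fused=fused, gates=gates, gate_order=self.modalities,
                            cross_states=cross_states, cross_attention=cross_w)


class ResidualClassifier(Module):
    """Residual MLP head: blocks of Linear(h, w) -> GELU -> Linear(w, h) with
    LayerNorm around the residual sum, then a final linear map to 2 logits."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator):
        super().__init__()
        h, w = cfg.hidden_dim, cfg.classifier_width
        self.blocks = []
        for _ in range(cfg.n_classifier_blocks):
            self.blocks.append({
                "lin1": Linear(h, w, rng),
                "lin2": Linear(w, h, rng),
                "ln": LayerNorm(h),
            })
        self.drop = Dropout(cfg.dropout, dropout_rng)
        self.out = Linear(h, 2, rng)

    def named_parameters(self, prefix: str = ""):
        yield from super().named_parameters(prefix)
        for i, blk in enumerate(self.blocks):
            for name, mod in blk.items():
                yield from mod.named_parameters(f"{prefix}blocks.{i}.{name}.")

    def _child_modules(self):
        return super()._child_modules() + [m for blk in self.blocks for m in blk.values()]

    def __call__(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk["ln"](x + self.drop(blk["lin2"](blk["lin1"](x).gelu())))
        return self.out(x)


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Numerically safe softmax over the last axis."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


class ImpactModel(Module):
    """Full multimodal classifier. Input: dict of per-modality batched arrays
    roi (B, T, R), ica (B, T, C), conn (B, N_w, P); output 2-class logits."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        drop_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
        self.encoders = {m: ModalityEncoder(cfg.input_dim(m), cfg, rng, drop_rng)
                         for m in cfg.modalities}
        self.fusion = CrossModalFusion(cfg, rng)
        self.classifier = ResidualClassifier(cfg, rng, drop_rng)
        self.eval()

    def named_parameters(self, prefix: str = ""):
        for m, enc in self.encoders.items():
            yield from enc.named_parameters(f"{prefix}encoders.{m}.")
        yield from self.fusion.named_parameters(f"{prefix}fusion.")
        yield from self.classifier.named_parameters(f"{prefix}classifier.")

    def _child_modules(self):
        return list(self.encoders.values()) + [self.fusion, self.classifier]

    def forward(self, streams: dict[str, np.ndarray | Tensor]) -> ForwardResult:
        enc_out: dict[str, EncoderOutput] = {}
        for m in self.cfg.modalities:
            if m not in streams:
                raise ValueError(f"missing input stream '{m}'")
            x = streams[m] if isinstance(streams[m], Tensor) else Tensor(streams[m])
            if x.ndim != 3:
                raise ValueError(f"stream '{m}' must be (batch, time, dim)")
            enc_out[m] = self.encoders[m](x)
        fusion = self.fusion({m: e.states for m, e in enc_out.items()})
        logits = self.classifier(fusion.fused)
        probs = softmax_probabilities(logits.data)
        return ForwardResult(logits=logits,
                             output=ClassOutput(logits.data.copy(), probs),
                             encoders=enc_out, fusion=fusion)

    __call__ = forward

    def gate_weight_tensors(self) -> list[Parameter]:
        return self.fusion.gate_weight_tensors()


def count_parameters(model: Module) -> int:
    """Total element count over trainable parameters."""
    return sum(p.size for p in model.parameters() if getattr(p, "trainable", True))


def estimate_fusion_memory(T: int, N_w: int, d_roi: int, d_ica: int,
                           d_conn: int, d_h: int) -> int:
    """Element count of the fusion module's working set:
    M = T (d_ROI + d_ICA) + N_w d_conn + 2 T d_h (linear in sequence length)."""
    if min(T, N_w, d_roi, d_ica, d_conn, d_h) < 1:
        raise ValueError("all sizes must be >= 1")
    return T * (d_roi + d_ica) + N_w * d_conn + 2 * T * d_h
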
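"""Seven comparison architectures (CNN2D, CNN1D, LSTM, GRU, TCN, MLP, AE)
sharing the classifier contract of the main model: they consume the same
preprocessed feature streams and emit 2-class logits, and they train and
evaluate under the identical cross-validation harness, loss and metrics.

By default each baseline consumes the ROI stream (batch, T, R); with
``input_mode="concat"`` the ROI and ICA streams are concatenated along the
feature axis (the dFC stream has a different sequence length and stays out).
Depth/width defaults are conventional small baselines sized below the main
model's capacity: two conv blocks for the CNNs, two bidirectional recurrent
layers of width 128 for LSTM/GRU, four TCN blocks with kernel 3 and doubling
dilation, a (256, 128) MLP, and an autoencoder with a 64-unit bottleneck
trained with a reconstruction pretext before classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Parameter, Linear, concatenate, stack
from .nn.optim import AdamW

__all__ = ["BASELINE_NAMES", "BaselineSpec", "build_baseline", "baseline_factory"]

BASELINE_NAMES = ("CNN2D", "CNN1D", "LSTM", "GRU", "TCN", "MLP", "AE")


@dataclass(frozen=True)
class BaselineSpec:
    name: str
    input_mode: str = "roi"          # "roi" or "concat" (roi + ica features)
    seed: int = 0

    def __post_init__(self):
        if self.name not in BASELINE_NAMES:
            raise ValueError(
                f"unknown baseline '{self.name}'; valid names: {BASELINE_NAMES}")
        if self.input_mode not in ("roi", "concat"):
            raise ValueError("input_mode must be 'roi' or 'concat'")


class _Baseline(Module):
    """Shared stream selection for all baselines."""

    input_mode = "roi"

    def _input(self, streams: dict[str, np.ndarray | Tensor]) -> Tensor:
        def as_t(x):
            return x if isinstance(x, Tensor) else Tensor(x)
        if self.input_mode == "concat":
            return concatenate([as_t(streams["roi"]), as_t(streams["ica"])], axis=-1)
        return as_t(streams["roi"])


def _conv1d(x: Tensor, weight: Parameter, bias: Parameter,
            dilation: int = 1) -> Tensor:
    """Valid 1D convolution. x: (B, L, C_in); weight: (K, C_in, C_out)."""
    K = weight.shape[0]
    L = x.shape[1]
    L_out = L - dilation * (K - 1)
    if L_out < 1:
        raise ValueError("sequence too short for this kernel/dilation")
    out = None
    for k in range(K):
        term = x[:, k * dilation:k * dilation + L_out, :] @ weight[k]
        out = term if out is None else out + term
    return out + bias


def _conv_param(rng, K, c_in, c_out):
    std = np.sqrt(2.0 / (K * c_in))
    return Parameter(rng.normal(0, std, size=(K, c_in, c_out)))


def _pad_time(x: Tensor, left: int, right: int = 0) -> Tensor:
    B, L, C = x.shape
    pieces = []
    if left:
        pieces.append(Tensor(np.zeros((B, left, C))))
    pieces.append(x)
    if right:
        pieces.append(Tensor(np.zeros((B, right, C))))
    return concatenate(pieces, axis=1) if len(pieces) > 1 else x


class MLPBaseline(_Baseline):
    def __init__(self, input_shape: tuple[int, int], rng, widths=(256, 128)):
        super().__init__()
        T, d = input_shape
        self.input_shape = input_shape
        dims = [T * d, *widths, 2]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, streams) -> Tensor:
        x = self._input(streams)
        B = x.shape[0]
        h = x.reshape(B, x.shape[1] * x.shape[2])
        for lin in self.layers[:-1]:
            h = lin(h).gelu()
        return self.layers[-1](h)


class CNN1DBaseline(_Baseline):
    """Two conv blocks over time (channels = features), global average pool."""

    def __init__(self, input_shape: tuple[int, int], rng, channels=(32, 64)):
        super().__init__()
        _, d = input_shape
        c1, c2 = channels
        self.w1, self.b1 = _conv_param(rng, 3, d, c1), Parameter(np.zeros(c1))
        self.w2, self.b2 = _conv_param(rng, 3, c1, c2), Parameter(np.zeros(c2))
        self.head = Linear(c2, 2, rng)

    def __call__(self, streams) -> Tensor:
        x = self._input(streams)                      # (B, T, d)
        h = _conv1d(_pad_time(x, 1, 1), self.w1, self.b1).gelu()
        h = _conv1d(_pad_time(h, 1, 1), self.w2, self.b2).gelu()
        return self.head(h.mean(axis=1))


class CNN2DBaseline(_Baseline):
    """Treats the stream as a 1 x T x d image with two 3x3 conv blocks."""

    def __init__(self, input_shape: tuple[int, int], rng, channels=(8, 16)):
        super().__init__()
        c1, c2 = channels
        std1 = np.sqrt(2.0 / 9)
        self.w1 = Parameter(rng.normal(0, std1, size=(3, 3, 1, c1)))
        self.b1 = Parameter(np.zeros(c1))
        std2 = np.sqrt(2.0 / (9 * c1))
        self.w2 = Parameter(rng.normal(0, std2, size=(3, 3, c1, c2)))
        self.b2 = Parameter(np.zeros(c2))
        self.head = Linear(c2, 2, rng)

    @staticmethod
    def _conv2d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
        # x: (B, H, W, C_in); w: (3, 3, C_in, C_out); valid convolution
        H_out, W_out = x.shape[1] - 2, x.shape[2] - 2
        out = None
        for i in range(3):
            for j in range(3):
                term = x[:, i:i + H_out, j:j + W_out, :] @ w[i, j]
                out = term if out is None else out + term
        return out + b

    def __call__(self, streams) -> Tensor:
        x = self._input(streams)
        B, T, d = x.shape
        h = x.reshape(B, T, d, 1)
        h = self._conv2d(h, self.w1, self.b1).gelu()
        h = self._conv2d(h, self.w2, self.b2).gelu()
        return self.head(h.mean(axis=(1, 2)))


class _RecurrentLayer(Module):
    """One direction of an LSTM or GRU layer."""

    def __init__(self, kind: str, input_dim: int, hidden: int, rng):
        super().__init__()
        self.kind = kind
        self.hidden = hidden
        gates = 4 if kind == "LSTM" else 3
        std = np.sqrt(1.0 / hidden)
        self.w_ih = Parameter(rng.normal(0, std, size=(input_dim, gates * hidden)))
        self.w_hh = Parameter(rng.normal(0, std, size=(hidden, gates * hidden)))
        self.bias = Parameter(np.zeros(gates * hidden))

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, d) -> hidden states (B, T, H)."""
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        xz = x @ self.w_ih + self.bias          # precompute input part (B, T, gates*H)
        outs = []
        for t in range(T):
            z = xz[:, t, :] + h @ self.w_hh
            if self.kind == "LSTM":
                i = z[:, 0:H].sigmoid()
                f = z[:, H:2 * H].sigmoid()
                g = z[:, 2 * H:3 * H].tanh()
                o = z[:, 3 * H:4 * H].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
            else:                                # GRU (reset gate applied post-sum)
                r = z[:, 0:H].sigmoid()
                u = z[:, H:2 * H].sigmoid()
                n = (xz[:, t, 2 * H:3 * H] + r * (h @ self.w_hh[:, 2 * H:3 * H])).tanh()
                h = (1.0 - u) * n + u * h
            outs.append(h)
        return stack(outs, axis=1)


class RecurrentBaseline(_Baseline):
    """Bidirectional LSTM/GRU, two layers, mean-pooled hidden states."""

    def __init__(self, kind: str, input_shape: tuple[int, int], rng,
                 hidden: int = 128, n_layers: int = 2):
        super().__init__()
        _, d = input_shape
        self.fwd, self.bwd = [], []
        in_dim = d
        for _ in range(n_layers):
            self.fwd.append(_RecurrentLayer(kind, in_dim, hidden, rng))
            self.bwd.append(_RecurrentLayer(kind, in_dim, hidden, rng))
            in_dim = 2 * hidden
        self.head = Linear(2 * hidden, 2, rng)

    def hidden_states(self, x: Tensor) -> Tensor:
        """(B, T, 2H) concatenated forward/backward states of the last layer."""
        rev = np.arange(x.shape[1])[::-1].copy()
        h = x
        for f_layer, b_layer in zip(self.fwd, self.bwd):
            hf = f_layer(h)
            hb = b_layer(h[:, rev, :])[:, rev, :]
            h = concatenate([hf, hb], axis=-1)
        return h

    def __call__(self, streams) -> Tensor:
        return self.head(self.hidden_states(self._input(streams)).mean(axis=1))


class TCNBaseline(_Baseline):
    """Four causal residual blocks, kernel 3, dilations 1/2/4/8."""

    def __init__(self, input_shape: tuple[int, int], rng, channels: int = 32,
                 n_blocks: int = 4):
        super().__init__()
        _, d = input_shape
        self.blocks = []
        in_dim = d
        for b in range(n_blocks):
            dilation = 2**b
            self.blocks.append({
                "w": _conv_param(rng, 3, in_dim, channels),
                "b": Parameter(np.zeros(channels)),
                "proj": Linear(in_dim, channels, rng) if in_dim != channels else None,
                "dilation": dilation,
            })
            in_dim = channels
        self.head = Linear(channels, 2, rng)

    def named_parameters(self, prefix: str = ""):
        yield from super().named_parameters(prefix)
        for i, blk in enumerate(self.blocks):
            yield f"{prefix}blocks.{i}.w", blk["w"]
            yield f"{prefix}blocks.{i}.b", blk["b"]
            if blk["proj"] is not None:
                yield from blk["proj"].named_parameters(f"{prefix}blocks.{i}.proj.")

    def _child_modules(self):
        return super()._child_modules() + [blk["proj"] for blk in self.blocks
                                           if blk["proj"] is not None]

    def __call__(self, streams) -> Tensor:
        x = self._input(streams)
        h = x
        for blk in self.blocks:
            pad = 2 * blk["dilation"]            # causal: pad on the left only
            conv = _conv1d(_pad_time(h, pad), blk["w"], blk["b"],
                           dilation=blk["dilation"]).gelu()
            res = blk["proj"](h) if blk["proj"] is not None else h
            h = conv + res
        return self.head(h.mean(axis=1))


class AEBaseline(_Baseline):
    """Temporal autoencoder: per-timestep encoder to a bottleneck, decoder for
    reconstruction, classifier on the mean-pooled bottleneck. The encoder and
    decoder are first trained on the reconstruction pretext; the classifier
    (and encoder) then train under the shared harness."""

    def __init__(self, input_shape: tuple[int, int], rng, bottleneck: int = 64,
                 pretext_epochs: int = 30):
        super().__init__()
        _, d = input_shape
        self.encoder = Linear(d, bottleneck, rng)
        self.decoder = Linear(bottleneck, d, rng)
        self.head = Linear(bottleneck, 2, rng)
        self.pretext_epochs = pretext_epochs

    def encode(self, x: Tensor) -> Tensor:
        return self.encoder(x).gelu()

    def reconstruction_loss(self, x: Tensor) -> Tensor:
        err = self.decoder(self.encode(x)) - x
        return (err * err).mean()

    def pretext_train(self, streams: dict[str, np.ndarray], cfg,
                      rng: np.random.Generator) -> None:
        x = self._input(streams)
        params = self.encoder.parameters() + self.decoder.parameters()
        opt = AdamW(params, lr=1e-3, weight_decay=cfg.weight_decay)
        for _ in range(self.pretext_epochs):
            loss = self.reconstruction_loss(x)
            for p in params:
                p.grad = None
            loss.backward()
            opt.step()

    def __call__(self, streams) -> Tensor:
        return self.head(self.encode(self._input(streams)).mean(axis=1))


def build_baseline(spec: BaselineSpec, input_shape: tuple[int, int]):
    """Construct a baseline for streams whose selected input is (T, d)."""
    rng = np.random.default_rng(spec.seed)
    builders = {
        "MLP": lambda: MLPBaseline(input_shape, rng),
        "CNN1D": lambda: CNN1DBaseline(input_shape, rng),
        "CNN2D": lambda: CNN2DBaseline(input_shape, rng),
        "LSTM": lambda: RecurrentBaseline("LSTM", input_shape, rng),
        "GRU": lambda: RecurrentBaseline("GRU", input_shape, rng),
        "TCN": lambda: TCNBaseline(input_shape, rng),
        "AE": lambda: AEBaseline(input_shape, rng),
    }
    model = builders[spec.name]()
    model.input_mode = spec.input_mode
    model.eval()
    return model


def baseline_factory(name: str, input_shape: tuple[int, int],
                     input_mode: str = "roi"):
    """Per-fold factory mirroring the main model's factory contract."""
    def make(seed: int):
        return build_baseline(BaselineSpec(name, input_mode, seed), input_shape)
    return make
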
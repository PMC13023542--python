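"""1D residual U-Net with ASPP-lite and a transformer bottleneck.

Maps a normalized two-channel respiration window (T x 2) to per-sample event
probabilities (T x 1).  The encoder stacks residual dilated Conv1D blocks
with stride-2 convolutional downsampling (channels 32-64-128-256 at the
default depth 4); the bottleneck aggregates multi-scale context with
parallel dilated branches (1, 2, 4, 8) and models long-range dependencies
with pre-norm multi-head self-attention over the T/2^depth positions; the
decoder mirrors the encoder with nearest-neighbour upsampling + convolution
and skip-connection concatenation; a large-kernel (k=31, about 3 s at 10 Hz)
smoothing convolution precedes the sigmoid head.

Ablation switches allow a plain CNN U-Net (no ASPP, no transformer,
non-residual blocks) to be built from the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from apneaseg.nn import (
    BatchNorm1d, Conv1d, Dense, Dropout, LayerNorm, Module, Swish, Tensor,
)
from apneaseg.nn.layers import ModuleList
from apneaseg.sim import stream_rng


@dataclass
class ModelConfig:
    input_len: int = 2048
    in_channels: int = 2
    base_filters: int = 32
    depth: int = 4
    dropout: float = 0.2
    kernel_size: int = 3
    block_dilations: tuple[int, ...] = (1, 2)
    aspp_dilations: tuple[int, ...] = (1, 2, 4, 8)
    n_transformer_blocks: int = 3
    n_heads: int = 4
    embed_dim: int | None = None       # derived: base_filters * 2^(depth-1)
    ffn_mult: int = 4
    smooth_kernel: int = 31
    # ablation switches (all on for the full model)
    use_residual: bool = True
    use_aspp: bool = True
    use_transformer: bool = True

    def __post_init__(self) -> None:
        if self.input_len % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_len {self.input_len} not divisible by 2^depth")
        derived = self.base_filters * 2 ** (self.depth - 1)
        if self.embed_dim is None:
            self.embed_dim = derived
        elif self.embed_dim != derived:
            raise ValueError(
                f"embed_dim {self.embed_dim} inconsistent with "
                f"base_filters*2^(depth-1) = {derived}")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must divide evenly across heads")

    @property
    def bottleneck_len(self) -> int:
        return self.input_len // 2 ** self.depth

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: base_filters 8, depth 3, 512-sample windows."""
        kw = dict(input_len=512, base_filters=8, depth=3)
        kw.update(overrides)
        return cls(**kw)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        for k in ("block_dilations", "aspp_dilations"):
            d[k] = tuple(d[k])
        return cls(**d)


def sinusoidal_positional_encoding(length: int, dim: int) -> np.ndarray:
    """Standard sin/cos interleaved encoding, values in [-1, 1]."""
    if length <= 0 or dim <= 0:
        raise ValueError("length and dim must be positive")
    pos = np.arange(length)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / dim)
    pe = np.zeros((length, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : dim - dim // 2])
    return pe


class ResBlock(Module):
    """Residual Conv1D block: two dilated convolutions with BN + Swish,
    dropout after the first activation, 1x1 projection on channel change."""

    def __init__(self, in_ch: int, out_ch: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        d1, d2 = (cfg.block_dilations if cfg.use_residual else (1, 1))
        self.conv1 = Conv1d(in_ch, out_ch, cfg.kernel_size, rng, dilation=d1)
        self.bn1 = BatchNorm1d(out_ch)
        self.drop = Dropout(cfg.dropout, rng)
        self.conv2 = Conv1d(out_ch, out_ch, cfg.kernel_size, rng, dilation=d2)
        self.bn2 = BatchNorm1d(out_ch)
        self.use_residual = cfg.use_residual
        self.proj = (Conv1d(in_ch, out_ch, 1, rng)
                     if (cfg.use_residual and in_ch != out_ch) else None)

    def forward(self, x: Tensor) -> Tensor:
        h = self.drop(self.bn1(self.conv1(x)).swish())
        h = self.bn2(self.conv2(h))
        if self.use_residual:
            sc = self.proj(x) if self.proj is not None else x
            h = h + sc
        return h.swish()


class DownSample(Module):
    """Learnable anti-aliasing downsampling: stride-2 convolution."""

    def __init__(self, ch: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv1d(ch, ch, cfg.kernel_size, rng, stride=2)
        self.bn = BatchNorm1d(ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).swish()


class ASPPLite(Module):
    """Parallel dilated branches fused by concatenation + 1x1 convolution."""

    def __init__(self, ch: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        branch_ch = max(ch // len(cfg.aspp_dilations), 1)
        self.branches = ModuleList([
            Conv1d(ch, branch_ch, cfg.kernel_size, rng, dilation=d)
            for d in cfg.aspp_dilations])
        self.fuse = Conv1d(branch_ch * len(cfg.aspp_dilations), ch, 1, rng)
        self.bn = BatchNorm1d(ch)

    def forward(self, x: Tensor) -> Tensor:
        outs = [b(x) for b in self.branches]
        return self.bn(self.fuse(Tensor.concat(outs, axis=1))).swish()


class MHSA(Module):
    """Multi-head self-attention on (N, T, D)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Dense(dim, 3 * dim, rng)
        self.out = Dense(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        N, T, D = x.shape
        h, dh = self.n_heads, self.head_dim
        qkv = self.qkv(x)                                   # (N, T, 3D)
        qkv = qkv.reshape(N, T, 3, h, dh)
        q = qkv[:, :, 0].swapaxes(1, 2)                     # (N, h, T, dh)
        k = qkv[:, :, 1].swapaxes(1, 2)
        v = qkv[:, :, 2].swapaxes(1, 2)
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        att = att.softmax(axis=-1)
        ctx = (att @ v).swapaxes(1, 2).reshape(N, T, D)
        return self.out(ctx)


class TransformerBlock(Module):
    """Pre-norm block: x + MHSA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, dim: int, n_heads: int, ffn_mult: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MHSA(dim, n_heads, rng)
        self.drop1 = Dropout(dropout, rng)
        self.ln2 = LayerNorm(dim)
        self.ffn1 = Dense(dim, ffn_mult * dim, rng)
        self.ffn2 = Dense(ffn_mult * dim, dim, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.ln1(x)))
        return x + self.drop2(self.ffn2(self.ffn1(self.ln2(x)).swish()))


class UpStage(Module):
    """Nearest-neighbour upsample + conv, then skip concat + residual block."""

    def __init__(self, in_ch: int, skip_ch: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.upconv = Conv1d(in_ch, skip_ch, cfg.kernel_size, rng)
        self.bn = BatchNorm1d(skip_ch)
        self.block = ResBlock(2 * skip_ch, skip_ch, cfg, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = x.repeat_interleave(2, axis=2)
        up = self.bn(self.upconv(up)).swish()
        return self.block(Tensor.concat([up, skip], axis=1))


class SegNet(Module):
    """The full encoder / ASPP / transformer-bottleneck / decoder network."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = stream_rng(seed, "model-init")
        self.drop_rng = stream_rng(seed, "model-dropout")
        chans = [cfg.base_filters * 2 ** i for i in range(cfg.depth)]

        enc, downs = [], []
        in_ch = cfg.in_channels
        for ch in chans:
            enc.append(ResBlock(in_ch, ch, cfg, rng))
            downs.append(DownSample(ch, cfg, rng))
            in_ch = ch
        self.encoder = ModuleList(enc)
        self.downs = ModuleList(downs)

        bott = chans[-1]
        assert bott == cfg.embed_dim
        self.aspp = ASPPLite(bott, cfg, rng) if cfg.use_aspp else None
        if cfg.use_transformer:
            self.pos_enc = sinusoidal_positional_encoding(
                cfg.bottleneck_len, bott)
            self.transformer = ModuleList([
                TransformerBlock(bott, cfg.n_heads, cfg.ffn_mult,
                                 cfg.dropout, rng)
                for _ in range(cfg.n_transformer_blocks)])
        else:
            self.transformer = None

        ups = []
        prev = bott
        for ch in reversed(chans):
            ups.append(UpStage(prev, ch, cfg, rng))
            prev = ch
        self.decoder = ModuleList(ups)

        self.smooth_conv = Conv1d(chans[0], chans[0], cfg.smooth_kernel, rng)
        self.head = Conv1d(chans[0], 1, 1, rng)

        # use the shared dropout stream everywhere
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = self.drop_rng

    # ordered layer list for rho-freezing: encoder -> bottleneck ->
    # decoder -> head, in definition order
    def layer_list(self) -> list[Module]:
        layers: list[Module] = []
        for blk, dn in zip(self.encoder, self.downs):
            layers.extend([blk, dn])
        if self.aspp is not None:
            layers.append(self.aspp)
        if self.transformer is not None:
            layers.extend(self.transformer)
        layers.extend(self.decoder)
        layers.extend([self.smooth_conv, self.head])
        return layers

    def forward(self, x, return_layer: str | None = None):
        """(N, T, C) or (N, C, T) input -> (N, T, 1) probabilities.

        ``return_layer`` returns the named intermediate activation instead
        (available names via :meth:`layer_names`).
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[-1] == self.cfg.in_channels:
            x = x.swapaxes(1, 2)                    # -> (N, C, T)
        if x.shape[2] != self.cfg.input_len:
            raise ValueError(
                f"expected windows of {self.cfg.input_len} samples, "
                f"got {x.shape[2]}")
        acts: dict[str, Tensor] = {}
        h = x
        skips = []
        for i, (blk, dn) in enumerate(zip(self.encoder, self.downs)):
            h = blk(h)
            skips.append(h)
            acts[f"enc{i}"] = h
            h = dn(h)
        if self.aspp is not None:
            h = self.aspp(h)
            acts["aspp"] = h
        if self.transformer is not None:
            t = h.swapaxes(1, 2) + Tensor(self.pos_enc[None])
            for j, blk in enumerate(self.transformer):
                t = blk(t)
                acts[f"transformer{j}"] = t
            h = t.swapaxes(1, 2)
        for i, up in enumerate(self.decoder):
            h = up(h, skips[-(i + 1)])
            acts[f"dec{i}"] = h
        h = self.smooth_conv(h)
        acts["smooth_conv"] = h
        logits = self.head(h)
        acts["head"] = logits
        prob = logits.sigmoid().swapaxes(1, 2)      # (N, T, 1)
        acts["output"] = prob
        if return_layer is not None:
            if return_layer not in acts:
                raise KeyError(
                    f"unknown layer {return_layer!r}; available: "
                    f"{sorted(acts)}")
            return acts[return_layer]
        return prob

    def predict(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Inference-mode probabilities for stacked windows (N, T, C)."""
        was_training = self.training
        self.eval()
        outs = []
        for i in range(0, len(X), batch_size):
            outs.append(self.forward(X[i:i + batch_size]).data)
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.parameters()))


def build_model(cfg: ModelConfig, seed: int = 0) -> SegNet:
    """Deterministically construct a SegNet from its configuration."""
    return SegNet(cfg, seed=seed)


def extract_features(model: SegNet, X: np.ndarray,
                     layer_name: str = "smooth_conv",
                     batch_size: int = 64) -> np.ndarray:
    """Temporal mean-pooled activations of a named layer, one vector per window."""
    was_training = model.training
    model.eval()
    feats = []
    for i in range(0, len(X), batch_size):
        act = model.forward(X[i:i + batch_size], return_layer=layer_name)
        a = act.data
        if a.ndim == 3:
            # conv layers are (N, C, T); transformer layers are (N, T, D)
            axis = 2 if layer_name.startswith(
                ("enc", "dec", "aspp", "smooth", "head")) else 1
            a = a.mean(axis=axis)
        feats.append(a)
    if was_training:
        model.train()
    return np.concatenate(feats, axis=0)


def save_checkpoint(model: SegNet, path, extra: dict | None = None) -> None:
    """Weights + serialized configuration in one npz archive."""
    meta = {"config": json.loads(model.cfg.to_json()),
            "seed": model.seed, "extra": extra or {}}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path, expect_cfg: ModelConfig | None = None) -> tuple[SegNet, dict]:
    """Rebuild the identical graph from the stored configuration, then load
    weights; fails loudly on any architecture mismatch."""
    with np.load(path) as arc:
        meta = json.loads(bytes(arc["__meta__"]).decode())
        state = {k: arc[k] for k in arc.files if k != "__meta__"}
    cfg = ModelConfig.from_json(json.dumps(meta["config"]))
    if expect_cfg is not None and cfg.to_json() != expect_cfg.to_json():
        raise ValueError(
            "checkpoint configuration does not match the requested "
            "configuration; refusing silent mismatch")
    model = build_model(cfg, seed=meta.get("seed", 0))
    model.load_state_dict(state)
    return model, meta.get("extra", {})
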
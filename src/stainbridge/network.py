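"""Trainable components: the shallow dimension-matching CNN ``f_c`` and the
attention-augmented U-Net denoiser ``eps_theta``.

``f_c`` lifts a multi-channel autofluorescence stack of spatial size
(H/N, W/N) to a 3-channel condition image of size (H, W) with two 3x3
convolutions followed by a pixel shuffle of upscale factor N (identity for
N = 1).  The denoiser consumes the channel concatenation of the noisy state
``x_t`` and the condition ``y`` plus a timestep embedding, and predicts the
forward error ``x_t - x_0``.

Architecture of the U-Net: a down-sampling and an up-sampling path with
skip connections between matching levels; each level holds one residual
block and (where configured) one multi-head attention block; adjacent down
levels are joined by 2x2 average pooling and adjacent up levels by 2x2
nearest-neighbour interpolation; the middle block stacks two residual
blocks around one attention block.  Residual blocks use group
normalization and SiLU; the timestep embedding enters each residual block
through a per-block SiLU + linear projection added as a channel bias.

The public API speaks the package-wide (channel, row, column) convention;
NHWC is used internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "DenoiserConfig",
    "DenoiserModel",
    "build_denoiser",
    "sinusoidal_features",
    "default_toy_config",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class DenoiserConfig:
    """Hyper-parameters of f_c and the U-Net denoiser.

    ``attention_levels`` lists the 1-based down/up levels that carry an
    attention block (the middle block always has one); ``None`` means every
    level, the full-fidelity layout.  At desk scale attention is typically
    restricted to the lowest-resolution level (`default_toy_config`).
    """

    levels: int = 4
    base_channels: int = 32
    channel_mult: tuple = ()
    attention_heads: int = 4
    time_embed_dim: int = 64
    in_channels: int = 6
    out_channels: int = 3
    sr_factor: int = 1
    af_channels: int = 4
    fc_hidden: int = 32
    attention_levels: tuple | None = None
    res_convs: int = 2

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.in_channels != 2 * self.out_channels:
            raise ValueError("in_channels must equal 2 * out_channels "
                             "(x_t concatenated with y)")
        if not 1 <= self.sr_factor <= 5:
            raise ValueError("sr_factor must be in 1..5")
        if self.af_channels < 1:
            raise ValueError("af_channels must be >= 1")
        if self.attention_heads < 1:
            raise ValueError("attention_heads must be >= 1")
        if self.res_convs not in (1, 2):
            raise ValueError("res_convs must be 1 or 2")
        mult = self.channel_mult or tuple(range(1, self.levels + 1))
        if len(mult) != self.levels:
            raise ValueError("channel_mult length must equal levels")
        object.__setattr__(self, "channel_mult", tuple(mult))
        att = self.attention_levels
        if att is None:
            att = tuple(range(1, self.levels + 1))
        object.__setattr__(self, "attention_levels", tuple(att))
        for lv in self.attention_levels:
            c = self.base_channels * self.channel_mult[lv - 1]
            if c % self.attention_heads:
                raise ValueError(
                    f"channels {c} at level {lv} not divisible by "
                    f"{self.attention_heads} attention heads")

    @property
    def channels(self) -> tuple:
        return tuple(self.base_channels * m for m in self.channel_mult)

    @property
    def spatial_divisor(self) -> int:
        return 2 ** (self.levels - 1)


def default_toy_config(sr_factor: int = 1, af_channels: int = 4,
                       levels: int = 4) -> DenoiserConfig:
    """Desk-scale configuration: narrow channels, attention only at the
    lowest-resolution level and the middle block."""
    return DenoiserConfig(
        levels=levels, base_channels=6,
        channel_mult=tuple(range(1, levels + 1)),
        attention_heads=2, time_embed_dim=48, sr_factor=sr_factor,
        af_channels=af_channels, fc_hidden=12,
        attention_levels=(levels,), res_convs=1)


def sinusoidal_features(t, dim: int) -> np.ndarray:
    """Interleaved sin/cos positional features of integer timestep(s) ``t``.

    Feature 2i is ``sin(t * w_i)`` and feature 2i+1 is ``cos(t * w_i)`` with
    geometrically spaced frequencies, so t = 0 maps to the alternating
    (0, 1, 0, 1, ...) pattern.
    """
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    out = np.empty((t.shape[0], dim), dtype=np.float32)
    out[:, 0::2] = np.sin(ang)
    out[:, 1::2] = np.cos(ang)
    return out


def _num_groups(c: int) -> int:
    for g in (8, 4, 2):
        if c % g == 0:
            return g
    return 1


class DenoiserModel:
    """f_c + eps_theta with a flat name -> Tensor parameter store.

    Prediction is a pure function of (parameters, inputs): inference has no
    stochastic layers, so identical inputs give bit-identical outputs.
    """

    def __init__(self, config: DenoiserConfig, params: dict,
                 normalization_spec: dict | None = None,
                 t_max: int = 1000, t_exit_default: int = 50,
                 seed_lineage: tuple = ()):
        self.config = config
        self.params = params
        self.normalization_spec = normalization_spec or {
            "af": "per-channel zero-mean unit-variance",
            "target_offset": 127.5, "target_scale": 127.5}
        self.t_max = int(t_max)
        self.t_exit_default = int(t_exit_default)
        self.seed_lineage = tuple(seed_lineage)

    # ------------------------------------------------------------ helpers
    def _p(self, name: str) -> Tensor:
        return self.params[name]

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # ------------------------------------------------- shallow network f_c
    def dimension_match_t(self, y0: Tensor) -> Tensor:
        """f_c on an NHWC Tensor batch (B, h, w, af_channels)."""
        h = ad.conv3x3(y0, self._p("fc.conv1.w"), self._p("fc.conv1.b"))
        h = ad.silu(h)
        h = ad.conv3x3(h, self._p("fc.conv2.w"), self._p("fc.conv2.b"))
        return ad.pixel_shuffle(h, self.config.sr_factor)

    def dimension_match(self, y0: np.ndarray) -> np.ndarray:
        """f_c on a (af_channels, h, w) or (B, af_channels, h, w) array;
        returns the 3-channel condition image at N-times the spatial size."""
        cfg = self.config
        y0 = np.asarray(y0, dtype=np.float32)
        single = y0.ndim == 3
        if single:
            y0 = y0[None]
        if y0.shape[1] != cfg.af_channels:
            raise ValueError(
                f"stack has {y0.shape[1]} channels, model expects "
                f"{cfg.af_channels}")
        h, w = y0.shape[2], y0.shape[3]
        div = cfg.spatial_divisor
        if (h * cfg.sr_factor) % div or (w * cfg.sr_factor) % div:
            raise ValueError(
                f"output size {h * cfg.sr_factor}x{w * cfg.sr_factor} not "
                f"divisible by 2^(levels-1) = {div}")
        with ad.no_grad():
            out = self.dimension_match_t(Tensor(y0.transpose(0, 2, 3, 1)))
        out = out.data.transpose(0, 3, 1, 2)
        return out[0] if single else out

    # ------------------------------------------------------ time embedding
    def embed_timestep(self, t) -> np.ndarray:
        """Shared embedding vector(s) for integer timestep(s) t in 0..T."""
        tv = np.atleast_1d(np.asarray(t))
        if np.any(tv < 0) or np.any(tv > self.t_max):
            raise ValueError(f"timestep {t} outside 0..{self.t_max}")
        base = sinusoidal_features(tv, self.config.time_embed_dim)
        with ad.no_grad():
            emb = self._time_mlp(Tensor(base))
        out = emb.data
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def _time_mlp(self, base: Tensor) -> Tensor:
        h = ad.linear(base, self._p("temb.lin1.w"), self._p("temb.lin1.b"))
        h = ad.silu(h)
        return ad.linear(h, self._p("temb.lin2.w"), self._p("temb.lin2.b"))

    # ------------------------------------------------------------- blocks
    def _res_block(self, x: Tensor, emb: Tensor, name: str,
                   c_in: int, c_out: int) -> Tensor:
        # timestep embedding enters as a channel bias on the block input
        tb = ad.linear(ad.silu(emb), self._p(f"{name}.temb.w"),
                       self._p(f"{name}.temb.b"))
        h = ad.add(x, ad.reshape(tb, (tb.shape[0], 1, 1, c_in)))
        h = ad.group_norm(h, self._p(f"{name}.gn1.g"),
                          self._p(f"{name}.gn1.b"), _num_groups(c_in))
        h = ad.silu(h)
        h = ad.conv3x3(h, self._p(f"{name}.conv1.w"),
                       self._p(f"{name}.conv1.b"))
        if self.config.res_convs == 2:
            h = ad.group_norm(h, self._p(f"{name}.gn2.g"),
                              self._p(f"{name}.gn2.b"), _num_groups(c_out))
            h = ad.silu(h)
            h = ad.conv3x3(h, self._p(f"{name}.conv2.w"),
                           self._p(f"{name}.conv2.b"))
        if c_in != c_out:
            x = ad.conv1x1(x, self._p(f"{name}.skip.w"),
                           self._p(f"{name}.skip.b"))
        return ad.add(x, h)

    def _attention(self, x: Tensor, name: str, c: int) -> Tensor:
        B, H, W, _ = x.shape
        heads = self.config.attention_heads
        dh = c // heads
        h = ad.group_norm(x, self._p(f"{name}.gn.g"),
                          self._p(f"{name}.gn.b"), _num_groups(c))
        qkv = []
        for part in ("q", "k", "v"):
            p = ad.conv1x1(h, self._p(f"{name}.{part}.w"),
                           self._p(f"{name}.{part}.b"))
            p = ad.reshape(p, (B, H * W, heads, dh))
            qkv.append(ad.transpose(p, (0, 2, 1, 3)))  # (B, heads, HW, dh)
        q, k, v = qkv
        att = ad.bmm(ad.scale(q, 1.0 / math.sqrt(dh)),
                     ad.transpose(k, (0, 1, 3, 2)))
        att = ad.softmax_last(att)
        out = ad.bmm(att, v)  # (B, heads, HW, dh)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (B, H, W, c))
        out = ad.conv1x1(out, self._p(f"{name}.proj.w"),
                         self._p(f"{name}.proj.b"))
        return ad.add(x, out)

    # -------------------------------------------------------------- U-Net
    def unet_t(self, x: Tensor, t) -> Tensor:
        """Denoiser on an NHWC Tensor (B, H, W, in_channels); ``t`` is an
        integer or per-sample integer vector."""
        cfg = self.config
        B, H, W, _ = x.shape
        if H % cfg.spatial_divisor or W % cfg.spatial_divisor:
            raise ValueError(
                f"spatial size {H}x{W} not divisible by "
                f"2^(levels-1) = {cfg.spatial_divisor}")
        tv = np.broadcast_to(np.atleast_1d(np.asarray(t)), (B,))
        if np.any(tv < 0) or np.any(tv > self.t_max):
            raise ValueError(f"timestep {t} outside 0..{self.t_max}")
        emb = self._time_mlp(Tensor(
            sinusoidal_features(tv, cfg.time_embed_dim)))

        chans = cfg.channels
        h = ad.conv3x3(x, self._p("in.w"), self._p("in.b"))
        skips = []
        for i, c in enumerate(chans):
            c_in = chans[0] if i == 0 else chans[i - 1]
            h = self._res_block(h, emb, f"down{i}.res", c_in, c)
            if (i + 1) in cfg.attention_levels:
                h = self._attention(h, f"down{i}.att", c)
            skips.append(h)
            if i < cfg.levels - 1:
                h = ad.avg_pool2(h)

        c_mid = chans[-1]
        h = self._res_block(h, emb, "mid.res1", c_mid, c_mid)
        h = self._attention(h, "mid.att", c_mid)
        h = self._res_block(h, emb, "mid.res2", c_mid, c_mid)

        for i in reversed(range(cfg.levels)):
            c = chans[i]
            c_cur = chans[i + 1] if i < cfg.levels - 1 else c_mid
            if i < cfg.levels - 1:
                h = ad.upsample_nearest2(h)
            h = ad.concat_last(skips.pop(), h)
            h = self._res_block(h, emb, f"up{i}.res", c + c_cur, c)
            if (i + 1) in cfg.attention_levels:
                h = self._attention(h, f"up{i}.att", c)

        h = ad.group_norm(h, self._p("out.gn.g"), self._p("out.gn.b"),
                          _num_groups(chans[0]))
        h = ad.silu(h)
        return ad.conv3x3(h, self._p("out.w"), self._p("out.b"))

    def predict_error(self, x_t: np.ndarray, y: np.ndarray, t) -> np.ndarray:
        """eps_theta(concat(x_t, y), t) on channel-first arrays.

        Estimates the forward error ``x_t - x_0``; output matches the
        spatial shape and channel count of ``x_t``.
        """
        x_t = np.asarray(x_t, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if x_t.shape != y.shape:
            raise ValueError(f"x_t {x_t.shape} and y {y.shape} differ")
        single = x_t.ndim == 3
        if single:
            x_t, y = x_t[None], y[None]
        if x_t.shape[1] != self.config.out_channels:
            raise ValueError(
                f"expected {self.config.out_channels}-channel images, "
                f"got {x_t.shape[1]}")
        xin = np.concatenate([x_t, y], axis=1).transpose(0, 2, 3, 1)
        with ad.no_grad():
            out = self.unet_t(Tensor(xin), t)
        out = out.data.transpose(0, 3, 1, 2)
        return out[0] if single else out

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "normalization_spec": self.normalization_spec,
            "T": self.t_max,
            "t_exit_default": self.t_exit_default,
            "seed_lineage": list(self.seed_lineage),
        }
        arrays = {f"param/{k}": p.data for k, p in self.params.items()}
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "DenoiserModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version {meta.get('version')!r} not "
                    f"supported (expected {CHECKPOINT_VERSION})")
            cfg_d = meta["config"]
            cfg_d["channel_mult"] = tuple(cfg_d["channel_mult"])
            if cfg_d.get("attention_levels") is not None:
                cfg_d["attention_levels"] = tuple(cfg_d["attention_levels"])
            config = DenoiserConfig(**cfg_d)
            params = {k[len("param/"):]: Tensor(z[k], requires_grad=True)
                      for k in z.files if k.startswith("param/")}
        return cls(config, params, meta["normalization_spec"], meta["T"],
                   meta["t_exit_default"], tuple(meta["seed_lineage"]))


def build_denoiser(config: DenoiserConfig, seed: int) -> DenoiserModel:
    """Construct f_c + eps_theta with seeded He-normal initialization.

    Output-facing convolutions (residual second conv, attention projection,
    final conv) start at a tenth of the He scale so the untrained network is
    close to the identity map on its skip connections while every branch
    still carries gradient.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}

    def conv_p(name, cin, cout, shrink=1.0):
        w = ad.parameter(rng, (3, 3, cin, cout), 9 * cin)
        w.data *= shrink
        params[f"{name}.w"] = w
        params[f"{name}.b"] = Tensor(np.zeros(cout, np.float32), True)

    def conv1_p(name, cin, cout, shrink=1.0):
        w = ad.parameter(rng, (cin, cout), cin)
        w.data *= shrink
        params[f"{name}.w"] = w
        params[f"{name}.b"] = Tensor(np.zeros(cout, np.float32), True)

    def lin_p(name, din, dout):
        params[f"{name}.w"] = ad.parameter(rng, (din, dout), din)
        params[f"{name}.b"] = Tensor(np.zeros(dout, np.float32), True)

    def norm_p(name, c):
        params[f"{name}.g"] = Tensor(np.ones(c, np.float32), True)
        params[f"{name}.b"] = Tensor(np.zeros(c, np.float32), True)

    def res_p(name, cin, cout):
        lin_p(f"{name}.temb", cfg.time_embed_dim, cin)
        norm_p(f"{name}.gn1", cin)
        conv_p(f"{name}.conv1", cin, cout,
               shrink=0.1 if cfg.res_convs == 1 else 1.0)
        if cfg.res_convs == 2:
            norm_p(f"{name}.gn2", cout)
            conv_p(f"{name}.conv2", cout, cout, shrink=0.1)
        if cin != cout:
            conv1_p(f"{name}.skip", cin, cout)

    def att_p(name, c):
        norm_p(f"{name}.gn", c)
        for part in ("q", "k", "v"):
            conv1_p(f"{name}.{part}", c, c)
        conv1_p(f"{name}.proj", c, c, shrink=0.1)

    # shallow dimension-matching network
    n2 = cfg.sr_factor ** 2
    conv_p("fc.conv1", cfg.af_channels, cfg.fc_hidden)
    conv_p("fc.conv2", cfg.fc_hidden, cfg.out_channels * n2)

    lin_p("temb.lin1", cfg.time_embed_dim, cfg.time_embed_dim)
    lin_p("temb.lin2", cfg.time_embed_dim, cfg.time_embed_dim)

    chans = cfg.channels
    conv_p("in", cfg.in_channels, chans[0])
    for i, c in enumerate(chans):
        cin = chans[0] if i == 0 else chans[i - 1]
        res_p(f"down{i}.res", cin, c)
        if (i + 1) in cfg.attention_levels:
            att_p(f"down{i}.att", c)
    res_p("mid.res1", chans[-1], chans[-1])
    att_p("mid.att", chans[-1])
    res_p("mid.res2", chans[-1], chans[-1])
    for i in reversed(range(cfg.levels)):
        c_cur = chans[i + 1] if i < cfg.levels - 1 else chans[-1]
        res_p(f"up{i}.res", chans[i] + c_cur, chans[i])
        if (i + 1) in cfg.attention_levels:
            att_p(f"up{i}.att", chans[i])
    norm_p("out.gn", chans[0])
    conv_p("out", chans[0], cfg.out_channels, shrink=0.1)

    return DenoiserModel(cfg, params, seed_lineage=(int(seed),))
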
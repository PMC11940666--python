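"""The contact-map enhancement network.

A hybrid CNN + transformer generator mapping one low-depth 40 x 40 contact
tile to an enhanced tile.  Four stages:

1. **PCFE** - a single 3x3 convolution lifting the 1-channel tile to C
   base feature channels.
2. **CCE** - a chain of hyper-residual modules (HRMs) built from cascading
   residual modules (CRMs) and dynamic residual enhancement modules
   (DREMs); all HRM outputs are concatenated into local features.
3. **TGFF** - a pre-norm transformer encoder block whose attention is an
   efficient multi-head self-attention (EMHSA): channels are halved by a
   reduction layer, the token axis is split into s contiguous segments,
   scaled dot-product attention runs within each segment, and an
   expansion layer restores the channels.  The MLP uses a SwiGLU gate.
4. **HRR** - two convolution + pixel-shuffle branches (one from the global
   features, one from the base features) summed into the output tile.

The depth-enhancement task keeps input and output at the same bin size,
so the pixel-shuffle scale defaults to 1; it is configurable for genuine
spatial upscaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, LayerNorm, Linear, Module, Parameter, Tensor

__all__ = ["ModelConfig", "HiCEnhancer", "PCFE", "CRM", "DREM", "HRM", "CCE", "EMHSA", "TGFF", "HRR"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``channels`` is the CNN width C, ``n_hrm`` the number of hyper-residual
    modules (their concatenated outputs give the transformer width
    ``n_hrm * C``), ``heads`` the attention head count m, ``segments`` the
    number of token segments s in EMHSA, and ``pixelshuffle_scale`` the
    spatial upscaling factor r (1 = depth enhancement at fixed bin size).
    """

    channels: int = 32
    n_hrm: int = 3
    crm_resblocks: int = 3
    drem_shared_count: int = 5
    heads: int = 8
    segments: int = 5
    mlp_expansion: int = 2
    pixelshuffle_scale: int = 1
    block_side: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels % 2:
            raise ValueError("channels must be even (EMHSA halves them)")
        c_red = self.n_hrm * self.channels // 2
        if c_red % self.heads:
            raise ValueError(
                f"reduced channel count {c_red} not divisible by heads={self.heads}"
            )
        r = self.pixelshuffle_scale
        if self.channels % (r * r):
            raise ValueError("channels must be divisible by pixelshuffle_scale^2")
        if self.segments < 1 or self.n_hrm < 1:
            raise ValueError("segments and n_hrm must be >= 1")


class PCFE(Module):
    """Preliminary feature extraction: one 3x3 convolution, 1 -> C channels."""

    def __init__(self, cfg: ModelConfig, rng):
        self.conv = Conv2d(1, cfg.channels, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != x.shape[-2]:
            raise ValueError(f"input tiles must be square, got {x.shape}")
        return self.conv(x)


class ResBlock(Module):
    """Two 3x3 convs, each followed by ReLU, with an identity skip."""

    def __init__(self, c: int, rng):
        self.conv1 = Conv2d(c, c, 3, rng)
        self.conv2 = Conv2d(c, c, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).relu()).relu()


class CRM(Module):
    """Cascading residual module: ResBlock -> concat with input -> 1x1 conv,
    repeated ``n_blocks`` times."""

    def __init__(self, c: int, rng, n_blocks: int = 3):
        self.blocks = [ResBlock(c, rng) for _ in range(n_blocks)]
        self.fuses = [Conv2d(2 * c, c, 1, rng) for _ in range(n_blocks)]

    def forward(self, x: Tensor) -> Tensor:
        for block, fuse in zip(self.blocks, self.fuses):
            x = fuse(Tensor.concat([block(x), x], axis=1))
        return x


class ResidualUnit(Module):
    """Two 3x3 convs with adaptive residual scaling:
    ``out = w_id * x + w_res * unit(x)`` (both scalars learnable, init 1)."""

    def __init__(self, c: int, rng):
        self.conv1 = Conv2d(c, c, 3, rng)
        self.conv2 = Conv2d(c, c, 3, rng)
        self.w_id = Parameter(np.ones(1))
        self.w_res = Parameter(np.ones(1))

    def forward(self, x: Tensor) -> Tensor:
        return self.w_id * x + self.w_res * self.conv2(self.conv1(x).relu())


class DREM(Module):
    """Dynamic residual enhancement: two sequential residual units whose
    outputs are concatenated, then fused by a 1x1 and a 3x3 convolution."""

    def __init__(self, c: int, rng):
        self.unit1 = ResidualUnit(c, rng)
        self.unit2 = ResidualUnit(c, rng)
        self.fuse1 = Conv2d(2 * c, c, 1, rng)
        self.fuse2 = Conv2d(c, c, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        u1 = self.unit1(x)
        u2 = self.unit2(u1)
        return self.fuse2(self.fuse1(Tensor.concat([u1, u2], axis=1)))


def _pad_even(x: Tensor) -> tuple[Tensor, int, int]:
    """Zero-pad bottom/right so spatial dims become even."""
    B, C, H, W = x.shape
    ph, pw = H % 2, W % 2
    if ph:
        x = Tensor.concat([x, Tensor(np.zeros((B, C, 1, W), dtype=np.float32))], axis=2)
    if pw:
        x = Tensor.concat(
            [x, Tensor(np.zeros((B, C, H + ph, 1), dtype=np.float32))], axis=3
        )
    return x, ph, pw


class HRM(Module):
    """Hyper-residual module.

    Pipeline: CRM -> DREM -> 2x2 average-pool down-sampling; in parallel a
    high-pass residual (input minus its smoothed, re-upsampled copy) is
    refined by one DREM; the pooled path runs through five weight-shared
    DREM applications (one parameter set) and is bilinearly upsampled;
    both paths are concatenated, fused (1x1 conv), refined (DREM, CRM) and
    added to the module input.
    """

    def __init__(self, cfg: ModelConfig, rng):
        c = cfg.channels
        self.crm_in = CRM(c, rng, cfg.crm_resblocks)
        self.drem_in = DREM(c, rng)
        self.drem_high = DREM(c, rng)
        self.drem_shared = DREM(c, rng)  # applied drem_shared_count times
        self.n_shared = cfg.drem_shared_count
        self.fuse = Conv2d(2 * c, c, 1, rng)
        self.drem_out = DREM(c, rng)
        self.crm_out = CRM(c, rng, cfg.crm_resblocks)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        y = self.drem_in(self.crm_in(x))
        y_pad, ph, pw = _pad_even(y)
        low = y_pad.avg_pool2()
        # high-pass branch: input minus its low-frequency (pooled+upsampled) copy
        x_pad, _, _ = _pad_even(x)
        smoothed = x_pad.avg_pool2().resize_bilinear(H + ph, W + pw)
        if ph or pw:
            smoothed = smoothed[:, :, :H, :W]
        p_high = x - smoothed
        p_high = self.drem_high(p_high)
        for _ in range(self.n_shared):
            low = self.drem_shared(low)
        up = low.resize_bilinear(H + ph, W + pw)
        if ph or pw:
            up = up[:, :, :H, :W]
        z = self.fuse(Tensor.concat([up, p_high], axis=1))
        z = self.crm_out(self.drem_out(z))
        return z + x


class CCE(Module):
    """Convolutional context enhancement: sequential HRMs, outputs concatenated."""

    def __init__(self, cfg: ModelConfig, rng):
        self.hrms = [HRM(cfg, rng) for _ in range(cfg.n_hrm)]

    def forward(self, f_base: Tensor) -> Tensor:
        outs = []
        f = f_base
        for hrm in self.hrms:
            f = hrm(f)
            outs.append(f)
        return outs[0] if len(outs) == 1 else Tensor.concat(outs, axis=1)


class EMHSA(Module):
    """Efficient multi-head self-attention over segmented tokens.

    Channels are halved by a 1x1 reduction, the H*W spatial positions are
    flattened into N tokens, Q/K/V are projected and split head-wise, the
    token axis is cut into ``s`` contiguous segments (zero-padded if N is
    not divisible by s), scaled dot-product attention runs per segment,
    and a 1x1 expansion restores the channel count.  Complexity drops
    from O(N^2) to O(N^2 / s).
    """

    def __init__(self, c_in: int, heads: int, segments: int, rng):
        if (c_in // 2) % heads:
            raise ValueError(
                f"reduced channels {c_in // 2} not divisible by heads={heads}"
            )
        self.c_in = c_in
        self.c_red = c_in // 2
        self.heads = heads
        self.segments = segments
        self.reduce = Conv2d(c_in, self.c_red, 1, rng)
        self.q = Linear(self.c_red, self.c_red, rng)
        self.k = Linear(self.c_red, self.c_red, rng)
        self.v = Linear(self.c_red, self.c_red, rng)
        self.expand = Linear(self.c_red, c_in, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        N = H * W
        m, s, d = self.heads, self.segments, self.c_red // self.heads
        t = self.reduce(x).reshape(B, self.c_red, N).transpose(0, 2, 1)  # (B,N,Cr)
        q, k, v = self.q(t), self.k(t), self.v(t)

        def split(z: Tensor) -> Tensor:
            z = z.reshape(B, N, m, d).transpose(0, 2, 1, 3)  # (B,m,N,d)
            pad = (-N) % s
            if pad:
                zeros = Tensor(np.zeros((B, m, pad, d), dtype=np.float32))
                z = Tensor.concat([z, zeros], axis=2)
            ns = (N + pad) // s
            return z.reshape(B, m, s, ns, d)

        qs, ks, vs = split(q), split(k), split(v)
        out = Tensor.sdpa(qs, ks, vs, 1.0 / np.sqrt(d))  # (B,m,s,ns,d)
        ns = out.shape[3]
        out = out.reshape(B, m, s * ns, d)
        if s * ns != N:
            out = out[:, :, :N, :]
        out = out.transpose(0, 2, 1, 3).reshape(B, N, self.c_red)
        out = self.expand(out)  # (B,N,C)
        return out.transpose(0, 2, 1).reshape(B, C, H, W)


class TGFF(Module):
    """Pre-norm transformer block: EMHSA then a SwiGLU MLP, each with a
    residual connection; layer norm acts over the channel axis of tokens."""

    def __init__(self, c_in: int, cfg: ModelConfig, rng):
        self.c_in = c_in
        self.norm1 = LayerNorm(c_in)
        self.attn = EMHSA(c_in, cfg.heads, cfg.segments, rng)
        self.norm2 = LayerNorm(c_in)
        hidden = cfg.mlp_expansion * c_in
        self.mlp_in = Linear(c_in, 2 * hidden, rng)  # gate and value halves
        self.mlp_out = Linear(hidden, c_in, rng)
        self.hidden = hidden

    def _tokens(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        return x.reshape(B, C, H * W).transpose(0, 2, 1)

    def _spatial(self, t: Tensor, H: int, W: int) -> Tensor:
        B, N, C = t.shape
        return t.transpose(0, 2, 1).reshape(B, C, H, W)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        t = self._tokens(x)
        ln1 = self._spatial(self.norm1(t), H, W)
        f_m = self.attn(ln1) + x
        tm = self._tokens(f_m)
        h = self.mlp_in(self.norm2(tm))
        gate = h[:, :, : self.hidden]
        val = h[:, :, self.hidden :]
        h = gate.silu() * val  # SwiGLU
        out = self.mlp_out(h)
        return self._spatial(out, H, W) + f_m


class HRR(Module):
    """High-resolution reconstruction: conv/pixel-shuffle branches from the
    global and base features, summed into the 1-channel output tile."""

    def __init__(self, c_global: int, cfg: ModelConfig, rng):
        c = cfg.channels
        r = cfg.pixelshuffle_scale
        self.r = r
        self.pre = Conv2d(c_global, c * r * r, 3, rng)
        self.post = Conv2d(c, 1, 3, rng)
        if c % (r * r):
            raise ValueError("base channels not divisible by pixelshuffle_scale^2")
        self.base_out = Conv2d(c // (r * r), 1, 3, rng)

    def forward(self, f_global: Tensor, f_base: Tensor) -> Tensor:
        main = self.post(self.pre(f_global).pixel_shuffle(self.r))
        skip = self.base_out(f_base.pixel_shuffle(self.r))
        return main + skip


class HiCEnhancer(Module):
    """Full generator: PCFE -> CCE -> TGFF -> HRR.

    ``forward(x, training=True)`` returns raw values; inference mode
    clamps the output into [0, 1] to match the scaled contact range.
    """

    def __init__(self, cfg: ModelConfig | None = None):
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(self.cfg.seed)
        c_local = self.cfg.n_hrm * self.cfg.channels
        self.pcfe = PCFE(self.cfg, rng)
        self.cce = CCE(self.cfg, rng)
        self.tgff = TGFF(c_local, self.cfg, rng)
        self.hrr = HRR(c_local, self.cfg, rng)

    def forward(self, x: Tensor, training: bool = True) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        f_base = self.pcfe(x)
        f_local = self.cce(f_base)
        f_global = self.tgff(f_local)
        out = self.hrr(f_global, f_base)
        return out if training else out.clamp01()

    def summary(self) -> dict[str, int]:
        """Trainable-parameter count per submodule and in total."""
        counts = {
            "pcfe": self.pcfe.n_parameters(),
            "cce": self.cce.n_parameters(),
            "tgff": self.tgff.n_parameters(),
            "hrr": self.hrr.n_parameters(),
        }
        counts["total"] = self.n_parameters()
        return counts
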
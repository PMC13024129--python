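"""The multi-task blood-pressure network: a residual 1-D U-Net with a
multi-scale channel-temporal-attention (CTA) bottleneck, a bidirectional
selective state-space (Mamba) block, and two heads — SBP/DBP regression and
auxiliary ABP waveform reconstruction.

The input is a three-channel stack of the radar pulse wave and its first
and second temporal derivatives (velocity/acceleration pulse waves), each
L2-normalized.  The encoder downsamples by 2 at four stage boundaries
(kernel-3 strided convolutions), so the bottleneck runs at L/16; the decoder
mirrors it with linear-interpolation upsampling and CTA-gated skip
concatenation.  ``ModelConfig.tiny()`` (base width 4, L=256) trains in
minutes on one CPU while exercising every branch of the full graph.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.autodiff import Tensor, concat, stack, upsample_linear2

__all__ = [
    "ModelConfig", "PredictionBundle", "derivative_channels", "ResidualBlock",
    "CTAttention", "MultiScaleBottleneck", "selective_ssm_scan", "MambaBlock",
    "BiMamba", "MARUMTL", "scan_step_counter",
]

# running count of executed scan timesteps (the linear-time contract of the
# selective scan is asserted against this)
scan_step_counter = {"steps": 0}

TEMPORAL_MODULES = ("bimamba", "mamba", "none")
BOTTLENECK_VARIANTS = ("multiscale_cta", "multiscale_plain", "single_scale")


# ---------------------------------------------------------------------------
# input construction
# ---------------------------------------------------------------------------

def derivative_channels(rpw: np.ndarray, fs: float = 100.0) -> np.ndarray:
    """Stack (RPW, VRPW, ARPW): the window, its first derivative (central
    differences, one-sided at the edges, scaled by fs) and its second
    derivative; each channel L2-normalized (all-zero channels stay zero)."""
    x = np.asarray(rpw, dtype=np.float64)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D window of at least 3 samples")
    v = np.gradient(x) * fs
    a = np.gradient(v) * fs
    out = np.stack([x, v, a])
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    # channels that are numerically zero (e.g. the second derivative of a
    # ramp) stay zero instead of amplifying rounding noise
    return np.divide(out, norms, out=np.zeros_like(out), where=norms > 1e-9)


@dataclass
class PredictionBundle:
    sbp: Tensor | np.ndarray       # (B,)
    dbp: Tensor | np.ndarray
    abp: Tensor | np.ndarray       # (B, L)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    input_len: int = 1024
    base_width: int = 64
    in_channels: int = 3
    blocks: tuple[int, ...] = (1, 2, 2, 2, 1)
    cta_reduction: int = 4
    cta_kernel: int = 7
    d_state: int = 16
    d_conv: int = 4
    expand: int = 2
    dropout: float = 0.1
    temporal_module: str = "bimamba"
    bottleneck: str = "multiscale_cta"

    def __post_init__(self):
        if self.input_len % 16 != 0:
            raise ValueError("input_len must be divisible by 16 (four 2x stages)")
        if self.base_width % self.cta_reduction != 0:
            raise ValueError("base width must be divisible by the CTA reduction")
        if self.temporal_module not in TEMPORAL_MODULES:
            raise ValueError(f"temporal_module must be one of {TEMPORAL_MODULES}")
        if self.bottleneck not in BOTTLENECK_VARIANTS:
            raise ValueError(f"bottleneck must be one of {BOTTLENECK_VARIANTS}")

    @property
    def channels(self) -> tuple[int, ...]:
        b = self.base_width
        return (b, 2 * b, 4 * b, 8 * b, 16 * b)

    @classmethod
    def tiny(cls, input_len: int = 256, **kwargs) -> "ModelConfig":
        return cls(input_len=input_len, base_width=4, **kwargs)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ResidualBlock(nn.Module):
    """Two Conv1d(k=3)-BN-ReLU stages with an identity shortcut, or a 1x1
    projection when the channel count changes."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv1d(cin, cout, 3, rng, padding=1)
        self.bn1 = nn.BatchNorm1d(cout)
        self.conv2 = nn.Conv1d(cout, cout, 3, rng, padding=1)
        self.bn2 = nn.BatchNorm1d(cout)
        self.proj = nn.Conv1d(cin, cout, 1, rng) if cin != cout else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        shortcut = self.proj(x) if self.proj is not None else x
        return (h + shortcut).relu()


class CTAttention(nn.Module):
    """Channel-temporal attention: a shared two-layer perceptron over global
    average/max channel descriptors gives the channel map; a kernel-7
    convolution over the channel-pooled average/max stack gives the temporal
    map; the input is recalibrated by both (sigmoid gates in (0, 1))."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, kernel: int = 7):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.mlp1 = nn.Linear(channels, hidden, rng)
        self.mlp2 = nn.Linear(hidden, channels, rng)
        self.temporal_conv = nn.Conv1d(2, 1, kernel, rng, padding=kernel // 2)

    def channel_map(self, x: Tensor) -> Tensor:
        avg = nn.global_avg_pool(x)           # (B, C)
        mx = nn.global_max_pool(x)
        # GELU rather than ReLU in the squeeze MLP: at tiny widths the
        # reduced hidden layer is 1-2 units and a hard ReLU can die
        gate = self.mlp2(self.mlp1(avg).gelu()) + self.mlp2(self.mlp1(mx).gelu())
        return gate.sigmoid()

    def temporal_map(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)   # (B, 1, L)
        mx = x.max(axis=1, keepdims=True)
        return self.temporal_conv(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        mc = self.channel_map(x)              # (B, C)
        mt = self.temporal_map(x)             # (B, 1, L)
        b, c = mc.shape
        return x * mc.reshape(b, c, 1) * mt


class MultiScaleBottleneck(nn.Module):
    """Parallel kernel-1/3/5 branches (conv-BN-ReLU, each CTA-refined),
    channel-concatenated and fused by a pointwise conv-BN-ReLU back to the
    bottleneck width.  ``variant`` drops CTA or the extra scales for
    ablation."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, cta_kernel: int = 7,
                 variant: str = "multiscale_cta"):
        super().__init__()
        self.variant = variant
        kernels = (1, 3, 5) if variant != "single_scale" else (3,)
        self.branch_convs = [nn.Conv1d(channels, channels, k, rng, padding=k // 2)
                             for k in kernels]
        self.branch_bns = [nn.BatchNorm1d(channels) for _ in kernels]
        self.branch_ctas = ([CTAttention(channels, rng, reduction, cta_kernel)
                             for _ in kernels] if variant == "multiscale_cta" else [])
        self.fuse = nn.Conv1d(channels * len(kernels), channels, 1, rng)
        self.fuse_bn = nn.BatchNorm1d(channels)

    def forward(self, x: Tensor) -> Tensor:
        outs = []
        for i, (conv, bn) in enumerate(zip(self.branch_convs, self.branch_bns)):
            z = bn(conv(x)).relu()
            if self.branch_ctas:
                z = self.branch_ctas[i](z)
            outs.append(z)
        fused = outs[0] if len(outs) == 1 else concat(outs, axis=1)
        return self.fuse_bn(self.fuse(fused)).relu()


# ---------------------------------------------------------------------------
# selective state-space scan and Mamba
# ---------------------------------------------------------------------------

def selective_ssm_scan(x, dt, A, B, C, D=None):
    """Input-dependent (selective) SSM recurrence, zero initial state:

        h_t = exp(dt_t * A) h_{t-1} + (dt_t * x_t) B_t,   y_t = <h_t, C_t> + D x_t

    Shapes: x, dt (batch, T, d_inner); A (d_inner, N); B, C (batch, T, N);
    D (d_inner,) optional skip.  Runs as an explicit scan, linear in T;
    accepts numpy arrays or autodiff tensors and differentiates through the
    recurrence in the latter case.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    dt = dt if isinstance(dt, Tensor) else Tensor(dt)
    A = A if isinstance(A, Tensor) else Tensor(A)
    B = B if isinstance(B, Tensor) else Tensor(B)
    C = C if isinstance(C, Tensor) else Tensor(C)
    for t in (x, dt, A, B, C):
        if not np.all(np.isfinite(t.data)):
            raise ValueError("non-finite SSM parameters")
    batch, T, d_inner = x.shape
    n = A.shape[1]
    dtA = dt.reshape(batch, T, d_inner, 1) * A.reshape(1, 1, d_inner, n)
    decay = dtA.exp()                                           # (B,T,I,N)
    drive = (dt * x).reshape(batch, T, d_inner, 1) * B.reshape(batch, T, 1, n)
    h = Tensor(np.zeros((batch, d_inner, n)))
    ys = []
    for t in range(T):
        h = decay[:, t] * h + drive[:, t]
        ys.append((h * C[:, t].reshape(batch, 1, n)).sum(axis=2))  # (B, I)
        scan_step_counter["steps"] += 1
    y = stack(ys, axis=1)                                       # (B, T, I)
    if D is not None:
        D = D if isinstance(D, Tensor) else Tensor(D)
        y = y + x * D.reshape(1, 1, d_inner)
    return y


class MambaBlock(nn.Module):
    """One causal selective-SSM (Mamba) block on (batch, T, d_model).

    Canonical formulation: input projection to an expanded width plus a
    gate, short causal depthwise convolution, input-dependent step size via
    softplus, diagonal state matrix A = -exp(A_log) with S4D-real
    initialization, zero-order-hold discretization, SiLU gating, output
    projection.
    """

    def __init__(self, d_model: int, rng: np.random.Generator, d_state: int = 16,
                 d_conv: int = 4, expand: int = 2):
        super().__init__()
        self.d_model = d_model
        self.d_state = d_state
        self.d_conv = d_conv
        self.d_inner = expand * d_model
        self.dt_rank = max(1, d_model // 16)
        self.in_proj = nn.Linear(d_model, 2 * self.d_inner, rng, bias=False)
        bound = 1.0 / np.sqrt(d_conv)
        self.conv_weight = nn.parameter(rng.uniform(-bound, bound,
                                                    (d_conv, self.d_inner)))
        self.conv_bias = nn.parameter(np.zeros(self.d_inner))
        self.x_proj = nn.Linear(self.d_inner, self.dt_rank + 2 * d_state, rng,
                                bias=False)
        self.dt_proj = nn.Linear(self.dt_rank, self.d_inner, rng)
        # bias such that softplus(bias) spans [1e-3, 1e-1] (standard dt init)
        dt_init = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), self.d_inner))
        self.dt_proj.bias.data = dt_init + np.log(-np.expm1(-dt_init))
        self.A_log = nn.parameter(np.log(np.tile(np.arange(1, d_state + 1, dtype=float),
                                                 (self.d_inner, 1))))
        self.D_skip = nn.parameter(np.ones(self.d_inner))
        self.out_proj = nn.Linear(self.d_inner, d_model, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        batch, T, _ = x.shape
        xz = self.in_proj(x)
        xi = xz[:, :, :self.d_inner]
        z = xz[:, :, self.d_inner:]
        # causal depthwise convolution along time
        padded = concat([Tensor(np.zeros((batch, self.d_conv - 1, self.d_inner))),
                         xi], axis=1)
        xc = None
        for k in range(self.d_conv):
            term = padded[:, k:k + T, :] * self.conv_weight[k]
            xc = term if xc is None else xc + term
        xc = (xc + self.conv_bias).silu()
        dbc = self.x_proj(xc)
        dt = (self.dt_proj(dbc[:, :, :self.dt_rank])).softplus()
        Bmat = dbc[:, :, self.dt_rank:self.dt_rank + self.d_state]
        Cmat = dbc[:, :, self.dt_rank + self.d_state:]
        A = -(self.A_log.exp())
        y = selective_ssm_scan(xc, dt, A, Bmat, Cmat, self.D_skip)
        return self.out_proj(y * z.silu())


class BiMamba(nn.Module):
    """Two independent Mamba branches over the sequence and its reversal;
    fused by a GELU-activated linear projection with a residual connection
    and layer normalization (h_out = LN(GELU(W [h_f; h_b]) + x))."""

    def __init__(self, d_model: int, rng: np.random.Generator, **mamba_kwargs):
        super().__init__()
        self.forward_branch = MambaBlock(d_model, rng, **mamba_kwargs)
        self.backward_branch = MambaBlock(d_model, rng, **mamba_kwargs)
        self.fuse = nn.Linear(2 * d_model, d_model, rng)
        self.ln = nn.LayerNorm(d_model)

    def fused_features(self, x: Tensor) -> Tensor:
        """Pre-residual fusion GELU(Linear([h_f; h_b]))."""
        h_f = self.forward_branch(x)
        h_b = self.backward_branch(x.flip(1)).flip(1)
        return self.fuse(concat([h_f, h_b], axis=2)).gelu()

    def forward(self, x: Tensor) -> Tensor:
        return self.ln(self.fused_features(x) + x)


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class MARUMTL(nn.Module):
    """Residual U-Net + multi-scale CTA bottleneck + Bi-Mamba + dual heads."""

    def __init__(self, config: ModelConfig | None = None, rng_seed: int = 0):
        super().__init__()
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(rng_seed)
        chans = cfg.channels

        # encoder: per stage a run of residual blocks, then (stages 1-4) a
        # kernel-3 stride-2 downsampling convolution
        self.enc_stages = []
        self.down_convs = []
        cin = cfg.in_channels
        for k, (c, n_blocks) in enumerate(zip(chans, cfg.blocks)):
            blocks = [ResidualBlock(cin if i == 0 else c, c, rng)
                      for i in range(n_blocks)]
            self.enc_stages.append(nn.Sequential(*blocks))
            if k < 4:
                self.down_convs.append(nn.Conv1d(c, chans[k + 1], 3, rng,
                                                 stride=2, padding=1))
            cin = chans[min(k + 1, 4)]

        d_model = chans[-1]
        self.bottleneck = MultiScaleBottleneck(
            d_model, rng, cfg.cta_reduction, cfg.cta_kernel, cfg.bottleneck)
        if cfg.temporal_module == "bimamba":
            self.temporal = BiMamba(d_model, rng, d_state=cfg.d_state,
                                    d_conv=cfg.d_conv, expand=cfg.expand)
        elif cfg.temporal_module == "mamba":
            self.temporal = MambaBlock(d_model, rng, d_state=cfg.d_state,
                                       d_conv=cfg.d_conv, expand=cfg.expand)
        else:
            self.temporal = None
        self.bottleneck_dropout = nn.Dropout(cfg.dropout,
                                             np.random.default_rng(rng_seed + 101))

        # decoder: 4 up-stages with CTA-gated skip concatenation
        self.skip_ctas = []
        self.dec_blocks = []
        for k in range(3, -1, -1):
            self.skip_ctas.append(CTAttention(chans[k], rng, cfg.cta_reduction,
                                              cfg.cta_kernel))
            self.dec_blocks.append(ResidualBlock(chans[k + 1] + chans[k],
                                                 chans[k], rng))

        base = chans[0]
        # regression head: GAP -> FC -> ReLU -> dropout -> FC -> (SBP, DBP)
        hidden = max(base // 2, 8)
        self.reg_fc1 = nn.Linear(base, hidden, rng)
        self.reg_drop = nn.Dropout(cfg.dropout, np.random.default_rng(rng_seed + 202))
        self.reg_fc2 = nn.Linear(hidden, 2, rng)
        # ABP head: two temporal convolutions then a pointwise projection
        mid1, mid2 = max(base // 2, 4), max(base // 4, 2)
        self.abp_conv1 = nn.Conv1d(base, mid1, 3, rng, padding=1)
        self.abp_conv2 = nn.Conv1d(mid1, mid2, 3, rng, padding=1)
        # no bias on the projection: the reconstruction loss instance-
        # normalizes the waveform, so an output offset is unidentifiable
        self.abp_conv3 = nn.Conv1d(mid2, 1, 1, rng, bias=False)

    # ------------------------------------------------------------------
    def set_output_bias(self, sbp: float, dbp: float) -> None:
        """Initialize the regression-head bias at the training-label mean so
        the mmHg-scale Huber loss starts near the data centre."""
        self.reg_fc2.bias.data = np.array([float(sbp), float(dbp)])

    def forward(self, x: Tensor | np.ndarray) -> PredictionBundle:
        x = x if isinstance(x, Tensor) else Tensor(x)
        cfg = self.config
        if x.shape[1] != cfg.in_channels or x.shape[2] != cfg.input_len:
            raise ValueError(f"expected input (B, {cfg.in_channels}, "
                             f"{cfg.input_len}), got {x.shape}")
        skips = []
        h = x
        for k, stage in enumerate(self.enc_stages):
            h = stage(h)
            if k < 4:
                skips.append(h)
                h = self.down_convs[k](h)

        h = self.bottleneck(h)
        if self.temporal is not None:
            seq = h.transpose(0, 2, 1)            # (B, T, d_model)
            seq = self.temporal(seq)
            h = seq.transpose(0, 2, 1)
        h = self.bottleneck_dropout(h)

        for cta, block, skip in zip(self.skip_ctas, self.dec_blocks,
                                    reversed(skips)):
            h = upsample_linear2(h)
            h = block(concat([h, cta(skip)], axis=1))

        pooled = nn.global_avg_pool(h)            # (B, base)
        reg = self.reg_fc2(self.reg_drop(self.reg_fc1(pooled).relu()))
        abp = self.abp_conv3(self.abp_conv2(self.abp_conv1(h).relu()).relu())
        return PredictionBundle(sbp=reg[:, 0], dbp=reg[:, 1], abp=abp[:, 0, :])
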
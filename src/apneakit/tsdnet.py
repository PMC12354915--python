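"""TSD-Net: a four-stage local-to-global attention network for 30-s epoch
classification of respiratory events.

The network maps a fixed-length epoch ``[B, 1, 256]`` (a 270-s context window
resampled to 256 samples) to a scalar event probability while retaining the
per-stage attention maps that drive the scale-diffusion explanations.

Architecture overview
---------------------
* **Stem** — two stride-2 convolutions (kernel 3, batch norm, GELU between),
  reducing length 256 -> 64 and lifting to the stage-1 embedding width.
* **Stages 1-2** — multi-scale convolutional attention (MSCA) blocks. Each
  block computes a value branch ``V = W_v X`` and a modulation branch
  ``M = CSEF(MHCE(W_s X))``, fuses them as ``SE(M ⊙ V)`` inside a pre-norm
  residual block with a feed-forward sublayer.
* **Stage 3** — interleaved MSCA and multi-head self-attention (MHSA) blocks,
  the transition from local to global context.
* **Stage 4** — MHSA only, with the feature map ``[B, C4, 8]`` feeding both
  the classification head and (after channel pooling) downstream fusion.
* Feature length halves and width doubles at every stage boundary via a
  strided convolution, giving the length trace 64 -> 32 -> 16 -> 8.

Two named variants are provided, ``tsdnet_t()`` (tiny) and ``tsdnet_b()``
(base); :func:`count_params_macs` reports their size and per-forward
multiply-accumulate cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "TSDNetConfig",
    "tsdnet_t",
    "tsdnet_b",
    "tsdnet_reduced",
    "AttentionStack",
    "TSDNet",
    "MHCE",
    "CSEF",
    "SEBlock",
    "MSCABlock",
    "MHSABlock",
    "extract_stage4_features",
    "count_params_macs",
]

INPUT_LEN = 256
STAGE_LENGTHS = (64, 32, 16, 8)


@dataclass(frozen=True)
class TSDNetConfig:
    """Structural hyperparameters of a TSD-Net.

    ``stage3_blocks`` is a pair ``(n_msca, n_mhsa)``; the blocks are
    interleaved starting with MSCA, any surplus of one kind trailing.
    """

    stage_dims: tuple[int, int, int, int] = (64, 128, 256, 512)
    stage12_blocks: tuple[int, int] = (2, 2)
    stage3_blocks: tuple[int, int] = (7, 7)
    stage4_blocks: int = 1
    conv_heads: tuple[int, int, int] = (4, 4, 4)      # MSCA heads, stages 1-3
    attn_heads: tuple[int, int] = (8, 16)             # MHSA heads, stages 3-4
    mlp_ratio: int = 2
    expand_ratio: int = 2
    head_kernel: int = 3
    multiscale_kernels: bool = True   # head j kernel = head_kernel + 2(j-1)
    se_reduction: int = 16
    stem_two_convs: bool = True
    pos_embedding: bool = True
    variant: str = "B"

    def __post_init__(self):
        if len(self.stage_dims) != 4:
            raise ValueError("stage_dims must have four entries")
        for a, b in zip(self.stage_dims, self.stage_dims[1:]):
            if b != 2 * a:
                raise ValueError("stage dims must double per stage")
        if self.mlp_ratio < 1 or self.expand_ratio < 1:
            raise ValueError("mlp_ratio and expand_ratio must be >= 1")

    def head_kernels(self, n_heads: int) -> tuple[int, ...]:
        if self.multiscale_kernels:
            return tuple(self.head_kernel + 2 * j for j in range(n_heads))
        return (self.head_kernel,) * n_heads


def tsdnet_t() -> TSDNetConfig:
    """Tiny variant: 3.7 M parameters, 0.05 Gmac on a [1,1,256] input."""
    return TSDNetConfig(stage_dims=(48, 96, 192, 384), stage3_blocks=(3, 4),
                        variant="T")


def tsdnet_b() -> TSDNetConfig:
    """Base variant: 10.0 M parameters, 0.15 Gmac on a [1,1,256] input."""
    return TSDNetConfig(stage_dims=(64, 128, 256, 512), stage3_blocks=(7, 7),
                        variant="B")


def tsdnet_reduced() -> TSDNetConfig:
    """Width-reduced trainable variant (dims 16/32/64/128) for CPU studies."""
    return TSDNetConfig(stage_dims=(16, 32, 64, 128), stage3_blocks=(3, 4),
                        variant="reduced")


@dataclass
class AttentionStack:
    """Per-stage attention retained during a forward pass.

    ``kinds[s]`` is ``"msca"`` (map shape ``[B, C_s, L_s]``, the modulation
    branch M) or ``"mhsa"`` (shape ``[B, heads, L_s, L_s]``, row-stochastic
    self-attention).
    """

    maps: list[np.ndarray] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)

    def length(self, stage: int) -> int:
        return self.maps[stage].shape[-1]


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class MHCE(nn.Module):
    """Multi-head convolutional encoder.

    Splits C channels into N contiguous head groups and applies a depthwise
    convolution with a head-specific kernel size ("same" padding) to each,
    concatenating the results in order.
    """

    def __init__(self, rng, c: int, heads: int, kernels: tuple[int, ...]):
        super().__init__()
        if c % heads:
            raise ValueError(f"channels ({c}) not divisible by heads ({heads})")
        self.heads = heads
        self.group = c // heads
        self.convs = [
            nn.Conv1d(rng, self.group, self.group, k, padding=k // 2,
                      groups=self.group)
            for k in kernels[:heads]
        ]

    def forward(self, x: Tensor) -> Tensor:
        parts = [
            conv(x.narrow(1, j * self.group, self.group))
            for j, conv in enumerate(self.convs)
        ]
        return parts[0] if len(parts) == 1 else nn.concat(parts, axis=1)


class CSEF(nn.Module):
    """Cross-scale encoding fusion.

    Regroups the head-major channel layout so group ``i`` holds channel ``i``
    of every head, mixes each group with a pointwise inverted bottleneck
    (``W_group``: expand by ``expand_ratio``, GELU, project back), and
    aggregates all channels with a pointwise convolution ``W_agg``.
    """

    def __init__(self, rng, c: int, heads: int, expand: int):
        super().__init__()
        if c % heads:
            raise ValueError(f"channels ({c}) not divisible by heads ({heads})")
        self.heads = heads
        self.n_groups = c // heads
        self.gather_idx = self.grouping_indices(c, heads)
        self.w_group_in = nn.Conv1d(rng, c, c * expand, 1, groups=self.n_groups)
        self.w_group_out = nn.Conv1d(rng, c * expand, c, 1, groups=self.n_groups)
        self.w_agg = nn.Conv1d(rng, c, c, 1)

    @staticmethod
    def grouping_indices(c: int, heads: int) -> np.ndarray:
        """Permutation taking head-major channels to group-major order.

        With C channels in N heads of size C/N, group i collects the i-th
        channel of every head: index (i, j) -> j * C/N + i.
        """
        group = c // heads
        return np.array([j * group + i for i in range(group) for j in range(heads)])

    def forward(self, h: Tensor) -> Tensor:
        g = h.index_select(1, self.gather_idx)
        g = self.w_group_out(nn.gelu(self.w_group_in(g)))
        return self.w_agg(g)


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gate (global pool -> bottleneck ->
    sigmoid -> rescale)."""

    def __init__(self, rng, c: int, reduction: int):
        super().__init__()
        hidden = max(c // reduction, 1)
        self.fc1 = nn.Linear(rng, c, hidden)
        self.fc2 = nn.Linear(rng, hidden, c)

    def gate(self, x: Tensor) -> Tensor:
        s = x.mean(axis=2)                       # [B, C]
        return nn.sigmoid(self.fc2(nn.relu(self.fc1(s))))

    def forward(self, x: Tensor) -> Tensor:
        g = self.gate(x)
        b, c = g.shape
        return x * g.reshape(b, c, 1)


class MSCABlock(nn.Module):
    """Pre-norm residual MSCA block: ``Z = SE(CSEF(MHCE(W_s X)) ⊙ W_v X)``
    followed by a feed-forward sublayer of width ``mlp_ratio * C``.

    The modulation branch M is kept on ``last_attention`` after each forward.
    """

    def __init__(self, rng, c: int, heads: int, kernels: tuple[int, ...],
                 expand: int, mlp_ratio: int, se_reduction: int):
        super().__init__()
        self.ln1 = nn.LayerNorm(c)
        self.w_s = nn.Conv1d(rng, c, c, 1)
        self.w_v = nn.Conv1d(rng, c, c, 1)
        self.mhce = MHCE(rng, c, heads, kernels)
        self.csef = CSEF(rng, c, heads, expand)
        self.se = SEBlock(rng, c, se_reduction)
        self.ln2 = nn.LayerNorm(c)
        self.ff1 = nn.Conv1d(rng, c, c * mlp_ratio, 1)
        self.ff2 = nn.Conv1d(rng, c * mlp_ratio, c, 1)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        v = self.w_v(h)
        m = self.csef(self.mhce(self.w_s(h)))
        self.last_attention = m.data.copy()
        x = x + self.se(m * v)
        return x + self.ff2(nn.gelu(self.ff1(self.ln2(x))))


class MHSABlock(nn.Module):
    """Pre-norm multi-head self-attention over the L positions of [B,C,L],
    with a feed-forward sublayer. Row-stochastic attention ([B,heads,L,L])
    is kept on ``last_attention``."""

    def __init__(self, rng, c: int, heads: int, mlp_ratio: int):
        super().__init__()
        if c % heads:
            raise ValueError(f"channels ({c}) not divisible by heads ({heads})")
        self.heads = heads
        self.dh = c // heads
        self.ln1 = nn.LayerNorm(c)
        self.qkv = nn.Linear(rng, c, 3 * c)
        self.proj = nn.Linear(rng, c, c)
        self.ln2 = nn.LayerNorm(c)
        self.ff1 = nn.Conv1d(rng, c, c * mlp_ratio, 1)
        self.ff2 = nn.Conv1d(rng, c * mlp_ratio, c, 1)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        b, c, l = x.shape
        t = self.ln1(x).transpose(0, 2, 1)           # [B, L, C]
        qkv = self.qkv(t).reshape(b, l, 3, self.heads, self.dh)
        q = qkv.narrow(2, 0, 1).reshape(b, l, self.heads, self.dh).transpose(0, 2, 1, 3)
        k = qkv.narrow(2, 1, 1).reshape(b, l, self.heads, self.dh).transpose(0, 2, 1, 3)
        v = qkv.narrow(2, 2, 1).reshape(b, l, self.heads, self.dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        attn = nn.softmax(scores, axis=-1)           # [B, heads, L, L]
        self.last_attention = attn.data.copy()
        y = (attn @ v).transpose(0, 2, 1, 3).reshape(b, l, c)
        x = x + self.proj(y).transpose(0, 2, 1)
        return x + self.ff2(nn.gelu(self.ff1(self.ln2(x))))


class Downsample(nn.Module):
    """Stage-boundary reduction: strided conv (kernel 3) halving L and
    doubling C, followed by batch norm."""

    def __init__(self, rng, cin: int, cout: int):
        super().__init__()
        self.conv = nn.Conv1d(rng, cin, cout, 3, stride=2, padding=1)
        self.bn = nn.BatchNorm1d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x))


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

def _interleave(n_msca: int, n_mhsa: int) -> list[str]:
    order: list[str] = []
    a, b = n_msca, n_mhsa
    while a or b:
        if a:
            order.append("msca")
            a -= 1
        if b:
            order.append("mhsa")
            b -= 1
    return order


class TSDNet(nn.Module):
    """Four-stage TSD-Net; see the module docstring for the layout."""

    def __init__(self, config: TSDNetConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        d = config.stage_dims

        if config.stem_two_convs:
            self.stem = nn.Sequential(
                nn.Conv1d(rng, 1, d[0], 3, stride=2, padding=1),
                nn.BatchNorm1d(d[0]), nn.GELU(),
                nn.Conv1d(rng, d[0], d[0], 3, stride=2, padding=1),
                nn.BatchNorm1d(d[0]))
        else:
            self.stem = nn.Sequential(
                nn.Conv1d(rng, 1, d[0], 7, stride=4, padding=3),
                nn.BatchNorm1d(d[0]))

        def msca(s):
            return MSCABlock(rng, d[s], config.conv_heads[s],
                             config.head_kernels(config.conv_heads[s]),
                             config.expand_ratio, config.mlp_ratio,
                             config.se_reduction)

        self.stage1 = [msca(0) for _ in range(config.stage12_blocks[0])]
        self.down1 = Downsample(rng, d[0], d[1])
        self.stage2 = [msca(1) for _ in range(config.stage12_blocks[1])]
        self.down2 = Downsample(rng, d[1], d[2])
        self.stage3_order = _interleave(*config.stage3_blocks)
        self.stage3 = [
            msca(2) if kind == "msca"
            else MHSABlock(rng, d[2], config.attn_heads[0], config.mlp_ratio)
            for kind in self.stage3_order
        ]
        self.down3 = Downsample(rng, d[2], d[3])
        self.stage4 = [MHSABlock(rng, d[3], config.attn_heads[1], config.mlp_ratio)
                       for _ in range(config.stage4_blocks)]
        if config.pos_embedding:
            self.pos3 = nn.Parameter(rng.normal(0, 0.02, (d[2], STAGE_LENGTHS[2])))
            self.pos4 = nn.Parameter(rng.normal(0, 0.02, (d[3], STAGE_LENGTHS[3])))
        else:
            self.pos3 = self.pos4 = None
        # head: final norm, adaptive average pool to the stage-4 length,
        # flatten, linear; keeping the 8 positions lets the classifier weight
        # the centre of the context window directly
        self.final_norm = nn.LayerNorm(d[3])
        self.head = nn.Linear(rng, d[3] * STAGE_LENGTHS[3], 1)

    # -- forward ------------------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:
        return self.forward_full(x)[0]

    def forward_full(self, x: Tensor) -> tuple[Tensor, AttentionStack, Tensor]:
        """Run the network, returning (probability [B], attention stack,
        stage-4 feature map [B, C4, 8])."""
        if x.shape[1] != 1 or x.shape[2] != INPUT_LEN:
            raise ValueError(
                f"expected input [B, 1, {INPUT_LEN}], got {tuple(x.shape)}")
        stack = AttentionStack()
        h = self.stem(x)
        for blk in self.stage1:
            h = blk(h)
        stack.maps.append(self.stage1[-1].last_attention)
        stack.kinds.append("msca")
        h = self.down1(h)
        for blk in self.stage2:
            h = blk(h)
        stack.maps.append(self.stage2[-1].last_attention)
        stack.kinds.append("msca")
        h = self.down2(h)
        if self.pos3 is not None:
            h = h + self.pos3.reshape(1, *self.pos3.shape)
        last_msca3 = None
        for blk, kind in zip(self.stage3, self.stage3_order):
            h = blk(h)
            if kind == "msca":
                last_msca3 = blk.last_attention
        if last_msca3 is not None:
            stack.maps.append(last_msca3)
            stack.kinds.append("msca")
        else:
            stack.maps.append(self.stage3[-1].last_attention)
            stack.kinds.append("mhsa")
        h = self.down3(h)
        if self.pos4 is not None:
            h = h + self.pos4.reshape(1, *self.pos4.shape)
        for blk in self.stage4:
            h = blk(h)
        stack.maps.append(self.stage4[-1].last_attention)
        stack.kinds.append("mhsa")
        # fusion consumes the raw stage-4 map: channel-pooling a layer-normed
        # map would give near-constant features (LN zeroes the channel mean)
        s4 = h
        h = self.final_norm(h)
        flat = h.reshape(h.shape[0], h.shape[1] * h.shape[2])   # [B, C4*8]
        prob = nn.sigmoid(self.head(flat)).reshape(h.shape[0])
        return prob, stack, s4

    def stage_trace(self, x: Tensor) -> list[tuple[int, int]]:
        """(C, L) after each stage, for shape-contract checks."""
        h = self.stem(x)
        trace = []
        for blocks, down in ((self.stage1, self.down1), (self.stage2, self.down2),
                             (self.stage3, self.down3), (self.stage4, None)):
            for blk in blocks:
                h = blk(h)
            trace.append((h.shape[1], h.shape[2]))
            if down is not None:
                h = down(h)
                if down is self.down2 and self.pos3 is not None:
                    h = h + self.pos3.reshape(1, *self.pos3.shape)
                if down is self.down3 and self.pos4 is not None:
                    h = h + self.pos4.reshape(1, *self.pos4.shape)
        return trace


def extract_stage4_features(stage4: np.ndarray | Tensor) -> np.ndarray:
    """Average the stage-4 feature map over its channel axis.

    [B, C4, 8] -> [B, 8]: one pooled feature per temporal position.
    """
    arr = stage4.data if isinstance(stage4, Tensor) else np.asarray(stage4)
    if arr.ndim != 3:
        raise ValueError("expected a [B, C, 8] stage-4 feature map")
    return arr.mean(axis=1)


# ---------------------------------------------------------------------------
# Parameter / MAC accounting
# ---------------------------------------------------------------------------

def _msca_macs(c: int, l: int, heads: int, kernels, expand: int, mlp: int,
               se_r: int) -> int:
    m = 3 * c * c * l                                   # W_s, W_v, W_agg
    m += sum((c // heads) * k * l for k in kernels[:heads])   # MHCE depthwise
    m += 2 * c * heads * expand * l                     # CSEF bottleneck
    m += 2 * c * max(c // se_r, 1)                      # SE MLP
    m += 2 * c * c * mlp * l                            # feed-forward
    return m


def _mhsa_macs(c: int, l: int, mlp: int) -> int:
    m = 4 * c * c * l                                   # qkv + proj
    m += 2 * l * l * c                                  # QK^T and AV
    m += 2 * c * c * mlp * l                            # feed-forward
    return m


def count_params_macs(config: TSDNetConfig) -> tuple[float, float]:
    """(parameters in millions, multiply-accumulates in Gmac) for one forward
    pass on a [1, 1, 256] input.

    Parameters are counted from an instantiated model (every trainable
    scalar); MACs count convolutions, linear layers and attention matmuls,
    ignoring normalisation and nonlinearities. 1 MAC = 1 multiply + 1 add.
    """
    model = TSDNet(config, seed=0)
    params = model.n_params()

    d = config.stage_dims
    macs = 0
    if config.stem_two_convs:
        macs += 1 * d[0] * 3 * 128 + d[0] * d[0] * 3 * 64
    else:
        macs += 1 * d[0] * 7 * 64
    for s in range(4):
        c, l = d[s], STAGE_LENGTHS[s]
        if s > 0:
            macs += d[s - 1] * c * 3 * l                # strided downsample
        if s < 2:
            n_msca, n_mhsa = config.stage12_blocks[s], 0
        elif s == 2:
            n_msca, n_mhsa = config.stage3_blocks
        else:
            n_msca, n_mhsa = 0, config.stage4_blocks
        if n_msca:
            kernels = config.head_kernels(config.conv_heads[s])
            macs += n_msca * _msca_macs(c, l, config.conv_heads[s], kernels,
                                        config.expand_ratio, config.mlp_ratio,
                                        config.se_reduction)
        if n_mhsa:
            macs += n_mhsa * _mhsa_macs(c, l, config.mlp_ratio)
    macs += d[3] * STAGE_LENGTHS[3]                     # head linear
    return params / 1e6, macs / 1e9
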
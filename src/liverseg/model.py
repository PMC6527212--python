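"""2D encoder--decoder segmentation network with valid-mode convolutions.

One network per slicing orientation (axial, coronal, sagittal). The shipped
default works on four resolution levels with 3x3 convolutions, 2x2
stride-2 (transposed) convolutions for rescaling, batch normalization and
ReLU after every convolution, long encoder-to-decoder concatenation skips,
short residual skips within each convolution block, and dropout in the
upscaling path. All convolutions are valid-mode, so an input of side N
yields an output of side N − (RF − 1), where RF is the receptive field.

Receptive-field accounting: each 3x3 convolution consumes (k−1)·jump = 2·jump
input pixels of context, where the jump is the input-pixel stride of the
current feature grid; the 2x2 stride-2 rescalers have kernel equal to
stride, tile the grid exactly and consume no context, only scaling the jump
by 2 (down) or 1/2 (up). The default block structure — encoder (2, 3, 2)
convolutions per level, 2 in the bottleneck, decoder (2, 2, 2) — gives
RF = 1 + 2·(2 + 2·3 + 4·2) + 8·2·2 + 2·(4·2 + 2·2 + 2) = 93, matching an
organ-scale context window at 2 mm voxels (~18.6 cm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .imaging_io import VolumeGeometry

ORIENTATIONS = ("axial", "coronal", "sagittal")

_PLANE_CODES = {"axial": frozenset("SI"), "coronal": frozenset("AP"),
                "sagittal": frozenset("RL")}


def orientation_axis(orientation: str, geometry: VolumeGeometry) -> int:
    """Array axis along which ``orientation`` slices are stacked.

    Axial slices are perpendicular to the superior--inferior axis, coronal
    to anterior--posterior, sagittal to left--right.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}; expected one of {ORIENTATIONS}")
    codes = _PLANE_CODES[orientation]
    for axis, code in enumerate(geometry.axcodes):
        if code in codes:
            return axis
    raise ValueError(f"geometry axcodes {geometry.axcodes} do not label a {orientation} axis")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``encoder_convs`` lists the 3x3 convolution count per encoder level
    (length ``levels − 1``); ``decoder_convs`` mirrors it from coarse to
    fine. Feature counts start at ``base_features`` and grow by
    ``feature_growth`` per level.
    """

    levels: int = 4
    encoder_convs: tuple[int, ...] = (2, 3, 2)
    bottleneck_convs: int = 2
    decoder_convs: tuple[int, ...] = (2, 2, 2)
    base_features: int = 32
    feature_growth: float = 2.0
    dropout_rate: float = 0.2
    kernel: int = 3
    target_receptive_field: int | None = 93

    def validate(self) -> None:
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.base_features < 1:
            raise ValueError(f"base_features must be >= 1, got {self.base_features}")
        if len(self.encoder_convs) != self.levels - 1:
            raise ValueError(
                f"encoder_convs must have {self.levels - 1} entries, got {self.encoder_convs}")
        if len(self.decoder_convs) != self.levels - 1:
            raise ValueError(
                f"decoder_convs must have {self.levels - 1} entries, got {self.decoder_convs}")
        if any(c < 1 for c in (*self.encoder_convs, self.bottleneck_convs, *self.decoder_convs)):
            raise ValueError("every block needs at least one convolution")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.kernel != 3:
            raise ValueError("only 3x3 convolutions are supported")
        if (self.target_receptive_field is not None
                and receptive_field(self) != self.target_receptive_field):
            raise ValueError(
                f"configured blocks give receptive field {receptive_field(self)}, "
                f"not the target {self.target_receptive_field}")

    @classmethod
    def small(cls, base_features: int = 8) -> "ModelConfig":
        """Two-level configuration (RF 17) for fast experiments and tests."""
        return cls(levels=2, encoder_convs=(2,), bottleneck_convs=2,
                   decoder_convs=(2,), base_features=base_features,
                   dropout_rate=0.0, target_receptive_field=17)

    def features(self, level: int) -> int:
        return int(round(self.base_features * self.feature_growth ** level))


def receptive_field(config: ModelConfig) -> int:
    """Receptive-field side length of one output pixel.

    Runs the context recursion over the layer sequence: RF grows by
    (k − 1)·jump per 3x3 convolution; the kernel-equals-stride 2x2
    rescalers scale the jump without consuming context (they tile the
    grid exactly, which is also why output size = input − (RF − 1)).
    """
    rf, jump = 1, 1
    for convs in config.encoder_convs:
        rf += (config.kernel - 1) * jump * convs
        jump *= 2
    rf += (config.kernel - 1) * jump * config.bottleneck_convs
    for convs in config.decoder_convs:
        jump //= 2
        rf += (config.kernel - 1) * jump * convs
    return rf


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class _ConvBlock:
    """Block of conv->BN->ReLU layers with a short residual skip.

    The identity path is center-cropped to the block output and projected
    with a 1x1 convolution when channel counts differ; it is added before
    the block's final ReLU.
    """

    def __init__(self, rng, in_ch, out_ch, n_convs):
        self.n_convs = n_convs
        self.convs, self.bns = [], []
        ch = in_ch
        for _ in range(n_convs):
            w = nn.Parameter(_he_init(rng, (out_ch, ch, 3, 3), ch * 9))
            b = nn.Parameter(np.zeros(out_ch))
            self.convs.append((w, b))
            self.bns.append(_BN(out_ch))
            ch = out_ch
        self.proj = None
        if in_ch != out_ch:
            self.proj = nn.Parameter(_he_init(rng, (out_ch, in_ch, 1, 1), in_ch))

    def params(self):
        ps = []
        for (w, b), bn in zip(self.convs, self.bns):
            ps += [w, b, bn.gamma, bn.beta]
        if self.proj is not None:
            ps.append(self.proj)
        return ps

    def forward(self, x, training):
        identity = x
        for i, ((w, b), bn) in enumerate(zip(self.convs, self.bns)):
            x = nn.conv2d(x, w, b)
            x = bn.forward(x, training)
            if i < self.n_convs - 1:
                x = nn.relu(x)
        skip = nn.center_crop(identity, x.data.shape[2:])
        if self.proj is not None:
            skip = nn.conv2d(skip, self.proj, None)
        return nn.relu(x + skip)

    def influence(self, x):
        shrink = 2 * self.n_convs
        out = x
        for (w, _), _bn in zip(self.convs, self.bns):
            out = _infl_conv(out, w.data)
        ident = x[:, :, shrink // 2:x.shape[2] - shrink // 2,
                  shrink // 2:x.shape[3] - shrink // 2]
        return out + ident.sum(axis=1, keepdims=True) * np.ones((1, out.shape[1], 1, 1))


class _BN:
    def __init__(self, ch):
        self.gamma = nn.Parameter(np.ones(ch))
        self.beta = nn.Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x, training):
        return nn.batch_norm(x, self.gamma, self.beta,
                             self.running_mean, self.running_var, training)


def _infl_conv(x, w, stride=1):
    """Influence propagation: convolution with |weights|, no bias."""
    f, c, kh, kw = w.shape
    n, _, h, wd = x.shape
    ho = (h - kh) // stride + 1
    wo = (wd - kw) // stride + 1
    out = np.zeros((n, f, ho, wo))
    aw = np.abs(w) + 1e-12
    for i in range(kh):
        for j in range(kw):
            xs = x[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            out += np.einsum("nchw,fc->nfhw", xs, aw[:, :, i, j], optimize=True)
    return out


class UNet2D:
    """The orientation model: a callable mapping a single-channel 2D patch
    to a per-pixel foreground probability map."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.training = False
        rng = np.random.Generator(np.random.PCG64(seed))
        self._dropout_rng = np.random.Generator(np.random.PCG64((seed, 0xD0)))
        L = config.levels
        feats = [config.features(i) for i in range(L)]

        self.enc_blocks, self.down = [], []
        in_ch = 1
        for lvl in range(L - 1):
            self.enc_blocks.append(_ConvBlock(rng, in_ch, feats[lvl], config.encoder_convs[lvl]))
            w = nn.Parameter(_he_init(rng, (feats[lvl + 1], feats[lvl], 2, 2), feats[lvl] * 4))
            b = nn.Parameter(np.zeros(feats[lvl + 1]))
            self.down.append((w, b, _BN(feats[lvl + 1])))
            in_ch = feats[lvl + 1]
        self.bottleneck = _ConvBlock(rng, feats[L - 1], feats[L - 1], config.bottleneck_convs)

        self.up, self.dec_blocks = [], []
        for lvl in range(L - 2, -1, -1):
            w = nn.Parameter(_he_init(rng, (feats[lvl + 1], feats[lvl], 2, 2), feats[lvl + 1]))
            b = nn.Parameter(np.zeros(feats[lvl]))
            self.up.append((w, b, _BN(feats[lvl])))
            dec_convs = config.decoder_convs[L - 2 - lvl]
            self.dec_blocks.append(_ConvBlock(rng, 2 * feats[lvl], feats[lvl], dec_convs))
        self.head_w = nn.Parameter(_he_init(rng, (2, feats[0], 1, 1), feats[0]))
        self.head_b = nn.Parameter(np.zeros(2))

    # ------------------------------------------------------------------
    def params(self) -> list[nn.Parameter]:
        ps = []
        for blk in self.enc_blocks:
            ps += blk.params()
        for w, b, bn in self.down:
            ps += [w, b, bn.gamma, bn.beta]
        ps += self.bottleneck.params()
        for w, b, bn in self.up:
            ps += [w, b, bn.gamma, bn.beta]
        for blk in self.dec_blocks:
            ps += blk.params()
        ps += [self.head_w, self.head_b]
        return ps

    def train(self, flag: bool = True):
        self.training = flag
        return self

    def eval(self):
        return self.train(False)

    # ------------------------------------------------------------------
    def valid_input_size(self, n: int) -> bool:
        try:
            self.output_size(n)
            return True
        except ValueError:
            return False

    def output_size(self, n: int) -> int:
        """Output side length for input side ``n`` (raises if the size does
        not tile through the stride-2 stages)."""
        cfg = self.config
        for convs in cfg.encoder_convs:
            n -= 2 * convs
            if n < 2 or n % 2:
                raise ValueError(f"input does not tile through the encoder (level size {n})")
            n //= 2
        n -= 2 * cfg.bottleneck_convs
        for convs in cfg.decoder_convs:
            n *= 2
            n -= 2 * convs
        if n < 1:
            raise ValueError("input too small for the network")
        return n

    def next_valid_input(self, n: int) -> int:
        m = n
        while not self.valid_input_size(m):
            m += 1
        return m

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.config)

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        """Map (N, 1, H, W) patches to (N, 2, h, w) class probabilities
        (channel 0 background, channel 1 liver)."""
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        if x.data.ndim != 4 or x.data.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.data.shape}")
        self.output_size(x.data.shape[2])
        self.output_size(x.data.shape[3])

        skips = []
        for blk, (dw, db, dbn) in zip(self.enc_blocks, self.down):
            x = blk.forward(x, self.training)
            skips.append(x)
            x = nn.relu(dbn.forward(nn.conv2d(x, dw, db, stride=2), self.training))
        x = self.bottleneck.forward(x, self.training)
        for (uw, ub, ubn), blk, skip in zip(self.up, self.dec_blocks, reversed(skips)):
            x = nn.relu(ubn.forward(nn.conv_transpose2x2(x, uw, ub), self.training))
            skip = nn.center_crop(skip, x.data.shape[2:])
            x = nn.concat_channels(x, skip)
            x = nn.dropout(x, self.config.dropout_rate, self._dropout_rng, self.training)
            x = blk.forward(x, self.training)
        logits = nn.conv2d(x, self.head_w, self.head_b)
        return nn.softmax_channels(logits)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Inference-mode foreground probabilities for (N, 1, H, W) input."""
        was_training = self.training
        self.training = False
        try:
            return self.forward(patches).data[:, 1]
        finally:
            self.training = was_training

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        return self.predict_proba(patches)

    # -- linearized influence propagation ------------------------------
    def influence(self, x: np.ndarray) -> np.ndarray:
        """Forward pass of the linearized network (bias-free, ReLU and
        batch norm disabled, weights replaced by their magnitudes): output
        is nonzero exactly where the input influences it."""
        x = np.asarray(x, dtype=np.float64)
        skips = []
        for blk, (dw, _, _bn) in zip(self.enc_blocks, self.down):
            x = blk.influence(x)
            skips.append(x)
            x = _infl_conv(x, dw.data, stride=2)
        x = self.bottleneck.influence(x)
        for (uw, _, _bn), blk, skip in zip(self.up, self.dec_blocks, reversed(skips)):
            up = np.zeros((x.shape[0], uw.data.shape[1], 2 * x.shape[2], 2 * x.shape[3]))
            for i in range(2):
                for j in range(2):
                    up[:, :, i::2, j::2] = np.einsum(
                        "nchw,cf->nfhw", x, np.abs(uw.data[:, :, i, j]) + 1e-12, optimize=True)
            th, tw = up.shape[2:]
            oh = (skip.shape[2] - th) // 2
            ow = (skip.shape[3] - tw) // 2
            x = np.concatenate([up, skip[:, :, oh:oh + th, ow:ow + tw]], axis=1)
            x = blk.influence(x)
        return _infl_conv(x, np.abs(self.head_w.data))

    # -- checkpointing --------------------------------------------------
    def _all_bns(self) -> list[_BN]:
        bns = [bn for blk in (*self.enc_blocks, self.bottleneck, *self.dec_blocks)
               for bn in blk.bns]
        bns += [bn for _, _, bn in self.down] + [bn for _, _, bn in self.up]
        return bns

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._all_bns()):
            state[f"bn_mean_{i}"] = bn.running_mean
            state[f"bn_var_{i}"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.data = np.array(state[f"param_{i}"], dtype=np.float64)
        for i, bn in enumerate(self._all_bns()):
            bn.running_mean = np.array(state[f"bn_mean_{i}"])
            bn.running_var = np.array(state[f"bn_var_{i}"])

    def save(self, path: str | Path, provenance: dict | None = None) -> None:
        """Checkpoint to ``<path>.npz`` plus a JSON sidecar with the
        architecture and training provenance."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(str(path.with_suffix(".npz")), **self.state_arrays())
        sidecar = {"model_config": asdict(self.config)}
        if provenance:
            sidecar["provenance"] = provenance
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNet2D":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = dict(sidecar["model_config"])
        for key in ("encoder_convs", "decoder_convs"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(ModelConfig(**cfg_dict))
        with np.load(str(path.with_suffix(".npz"))) as data:
            model.load_state_arrays(dict(data))
        return model


def build_model(config: ModelConfig | None = None, seed: int = 0) -> UNet2D:
    """Construct one orientation model from its configuration."""
    return UNet2D(config or ModelConfig(), seed=seed)


def perturbation_receptive_field(config: ModelConfig, input_size: int | None = None
                                 ) -> tuple[int, np.ndarray]:
    """Measure the receptive field of the built network by single-pixel
    perturbations of a linearized copy (bias-free, ReLU and batch norm
    disabled, weight magnitudes, so influence cannot cancel).

    Influence propagation depends only on the layer structure, so the
    probe uses a single-feature structural clone of ``config`` for speed.
    One input column at a time is perturbed and the influence matrix
    records which output columns change. Because stride-2 stages tie
    neighbouring input pixels together, raw per-output influence windows
    are position dependent; the receptive field is their
    translation-normalized span, ``max_j hi_j − min_j lo_j + 1 − (n_out − 1)``,
    which removes the one-output-pixel shift per input-pixel shift.
    Returns the measured RF and the raw per-output window widths.
    """
    from dataclasses import replace
    probe = UNet2D(replace(config, base_features=1, feature_growth=1.0), seed=0)
    if input_size is None:
        input_size = probe.next_valid_input(2 * receptive_field(config))
    height = probe.next_valid_input(2)

    n_out_w = probe.output_size(input_size)
    base = np.zeros((input_size, 1, height, input_size))
    for p in range(input_size):
        base[p, 0, :, p] = 1.0
    # batch all single-pixel probes through the linearized network
    out = probe.influence(base)
    influence = np.abs(out).sum(axis=(1, 2)) > 1e-9  # (n_in, n_out)

    if not influence.any(axis=1).all():
        raise AssertionError("some input columns influence no output")
    lows = np.array([np.flatnonzero(influence[:, j])[0] for j in range(n_out_w)])
    highs = np.array([np.flatnonzero(influence[:, j])[-1] for j in range(n_out_w)])
    span = highs.max() - lows.min() + 1
    measured = int(span - (n_out_w - 1))
    widths = highs - lows + 1
    return measured, widths
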
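"""Denoising network architectures.

Four compact encoder–decoder families for image-to-image restoration of
fluorescence micrographs:

``unet``
    Conventional U-Net: channel depth doubles after every max-pooling
    step and halves after every up-sampling step; long skip connections
    concatenate encoder feature maps into the decoder.
``unet_fixed``
    Same topology, but every feature map holds ``base_channels``
    channels.  This is one of the two optimized architectures; fixing
    the channel depth shrinks the model by more than an order of
    magnitude at equal accuracy.
``hourglass_wores``
    Hourglass variant: skip connections pass through trainable side
    blocks and are merged by summation instead of concatenation;
    channel depth doubles with depth; no short residuals.
``hourglass_wres``
    Fixed-channel hourglass with identity (short-range) residual
    connections inside every convolutional block.  Summation residuals
    require equal input/output channel counts, hence fixed channels.

All families share one calibrated layer table: a 3x3 stem convolution,
``levels`` encoder stages of ``blocks_per_level`` two-convolution
blocks, ``bottleneck_blocks`` blocks at the bottom, a mirrored decoder
(nearest-neighbour upsampling followed by a 1x1 mixing convolution),
and a head of two 1x1 convolutions plus a linear 3x3 output layer.
At the defaults (4 levels, 32 channels, 6 blocks per level, 3
bottleneck blocks, 3x3 kernels, 2D mode) the table yields 987,105
trainable parameters for ``unet_fixed`` and 958,689 for
``hourglass_wres`` — 3.77 MB and 3.66 MB at 4 bytes per parameter.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import Conv, Pool2, Upsample2

FAMILIES = ("unet", "unet_fixed", "hourglass_wores", "hourglass_wres")
_FIXED_BY_DEFAULT = {"unet": False, "unet_fixed": True,
                     "hourglass_wores": False, "hourglass_wres": True}


@dataclass
class ArchitectureSpec:
    """Declarative description of a denoising network.

    Parameters
    ----------
    family : str
        One of ``unet``, ``unet_fixed``, ``hourglass_wores``,
        ``hourglass_wres``.
    levels : int
        Number of max-pooling (and up-sampling) stages.
    base_channels : int
        Channels of the first feature map (and of all feature maps when
        ``fixed_channels``).
    kernel : int
        Side of the square (or cubic) convolution kernels, 3 or 5.
    mode : str
        ``2d`` (plane to plane), ``2p5d`` (a stack of ``2*context_d+1``
        planes in, the centre plane out) or ``3d`` (a ``context_d``-deep
        chunk in and out, 3D convolutions).
    context_d : int
        The z-context parameter *d*; ignored in 2d mode.
    """

    family: str = "unet_fixed"
    levels: int = 4
    base_channels: int = 32
    fixed_channels: bool | None = None
    kernel: int = 3
    mode: str = "2d"
    context_d: int = 0
    convs_per_block: int = 2
    blocks_per_level: int = 6
    bottleneck_blocks: int = 3

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported architecture family {self.family!r}")
        if self.fixed_channels is None:
            self.fixed_channels = _FIXED_BY_DEFAULT[self.family]
        if self.family == "hourglass_wres" and not self.fixed_channels:
            raise ValueError(
                "hourglass_wres requires fixed_channels: summing a block's "
                "input into its output needs equal feature depths")
        if self.kernel not in (3, 5):
            raise ValueError("kernel must be 3 or 5")
        if self.mode not in ("2d", "2p5d", "3d"):
            raise ValueError("mode must be one of 2d, 2p5d, 3d")
        if self.mode != "2d" and self.context_d < 1:
            raise ValueError(f"mode {self.mode} requires context_d >= 1")

    @property
    def in_channels(self) -> int:
        return 2 * self.context_d + 1 if self.mode == "2p5d" else 1

    @property
    def out_channels(self) -> int:
        return 1

    def channels(self, level: int) -> int:
        """Feature-map depth at pyramid depth ``level`` (0 = full res)."""
        if self.fixed_channels:
            return self.base_channels
        return self.base_channels * 2 ** level


class _Block:
    """``convs_per_block`` convolutions with ReLU, optional identity skip.

    Plain blocks are conv+ReLU chains.  Residual blocks use the classic
    form ``relu(x + F(x))`` with a linear final convolution in the
    branch, which keeps activation means bounded over long stacks of
    blocks; the parameter count is identical either way.
    """

    def __init__(self, c_in, c_out, kernel, ndim, n_convs, residual):
        self.residual = residual
        self.convs = [Conv(c_in if i == 0 else c_out, c_out, kernel,
                           ndim=ndim,
                           relu=not (residual and i == n_convs - 1))
                      for i in range(n_convs)]
        self._cache = None

    def forward(self, x, train=False):
        h = x
        for conv in self.convs:
            h = conv.forward(h, train)
        if not self.residual:
            return h
        out = np.maximum(h + x, 0.0)
        if train:
            self._cache = out
        return out

    def backward(self, dy):
        if self.residual:
            dy = dy * (self._cache > 0)
            self._cache = None
        dh = dy
        for conv in reversed(self.convs):
            dh = conv.backward(dh)
        return dh + dy if self.residual else dh


class Network:
    """Executable encoder–decoder assembled from an ArchitectureSpec."""

    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        s = spec
        ndim = 3 if s.mode == "3d" else 2
        self.ndim = ndim
        k = (min(3, s.kernel), s.kernel, s.kernel) if ndim == 3 else s.kernel
        is_unet = s.family.startswith("unet")
        residual = s.family == "hourglass_wres"
        ch = s.channels

        self.stem = Conv(s.in_channels, ch(0), k, ndim=ndim, relu=True)
        self.enc = []
        for lev in range(s.levels):
            blocks = []
            for b in range(s.blocks_per_level):
                c_in = ch(lev - 1) if (b == 0 and lev > 0) else ch(lev)
                blocks.append(_Block(c_in, ch(lev), k, ndim,
                                     s.convs_per_block,
                                     residual and c_in == ch(lev)))
            self.enc.append(blocks)
        self.pool = Pool2()
        L = s.levels
        self.bottleneck = []
        for b in range(s.bottleneck_blocks):
            c_in = ch(L - 1) if b == 0 else ch(L)
            self.bottleneck.append(_Block(c_in, ch(L), k, ndim,
                                          s.convs_per_block,
                                          residual and c_in == ch(L)))
        self.upsample = Upsample2()
        self.up_mix = [Conv(ch(lev + 1), ch(lev), 1, ndim=ndim, relu=True)
                       for lev in range(L)]
        if is_unet:
            self.side = None
        else:
            self.side = [[Conv(ch(lev), ch(lev), 1, ndim=ndim, relu=True)
                          for _ in range(2)] for lev in range(L)]
        self.dec = []
        for lev in range(L):
            blocks = []
            for b in range(s.blocks_per_level):
                c_in = 2 * ch(lev) if (b == 0 and is_unet) else ch(lev)
                blocks.append(_Block(c_in, ch(lev), k, ndim,
                                     s.convs_per_block,
                                     residual and c_in == ch(lev)))
            self.dec.append(blocks)
        self.head = [Conv(ch(0), ch(0), 1, ndim=ndim, relu=True)
                     for _ in range(2)]
        self.final = Conv(ch(0), s.out_channels, k, ndim=ndim, relu=False)
        self._is_unet = is_unet

    # -- parameter plumbing -------------------------------------------------
    def _convs(self):
        yield self.stem
        for blocks in self.enc:
            for blk in blocks:
                yield from blk.convs
        for blk in self.bottleneck:
            yield from blk.convs
        for lev in range(self.spec.levels):
            yield self.up_mix[lev]
            if self.side is not None:
                yield from self.side[lev]
            for blk in self.dec[lev]:
                yield from blk.convs
        yield from self.head
        yield self.final

    def params(self):
        out = []
        for conv in self._convs():
            out.extend(conv.params())
        return out

    def grads(self):
        out = []
        for conv in self._convs():
            out.extend(conv.grads())
        return out

    def n_params(self) -> int:
        return sum(conv.n_params for conv in self._convs())

    def init(self, rng: np.random.Generator) -> None:
        for conv in self._convs():
            conv.init(rng)
        # residual blocks: damp the branch at init so the summed variance
        # stays bounded across the many stacked blocks
        for blk in self._blocks():
            if blk.residual:
                blk.convs[-1].w *= 0.1

    def _blocks(self):
        for blocks in self.enc:
            yield from blocks
        yield from self.bottleneck
        for blocks in self.dec:
            yield from blocks

    # -- execution ----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        L = self.spec.levels
        pools = [Pool2() for _ in range(L)]
        self._pool_stack = pools
        h = self.stem.forward(x, train)
        skips = []
        for lev in range(L):
            for blk in self.enc[lev]:
                h = blk.forward(h, train)
            skips.append(h)
            h = pools[lev].forward(h, train)
        for blk in self.bottleneck:
            h = blk.forward(h, train)
        for lev in range(L - 1, -1, -1):
            h = self.upsample.forward(h, train)
            h = self.up_mix[lev].forward(h, train)
            if self._is_unet:
                h = np.concatenate([h, skips[lev]], axis=-1)
            else:
                side = skips[lev]
                for conv in self.side[lev]:
                    side = conv.forward(side, train)
                h = h + side
            for blk in self.dec[lev]:
                h = blk.forward(h, train)
        for conv in self.head:
            h = conv.forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate; call directly after ``forward(..., train=True)``."""
        L = self.spec.levels
        dh = self.final.backward(dy)
        for conv in reversed(self.head):
            dh = conv.backward(dh)
        dskips = [None] * L
        for lev in range(L):  # reverse of decoder execution order
            for blk in reversed(self.dec[lev]):
                dh = blk.backward(dh)
            if self._is_unet:
                c = self.spec.channels(lev)
                dh, dskip = dh[..., :c], dh[..., c:]
            else:
                dskip = dh
                for conv in reversed(self.side[lev]):
                    dskip = conv.backward(dskip)
            dskips[lev] = dskip
            dh = self.up_mix[lev].backward(dh)
            dh = self.upsample.backward(dh)
        for blk in reversed(self.bottleneck):
            dh = blk.backward(dh)
        for lev in range(L - 1, -1, -1):
            dh = self._pool_stack[lev].backward(dh)
            dh = dh + dskips[lev]
            for blk in reversed(self.enc[lev]):
                dh = blk.backward(dh)
        return self.stem.backward(dh)


@dataclass
class ModelHandle:
    """A built (and possibly trained) network plus its provenance."""

    spec: ArchitectureSpec
    net: Network
    trained: bool = False
    provenance: dict = field(default_factory=dict)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> ModelHandle:
    """Instantiate a network with seeded fan-in uniform initialization."""
    net = Network(spec)
    net.init(np.random.default_rng(seed))
    return ModelHandle(spec=spec, net=net, trained=False,
                       provenance={"seed": int(seed)})


def count_parameters(model: ModelHandle) -> int:
    """Number of trainable parameters (a pure function of the spec)."""
    return model.net.n_params()


def model_size_mb(model: ModelHandle) -> float:
    """Model size in MB at 4 bytes/parameter, rounded to 2 decimals."""
    return round(count_parameters(model) * 4 / 2 ** 20, 2)


def _pad_to_multiple(x: np.ndarray, mult: int, ndim: int):
    """Reflect-pad the H and W axes (the two before C) to multiples."""
    spatial_axes = [x.ndim - 3, x.ndim - 2]
    pads = [(0, 0)] * x.ndim
    crops = []
    for ax in spatial_axes:
        size = x.shape[ax]
        target = -(-size // mult) * mult
        pads[ax] = (0, target - size)
        crops.append((ax, size))
    if any(p != (0, 0) for p in pads):
        x = np.pad(x, pads, mode="reflect")
    return x, crops


def forward(model: ModelHandle, batch: np.ndarray) -> np.ndarray:
    """Run inference on a channels-last batch.

    2d/2p5d: batch ``(N, H, W, C_in)``; 3d: ``(N, D, H, W, 1)``.  H and W
    are reflect-padded up to a multiple of ``2**levels`` and the output
    cropped back, so arbitrary plane sizes are accepted.
    """
    s = model.spec
    if batch.ndim != (5 if s.mode == "3d" else 4):
        raise ValueError(f"batch rank {batch.ndim} does not match mode {s.mode}")
    if batch.shape[-1] != s.in_channels:
        raise ValueError(
            f"mode {s.mode} (context_d={s.context_d}) expects "
            f"{s.in_channels} input channels, got {batch.shape[-1]}")
    mult = 2 ** s.levels
    x = batch.astype(np.float32, copy=False)
    xp, crops = _pad_to_multiple(x, mult, model.net.ndim)
    y = model.net.forward(xp, train=False)
    (ax_h, h), (ax_w, w) = crops
    sl = [slice(None)] * y.ndim
    sl[ax_h] = slice(0, h)
    sl[ax_w] = slice(0, w)
    return y[tuple(sl)]


# ---------------------------------------------------------------------------
# checkpoints: a single zip archive with the spec as JSON text + tensors
# ---------------------------------------------------------------------------

def save_checkpoint(model: ModelHandle, path) -> None:
    path = Path(path)
    params = model.net.params()
    buf = io.BytesIO()
    np.savez(buf, **{f"p{i}": p for i, p in enumerate(params)})
    meta = {"spec": asdict(model.spec), "trained": model.trained,
            "provenance": model.provenance, "n_arrays": len(params)}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("spec.json", json.dumps(meta, indent=1))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path) -> ModelHandle:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("spec.json"))
        npz = np.load(io.BytesIO(zf.read("params.npz")))
        arrays = [npz[f"p{i}"] for i in range(meta["n_arrays"])]
    spec = ArchitectureSpec(**meta["spec"])
    net = Network(spec)
    params = net.params()
    if len(params) != len(arrays):
        raise ValueError("checkpoint does not match architecture")
    for p, a in zip(params, arrays):
        p[...] = a
    return ModelHandle(spec=spec, net=net, trained=meta["trained"],
                       provenance=meta.get("provenance", {}))
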
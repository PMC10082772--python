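"""Light-weight depth-2 U-Net family for blind-spot denoising.

The architecture is deliberately small so that inference fits inside a
streaming reconstruction pipeline: two down/upsampling steps, ``n`` filters in
the uppermost level doubling per level (``4n`` at the bottleneck), 2x2/stride-2
max pooling down and transposed convolution up.  Two switches ablate the
connections known to cause high-frequency checkerboard artifacts in blind-spot
U-Nets: ``residual`` (global input-to-output addition) and ``top_skip`` (the
uppermost encoder-decoder concatenation).  The lower skip connection is always
present.

Every 3x3 convolution is size preserving and followed by batch normalization
and ReLU; the bottleneck holds a single such block so that the theoretical
receptive field (36x36) stays inside the 41x41 budget covered by 20 A-scans of
lateral padding in the deployment pipeline.  The output head is a linear 1x1
projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam  # noqa: F401  (re-export convenience for training code)
from .nn.layers import (F16, F32, BatchNorm2d, Conv2d, ConvTranspose2d, Layer,
                        MaxPool2d, ReLU)


@dataclass
class NetSpec:
    """Architecture configuration of the U-Net family.

    ``n`` is the number of filters in the uppermost level; level ``l`` has
    ``n * 2**l`` channels.  ``residual``/``top_skip`` select the U-Net variant
    (True/True is the classic U-Net; False/False the artifact-suppressing one).
    """

    n: int = 4
    residual: bool = False
    top_skip: bool = False
    depth: int = 2
    convs_per_level: int = 2
    bottleneck_convs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.depth != 2:
            raise ValueError("only depth 2 is supported")
        if self.convs_per_level < 1 or self.bottleneck_convs < 1:
            raise ValueError("conv counts must be >= 1")

    def channels(self) -> tuple[int, int, int]:
        """Encoder-side channel widths per level (top, middle, bottleneck)."""
        return (self.n, 2 * self.n, 4 * self.n)


class _ConvBlock:
    """Conv -> BatchNorm -> ReLU, the fused unit of the deployed network."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.conv = Conv2d(cin, cout, 3, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.relu = ReLU()

    def layers(self) -> list[Layer]:
        return [self.conv, self.bn, self.relu]

    def forward(self, x, train=False):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.relu.backward(g)))

    def forward_inference(self, x, half=False):
        scale, shift = self.bn.fold()
        return self.relu.forward_inference(
            self.conv.forward_inference(x, scale=scale, shift=shift, half=half))


class UNet:
    """Depth-2 U-Net with switchable residual and top-level skip connections.

    ``in_channels``/``out_channels``/``width_mult`` support the pseudo-batch
    export, where an independent copy of the single-channel network runs in
    each of ``k`` channels.
    """

    def __init__(self, spec: NetSpec, in_channels: int = 1, out_channels: int = 1,
                 width_mult: int = 1) -> None:
        self.spec = spec
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.width_mult = width_mult
        k = width_mult
        n1, n2, n3 = (c * k for c in spec.channels())
        rng = np.random.default_rng(spec.seed)

        def blocks(cin, cout, count):
            blks = [_ConvBlock(cin, cout, rng)]
            for _ in range(count - 1):
                blks.append(_ConvBlock(cout, cout, rng))
            return blks

        self.enc1 = blocks(in_channels, n1, spec.convs_per_level)
        self.pool1 = MaxPool2d()
        self.enc2 = blocks(n1, n2, spec.convs_per_level)
        self.pool2 = MaxPool2d()
        self.bottleneck = blocks(n2, n3, spec.bottleneck_convs)
        self.up1 = ConvTranspose2d(n3, n2, rng=rng)
        self.dec2 = blocks(2 * n2, n2, spec.convs_per_level)
        self.up2 = ConvTranspose2d(n2, n1, rng=rng)
        dec1_in = 2 * n1 if spec.top_skip else n1
        self.dec1 = blocks(dec1_in, n1, spec.convs_per_level)
        self.head = Conv2d(n1, out_channels, 1, rng=rng)
        self._s1_channels = n1
        self._s2_channels = n2

    # -- plumbing ---------------------------------------------------------

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in self.enc1 + self.enc2 + self.bottleneck + self.dec2 + self.dec1:
            out.extend(blk.layers())
        out.extend([self.pool1, self.pool2, self.up1, self.up2, self.head])
        return out

    def conv_layers(self) -> list[Layer]:
        return [l for l in self.layers() if isinstance(l, (Conv2d, ConvTranspose2d))]

    def zero_grad(self) -> None:
        for lyr in self.layers():
            lyr.zero_grad()

    def state_dict(self) -> dict:
        state = {}
        for i, lyr in enumerate(self.layers()):
            for name, p in lyr.params.items():
                state[f"{i}.{name}"] = p.copy()
            for name, b in lyr.buffers.items():
                state[f"{i}.buf.{name}"] = b.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, lyr in enumerate(self.layers()):
            for name in lyr.params:
                lyr.params[name][...] = state[f"{i}.{name}"]
            for name in lyr.buffers:
                lyr.buffers[name][...] = state[f"{i}.buf.{name}"]

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected NCHW input with {self.in_channels} channels, "
                             f"got shape {x.shape}")
        h, w = x.shape[2:]
        if h % 4 or w % 4:
            raise ValueError(
                f"spatial dims must be divisible by 4 (two 2x poolings); got "
                f"{h}x{w} — pad to {-(-h // 4) * 4}x{-(-w // 4) * 4} first")

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=F32)
        a = x
        for blk in self.enc1:
            a = blk.forward(a, train)
        s1 = a
        a = self.pool1.forward(a, train)
        for blk in self.enc2:
            a = blk.forward(a, train)
        s2 = a
        a = self.pool2.forward(a, train)
        for blk in self.bottleneck:
            a = blk.forward(a, train)
        a = self.up1.forward(a, train)
        a = np.concatenate([a, s2], axis=1)
        for blk in self.dec2:
            a = blk.forward(a, train)
        a = self.up2.forward(a, train)
        if self.spec.top_skip:
            a = np.concatenate([a, s1], axis=1)
        for blk in self.dec1:
            a = blk.forward(a, train)
        out = self.head.forward(a, train)
        if self.spec.residual:
            out = out + x
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = np.ascontiguousarray(g, dtype=F32)
        g_res = g if self.spec.residual else None
        a = self.head.backward(g)
        for blk in reversed(self.dec1):
            a = blk.backward(a)
        if self.spec.top_skip:
            a, g_s1 = a[:, :self._s1_channels], a[:, self._s1_channels:]
        else:
            g_s1 = None
        a = self.up2.backward(a)
        for blk in reversed(self.dec2):
            a = blk.backward(a)
        a, g_s2 = a[:, :self._s2_channels], a[:, self._s2_channels:]
        a = self.up1.backward(a)
        for blk in reversed(self.bottleneck):
            a = blk.backward(a)
        a = self.pool2.backward(a)
        a = a + g_s2
        for blk in reversed(self.enc2):
            a = blk.backward(a)
        a = self.pool1.backward(a)
        if g_s1 is not None:
            a = a + g_s1
        for blk in reversed(self.enc1):
            a = blk.backward(a)
        dx = a
        if g_res is not None:
            dx = dx + g_res
        return dx

    def forward_inference(self, x: np.ndarray, half: bool = False) -> np.ndarray:
        """Deployment-style forward: frozen BN folded into convs; optional fp16.

        In half mode weights and activations are stored as float16 (float32
        accumulation inside each fused block), emulating fused half-precision
        inference; the result is returned as float32.
        """
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=F16 if half else F32)
        a = x
        for blk in self.enc1:
            a = blk.forward_inference(a, half)
        s1 = a
        a = self.pool1.forward_inference(a, half)
        for blk in self.enc2:
            a = blk.forward_inference(a, half)
        s2 = a
        a = self.pool2.forward_inference(a, half)
        for blk in self.bottleneck:
            a = blk.forward_inference(a, half)
        a = self.up1.forward_inference(a, half)
        a = np.concatenate([a, s2], axis=1)
        for blk in self.dec2:
            a = blk.forward_inference(a, half)
        a = self.up2.forward_inference(a, half)
        if self.spec.top_skip:
            a = np.concatenate([a, s1], axis=1)
        for blk in self.dec1:
            a = blk.forward_inference(a, half)
        out = self.head.forward_inference(a, half=half)
        if self.spec.residual:
            out = out + x
        return out.astype(F32)

    # -- derived quantities ----------------------------------------------

    def receptive_field(self) -> tuple[int, int]:
        """Theoretical receptive-field extent (axial, lateral) of one output px."""
        r, j = 1, 1
        for _ in range(self.spec.convs_per_level):
            r += 2 * j
        r += j; j *= 2                       # pool1
        for _ in range(self.spec.convs_per_level):
            r += 2 * j
        r += j; j *= 2                       # pool2
        for _ in range(self.spec.bottleneck_convs):
            r += 2 * j
        j //= 2                              # up1 (kernel 2 = stride: no growth)
        for _ in range(self.spec.convs_per_level):
            r += 2 * j
        j //= 2                              # up2
        for _ in range(self.spec.convs_per_level):
            r += 2 * j
        return (r, r)


def build_unet(spec: NetSpec) -> UNet:
    """Construct a single-channel U-Net from its architecture spec."""
    return UNet(spec)


def measure_receptive_field(model, size: int = 64, max_size: int = 1024,
                            n_draws: int = 5) -> tuple[int, int]:
    """Empirical receptive field of one central output pixel.

    Backpropagates a unit gradient from the central output pixel to the input
    and returns the bounding-box extents of the nonzero-gradient footprint,
    maximized over ``n_draws`` random re-initializations (ReLU gating can hide
    parts of the footprint for a single draw).  The probe image is grown until
    the footprint is clear of the borders.
    """
    spec = getattr(model, "spec", None)
    while size <= max_size:
        best = (0, 0)
        ok = True
        for draw in range(n_draws):
            if spec is not None:
                probe = type(model)(type(spec)(**{**spec.__dict__, "seed": spec.seed + draw}),
                                    in_channels=model.in_channels,
                                    out_channels=model.out_channels,
                                    width_mult=model.width_mult)
            elif draw == 0:
                probe = model
            else:
                break
            x = np.full((1, getattr(probe, "in_channels", 1), size, size), 0.5, dtype=F32)
            y = probe.forward(x, train=False)
            g = np.zeros_like(y)
            g[0, 0, y.shape[2] // 2, y.shape[3] // 2] = 1.0
            dx = probe.backward(g)
            hit = np.abs(dx[0]).max(axis=0) > 0
            rows = np.flatnonzero(hit.any(axis=1))
            cols = np.flatnonzero(hit.any(axis=0))
            if rows.size == 0:
                continue
            if (rows[0] == 0 or cols[0] == 0 or rows[-1] == size - 1
                    or cols[-1] == size - 1):
                ok = False
                break
            best = (max(best[0], rows[-1] - rows[0] + 1),
                    max(best[1], cols[-1] - cols[0] + 1))
        if ok and best != (0, 0):
            return best
        size *= 2
    raise ValueError("receptive-field footprint touches the probe border even at "
                     f"{max_size} px; increase max_size")


def export_pseudobatch(model: UNet, channels: int = 4) -> UNet:
    """Replicate a 1-channel model into ``channels`` independent channels.

    Weights are copied into block-diagonal form so that every entry coupling
    channel group i to group j != i is exactly zero; batch-norm statistics are
    frozen (the exported model is inference-only), so output channel i equals
    the single-channel model applied to input channel i.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    if model.in_channels != 1 or model.out_channels != 1:
        raise ValueError("pseudo-batch export expects a 1-in/1-out model")
    k = channels
    out = UNet(model.spec, in_channels=k, out_channels=k, width_mult=k)
    n1 = model.spec.n

    def expand_conv(src: Conv2d, dst: Conv2d, segments: list[int]) -> None:
        """Block-diagonal weight expansion honouring concatenation layout.

        ``segments`` are the input-channel segment sizes of the *single* model
        (e.g. [2n, 2n] after a skip concatenation): in the k-channel model each
        segment appears as k contiguous groups, so source channel c of group g
        inside segment s lives at offset k*(segment start) + g*len(s) + c.
        """
        dst.params["W"][...] = 0.0
        co, ci = src.cout, src.cin
        starts = np.cumsum([0] + segments[:-1])
        for g in range(k):
            col = []
            for s_start, s_len in zip(starts, segments):
                col.extend(range(k * s_start + g * s_len,
                                 k * s_start + g * s_len + s_len))
            dst.params["W"][g * co:(g + 1) * co, col] = src.params["W"]
            dst.params["b"][g * co:(g + 1) * co] = src.params["b"]

    def expand_upconv(src: ConvTranspose2d, dst: ConvTranspose2d) -> None:
        dst.params["W"][...] = 0.0
        ci, co = src.cin, src.cout
        for g in range(k):
            dst.params["W"][g * ci:(g + 1) * ci, g * co:(g + 1) * co] = src.params["W"]
            dst.params["b"][g * co:(g + 1) * co] = src.params["b"]

    def expand_bn(src: BatchNorm2d, dst: BatchNorm2d) -> None:
        for name in ("gamma", "beta"):
            dst.params[name][...] = np.tile(src.params[name], k)
        for name in ("running_mean", "running_var"):
            dst.buffers[name][...] = np.tile(src.buffers[name], k)

    def expand_blocks(src_blocks, dst_blocks, first_segments) -> None:
        for i, (sb, db) in enumerate(zip(src_blocks, dst_blocks)):
            segs = first_segments if i == 0 else [sb.conv.cin]
            expand_conv(sb.conv, db.conv, segs)
            expand_bn(sb.bn, db.bn)

    expand_blocks(model.enc1, out.enc1, [1])
    expand_blocks(model.enc2, out.enc2, [n1])
    expand_blocks(model.bottleneck, out.bottleneck, [2 * n1])
    expand_upconv(model.up1, out.up1)
    expand_blocks(model.dec2, out.dec2, [2 * n1, 2 * n1])
    expand_upconv(model.up2, out.up2)
    if model.spec.top_skip:
        expand_blocks(model.dec1, out.dec1, [n1, n1])
    else:
        expand_blocks(model.dec1, out.dec1, [n1])
    expand_conv(model.head, out.head, [n1])
    return out


def copy_model(model: UNet) -> UNet:
    clone = UNet(model.spec, model.in_channels, model.out_channels, model.width_mult)
    clone.load_state_dict(model.state_dict())
    return clone


def predict_image(model: UNet, image: np.ndarray, half: bool = False) -> np.ndarray:
    """Denoise one 2D image with a 1-channel model (deployment-style forward).

    Images whose sides are not divisible by 4 are edge-replicated up to the
    next multiple and cropped back after inference.
    """
    img = np.asarray(image, dtype=F32)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    h, w = img.shape
    ph, pw = (-h) % 4, (-w) % 4
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    out = model.forward_inference(img[None, None], half=half)[0, 0]
    return out[:h, :w]


def save_checkpoint(path, model: UNet, history=None, best_epoch=None) -> None:
    """Save spec + weights (+ optional training history) into one .npz file."""
    import json

    arrays = {f"w:{k}": v for k, v in model.state_dict().items()}
    meta = {"spec": model.spec.__dict__,
            "best_epoch": best_epoch,
            "history": history if history is not None else []}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns (model, history, best_epoch)."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = NetSpec(**meta["spec"])
        model = UNet(spec)
        state = {k[2:]: data[k] for k in data.files if k.startswith("w:")}
    model.load_state_dict(state)
    return model, meta["history"], meta["best_epoch"]
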
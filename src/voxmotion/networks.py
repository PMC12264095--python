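"""The five 2D-to-3D registration architectures and their layer grammar.

Every variant shares the same grammar: one or more residual encoding arms
reduce the 2D (or 3D) inputs to a k x 1 (x 1) latent; the latent is
reshaped to k x 1 x 1 x 1 and a residual 3D decoding arm expands it to a
3-channel stationary velocity field at the output grid; scaling-and-
squaring integration layers then produce the predicted DVF, which is
diffeomorphic whenever the velocity stays in the smooth regime.

Encoder residual blocks convolve with a 4x4 kernel (stride 2, padding 1),
then a 3x3 kernel (stride 1, padding 1) with batch normalisation; block
output channels double the block input channels, and the number of blocks
is determined intrinsically by image size (log2 of the input width, so 7
blocks for 128 x 128 inputs).  Decoder blocks mirror this with 4x4x4
transpose convolutions and 3x3x3 convolutions; two additional 3x3x3
convolutions at the output size produce the 3-channel field, with Tanh on
the penultimate layer and a linear final layer.  All other layers use
ReLU; convolutions carry no bias where batch normalisation follows.

Channel schedule calibration
----------------------------
The per-layer widths are not fully specified in prose, so they are pinned
against the published trainable-parameter totals, which act as an
architecture checksum.  The doubling rule applied to the raw input channel
count, together with a decoder that halves the concatenated latent width
per block and finishes its last block at 3 channels, reproduces every
published total exactly; the single-encoder variant A (which has no latent
concatenation to merge) keeps its latent width through the first decoder
block and halves thereafter.  At 128-input / 128^3-output this yields

=========  ==========  ==================
variant    encoders    trainable params
=========  ==========  ==================
A          1 x 2-ch    10,836,973
B          2 x 1-ch     4,130,925
C          2D + 3D      5,048,373
D          2 x 2-ch    16,516,901
E          4 x 2-ch    19,489,717
=========  ==========  ==================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor
from .fields import DisplacementField, Grid3, Volume3D

__all__ = [
    "NetworkSpec",
    "NetworkInputs",
    "Network",
    "build_network",
    "count_parameters",
    "predict_dvf",
    "encoder_channels",
    "decoder_channels",
    "save_network",
    "load_network",
    "summary",
]

ARCHITECTURES = ("A", "B", "C", "D", "E")
#: number of 2D encoding arms and their input channels, per variant
ENCODER_LAYOUT = {
    "A": [2],          # early fusion of (x_alpha, y_alpha)
    "B": [1, 1],       # separate acquired / reference encoders
    "C": [1],          # acquired projection; plus one 3D encoder (reference volume)
    "D": [2, 2],       # {x_c, x_s} and {y_c, y_s} pairs
    "E": [2, 2, 2, 2]  # real coronal, real sagittal, imag coronal, imag sagittal pairs
}
MODALITY = {"A": "xray", "B": "xray", "C": "xray", "D": "mri", "E": "kspace"}


def _log2(n: int, what: str) -> int:
    k = int(round(math.log2(n)))
    if 2**k != n:
        raise ValueError(f"{what} must be a power of two, got {n}")
    return k


@dataclass
class NetworkSpec:
    """Declarative description of one registration network.

    ``base_channels`` defaults to twice the encoder input channel count
    (the calibrated schedule); it can be overridden for scaled-down
    experiments.  ``velocity_scale_mm`` multiplies the network's final
    (Tanh-bounded then linear) output to express the velocity in mm;
    the default is a quarter of the mean output-grid extent.
    """

    architecture: str
    input_size: int = 128
    output_grid: Grid3 = dc_field(default_factory=lambda: Grid3((128, 128, 128), (4.0, 2.0, 4.0)))
    base_channels: int | None = None
    integration_steps: int = 10
    velocity_scale_mm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        _log2(self.input_size, "input image size")
        if len(set(self.output_grid.shape)) != 1:
            raise ValueError("output grid must be cubic")
        _log2(self.output_grid.shape[0], "output grid size")
        if self.integration_steps < 1:
            raise ValueError("integration_steps must be >= 1")

    @property
    def encoder_depth(self) -> int:
        """Number of residual blocks per encoding arm (log2 of input size)."""
        return _log2(self.input_size, "input image size")

    @property
    def decoder_depth(self) -> int:
        return _log2(self.output_grid.shape[0], "output grid size")

    @property
    def modality(self) -> str:
        return MODALITY[self.architecture]

    def velocity_scale(self) -> float:
        if self.velocity_scale_mm is not None:
            return float(self.velocity_scale_mm)
        return 0.25 * float(np.mean(self.output_grid.extent_mm))


def encoder_channels(cin: int, depth: int, base: int | None = None) -> list[int]:
    """Per-block output channels: double the input count every block."""
    b0 = base if base is not None else 2 * cin
    return [b0 * 2**i for i in range(depth)]


def decoder_channels(architecture: str, latent: int, depth: int) -> list[int]:
    """Per-block decoder output channels.

    Multi-encoder variants halve the concatenated latent each block and pin
    the last block at 3 channels; variant A keeps its (unconcatenated)
    latent width through the first block and halves thereafter.
    """
    if architecture == "A":
        return [latent >> i for i in range(depth)]
    return [latent >> (i + 1) for i in range(depth - 1)] + [3]


@dataclass
class NetworkInputs:
    """Variant-tagged 2D (and optional 3D) input payload.

    ``planes`` is a list of arrays, one per encoding arm, each of shape
    (C, H, W) matching :data:`ENCODER_LAYOUT`; ``volume`` carries the
    reference 3D image for variant C.
    """

    architecture: str
    planes: list[np.ndarray]
    volume: np.ndarray | None = None

    def __post_init__(self) -> None:
        layout = ENCODER_LAYOUT[self.architecture]
        if len(self.planes) != len(layout):
            raise ValueError(
                f"variant {self.architecture} expects {len(layout)} plane groups, got {len(self.planes)}"
            )
        for arr, c in zip(self.planes, layout):
            if arr.ndim != 3 or arr.shape[0] != c:
                raise ValueError(f"variant {self.architecture} expects (C={c}, H, W) planes, got {arr.shape}")
        if (self.architecture == "C") != (self.volume is not None):
            raise ValueError("a reference volume is required exactly for variant C")


class _ResBlock(Module):
    """down/up conv + 3^k conv with batch norm, residual over the inner conv.

    Decoder (transpose) blocks use edge-replicate padding on the inner
    convolution so the velocity field stays smooth up to the grid boundary.
    """

    def __init__(self, nd: int, cin: int, cout: int, transpose: bool, rng: np.random.Generator):
        if transpose:
            self.main = ad.ConvTransposeNd(nd, cin, cout, 4, 2, 1, rng)
        else:
            self.main = ad.ConvNd(nd, cin, cout, 4, 2, 1, rng)
        self.inner = ad.ConvNd(nd, cout, cout, 3, 1, 1, rng, pad_mode="edge" if transpose else "zeros")
        self.bn = ad.BatchNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.main(x))
        r = self.bn(self.inner(h))
        return ad.relu(ad.add(h, r))


class _Encoder(Module):
    def __init__(self, nd: int, cin: int, channels: list[int], rng: np.random.Generator):
        self.blocks = []
        a = cin
        for b in channels:
            self.blocks.append(_ResBlock(nd, a, b, transpose=False, rng=rng))
            a = b

    def __call__(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return x


class _Decoder(Module):
    def __init__(self, latent: int, channels: list[int], rng: np.random.Generator):
        self.blocks = []
        a = latent
        for b in channels:
            self.blocks.append(_ResBlock(3, a, b, transpose=True, rng=rng))
            a = b
        self.penultimate = ad.ConvBias(3, a, 3, 3, 1, 1, rng, pad_mode="edge")
        self.final = ad.ConvBias(3, 3, 3, 3, 1, 1, rng, pad_mode="edge")

    def __call__(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = blk(x)
        return self.final(ad.tanh(self.penultimate(x)))


class Network(Module):
    """A built registration network (encoders + decoder + integration)."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        layout = ENCODER_LAYOUT[spec.architecture]
        depth = spec.encoder_depth
        base = spec.base_channels
        self.encoders = [
            _Encoder(2, cin, encoder_channels(cin, depth, base), rng) for cin in layout
        ]
        latents = [encoder_channels(cin, depth, base)[-1] for cin in layout]
        self.encoder3d = None
        if spec.architecture == "C":
            ch3 = encoder_channels(1, depth, base)
            self.encoder3d = _Encoder(3, 1, ch3, rng)
            latents.append(ch3[-1])
        if spec.architecture == "E":
            # real pair and imaginary pair latents are added, then concatenated
            latent = latents[0] + latents[2]
        else:
            latent = sum(latents)
        self.decoder = _Decoder(latent, decoder_channels(spec.architecture, latent, spec.decoder_depth), rng)
        #: input normalisation (lo, hi) per arm, recorded at training time
        self.input_norm: list[tuple[float, float]] | None = None
        self.volume_norm: tuple[float, float] | None = None

    # -- forward ----------------------------------------------------------
    def velocity(self, planes: list[Tensor], volume: Tensor | None = None) -> Tensor:
        """Velocity field tensor (B, 3, D, H, W) in mm, before integration."""
        latents = [enc(x) for enc, x in zip(self.encoders, planes)]
        if self.spec.architecture == "E":
            latents = [ad.add(latents[0], latents[1]), ad.add(latents[2], latents[3])]
        if self.encoder3d is not None:
            if volume is None:
                raise ValueError("variant C requires the reference volume")
            latents.append(self.encoder3d(volume))
        B = latents[0].shape[0]
        flat = [ad.reshape(z, (B, z.shape[1], 1, 1, 1)) for z in latents]
        z = flat[0] if len(flat) == 1 else ad.concat(flat, axis=1)
        vel = self.decoder(z)
        # boundary condition: the outermost ring of a transposed-convolution
        # stack has reduced support and no supervision; replicate inward
        vel = ad.replicate_border(vel)
        return ad.scale(vel, self.spec.velocity_scale())

    def forward(
        self,
        planes: list[np.ndarray],
        volume: np.ndarray | None = None,
        return_velocity: bool = False,
    ):
        """Integrated displacement tensor (B, 3, D, H, W) in mm.

        With ``return_velocity`` the (pre-integration) velocity tensor is
        returned alongside, for training-time regularisation.
        """
        pt = [Tensor(p) for p in planes]
        vt = Tensor(volume) if volume is not None else None
        vel = self.velocity(pt, vt)
        disp = ad.integrate_displacement(vel, self.spec.integration_steps, self.spec.output_grid.spacing)
        if return_velocity:
            return disp, vel
        return disp

    # -- inference --------------------------------------------------------
    def normalise(self, inputs: NetworkInputs) -> tuple[list[np.ndarray], np.ndarray | None]:
        planes = [p.astype(np.float32) for p in inputs.planes]
        if self.input_norm is not None:
            planes = [
                2.0 * (p - lo) / max(hi - lo, 1e-12) - 1.0
                for p, (lo, hi) in zip(planes, self.input_norm)
            ]
        vol = None
        if inputs.volume is not None:
            vol = inputs.volume.astype(np.float32)
            if self.volume_norm is not None:
                lo, hi = self.volume_norm
                vol = 2.0 * (vol - lo) / max(hi - lo, 1e-12) - 1.0
        return planes, vol


def build_network(spec: NetworkSpec) -> Network:
    """Instantiate a network with seeded (He-normal) initialisation."""
    return Network(spec)


def count_parameters(net: Network) -> int:
    """Total trainable weights, biases and batch-norm affine parameters."""
    return net.num_parameters()


def predict_dvf(net: Network, inputs: NetworkInputs) -> DisplacementField:
    """Predict the integrated DVF for one sample (evaluation mode)."""
    if inputs.architecture != net.spec.architecture:
        raise ValueError(
            f"inputs are for variant {inputs.architecture}, network is {net.spec.architecture}"
        )
    net.eval()
    planes, vol = net.normalise(inputs)
    batch = [p[None] for p in planes]
    vb = vol[None, None] if vol is not None else None
    disp = net.forward(batch, vb)
    return DisplacementField(
        net.spec.output_grid, disp.data[0].astype(np.float64), provenance="predicted"
    )


# ---------------------------------------------------------------------------
# serialisation and summary

def save_network(net: Network, prefix: str) -> None:
    """Write weights (npz) and spec (YAML) side by side."""
    import yaml

    state = net.state_dict()
    np.savez(f"{prefix}.weights.npz", **state)
    spec = net.spec
    meta = {
        "architecture": spec.architecture,
        "input_size": spec.input_size,
        "output_shape": list(spec.output_grid.shape),
        "output_spacing": list(spec.output_grid.spacing),
        "output_origin": list(spec.output_grid.origin),
        "base_channels": spec.base_channels,
        "integration_steps": spec.integration_steps,
        "velocity_scale_mm": spec.velocity_scale(),
        "seed": spec.seed,
        "input_norm": [list(map(float, n)) for n in net.input_norm] if net.input_norm else None,
        "volume_norm": list(map(float, net.volume_norm)) if net.volume_norm else None,
    }
    with open(f"{prefix}.spec.yaml", "w") as f:
        yaml.safe_dump(meta, f)


def load_network(prefix: str) -> Network:
    import yaml

    with open(f"{prefix}.spec.yaml") as f:
        meta = yaml.safe_load(f)
    spec = NetworkSpec(
        architecture=meta["architecture"],
        input_size=meta["input_size"],
        output_grid=Grid3(
            tuple(meta["output_shape"]), tuple(meta["output_spacing"]), tuple(meta["output_origin"])
        ),
        base_channels=meta["base_channels"],
        integration_steps=meta["integration_steps"],
        velocity_scale_mm=meta["velocity_scale_mm"],
        seed=meta["seed"],
    )
    net = Network(spec)
    state = dict(np.load(f"{prefix}.weights.npz"))
    net.load_state_dict(state)
    if meta.get("input_norm"):
        net.input_norm = [tuple(n) for n in meta["input_norm"]]
    if meta.get("volume_norm"):
        net.volume_norm = tuple(meta["volume_norm"])
    return net


def summary(net: Network) -> str:
    """Human-readable per-arm channel plan and the parameter count."""
    spec = net.spec
    lines = [f"Network {spec.architecture}: input {spec.input_size}, output {spec.output_grid.shape}"]
    for i, (enc, cin) in enumerate(zip(net.encoders, ENCODER_LAYOUT[spec.architecture])):
        ch = [blk.bn.gamma.data.size for blk in enc.blocks]
        lines.append(f"  encoder[{i}] (2D, {cin} ch in): {len(enc.blocks)} residual blocks, channels {ch}")
    if net.encoder3d is not None:
        ch = [blk.bn.gamma.data.size for blk in net.encoder3d.blocks]
        lines.append(f"  encoder3d (1 ch in): {len(ch)} residual blocks, channels {ch}")
    ch = [blk.bn.gamma.data.size for blk in net.decoder.blocks]
    lines.append(f"  decoder (3D): {len(ch)} residual blocks, channels {ch} -> 3 -> 3")
    lines.append(f"  integration: scaling and squaring, T={spec.integration_steps}")
    lines.append(f"  velocity scale: {spec.velocity_scale():.2f} mm")
    lines.append(f"  trainable parameters: {net.num_parameters():,}")
    return "\n".join(lines)
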
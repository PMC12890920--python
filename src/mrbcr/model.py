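"""Multi-resolution residual BCR restoration network (m-rBCR).

The building block is a *residual BCR unit*: a convolutional realization of
the Beylkin-Coifman-Rokhlin nonstandard wavelet form of an integral
operator. Feature maps are restricted through L dyadic levels by stride-2
convolutions, a small stack of local "band" convolutions acts at every
level, and the levels are recombined coarse-to-fine by 2x upsampling plus
convolution. The recombined correction is added back to the unit input, so
the unit is exactly the identity map at initialization (its output
convolution starts at zero).

A single-resolution restoration block (s-rBCR) wraps one unit with an input
embedding and a linear output projection, with a global residual from the
block input. The multi-resolution assembly (m-rBCR) runs one s-rBCR per
scale of an input pyramid (2x average-pool downsampling), coarsest first,
fusing each scale's embedding with the upsampled features of the
next-coarser scale (channel concatenation + 1x1 convolution). Every scale
emits a restored image; the finest one is the prediction.

Layer inventory per scale (c channels, k x k kernels, L levels, B band
convolutions per level) — the basis for the parameter-count arithmetic:

    embed         conv k x k, 1  -> c          (activation)
    fuse          conv 1 x 1, 2c -> c          (all scales except coarsest)
    restrict x L  conv k x k, c -> c, stride 2 (activation)
    band x (L*B)  conv k x k, c -> c           (activation)
    recon x (L-1) conv k x k, c -> c           (after 2x upsample)
    lift          conv k x k, c -> c           (after final 2x upsample)
    unit_out      conv k x k, c -> c           (zero-initialized)
    project       conv 1 x 1, c -> 1           (zero-initialized)

Each convolution holds in*out*k^2 weights plus out biases.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = [
    "ModelSpec",
    "BCRUnit",
    "MRBCR",
    "build_model",
    "bcr_unit_forward",
    "mrbcr_forward",
    "count_parameters",
    "save_model",
    "load_model",
]


@dataclass
class ModelSpec:
    """Architecture hyperparameters of the m-rBCR network.

    scales
        Number of resolution levels S of the input pyramid (original image
        plus S-1 successively 2x-downsampled copies).
    bcr_levels
        Number of dyadic decomposition levels L inside each BCR unit.
    base_channels
        Feature-channel count c used at every scale.
    band_convs
        Number of local convolutions applied per decomposition level.
    kernel_size
        Odd spatial kernel extent of all non-1x1 convolutions.
    activation
        'relu' (default) or 'linear' (identity; makes the unit a linear
        operator at zero bias, used for analysis).
    multiscale_supervision
        When True the training loss also supervises the restored image
        emitted at every coarser scale.
    """

    scales: int = 3
    bcr_levels: int = 4
    base_channels: int = 16
    band_convs: int = 2
    kernel_size: int = 3
    activation: str = "relu"
    multiscale_supervision: bool = False

    def __post_init__(self):
        if self.scales < 1 or self.bcr_levels < 1:
            raise ValueError("scales and bcr_levels must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.band_convs < 0:
            raise ValueError("band_convs must be >= 0")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation '{self.activation}'")

    def validate_patch_size(self, patch_size: int) -> None:
        """Every restriction and every pyramid level must halve an even
        extent, i.e. patch_size must be divisible by 2**(scales-1+bcr_levels)."""
        div = 2 ** (self.scales - 1 + self.bcr_levels)
        if patch_size % div != 0 or patch_size // div < 1:
            raise ValueError(
                f"patch size {patch_size} incompatible with spec: must be a "
                f"positive multiple of 2**(scales-1+bcr_levels) = {div}"
            )


def _he_conv(rng: np.random.Generator, k: int, cin: int, cout: int, zero: bool = False):
    """He-normal weight (k,k,cin,cout) and zero bias as trainable Tensors."""
    if zero:
        w = np.zeros((k, k, cin, cout), np.float32)
    else:
        std = np.sqrt(2.0 / (k * k * cin))
        w = rng.normal(0.0, std, size=(k, k, cin, cout)).astype(np.float32)
    return Tensor(w, requires_grad=True), Tensor(np.zeros(cout, np.float32), requires_grad=True)


class _Conv:
    def __init__(self, rng, name, k, cin, cout, zero=False):
        self.name = name
        self.w, self.b = _he_conv(rng, k, cin, cout, zero=zero)
        self.w.name, self.b.name = f"{name}.w", f"{name}.b"

    def __call__(self, x: Tensor, stride: int = 1) -> Tensor:
        return ag.conv2d(x, self.w, self.b, stride=stride)

    @property
    def params(self):
        return [self.w, self.b]


class BCRUnit:
    """One residual BCR decomposition unit over c-channel feature maps."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator, name: str = "unit"):
        self.spec = spec
        c, k, L, B = spec.base_channels, spec.kernel_size, spec.bcr_levels, spec.band_convs
        self.restrict = [_Conv(rng, f"{name}.restrict{l}", k, c, c) for l in range(L)]
        self.band = [
            [_Conv(rng, f"{name}.band{l}_{j}", k, c, c) for j in range(B)] for l in range(L)
        ]
        self.recon = [_Conv(rng, f"{name}.recon{l}", k, c, c) for l in range(L - 1)]
        self.lift = _Conv(rng, f"{name}.lift", k, c, c)
        self.out = _Conv(rng, f"{name}.out", k, c, c, zero=True)

    def _act(self, x: Tensor) -> Tensor:
        return ag.relu(x) if self.spec.activation == "relu" else x

    def forward(self, f: Tensor) -> Tensor:
        L = self.spec.bcr_levels
        h, w = f.shape[1], f.shape[2]
        if h % (1 << L) or w % (1 << L):
            raise ValueError(
                f"BCR unit input extent {(h, w)} not divisible by 2**bcr_levels = {1 << L}"
            )
        # (i) dyadic restriction
        d = f
        levels = []
        for conv in self.restrict:
            d = self._act(conv(d, stride=2))
            levels.append(d)
        # (ii) band operators per level
        bands = []
        for lvl, convs in zip(levels, self.band):
            g = lvl
            for conv in convs:
                g = self._act(conv(g))
            bands.append(g)
        # (iii) coarse-to-fine reconstruction
        u = bands[-1]
        for l in range(L - 2, -1, -1):
            u = ag.add(bands[l], self.recon[l](ag.upsample2(u)))
        corr = self.lift(ag.upsample2(u))
        # (iv) residual correction (zero at initialization)
        return ag.add(f, self.out(corr))

    @property
    def params(self):
        out = []
        for conv in self.restrict:
            out += conv.params
        for convs in self.band:
            for conv in convs:
                out += conv.params
        for conv in self.recon:
            out += conv.params
        out += self.lift.params + self.out.params
        return out


class MRBCR:
    """The multi-resolution residual BCR network."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        S, c, k = spec.scales, spec.base_channels, spec.kernel_size
        # scale 0 = finest; built finest-first so seeding is layout-stable
        self.embed = [_Conv(rng, f"s{s}.embed", k, 1, c) for s in range(S)]
        self.fuse = [_Conv(rng, f"s{s}.fuse", 1, 2 * c, c) for s in range(S - 1)]
        self.units = [BCRUnit(spec, rng, name=f"s{s}.unit") for s in range(S)]
        self.project = [_Conv(rng, f"s{s}.project", 1, c, 1, zero=True) for s in range(S)]

    def _act(self, x: Tensor) -> Tensor:
        return ag.relu(x) if self.spec.activation == "relu" else x

    @property
    def params(self):
        out = []
        for s in range(self.spec.scales):
            out += self.embed[s].params
            if s < self.spec.scales - 1:
                out += self.fuse[s].params
            out += self.units[s].params
            out += self.project[s].params
        return out

    @property
    def parameter_count(self) -> int:
        return sum(int(p.data.size) for p in self.params)

    def forward(self, batch: np.ndarray) -> list[Tensor]:
        """Run the network on a (B, P, P) batch.

        Returns the per-scale restored images as Tensors of shape
        (B, P/2^s, P/2^s, 1), finest scale first; element 0 is the
        prediction.
        """
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 3 or batch.shape[1] != batch.shape[2]:
            raise ValueError(f"expected a (B, P, P) square batch, got {batch.shape}")
        self.spec.validate_patch_size(batch.shape[1])
        S = self.spec.scales
        # input pyramid, finest first
        pyramid = [Tensor(batch[..., None])]
        for _ in range(S - 1):
            pyramid.append(ag.avg_pool2(pyramid[-1]))
        outputs: list[Tensor | None] = [None] * S
        feats = None
        for s in range(S - 1, -1, -1):  # coarsest -> finest
            e = self._act(self.embed[s](pyramid[s]))
            if feats is not None:
                e = self.fuse[s](ag.concat_channels(e, ag.upsample2(feats)))
            feats = self.units[s].forward(e)
            outputs[s] = ag.add(pyramid[s], self.project[s](feats))
        return outputs

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Finest-scale restored images for a (B, P, P) batch, as (B, P, P)."""
        return self.forward(batch)[0].data[..., 0]

    # ------------------------------------------------------------- weights

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params:
            if p.name not in state:
                raise KeyError(f"checkpoint is missing weight tensor '{p.name}'")
            arr = np.asarray(state[p.name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint tensor '{p.name}' has shape {arr.shape}, "
                    f"expected {p.data.shape}"
                )
            p.data = arr.copy()


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> MRBCR:
    """Construct an m-rBCR network with deterministic seeded initialization."""
    return MRBCR(spec or ModelSpec(), seed=seed)


def bcr_unit_forward(unit: BCRUnit, features: np.ndarray) -> np.ndarray:
    """Apply one residual BCR unit to a (B, h, w, c) feature array."""
    return unit.forward(Tensor(np.asarray(features, np.float32))).data


def mrbcr_forward(model: MRBCR, batch: np.ndarray) -> np.ndarray:
    """Restore a (B, P, P) batch; returns the finest-scale prediction."""
    return model.predict(batch)


def count_parameters(model: MRBCR) -> int:
    """Total number of trainable scalar parameters."""
    return model.parameter_count


# ---------------------------------------------------------------- checkpoint


def save_model(path: str | Path, model: MRBCR) -> Path:
    """Save spec + named weight tensors to a single NPZ checkpoint."""
    path = Path(path)
    payload = {f"w:{k}": v for k, v in model.state_dict().items()}
    payload["spec_json"] = np.frombuffer(
        json.dumps(asdict(model.spec)).encode(), dtype=np.uint8
    )
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".npz")
    os.close(fd)
    try:
        np.savez(tmp, **payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def load_model(path: str | Path, spec: ModelSpec | None = None) -> MRBCR:
    """Load a checkpoint; if ``spec`` is given it must match the stored one."""
    path = Path(path)
    with np.load(path) as npz:
        stored = ModelSpec(**json.loads(bytes(npz["spec_json"]).decode()))
        if spec is not None and spec != stored:
            raise ValueError(f"checkpoint spec {stored} does not match requested {spec}")
        state = {k[2:]: npz[k] for k in npz.files if k.startswith("w:")}
    model = MRBCR(stored, seed=0)
    model.load_state_dict(state)
    return model
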
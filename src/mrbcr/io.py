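"""File I/O for the restoration workflow: TIFF stacks, NPZ paired datasets,
and YAML training configurations.

All writers are atomic (temp file in the destination directory + rename), so
an interrupted write never leaves a truncated artifact behind. All readers
validate shapes and dtypes and never mutate the file.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .model import ModelSpec

__all__ = [
    "ImageStack",
    "DatasetSplit",
    "TrainConfig",
    "read_image",
    "write_image",
    "read_dataset",
    "write_dataset",
    "read_config",
    "write_config",
]

_SPLIT_KEYS = [
    ("X_train", "Y_train"),
    ("X_val", "Y_val"),
    ("X_test", "Y_test"),
]


@dataclass
class ImageStack:
    """A single-channel image stack of shape (N, H, W).

    A bare (H, W) image is promoted to (1, H, W) on construction.
    Intensities are arbitrary before normalization and lie in [0, 1]
    afterwards. ``pixel_size`` (physical length per pixel, e.g. nm) is
    carried only for frequency-axis labelling and never affects processing.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim != 3:
            raise ValueError(f"expected (H, W) or (N, H, W) pixels, got shape {arr.shape}")
        if arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError(f"empty image dimensions in shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("image stack contains non-finite values")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class DatasetSplit:
    """Paired input (X) / ground-truth (Y) patches split into train/val/test.

    Every array has shape (N_split, P, P); within a split X and Y are
    aligned one-to-one. Empty splits are zero-length arrays.
    """

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 0), np.float32))
    y_val: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 0), np.float32))
    x_test: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 0), np.float32))
    y_test: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 0), np.float32))

    def __post_init__(self):
        for name in ("x_train", "y_train", "x_val", "y_val", "x_test", "y_test"):
            setattr(self, name, np.asarray(getattr(self, name)))
        for x_name, y_name in (("x_train", "y_train"), ("x_val", "y_val"), ("x_test", "y_test")):
            x, y = getattr(self, x_name), getattr(self, y_name)
            if x.shape != y.shape:
                raise ValueError(
                    f"{x_name} shape {x.shape} does not match {y_name} shape {y.shape}"
                )

    @property
    def patch_size(self) -> int:
        for arr in (self.x_train, self.x_val, self.x_test):
            if arr.size:
                return arr.shape[-1]
        return 0

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.x_train), len(self.x_val), len(self.x_test))


@dataclass
class TrainConfig:
    """All optimization hyperparameters, round-trippable through YAML.

    Defaults are the benchmark training configuration: patch size 128,
    Adam at learning rate 1e-3, batch size 32, up to 2000 epochs with
    early stopping, and the combined loss weights 1.0 (pixel MSE) and
    0.5 (Fourier-magnitude term).
    """

    patch_size: int = 128
    batch_size: int = 32
    learning_rate: float = 0.001
    max_epochs: int = 2000
    early_stop_patience: int = 50
    loss_weight_mse: float = 1.0
    loss_weight_ft: float = 0.5
    seed: int = 0
    model: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self):
        if isinstance(self.model, dict):
            self.model = ModelSpec(**self.model)
        for name in ("patch_size", "batch_size", "max_epochs", "early_stop_patience"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
            setattr(self, name, int(getattr(self, name)))
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss_weight_mse < 0 or self.loss_weight_ft < 0:
            raise ValueError("loss weights must be >= 0")


# --------------------------------------------------------------- atomic write


def _atomic_save(path: Path, save_fn) -> None:
    """Run ``save_fn(tmp_path)`` then atomically rename onto ``path``."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        save_fn(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# --------------------------------------------------------------------- TIFF


def read_image(path: str | Path) -> ImageStack:
    """Read a single-channel TIFF into an ImageStack (multi-page = stack)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.samplesperpixel and page.samplesperpixel > 1:
            raise ValueError(
                f"{path} has {page.samplesperpixel} samples per pixel; "
                "only single-channel images are supported"
            )
        arr = tif.asarray()
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise ValueError(f"{path} looks like an RGB(A) image; unsupported layout")
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path} has unsupported dimensionality {arr.ndim}")
    return ImageStack(arr)


def write_image(path: str | Path, stack: ImageStack) -> Path:
    """Write an ImageStack as a (multi-page) single-channel TIFF."""
    path = Path(path)
    _atomic_save(
        path,
        lambda tmp: tifffile.imwrite(tmp, stack.pixels, photometric="minisblack"),
    )
    return path


# ---------------------------------------------------------------------- NPZ


def read_dataset(path: str | Path) -> DatasetSplit:
    """Read a paired patch dataset from an NPZ container.

    Expected keys are X_train/Y_train, X_val/Y_val, X_test/Y_test with
    X = network input and Y = ground truth. A split may be absent entirely
    (treated as empty), but a split with only one of its two arrays present
    raises a KeyError naming the missing entry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset file: {path}")
    with np.load(path) as npz:
        arrays = {}
        for xk, yk in _SPLIT_KEYS:
            have_x, have_y = xk in npz, yk in npz
            if have_x != have_y:
                missing = yk if have_x else xk
                raise KeyError(f"dataset {path} is missing the '{missing}' array")
            if have_x:
                arrays[xk], arrays[yk] = npz[xk], npz[yk]
            else:
                arrays[xk] = arrays[yk] = np.zeros((0, 0, 0), np.float32)
        if not len(arrays["X_train"]) and "X_train" not in npz:
            raise KeyError(f"dataset {path} is missing the 'X_train' array")
    return DatasetSplit(
        x_train=arrays["X_train"],
        y_train=arrays["Y_train"],
        x_val=arrays["X_val"],
        y_val=arrays["Y_val"],
        x_test=arrays["X_test"],
        y_test=arrays["Y_test"],
    )


def write_dataset(path: str | Path, split: DatasetSplit) -> Path:
    """Write a DatasetSplit to NPZ with the six canonical keys."""
    path = Path(path)
    payload = {
        "X_train": split.x_train,
        "Y_train": split.y_train,
        "X_val": split.x_val,
        "Y_val": split.y_val,
        "X_test": split.x_test,
        "Y_test": split.y_test,
    }
    _atomic_save(path, lambda tmp: np.savez(tmp, **payload))
    return path


# --------------------------------------------------------------------- YAML

_NUMERIC_FIELDS = {
    "patch_size": int,
    "batch_size": int,
    "max_epochs": int,
    "early_stop_patience": int,
    "seed": int,
    "learning_rate": float,
    "loss_weight_mse": float,
    "loss_weight_ft": float,
}
_MODEL_FIELDS = {
    "scales": int,
    "bcr_levels": int,
    "base_channels": int,
    "band_convs": int,
    "kernel_size": int,
    "activation": str,
    "multiscale_supervision": bool,
}


def _coerce(key: str, value, typ):
    if typ is str:
        return str(value)
    if typ is bool:
        if isinstance(value, bool):
            return value
        raise ValueError(f"config field '{key}' expects a boolean, got {value!r}")
    try:
        return typ(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"config field '{key}' expects a {typ.__name__}, got {value!r}"
        ) from None


def read_config(path: str | Path) -> TrainConfig:
    """Read a YAML training configuration; unspecified keys use defaults,
    unknown keys warn rather than fail."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a key/value mapping")
    kwargs = {}
    for key, value in raw.items():
        if key == "model":
            model_kwargs = {}
            for mkey, mval in (value or {}).items():
                if mkey not in _MODEL_FIELDS:
                    warnings.warn(f"unknown model config key '{mkey}' ignored", stacklevel=2)
                    continue
                model_kwargs[mkey] = _coerce(f"model.{mkey}", mval, _MODEL_FIELDS[mkey])
            kwargs["model"] = ModelSpec(**model_kwargs)
        elif key in _NUMERIC_FIELDS:
            kwargs[key] = _coerce(key, value, _NUMERIC_FIELDS[key])
        else:
            warnings.warn(f"unknown config key '{key}' ignored", stacklevel=2)
    return TrainConfig(**kwargs)


def write_config(path: str | Path, cfg: TrainConfig) -> Path:
    """Write a TrainConfig as YAML (full round-trip with read_config)."""
    path = Path(path)
    doc = {name: getattr(cfg, name) for name in _NUMERIC_FIELDS}
    doc["model"] = {name: getattr(cfg.model, name) for name in _MODEL_FIELDS}
    _atomic_save(path, lambda tmp: Path(tmp).write_text(yaml.safe_dump(doc, sort_keys=False)))
    return path
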
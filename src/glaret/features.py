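"""Activation tensors, pluggable backbones, and tensor I/O.

A convolutional layer's output for one image is an ``h x w x d`` grid of
non-negative activations: ``d`` feature maps of size ``h x w``, or
equivalently ``h*w`` deep descriptors of dimension ``d``.  Both feature
streams consume this tensor; everything image- and file-shaped lives here so
the streams never touch I/O.

Backbones are adapters: anything callable as ``record -> ActivationTensor``
with a fixed output shape can be registered.  Two ship with the package — an
``identity`` pass-through (a stored tensor is its own activation) and
``patchnet``, a deterministic seeded filter bank (block statistics followed
by a fixed random projection and rectification) that exercises the full
image -> tensor path without any downloaded weights.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Callable, Mapping

import h5py
import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "ImageRecord",
    "BackboneSpec",
    "ActivationTensor",
    "DecodeError",
    "ConfigurationError",
    "ContractViolationError",
    "load_image",
    "extract_activations",
    "descriptor_at",
    "store_tensors",
    "load_tensors",
    "register_backbone",
    "flat_index",
    "position_of",
]


class DecodeError(RuntimeError):
    """An image file could not be read or decoded."""


class ConfigurationError(ValueError):
    """A backbone spec does not resolve to a registered adapter."""


class ContractViolationError(ValueError):
    """A custom backbone produced output violating the activation contract."""


def flat_index(row: int, col: int, w: int) -> int:
    """Row-major flat id of a grid position."""
    return row * w + col


def position_of(flat_id: int, w: int) -> tuple[int, int]:
    """Inverse of :func:`flat_index`."""
    return divmod(flat_id, w)


@dataclasses.dataclass(frozen=True)
class ImageRecord:
    """A decoded raster image keyed by a corpus-unique id."""

    id: str
    pixels: np.ndarray  # H x W x 3, uint8
    label: str | None = None

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(f"pixels must be HxWxC with C in {{1,3}}, got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")


@dataclasses.dataclass(frozen=True)
class BackboneSpec:
    """Identifies a convolutional feature extractor and the tapped layer.

    ``input_side`` fixes the square input resolution; for a fixed spec the
    output shape ``(h, w, d)`` is fixed.  ``deterministic`` promises
    bit-identical tensors for identical inputs.
    """

    name: str
    layer: str = "pool5"
    input_side: int = 224
    deterministic: bool = True


class ActivationTensor:
    """An ``h x w x d`` grid of non-negative, finite activations.

    Non-negativity (post-rectification) is enforced here, at the boundary,
    and assumed by everything downstream.
    """

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray) -> None:
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"activation tensor must be 3-D (h, w, d), got {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError(f"degenerate tensor shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("activation tensor contains non-finite entries")
        if np.any(arr < 0):
            raise ValueError("activation tensor contains negative entries")
        self.values = arr

    @property
    def h(self) -> int:
        return self.values.shape[0]

    @property
    def w(self) -> int:
        return self.values.shape[1]

    @property
    def d(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ActivationTensor(h={self.h}, w={self.w}, d={self.d})"


def descriptor_at(tensor: ActivationTensor, pos: tuple[int, int]) -> np.ndarray:
    """The d-dimensional deep descriptor at one spatial cell."""
    row, col = pos
    if not (0 <= row < tensor.h and 0 <= col < tensor.w):
        raise IndexError(f"position {pos} outside {tensor.h}x{tensor.w} grid")
    return tensor.values[row, col, :].copy()


# ---------------------------------------------------------------------------
# image loading
# ---------------------------------------------------------------------------

def load_image(path, input_side: int = 224, id: str | None = None) -> ImageRecord:
    """Decode a PNG/JPEG, resize to ``input_side`` square, replicate grayscale.

    Plain bilinear resize without aspect-ratio preservation or cropping.
    """
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            im = im.resize((input_side, input_side), Image.BILINEAR)
            pixels = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise DecodeError(f"cannot decode image file {path!s}: {exc}") from exc
    return ImageRecord(id=id if id is not None else str(path), pixels=pixels)


# ---------------------------------------------------------------------------
# backbone registry
# ---------------------------------------------------------------------------

BackboneFn = Callable[[ImageRecord], ActivationTensor]
_BACKBONES: dict[str, Callable[[BackboneSpec], BackboneFn]] = {}


def register_backbone(name: str, factory: Callable[[BackboneSpec], BackboneFn]) -> None:
    """Register a backbone adapter factory under ``name``."""
    _BACKBONES[name] = factory


def _identity_factory(spec: BackboneSpec) -> BackboneFn:
    def run(record: ImageRecord) -> ActivationTensor:
        return ActivationTensor(record.pixels.astype(np.float64))

    return run


def _patchnet_factory(spec: BackboneSpec) -> BackboneFn:
    """Seeded filter bank: per-cell block statistics -> fixed random
    projection -> rectification.  Output grid is input_side/32 square with
    512 channels, mirroring the last-pooling-layer geometry of a VGG-16-class
    network (224 -> 7x7x512)."""
    side = spec.input_side
    grid = max(side // 32, 1)
    d = 512
    n_stats = 8  # mean/std per channel + 2 gradient magnitudes
    # Weights are a pure function of the spec, never of the image; a stable
    # digest (not builtin hash, which is salted per process) seeds them.
    digest = hashlib.sha256(f"{spec.name}:{spec.layer}:{side}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:4], "big"))
    weights = rng.standard_normal((n_stats, d))
    bias = rng.standard_normal(d) * 0.1

    def run(record: ImageRecord) -> ActivationTensor:
        px = record.pixels.astype(np.float64) / 255.0
        if px.shape[0] != side or px.shape[1] != side:
            raise ValueError(
                f"image {record.id!r} is {px.shape[0]}x{px.shape[1]}, spec expects {side}x{side}"
            )
        if px.shape[2] == 1:
            px = np.repeat(px, 3, axis=2)
        cell = side // grid
        blocks = px[: grid * cell, : grid * cell].reshape(grid, cell, grid, cell, 3)
        mean = blocks.mean(axis=(1, 3))  # grid x grid x 3
        std = blocks.std(axis=(1, 3))  # grid x grid x 3
        # mean vertical / horizontal gradient magnitude within each block
        lum = blocks.mean(axis=4)
        if cell >= 2:
            gy = np.abs(np.diff(lum, axis=1)).mean(axis=(1, 3))
            gx = np.abs(np.diff(lum, axis=3)).mean(axis=(1, 3))
        else:
            gy = np.zeros((grid, grid))
            gx = np.zeros((grid, grid))
        stats = np.concatenate([mean, std, gy[..., None], gx[..., None]], axis=2)
        out = np.maximum(stats @ weights + bias, 0.0)
        return ActivationTensor(out)

    return run


register_backbone("identity", _identity_factory)
register_backbone("patchnet", _patchnet_factory)


def extract_activations(image: ImageRecord, spec: BackboneSpec) -> ActivationTensor:
    """Run the backbone the spec names and validate the activation contract."""
    try:
        factory = _BACKBONES[spec.name]
    except KeyError:
        raise ConfigurationError(
            f"unknown backbone {spec.name!r}; registered: {sorted(_BACKBONES)}"
        ) from None
    raw = factory(spec)(image)
    if not isinstance(raw, ActivationTensor):
        try:
            raw = ActivationTensor(np.asarray(raw))
        except ValueError as exc:
            raise ContractViolationError(
                f"backbone {spec.name!r} violated the activation contract: {exc}"
            ) from exc
    return raw


# ---------------------------------------------------------------------------
# HDF5 tensor store
# ---------------------------------------------------------------------------

def store_tensors(records: Mapping[str, ActivationTensor], path) -> None:
    """Write tensors to an HDF5 store, one dataset per id (lossless)."""
    ids = list(records)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in tensor map")
    with h5py.File(path, "w") as f:
        for key, tensor in records.items():
            ds = f.create_dataset(key, data=tensor.values)
            ds.attrs["h"] = tensor.h
            ds.attrs["w"] = tensor.w
            ds.attrs["d"] = tensor.d


def load_tensors(path) -> dict[str, ActivationTensor]:
    """Read back a tensor store written by :func:`store_tensors`."""
    out: dict[str, ActivationTensor] = {}
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            out[key] = ActivationTensor(f[key][()])
    return out


def load_labels(path) -> dict[str, str]:
    """Read a two-column (id, label) TSV sidecar."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, label = line.split("\t")
            labels[key] = label
    return labels


def store_labels(labels: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for key in sorted(labels):
            fh.write(f"{key}\t{labels[key]}\n")
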
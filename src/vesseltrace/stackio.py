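"""Multi-page TIFF stack I/O with explicit voxel metadata.

Voxel sizes travel in a JSON sidecar (``<stack>.meta.json``) next to the
TIFF rather than in TIFF resolution tags, which are dialect-prone.  Reading
a stack without a sidecar requires an explicit voxel-size override; a
missing voxel size is an error, never a silent assumption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["StackMeta", "read_stack", "write_stack", "downsample", "downsample_stack"]

_SUPPORTED_DTYPES = ("uint8", "uint16")


@dataclass(frozen=True)
class StackMeta:
    shape: tuple[int, int, int]
    dtype: str
    voxel_um: tuple[float, float, float]  # (z, y, x)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel sizes must be positive")
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_um", tuple(float(v) for v in self.voxel_um))
        object.__setattr__(self, "provenance", tuple(self.provenance))

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "dtype": self.dtype,
            "voxel_um": list(self.voxel_um),
            "origin_um": list(self.origin_um),
            "provenance": list(self.provenance),
        }


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_stack(path: str | Path, volume: np.ndarray, meta: StackMeta) -> Path:
    """Write a depth-major volume as a multi-page grayscale TIFF + sidecar."""
    path = Path(path)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    if str(volume.dtype) not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported dtype {volume.dtype}; use uint8 or uint16")
    tifffile.imwrite(path, volume, photometric="minisblack")
    meta = replace(meta, shape=volume.shape, dtype=str(volume.dtype))
    _sidecar(path).write_text(json.dumps(meta.to_dict(), indent=1, sort_keys=True))
    return path


def read_stack(
    path: str | Path,
    voxel_um: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, StackMeta]:
    """Read a multi-page grayscale TIFF into a depth-major array.

    Voxel size comes from the JSON sidecar when present, else from the
    ``voxel_um`` override; without either, this is an error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.series) != 1:
            raise ValueError(f"{path}: mixed page shapes (multiple TIFF series)")
        series = tf.series[0]
        if tf.pages[0].samplesperpixel > 1:
            raise ValueError(f"{path}: RGB/multichannel TIFF not supported")
        vol = series.asarray()
    if vol.ndim == 2:
        vol = vol[None, ...]
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3D grayscale stack, got shape {vol.shape}")
    if str(vol.dtype) not in _SUPPORTED_DTYPES:
        raise ValueError(f"{path}: unsupported dtype {vol.dtype}; need 8/16-bit grayscale")

    side = _sidecar(path)
    if side.exists():
        d = json.loads(side.read_text())
        meta = StackMeta(
            shape=tuple(d["shape"]),
            dtype=d["dtype"],
            voxel_um=tuple(d["voxel_um"]),
            origin_um=tuple(d.get("origin_um", (0.0, 0.0, 0.0))),
            provenance=tuple(d.get("provenance", ())),
        )
    elif voxel_um is not None:
        meta = StackMeta(vol.shape, str(vol.dtype), tuple(voxel_um),
                         provenance=(f"read {path.name} (voxel size from override)",))
    else:
        raise ValueError(
            f"{path}: no voxel-size metadata ({side.name} missing) and no override given"
        )
    if tuple(meta.shape) != vol.shape:
        meta = replace(meta, shape=vol.shape)
    return vol, meta


def downsample(volume: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Block-mean reduction; output shape is ceil(input / factor) per axis.

    Edge blocks are padded by edge replication so partial blocks average
    only real data statistics (a constant volume stays exactly constant).
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    f = tuple(int(x) for x in factors)
    if len(f) != 3 or any(x < 1 for x in f) or tuple(factors) != f:
        raise ValueError("factors must be three integers >= 1")
    if f == (1, 1, 1):
        return vol.copy()
    pad = [(0, (-s) % k) for s, k in zip(vol.shape, f)]
    v = np.pad(vol.astype(np.float64), pad, mode="edge")
    nz, ny, nx = (v.shape[i] // f[i] for i in range(3))
    v = v.reshape(nz, f[0], ny, f[1], nx, f[2])
    return v.mean(axis=(1, 3, 5))


def downsample_stack(
    volume: np.ndarray, meta: StackMeta, factors: tuple[int, int, int]
) -> tuple[np.ndarray, StackMeta]:
    """Downsample a stack and record the enlarged voxel size in its metadata."""
    out = downsample(volume, factors)
    new_meta = replace(
        meta,
        shape=out.shape,
        dtype=meta.dtype,
        voxel_um=tuple(v * k for v, k in zip(meta.voxel_um, factors)),
        provenance=meta.provenance + (f"downsampled by factors {tuple(factors)}",),
    )
    return out, new_meta
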
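"""Reading, writing and projecting multi-channel confocal stacks.

The analysis consumes two 2-D views of the N-cadherin channel of a confocal
z-stack: a median-filtered maximum-intensity projection (region detection) and
a median-filtered mean-intensity projection (halo and tendril measurements).
Stacks are plain multi-page TIFFs; pixel size is supplied by the caller because
the downstream area exclusion (176 µm²) is meaningless without it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import scipy.ndimage as ndi
import tifffile

__all__ = [
    "ImageStack",
    "Projection",
    "read_stack",
    "write_stack",
    "project",
    "median_filter",
]


@dataclass(frozen=True)
class ImageStack:
    """Multi-channel, multi-plane raster with physical metadata.

    Parameters
    ----------
    channels
        Mapping from channel name (at minimum ``"ncadherin"``) to a
        ``(z, row, col)`` array. All channels must share one shape.
    pixel_size_um
        Microns per pixel, > 0.
    z_step_um
        Microns between z-planes, > 0. Default 1.5, the acquisition interval
        used for the micropatterned-tissue confocal stacks this pipeline was
        designed around.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float = 1.5

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.z_step_um <= 0:
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        ref = next(iter(shapes.values()))
        if any(len(s) != 3 for s in shapes.values()):
            raise ValueError(f"channels must be (z, row, col) arrays, got shapes {shapes}")
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"all channels must share one shape, got {shapes}")
        for name, arr in self.channels.items():
            a = np.asarray(arr)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {name!r} contains non-finite intensities")
            if a.min() < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_planes(self) -> int:
        return self.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.channels[name])
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass(frozen=True)
class Projection:
    """A 2-D per-pixel reduction (max or mean) of one stack channel."""

    image: np.ndarray
    kind: str
    source_channel: str
    filtered: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("max", "mean"):
            raise ValueError(f"kind must be 'max' or 'mean', got {self.kind!r}")
        if np.asarray(self.image).ndim != 2:
            raise ValueError("projection image must be 2-D")


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size_um: float,
    z_step_um: float = 1.5,
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Accepted array layouts: ``(row, col)`` (single plane, single channel),
    ``(z, row, col)`` when ``channel_map`` has one entry, ``(c, row, col)``
    when it has several and the file has as many pages as channels, and
    ``(z, c, row, col)``. Single-plane inputs become z=1 stacks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None, None]  # (1, 1, row, col)
    elif arr.ndim == 3:
        if len(channel_map) > 1:
            if arr.shape[0] < len(channel_map):
                raise ValueError(
                    f"{path}: {arr.shape[0]} pages cannot hold "
                    f"{len(channel_map)} channels"
                )
            arr = arr[None]  # (1, c, row, col)
        else:
            arr = arr[:, None]  # (z, 1, row, col)
    elif arr.ndim != 4:
        raise ValueError(f"{path}: cannot interpret array of shape {arr.shape}")
    n_chan = arr.shape[1]
    channels = {}
    for name, idx in channel_map.items():
        if not 0 <= idx < n_chan:
            raise ValueError(
                f"channel {name!r} index {idx} out of range for {n_chan} channel(s)"
            )
        channels[name] = np.ascontiguousarray(arr[:, idx]).astype(np.float64, copy=False)
    return ImageStack(channels=channels, pixel_size_um=pixel_size_um, z_step_um=z_step_um)


def write_stack(stack: ImageStack, path: str | Path, channel_order: list[str] | None = None) -> None:
    """Write a stack as a ``(z, c, row, col)`` multi-page TIFF.

    Integer-typed channels round-trip bit-exactly through
    :func:`read_stack` with the matching ``channel_map``.
    """
    names = channel_order if channel_order is not None else sorted(stack.channels)
    planes = np.stack([np.asarray(stack.channels[n]) for n in names], axis=1)
    tifffile.imwrite(Path(path), planes, metadata={"axes": "ZCYX"})


def project(stack: ImageStack, channel: str, kind: str) -> Projection:
    """Per-pixel max or mean across z for one channel."""
    planes = stack.channel(channel).astype(np.float64, copy=False)
    if kind == "max":
        image = planes.max(axis=0)
    elif kind == "mean":
        image = planes.mean(axis=0)
    else:
        raise ValueError(f"kind must be 'max' or 'mean', got {kind!r}")
    return Projection(image=image, kind=kind, source_channel=channel, filtered=False)


def median_filter(p: Projection, kernel_px: int = 3) -> Projection:
    """Square median filter with reflect padding; kernel must be odd, >= 1.

    Reflect padding avoids border darkening that would bias intensity
    sampling near the tissue edge.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError(f"kernel_px must be odd and >= 1, got {kernel_px}")
    if kernel_px == 1:
        image = np.asarray(p.image, dtype=np.float64)
    else:
        image = ndi.median_filter(
            np.asarray(p.image, dtype=np.float64), size=kernel_px, mode="reflect"
        )
    return Projection(image=image, kind=p.kind, source_channel=p.source_channel, filtered=True)
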
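"""Reading and writing serial-section image stacks with physical metadata.

A *stack* is an ordered series of RGB photographs of consecutive microtome
sections, each a few micrometres thick.  Because individual sections may be
lost or excluded during staining, the stack keeps the original cut index of
every section: index ``i`` sits at physical depth ``i * thickness_um``, and
gaps left by excluded sections still occupy depth.

The on-disk representation is one image file per section (TIFF written
uncompressed, PNG, or JPEG) plus a YAML/JSON *manifest* sidecar carrying the
physical metadata the image formats cannot: pixel size, section thickness,
cut indices, and the immunostain marker applied to each section.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "SectionImage",
    "StackManifest",
    "SectionRecord",
    "Stack",
    "read_stack",
    "write_stack",
    "z_extent",
    "marker_schedule",
    "stack_array",
]

#: bits per pixel reported for 8-bit-per-channel RGB input
RGB_BITS_PER_PIXEL = 24

#: default JPEG quality; bit-exact round trips are only promised for TIFF/PNG
JPEG_QUALITY = 95


class StackValidationError(ValueError):
    """Raised when a manifest or stack violates its invariants."""


class UnsupportedFormatError(ValueError):
    """Raised for image files that are not 8-bit RGB (or 8-bit grayscale)."""


@dataclass
class SectionImage:
    """One section photograph with its physical metadata.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), dtype uint8
        RGB channel values in [0, 255].
    pixel_size_um : float
        Physical edge length of one pixel, in micrometres.
    section_index : int
        0-based position in the cut series (the physical cut order, not the
        position among included sections).
    thickness_um : float
        Physical section thickness in micrometres.
    marker : str or None
        Name of the immunostain marker on this section, if any.
    """

    pixels: np.ndarray
    pixel_size_um: float
    section_index: int
    thickness_um: float
    marker: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise StackValidationError(
                f"section {self.section_index}: pixels must be H x W x 3, "
                f"got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise StackValidationError("image must be at least 1 x 1")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise StackValidationError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise StackValidationError("pixel_size_um must be positive")
        if not self.thickness_um > 0:
            raise StackValidationError("thickness_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the pixel grid."""
        return self.pixels.shape[:2]

    @property
    def bits_per_pixel(self) -> int:
        return RGB_BITS_PER_PIXEL

    def with_pixels(self, pixels: np.ndarray, **meta) -> "SectionImage":
        """Copy of this section with new pixels (and optional metadata)."""
        out = replace(self, pixels=pixels)
        for k, v in meta.items():
            setattr(out, k, v)
        return out


@dataclass
class SectionRecord:
    section_index: int
    file: str
    marker: str | None = None


@dataclass
class StackManifest:
    """Ordered list of section records plus the stack-global physical metadata."""

    sections: list[SectionRecord]
    thickness_um: float
    pixel_size_um: float
    sampling_interval: int = 1
    resize_to: tuple[int, int] | None = None  # (W, H) target, optional

    def __post_init__(self) -> None:
        if not self.sections:
            raise StackValidationError("manifest lists no sections")
        idx = [s.section_index for s in self.sections]
        self.sections = [s for _, s in sorted(zip(idx, self.sections), key=lambda p: p[0])]
        idx = [s.section_index for s in self.sections]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StackValidationError("section_index values must be strictly increasing")
        if not self.thickness_um > 0:
            raise StackValidationError("thickness_um must be positive")
        if not self.pixel_size_um > 0:
            raise StackValidationError("pixel_size_um must be positive")
        if self.sampling_interval < 1:
            raise StackValidationError("sampling_interval must be >= 1")

    @property
    def indices(self) -> list[int]:
        return [s.section_index for s in self.sections]


@dataclass
class Stack:
    """A loaded stack: manifest plus the section images, in cut order."""

    manifest: StackManifest
    sections: list[SectionImage]

    @property
    def bits_per_pixel(self) -> int:
        return RGB_BITS_PER_PIXEL

    @property
    def z_extent_um(self) -> float:
        return z_extent(self.manifest)

    def __len__(self) -> int:
        return len(self.sections)


def z_extent(manifest: StackManifest) -> float:
    """Physical depth spanned by the stack, in micrometres.

    Uses the true cut indices, so gaps left by excluded sections still occupy
    depth: a manifest with indices {0, 1, 3} at 5 um spans (3 - 0 + 1) * 5 = 20 um.
    """
    idx = manifest.indices
    return (max(idx) - min(idx) + 1) * manifest.thickness_um


def marker_schedule(n_sections: int, interval: int, offset: int = 0) -> list[int]:
    """Cut indices carrying a marker stained on every ``interval``-th section.

    Returns ``{i : i = offset (mod interval), 0 <= i < n_sections}``.  With 50
    sections and an interval of 10, each marker appears on 5 sections.
    """
    if n_sections < 1:
        raise StackValidationError("n_sections must be >= 1")
    if interval < 1:
        raise StackValidationError("interval must be >= 1")
    if not 0 <= offset < interval:
        raise StackValidationError("offset must satisfy 0 <= offset < interval")
    return list(range(offset, n_sections, interval))


def _load_manifest(path: Path) -> StackManifest:
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise StackValidationError(f"manifest {path} is not a mapping")
    if not data.get("sections"):
        raise StackValidationError(f"manifest {path} lists no sections")
    records = [
        SectionRecord(
            section_index=int(rec["index"]),
            file=str(rec["file"]),
            marker=rec.get("marker"),
        )
        for rec in data["sections"]
    ]
    resize_to = data.get("resize_to")
    if resize_to is not None:
        resize_to = (int(resize_to[0]), int(resize_to[1]))
    return StackManifest(
        sections=records,
        thickness_um=float(data["thickness_um"]),
        pixel_size_um=float(data["pixel_size_um"]),
        sampling_interval=int(data.get("sampling_interval", 1)),
        resize_to=resize_to,
    )


def _read_image(path: Path, section_index: int) -> np.ndarray:
    if not path.exists():
        raise IOError(f"section {section_index}: image file not found: {path}")
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise UnsupportedFormatError(
            f"section {section_index}: {path.name} is not 8-bit (dtype {arr.dtype})"
        )
    if arr.ndim == 2:  # grayscale input promoted to RGB
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise UnsupportedFormatError(
            f"section {section_index}: {path.name} has unsupported shape {arr.shape}"
        )
    return arr


def read_stack(manifest_path: str | os.PathLike) -> Stack:
    """Load a stack from its manifest sidecar.

    Sections come back in cut order.  All images must share one H x W unless
    the manifest declares a ``resize_to`` target, in which case every section
    is area-resampled to that size on load.
    """
    mpath = Path(manifest_path)
    if not mpath.exists():
        raise IOError(f"manifest not found: {mpath}")
    manifest = _load_manifest(mpath)
    base = mpath.parent
    sections: list[SectionImage] = []
    shape: tuple[int, int] | None = None
    for rec in manifest.sections:
        arr = _read_image(base / rec.file, rec.section_index)
        pixel_size = manifest.pixel_size_um
        if manifest.resize_to is not None:
            from .enhance import _resize_array  # local import to avoid cycle

            w, h = manifest.resize_to
            pixel_size *= arr.shape[1] / w
            arr = _resize_array(arr, (w, h))
        if shape is None:
            shape = arr.shape[:2]
        elif arr.shape[:2] != shape:
            raise StackValidationError(
                f"section {rec.section_index}: dimensions {arr.shape[:2]} differ from "
                f"{shape}; declare resize_to in the manifest to resample on load"
            )
        sections.append(
            SectionImage(
                pixels=arr,
                pixel_size_um=pixel_size,
                section_index=rec.section_index,
                thickness_um=manifest.thickness_um,
                marker=rec.marker,
            )
        )
    return Stack(manifest=manifest, sections=sections)


def write_stack(
    stack: Stack | Sequence[SectionImage],
    directory: str | os.PathLike,
    format: str = "tiff",
    prefix: str = "section",
) -> Path:
    """Write one image file per section plus a rewritten manifest sidecar.

    TIFF is written uncompressed; TIFF and PNG round-trip bit-exactly.  JPEG
    (quality 95) is lossy and excluded from any bit-exactness promise.

    Returns the path of the written manifest.
    """
    fmt = format.lower()
    if fmt not in ("tiff", "png", "jpeg"):
        raise StackValidationError(f"unknown format {format!r}")
    sections = stack.sections if isinstance(stack, Stack) else list(stack)
    if not sections:
        raise StackValidationError("refusing to write an empty stack")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": "tif", "png": "png", "jpeg": "jpg"}[fmt]
    records = []
    for sec in sections:
        name = f"{prefix}_{sec.section_index:04d}.{ext}"
        path = directory / name
        if fmt == "tiff":
            tifffile.imwrite(path, sec.pixels, compression=None, photometric="rgb")
        elif fmt == "png":
            iio.imwrite(path, sec.pixels, extension=".png")
        else:
            iio.imwrite(path, sec.pixels, extension=".jpg", quality=JPEG_QUALITY)
        records.append({"index": sec.section_index, "file": name, "marker": sec.marker})
    first = sections[0]
    manifest = {
        "pixel_size_um": float(first.pixel_size_um),
        "thickness_um": float(first.thickness_um),
        "sampling_interval": (
            stack.manifest.sampling_interval if isinstance(stack, Stack) else 1
        ),
        "sections": records,
    }
    mpath = directory / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath


def stack_array(
    sections: Sequence[SectionImage],
    gap_fill: str = "skip",
) -> np.ndarray:
    """Stack sections into a (Z, H, W, 3) array.

    ``gap_fill`` controls how cut indices missing from the series (excluded
    sections) are treated when voxelizing:

    - ``"skip"`` (default): missing planes are simply omitted, so Z equals the
      number of included sections.  Nothing in the source material says lost
      sections were duplicated, so this is the conservative choice.
    - ``"nearest"``: every cut index from min to max gets a plane, missing ones
      filled with a copy of the nearest included section, preserving physical
      z geometry at the cost of duplicated data.
    """
    if not sections:
        raise StackValidationError("no sections to stack")
    shapes = {s.shape for s in sections}
    if len(shapes) != 1:
        raise StackValidationError(f"sections have mixed dimensions: {shapes}")
    ordered = sorted(sections, key=lambda s: s.section_index)
    if gap_fill == "skip":
        return np.stack([s.pixels for s in ordered])
    if gap_fill == "nearest":
        idx = np.array([s.section_index for s in ordered])
        planes = []
        for i in range(idx.min(), idx.max() + 1):
            j = int(np.argmin(np.abs(idx - i)))
            planes.append(ordered[j].pixels)
        return np.stack(planes)
    raise StackValidationError(f"unknown gap_fill {gap_fill!r}")
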
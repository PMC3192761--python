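"""Deterministic image-editing operators for stained-section stacks.

The editing stage of the reconstruction protocol — contrast/brightness,
forcing the background to pure white, removing dark background noise by color
selection, color inversion, downsizing, and grayscale conversion — was
originally performed interactively.  Here each step is a parameterized,
reproducible operator whose settings are logged, so a whole stack can be
processed identically and a run can be repeated bit-for-bit.

All operators keep values in [0, 255] and preserve image dimensions except
:func:`resize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .stack_io import SectionImage

__all__ = [
    "EnhanceParams",
    "adjust_brightness_contrast",
    "whiten_background",
    "remove_color_range_noise",
    "invert_channels",
    "resize",
    "to_grayscale",
    "enhance_lumina",
    "estimate_background_color",
]

WHITE = np.array([255, 255, 255], dtype=np.uint8)

#: ITU-R BT.601 luma weights used for grayscale conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class EnhanceParams:
    """Settings for the editing operators.

    brightness_offset : additive shift per channel (gray levels).
    contrast_slope : multiplicative gain about mid-gray 128 (>0); in
        :func:`enhance_lumina` a slope < 1 sets the tissue brightness ceiling.
    background_tolerance : max per-channel distance from the background color
        for a pixel to count as background when whitening.
    color_range_target : (R, G, B) center of the noise color selection.
    color_range_tolerance : per-channel half-width of that selection.
    refine_radius : morphological radius (px) used to refine the selection
        edge (closing then opening).
    min_noise_size : selected connected regions smaller than this area (px)
        are treated as noise and whitened; larger ones are kept.
    """

    brightness_offset: float = 0.0
    contrast_slope: float = 1.0
    background_tolerance: int = 12
    color_range_target: tuple[int, int, int] = (40, 35, 30)
    color_range_tolerance: int = 30
    refine_radius: int = 1
    min_noise_size: int = 25

    def __post_init__(self) -> None:
        if not self.contrast_slope > 0:
            raise ValueError("contrast_slope must be positive")
        if self.background_tolerance < 0 or self.color_range_tolerance < 0:
            raise ValueError("tolerances must be >= 0")
        if self.refine_radius < 0:
            raise ValueError("refine_radius must be >= 0")


def adjust_brightness_contrast(
    section: SectionImage, params: EnhanceParams
) -> SectionImage:
    """v' = clip(slope * (v - 128) + 128 + offset, 0, 255), rounded."""
    v = section.pixels.astype(float)
    out = params.contrast_slope * (v - 128.0) + 128.0 + params.brightness_offset
    return section.with_pixels(np.clip(np.round(out), 0, 255).astype(np.uint8))


def estimate_background_color(pixels: np.ndarray) -> np.ndarray:
    """Background color estimated as the most frequent color on the 1-px border."""
    border = np.concatenate(
        [pixels[0], pixels[-1], pixels[:, 0], pixels[:, -1]], axis=0
    )
    colors, counts = np.unique(border.reshape(-1, 3), axis=0, return_counts=True)
    return colors[np.argmax(counts)]


def whiten_background(
    section: SectionImage,
    params: EnhanceParams,
    background: tuple[int, int, int] | None = None,
) -> SectionImage:
    """Force background pixels to pure white, leaving everything else untouched.

    A pixel is background when every channel is within ``background_tolerance``
    of the background color (supplied, or estimated from the image border).
    A homogeneous pure-white background is what makes the later alpha
    computation map background to fully transparent.
    """
    bg = (
        np.asarray(background, dtype=int)
        if background is not None
        else estimate_background_color(section.pixels).astype(int)
    )
    dist = np.abs(section.pixels.astype(int) - bg)
    mask = (dist <= params.background_tolerance).all(axis=-1)
    out = section.pixels.copy()
    out[mask] = WHITE
    return section.with_pixels(out)


def remove_color_range_noise(
    section: SectionImage, params: EnhanceParams
) -> SectionImage:
    """Whiten small dark specks selected by color range, keep genuine stain.

    Pixels within ``color_range_tolerance`` of ``color_range_target`` are
    selected; the selection edge is refined by morphological closing then
    opening with ``refine_radius``; selected connected regions smaller than
    ``min_noise_size`` pixels are replaced by pure white.  Larger selected
    regions (actual stain of a similar color) are retained bit-exactly.
    """
    target = np.asarray(params.color_range_target, dtype=int)
    dist = np.abs(section.pixels.astype(int) - target)
    sel = (dist <= params.color_range_tolerance).all(axis=-1)
    if not sel.any():
        return section.with_pixels(section.pixels.copy())
    if params.refine_radius > 0:
        r = params.refine_radius
        yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
        disk = (xx**2 + yy**2) <= r**2
        sel = ndi.binary_closing(sel, structure=disk)
        sel = ndi.binary_opening(sel, structure=disk)
    labels, n = ndi.label(sel)
    if n == 0:
        return section.with_pixels(section.pixels.copy())
    sizes = np.bincount(labels.ravel())
    small = np.zeros(n + 1, dtype=bool)
    small[1:] = sizes[1:] < params.min_noise_size
    noise = small[labels]
    out = section.pixels.copy()
    out[noise] = WHITE
    return section.with_pixels(out)


def invert_channels(section: SectionImage) -> SectionImage:
    """Per-channel inversion v -> 255 - v.

    An involution: the same formula serves both the inversion before channel
    combination and the re-inversion afterwards (multiply by -1, add 255).
    """
    return section.with_pixels(255 - section.pixels)


def _resize_array(pixels: np.ndarray, target_wh: tuple[int, int]) -> np.ndarray:
    """Area-weighted resize of an (H, W[, C]) uint8 array to (W, H) target."""
    from PIL import Image

    w, h = target_wh
    if w < 1 or h < 1:
        raise ValueError("target dimensions must be >= 1")
    img = Image.fromarray(pixels)
    out = img.resize((w, h), resample=Image.BOX)
    return np.asarray(out)


def _block_halve(pixels: np.ndarray) -> np.ndarray:
    """Exact 2x2 block averaging (partial edge blocks average what exists)."""
    h, w = pixels.shape[:2]
    rows = np.arange(0, h, 2)
    cols = np.arange(0, w, 2)
    s = np.add.reduceat(np.add.reduceat(pixels.astype(float), rows, axis=0), cols, axis=1)
    rh = np.diff(np.append(rows, h))
    cw = np.diff(np.append(cols, w))
    counts = np.outer(rh, cw)[..., None]
    return np.clip(np.round(s / counts), 0, 255).astype(np.uint8)


def resize(section: SectionImage, mode="half") -> SectionImage:
    """Downsize a section by area (block) averaging.

    ``mode="half"`` maps W x H to ceil(W/2) x ceil(H/2) by 2x2 block
    averaging (unbiased: block means rounded to nearest, so the image mean is
    preserved to within half a gray level) and doubles the physical pixel
    size; an explicit ``(W, H)`` tuple uses area-weighted interpolation.  The
    protocol's own downsizing — 1392 x 1040 camera frames to 696 x 520 — is
    exactly the "half" mode.
    """
    h, w = section.shape
    if mode == "half":
        tw, th = (w + 1) // 2, (h + 1) // 2
        return section.with_pixels(
            _block_halve(section.pixels), pixel_size_um=section.pixel_size_um * (w / tw)
        )
    else:
        tw, th = int(mode[0]), int(mode[1])
        if tw < 1 or th < 1:
            raise ValueError("target dimensions must be >= 1")
    out = _resize_array(section.pixels, (tw, th))
    return section.with_pixels(out, pixel_size_um=section.pixel_size_um * (w / tw))


def to_grayscale(section: SectionImage) -> np.ndarray:
    """Luma grayscale g = round(0.299 R + 0.587 G + 0.114 B), uint8 (H, W)."""
    wr, wg, wb = LUMA_WEIGHTS
    p = section.pixels.astype(float)
    g = wr * p[..., 0] + wg * p[..., 1] + wb * p[..., 2]
    return np.clip(np.round(g), 0, 255).astype(np.uint8)


def enhance_lumina(
    section: SectionImage,
    params: EnhanceParams,
    white_threshold: int = 245,
) -> SectionImage:
    """Darken tissue so the bright vessel lumina stand out, then whiten lumina.

    Pixels whose channels all reach ``white_threshold`` are lumen/background
    and are set to pure white; all other (tissue) pixels are clamped to a
    brightness ceiling of ``round(contrast_slope * 255)`` per channel.  The
    clamp formulation darkens tissue with a slope-controlled strength, never
    darkens a pixel already at 255, and is exactly idempotent — a second
    application is a no-op.
    """
    ceiling = int(round(min(params.contrast_slope, 1.0) * 255))
    p = section.pixels
    lumen = (p >= white_threshold).all(axis=-1)
    out = np.minimum(p, ceiling).astype(np.uint8)
    out[lumen] = WHITE
    return section.with_pixels(out)
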
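"""Rigid registration of consecutive sections.

Serial sections are photographed independently, so each lands on the slide
with its own small rotation and shift.  Alignment recovers, per section, a
rigid transform (rotation + translation, no scale or shear — scaling would
destroy the physical pixel size) into a common reference frame.  The primary
path is landmark-based: paired points clicked on consecutive sections, fitted
by 2D orthogonal Procrustes.  A phase-correlation auto-aligner is provided as
a convenience heuristic; the landmark path remains the reference behavior.

Coordinate convention: points are (x, y) with x = column and y = row, in
pixels.  Rotations are counterclockwise in that frame.  Transforms act about
the origin internally; :meth:`RigidTransform2D.about_center` builds the
rotation-about-image-center transforms used for section resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .stack_io import SectionImage

__all__ = [
    "RigidTransform2D",
    "LandmarkPairs",
    "estimate_rigid_from_landmarks",
    "compose_to_reference",
    "resample_section",
    "auto_align_pair",
]


class DegenerateLandmarksError(ValueError):
    """Fewer than two distinct landmark pairs: the rigid fit is underdetermined."""


class AlignmentFailureError(RuntimeError):
    """Automatic alignment cannot proceed (e.g. featureless images)."""


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``theta`` (radians, CCW) about the origin, then translation.

    Maps a point p to R(theta) p + (tx, ty).  The linear part is a pure
    rotation (det +1); every transform is invertible and composition is
    matrix composition.
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0)

    @classmethod
    def about_center(
        cls, theta: float, translation: tuple[float, float], center: tuple[float, float]
    ) -> "RigidTransform2D":
        """Rotation by ``theta`` about ``center`` followed by ``translation``.

        Rotating about the image center (rather than the corner) matches how a
        section is manually nudged into place and decouples the fitted angle
        from the translation.
        """
        c, s = math.cos(theta), math.sin(theta)
        cx, cy = center
        tx = cx - (c * cx - s * cy) + translation[0]
        ty = cy - (s * cx + c * cy) + translation[1]
        return cls(theta, tx, ty)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform2D":
        m = np.asarray(m, dtype=float)
        theta = math.atan2(m[1, 0], m[0, 0])
        return cls(theta, float(m[0, 2]), float(m[1, 2]))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors (x, y, 1)."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.array([[c, -s, self.tx], [s, c, self.ty], [0.0, 0.0, 1.0]])

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform2D.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform2D":
        c, s = math.cos(self.theta), math.sin(self.theta)
        tx = -(c * self.tx + s * self.ty)
        ty = -(-s * self.tx + c * self.ty)
        return RigidTransform2D(-self.theta, tx, ty)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = math.cos(self.theta), math.sin(self.theta)
        r = np.array([[c, -s], [s, c]])
        return pts @ r.T + np.array([self.tx, self.ty])

    def params_about_center(self, center: tuple[float, float]) -> tuple[float, float, float]:
        """(theta_deg, tx, ty) with the rotation re-expressed about ``center``."""
        cx, cy = center
        c, s = math.cos(self.theta), math.sin(self.theta)
        tx = self.tx - cx + (c * cx - s * cy)
        ty = self.ty - cy + (s * cx + c * cy)
        return (math.degrees(self.theta), tx, ty)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            abs(self.theta) <= tol and abs(self.tx) <= tol and abs(self.ty) <= tol
        )


@dataclass
class LandmarkPairs:
    """Paired points: ``fixed[i]`` on the reference section corresponds to
    ``moving[i]`` on the section being aligned.  Coordinates in pixels."""

    fixed: np.ndarray
    moving: np.ndarray

    def __post_init__(self) -> None:
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        if self.fixed.shape != self.moving.shape or self.fixed.shape[1] != 2:
            raise DegenerateLandmarksError("fixed and moving must both be (N, 2)")
        if len(self.fixed) < 2:
            raise DegenerateLandmarksError("need at least 2 landmark pairs")
        if not (np.isfinite(self.fixed).all() and np.isfinite(self.moving).all()):
            raise DegenerateLandmarksError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.fixed)


def estimate_rigid_from_landmarks(
    landmarks: LandmarkPairs,
) -> tuple[RigidTransform2D, float]:
    """Least-squares rigid transform mapping moving points onto fixed points.

    2D orthogonal Procrustes (Kabsch): centroids are removed, the rotation
    comes from the SVD of the cross-covariance with reflections excluded, and
    the translation re-attaches the centroids.  Returns the transform and the
    residual RMS in pixels.
    """
    f, m = landmarks.fixed, landmarks.moving
    cf = f.mean(axis=0)
    cm = m.mean(axis=0)
    fc = f - cf
    mc = m - cm
    if np.allclose(mc, 0) or np.allclose(fc, 0):
        raise DegenerateLandmarksError("landmarks are coincident; rotation undefined")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    theta = math.atan2(r[1, 0], r[0, 0])
    t = cf - r @ cm
    transform = RigidTransform2D(theta, float(t[0]), float(t[1]))
    resid = transform.apply(m) - f
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms


def compose_to_reference(
    pairwise: Sequence[RigidTransform2D],
) -> list[RigidTransform2D]:
    """Chain pairwise transforms into per-section absolute transforms.

    ``pairwise[i]`` maps section i+1 into the frame of section i.  The first
    included section is the reference: ``absolute[0]`` is the identity and
    ``absolute[i+1] = absolute[i] o pairwise[i]``, so applying ``absolute[i]``
    brings section i into the reference frame.
    """
    absolute = [RigidTransform2D.identity()]
    for t in pairwise:
        absolute.append(absolute[-1].compose(t))
    return absolute


def resample_section(
    section: SectionImage,
    transform: RigidTransform2D,
    interpolation: str = "bilinear",
    fill: int = 255,
) -> SectionImage:
    """Apply a rigid transform to a section by inverse mapping.

    Output pixel p takes the value at ``transform^-1(p)`` in the input, so the
    image content moves *forward* under ``transform``.  Samples falling
    outside the input are filled with pure white (the background convention of
    the editing stage) unless ``fill`` overrides it — use ``fill=0`` and
    nearest interpolation for label masks to avoid label mixing.
    """
    orders = {"nearest": 0, "bilinear": 1}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = orders[interpolation]
    inv = transform.inverse()
    c, s = math.cos(inv.theta), math.sin(inv.theta)
    # scipy's affine_transform maps *output* (row, col) to input (row, col):
    # in xy the inverse map is p_in = R(inv.theta) p_out + (inv.tx, inv.ty).
    # round away float epsilons so exact index remaps (e.g. quarter turns)
    # do not fall a hair outside the grid
    m_yx = np.round(np.array([[c, s], [-s, c]]), 12)
    off_yx = np.round(np.array([inv.ty, inv.tx]), 12)
    out = np.empty_like(section.pixels)
    for ch in range(section.pixels.shape[2]):
        out[:, :, ch] = ndi.affine_transform(
            section.pixels[:, :, ch].astype(float),
            m_yx,
            offset=off_yx,
            order=order,
            mode="constant",
            cval=float(fill),
        ).round().clip(0, 255).astype(np.uint8)
    return section.with_pixels(out)


def _luma(pixels: np.ndarray) -> np.ndarray:
    return pixels[..., 0] * 0.299 + pixels[..., 1] * 0.587 + pixels[..., 2] * 0.114


def auto_align_pair(
    fixed: SectionImage,
    moving: SectionImage,
    angle_range_deg: float = 5.0,
    angle_step_deg: float = 0.5,
) -> RigidTransform2D:
    """Estimate a rigid transform mapping ``moving`` onto ``fixed`` without landmarks.

    Heuristic: a coarse search over rotation angles (about the image center),
    each scored by the phase-correlation peak against the fixed image; the
    winning angle's phase-correlation shift gives the translation.  Intended as
    a convenience — landmark-based estimation is the reference path.
    """
    if fixed.shape != moving.shape:
        raise ValueError("auto-alignment requires equally sized images")
    fg = _luma(fixed.pixels.astype(float))
    mg = _luma(moving.pixels.astype(float))
    if fg.std() == 0 or mg.std() == 0:
        raise AlignmentFailureError("featureless image: nothing to align")
    h, w = fg.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    best: tuple[float, RigidTransform2D] | None = None
    angles = np.arange(-angle_range_deg, angle_range_deg + 1e-9, angle_step_deg)
    for ang in angles:
        rot = RigidTransform2D.about_center(math.radians(ang), (0.0, 0.0), center)
        if ang == 0.0:
            rotated = mg
        else:
            inv = rot.inverse()
            c, s = math.cos(inv.theta), math.sin(inv.theta)
            rotated = ndi.affine_transform(
                mg,
                np.array([[c, s], [-s, c]]),
                offset=np.array([inv.ty, inv.tx]),
                order=1,
                mode="constant",
                cval=255.0,
            )
        shift, error, _ = phase_cross_correlation(
            fg, rotated, upsample_factor=10, normalization=None
        )
        score = -error
        trans = RigidTransform2D(0.0, float(shift[1]), float(shift[0])).compose(rot)
        if best is None or score > best[0]:
            best = (score, trans)
    assert best is not None
    return best[1]
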
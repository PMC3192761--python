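"""Synthetic branching-duct phantoms with ground truth.

The original reconstructions were built from serially sectioned human liver,
which cannot be redistributed.  The phantom module stands in for it: a
branching tube tree (a portal-vein-like trunk with duct branches, optionally
wrapped in an annular "ductal-plate" sleeve) is rasterized into an isotropic
micrometre grid, virtually sectioned into thin RGB "histology" images with a
brown stain on the tube walls, a pale counterstained parenchyma and a
near-white background, and optionally mis-aligned section by section with
known rigid transforms.  Every stage retains ground truth — the voxel labels,
the tree topology, the per-section class masks, and the exact transforms — so
each pipeline stage can be scored against what it should recover.

All randomness flows from the seed in the spec (or passed explicitly):
identical inputs give bit-identical phantoms.  The grid is isotropic in
micrometres; anisotropy enters only downstream, at the voxelization spacing,
mirroring how real stacks acquire it (thin sections, coarse z sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import RigidTransform2D, resample_section
from .stack_io import SectionImage

__all__ = [
    "TubeTreeSpec",
    "StainModel",
    "PhantomGrid",
    "Topology",
    "generate_tube_tree",
    "virtual_sections",
    "perturb_alignment",
    "BG",
    "TISSUE",
    "LUMEN",
    "WALL",
    "SLEEVE",
    "DETACHED",
]

# voxel class codes in the ground-truth grid
BG, TISSUE, LUMEN, WALL, SLEEVE, DETACHED = 0, 1, 2, 3, 4, 5

#: classes rendered as immunostain (DAB brown)
STAIN_CLASSES = (WALL, SLEEVE, DETACHED)


class PhantomBoundsError(ValueError):
    """The tube tree does not fit the grid; use a larger grid or shorter segments."""


@dataclass
class TubeTreeSpec:
    """Geometry of the synthetic duct tree.

    trunk_radius_um : lumen radius of the trunk tube.
    wall_thickness_um : thickness of the stained wall around every lumen.
    branch_factor : children per segment at each branching.
    depth : number of branching generations (0 = a single straight tube).
    branch_angle_deg : (lo, hi) range of the child-direction deviation.
    segment_length_um : (lo, hi) range of segment lengths.
    sleeve_thickness_um : if set, an annular stained sleeve (a ductal-plate
        analogue) is drawn around trunk segments at ``sleeve_gap_um`` outside
        the wall.
    detached_bodies : number of stained spheres deliberately placed away from
        the tree — isolated aggregations with no connection to the duct system.
    seed : fixes all randomness of the geometry.
    """

    trunk_radius_um: float = 10.0
    wall_thickness_um: float = 4.0
    branch_factor: int = 2
    depth: int = 2
    branch_angle_deg: tuple[float, float] = (25.0, 40.0)
    segment_length_um: tuple[float, float] = (50.0, 90.0)
    radius_decay: float = 0.75
    sleeve_thickness_um: float | None = None
    sleeve_gap_um: float = 6.0
    detached_bodies: int = 0
    detached_radius_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.trunk_radius_um > 0:
            raise ValueError("trunk_radius_um must be positive")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.branch_factor < 1:
            raise ValueError("branch_factor must be >= 1")


@dataclass
class StainModel:
    """Colors and noise of the virtual histology rendering.

    Defaults emulate DAB immunostain (warm brown) over a pale hematoxylin
    counterstain on a near-white slide.  ``noise_sigma`` is the per-channel
    Gaussian sigma in gray levels; ``speck_rate`` the mean density of small
    dark debris specks per mm^2 of section area.
    """

    stain_color: tuple[int, int, int] = (120, 70, 40)
    counterstain_color: tuple[int, int, int] = (190, 175, 210)
    background_color: tuple[int, int, int] = (248, 247, 245)
    lumen_color: tuple[int, int, int] = (252, 252, 252)
    speck_color: tuple[int, int, int] = (40, 35, 30)
    noise_sigma: float = 3.0
    speck_rate: float = 20.0

    def __post_init__(self) -> None:
        for c in (self.stain_color, self.counterstain_color, self.background_color):
            if any(not 0 <= v <= 255 for v in c):
                raise ValueError("colors must lie in [0, 255]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class Segment:
    id: int
    parent: int | None
    level: int
    p0: np.ndarray  # (x, y, z) um
    p1: np.ndarray
    radius: float  # lumen radius um


@dataclass
class Topology:
    """Ground-truth record of the tree and its stained components."""

    segments: list[Segment]
    n_stained_components: int
    n_connected_to_trunk: int
    n_detached: int
    component_touches_trunk: list[bool]


@dataclass
class PhantomGrid:
    """Isotropic ground-truth voxel grid, labels (Z, Y, X) with class codes."""

    labels: np.ndarray
    voxel_size_um: float
    topology: Topology

    @property
    def z_extent_um(self) -> float:
        return self.labels.shape[0] * self.voxel_size_um


def _rotate_toward(direction: np.ndarray, angle: float, azimuth: float) -> np.ndarray:
    """Deviate a unit vector by ``angle`` radians, around the given azimuth."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    lateral = math.cos(azimuth) * u + math.sin(azimuth) * v
    out = math.cos(angle) * d + math.sin(angle) * lateral
    return out / np.linalg.norm(out)


def _grow_tree(spec: TubeTreeSpec, shape_um: tuple[float, float, float], rng) -> list[Segment]:
    x_um, y_um, z_um = shape_um
    segments: list[Segment] = []
    start = np.array([x_um / 2.0, y_um / 2.0, 2.0])
    direction = _rotate_toward(np.array([0.0, 0.0, 1.0]), math.radians(5.0), rng.uniform(0, 2 * math.pi))
    frontier = [(None, start, direction, spec.trunk_radius_um, 0)]
    next_id = 0
    while frontier:
        parent, p0, d, radius, level = frontier.pop(0)
        length = rng.uniform(*spec.segment_length_um)
        p1 = p0 + length * d
        seg = Segment(next_id, parent, level, p0, p1, radius)
        segments.append(seg)
        next_id += 1
        if level < spec.depth:
            base_az = rng.uniform(0, 2 * math.pi)
            for k in range(spec.branch_factor):
                ang = math.radians(rng.uniform(*spec.branch_angle_deg))
                az = base_az + 2 * math.pi * k / spec.branch_factor
                child_dir = _rotate_toward(d, ang, az)
                if child_dir[2] < 0.15:  # keep the tree growing upward through z
                    child_dir[2] = 0.15
                    child_dir /= np.linalg.norm(child_dir)
                frontier.append((seg.id, p1.copy(), child_dir, radius * spec.radius_decay, level + 1))
    return segments


def _capsule_distance_box(labels_shape, p0, p1, r_outer, voxel):
    """Index bounds and coordinate grids for a capsule's bounding box."""
    nz, ny, nx = labels_shape
    lo = np.minimum(p0, p1) - r_outer - voxel
    hi = np.maximum(p0, p1) + r_outer + voxel
    x0, y0, z0 = (max(0, int(lo[i] / voxel)) for i in range(3))
    x1 = min(nx, int(math.ceil(hi[0] / voxel)) + 1)
    y1 = min(ny, int(math.ceil(hi[1] / voxel)) + 1)
    z1 = min(nz, int(math.ceil(hi[2] / voxel)) + 1)
    return (z0, z1, y0, y1, x0, x1)


def _segment_distances(p0, p1, box, voxel):
    z0, z1, y0, y1, x0, x1 = box
    zz, yy, xx = np.meshgrid(
        (np.arange(z0, z1) + 0.5) * voxel,
        (np.arange(y0, y1) + 0.5) * voxel,
        (np.arange(x0, x1) + 0.5) * voxel,
        indexing="ij",
    )
    p = np.stack([xx, yy, zz], axis=-1)
    v = p1 - p0
    vv = float(v @ v)
    t = np.clip(((p - p0) @ v) / vv, 0.0, 1.0) if vv > 0 else np.zeros(p.shape[:-1])
    closest = p0 + t[..., None] * v
    return np.linalg.norm(p - closest, axis=-1)


def generate_tube_tree(
    spec: TubeTreeSpec,
    shape_um: tuple[float, float, float] = (160.0, 160.0, 250.0),
    voxel_size_um: float = 1.0,
) -> PhantomGrid:
    """Rasterize a branching tube tree into an isotropic label grid.

    shape_um : physical (x, y, z) extents of the grid.
    Returns the labeled grid plus a topology record (parent/child segments
    and which stained components touch the trunk).  Raises
    :class:`PhantomBoundsError` if the tree does not fit the grid.
    """
    rng = np.random.default_rng(spec.seed)
    x_um, y_um, z_um = shape_um
    nx = int(round(x_um / voxel_size_um))
    ny = int(round(y_um / voxel_size_um))
    nz = int(round(z_um / voxel_size_um))
    segments = _grow_tree(spec, shape_um, rng)

    sleeve_extra = (
        spec.sleeve_gap_um + spec.sleeve_thickness_um if spec.sleeve_thickness_um else 0.0
    )
    for seg in segments:
        r_out = seg.radius + spec.wall_thickness_um + (sleeve_extra if seg.level == 0 else 0.0)
        for p in (seg.p0, seg.p1):
            if (p[0] - r_out < 0 or p[0] + r_out > x_um
                    or p[1] - r_out < 0 or p[1] + r_out > y_um
                    or p[2] < 0 or p[2] > z_um):
                raise PhantomBoundsError(
                    f"segment {seg.id} (level {seg.level}) leaves the grid; "
                    "enlarge shape_um or shorten segment_length_um"
                )

    lumen = np.zeros((nz, ny, nx), dtype=bool)
    wall = np.zeros_like(lumen)
    sleeve = np.zeros_like(lumen)
    trunk_wall = np.zeros_like(lumen)
    for seg in segments:
        r_wall = seg.radius + spec.wall_thickness_um
        r_out = r_wall + (sleeve_extra if seg.level == 0 and sleeve_extra else 0.0)
        box = _capsule_distance_box(lumen.shape, seg.p0, seg.p1, r_out, voxel_size_um)
        d = _segment_distances(seg.p0, seg.p1, box, voxel_size_um)
        z0, z1, y0, y1, x0, x1 = box
        sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        lumen[sl] |= d <= seg.radius
        seg_wall = (d > seg.radius) & (d <= r_wall)
        wall[sl] |= seg_wall
        if seg.level == 0:
            trunk_wall[sl] |= seg_wall
            if spec.sleeve_thickness_um:
                inner = r_wall + spec.sleeve_gap_um
                sleeve[sl] |= (d > inner) & (d <= inner + spec.sleeve_thickness_um)

    detached = np.zeros_like(lumen)
    if spec.detached_bodies:
        margin = spec.detached_radius_um + spec.wall_thickness_um + sleeve_extra + 8.0
        placed = 0
        for _ in range(500):
            if placed == spec.detached_bodies:
                break
            c = np.array([
                rng.uniform(spec.detached_radius_um + 2, x_um - spec.detached_radius_um - 2),
                rng.uniform(spec.detached_radius_um + 2, y_um - spec.detached_radius_um - 2),
                rng.uniform(spec.detached_radius_um + 2, z_um - spec.detached_radius_um - 2),
            ])
            # keep aggregations well inside the parenchyma (tissue ellipsoid),
            # never floating on the slide background
            ell = (
                ((c[0] - x_um / 2) / (0.49 * x_um)) ** 2
                + ((c[1] - y_um / 2) / (0.49 * y_um)) ** 2
                + ((c[2] - z_um / 2) / (0.60 * z_um)) ** 2
            )
            if ell > 0.55:
                continue
            ok = True
            for seg in segments:
                v = seg.p1 - seg.p0
                t = np.clip(float((c - seg.p0) @ v) / float(v @ v), 0.0, 1.0)
                if np.linalg.norm(c - (seg.p0 + t * v)) < seg.radius + margin:
                    ok = False
                    break
            if not ok:
                continue
            box = _capsule_distance_box(lumen.shape, c, c, spec.detached_radius_um, voxel_size_um)
            d = _segment_distances(c, c, box, voxel_size_um)
            z0, z1, y0, y1, x0, x1 = box
            detached[z0:z1, y0:y1, x0:x1] |= d <= spec.detached_radius_um
            placed += 1
        if placed < spec.detached_bodies:
            raise PhantomBoundsError("could not place all detached bodies; enlarge the grid")

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    tissue = (
        ((xx - cx) / (0.49 * nx)) ** 2
        + ((yy - cy) / (0.49 * ny)) ** 2
        + ((zz - cz) / (0.60 * nz)) ** 2
    ) <= 1.0
    labels[tissue] = TISSUE
    labels[sleeve] = SLEEVE
    labels[wall] = WALL
    labels[detached] = DETACHED
    labels[lumen] = LUMEN

    topology = _topology_record(labels, trunk_wall & (labels == WALL), segments)
    return PhantomGrid(labels=labels, voxel_size_um=voxel_size_um, topology=topology)


def _topology_record(labels, trunk_wall, segments) -> Topology:
    import scipy.ndimage as ndi

    stained = np.isin(labels, STAIN_CLASSES)
    comp, n = ndi.label(stained, structure=ndi.generate_binary_structure(3, 3))
    touches = []
    trunk_ids = set(np.unique(comp[trunk_wall])) - {0}
    for cid in range(1, n + 1):
        touches.append(cid in trunk_ids)
    n_conn = sum(touches)
    return Topology(
        segments=segments,
        n_stained_components=n,
        n_connected_to_trunk=n_conn,
        n_detached=n - n_conn,
        component_touches_trunk=touches,
    )


def virtual_sections(
    grid: PhantomGrid,
    thickness_um: float = 5.0,
    stain: StainModel | None = None,
    seed: int | None = None,
    marker: str | None = "CK19",
) -> tuple[list[SectionImage], list[dict[str, np.ndarray]]]:
    """Cut the phantom into thin sections and render them as stained RGB images.

    ``thickness_um`` must be an integer multiple of the grid's voxel size;
    the section count is exactly z-extent / thickness.  Each section renders,
    per pixel, the most salient class in its slab (stain over lumen over
    tissue over background), then adds Gaussian color noise and Poisson-placed
    dark specks.  Returned ground-truth masks ("stain", "lumen", "tissue")
    are noise-free.
    """
    stain = stain or StainModel()
    ratio = thickness_um / grid.voxel_size_um
    per = int(round(ratio))
    if abs(ratio - per) > 1e-9 or per < 1:
        raise ValueError(
            f"thickness {thickness_um} um is not a multiple of the voxel size "
            f"{grid.voxel_size_um} um"
        )
    nz = grid.labels.shape[0]
    if nz % per != 0:
        raise ValueError("grid z extent is not divisible by the section thickness")
    n_sections = nz // per
    rng = np.random.default_rng(seed)
    h, w = grid.labels.shape[1:]
    area_mm2 = (h * grid.voxel_size_um / 1000.0) * (w * grid.voxel_size_um / 1000.0)

    sections: list[SectionImage] = []
    masks: list[dict[str, np.ndarray]] = []
    for i in range(n_sections):
        slab = grid.labels[i * per : (i + 1) * per]
        stain_mask = np.isin(slab, STAIN_CLASSES).any(axis=0)
        lumen_mask = (slab == LUMEN).any(axis=0) & ~stain_mask
        tissue_mask = (slab == TISSUE).any(axis=0) & ~stain_mask & ~lumen_mask
        img = np.empty((h, w, 3), dtype=float)
        img[:] = stain.background_color
        img[tissue_mask] = stain.counterstain_color
        img[lumen_mask] = stain.lumen_color
        img[stain_mask] = stain.stain_color
        if stain.noise_sigma > 0:
            img += rng.normal(0.0, stain.noise_sigma, img.shape)
        n_specks = rng.poisson(stain.speck_rate * area_mm2) if stain.speck_rate > 0 else 0
        for _ in range(n_specks):
            sy = rng.integers(1, h - 1)
            sx = rng.integers(1, w - 1)
            img[sy - 1 : sy + 2, sx - 1 : sx + 2][
                np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
            ] = stain.speck_color
        sections.append(
            SectionImage(
                pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
                pixel_size_um=grid.voxel_size_um,
                section_index=i,
                thickness_um=thickness_um,
                marker=marker,
            )
        )
        masks.append({"stain": stain_mask, "lumen": lumen_mask, "tissue": tissue_mask})
    return sections, masks


def perturb_alignment(
    sections: list[SectionImage],
    sigma_t_px: float,
    sigma_theta_deg: float,
    seed: int,
    interpolation: str = "nearest",
) -> tuple[list[SectionImage], list[RigidTransform2D]]:
    """Displace each section by a random rigid transform, keeping ground truth.

    Each section is rotated about its center and shifted by draws from
    centered Gaussians (sigma_t_px pixels, sigma_theta_deg degrees).  Returns
    the misaligned sections and, per section, the *correcting* transform — the
    exact inverse of the applied displacement, i.e. what a perfect alignment
    stage should recover.
    """
    if sigma_t_px < 0 or sigma_theta_deg < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[SectionImage] = []
    corrections: list[RigidTransform2D] = []
    for sec in sections:
        theta = math.radians(rng.normal(0.0, sigma_theta_deg))
        tx, ty = rng.normal(0.0, sigma_t_px, 2)
        h, w = sec.shape
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        t = RigidTransform2D.about_center(theta, (tx, ty), center)
        if t.is_identity():
            out.append(sec.with_pixels(sec.pixels.copy()))
        else:
            out.append(resample_section(sec, t, interpolation=interpolation))
        corrections.append(t.inverse())
    return out, corrections
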
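"""Deterministic voxel phantoms and auxiliary ring structures.

The phantoms emulate the geometric situation of pancreatic SBRT planning:
a roughly spherical planning target volume (PTV) abutted by a serial organ
at risk (the duodenum), a distant serial organ (spinal cord) and two lateral
parallel organs (kidneys), all embedded in a water-equivalent body outline.
Concentric ring ("shell") structures around the target are generated to
shape the dose fall-off during optimization.

All lengths are millimetres; voxel indices are 0-based; physical coordinates
refer to voxel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "StructureMask",
    "StructureSet",
    "build_reference_phantom",
    "generate_rings",
    "PRESETS",
]

ROLES = ("target", "oar_serial", "oar_parallel", "ring", "body")


class PhantomConfigError(ValueError):
    """Raised for invalid phantom presets or structure-set configurations."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid: shape (nx, ny, nz), spacing and origin in mm.

    ``origin`` is the physical coordinate of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of physical voxel-center coordinates, C-order flattened."""
        xs, ys, zs = (self.axis_coords(a) for a in range(3))
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    @staticmethod
    def centered(shape: tuple[int, int, int], spacing: float) -> "VoxelGrid":
        """Grid of isotropic spacing with the physical origin at its center."""
        sp = (float(spacing),) * 3
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, sp))
        return VoxelGrid(shape=tuple(shape), spacing=sp, origin=origin)


@dataclass
class StructureMask:
    """Named boolean mask over a grid with a planning role."""

    name: str
    role: str
    mask: np.ndarray  # boolean, grid shape

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; valid roles: {ROLES}")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        """Flat (C-order) voxel indices of the mask."""
        return np.flatnonzero(self.mask.ravel())


@dataclass
class StructureSet:
    """A grid plus an ordered collection of uniquely named structures."""

    grid: VoxelGrid
    structures: list[StructureMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.structures]
        if len(names) != len(set(names)):
            raise ValueError("structure names must be unique")
        for s in self.structures:
            if s.mask.shape != self.grid.shape:
                raise ValueError(f"mask shape {s.mask.shape} of {s.name!r} != grid {self.grid.shape}")

    def __getitem__(self, name: str) -> StructureMask:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.structures)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def add(self, structure: StructureMask) -> None:
        if structure.name in self:
            raise ValueError(f"duplicate structure name {structure.name!r}")
        if structure.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        self.structures.append(structure)

    def by_role(self, role: str) -> list[StructureMask]:
        return [s for s in self.structures if s.role == role]

    @property
    def body(self) -> StructureMask:
        bodies = self.by_role("body")
        if len(bodies) != 1:
            raise ValueError(f"expected exactly one body structure, found {len(bodies)}")
        return bodies[0]

    @property
    def targets(self) -> list[StructureMask]:
        targets = self.by_role("target")
        if not targets:
            raise ValueError("structure set has no target")
        return targets

    @property
    def oars(self) -> list[StructureMask]:
        return [s for s in self.structures if s.role in ("oar_serial", "oar_parallel")]

    @property
    def rings(self) -> list[StructureMask]:
        return self.by_role("ring")

    def validate(self) -> None:
        """Check the structural invariants (one body, >=1 target, containment)."""
        body = self.body
        for t in self.targets:
            if np.any(t.mask & ~body.mask):
                raise ValueError(f"target {t.name!r} is not contained in the body")
        rings = self.rings
        target_union = np.zeros(self.grid.shape, dtype=bool)
        for t in self.targets:
            target_union |= t.mask
        for i, r in enumerate(rings):
            if np.any(r.mask & target_union):
                raise ValueError(f"ring {r.name!r} overlaps a target")
            for r2 in rings[i + 1:]:
                if np.any(r.mask & r2.mask):
                    raise ValueError(f"rings {r.name!r} and {r2.name!r} overlap")


def _ellipsoid(grid: VoxelGrid, center: tuple[float, float, float],
               semi_axes: tuple[float, float, float]) -> np.ndarray:
    """Boolean mask of voxel centers inside an axis-aligned ellipsoid.

    On single-slice (nz == 1) grids the z term is dropped, yielding the
    2D ellipse / infinite elliptic cylinder.
    """
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    q = ((xs - center[0]) / semi_axes[0]) ** 2 + ((ys - center[1]) / semi_axes[1]) ** 2
    if grid.shape[2] > 1:
        q = q + ((zs - center[2]) / semi_axes[2]) ** 2
    else:
        q = np.broadcast_to(q, grid.shape).copy()
    return q <= 1.0


def _sphere(grid: VoxelGrid, center, radius: float) -> np.ndarray:
    return _ellipsoid(grid, center, (radius, radius, radius))


def _tube(grid: VoxelGrid, center_xy: tuple[float, float], radius: float,
          z_half_length: float | None = None) -> np.ndarray:
    """Circular tube along z; optionally limited to |z - 0| <= z_half_length."""
    mask = _ellipsoid(grid, (center_xy[0], center_xy[1], 0.0), (radius, radius, np.inf))
    if z_half_length is not None and grid.shape[2] > 1:
        zs = grid.axis_coords(2)
        mask &= (np.abs(zs) <= z_half_length)[None, None, :]
    return mask


def _build_pancreas(grid: VoxelGrid, seed: int, body_radius: float) -> StructureSet:
    # Jitter of +-1 mm per coordinate keeps the anatomical constraints
    # (abutment gap <= 5 mm, cord stand-off >= 60 mm) with margin.
    rng = np.random.default_rng(seed)
    jit = lambda: float(rng.uniform(-1.0, 1.0))  # noqa: E731

    three_d = grid.shape[2] > 1
    ptv_r = 15.0
    ptv_c = (jit(), jit(), 0.0)

    duo_r = 9.0 if three_d else 10.0
    gap = 2.5  # nominal surface-to-surface gap to the PTV
    duo_c = (ptv_c[0] + ptv_r + gap + duo_r + jit(), ptv_c[1] + jit())

    cord_r = 4.5 if three_d else 5.0
    cord_standoff = 65.0  # nominal surface distance, posterior
    cord_c = (ptv_c[0] + jit(), ptv_c[1] - (ptv_r + cord_standoff + cord_r) + jit())

    kid_semi = (16.0, 24.0, 40.0) if three_d else (18.0, 30.0, np.inf)
    kid_x, kid_y = (80.0, -30.0) if three_d else (85.0, -40.0)

    structures = [
        StructureMask("body", "body", _tube(grid, (0.0, 0.0), body_radius)),
        StructureMask("ptv", "target", _sphere(grid, ptv_c, ptv_r)),
        StructureMask("duodenum", "oar_serial",
                      _tube(grid, duo_c, duo_r, z_half_length=40.0)),
        StructureMask("cord", "oar_serial", _tube(grid, cord_c, cord_r)),
        StructureMask("kidney_l", "oar_parallel",
                      _ellipsoid(grid, (-kid_x + jit(), kid_y + jit(), 0.0), kid_semi)),
        StructureMask("kidney_r", "oar_parallel",
                      _ellipsoid(grid, (kid_x + jit(), kid_y + jit(), 0.0), kid_semi)),
    ]
    ss = StructureSet(grid=grid, structures=structures)
    ss.validate()
    return ss


def _pancreas2d(seed: int) -> StructureSet:
    return _build_pancreas(VoxelGrid.centered((96, 96, 1), 4.0), seed, body_radius=120.0)


def _pancreas3d(seed: int) -> StructureSet:
    return _build_pancreas(VoxelGrid.centered((64, 64, 32), 4.0), seed, body_radius=108.0)


PRESETS = {"pancreas2d": _pancreas2d, "pancreas3d": _pancreas3d}


def build_reference_phantom(preset_name: str, seed: int = 0) -> StructureSet:
    """Build a deterministic reference phantom.

    Parameters
    ----------
    preset_name : str
        Registered preset: ``"pancreas2d"`` (96x96x1 voxels at 4 mm, the fast
        single-slice fixture) or ``"pancreas3d"`` (64x64x32 at 4 mm).
    seed : int
        Controls small (+-1 mm) jitter of the structure centers, emulating
        per-patient anatomical variation; identical (preset, seed) pairs give
        bit-identical masks.
    """
    try:
        builder = PRESETS[preset_name]
    except KeyError:
        raise PhantomConfigError(
            f"unknown phantom preset {preset_name!r}; valid presets: {sorted(PRESETS)}"
        ) from None
    return builder(int(seed))


def target_surface(structures: StructureSet) -> np.ndarray:
    """Boolean mask of target-surface voxels.

    A target voxel is on the surface if at least one of its 6-neighbors is
    not a target voxel (grid-boundary neighbors count as non-target).
    """
    union = np.zeros(structures.grid.shape, dtype=bool)
    for t in structures.targets:
        union |= t.mask
    eroded = ndimage.binary_erosion(union, structure=ndimage.generate_binary_structure(3, 1))
    return union & ~eroded


def distance_to_target(structures: StructureSet) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to the nearest target voxel center.

    For voxels outside the target the nearest target voxel is necessarily a
    surface voxel, so this equals the distance to the target surface.
    """
    union = np.zeros(structures.grid.shape, dtype=bool)
    for t in structures.targets:
        union |= t.mask
    if not union.any():
        raise ValueError("no target voxels; cannot compute target distance")
    return ndimage.distance_transform_edt(~union, sampling=structures.grid.spacing)


def generate_rings(structures: StructureSet, offsets=(5.0, 35.0, 55.0),
                   width: float = 10.0) -> StructureSet:
    """Add concentric ring structures around the target(s).

    Ring ``k`` collects body voxels whose center lies at a distance
    ``offsets[k] <= d < offsets[k] + width`` (mm) from the target surface,
    excluding target voxels and voxels already claimed by an earlier ring.
    Rings may overlap organs at risk. Empty rings are dropped with a warning.
    """
    offsets = [float(o) for o in offsets]
    if any(b <= a for a, b in zip(offsets, offsets[1:])):
        raise ValueError(f"ring offsets must be strictly increasing, got {offsets}")
    if width <= 0:
        raise ValueError(f"ring width must be positive, got {width}")

    dist = distance_to_target(structures)
    body = structures.body.mask
    target_union = np.zeros(structures.grid.shape, dtype=bool)
    for t in structures.targets:
        target_union |= t.mask

    out = StructureSet(grid=structures.grid, structures=list(structures.structures))
    claimed = target_union.copy()
    ring_idx = 0
    for k, off in enumerate(offsets, start=1):
        ring = body & (dist >= off) & (dist < off + width) & ~claimed
        if not ring.any():
            warnings.warn(f"ring at offset {off} mm is empty and was dropped", stacklevel=2)
            continue
        ring_idx += 1
        out.add(StructureMask(f"ring_{ring_idx}", "ring", ring))
        claimed |= ring
    return out
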
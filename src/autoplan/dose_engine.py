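"""Simplified linear beamlet dose model (pencil-beam surrogate).

Dose is linear in beamlet fluence: ``d = D x`` with ``D`` a sparse
dose-influence matrix over grid voxels and beamlets. Each beamlet deposits

    dose(depth, r) = C * exp(-mu * depth) * exp(-r^2 / (2 sigma_p^2))

where ``depth`` is the water-equivalent path length (mm) inside the body
along the (parallel) beamlet axis, ``r`` the lateral distance (mm) from the
axis, ``mu = 0.005 /mm`` an effective 6 MV attenuation coefficient,
``sigma_p = 0.6 * beamlet_width`` the lateral pencil-beam spread, and ``C``
calibrated so a unit-fluence beamlet deposits 1 Gy at 100 mm depth on axis.
The body is homogeneous water; arcs are emulated by a dense set of
equispaced coplanar static beams.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .phantoms import StructureSet, VoxelGrid

__all__ = [
    "BeamletBasis",
    "DoseInfluenceMatrix",
    "make_beams",
    "compute_dose_influence",
    "dose_from_fluence",
    "beamlet_dose_kernel",
    "save_dose_influence",
    "load_dose_influence",
]

MU_WATER = 0.005          # /mm, effective attenuation
SIGMA_FACTOR = 0.6        # sigma_p = SIGMA_FACTOR * beamlet_width
CALIBRATION_DEPTH = 100.0  # mm; unit fluence -> 1 Gy on axis at this depth
TRUNCATION = 1e-4         # drop entries below this fraction of the beamlet max


@dataclass(frozen=True)
class BeamletBasis:
    """Coplanar equispaced beams, each a rectangular grid of parallel beamlets.

    ``lateral_offsets`` (in-plane, perpendicular to the beam axis) and
    ``z_offsets`` are shared by all beams and expressed in mm at the
    isocenter; single-slice grids use a single z offset of 0.
    """

    gantry_angles: tuple[float, ...]
    lateral_offsets: tuple[float, ...]
    z_offsets: tuple[float, ...]
    beamlet_width: float
    isocenter: tuple[float, float, float]
    source_distance: float = 1000.0

    def __post_init__(self) -> None:
        if len(self.gantry_angles) < 2:
            raise ValueError("at least 2 beams are required")
        if self.beamlet_width <= 0:
            raise ValueError("beamlet_width must be positive")

    @property
    def n_beams(self) -> int:
        return len(self.gantry_angles)

    @property
    def beamlets_per_beam(self) -> int:
        return len(self.lateral_offsets) * len(self.z_offsets)

    @property
    def n_beamlets(self) -> int:
        return self.n_beams * self.beamlets_per_beam

    def beam_axes(self, angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unit propagation direction and the two transverse axes of one beam.

        Gantry angle 0 means the beam enters from +y travelling toward -y;
        angles increase clockwise when viewed from +z.
        """
        th = np.deg2rad(angle_deg)
        u = np.array([np.sin(th), -np.cos(th), 0.0])      # propagation
        v = np.array([np.cos(th), np.sin(th), 0.0])       # in-plane lateral
        w = np.array([0.0, 0.0, 1.0])
        return u, v, w


def make_beams(n_beams: int, structures: StructureSet, beamlet_width: float = 4.0,
               margin: float = 10.0) -> BeamletBasis:
    """Equispace ``n_beams`` coplanar beams over 360 degrees around the target.

    The beamlet fan of every beam covers the target cross-section plus
    ``margin`` mm on each side at the isocenter (the target centroid).
    """
    if n_beams < 2:
        raise ValueError(f"at least 2 beams are required, got {n_beams}")
    angles = tuple(360.0 * k / n_beams for k in range(n_beams))

    centers = structures.grid.voxel_centers()
    tmask = np.zeros(structures.grid.n_voxels, dtype=bool)
    for t in structures.targets:
        tmask[t.indices] = True
    tpts = centers[tmask]
    iso = tpts.mean(axis=0)

    def _offsets(half_extent: float) -> tuple[float, ...]:
        n = max(1, int(np.ceil(2.0 * half_extent / beamlet_width)))
        return tuple((np.arange(n) - (n - 1) / 2.0) * beamlet_width)

    r_plane = np.sqrt(((tpts[:, :2] - iso[:2]) ** 2).sum(axis=1)).max()
    lateral = _offsets(r_plane + margin)
    if structures.grid.shape[2] > 1:
        z_half = np.abs(tpts[:, 2] - iso[2]).max() + margin
        z_off = _offsets(z_half)
    else:
        z_off = (0.0,)
    return BeamletBasis(gantry_angles=angles, lateral_offsets=lateral, z_offsets=z_off,
                        beamlet_width=beamlet_width, isocenter=tuple(iso))


@dataclass
class DoseInfluenceMatrix:
    """Sparse beamlet-to-voxel dose operator (Gy per unit fluence)."""

    matrix: sparse.csr_matrix  # (n_grid_voxels, n_beamlets)
    grid: VoxelGrid
    basis: BeamletBasis

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]


def beamlet_dose_kernel(depth: np.ndarray, lateral_r2: np.ndarray,
                        beamlet_width: float, mu: float = MU_WATER) -> np.ndarray:
    """Pencil-beam dose kernel: attenuation times lateral Gaussian."""
    sigma = SIGMA_FACTOR * beamlet_width
    c = np.exp(mu * CALIBRATION_DEPTH)
    return c * np.exp(-mu * np.asarray(depth)) * np.exp(-np.asarray(lateral_r2) / (2.0 * sigma ** 2))


def _radiological_depth(grid: VoxelGrid, body: np.ndarray, points: np.ndarray,
                        direction: np.ndarray, step: float = 2.0,
                        chunk: int = 20000) -> np.ndarray:
    """Water-equivalent path length (mm) upstream of each point along -direction.

    Computed by ray marching with ``step`` mm sampling of the body mask
    (nearest-voxel lookup); counts all body material traversed, which for the
    convex phantom bodies equals depth from the entry surface.
    """
    extent = np.linalg.norm(np.asarray(grid.shape) * np.asarray(grid.spacing))
    ts = np.arange(step, extent + step, step)
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)

    depth = np.empty(points.shape[0])
    for lo in range(0, points.shape[0], chunk):
        pts = points[lo:lo + chunk]
        # (n, T, 3) sample positions marching upstream
        pos = pts[:, None, :] - direction[None, None, :] * ts[None, :, None]
        idx = np.rint((pos - origin) / spacing).astype(np.int64)
        valid = np.all((idx >= 0) & (idx < shape), axis=2)
        idx_clipped = np.clip(idx, 0, shape - 1)
        inside = body[idx_clipped[..., 0], idx_clipped[..., 1], idx_clipped[..., 2]] & valid
        depth[lo:lo + chunk] = inside.sum(axis=1) * step
    return depth


def compute_dose_influence(basis: BeamletBasis, structures: StructureSet,
                           mu: float = MU_WATER, truncation: float = TRUNCATION,
                           step: float = 2.0) -> DoseInfluenceMatrix:
    """Assemble the sparse dose-influence matrix on the phantom grid.

    Dose is deposited only inside the body; entries smaller than
    ``truncation`` times the beamlet's maximum are dropped for sparsity.
    """
    grid = structures.grid
    body = structures.body.mask
    if not body.any():
        raise ValueError("body mask is empty")
    body_idx = np.flatnonzero(body.ravel())
    pts = grid.voxel_centers()[body_idx]
    iso = np.asarray(basis.isocenter)

    cols: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b = 0
    for angle in basis.gantry_angles:
        u, v, w = basis.beam_axes(angle)
        depth = _radiological_depth(grid, body, pts, u, step=step)
        atten = beamlet_dose_kernel(depth, np.zeros_like(depth), basis.beamlet_width, mu=mu)
        s_lat = (pts - iso) @ v
        s_z = (pts - iso) @ w
        sigma = SIGMA_FACTOR * basis.beamlet_width
        for oz in basis.z_offsets:
            gz = np.exp(-((s_z - oz) ** 2) / (2.0 * sigma ** 2))
            for ol in basis.lateral_offsets:
                gl = np.exp(-((s_lat - ol) ** 2) / (2.0 * sigma ** 2))
                dose = atten * gz * gl
                dmax = dose.max() if dose.size else 0.0
                if dmax <= 0.0:
                    warnings.warn(f"beamlet {b} misses the body entirely", stacklevel=2)
                    b += 1
                    continue
                keep = dose >= truncation * dmax
                rows.append(body_idx[keep])
                cols.append(np.full(keep.sum(), b, dtype=np.int64))
                vals.append(dose[keep])
                b += 1

    if vals:
        data = np.concatenate(vals)
        rix = np.concatenate(rows)
        cix = np.concatenate(cols)
    else:  # pragma: no cover - every beamlet missed the body
        data = rix = cix = np.empty(0)
    mat = sparse.csr_matrix((data, (rix, cix)),
                            shape=(grid.n_voxels, basis.n_beamlets))
    return DoseInfluenceMatrix(matrix=mat, grid=grid, basis=basis)


def dose_from_fluence(dim: DoseInfluenceMatrix, fluence: np.ndarray) -> np.ndarray:
    """Total plan dose (Gy) per grid voxel for a non-negative fluence map."""
    x = np.asarray(fluence, dtype=float)
    if x.shape != (dim.n_beamlets,):
        raise ValueError(f"fluence shape {x.shape} != ({dim.n_beamlets},)")
    if np.any(x < 0):
        raise ValueError("fluence must be non-negative")
    return dim.matrix @ x


def save_dose_influence(path, dim: DoseInfluenceMatrix) -> None:
    """Persist the matrix in HDF5 (COO triplets + JSON metadata attrs)."""
    import h5py

    coo = dim.matrix.tocoo()
    meta = {
        "grid": {"shape": dim.grid.shape, "spacing": dim.grid.spacing, "origin": dim.grid.origin},
        "basis": {
            "gantry_angles": dim.basis.gantry_angles,
            "lateral_offsets": dim.basis.lateral_offsets,
            "z_offsets": dim.basis.z_offsets,
            "beamlet_width": dim.basis.beamlet_width,
            "isocenter": dim.basis.isocenter,
            "source_distance": dim.basis.source_distance,
        },
        "shape": dim.matrix.shape,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("row", data=coo.row)
        f.create_dataset("col", data=coo.col)
        f.create_dataset("data", data=coo.data)
        f.attrs["meta"] = json.dumps(meta)


def load_dose_influence(path) -> DoseInfluenceMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        mat = sparse.csr_matrix(
            (f["data"][:], (f["row"][:], f["col"][:])), shape=tuple(meta["shape"])
        )
    grid = VoxelGrid(shape=tuple(meta["grid"]["shape"]),
                     spacing=tuple(meta["grid"]["spacing"]),
                     origin=tuple(meta["grid"]["origin"]))
    bm = meta["basis"]
    basis = BeamletBasis(gantry_angles=tuple(bm["gantry_angles"]),
                         lateral_offsets=tuple(bm["lateral_offsets"]),
                         z_offsets=tuple(bm["z_offsets"]),
                         beamlet_width=bm["beamlet_width"],
                         isocenter=tuple(bm["isocenter"]),
                         source_distance=bm["source_distance"])
    return DoseInfluenceMatrix(matrix=mat, grid=grid, basis=basis)
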
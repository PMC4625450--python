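"""Cross-sectional area profiling of a segmented 3D mandible model.

The voxel model is divided into six equal-length sections along its long
axis, from the distal tip toward the base, and the cross-sectional area
at the four distal-most section boundaries (1/6, 2/6, 3/6, 4/6 of the
axial extent) is reported, each as a percentage of the area at the 4/6
position.  A slim distal incisor shows up as small 1/6-3/6 percentages.

Conventions (the acquisition pipeline does not dictate them):

* the long axis is the dominant eigenvector of the occupied-voxel second
  moment matrix, overridable;
* the distal tip is the end with the smaller local cross-section
  (mandibles have a slim distal incisor), overridable;
* a "position" is a planar cross-section: after rotation-resampling the
  grid so the axis is grid-aligned, the area is the occupied voxel count
  of the one-voxel-thick slab at that position times the in-plane voxel
  area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "VoxelModel",
    "SectionProfile",
    "load_voxels",
    "principal_axis",
    "section_areas",
    "area_ratios",
]


@dataclass
class VoxelModel:
    """Binary occupancy grid with isotropic voxel spacing."""

    grid: np.ndarray          # 3D boolean
    spacing: float = 1.0      # physical units per voxel edge

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3D")
        if not self.grid.any():
            raise ValueError("empty voxel model")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class SectionProfile:
    axis: np.ndarray                  # unit 3-vector, tip -> base
    positions: tuple[float, ...]      # fractions of axial extent from the tip
    areas: dict[float, float]         # position -> area (spacing^2 units)
    ratios: dict[float, float]        # position -> % of the 4/6 (last) area


def load_voxels(path: str | Path, spacing: float = 1.0) -> VoxelModel:
    """Load a voxel model from a multipage TIFF stack or a .npy array."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        grid = np.load(path)
    else:
        import tifffile
        grid = tifffile.imread(str(path))
    return VoxelModel(grid=grid > 0, spacing=spacing)


def principal_axis(model: VoxelModel,
                   tip_override: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Long axis of the model, oriented from the distal tip to the base.

    Returns ``(axis, centroid)`` in voxel-index coordinates.  The axis is
    the dominant eigenvector of the second-moment (covariance) matrix of
    occupied voxel centers.  Tip disambiguation: the end with the smaller
    nearby occupied cross-section is the tip; ``tip_override`` (+1 or -1)
    forces the orientation instead.
    """
    pts = np.argwhere(model.grid).astype(float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[-1] > 0 and (eigval[-1] - eigval[-2]) / eigval[-1] < 0.05:
        log.warning("no dominant axis: top eigenvalues within 5%% "
                    "(%.3g vs %.3g)", eigval[-1], eigval[-2])
    axis = eigvec[:, -1]
    proj = (pts - centroid) @ axis
    lo, hi = proj.min(), proj.max()
    slab = max((hi - lo) * 0.05, 1.0)
    n_lo = int(np.sum(proj <= lo + slab))
    n_hi = int(np.sum(proj >= hi - slab))
    if tip_override is not None:
        sign = 1.0 if tip_override > 0 else -1.0
    else:
        # orient so the slimmer end sits at negative projections (the tip)
        sign = 1.0 if n_lo <= n_hi else -1.0
    return axis * sign, centroid


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ``axis`` to the +z grid direction (axis 0)."""
    a = axis / np.linalg.norm(axis)
    z = np.array([1.0, 0.0, 0.0])  # numpy axis 0 plays the role of z
    v = np.cross(a, z)
    c = float(a @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _axis_aligned_grid(model: VoxelModel, axis: np.ndarray,
                       centroid: np.ndarray) -> np.ndarray:
    """Nearest-neighbour resample of the grid with ``axis`` mapped to grid
    axis 0."""
    rot = _rotation_to_z(axis)
    # cube large enough that no voxel clips: the centroid need not be the
    # midpoint of the extent (mass can concentrate toward the base)
    corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
                       ) * (np.asarray(model.grid.shape) - 1)
    half = int(np.ceil(np.max(np.linalg.norm(corners - centroid, axis=1)))) + 2
    n_out = 2 * half + 1
    c_out = np.full(3, half, dtype=float)
    # output[y] = input[R^T (y - c_out) + centroid]
    matrix = rot.T
    offset = centroid - matrix @ c_out
    out = ndimage.affine_transform(model.grid.astype(np.uint8), matrix,
                                   offset=offset, output_shape=(n_out,) * 3,
                                   order=0, prefilter=False)
    return out.astype(bool)


def section_areas(model: VoxelModel, n_sections: int = 6,
                  axis: np.ndarray | None = None,
                  tip_override: int | None = None) -> SectionProfile:
    """Divide the occupied axial extent into ``n_sections`` equal sections
    from tip to base and measure the planar cross-sectional area at the
    distal section boundaries i/n, i = 1..4 (i = 1..n-2 for other n)."""
    if axis is None:
        axis, centroid = principal_axis(model, tip_override=tip_override)
    else:
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        centroid = np.argwhere(model.grid).astype(float).mean(axis=0)
    aligned = _axis_aligned_grid(model, axis, centroid)
    occ_per_slice = aligned.sum(axis=(1, 2))
    nz = np.nonzero(occ_per_slice)[0]
    zmin, zmax = int(nz[0]), int(nz[-1])
    if zmax - zmin + 1 < n_sections:
        raise ValueError(
            f"axial extent ({zmax - zmin + 1} voxels) shorter than "
            f"{n_sections} sections; increase resolution")
    n_top = min(4, n_sections - 2)
    fracs = tuple((i + 1) / n_sections for i in range(n_top))
    areas: dict[float, float] = {}
    for f in fracs:
        z = int(round(zmin + f * (zmax - zmin)))
        areas[f] = float(occ_per_slice[z]) * model.spacing ** 2
    profile = SectionProfile(axis=axis, positions=fracs, areas=areas, ratios={})
    profile.ratios = area_ratios(profile)
    return profile


def area_ratios(profile: SectionProfile) -> dict[float, float]:
    """Each position's area as a percentage of the last (4/6) position."""
    ref = profile.areas[profile.positions[-1]]
    if ref <= 0:
        raise ValueError("zero reference area at the proximal position")
    return {p: 100.0 * a / ref for p, a in profile.areas.items()}
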
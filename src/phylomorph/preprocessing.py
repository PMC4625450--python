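"""Outline preprocessing: equal arc-length semi-landmark resampling.

A digitized mandible outline (an ordered polyline of arbitrarily many
points) is converted into a fixed-count configuration of semi-landmarks
placed at equal arc-length spacing along the polyline, endpoints anchored
to the curve endpoints.  No spline smoothing and no semi-landmark sliding
is applied: resampled points are treated as fixed landmarks downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .io_formats import RawCurve

__all__ = [
    "LandmarkConfiguration",
    "OrientationPolicy",
    "resample_curve",
    "standardize_orientation",
    "signed_area",
]


class DegenerateInputError(ValueError):
    pass


@dataclass
class LandmarkConfiguration:
    """An ordered set of k 2D semi-landmarks for one specimen.

    ``centroid_size`` is the root summed squared distance of the landmarks
    from their centroid; it is populated by ``procrustes.center_and_scale``
    with the pre-scaling size and left ``None`` for raw configurations.
    """

    specimen_id: str
    coords: np.ndarray  # (k, 2)
    centroid_size: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if self.coords.shape[0] < 3:
            raise ValueError("a configuration needs k >= 3 landmarks")
        if np.isnan(self.coords).any():
            raise ValueError(f"{self.specimen_id!r}: NaN in coordinates")
        if np.allclose(self.coords, self.coords[0]):
            raise DegenerateInputError(
                f"{self.specimen_id!r}: all landmarks coincident")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def copy_with(self, coords: np.ndarray,
                  centroid_size: float | None = None) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            specimen_id=self.specimen_id, coords=np.asarray(coords, float),
            centroid_size=self.centroid_size if centroid_size is None else centroid_size)


class OrientationPolicy(str, Enum):
    NONE = "none"
    FORCE_CCW_SIGNED_AREA = "force_ccw_signed_area"
    REFLECT_X = "reflect_x"


def resample_curve(curve: RawCurve, k: int = 50) -> LandmarkConfiguration:
    """Resample a polyline into ``k`` points at equal arc-length spacing.

    The first and last output points coincide with the curve endpoints and
    point order preserves the digitization direction.  Linear interpolation
    along the polyline; duplicated consecutive input points are harmless.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    pts = np.asarray(curve.points, dtype=float)
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seglen.sum()
    if total <= 0:
        raise DegenerateInputError(f"{curve.specimen_id!r}: zero-length curve")
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, total, k)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    coords = np.column_stack([x, y])
    coords[0], coords[-1] = pts[0], pts[-1]  # anchor endpoints exactly
    return LandmarkConfiguration(specimen_id=curve.specimen_id, coords=coords)


def signed_area(coords: np.ndarray) -> float:
    """Shoelace signed area of the polygon obtained by closing the outline."""
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def standardize_orientation(
    config: LandmarkConfiguration,
    policy: OrientationPolicy | str = OrientationPolicy.NONE,
) -> LandmarkConfiguration:
    """Make left/right outlines comparable before superimposition.

    ``force_ccw_signed_area`` reflects the configuration across the x axis
    whenever the closed outline's signed area is negative, so the result
    always has non-negative (counter-clockwise) signed area; idempotent.
    ``reflect_x`` unconditionally reflects; ``none`` is the identity.
    """
    policy = OrientationPolicy(policy)
    if policy is OrientationPolicy.NONE:
        return config
    if policy is OrientationPolicy.REFLECT_X:
        return config.copy_with(config.coords * np.array([1.0, -1.0]))
    if signed_area(config.coords) < 0:
        return config.copy_with(config.coords * np.array([1.0, -1.0]))
    return config
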
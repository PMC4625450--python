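"""Generalized Procrustes analysis for 2D landmark configurations.

Superimposition removes translation (centering), size (unit centroid
size) and rotation (least-squares optimal rotation against the running
consensus).  Reflections are disallowed by default: mandibles are chiral,
and silently reflecting a left outline onto a right one would fabricate
similarity; set ``allow_reflection=True` only for deliberately mirrored
comparisons.

Shape coordinates are obtained by orthogonal projection of the aligned,
flattened configurations onto the tangent space of shape space at the
consensus, the standard linearization used for PCA/CVA of Procrustes
shape data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import DegenerateInputError, LandmarkConfiguration

__all__ = [
    "AlignedSample",
    "centroid_size",
    "center_and_scale",
    "optimal_rotation_matrix",
    "optimal_rotation",
    "gpa",
    "procrustes_distance",
    "mean_shape",
]


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distances of the landmarks from their centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(c * c)))


def center_and_scale(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Translate the centroid to the origin and scale to unit centroid size.

    The pre-scaling centroid size is stored on the returned configuration.
    """
    centered = config.coords - config.coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered * centered)))
    if size <= 0:
        raise DegenerateInputError(
            f"{config.specimen_id!r}: zero centroid size (coincident points)")
    return config.copy_with(centered / size, centroid_size=size)


def optimal_rotation_matrix(coords: np.ndarray, reference: np.ndarray,
                            allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal 2x2 matrix R (det +1 unless reflections allowed) minimizing
    ``||coords @ R - reference||_F`` for centered configurations."""
    h = coords.T @ reference
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def optimal_rotation(config: LandmarkConfiguration,
                     reference: LandmarkConfiguration,
                     allow_reflection: bool = False) -> LandmarkConfiguration:
    """Rotate ``config`` onto ``reference`` (both assumed centered)."""
    if config.k != reference.k:
        raise ValueError(
            f"landmark count mismatch: {config.k} vs {reference.k}")
    r = optimal_rotation_matrix(config.coords, reference.coords,
                                allow_reflection=allow_reflection)
    return config.copy_with(config.coords @ r)


@dataclass
class AlignedSample:
    """A Procrustes-superimposed sample.

    configs
        Aligned configurations: centered, unit centroid size, rotated to
        the consensus.  Order matches the input.
    consensus
        The unit-size mean configuration the sample is aligned to.
    tangent_coords
        (n, 2k) matrix of tangent-space shape coordinates: each aligned
        configuration flattened and orthogonally projected onto the plane
        normal to the consensus direction.  Their sample mean is the zero
        vector up to the convergence tolerance.
    """

    configs: list[LandmarkConfiguration]
    consensus: LandmarkConfiguration
    tangent_coords: np.ndarray
    iterations_used: int
    converged: bool

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configs]

    def index_of(self, specimen_id: str) -> int:
        return self.specimen_ids.index(specimen_id)


def tangent_project(flat_coords: np.ndarray, consensus_flat: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the tangent space at the consensus.

    Linear in its first argument, which the ancestral-shape projection
    relies on.
    """
    c = consensus_flat / np.linalg.norm(consensus_flat)
    x = np.atleast_2d(flat_coords)
    out = x - np.outer(x @ c, c)
    return out if flat_coords.ndim == 2 else out[0]


def gpa(configs: list[LandmarkConfiguration], tol: float = 1e-10,
        max_iter: int = 100, allow_reflection: bool = False,
        project_tangent: bool = True) -> AlignedSample:
    """Iterative generalized Procrustes superimposition.

    All configurations are centered and scaled to unit centroid size, then
    repeatedly rotated to the running consensus (initially the first
    configuration); the consensus is the coordinate-wise mean rescaled to
    unit size.  Iteration stops when the Procrustes distance between
    successive consensuses drops below ``tol``; non-convergence within
    ``max_iter`` iterations is flagged, not raised.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = configs[0].k
    if any(c.k != k for c in configs):
        raise ValueError("all configurations must share the landmark count")
    scaled = [center_and_scale(c) for c in configs]
    coords = np.stack([c.coords for c in scaled])  # (n, k, 2)
    consensus = coords[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(coords)):
            r = optimal_rotation_matrix(coords[i], consensus,
                                        allow_reflection=allow_reflection)
            coords[i] = coords[i] @ r
        new_consensus = coords.mean(axis=0)
        new_consensus /= np.sqrt(np.sum(new_consensus ** 2))
        delta = procrustes_distance_coords(consensus, new_consensus,
                                           allow_reflection=allow_reflection)
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    aligned = [c.copy_with(coords[i]) for i, c in enumerate(scaled)]
    flat = coords.reshape(len(coords), -1)
    cons_flat = consensus.reshape(-1)
    tangent = tangent_project(flat, cons_flat) if project_tangent \
        else flat - cons_flat
    cons_cfg = LandmarkConfiguration("consensus", consensus, centroid_size=1.0)
    return AlignedSample(configs=aligned, consensus=cons_cfg,
                         tangent_coords=tangent,
                         iterations_used=iterations, converged=converged)


def procrustes_distance_coords(a: np.ndarray, b: np.ndarray,
                               allow_reflection: bool = False) -> float:
    """Partial Procrustes distance between two raw coordinate arrays."""
    ac = a - a.mean(axis=0)
    ac /= np.sqrt(np.sum(ac ** 2))
    bc = b - b.mean(axis=0)
    bc /= np.sqrt(np.sum(bc ** 2))
    r = optimal_rotation_matrix(ac, bc, allow_reflection=allow_reflection)
    return float(np.linalg.norm(ac @ r - bc))


def procrustes_distance(a: LandmarkConfiguration, b: LandmarkConfiguration,
                        allow_reflection: bool = False) -> float:
    """Root of the minimized summed squared differences after centering,
    unit scaling and optimal rotation (partial Procrustes distance)."""
    if a.k != b.k:
        raise ValueError(f"landmark count mismatch: {a.k} vs {b.k}")
    return procrustes_distance_coords(a.coords, b.coords,
                                      allow_reflection=allow_reflection)


def mean_shape(configs: list[LandmarkConfiguration],
               weights: np.ndarray | None = None,
               specimen_id: str = "mean") -> LandmarkConfiguration:
    """Coordinate-wise (weighted) mean of aligned configurations, rescaled
    to unit centroid size.  Inputs must already be superimposed."""
    if len(configs) == 0:
        raise ValueError("mean_shape of an empty set")
    coords = np.stack([c.coords for c in configs])
    m = np.average(coords, axis=0, weights=weights)
    m = m - m.mean(axis=0)
    size = np.sqrt(np.sum(m ** 2))
    if size <= 0:
        raise DegenerateInputError("degenerate mean shape")
    return LandmarkConfiguration(specimen_id, m / size, centroid_size=1.0)
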
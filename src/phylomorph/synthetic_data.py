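"""Synthetic inputs with known ground truth for every pipeline stage.

The specimen data behind the original mandible study are not deposited,
so verification rests on generated data: three feeding-type groups of
50-point outline configurations with distinct mean shapes and isotropic
within-group noise; Brownian-motion shape evolution on a tree with known
internal-node states; and analytic voxel solids for the cross-section
module.  All generators are pure functions of (parameters, seed).

The three template outlines encode the qualitative contrasts of the real
feeding types: an elongate, narrow, distally slim blade (coprophagy), a
shorter outline with a strongly curved hooked tip (phytophagy), and a
short broad blunt outline (omnivory).

Default study size is 3 groups x 30 specimens spread over 5 terminals
per group (a desk-scale stand-in for the 187-specimen, 50-terminal
original design), with isotropic within-group noise sd 0.02 per
coordinate in shape space, which puts the per-group total shape variance
in the few-percent range typical of this kind of data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_formats import FeedingType, RawCurve, SpecimenMeta
from .phylo_ancestral import LabeledTree
from .preprocessing import LandmarkConfiguration, resample_curve
from .procrustes import center_and_scale

__all__ = [
    "GroupModel",
    "BmModel",
    "template_shapes",
    "sample_groups",
    "simulate_bm",
    "make_solid",
    "three_group_tree_newick",
    "star_tree",
]

_TYPES = [FeedingType.OM, FeedingType.PH, FeedingType.CO]


def _blade_outline(length: float, width: float, hook: float,
                   taper: str, n_dense: int = 400) -> np.ndarray:
    """Open outline of a blade: up the upper margin from base to tip, back
    along the lower margin.  ``taper`` controls the width profile."""
    s = np.linspace(0.0, 1.0, n_dense)
    x = length * s
    y_spine = hook * s ** 2
    if taper == "linear":
        w = width * (1.0 - 0.95 * s)
    elif taper == "blunt":
        w = width * np.sqrt(np.clip(1.0 - s ** 2, 0.0, None))
    else:
        raise ValueError(f"unknown taper {taper!r}")
    upper = np.column_stack([x, y_spine + w / 2])
    lower = np.column_stack([x, y_spine - w / 2])[::-1]
    return np.concatenate([upper, lower[1:]])


def template_shapes(k: int = 50) -> dict[FeedingType, LandmarkConfiguration]:
    """Deterministic mean outlines for the three feeding types, resampled
    to ``k`` semi-landmarks and standardized to unit centroid size.

    The coprophagous template has a larger length/width aspect ratio than
    either other template, and all pairwise Procrustes distances exceed
    0.1 — comfortably larger than the default within-group noise.
    """
    specs = {
        FeedingType.CO: dict(length=3.0, width=0.45, hook=0.05, taper="linear"),
        FeedingType.PH: dict(length=1.4, width=0.50, hook=0.90, taper="linear"),
        FeedingType.OM: dict(length=1.2, width=0.90, hook=0.15, taper="blunt"),
    }
    out = {}
    for ft, kw in specs.items():
        curve = RawCurve(specimen_id=f"template_{ft.value}",
                         points=_blade_outline(**kw))
        cfg = center_and_scale(resample_curve(curve, k=k))
        cfg.specimen_id = f"template_{ft.value}"
        out[ft] = cfg
    return out


@dataclass
class GroupModel:
    """Three feeding-type groups with isotropic within-group shape noise."""

    mean_shapes: dict[FeedingType, LandmarkConfiguration] = field(
        default_factory=template_shapes)
    within_sd: float = 0.02
    n_per_group: int = 30
    terminals_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_sd <= 0:
            raise ValueError("within_sd must be > 0")


def sample_groups(model: GroupModel
                  ) -> tuple[list[LandmarkConfiguration], list[SpecimenMeta]]:
    """Draw specimens: group mean + isotropic Gaussian perturbation of each
    coordinate (sd = ``within_sd``), re-centered and rescaled to unit
    centroid size.  Specimens are assigned round-robin to
    ``terminals_per_group`` terminals per group (standing in for genera).
    """
    rng = np.random.default_rng(model.seed)
    configs: list[LandmarkConfiguration] = []
    meta: list[SpecimenMeta] = []
    for ft in _TYPES:
        mean = model.mean_shapes[ft]
        noise = rng.normal(0.0, model.within_sd,
                           size=(model.n_per_group,) + mean.coords.shape)
        for i in range(model.n_per_group):
            sid = f"{ft.value}_{i:03d}"
            cfg = center_and_scale(LandmarkConfiguration(
                sid, mean.coords + noise[i]))
            configs.append(cfg)
            term = f"{ft.value}_t{i % model.terminals_per_group + 1}"
            meta.append(SpecimenMeta(specimen_id=sid, taxon=f"{term}_sp{i}",
                                     terminal=term, feeding_type=ft))
    return configs, meta


def _ladder(labels: list[str]) -> str:
    clause = labels[0]
    for lab in labels[1:]:
        clause = f"({clause},{lab})"
    return clause


def three_group_tree_newick(terminals_per_group: int = 5) -> str:
    """Rooted newick over the synthetic terminals, one clade per feeding
    type: ((CO clade, PH clade), OM clade)."""
    clades = {ft: _ladder([f"{ft.value}_t{j + 1}"
                           for j in range(terminals_per_group)])
              for ft in _TYPES}
    return (f"(({clades[FeedingType.CO]},{clades[FeedingType.PH]}),"
            f"{clades[FeedingType.OM]});")


def star_tree(n_tips: int, prefix: str = "t") -> dendropy.Tree:
    newick = "(" + ",".join(f"{prefix}{i}" for i in range(n_tips)) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


@dataclass
class BmModel:
    """Brownian-motion shape evolution: each branch adds an independent
    Gaussian step of per-coordinate variance ``rate`` x branch length
    (all lengths equal 1, matching the reconstruction's model)."""

    tree: dendropy.Tree
    root_shape: LandmarkConfiguration
    rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")


def simulate_bm(model: BmModel
                ) -> tuple[LabeledTree, dict[str, LandmarkConfiguration]]:
    """Simulate trait evolution down the tree.

    Returns the :class:`LabeledTree` whose tips carry the simulated
    shapes (the pipeline input) and the true internal-node states keyed
    by node id (the evaluation target, including the root).
    """
    rng = np.random.default_rng(model.seed)
    tree = model.tree
    states: dict[int, np.ndarray] = {}
    shape = model.root_shape.coords.shape
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = model.root_shape.coords.copy()
        else:
            step = rng.normal(0.0, np.sqrt(model.rate), size=shape)
            states[id(node)] = states[id(node.parent_node)] + step
    tip_shapes = {leaf.taxon.label: LandmarkConfiguration(
                      leaf.taxon.label, states[id(leaf)])
                  for leaf in tree.leaf_node_iter()}
    ltree = LabeledTree(tree, tip_shapes)
    true_internal = {
        node.node_id: LandmarkConfiguration(node.node_id, states[id(node)])
        for node in tree.postorder_internal_node_iter()}
    return ltree, true_internal


# ---------------------------------------------------------------------------
# Voxel solids

def make_solid(kind: str, dims: dict[str, float], resolution: int = 64,
               rotation: np.ndarray | None = None,
               translation: np.ndarray | None = None):
    """Exact-geometry voxelization of an analytic solid.

    kind
        ``cylinder`` (radius, height), ``cone`` (radius, height; apex at
        the tip end) or ``tapered_blade`` (length, width, thickness; a
        flat blade whose cross-section shrinks toward the tip, mimicking
        a distally slim mandible).
    resolution
        Number of voxels along the solid's own axis (>= 32).
    rotation, translation
        Optional rigid pose applied to the solid before voxelization.

    A voxel is occupied iff its center lies inside the posed solid.
    Returns a :class:`~phylomorph.cross_section.VoxelModel`.
    """
    from .cross_section import VoxelModel

    if resolution < 32:
        raise ValueError("resolution must be >= 32 voxels along the axis")
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    trans = np.zeros(3) if translation is None else np.asarray(translation, float)

    if kind == "cylinder":
        r, h = dims["radius"], dims["height"]
        bbox = np.array([[0.0, h], [-r, r], [-r, r]])
        def inside(z, x, y):
            return (z >= 0) & (z <= h) & (x ** 2 + y ** 2 <= r ** 2)
    elif kind == "cone":
        r, h = dims["radius"], dims["height"]
        bbox = np.array([[0.0, h], [-r, r], [-r, r]])
        def inside(z, x, y):
            return (z >= 0) & (z <= h) & (x ** 2 + y ** 2 <= (r * z / h) ** 2)
    elif kind == "tapered_blade":
        l, w, t = dims["length"], dims["width"], dims["thickness"]
        bbox = np.array([[0.0, l], [-w / 2, w / 2], [-t / 2, t / 2]])
        def inside(z, x, y):
            f = np.clip(z / l, 0.0, 1.0)
            return ((z >= 0) & (z <= l)
                    & (np.abs(x) <= (w / 2) * (0.05 + 0.95 * f))
                    & (np.abs(y) <= (t / 2) * (0.05 + 0.95 * f ** 2)))
    else:
        raise ValueError(f"unknown solid kind {kind!r}")

    axis_len = bbox[0, 1] - bbox[0, 0]
    spacing = axis_len / resolution
    corners = np.array([[bbox[0, i], bbox[1, j], bbox[2, k]]
                        for i in (0, 1) for j in (0, 1) for k in (0, 1)])
    world = corners @ rot.T + trans
    lo = world.min(axis=0) - 2 * spacing
    hi = world.max(axis=0) + 2 * spacing
    n = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    idx = [lo[i] + (np.arange(n[i]) + 0.5) * spacing for i in range(3)]
    zz, xx, yy = np.meshgrid(*idx, indexing="ij")
    pts = np.stack([zz, xx, yy], axis=-1)
    local = (pts - trans) @ rot  # rot^T applied from the right
    grid = inside(local[..., 0], local[..., 1], local[..., 2])
    return VoxelModel(grid=grid, spacing=spacing)
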
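"""Ancestral shape reconstruction and feeding-type classification of nodes.

Terminal taxa (genus means for the focal clade, higher-taxon means for
outgroups) carry Procrustes-aligned mean shapes.  All branch lengths are
set equal (1.0) — an explicit evolutionary model assuming the same
expected amount of morphological change on every branch — and internal
node shapes are reconstructed by squared-change parsimony: the internal
coordinates minimize the sum over edges of squared coordinate changes.
With tip values fixed this is a sparse linear system in the tree
Laplacian, solved exactly per coordinate, and coincides with the
Brownian-motion maximum-likelihood ancestral states for these branch
lengths.  Polytomies are handled natively by the solver.

Each reconstructed node is then compared with the three feeding-type
groups of extant specimens: Procrustes distance to each group mean shape,
and Mahalanobis distance in the CVA-retained principal-component subspace
using the pooled within-group covariance of the extant sample (ancestors
are out-of-sample points and contribute nothing to the covariance).  The
reciprocal transformation converts distances into pie-chart support
proportions: support(g) = (1/d_g) / sum_h (1/d_h); a zero distance takes
all the support (ties among zeros split equally).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from .io_formats import FeedingType, SpecimenMeta, tree_has_branch_lengths
from .multivariate import CvaResult, PcaResult
from .preprocessing import LandmarkConfiguration
from .procrustes import (AlignedSample, mean_shape, procrustes_distance,
                         tangent_project)

log = logging.getLogger(__name__)

__all__ = [
    "LabeledTree",
    "NodeAssignment",
    "terminal_means",
    "reconstruct_ancestors",
    "classify_node",
    "classify_nodes",
    "annotate_tree",
    "parse_annotated_newick",
    "project_nodes",
    "squared_change_objective",
]


@dataclass
class LabeledTree:
    """Rooted tree with tips bound to terminal mean shapes and all branch
    lengths equalized to 1.0."""

    tree: dendropy.Tree
    tip_shapes: dict[str, LandmarkConfiguration]

    def __post_init__(self) -> None:
        if tree_has_branch_lengths(self.tree):
            log.warning("replacing input branch lengths with equal lengths 1.0")
        for edge in self.tree.preorder_edge_iter():
            edge.length = 1.0
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = sorted(tips - set(self.tip_shapes))
        if missing:
            raise ValueError(f"tips without a terminal mean shape: {missing}")
        self._assign_node_ids()

    def _assign_node_ids(self) -> None:
        """Tips keep their taxon label; unlabeled internal nodes are numbered
        by post-order traversal (node1, node2, ...)."""
        counter = 0
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.node_id = node.taxon.label
            elif node.label:
                node.node_id = node.label
            else:
                counter += 1
                node.node_id = f"node{counter}"

    @property
    def internal_ids(self) -> list[str]:
        return [n.node_id for n in self.tree.postorder_internal_node_iter()]


def terminal_means(sample: AlignedSample,
                   meta: list[SpecimenMeta],
                   terminals: list[str] | None = None
                   ) -> dict[str, LandmarkConfiguration]:
    """Per-terminal mean shapes of the aligned specimens.

    ``terminals`` (e.g. the tree's tip labels) restricts and validates the
    output; a requested terminal with no specimens is an error.
    """
    by_terminal: dict[str, list[int]] = {}
    index = {m.specimen_id: m for m in meta}
    for i, sid in enumerate(sample.specimen_ids):
        if sid not in index:
            raise ValueError(f"specimen {sid!r} missing from metadata")
        by_terminal.setdefault(index[sid].terminal, []).append(i)
    wanted = terminals if terminals is not None else sorted(by_terminal)
    missing = [t for t in wanted if t not in by_terminal]
    if missing:
        raise ValueError(f"terminals with no specimens: {missing}")
    return {t: mean_shape([sample.configs[i] for i in by_terminal[t]],
                          specimen_id=t) for t in wanted}


def reconstruct_ancestors(ltree: LabeledTree) -> dict[str, LandmarkConfiguration]:
    """Squared-change parsimony reconstruction of internal node shapes.

    Minimizes sum over edges of ||x_parent - x_child||^2 (all branch
    lengths equal) with tip shapes fixed; the normal equations form a
    sparse symmetric system over internal nodes, solved per coordinate
    block.  The solution is linear in the tip data.
    """
    internal = list(ltree.tree.postorder_internal_node_iter())
    index = {id(n): i for i, n in enumerate(internal)}
    k2 = next(iter(ltree.tip_shapes.values())).coords.size
    lap = lil_matrix((len(internal), len(internal)))
    rhs = np.zeros((len(internal), k2))
    for node in internal:
        i = index[id(node)]
        neighbors = list(node.child_nodes())
        if node.parent_node is not None:
            neighbors.append(node.parent_node)
        for nb in neighbors:
            lap[i, i] += 1.0
            if nb.is_leaf():
                rhs[i] += ltree.tip_shapes[nb.taxon.label].coords.reshape(-1)
            else:
                lap[i, index[id(nb)]] -= 1.0
    sol = spsolve(lap.tocsr(), rhs)
    sol = np.atleast_2d(sol)
    return {node.node_id: LandmarkConfiguration(
                node.node_id, sol[index[id(node)]].reshape(-1, 2))
            for node in internal}


def squared_change_objective(ltree: LabeledTree,
                             node_shapes: dict[str, np.ndarray | LandmarkConfiguration]
                             ) -> float:
    """Sum over edges of squared coordinate change; the quantity the
    reconstruction minimizes.  Useful for optimality checks."""
    def coords_of(node):
        if node.is_leaf():
            return ltree.tip_shapes[node.taxon.label].coords
        v = node_shapes[node.node_id]
        return v.coords if isinstance(v, LandmarkConfiguration) else np.asarray(v)

    total = 0.0
    for node in ltree.tree.preorder_node_iter():
        for child in node.child_nodes():
            diff = coords_of(node) - coords_of(child)
            total += float(np.sum(diff * diff))
    return total


@dataclass
class NodeAssignment:
    """Feeding-type support for one ancestral node, per distance metric."""

    node_id: str
    d_procrustes: dict[FeedingType, float]
    d_mahalanobis: dict[FeedingType, float]
    support_procrustes: dict[FeedingType, float]
    support_mahalanobis: dict[FeedingType, float]

    def argmax(self, metric: str = "procrustes") -> FeedingType:
        sup = (self.support_procrustes if metric == "procrustes"
               else self.support_mahalanobis)
        return max(sup, key=sup.get)


def reciprocal_support(distances: dict[FeedingType, float]) -> dict[FeedingType, float]:
    """Normalized inverse distances; zero distances take all the support
    (split equally among ties at zero)."""
    zeros = [g for g, d in distances.items() if d == 0.0]
    if zeros:
        return {g: (1.0 / len(zeros) if g in zeros else 0.0) for g in distances}
    inv = {g: 1.0 / d for g, d in distances.items()}
    total = sum(inv.values())
    return {g: v / total for g, v in inv.items()}


def classify_node(node_shape: LandmarkConfiguration,
                  group_means: dict[FeedingType, LandmarkConfiguration],
                  cva_result: CvaResult,
                  consensus_flat: np.ndarray) -> NodeAssignment:
    """Distances from a reconstructed node shape to each feeding-type group
    and the reciprocal-transform support proportions."""
    if set(group_means) != set(FeedingType):
        missing = set(FeedingType) - set(group_means)
        raise ValueError(f"missing feeding-type group means: {sorted(g.value for g in missing)}")
    d_proc = {g: procrustes_distance(node_shape, m)
              for g, m in group_means.items()}
    tang = tangent_project(node_shape.coords.reshape(-1), consensus_flat)
    order = [FeedingType(str(l)) if not isinstance(l, FeedingType) else l
             for l in cva_result.group_labels]
    dm = cva_result.mahalanobis_to_groups(tang)[0]
    d_maha = {g: float(dm[i]) for i, g in enumerate(order)}
    return NodeAssignment(
        node_id=node_shape.specimen_id,
        d_procrustes=d_proc, d_mahalanobis=d_maha,
        support_procrustes=reciprocal_support(d_proc),
        support_mahalanobis=reciprocal_support(d_maha))


def classify_nodes(node_shapes: dict[str, LandmarkConfiguration],
                   group_means: dict[FeedingType, LandmarkConfiguration],
                   cva_result: CvaResult,
                   consensus_flat: np.ndarray) -> list[NodeAssignment]:
    return [classify_node(shape, group_means, cva_result, consensus_flat)
            for shape in node_shapes.values()]


# ---------------------------------------------------------------------------
# Output

_TYPES = [FeedingType.OM, FeedingType.PH, FeedingType.CO]


def annotate_tree(ltree: LabeledTree,
                  assignments: list[NodeAssignment]) -> tuple[str, pd.DataFrame]:
    """Newick with per-node support comments plus a flat assignment table.

    The newick annotates each internal node with
    ``[&pOM=..,pPH=..,pCO=..,mOM=..,mPH=..,mCO=..]`` (Procrustes- and
    Mahalanobis-based supports); the table carries distances, supports and
    the argmax feeding type per metric.
    """
    by_id = {a.node_id: a for a in assignments}
    missing = [nid for nid in ltree.internal_ids if nid not in by_id]
    if missing:
        raise ValueError(f"missing assignments for nodes: {missing}")

    def render(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        a = by_id[node.node_id]
        fields = [f"p{t.value}={a.support_procrustes[t]:.12g}" for t in _TYPES]
        fields += [f"m{t.value}={a.support_mahalanobis[t]:.12g}" for t in _TYPES]
        children = ",".join(render(c) for c in node.child_nodes())
        return f"({children}){node.node_id}[&{','.join(fields)}]"

    newick = render(ltree.tree.seed_node) + ";"

    rows = []
    for nid in ltree.internal_ids:
        a = by_id[nid]
        row: dict[str, object] = {"node_id": nid}
        for t in _TYPES:
            row[f"d_procrustes_{t.value}"] = a.d_procrustes[t]
            row[f"d_mahalanobis_{t.value}"] = a.d_mahalanobis[t]
            row[f"support_procrustes_{t.value}"] = a.support_procrustes[t]
            row[f"support_mahalanobis_{t.value}"] = a.support_mahalanobis[t]
        row["argmax_procrustes"] = a.argmax("procrustes").value
        row["argmax_mahalanobis"] = a.argmax("mahalanobis").value
        rows.append(row)
    return newick, pd.DataFrame(rows)


_ANNOT_RE = re.compile(r"\)([^\[\](),;]*)\[&([^\]]*)\]")


def parse_annotated_newick(newick: str) -> dict[str, dict[str, float]]:
    """Recover the per-node support annotations written by
    :func:`annotate_tree` (round-trip check)."""
    out: dict[str, dict[str, float]] = {}
    for m in _ANNOT_RE.finditer(newick):
        node_id = m.group(1)
        fields = dict(f.split("=") for f in m.group(2).split(","))
        out[node_id] = {k: float(v) for k, v in fields.items()}
    return out


def project_nodes(pca_result: PcaResult,
                  node_shapes: dict[str, LandmarkConfiguration],
                  consensus_flat: np.ndarray) -> pd.DataFrame:
    """Scores of reconstructed node shapes in the extant-specimen PCA space.

    Node coordinates are projected onto the tangent space at the extant
    consensus and then onto the extant PCA axes; the whole map is linear
    in the node coordinates, so e.g. a star-tree root projects to the mean
    of its tip projections.
    """
    ids = list(node_shapes)
    flat = np.stack([node_shapes[i].coords.reshape(-1) for i in ids])
    if flat.shape[1] != consensus_flat.size:
        raise ValueError("node shape dimension does not match the sample")
    scores = pca_result.project(tangent_project(flat, consensus_flat))
    df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    df.insert(0, "node_id", ids)
    return df
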
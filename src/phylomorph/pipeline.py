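"""End-to-end orchestration of the shape-evolution analysis.

``run_full_analysis`` takes a :class:`RunConfig` and executes the whole
chain: outline resampling, generalized Procrustes superimposition, PCA
with per-group total variances and 90% equal-frequency ellipses, CVA
with pairwise permutation tests, terminal mean shapes, squared-change
parsimony ancestral reconstruction, reciprocal-distance feeding-type
classification of every internal node, projection of the ancestors into
the extant PCA space, and a written result bundle with a manifest.  Runs
are fully reproducible from the config and seed, both of which are
serialized into the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cross_section import load_voxels, section_areas
from .io_formats import (FeedingType, read_landmark_csv, read_metadata,
                         read_newick, read_tps, write_landmark_csv,
                         write_results)
from .multivariate import (cva, equal_frequency_ellipse, group_total_variance,
                           pca, permutation_test)
from .phylo_ancestral import (LabeledTree, annotate_tree, classify_nodes,
                              project_nodes, reconstruct_ancestors,
                              terminal_means)
from .preprocessing import resample_curve, standardize_orientation
from .procrustes import gpa, mean_shape

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_full_analysis",
           "run_cross_section"]

_TYPES = [FeedingType.OM, FeedingType.PH, FeedingType.CO]
_PAIRS = [(FeedingType.OM, FeedingType.PH),
          (FeedingType.OM, FeedingType.CO),
          (FeedingType.PH, FeedingType.CO)]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending record."""


@dataclass
class RunConfig:
    landmarks: str | Path | None = None
    metadata: str | Path | None = None
    tree: str | Path | None = None
    outdir: str | Path = "results"
    k: int = 50
    orientation_policy: str = "none"
    allow_reflection: bool = False
    retained_dims: int | str = "auto"
    n_perm: int = 10000
    seed: int = 0
    coverage: float = 0.90
    voxels: str | Path | None = None
    spacing: float = 1.0
    n_sections: int = 6

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("landmarks", "metadata", "tree", "outdir", "voxels"):
            if d[key] is not None:
                d[key] = str(d[key])
        d["version"] = __version__
        return d

    def validate(self) -> None:
        if self.k < 3:
            raise PipelineError(f"config: k must be >= 3, got {self.k}")
        if self.n_perm < 1:
            raise PipelineError("config: n_perm must be >= 1")
        if not 0 < self.coverage < 1:
            raise PipelineError("config: coverage must be in (0, 1)")


def _pair_cols(matrix: np.ndarray, order: list[FeedingType]) -> list[float]:
    idx = {g: i for i, g in enumerate(order)}
    return [float(matrix[idx[a], idx[b]]) for a, b in _PAIRS]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full analysis and write the result bundle.

    Returns an in-memory bundle with the intermediate objects (aligned
    sample, PCA/CVA results, node assignments, ...) for programmatic use.
    """
    config.validate()
    outdir = Path(config.outdir)

    # --- inputs ------------------------------------------------------------
    try:
        path = Path(config.landmarks)
        curves = (read_landmark_csv(path) if path.suffix.lower() == ".csv"
                  else read_tps(path))
        meta = read_metadata(config.metadata)
        tree = read_newick(config.tree)
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc

    meta_by_id = {m.specimen_id: m for m in meta}
    missing_meta = [c.specimen_id for c in curves if c.specimen_id not in meta_by_id]
    if missing_meta:
        raise PipelineError(f"input stage: specimens without metadata: {missing_meta}")
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    terminals_seen = {m.terminal for m in meta}
    orphan_tips = [t for t in tips if t not in terminals_seen]
    if orphan_tips:
        raise PipelineError(
            f"input stage: tree tips without specimens: {orphan_tips}")

    # --- preprocessing + superimposition ------------------------------------
    try:
        configs = [standardize_orientation(resample_curve(c, k=config.k),
                                           config.orientation_policy)
                   for c in curves]
    except Exception as exc:
        raise PipelineError(f"preprocessing stage: {exc}") from exc
    sample = gpa(configs, allow_reflection=config.allow_reflection)
    if not sample.converged:
        log.warning("GPA did not converge within the iteration cap")
    labels = [meta_by_id[sid].feeding_type for sid in sample.specimen_ids]

    # --- ordination ---------------------------------------------------------
    pca_res = pca(sample)
    group_idx = {g: [i for i, l in enumerate(labels) if l == g] for g in _TYPES}
    variances = {g.value: group_total_variance(sample, idx)
                 for g, idx in group_idx.items()}
    ellipses = {}
    for g, idx in group_idx.items():
        try:
            e = equal_frequency_ellipse(pca_res.scores[idx, :2],
                                        coverage=config.coverage)
            ellipses[g.value] = {
                "center": e.center.tolist(),
                "semi_axes": e.semi_axes.tolist(),
                "angle": e.angle, "coverage": e.coverage}
        except ValueError as exc:
            log.warning("ellipse for %s skipped: %s", g.value, exc)

    # --- discrimination -----------------------------------------------------
    cva_res = cva(sample, labels, retained_dims=config.retained_dims)
    perm_m = permutation_test(sample, labels, "mahalanobis",
                              n_perm=config.n_perm, seed=config.seed,
                              retained_dims=config.retained_dims)
    perm_p = permutation_test(sample, labels, "procrustes",
                              n_perm=config.n_perm, seed=config.seed)
    cva_res.p_mahalanobis = perm_m.p_values
    cva_res.p_procrustes = perm_p.p_values
    cva_res.n_permutations = config.n_perm

    # --- phylogeny ----------------------------------------------------------
    try:
        t_means = terminal_means(sample, meta, terminals=tips)
    except ValueError as exc:
        raise PipelineError(f"terminal-mean stage: {exc}") from exc
    ltree = LabeledTree(tree, t_means)
    node_shapes = reconstruct_ancestors(ltree)
    group_means = {g: mean_shape([sample.configs[i] for i in group_idx[g]],
                                 specimen_id=g.value) for g in _TYPES}
    consensus_flat = sample.consensus.coords.reshape(-1)
    assignments = classify_nodes(node_shapes, group_means, cva_res,
                                 consensus_flat)
    newick, node_table = annotate_tree(ltree, assignments)
    node_scores = project_nodes(pca_res, node_shapes, consensus_flat)

    # --- output -------------------------------------------------------------
    pair_names = [f"{a.value}-vs-{b.value}" for a, b in _PAIRS]
    table1 = pd.DataFrame(
        [["mahalanobis_distance"] + _pair_cols(cva_res.mahalanobis,
                                               cva_res.group_labels),
         ["p_mahalanobis"] + _pair_cols(perm_m.p_values, perm_m.group_labels),
         ["procrustes_distance"] + _pair_cols(cva_res.procrustes_d,
                                              cva_res.group_labels),
         ["p_procrustes"] + _pair_cols(perm_p.p_values, perm_p.group_labels)],
        columns=["statistic"] + pair_names)

    scores_df = pd.DataFrame(pca_res.scores,
                             columns=[f"PC{i+1}" for i in range(pca_res.scores.shape[1])])
    scores_df.insert(0, "specimen_id", sample.specimen_ids)
    scores_df.insert(1, "feeding_type", [l.value for l in labels])
    eig_df = pd.DataFrame({
        "component": np.arange(1, len(pca_res.eigenvalues) + 1),
        "eigenvalue": pca_res.eigenvalues,
        "variance_proportion": pca_res.variance_proportions})

    aligned_rows = []
    for cfg in sample.configs + [sample.consensus]:
        for idx, (x, y) in enumerate(cfg.coords):
            aligned_rows.append((cfg.specimen_id, idx, x, y))
    aligned_df = pd.DataFrame(aligned_rows,
                              columns=["specimen_id", "point_index", "x", "y"])

    assignments_json = {
        a.node_id: {
            "d_procrustes": {t.value: a.d_procrustes[t] for t in _TYPES},
            "d_mahalanobis": {t.value: a.d_mahalanobis[t] for t in _TYPES},
            "support_procrustes": {t.value: a.support_procrustes[t] for t in _TYPES},
            "support_mahalanobis": {t.value: a.support_mahalanobis[t] for t in _TYPES},
        } for a in assignments}

    results = {
        "aligned_coords": aligned_df,
        "pca_scores": scores_df,
        "pca_eigenvalues": eig_df,
        "group_variances": variances,
        "ellipses": ellipses,
        "cva_table": table1,
        "node_assignments": node_table,
        "node_assignments_detail": assignments_json,
        "node_scores": node_scores,
        "config": config.to_json(),
    }
    manifest = write_results(results, outdir)
    (outdir / "annotated_tree.nwk").write_text(newick + "\n")
    manifest.append("annotated_tree.nwk")
    (outdir / "manifest.json").write_text(json.dumps(sorted(manifest), indent=2))

    return {"sample": sample, "pca": pca_res, "cva": cva_res,
            "perm_mahalanobis": perm_m, "perm_procrustes": perm_p,
            "group_variances": variances, "ellipses": ellipses,
            "terminal_means": t_means, "tree": ltree,
            "node_shapes": node_shapes, "assignments": assignments,
            "node_scores": node_scores, "annotated_newick": newick,
            "table1": table1, "manifest": manifest}


def run_cross_section(config: RunConfig) -> dict:
    """Load a voxel model, profile its cross-sections, write CSV + JSON."""
    if config.voxels is None:
        raise PipelineError("cross-section stage: no voxel input configured")
    path = Path(config.voxels)
    if not path.exists():
        raise PipelineError(f"cross-section stage: missing input {path}")
    model = load_voxels(path, spacing=config.spacing)
    profile = section_areas(model, n_sections=config.n_sections)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "position": list(profile.areas),
        "area": [profile.areas[p] for p in profile.areas],
        "ratio_pct": [profile.ratios[p] for p in profile.areas]})
    df.to_csv(outdir / "cross_sections.csv", index=False, float_format="%.12e")
    (outdir / "cross_sections.json").write_text(json.dumps({
        "axis": profile.axis.tolist(),
        "positions": list(profile.positions),
        "areas": {str(p): a for p, a in profile.areas.items()},
        "ratios_pct": {str(p): r for p, r in profile.ratios.items()},
        "config": config.to_json()}, indent=2))
    return {"profile": profile, "table": df}
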
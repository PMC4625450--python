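import dendropy
import numpy as np
import pytest
from scipy.optimize import minimize

from phylomorph.io_formats import FeedingType
from phylomorph.multivariate import cva
from phylomorph.phylo_ancestral import (LabeledTree, NodeAssignment,
                                        annotate_tree, classify_node,
                                        classify_nodes, parse_annotated_newick,
                                        project_nodes, reciprocal_support,
                                        reconstruct_ancestors,
                                        squared_change_objective,
                                        terminal_means)
from phylomorph.preprocessing import LandmarkConfiguration
from phylomorph.procrustes import mean_shape, procrustes_distance, tangent_project
from phylomorph.multivariate import pca
from phylomorph.synthetic_data import star_tree


def get_tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


def shapes_from(values, k=3):
    """Scalar tip values -> degenerate-free configurations embedding the
    scalar in one coordinate."""
    out = {}
    base = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    for name, v in values.items():
        coords = base.copy()
        coords[0, 0] = v
        out[name] = LandmarkConfiguration(name, coords)
    return out


class TestTerminalMeans:
    def test_single_specimen_terminal(self, small_study):
        sample, meta, _ = small_study
        sub_meta = [m for m in meta]
        means = terminal_means(sample, sub_meta)
        one = [m.terminal for m in meta].count(meta[0].terminal)
        assert set(means) == {m.terminal for m in meta}

    def test_permutation_invariance(self, small_study):
        sample, meta, _ = small_study
        m1 = terminal_means(sample, meta)
        m2 = terminal_means(sample, list(reversed(meta)))
        for t in m1:
            np.testing.assert_allclose(m1[t].coords, m2[t].coords, atol=1e-12)

    def test_missing_terminal_error(self, small_study):
        sample, meta, _ = small_study
        with pytest.raises(ValueError, match="ghost"):
            terminal_means(sample, meta, terminals=["ghost"])


class TestReconstructAncestors:
    def test_star_tree_root_is_tip_mean(self, rng):
        tree = star_tree(6)
        tips = {f"t{i}": LandmarkConfiguration(f"t{i}", rng.normal(size=(4, 2)))
                for i in range(6)}
        ltree = LabeledTree(tree, tips)
        anc = reconstruct_ancestors(ltree)
        assert len(anc) == 1
        expected = np.mean([tips[f"t{i}"].coords for i in range(6)], axis=0)
        np.testing.assert_allclose(list(anc.values())[0].coords, expected,
                                   atol=1e-10)

    def test_two_tip_midpoint(self, rng):
        tree = get_tree("(a,b);")
        tips = {n: LandmarkConfiguration(n, rng.normal(size=(5, 2)))
                for n in "ab"}
        anc = reconstruct_ancestors(LabeledTree(tree, tips))
        mid = (tips["a"].coords + tips["b"].coords) / 2
        np.testing.assert_allclose(list(anc.values())[0].coords, mid, atol=1e-10)

    def test_matches_numeric_quadratic_minimizer(self):
        tree = get_tree("((A,B),(C,D));")
        values = {"A": 0.0, "B": 2.0, "C": 10.0, "D": 14.0}
        ltree = LabeledTree(tree, shapes_from(values))
        anc = reconstruct_ancestors(ltree)
        ids = ltree.internal_ids
        x0 = np.zeros(len(ids))

        def objective(x):
            shapes = {nid: shapes_from({nid: x[i]})[nid]
                      for i, nid in enumerate(ids)}
            return squared_change_objective(ltree, shapes)

        res = minimize(objective, x0, method="BFGS", tol=1e-12)
        ours = np.array([anc[nid].coords[0, 0] for nid in ids])
        np.testing.assert_allclose(ours, res.x, atol=1e-6)

    def test_perturbation_never_improves(self, rng):
        tree = get_tree("((A,(B,E)),(C,D));")
        tips = {n: LandmarkConfiguration(n, rng.normal(size=(4, 2)))
                for n in "ABCDE"}
        ltree = LabeledTree(tree, tips)
        anc = reconstruct_ancestors(ltree)
        base = squared_change_objective(ltree, anc)
        for _ in range(100):
            perturbed = {nid: cfg.coords + rng.normal(0, 1e-3, cfg.coords.shape)
                         for nid, cfg in anc.items()}
            assert squared_change_objective(ltree, perturbed) >= base - 1e-12

    def test_linearity_in_tip_data(self, rng):
        tree_str = "((A,B),(C,(D,E)));"
        tips_x = {n: rng.normal(size=(4, 2)) for n in "ABCDE"}
        tips_y = {n: rng.normal(size=(4, 2)) for n in "ABCDE"}
        a, b = 0.7, -1.3

        def solve(tipvals):
            t = get_tree(tree_str)
            lt = LabeledTree(t, {n: LandmarkConfiguration(n, v)
                                 for n, v in tipvals.items()})
            return {k: v.coords for k, v in reconstruct_ancestors(lt).items()}

        sx, sy = solve(tips_x), solve(tips_y)
        sxy = solve({n: a * tips_x[n] + b * tips_y[n] for n in tips_x})
        for nid in sx:
            np.testing.assert_allclose(sxy[nid], a * sx[nid] + b * sy[nid],
                                       atol=1e-9)

    def test_polytomy_handled(self, rng):
        tree = get_tree("(A,B,C,(D,E));")
        tips = {n: LandmarkConfiguration(n, rng.normal(size=(4, 2)))
                for n in "ABCDE"}
        anc = reconstruct_ancestors(LabeledTree(tree, tips))
        assert len(anc) == 2

    def test_unshaped_tip_error(self, rng):
        tree = get_tree("(A,B);")
        with pytest.raises(ValueError, match="B"):
            LabeledTree(tree, {"A": LandmarkConfiguration(
                "A", rng.normal(size=(4, 2)))})


class TestReciprocalSupport:
    def test_direct_arithmetic(self):
        d = {FeedingType.OM: 1.0, FeedingType.PH: 2.0, FeedingType.CO: 4.0}
        s = reciprocal_support(d)
        assert s[FeedingType.OM] == pytest.approx(4 / 7)
        assert s[FeedingType.PH] == pytest.approx(2 / 7)
        assert s[FeedingType.CO] == pytest.approx(1 / 7)

    def test_zero_distance_takes_all(self):
        d = {FeedingType.OM: 0.3, FeedingType.PH: 0.0, FeedingType.CO: 0.5}
        s = reciprocal_support(d)
        assert s == {FeedingType.OM: 0.0, FeedingType.PH: 1.0,
                     FeedingType.CO: 0.0}

    def test_equidistant_thirds(self):
        d = {g: 0.7 for g in FeedingType}
        s = reciprocal_support(d)
        for g in FeedingType:
            assert s[g] == pytest.approx(1 / 3)

    def test_support_order_reverses_distance_order(self, rng):
        for _ in range(10):
            d = {g: float(v) for g, v in zip(FeedingType,
                                             rng.uniform(0.1, 2.0, 3))}
            s = reciprocal_support(d)
            assert sum(s.values()) == pytest.approx(1.0, abs=1e-12)
            by_d = sorted(FeedingType, key=d.get)
            by_s = sorted(FeedingType, key=s.get, reverse=True)
            assert by_d == by_s


class TestClassifyAndAnnotate:
    @pytest.fixture
    def study_context(self, small_study):
        sample, meta, labels = small_study
        cva_res = cva(sample, labels)
        group_idx = {g: [i for i, l in enumerate(labels) if l == g]
                     for g in FeedingType}
        group_means = {g: mean_shape([sample.configs[i] for i in idx],
                                     specimen_id=g.value)
                       for g, idx in group_idx.items()}
        consensus = sample.consensus.coords.reshape(-1)
        return sample, cva_res, group_means, consensus

    def test_node_at_group_mean_gets_full_procrustes_support(self, study_context):
        _, cva_res, group_means, consensus = study_context
        node = group_means[FeedingType.CO].copy_with(
            group_means[FeedingType.CO].coords)
        node.specimen_id = "n1"
        a = classify_node(node, group_means, cva_res, consensus)
        assert a.support_procrustes[FeedingType.CO] == pytest.approx(1.0)
        assert a.argmax("procrustes") is FeedingType.CO

    def test_missing_group_error(self, study_context):
        _, cva_res, group_means, consensus = study_context
        partial = {FeedingType.CO: group_means[FeedingType.CO]}
        with pytest.raises(ValueError, match="missing"):
            classify_node(group_means[FeedingType.CO], partial, cva_res,
                          consensus)

    def test_annotation_roundtrip(self, study_context, small_study):
        sample, meta, labels = small_study
        _, cva_res, group_means, consensus = study_context
        terms = sorted({m.terminal for m in meta})
        newick_in = "(" + ",".join(terms) + ");"
        ltree = LabeledTree(get_tree(newick_in),
                            terminal_means(sample, meta, terminals=terms))
        node_shapes = reconstruct_ancestors(ltree)
        assignments = classify_nodes(node_shapes, group_means, cva_res,
                                     consensus)
        newick, table = annotate_tree(ltree, assignments)
        parsed = parse_annotated_newick(newick)
        for a in assignments:
            for t in FeedingType:
                assert parsed[a.node_id][f"p{t.value}"] == pytest.approx(
                    a.support_procrustes[t], abs=1e-9)
                assert parsed[a.node_id][f"m{t.value}"] == pytest.approx(
                    a.support_mahalanobis[t], abs=1e-9)
        row = table.set_index("node_id")
        for a in assignments:
            s = sum(row.loc[a.node_id, f"support_procrustes_{t.value}"]
                    for t in FeedingType)
            assert s == pytest.approx(1.0, abs=1e-9)

    def test_missing_assignment_error(self, study_context, small_study):
        sample, meta, _ = small_study
        terms = sorted({m.terminal for m in meta})
        ltree = LabeledTree(get_tree("(" + ",".join(terms) + ");"),
                            terminal_means(sample, meta, terminals=terms))
        with pytest.raises(ValueError, match="missing"):
            annotate_tree(ltree, [])


class TestProjectNodes:
    def test_consensus_projects_to_origin(self, small_study):
        sample, _, _ = small_study
        res = pca(sample)
        cons = sample.consensus
        df = project_nodes(res, {"cons": cons}, cons.coords.reshape(-1))
        assert np.abs(df.iloc[0, 1:].to_numpy(float)).max() < 1e-8

    def test_extant_specimen_reproduces_its_score(self, small_study):
        sample, _, _ = small_study
        res = pca(sample)
        cfg = sample.configs[3]
        df = project_nodes(res, {"x": cfg}, sample.consensus.coords.reshape(-1))
        np.testing.assert_allclose(df.iloc[0, 1:].to_numpy(float),
                                   res.scores[3], atol=1e-10)

    def test_star_root_is_mean_of_tip_projections(self, small_study, rng):
        sample, _, _ = small_study
        res = pca(sample)
        cons_flat = sample.consensus.coords.reshape(-1)
        tree = star_tree(5)
        tips = {f"t{i}": sample.consensus.copy_with(
                    sample.consensus.coords + rng.normal(0, 0.01, (50, 2)))
                for i in range(5)}
        for name, cfg in tips.items():
            cfg.specimen_id = name
        ltree = LabeledTree(tree, tips)
        anc = reconstruct_ancestors(ltree)
        root_scores = project_nodes(res, anc, cons_flat).iloc[0, 1:].to_numpy(float)
        tip_scores = project_nodes(res, tips, cons_flat).iloc[:, 1:].to_numpy(float)
        np.testing.assert_allclose(root_scores, tip_scores.mean(axis=0),
                                   atol=1e-9)

    def test_dimension_mismatch_error(self, small_study, rng):
        sample, _, _ = small_study
        res = pca(sample)
        bad = LandmarkConfiguration("bad", rng.normal(size=(7, 2)))
        with pytest.raises(ValueError, match="dimension"):
            project_nodes(res, {"bad": bad}, sample.consensus.coords.reshape(-1))
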
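"""Trees, contrasts, and Brownian-motion ancestral state reconstruction."""

import json
import shutil
import subprocess

import numpy as np
import pytest
from scipy.optimize import minimize

from revecol.ancestral import (Tree, anc_ml, annotate_tree, pic_contrasts,
                               read_newick, recovery_metrics, root_estimate,
                               write_newick)
from revecol.synthetic import gen_tree, simulate_bm


def brute_force_states(tree: Tree, tips: dict) -> dict:
    """Independent oracle: numerically maximize the joint BM likelihood.

    For fixed tips the log-likelihood is, up to constants and the rate,
    −Σ_edges (z_child − z_parent)²/v, a smooth quadratic in the internal
    states; BFGS from zero recovers the global maximum.
    """
    internals = tree.internal_labels()
    idx = {lab: i for i, lab in enumerate(internals)}
    edges = []
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child = node.taxon.label if node.is_leaf() else node.label
        edges.append((child, node.parent_node.label, float(node.edge.length)))

    def neg_loglik(z):
        val = {**tips, **{lab: z[i] for lab, i in idx.items()}}
        return sum((val[c] - val[p]) ** 2 / v for c, p, v in edges)

    res = minimize(neg_loglik, np.zeros(len(internals)), method="BFGS",
                   tol=1e-14)
    return {lab: res.x[i] for lab, i in idx.items()}


class TestNewickIO:
    def test_parse_counts(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips() == 3
        assert len(t.internal_labels()) == 2

    def test_roundtrip_stability(self):
        t = gen_tree(16, "random-split", seed=0)
        text = t.to_newick()
        assert Tree.from_newick(text).to_newick() == text

    def test_polytomy_resolved_by_binarize(self):
        t = read_newick("(A:1,B:1,C:1);").binarize()
        assert t.is_binary()
        for node in t.dendropy_tree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length > 0

    def test_malformed_raises(self):
        with pytest.raises(ValueError):
            read_newick("((A:1,B:1;")

    def test_file_roundtrip(self, tmp_path):
        t = gen_tree(8, "balanced", seed=1)
        path = tmp_path / "tree.nwk"
        write_newick(t, path)
        assert read_newick(path).to_newick() == t.to_newick()


class TestContrasts:
    def test_cherry_contrast(self):
        t = read_newick("(A:1,B:1);")
        contrasts, sigma2 = pic_contrasts(t, {"A": 0.0, "B": 2.0})
        assert len(contrasts) == 1
        c, v = contrasts[0]
        assert abs(c) == pytest.approx(2.0)
        assert v == pytest.approx(2.0)
        assert sigma2 == pytest.approx(4.0 / 2.0)

    def test_identical_tips_zero_contrasts(self):
        t = gen_tree(10, "random-split", seed=2)
        contrasts, sigma2 = pic_contrasts(t, {tip: 1.7 for tip in t.tip_labels()})
        assert all(c == pytest.approx(0.0) for c, _ in contrasts)
        assert sigma2 == pytest.approx(0.0)

    def test_contrast_count(self):
        t = gen_tree(12, "balanced", seed=3)
        tips, _ = simulate_bm(t, 1.0, 0.0, seed=4)
        contrasts, _ = pic_contrasts(t, tips)
        assert len(contrasts) == 11

    def test_standardized_contrasts_unit_variance(self):
        t = gen_tree(16, "random-split", seed=5)
        zs = []
        for rep in range(600):
            tips, _ = simulate_bm(t, 1.0, 0.0, seed=1000 + rep)
            contrasts, _ = pic_contrasts(t, tips)
            zs.extend(c / np.sqrt(v) for c, v in contrasts)
        assert np.var(zs) == pytest.approx(1.0, abs=0.1)

    def test_missing_tip_errors(self):
        t = read_newick("(A:1,B:1);")
        with pytest.raises(KeyError, match="B"):
            pic_contrasts(t, {"A": 0.0})


class TestAncMl:
    def test_two_tip_symmetric_midpoint(self):
        t = read_newick("(A:1,B:1);")
        est = anc_ml(t, {"A": 0.0, "B": 10.0})
        assert est.states["n0"] == pytest.approx(5.0)

    def test_two_tip_inverse_length_weighting(self):
        t = read_newick("(A:1,B:3);")
        est = anc_ml(t, {"A": 0.0, "B": 4.0})
        assert est.states["n0"] == pytest.approx(1.0)

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(3, 7))
            t = gen_tree(n, "random-split", seed=trial)
            tips, _ = simulate_bm(t, 1.0, 0.0, seed=500 + trial)
            est = anc_ml(t, tips)
            oracle = brute_force_states(t, tips)
            for lab, z in oracle.items():
                assert est.states[lab] == pytest.approx(z, abs=1e-6)

    def test_affine_equivariance(self):
        t = gen_tree(10, "random-split", seed=9)
        tips, _ = simulate_bm(t, 1.0, 0.0, seed=10)
        est = anc_ml(t, tips)
        a, b = 2.5, -40.0
        est2 = anc_ml(t, {k: a * v + b for k, v in tips.items()})
        for lab in est.states:
            assert est2.states[lab] == pytest.approx(a * est.states[lab] + b)

    def test_rerooting_identity(self):
        t = gen_tree(12, "random-split", seed=11)
        tips, _ = simulate_bm(t, 1.0, 0.0, seed=12)
        est = anc_ml(t, tips)
        target = t.internal_labels()[3]
        # re-root a copy at the same node and take its root estimate
        copy = Tree.from_newick(t.to_newick())
        node = next(n for n in copy.dendropy_tree.preorder_node_iter()
                    if not n.is_leaf() and n.label == target)
        copy.dendropy_tree.reroot_at_node(node)
        x, _ = root_estimate(Tree(copy.dendropy_tree), tips)
        assert x == pytest.approx(est.states[target], abs=1e-9)

    def test_ci_contains_state(self):
        t = gen_tree(8, "balanced", seed=13)
        tips, _ = simulate_bm(t, 1.0, 0.0, seed=14)
        est = anc_ml(t, tips)
        for lab, (lo, hi) in est.ci95.items():
            assert lo <= est.states[lab] <= hi
            assert hi - lo == pytest.approx(
                2 * 1.959963984540054 * np.sqrt(est.variances[lab]))

    def test_root_rmse_decreases_with_tip_count(self):
        # fixed tree height: more tips = more independent basal lineages
        rmses = []
        for n_tips in (8, 64):
            levels = int(np.log2(n_tips))
            h = 1.0 / levels
            errs = []
            for rep in range(200):
                t = gen_tree(n_tips, "balanced", seed=rep,
                             branch_range=(h, h))
                tips, _ = simulate_bm(t, 1.0, 0.0, seed=3000 + rep)
                x, _ = root_estimate(t, tips)
                errs.append(x)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[1] < rmses[0]


class TestRecoveryAndAnnotation:
    def test_perfect_estimates(self):
        t = gen_tree(8, "balanced", seed=20)
        tips, truth = simulate_bm(t, 1.0, 0.0, seed=21)
        est = anc_ml(t, tips)
        est.states = dict(truth)
        rmse, bias, cover = recovery_metrics(truth, est)
        assert rmse == 0.0 and bias == 0.0

    def test_constant_shift_bias(self):
        t = gen_tree(8, "balanced", seed=22)
        tips, truth = simulate_bm(t, 1.0, 0.0, seed=23)
        est = anc_ml(t, tips)
        est.states = {k: v + 1.0 for k, v in truth.items()}
        _, bias, _ = recovery_metrics(truth, est)
        assert bias == pytest.approx(1.0)

    def test_mismatched_nodes_error(self):
        t = gen_tree(4, "balanced", seed=24)
        tips, truth = simulate_bm(t, 1.0, 0.0, seed=25)
        est = anc_ml(t, tips)
        with pytest.raises(ValueError):
            recovery_metrics({"bogus": 1.0}, est)

    def test_annotation_roundtrip(self):
        t = read_newick("(A:1,B:1);")
        est = anc_ml(t, {"A": 0.0, "B": 10.0})
        newick, table = annotate_tree(t, est)
        assert ")5.00" in newick
        assert len(table) == 1
        reparsed = Tree.from_newick(newick)
        assert reparsed.internal_labels() == ["5.00"]

    def test_node_table_covers_internals(self):
        t = gen_tree(10, "random-split", seed=26)
        tips, _ = simulate_bm(t, 1.0, 0.0, seed=27)
        _, table = annotate_tree(t, anc_ml(t, tips))
        assert len(table) == len(t.internal_labels())


def test_matches_phytools_fastanc():
    """Cross-check against the R phytools implementation on one tree."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable for cross-check")
    t = gen_tree(6, "random-split", seed=42)
    tips, _ = simulate_bm(t, 2.0, 5.0, seed=7)
    est = anc_ml(t, tips)
    script = f"""
    suppressMessages(library(phytools))
    tree <- read.tree(text='{t.to_newick()}')
    x <- unlist(jsonlite::fromJSON('{json.dumps(tips)}'))
    fa <- fastAnc(tree, x, vars=TRUE)
    cat(jsonlite::toJSON(list(states=unname(fa$ace), vars=unname(fa$var)),
                         digits=15))
    """
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    r = json.loads(out.stdout)
    # phytools numbers nodes in the same preorder as our n0..n4 labelling
    labels = t.internal_labels()
    for lab, state, var in zip(labels, r["states"], r["vars"]):
        assert est.states[lab] == pytest.approx(state, abs=1e-6)
        assert est.variances[lab] == pytest.approx(var, rel=1e-6)
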
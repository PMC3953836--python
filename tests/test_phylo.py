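import numpy as np
import pytest

from tetracolour.phylo import (
    Phylogeny,
    RateMatrix,
    TraitMatrix,
    estimate_rate_matrix,
    prune_tree,
    read_tree,
    reconstruct_ancestral_states,
    simulate_bm,
    simulate_bm_batch,
)

NEXUS = """#NEXUS
BEGIN TAXA;
  DIMENSIONS NTAX=3;
  TAXLABELS A B C;
END;
BEGIN TREES;
  TREE test = ((A:1,B:2):0.5,C:3);
END;
"""


def shared_path_matrix(tree):
    """Dense covariance scaffold: C[i, j] = length of the shared root path
    of nodes i and j (preorder indexing). Independent of the package's
    reconstruction machinery."""
    n = len(tree.nodes)
    depth = tree.node_depths()
    anc = []
    for node in tree.nodes:
        chain = set()
        cur = node
        while cur is not None:
            chain.add(cur.index)
            cur = cur.parent
        anc.append(chain)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            common = anc[i] & anc[j]
            # the MRCA is the deepest common ancestor
            C[i, j] = max(depth[k] for k in common)
    return C


def gls_reconstruction(tree, tip_values):
    """Brute-force GLS oracle for one trait axis: ML root state, then the
    conditional Gaussian mean for every internal node."""
    C = shared_path_matrix(tree)
    tip_idx = [n.index for n in tree.tips]
    V = C[np.ix_(tip_idx, tip_idx)]
    Vinv = np.linalg.inv(V)
    ones = np.ones(len(tip_idx))
    x = np.asarray(tip_values, dtype=float)
    mu = (ones @ Vinv @ x) / (ones @ Vinv @ ones)
    out = {}
    for node in tree.internal_nodes:
        c = C[node.index, tip_idx]
        out[node.name] = mu + c @ Vinv @ (x - mu)
    return out


class TestReadTree:
    def test_two_tip_newick(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1);\n")
        tree = read_tree(p)
        assert sorted(tree.tip_labels) == ["A", "B"]
        assert all(t.length == 1 for t in tree.tips)
        assert len(tree.internal_nodes) == 1

    def test_polytomy_preserved(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1,C:1);\n")
        tree = read_tree(p)
        assert len(tree.root.children) == 3

    def test_nexus_equals_newick(self, tmp_path):
        nex = tmp_path / "t.nex"
        nex.write_text(NEXUS)
        nwk = tmp_path / "t.nwk"
        nwk.write_text("((A:1,B:2):0.5,C:3);\n")
        t1, t2 = read_tree(nex), read_tree(nwk)
        assert t1.to_newick() == t2.to_newick()
        assert t1.depth() == pytest.approx(t2.depth())

    def test_missing_branch_length(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B);\n")
        with pytest.raises(ValueError, match="branch length"):
            read_tree(p)

    def test_duplicate_tip_labels(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,(A:1,B:1):1);\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_tree(p)

    def test_zero_branch_perturbed_with_warning(self):
        with pytest.warns(UserWarning, match="zero-length"):
            tree = Phylogeny.from_newick("(A:0,B:1);")
        a = next(t for t in tree.tips if t.name == "A")
        assert 0 < a.length < 1e-6

    def test_newick_roundtrip(self):
        tree = Phylogeny.from_newick("((A:1.5,B:2):0.5,(C:1,D:1,E:1):2);")
        again = Phylogeny.from_newick(tree.to_newick())
        assert again.to_newick() == tree.to_newick()


class TestPruneTree:
    def test_prune_collapses_unary(self):
        tree = Phylogeny.from_newick("((A:1,B:2):0.5,C:3);")
        pruned = prune_tree(tree, {"A", "C"})
        assert sorted(pruned.tip_labels) == ["A", "C"]
        a = next(t for t in pruned.tips if t.name == "A")
        assert a.length == pytest.approx(1.5)  # 1 + 0.5 merged

    def test_prune_unknown_tip(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="not in tree"):
            prune_tree(tree, {"A", "Z"})


class TestReconstruction:
    def test_constant_tips_constant_nodes(self):
        tree = Phylogeny.from_newick("((A:1,B:2):0.5,(C:1,D:3):1.5);")
        tips = TraitMatrix({t: [0.7, -1.2, 3.0] for t in tree.tip_labels})
        full = reconstruct_ancestral_states(tree, tips)
        for node in tree.internal_nodes:
            np.testing.assert_allclose(full[node.name], [0.7, -1.2, 3.0], atol=1e-10)

    def test_two_tip_closed_form(self):
        tree = Phylogeny.from_newick("(A:1,B:3);")
        tips = TraitMatrix({"A": [0, 0, 0], "B": [1, 1, 1]})
        full = reconstruct_ancestral_states(tree, tips)
        np.testing.assert_allclose(full[tree.root.name], 0.25, atol=1e-12)

    def test_balanced_four_tip_vs_gls(self, rng):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        X = rng.standard_normal((4, 3))
        tips = TraitMatrix.from_arrays(tree.tip_labels, X)
        full = reconstruct_ancestral_states(tree, tips)
        for axis in range(3):
            oracle = gls_reconstruction(tree, X[:, axis])
            for name, val in oracle.items():
                assert full[name][axis] == pytest.approx(val, abs=1e-8)

    def test_six_tip_unbalanced_vs_gls(self, rng):
        tree = Phylogeny.from_newick(
            "(((A:0.3,B:1.1):0.4,(C:0.9,D:0.2,E:0.8):0.6):0.5,F:2.2);"
        )
        X = rng.standard_normal((6, 3)) * 2.0
        tips = TraitMatrix.from_arrays(tree.tip_labels, X)
        full = reconstruct_ancestral_states(tree, tips)
        for axis in range(3):
            oracle = gls_reconstruction(tree, X[:, axis])
            for name, val in oracle.items():
                assert full[name][axis] == pytest.approx(val, abs=1e-8)

    def test_star_tree_root_is_mean(self, rng):
        tree = Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        X = rng.standard_normal((5, 3))
        tips = TraitMatrix.from_arrays(tree.tip_labels, X)
        full = reconstruct_ancestral_states(tree, tips)
        np.testing.assert_allclose(full[tree.root.name], X.mean(axis=0), atol=1e-10)

    def test_linearity(self, rng):
        tree = Phylogeny.from_newick("((A:1,B:2):0.5,(C:1,D:3):1.5);")
        X = rng.standard_normal((4, 3))
        a, b = np.array([1.0, -2.0, 0.5]), 3.0
        f1 = reconstruct_ancestral_states(tree, TraitMatrix.from_arrays(tree.tip_labels, X))
        f2 = reconstruct_ancestral_states(
            tree, TraitMatrix.from_arrays(tree.tip_labels, a + b * X)
        )
        for node in tree.internal_nodes:
            np.testing.assert_allclose(f2[node.name], a + b * f1[node.name], atol=1e-9)

    def test_missing_tip_state(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        with pytest.raises(KeyError, match="B"):
            reconstruct_ancestral_states(tree, TraitMatrix({"A": [0, 0, 0]}))


class TestRateMatrix:
    def test_identical_tips_zero_matrix(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = TraitMatrix({t: [1.0, 2.0, 3.0] for t in tree.tip_labels})
        rate = estimate_rate_matrix(tree, tips)
        np.testing.assert_allclose(rate.matrix, 0, atol=1e-12)

    def test_star_tree_hand_enumeration(self):
        """Star tree, unit branches, 3 tips: sequential pairing gives
        contrasts (x1-x2)/sqrt(2) and ((x1+x2)/2 - x3)/sqrt(1.5)."""
        tree = Phylogeny.from_newick("(A:1,B:1,C:1);")
        X = np.array([[1.0, 0.0, 2.0], [3.0, 1.0, -1.0], [0.0, 5.0, 0.5]])
        tips = TraitMatrix.from_arrays(["A", "B", "C"], X)
        rate = estimate_rate_matrix(tree, tips)
        u1 = (X[0] - X[1]) / np.sqrt(2.0)
        u2 = ((X[0] + X[1]) / 2.0 - X[2]) / np.sqrt(1.5)
        expected = (np.outer(u1, u1) + np.outer(u2, u2)) / 2.0
        np.testing.assert_allclose(rate.matrix, expected, atol=1e-12)

    def test_positive_semidefinite(self, rng):
        from tetracolour.synthetic import yule_tree

        tree = yule_tree(30, seed=4)
        tips = TraitMatrix.from_arrays(
            tree.tip_labels, rng.standard_normal((30, 3))
        )
        rate = estimate_rate_matrix(tree, tips)
        assert np.linalg.eigvalsh(rate.matrix).min() >= -1e-12

    def test_parameter_recovery(self):
        """Estimate within 25% Frobenius error of the true rate, averaged
        over 50 seeded replicates on a 200-tip tree."""
        from tetracolour.synthetic import yule_tree

        true = RateMatrix(np.array([[1.0, 0.3, 0.0], [0.3, 0.8, -0.2], [0.0, -0.2, 1.2]]))
        tree = yule_tree(200, seed=21)
        errs = []
        for rep in range(50):
            sim = simulate_bm(tree, np.zeros(3), true, seed=1000 + rep)
            tips = TraitMatrix({t.name: sim[t.name] for t in tree.tips})
            est = estimate_rate_matrix(tree, tips)
            errs.append(
                np.linalg.norm(est.matrix - true.matrix) / np.linalg.norm(true.matrix)
            )
        assert np.mean(errs) < 0.25

    def test_too_few_tips(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        tips = TraitMatrix({"A": [0, 0, 0], "B": [1, 1, 1]})
        with pytest.raises(ValueError, match="3 tips"):
            estimate_rate_matrix(tree, tips)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="semidefinite"):
            RateMatrix(np.diag([1.0, -0.5, 1.0]))


class TestSimulateBM:
    def test_zero_rate_constant(self):
        tree = Phylogeny.from_newick("((A:1,B:2):0.5,C:3);")
        root = np.array([1.0, 2.0, 3.0])
        sim = simulate_bm(tree, root, RateMatrix(np.zeros((3, 3))), seed=0)
        for node in tree.nodes:
            np.testing.assert_allclose(sim[node.name], root)

    def test_tip_variance_moment(self):
        """2-tip tree of depth t: per-axis tip variance ~ sigma^2 * t."""
        tree = Phylogeny.from_newick("(A:2,B:2);")
        sigma2 = 0.7
        rng = np.random.default_rng(5)
        states = simulate_bm_batch(tree, np.zeros(3), RateMatrix.isotropic(sigma2), 1000, rng)
        a_idx = next(n.index for n in tree.nodes if n.name == "A")
        var = states[:, a_idx, :].var(axis=0, ddof=1)
        expected = sigma2 * 2.0
        se = expected * np.sqrt(2.0 / 999)
        assert np.all(np.abs(var - expected) <= 3 * se)

    def test_sister_covariance_moment(self):
        """Sister tips share path length s: covariance ~ sigma^2 * s."""
        tree = Phylogeny.from_newick("((A:1,B:1):1.5,C:2.5);")
        sigma2 = 1.0
        rng = np.random.default_rng(6)
        n = 4000
        states = simulate_bm_batch(tree, np.zeros(3), RateMatrix.isotropic(sigma2), n, rng)
        a = next(i.index for i in tree.nodes if i.name == "A")
        b = next(i.index for i in tree.nodes if i.name == "B")
        cov = np.mean(states[:, a, 0] * states[:, b, 0])  # known zero mean
        expected = sigma2 * 1.5
        # var of the MC covariance estimate: (var_a*var_b + cov^2)/n
        se = np.sqrt((2.5 * 2.5 + expected**2) / n)
        assert abs(cov - expected) <= 3 * se

    def test_reconstruction_centres_on_true_root(self):
        from tetracolour.synthetic import yule_tree

        tree = yule_tree(60, seed=9)
        root = np.array([2.0, -1.0, 0.5])
        rate = RateMatrix.isotropic(0.5)
        ests = []
        for rep in range(40):
            sim = simulate_bm(tree, root, rate, seed=rep)
            tips = TraitMatrix({t.name: sim[t.name] for t in tree.tips})
            full = reconstruct_ancestral_states(tree, tips)
            ests.append(full[tree.root.name])
        bias = np.mean(ests, axis=0) - root
        # root GLS variance is well below 0.5; 3 sigma over 40 reps
        assert np.all(np.abs(bias) < 3 * np.sqrt(0.5 / 40))

    def test_determinism(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        r = RateMatrix.isotropic(1.0)
        s1 = simulate_bm(tree, np.zeros(3), r, seed=42)
        s2 = simulate_bm(tree, np.zeros(3), r, seed=42)
        for name in s1.states:
            np.testing.assert_array_equal(s1[name], s2[name])


class TestTraitMatrixIO:
    def test_csv_roundtrip(self, tmp_path):
        tm = TraitMatrix({"sp1": [0.1, 0.2, 0.3], "sp2": [-1, 0, 1]})
        p = tmp_path / "traits.csv"
        tm.to_csv(p)
        back = TraitMatrix.from_csv(p)
        for k in tm.states:
            np.testing.assert_allclose(back[k], tm[k])

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            TraitMatrix({"a": [1.0, 2.0]})
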
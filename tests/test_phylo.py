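"""Phylogenetic covariance, Blomberg's K, pPCA, PACA, axis removal."""

import numpy as np
import pandas as pd
import pytest

from beakmorph import phylo, synthetic
from beakmorph.core import InvalidParameterError


def star_tree(n, depth=1.0):
    nw = "(" + ",".join(f"t{i}:{depth}" for i in range(n)) + ");"
    return phylo.Phylogeny.from_newick(nw)


def blomberg_oracle(x, C):
    """Independent transcription of the K formula (different linear
    algebra route: explicit solves, no shared code with the package)."""
    x = np.asarray(x, float)
    n = len(x)
    ones = np.ones(n)
    Ci_one = np.linalg.solve(C, ones)
    Ci_x = np.linalg.solve(C, x)
    a = (ones @ Ci_x) / (ones @ Ci_one)
    d = x - a
    mse0 = d @ d / (n - 1)
    mse = d @ np.linalg.solve(C, d) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Ci_one)) / (n - 1)
    return (mse0 / mse) / expected


class TestPhyloCovariance:
    def test_star_tree_is_scaled_identity(self):
        cov = phylo.phylo_covariance(star_tree(6, depth=2.5))
        assert np.allclose(cov.C, 2.5 * np.eye(6), atol=1e-12)

    def test_two_sisters_share_stem(self):
        tree = phylo.Phylogeny.from_newick("((A:2.0,B:2.0):1.0,C:3.0);")
        cov = phylo.phylo_covariance(tree)
        df = pd.DataFrame(cov.C, index=cov.tip_order, columns=cov.tip_order)
        assert df.loc["A", "B"] == pytest.approx(1.0)
        assert df.loc["A", "A"] == pytest.approx(3.0)
        assert df.loc["A", "C"] == pytest.approx(0.0)

    def test_tip_permutation_equivariance(self):
        clade = synthetic.simulate_clade(12, seed=1)
        cov = phylo.phylo_covariance(clade.tree)
        perm = list(reversed(cov.tip_order))
        cov2 = cov.reorder(perm)
        idx = [cov.tip_order.index(t) for t in perm]
        assert np.allclose(cov2.C, cov.C[np.ix_(idx, idx)], atol=1e-15)


class TestBlombergK:
    def test_affine_invariance_exact(self):
        clade = synthetic.simulate_clade(16, sigma=[0.5], seed=2, trait_names=("x",))
        x = clade.tip_traits["x"]
        k1 = phylo.blomberg_K(x, clade.tree)
        k2 = phylo.blomberg_K(3.0 - 2.5 * x, clade.tree)
        assert k1 == pytest.approx(k2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_oracle(self, seed):
        clade = synthetic.simulate_clade(
            6, sigma=[0.8], seed=100 + seed, trait_names=("x",)
        )
        cov = phylo.phylo_covariance(clade.tree)
        x = clade.tip_traits.loc[cov.tip_order, "x"].values
        ours = phylo.blomberg_K(clade.tip_traits["x"], clade.tree)
        assert ours == pytest.approx(blomberg_oracle(x, cov.C), abs=1e-10)

    def test_constant_trait_rejected(self):
        tree = star_tree(5)
        x = pd.Series(1.0, index=tree.tip_labels)
        with pytest.raises(InvalidParameterError):
            phylo.blomberg_K(x, tree)

    def test_bm_calibration_quick(self):
        ks = []
        for i in range(40):
            clade = synthetic.simulate_clade(
                32, sigma=[0.4], seed=200 + i, trait_names=("x",)
            )
            ks.append(phylo.blomberg_K(clade.tip_traits["x"], clade.tree))
        assert 0.85 < np.mean(ks) < 1.15


class TestMultivariateK:
    def test_reduces_to_univariate(self):
        clade = synthetic.simulate_clade(10, sigma=[0.5], seed=3, trait_names=("x",))
        k1 = phylo.blomberg_K(clade.tip_traits["x"], clade.tree)
        km = phylo.multivariate_K(clade.tip_traits[["x"]], clade.tree)
        assert km == pytest.approx(k1, abs=1e-10)

    def test_duplicated_column_unchanged(self):
        clade = synthetic.simulate_clade(10, sigma=[0.5], seed=4, trait_names=("x",))
        x = clade.tip_traits["x"]
        km1 = phylo.multivariate_K(x.to_frame(), clade.tree)
        km2 = phylo.multivariate_K(
            pd.DataFrame({"a": x, "b": x}), clade.tree
        )
        assert km2 == pytest.approx(km1, abs=1e-12)


class TestPhyloPCA:
    def test_star_tree_equals_ordinary_pca(self):
        tree = star_tree(20)
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 5)), index=tree.tip_labels)
        scores, vecs, evals = phylo.phylo_pca(X, tree)
        Xc = X.values - X.values.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        assert np.allclose(evals[:5], s**2 / 19, atol=1e-8)
        for j in range(5):
            cos = abs(vecs[:, j] @ vt[j])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_eigenvalues_non_negative_and_reconstruction(self):
        clade = synthetic.simulate_clade(15, sigma=[0.5] * 4, seed=5,
                                         trait_names=("a", "b", "c", "d"))
        X = clade.tip_traits
        scores, vecs, evals = phylo.phylo_pca(X, clade.tree)
        assert (evals >= 0).all()
        cov = phylo.phylo_covariance(clade.tree)
        arr = X.loc[cov.tip_order].values
        Cinv = np.linalg.inv(cov.C)
        ones = np.ones(len(arr))
        a = (ones @ Cinv @ arr) / (ones @ Cinv @ ones)
        assert np.abs(scores @ vecs.T + a - arr).max() < 1e-8


class TestPACA:
    def test_planted_alignment_recovered(self):
        rng = np.random.default_rng(0)
        clade = synthetic.simulate_clade(48, sigma=[1.0], seed=5, trait_names=("s",))
        tips = clade.tree.tip_labels
        X = np.column_stack(
            [2.0 * clade.tip_traits.loc[tips, "s"].values]
            + [rng.normal(size=48) for _ in range(7)]
        )
        comps, scores = phylo.paca(pd.DataFrame(X, index=tips), clade.tree)
        assert abs(comps[0, 0]) > 0.95

    def test_components_orthonormal(self):
        clade = synthetic.simulate_clade(20, sigma=[0.5] * 6, seed=6,
                                         trait_names=tuple("abcdef"))
        comps, _ = phylo.paca(clade.tip_traits, clade.tree)
        assert np.abs(comps.T @ comps - np.eye(6)).max() < 1e-9

    def test_first_axis_concentrates_signal(self):
        diffs = []
        for rep in range(8):
            tree, X = synthetic.simulate_phylo_latents(64, 8, 0.4, seed=300 + rep)
            _, pacs = phylo.paca(X, tree)
            Xc = X.values - X.values.mean(axis=0)
            _, _, vt = np.linalg.svd(Xc, full_matrices=False)
            pc1 = pd.Series(Xc @ vt[0], index=tree.tip_labels)
            pa1 = pd.Series(pacs[:, 0], index=tree.tip_labels)
            diffs.append(
                phylo.blomberg_K(pa1, tree) - phylo.blomberg_K(pc1, tree)
            )
        assert np.median(diffs) >= 0


class TestSignalProfile:
    def test_columnwise_and_permutation_null(self):
        tree, X = synthetic.simulate_phylo_latents(48, 6, 0.5, seed=9)
        prof = phylo.signal_profile(X, tree)
        assert prof.shape == (6,)
        rng = np.random.default_rng(0)
        perm = X.copy()
        perm.index = rng.permutation(X.index.values)
        prof_perm = phylo.signal_profile(perm, tree)
        assert np.nanmean(prof_perm) < np.nanmean(prof)

    def test_constant_column_flagged(self):
        tree = star_tree(10)
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10, 3)), index=tree.tip_labels)
        X.iloc[:, 1] = 5.0
        with pytest.warns(UserWarning):
            prof = phylo.signal_profile(X, tree)
        assert np.isnan(prof[1])
        assert np.isfinite(prof[[0, 2]]).all()


class TestAxisRemoval:
    def config(self, seed=0):
        return dict(
            model="random_forest",
            grid=[{"trees": 100}],
            n_mc_splits=4,
            seed=seed,
            test_prop=0.25,
        )

    def test_zero_drop_reproduces_baseline(self):
        tree, X = synthetic.simulate_phylo_latents(40, 6, 0.5, seed=11)
        labels = synthetic.labels_from_clades(tree, 2)
        a = phylo.axis_removal_experiment(X, tree, labels, self.config(), n_drop=0)
        b = phylo.axis_removal_experiment(X, tree, labels, self.config(), n_drop=0)
        assert a.balanced_accuracy == b.balanced_accuracy
        assert a.confusion.equals(b.confusion)

    def test_phylogenetic_labels_lose_accuracy_when_axis_removed(self):
        tree, X = synthetic.simulate_phylo_latents(96, 16, 0.5, seed=7)
        labels = synthetic.labels_from_clades(tree, 3)
        base = phylo.axis_removal_experiment(X, tree, labels, self.config(), n_drop=0)
        drop = phylo.axis_removal_experiment(X, tree, labels, self.config(), n_drop=1)
        assert drop.balanced_accuracy < base.balanced_accuracy

    def test_independent_labels_unaffected_within_noise(self):
        deltas = []
        for seed in range(10):
            tree, X = synthetic.simulate_phylo_latents(60, 8, 0.4, seed=500 + seed)
            rng = np.random.default_rng(seed)
            labels = pd.Series(
                rng.choice(["u", "v"], size=60), index=tree.tip_labels
            )
            base = phylo.axis_removal_experiment(
                X, tree, labels, self.config(seed), n_drop=0
            )
            drop = phylo.axis_removal_experiment(
                X, tree, labels, self.config(seed), n_drop=1
            )
            deltas.append(drop.balanced_accuracy - base.balanced_accuracy)
        assert abs(np.mean(deltas)) <= 0.05

    def test_invalid_drop_rejected(self):
        tree, X = synthetic.simulate_phylo_latents(20, 4, 0.5, seed=1)
        labels = synthetic.labels_from_clades(tree, 2)
        with pytest.raises(InvalidParameterError):
            phylo.axis_removal_experiment(X, tree, labels, self.config(), n_drop=4)
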
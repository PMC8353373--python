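import numpy as np
import pandas as pd
import pytest
import skbio

from bovarch.io import allele_frequencies
from bovarch.structure import genotype_pca, ld_prune, nj_tree, population_distance

from conftest import make_panel


def tree_distances(newick, labels):
    t = skbio.TreeNode.read([newick])
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i in labels:
        for j in labels:
            if i != j:
                out.loc[i, j] = t.find(i).distance(t.find(j))
    return out


def random_additive_matrix(n_leaves, seed):
    """Distances from a random binary tree with positive branch lengths."""
    rng = np.random.default_rng(seed)
    labels = [f"L{i}" for i in range(n_leaves)]
    nodes = {l: l for l in labels}
    items = list(labels)
    while len(items) > 2:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        a, b = items[j], items[i]  # pop larger index first
        items.remove(a); items.remove(b)
        bl_a, bl_b = rng.uniform(0.1, 2.0, 2)
        merged = f"({nodes[a]}:{bl_a:.6f},{nodes[b]}:{bl_b:.6f})"
        key = f"{a}|{b}"
        nodes[key] = merged
        items.append(key)
    bl = rng.uniform(0.1, 2.0, 2)
    nwk = f"({nodes[items[0]]}:{bl[0]:.6f},{nodes[items[1]]}:{bl[1]:.6f});"
    d = tree_distances(nwk, labels)
    d = (d + d.T) / 2  # remove float asymmetry from path summation
    return d, labels


class TestPopulationDistance:
    def test_identical_vectors(self):
        f = pd.DataFrame({"A": [0.1, 0.5], "B": [0.1, 0.5]})
        d = population_distance(f)
        assert d.loc["A", "B"] == 0.0

    def test_orthogonal_unit_vectors(self):
        f = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]})
        assert population_distance(f).loc["A", "B"] == pytest.approx(np.sqrt(2))

    def test_hand_computed_matrix(self):
        rng = np.random.default_rng(0)
        f = pd.DataFrame(rng.random((5, 3)), columns=["A", "B", "C"])
        d = population_distance(f)
        for a in "ABC":
            for b in "ABC":
                expected = np.sqrt(((f[a] - f[b]) ** 2).sum())
                assert d.loc[a, b] == pytest.approx(expected)
        # symmetry and zero diagonal
        np.testing.assert_allclose(d.to_numpy(), d.to_numpy().T)
        assert (np.diag(d.to_numpy()) == 0).all()

    def test_nan_markers_dropped(self):
        f = pd.DataFrame({"A": [0.0, 0.5], "B": [1.0, np.nan]})
        assert population_distance(f).loc["A", "B"] == pytest.approx(1.0)

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(1)
        f = pd.DataFrame(rng.random((10, 3)), columns=list("ABC"))
        d1 = population_distance(f)
        d2 = population_distance(f.iloc[::-1])
        pd.testing.assert_frame_equal(d1, d2)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            population_distance(pd.DataFrame({"A": [0.1]}))


class TestNJTree:
    def test_three_taxa_closed_form(self):
        # pendant lengths solve la+lb=dab, la+lc=dac, lb+lc=dbc
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        t = nj_tree(d)
        got = tree_distances(t.newick, list("ABC"))
        np.testing.assert_allclose(got.to_numpy(), d.to_numpy(), atol=1e-9)

    def test_four_taxon_additivity(self):
        d, labels = random_additive_matrix(4, seed=3)
        t = nj_tree(d)
        got = tree_distances(t.newick, labels)
        np.testing.assert_allclose(got.to_numpy(), d.to_numpy(), atol=1e-9)

    @pytest.mark.parametrize("n_leaves,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_random_tree_path_lengths_recovered(self, n_leaves, seed):
        d, labels = random_additive_matrix(n_leaves, seed)
        t = nj_tree(d)
        got = tree_distances(t.newick, labels)
        np.testing.assert_allclose(got.to_numpy(), d.to_numpy(), atol=1e-9)

    def test_agreement_with_reference_implementation(self):
        d, labels = random_additive_matrix(6, seed=7)
        mine = tree_distances(nj_tree(d).newick, labels)
        ref = skbio.tree.nj(skbio.DistanceMatrix(d.to_numpy(), ids=labels))
        for i in labels:
            for j in labels:
                if i != j:
                    assert mine.loc[i, j] == pytest.approx(
                        ref.find(i).distance(ref.find(j)), abs=1e-9)

    def test_equidistant_taxa_star_resolution(self):
        labels = list("ABCD")
        d = pd.DataFrame(2.0, index=labels, columns=labels)
        np.fill_diagonal(d.to_numpy(), 0.0)
        d = pd.DataFrame(np.where(np.eye(4), 0.0, 2.0), index=labels, columns=labels)
        t = nj_tree(d)
        got = tree_distances(t.newick, labels)
        np.testing.assert_allclose(got.to_numpy()[~np.eye(4, dtype=bool)], 2.0, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d)

    def test_fewer_than_three_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"),
                         dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d)


class TestPCA:
    def _diverged_panel(self):
        from bovarch.simulate import SimConfig, simulate_population

        panels = []
        for seed, label in ((1, "A"), (2, "B")):
            cfg = SimConfig(effective_size=30, sample_n=20, generations=60, seed=seed,
                            n_chromosomes=2, chromosome_length_bp=5_000_000,
                            marker_spacing_bp=25_000, breed_label=label)
            panels.append(simulate_population(cfg))
        a, b = panels
        dosages = np.vstack([a.dosages, b.dosages])
        samples = pd.concat([a.samples, b.samples], ignore_index=True)
        samples["sample_id"] = [f"x{i}" for i in range(len(samples))]
        from bovarch.core import GenotypeMatrix
        return GenotypeMatrix(samples=samples, markers=a.markers, dosages=dosages)

    def test_pc1_separates_diverged_populations(self):
        g = self._diverged_panel()
        pca = genotype_pca(g, n_components=2)
        pc1 = pca.scores["PC1"].to_numpy()
        a, b = pc1[:20], pc1[20:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            min(a.max(), b.max()) < max(a.min(), b.min())
        # zero overlap of score ranges
        assert a.max() < b.min() or b.max() < a.min()

    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        d[9] = d[0]
        g = make_panel(d)
        pca = genotype_pca(g, n_components=3)
        np.testing.assert_allclose(pca.scores.iloc[0], pca.scores.iloc[9], atol=1e-9)

    def test_explained_variance_non_increasing_and_bounded(self):
        rng = np.random.default_rng(5)
        g = make_panel(rng.integers(0, 3, size=(15, 40)).astype(np.int8))
        pca = genotype_pca(g, n_components=5)
        ev = pca.explained_variance_ratio
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1.0 + 1e-12

    def test_marker_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
        g1 = make_panel(d)
        perm = rng.permutation(20)
        g2 = g1.subset(marker_idx=perm)
        s1 = genotype_pca(g1, n_components=3).scores.to_numpy()
        s2 = genotype_pca(g2, n_components=3).scores.to_numpy()
        for c in range(3):
            assert (np.allclose(s1[:, c], s2[:, c], atol=1e-8)
                    or np.allclose(s1[:, c], -s2[:, c], atol=1e-8))

    def test_excess_components_reduced_with_warning(self):
        g = make_panel(np.array([[0, 1], [1, 0], [2, 2]], dtype=np.int8))
        with pytest.warns(UserWarning, match="reduced"):
            pca = genotype_pca(g, n_components=10)
        assert pca.scores.shape[1] <= 2


class TestLDPrune:
    def test_pruning_removes_duplicate_columns(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
        d = np.column_stack([base, base[:, 0]])  # marker 5 duplicates marker 0
        g = make_panel(d)
        keep = ld_prune(g, r2_threshold=0.99)
        assert 5 not in keep


class TestFrequencyPipelinePlumbing:
    def test_breed_frequency_table_feeds_distance(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(20, 15)).astype(np.int8)
        g = make_panel(d, breeds=["A"] * 10 + ["B"] * 10)
        freqs = allele_frequencies(g, by_breed=True)
        dist = population_distance(freqs)
        assert dist.shape == (2, 2)
        assert dist.loc["A", "B"] > 0
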
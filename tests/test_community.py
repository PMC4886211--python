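import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fermlink.community import (
    CommunityError, DistanceMatrix, StagePartition,
    hellinger, pca, pcoa, correlation_scaled_biplot,
    ward_hca, cut_to_groups, linkage_to_newick, amova, spearman_env,
)
from fermlink.tables import min_max_normalize
from fermlink.synthetic import LatentSpec, assemble_dataset
from conftest import small_abundance


def _dist_from(points):
    """Euclidean distance matrix from coordinates."""
    from scipy.spatial.distance import pdist, squareform

    pts = np.asarray(points, dtype=float)
    D = squareform(pdist(pts))
    ids = [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(pd.DataFrame(D, index=ids, columns=ids))


class TestHellinger:
    def test_identical_compositions_zero(self):
        a = small_abundance([[2.0, 4.0], [6.0, 12.0]])
        D = hellinger(a)
        assert D.values.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_compositions_sqrt2(self):
        a = small_abundance([[1.0, 0.0], [0.0, 1.0]])
        assert hellinger(a).values.iloc[0, 1] == pytest.approx(np.sqrt(2))

    def test_hand_value(self):
        a = small_abundance([[3.0, 1.0], [1.0, 3.0]])
        expected = np.sqrt(2 * (np.sqrt(0.75) - np.sqrt(0.25)) ** 2)
        assert hellinger(a).values.iloc[0, 1] == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.5176, abs=1e-4)

    def test_zero_sum_sample_errors(self):
        a = small_abundance([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(CommunityError, match="zero-sum"):
            hellinger(a)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a = small_abundance(rng.random((5, 3)) + 0.01)
        D = hellinger(a).values.to_numpy()
        assert D[0, 2] <= D[0, 1] + D[1, 2] + 1e-12
        assert D.max() <= np.sqrt(2) + 1e-12


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(-1, 1, 8)
        M = pd.DataFrame(np.column_stack([2 * t, -3 * t]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pca(M, n_components=2)
        assert res.explained[0] == pytest.approx(1.0)

    def test_matches_sklearn_oracle(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(17)
        M = pd.DataFrame(rng.normal(0, 1, (15, 6)))
        res = pca(M, n_components=3)
        sk = SkPCA(n_components=3).fit(M.to_numpy())
        sk_scores = sk.transform(M.to_numpy())
        for a in range(3):
            ours = res.scores.iloc[:, a].to_numpy()
            theirs = sk_scores[:, a]
            if ours @ theirs < 0:
                theirs = -theirs
            assert np.abs(ours - theirs).max() < 1e-8
        assert np.allclose(res.explained, sk.explained_variance_ratio_, atol=1e-10)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(18)
        M = pd.DataFrame(rng.normal(0, 1, (10, 4)))
        res = pca(M, n_components=4)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        Xc = M.to_numpy() - M.to_numpy().mean(axis=0)
        assert np.abs(recon - Xc).max() < 1e-8

    def test_rank_truncation_warns(self):
        t = np.linspace(0, 1, 6)
        M = pd.DataFrame(np.column_stack([t, 2 * t, 3 * t]))
        with pytest.warns(UserWarning, match="truncating"):
            res = pca(M, n_components=3)
        assert res.scores.shape[1] == 1


class TestPCoA:
    def test_matches_skbio_oracle(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(19)
        pts = rng.normal(0, 1, (10, 4))
        D = _dist_from(pts)
        res = pcoa(D, n_components=2)
        ref = skbio_pcoa(D.values.to_numpy(), number_of_dimensions=2)
        for a in range(2):
            ours = res.scores.iloc[:, a].to_numpy()
            theirs = ref.samples.iloc[:, a].to_numpy()
            if ours @ theirs < 0:
                theirs = -theirs
            assert np.abs(ours - theirs).max() < 1e-8

    def test_euclidean_distances_recover_configuration(self):
        rng = np.random.default_rng(20)
        pts = rng.normal(0, 1, (8, 2))
        res = pcoa(_dist_from(pts), n_components=2)
        from scipy.spatial.distance import pdist

        orig = pdist(pts)
        recon = pdist(res.scores.to_numpy())
        assert np.abs(orig - recon).max() < 1e-8


class TestBiplot:
    def test_feature_equal_to_score_has_unit_loading(self):
        rng = np.random.default_rng(21)
        M = pd.DataFrame(rng.normal(0, 1, (12, 4)))
        res = pca(M, n_components=2)
        M2 = M.copy()
        M2["t1copy"] = res.scores.iloc[:, 0]
        res2 = pca(M2, n_components=2)
        t_corr, p_corr = correlation_scaled_biplot(res2, M2)
        # the copied score correlates ~1 with the first component
        assert abs(p_corr.loc["t1copy"].abs().max() - 1.0) < 0.05

    def test_observation_radii_inside_unit_disk(self, prepared):
        fl = prepared["fl_norm"]
        res = pca(fl.values.T, n_components=2)
        t_corr, p_corr = correlation_scaled_biplot(res, fl.values.T)
        radii = np.sqrt((t_corr.to_numpy() ** 2).sum(axis=1))
        assert radii.max() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(p_corr.to_numpy()).max() <= 1.0 + 1e-12

    def test_p_corr_matches_association_pearson(self):
        """Cross-module oracle: p(corr) equals the pairwise Pearson matrix."""
        from fermlink.association import correlation_matrix
        from conftest import small_abundance, small_flavours

        rng = np.random.default_rng(22)
        M = pd.DataFrame(rng.normal(3, 1, (4, 3)),
                         columns=["f0", "f1", "f2"])
        res = pca(M, n_components=2)
        _, p_corr = correlation_scaled_biplot(res, M)
        # per-feature Pearson with each score, via the association module
        a = small_abundance(res.scores.to_numpy().T + 10,
                            taxa=["PC1", "PC2"], samples=list("wxyz"))
        f = small_flavours(M.to_numpy().T, flavours=list(M.columns),
                           samples=list("wxyz"))
        R = correlation_matrix(a, f)
        assert np.abs(p_corr.to_numpy() - R.to_numpy().T).max() < 1e-10


class TestWard:
    def test_two_samples_single_merge(self):
        D = _dist_from([[0.0], [3.0]])
        Z = ward_hca(D)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(3.0)

    def test_collinear_points_cut(self):
        D = _dist_from([[0.0], [1.0], [10.0]])
        part = cut_to_groups(ward_hca(D), 2, D.samples)
        labels = part.labels
        assert labels["s0"] == labels["s1"] != labels["s2"]

    def test_identical_samples_merge_first_at_zero(self):
        D = _dist_from([[0.0], [0.0], [5.0]])
        Z = ward_hca(D)
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_cut_too_many_groups(self):
        D = _dist_from([[0.0], [1.0]])
        with pytest.raises(CommunityError):
            cut_to_groups(ward_hca(D), 3, D.samples)

    def test_newick_export_parses(self):
        import io
        from Bio import Phylo

        D = _dist_from([[0.0], [1.0], [10.0], [11.0]])
        nwk = linkage_to_newick(ward_hca(D), D.samples)
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["s0", "s1", "s2", "s3"]

    def test_recovers_sharp_stage_structure(self):
        """Ward on flavours recovers the planted stages when transitions are
        crisp and the secondary succession component is negligible."""
        from itertools import combinations

        hits = 0
        for seed in range(5):
            spec = LatentSpec(seed=seed, stage_sharpness=0.5,
                              score_scales=(4.3, 0.05))
            ds = assemble_dataset(spec)
            fl = min_max_normalize(ds.flavours)
            part = cut_to_groups(ward_hca(fl.values.T), 3, fl.samples)
            truth = ds.metadata.table["stage"]
            a = part.labels.to_numpy()
            b = truth.to_numpy()
            same_a = a[:, None] == a[None, :]
            same_b = b[:, None] == b[None, :]
            iu = np.triu_indices(len(a), 1)
            rand = (same_a[iu] == same_b[iu]).mean()
            if rand >= 0.9:
                hits += 1
        assert hits >= 4


class TestAmova:
    def test_two_plus_two_exhaustive(self):
        """Two separated pairs: observed Fs is maximal; exact p = 1/3."""
        D = _dist_from([[0.0], [0.1], [10.0], [10.1]])
        part = StagePartition(pd.Series(["a", "a", "b", "b"], index=D.samples))
        res = amova(D, part, n_permutations=None)
        assert res.exhaustive
        assert res.p_value == pytest.approx(1 / 3)

    def test_matches_skbio_permanova_statistic(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova

        rng = np.random.default_rng(23)
        pts = rng.normal(0, 1, (12, 3))
        pts[:6] += 2.0
        D = _dist_from(pts)
        labels = ["a"] * 6 + ["b"] * 6
        part = StagePartition(pd.Series(labels, index=D.samples))
        res = amova(D, part, n_permutations=99, seed=1)
        ref = permanova(SkbioDM(D.values.to_numpy(), ids=list(D.samples)),
                        grouping=labels, permutations=0)
        assert res.fs == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_relabelling_within_orbit_leaves_fs_unchanged(self):
        rng = np.random.default_rng(24)
        pts = rng.normal(0, 1, (9, 2))
        D = _dist_from(pts)
        labels = ["x"] * 3 + ["y"] * 3 + ["z"] * 3
        part1 = StagePartition(pd.Series(labels, index=D.samples))
        relabel = {"x": "z", "y": "x", "z": "y"}
        part2 = StagePartition(pd.Series([relabel[l] for l in labels],
                                         index=D.samples))
        f1 = amova(D, part1, n_permutations=10, seed=0).fs
        f2 = amova(D, part2, n_permutations=10, seed=0).fs
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_single_sample_group_errors(self):
        D = _dist_from([[0.0], [1.0], [2.0]])
        part = StagePartition(pd.Series(["a", "a", "b"], index=D.samples))
        with pytest.raises(CommunityError, match="fewer than 2"):
            amova(D, part, n_permutations=10)

    def test_pairwise_results_present(self):
        rng = np.random.default_rng(25)
        pts = np.vstack([rng.normal(i * 3, 0.5, (4, 2)) for i in range(3)])
        D = _dist_from(pts)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        part = StagePartition(pd.Series(labels, index=D.samples))
        res = amova(D, part, n_permutations=49, seed=2, pairwise=True)
        assert set(res.pairwise) == {("a", "b"), ("a", "c"), ("b", "c")}
        for sub in res.pairwise.values():
            assert sub.fs > 1.0


class TestSpearman:
    def test_covariate_equal_to_axis(self):
        s = pd.Series([0.1, 0.5, 0.9, 1.2], index=list("abcd"))
        assert spearman_env(s, s) == pytest.approx(1.0)
        assert spearman_env(s, -s) == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        c = pd.Series([1.0, 3.0, 2.0, 4.0], index=list("abcd"))
        assert spearman_env(s, c) == pytest.approx(0.8)

    def test_constant_covariate_flagged(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        c = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman_env(s, c))

    def test_succession_axis_tracks_acidity(self):
        """Community PC1 follows the acidity gradient when the secondary
        (hump) component is weak relative to the succession axis."""
        from fermlink.tables import to_relative

        hits = 0
        for seed in range(5):
            ds = assemble_dataset(LatentSpec(seed=seed, score_scales=(4.3, 1.2)))
            rel = to_relative(ds.abundance)
            D = hellinger(rel)
            res = pcoa(D, n_components=2)
            rho = spearman_env(res.scores.iloc[:, 0],
                               ds.metadata.table["titratable_acidity"])
            if abs(rho) > 0.8:
                hits += 1
        assert hits >= 4
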
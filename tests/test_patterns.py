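"""Venn accounting, trajectory labels, SE-specific groups, k-means, PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import tfqpcr
from tfqpcr.patterns import ContrastCall, GenotypeCalls


class TestVennRegions:
    def test_three_set_enumeration(self):
        regions = tfqpcr.venn_regions(
            {"A": {"a", "b", "c"}, "B": {"b", "c"}, "C": {"c"}}
        )
        assert regions["A"] == 1
        assert regions["A&B"] == 1
        assert regions["A&B&C"] == 1
        assert sum(regions.values()) == 3
        assert regions["B"] == regions["C"] == regions["B&C"] == 0

    def test_empty_sets(self):
        assert all(
            v == 0 for v in tfqpcr.venn_regions({"A": set(), "B": set()}).values()
        )

    def test_identical_sets_fill_full_intersection(self):
        s = {"x", "y"}
        regions = tfqpcr.venn_regions({"A": s, "B": s, "C": s})
        assert regions["A&B&C"] == 2
        assert sum(regions.values()) == 2

    @given(
        st.dictionaries(
            st.sampled_from(["A", "B", "C"]),
            st.sets(st.integers(0, 30)),
            min_size=2, max_size=3,
        )
    )
    def test_regions_partition_the_union(self, sets):
        regions = tfqpcr.venn_regions(sets)
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)


class TestTrajectory:
    @pytest.mark.parametrize(
        "induction, formation, expected",
        [
            ((+16.0, True), (+1.5, False), ("up_x10", "steady")),
            ((-3.0, True), (+2.2, True), ("down_x2", "up_x2")),
            ((+1.1, False), (-1.3, False), ("steady", "steady")),
            ((-12.0, True), (-48.8, True), ("down_x10", "down_x10")),
        ],
    )
    def test_labels(self, induction, formation, expected):
        assert tfqpcr.classify_trajectory(induction, formation) == expected

    def test_crosstab_matches_brute_force(self):
        rng = np.random.default_rng(5)
        classes = ["up_x2", "up_x10", "down_x2", "down_x10", "steady"]
        labels = pd.DataFrame({
            "induction_class": rng.choice(classes, 40),
            "formation_class": rng.choice(classes, 40),
        })
        tab = tfqpcr.crosstab_trajectories(labels)
        # finest-label cells reproduce a direct tally
        for r in classes:
            for c in classes:
                expect = len(labels[
                    labels["induction_class"].isin(
                        {r, r.replace("_x2", "_x10")} if r.endswith("_x2") else {r}
                    )
                    & labels["formation_class"].isin(
                        {c, c.replace("_x2", "_x10")} if c.endswith("_x2") else {c}
                    )
                ])
                assert tab.loc[r, c] == expect
        # x>=10 rows nested inside x>=2 rows, cell-wise
        assert (tab.loc["up_x10"] <= tab.loc["up_x2"]).all()
        assert (tab.loc["down_x10"] <= tab.loc["down_x2"]).all()
        # marginals conserve the labelled genes
        finest = tab.loc[["up_x10", "down_x10", "steady"], "row_total"].sum()
        only_x2 = (
            tab.loc["up_x2", "row_total"] - tab.loc["up_x10", "row_total"]
            + tab.loc["down_x2", "row_total"] - tab.loc["down_x10", "row_total"]
        )
        assert finest + only_x2 == len(labels)

    def test_empty_labels_all_zero(self):
        tab = tfqpcr.crosstab_trajectories(
            pd.DataFrame(columns=["induction_class", "formation_class"])
        )
        assert (tab.to_numpy() == 0).all()


def _calls(expressed, ind_fc, ind_mod, form_fc=1.0, form_mod=False):
    return GenotypeCalls(
        expressed=expressed,
        induction=ContrastCall(ind_fc, ind_mod),
        formation=ContrastCall(form_fc, form_mod),
    )


class TestSeSpecific:
    def test_modulated_vs_steady_is_group_ii(self):
        # 30.06-fold up at induction, mutant steady in both contrasts
        emb = _calls(True, 30.06, True, 2.10, True)
        mut = _calls(True, 1.1, False, -1.2, False)
        assert tfqpcr.classify_se_specific(emb, mut) == "ii"

    def test_opposite_directions_group_iii_b(self):
        # down in the embryogenic culture, strongly up in the mutant
        emb = _calls(True, -2.97, True, -48.84, True)
        mut = _calls(True, 344.89, True, -2.03, True)
        assert tfqpcr.classify_se_specific(emb, mut) == "iii_b"

    def test_opposite_directions_group_iii_a(self):
        emb = _calls(True, 8.0, True)
        mut = _calls(True, -8.0, True)
        assert tfqpcr.classify_se_specific(emb, mut) == "iii_a"

    def test_exclusive_expression_group_i(self):
        emb = _calls(True, 12.0, True)
        mut = _calls(False, float("nan"), False)
        assert tfqpcr.classify_se_specific(emb, mut) == "i"

    def test_mutant_down_with_distinct_profile_group_iv(self):
        emb = _calls(True, -2.1, True)  # down_x2
        mut = _calls(True, -33.4, True)  # down_x10: profiles differ
        assert tfqpcr.classify_se_specific(emb, mut) == "iv"

    def test_shared_profile_is_not_se_specific(self):
        emb = _calls(True, -4.0, True)
        mut = _calls(True, -4.2, True)  # same label (down_x2) both stages
        assert tfqpcr.classify_se_specific(emb, mut) == "none"

    def test_steady_everywhere_is_none(self):
        emb = _calls(True, 1.2, False)
        mut = _calls(True, -1.1, False)
        assert tfqpcr.classify_se_specific(emb, mut) == "none"

    def test_assignment_is_single_valued(self, small_noiseless):
        _, _, truth, calls = small_noiseless
        from tfqpcr.patterns import SE_GROUPS

        se = tfqpcr.se_groups_from_calls(calls, "Col-0", "tan1-2")
        assert se.index.is_unique
        assert set(se) <= set(SE_GROUPS)

    def test_noiseless_groups_recovered_exactly(self, small_noiseless):
        _, _, truth, calls = small_noiseless
        se = tfqpcr.se_groups_from_calls(calls, "Col-0", "tan1-2")
        aligned = se.reindex(truth.index)
        assert (aligned == truth["se_group"]).all()


class TestKmeans:
    @staticmethod
    def _archetypes(n_per=30, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        shapes = {
            "down": [35.0, 30.0, 28.0],
            "up_early": [28.0, 36.0, 29.0],
            "up_sustained": [28.0, 35.0, 35.0],
            "flat": [30.0, 30.0, 30.0],
        }
        rows, labels = [], []
        for name, centre in shapes.items():
            for _ in range(n_per):
                rows.append(np.asarray(centre) + rng.normal(0, noise, 3))
                labels.append(name)
        idx = [f"G{i:04d}" for i in range(len(rows))]
        profiles = pd.DataFrame(rows, index=idx, columns=["0d", "5d", "10d"])
        return profiles, pd.Series(labels, index=idx)

    def test_separated_archetypes_fully_recovered(self):
        profiles, planted = self._archetypes()
        labels, centroids = tfqpcr.kmeans_patterns(profiles, k=4, seed=1)
        assert adjusted_rand_score(planted, labels) == 1.0
        assert set(labels) == {1, 2, 3, 4}
        # clusters renumbered by descending centroid mean
        means = centroids.mean(axis=1)
        assert (means.diff().dropna() <= 1e-9).all()

    def test_k1_centroid_is_grand_mean(self):
        profiles, _ = self._archetypes(n_per=5)
        labels, centroids = tfqpcr.kmeans_patterns(profiles, k=1, seed=0)
        assert (labels == 1).all()
        assert centroids.loc[1].to_numpy() == pytest.approx(
            profiles.mean(axis=0).to_numpy()
        )

    def test_deterministic_given_seed(self):
        profiles, _ = self._archetypes()
        l1, c1 = tfqpcr.kmeans_patterns(profiles, k=4, seed=9)
        l2, c2 = tfqpcr.kmeans_patterns(profiles, k=4, seed=9)
        assert l1.equals(l2)
        assert np.allclose(c1, c2)

    def test_points_assigned_to_nearest_centroid(self):
        profiles, _ = self._archetypes()
        labels, centroids = tfqpcr.kmeans_patterns(profiles, k=4, seed=2)
        X = profiles.to_numpy()
        C = centroids.to_numpy()
        nearest = np.argmin(
            ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1), axis=1
        ) + 1
        assert (labels.to_numpy() == nearest).all()

    def test_k_exceeding_distinct_profiles_rejected(self):
        profiles = pd.DataFrame([[1.0, 1.0]] * 5, columns=["0d", "5d"])
        with pytest.raises(tfqpcr.errors.ConfigError):
            tfqpcr.kmeans_patterns(profiles, k=2)


class TestPca:
    def test_rank_one_matrix(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([2.0, -1.0, 0.5])
        matrix = pd.DataFrame(np.outer(v, w))
        _, _, fractions = tfqpcr.pca_samples(matrix)
        assert fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.normal(size=(10, 25)))
        _, _, fractions = tfqpcr.pca_samples(matrix)
        assert fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.normal(size=(8, 12)))
        scores, loadings, _ = tfqpcr.pca_samples(matrix)
        centered = matrix - matrix.mean(axis=0)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        assert np.abs(recon - centered.to_numpy()).max() < 1e-10

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(rng.normal(size=(6, 9)))
        _, loadings, _ = tfqpcr.pca_samples(matrix)
        for pc in loadings.columns:
            col = loadings[pc].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_replicates_cluster_in_pc_space(self):
        """Planted condition effects 10x the replicate noise: replicate
        triplets are mutually nearest neighbours in PC1-PC2."""
        rng = np.random.default_rng(6)
        noise = 0.25
        conditions = [f"{g}:{t}" for g in ("Col-0", "tan1-2")
                      for t in (0, 5, 10) for _ in range(3)]
        means = {c: rng.normal(30, 10 * noise, 60)
                 for c in dict.fromkeys(conditions)}
        matrix = pd.DataFrame(
            [means[c] + rng.normal(0, noise, 60) for c in conditions]
        )
        scores, _, _ = tfqpcr.pca_samples(matrix)
        xy = scores[["PC1", "PC2"]].to_numpy()
        d = ((xy[:, None] - xy[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d, np.inf)
        for i in range(len(xy)):
            assert conditions[int(np.argmin(d[i]))] == conditions[i]

    def test_too_few_samples_rejected(self):
        with pytest.raises(tfqpcr.errors.ConfigError):
            tfqpcr.pca_samples(pd.DataFrame([[1.0, 2.0]]))
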
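"""MAD selection, Ward linkage against a naive Lance-Williams oracle,
consensus clustering, binary encoding, COCA, and cluster ordering."""
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_rand_score

import oncomet as om
from oncomet.clustering import ward_linkage


def matrix_from(values, scale_tag="log2"):
    arr = np.asarray(values, dtype=float)
    return om.AbundanceMatrix(
        pd.DataFrame(arr,
                     index=[f"F{i:03d}" for i in range(arr.shape[0])],
                     columns=[f"S{j:02d}" for j in range(arr.shape[1])]),
        scale_tag=scale_tag,
    )


def naive_ward(x):
    """O(n³) bottom-up Ward using the Lance-Williams update on squared
    Euclidean distances; returns merge heights in scipy's convention
    (sqrt of the minimized squared-distance criterion)."""
    n = x.shape[0]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)
    active = {i: 1 for i in range(n)}  # cluster id -> size
    heights = []
    current = {i: i for i in range(n)}
    next_id = n
    d2 = d2.astype(float)
    ids = list(range(n))
    dist = {(min(a, b), max(a, b)): d2[a, b] for a in ids for b in ids if a < b}
    sizes = {i: 1 for i in ids}
    while len(ids) > 1:
        (a, b), best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(best))
        sa, sb = sizes[a], sizes[b]
        merged = next_id
        next_id += 1
        for c in ids:
            if c in (a, b):
                continue
            sc = sizes[c]
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            dab = best
            new = ((sa + sc) * dac + (sb + sc) * dbc - sc * dab) / (sa + sb + sc)
            dist[(min(merged, c), max(merged, c))] = new
        for c in ids:
            dist.pop((min(a, c), max(a, c)), None)
            dist.pop((min(b, c), max(b, c)), None)
        ids = [c for c in ids if c not in (a, b)] + [merged]
        sizes[merged] = sa + sb
    return np.array(heights)


class TestMADSelect:
    def test_constant_feature_loses(self):
        m = matrix_from([[1.0, 1.0, 1.0, 1.0], [1.0, 5.0, 2.0, 9.0]])
        out = om.mad_select(m, 1)
        assert out.feature_ids == ["F001"]

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(6)
        m = matrix_from(rng.normal(size=(100, 15)))
        out = om.mad_select(m, 30)
        mads = {
            fid: np.median(np.abs(row - np.median(row)))
            for fid, row in m.data.iterrows()
        }
        expected = sorted(mads, key=lambda f: (-mads[f], f))[:30]
        assert out.feature_ids == expected

    def test_invalid_top_n(self, small_matrix):
        with pytest.raises(om.DataError):
            om.mad_select(small_matrix, 0)
        with pytest.raises(om.DataError):
            om.mad_select(small_matrix, 99)


class TestWardHclust:
    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        cloud_a = rng.normal(0, 1, size=(5, 8))
        cloud_b = rng.normal(100, 1, size=(5, 8))
        m = matrix_from(np.vstack([np.hstack([cloud_a, cloud_b])]))
        labels = om.ward_hclust(m, 2)
        assert labels.iloc[:8].nunique() == 1
        assert labels.iloc[8:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_equals_n_singletons(self, small_matrix):
        labels = om.ward_hclust(small_matrix, small_matrix.n_samples)
        assert labels.nunique() == small_matrix.n_samples

    def test_k_too_large_raises(self, small_matrix):
        with pytest.raises(om.DataError):
            om.ward_hclust(small_matrix, 99)

    def test_six_point_hand_traceable_merge_heights(self):
        # 2-D points whose Ward merges can be traced by hand through the
        # Lance-Williams recurrence
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.0, 1.2],
                        [10.0, 0.0], [10.0, 0.5]])
        z = ward_linkage(pts)
        np.testing.assert_allclose(np.sort(z[:, 2])[:3],
                                   np.sort([1.0, 1.2, 0.5]))
        np.testing.assert_allclose(z[:, 2], naive_ward(pts), rtol=1e-10)

    def test_matches_naive_lance_williams_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            x = rng.normal(size=(n, int(rng.integers(2, 6))))
            np.testing.assert_allclose(ward_linkage(x)[:, 2], naive_ward(x),
                                       rtol=1e-8)


class TestConsensusCluster:
    def separable_matrix(self, k=3, per=10, seed=0):
        cfg = om.SimulationConfig(
            n_tumor=k * per, n_normal=0, n_metabolites=200, n_blocks=1,
            censor_quantile=0.0, dilution_range=(1.0, 1.0), n_freeze_assoc=0,
            n_latent_clusters=k, cluster_sep=4.0, n_cluster_features=60,
            seed=seed,
        )
        m, ann, truth = om.simulate_metabolomics(cfg)
        log2m = om.log2_transform(om.pqn_normalize(om.impute_min(m))[0])
        return om.mad_select(log2m, 150), truth

    def test_full_subsample_yields_binary_consensus(self):
        m, _ = self.separable_matrix()
        results = om.consensus_cluster(m, k_range=(3,), n_iter=5,
                                       subsample_fraction=1.0, seed=0)
        c = results[3].consensus.to_numpy()
        assert np.isin(c, [0.0, 1.0]).all()
        assert results[3].concordance == pytest.approx(1.0)

    def test_recovers_three_clusters(self):
        m, truth = self.separable_matrix()
        results = om.consensus_cluster(m, k_range=(2, 3, 4, 5, 6),
                                       n_iter=50, subsample_fraction=0.8, seed=7)
        best = om.select_best_k(results)
        assert best == 3
        member = results[3].membership
        true_labels = [truth.true_clusters[s] for s in member.index]
        assert adjusted_rand_score(true_labels, member.to_numpy()) == 1.0

    def test_consensus_matrix_invariants(self):
        m, _ = self.separable_matrix(seed=5)
        res = om.consensus_cluster(m, k_range=(3,), n_iter=20, seed=5)[3]
        c = res.consensus.to_numpy()
        assert np.nanmax(c) <= 1.0 and np.nanmin(c) >= 0.0
        np.testing.assert_allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)

    def test_deterministic_under_seed(self):
        m, _ = self.separable_matrix(seed=2)
        r1 = om.consensus_cluster(m, k_range=(2, 3), n_iter=10, seed=42)
        r2 = om.consensus_cluster(m, k_range=(2, 3), n_iter=10, seed=42)
        for k in (2, 3):
            pd.testing.assert_frame_equal(r1[k].consensus, r2[k].consensus)
            pd.testing.assert_series_equal(r1[k].membership, r2[k].membership)
            assert r1[k].concordance == r2[k].concordance

    def test_k_range_extension_does_not_perturb_existing_k(self):
        m, _ = self.separable_matrix(seed=3)
        narrow = om.consensus_cluster(m, k_range=(3,), n_iter=10, seed=11)
        wide = om.consensus_cluster(m, k_range=(2, 3, 4), n_iter=10, seed=11)
        pd.testing.assert_frame_equal(narrow[3].consensus, wide[3].consensus)


class TestEncodeBinary:
    def test_single_modality_one_hot(self):
        member = pd.Series([1, 2, 3, 1, 2], index=[f"S{i}" for i in range(5)])
        binary = om.encode_binary({"rna": member})
        assert binary.shape == (5, 3)
        assert (binary.sum(axis=1) == 1).all()

    def test_two_modalities_row_sums(self):
        idx = [f"S{i}" for i in range(6)]
        binary = om.encode_binary({
            "rna": pd.Series([1, 1, 2, 2, 3, 3], index=idx),
            "metab": pd.Series([1, 2, 1, 2, 1, 2], index=idx),
        })
        assert (binary.sum(axis=1) == 2).all()

    def test_argmax_recovers_memberships(self):
        rng = np.random.default_rng(8)
        idx = [f"S{i}" for i in range(20)]
        memberships = {
            "rna": pd.Series(rng.integers(1, 4, 20), index=idx),
            "metab": pd.Series(rng.integers(1, 5, 20), index=idx),
        }
        binary = om.encode_binary(memberships)
        for modality, member in memberships.items():
            cols = [c for c in binary.columns if c.startswith(f"{modality}:")]
            recovered = binary[cols].idxmax(axis=1).str.split(":").str[1].astype(int)
            pd.testing.assert_series_equal(recovered, member, check_names=False)

    def test_partial_overlap_drops_with_warning(self):
        a = pd.Series([1, 2], index=["S0", "S1"])
        b = pd.Series([1, 2], index=["S1", "S2"])
        with pytest.warns(UserWarning, match="dropped"):
            binary = om.encode_binary({"rna": a, "metab": b})
        assert list(binary.index) == ["S1"]


class TestCOCA:
    def test_identical_memberships_recovered(self):
        idx = [f"S{i}" for i in range(18)]
        member = pd.Series([1, 2, 3] * 6, index=idx)
        result = om.coca({"rna": member, "metab": member},
                         k_range=(2, 3, 4), n_iter=30, seed=0)
        assert result.k == 3
        assert adjusted_rand_score(member, result.membership) == 1.0

    def test_requires_two_modalities(self):
        member = pd.Series([1, 2], index=["S0", "S1"])
        with pytest.raises(om.DataError, match="modalities"):
            om.coca({"rna": member})

    def test_k_override_respected_and_curve_reported(self):
        idx = [f"S{i}" for i in range(20)]
        rng = np.random.default_rng(3)
        ms = {"rna": pd.Series(rng.integers(1, 4, 20), index=idx),
              "metab": pd.Series(rng.integers(1, 4, 20), index=idx)}
        result = om.coca(ms, k_range=(2, 3, 4), n_iter=20, seed=1, k_override=4)
        assert result.k == 4
        assert set(result.concordance_by_k) == {2, 3, 4}


class TestOrderClusters:
    def annotations(self, histology, recurrence=None):
        n = len(histology)
        recurrence = recurrence or [False] * n
        return om.SampleAnnotation(pd.DataFrame(
            {"group": ["tumor"] * n, "histology": histology,
             "recurrence": recurrence},
            index=pd.Index([f"S{i}" for i in range(n)], name="sample_id")))

    def test_orders_by_proportion(self):
        # per-cluster aggressive proportions 0.67, 0.17, 0.57, 0.29 must map
        # to C4, C1, C3, C2
        hist, members = [], []
        for cid, (n, n_agg) in enumerate([(6, 4), (6, 1), (7, 4), (7, 2)], start=1):
            for j in range(n):
                members.append(cid)
                hist.append("HWIDE" if j < n_agg else "HMIN")
        membership = pd.Series(members, index=[f"S{i}" for i in range(len(members))])
        labels, label_map, props = om.order_clusters_by_aggressiveness(
            membership, self.annotations(hist))
        assert label_map == {2: "C1", 4: "C2", 3: "C3", 1: "C4"}
        assert props["C1"] == pytest.approx(1 / 6)
        assert props["C4"] == pytest.approx(4 / 6)

    def test_tie_break_by_size(self):
        membership = pd.Series([1, 1, 1, 2, 2], index=[f"S{i}" for i in range(5)])
        labels, label_map, _ = om.order_clusters_by_aggressiveness(
            membership, self.annotations(["HMIN"] * 5))
        assert label_map == {2: "C1", 1: "C2"}  # equal proportions: smaller first

    def test_single_cluster_is_c1(self):
        membership = pd.Series([1, 1], index=["S0", "S1"])
        labels, _, _ = om.order_clusters_by_aggressiveness(
            membership, self.annotations(["HWIDE", "HMIN"]))
        assert set(labels) == {"C1"}
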
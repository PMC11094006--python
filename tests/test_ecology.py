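"""Grouping rules, Bray-Curtis, PCoA and ANOSIM tests with oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from oracles import anosim_r
from thermarch import ecology as eco
from thermarch.abundance import AbundanceMatrix


class TestAssignGroups:
    @pytest.mark.parametrize(
        "ph,temp,ph_class,temp_class",
        [
            (2.11, 38.1, "acidic", "mesothermal"),
            (9.98, 64.7, "alkaline", "thermal"),
            (7.47, 36.0, "neutral", "mesothermal"),
            (5.5, 60.0, "neutral", "thermal"),  # boundaries to upper class
            (8.5, 80.0, "alkaline", "hyperthermal"),
            (5.49, 59.9, "acidic", "mesothermal"),
        ],
    )
    def test_threshold_rules(self, ph, temp, ph_class, temp_class):
        meta = pd.DataFrame(
            {"sample_id": ["x"], "pH": [ph], "temperature_C": [temp]}
        )
        out = eco.assign_groups(meta)
        assert out.loc["x", "ph_class"] == ph_class
        assert out.loc["x", "temp_class"] == temp_class
        assert not out.loc["x", "ungrouped"]

    def test_missing_values_flagged(self):
        meta = pd.DataFrame(
            {"sample_id": ["x"], "pH": [np.nan], "temperature_C": [50.0]}
        )
        out = eco.assign_groups(meta)
        assert out.loc["x", "ungrouped"]

    def test_pure_function(self):
        meta = pd.DataFrame(
            {"sample_id": list("abc"), "pH": [3, 7, 9],
             "temperature_C": [50, 70, 90]}
        )
        assert eco.assign_groups(meta).equals(eco.assign_groups(meta))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        data = pd.DataFrame(
            {"S1": [1, 0], "S2": [1, 0], "S3": [0, 2]}, index=["a", "b"]
        )
        dm = eco.bray_curtis(AbundanceMatrix(data=data))
        assert dm["S1", "S2"] == 0.0
        assert dm["S1", "S3"] == 1.0

    def test_hand_computed_value(self):
        data = pd.DataFrame({"S1": [1, 1], "S2": [0, 2]}, index=["a", "b"])
        dm = eco.bray_curtis(AbundanceMatrix(data=data))
        assert dm["S1", "S2"] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self):
        data = pd.DataFrame({"S1": [1, 1], "S2": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            eco.bray_curtis(AbundanceMatrix(data=data))


class TestPcoa:
    def _euclidean_dm(self, points, ids=None):
        ids = ids or [f"s{i}" for i in range(len(points))]
        return DistanceMatrix(squareform(pdist(np.asarray(points))), ids=ids)

    def test_collinear_points_one_axis(self):
        points = [[0, 0], [1, 2], [2, 4], [3, 6], [4, 8]]
        res = eco.pcoa(self._euclidean_dm(points))
        assert res.proportion_explained[0] > 0.999

    def test_round_trip_euclidean(self, rng):
        points = rng.normal(size=(8, 3))
        dm = self._euclidean_dm(points.tolist())
        res = eco.pcoa(dm)
        recon = squareform(pdist(res.coordinates.values))
        assert np.abs(recon - dm.data).max() < 1e-8

    def test_relabelling_invariance(self, rng):
        points = rng.normal(size=(6, 2))
        dm = self._euclidean_dm(points.tolist())
        res = eco.pcoa(dm)
        perm = [3, 1, 5, 0, 2, 4]
        ids = [dm.ids[i] for i in perm]
        dm2 = DistanceMatrix(dm.data[np.ix_(perm, perm)], ids=ids)
        res2 = eco.pcoa(dm2)
        a = res.coordinates.loc[ids].values
        b = res2.coordinates.values
        # coordinates agree up to per-axis sign
        for col in range(min(a.shape[1], b.shape[1])):
            assert np.allclose(a[:, col], b[:, col], atol=1e-8) or np.allclose(
                a[:, col], -b[:, col], atol=1e-8
            )

    def test_variance_equals_centered_trace(self, rng):
        data = pd.DataFrame(
            rng.dirichlet(np.ones(5), size=6).T,
            index=list("abcde"),
            columns=[f"s{i}" for i in range(6)],
        )
        dm = eco.bray_curtis(AbundanceMatrix(data=data))
        res = eco.pcoa(dm)
        n = dm.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dm.data**2) @ j
        total = res.eigenvalues.sum() - res.negative_eigenvalues.sum()
        assert total == pytest.approx(np.trace(b), abs=1e-9)

    def test_matches_skbio(self, rng):
        points = rng.normal(size=(7, 3))
        dm = self._euclidean_dm(points.tolist())
        res = eco.pcoa(dm)
        from skbio.stats.ordination import pcoa as skbio_pcoa

        ref = skbio_pcoa(dm, method="eigh")
        ref_pos = np.sort(ref.eigvals[ref.eigvals > 1e-10].values)[::-1]
        assert np.allclose(res.eigenvalues, ref_pos, atol=1e-8)

    def test_too_few_samples(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            eco.pcoa(dm)


class TestAnosim:
    def _clustered_dm(self, rng, separated=True):
        a = rng.normal(0, 0.1, size=(4, 2))
        offset = 10.0 if separated else 0.0
        b = rng.normal(offset, 0.1, size=(4, 2))
        pts = np.vstack([a, b])
        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=ids)
        return dm, groups

    def test_perfect_separation_r_one(self, rng):
        dm, groups = self._clustered_dm(rng, separated=True)
        res = eco.anosim(dm, groups, permutations=199, seed=0)
        assert res["R"] == pytest.approx(1.0)

    def test_random_labels_r_near_zero(self, rng):
        dm, groups = self._clustered_dm(rng, separated=False)
        res = eco.anosim(dm, groups, permutations=499, seed=1)
        assert abs(res["R"]) < 0.15 or res["p"] > 0.05

    def test_r_matches_independent_oracle_and_skbio(self, rng):
        dm, groups = self._clustered_dm(rng, separated=True)
        want = anosim_r(dm.data, groups.values)
        res = eco.anosim(dm, groups, permutations=99, seed=0)
        assert res["R"] == pytest.approx(want)
        ref = skbio_anosim(dm, groups.values, permutations=0)
        assert res["R"] == pytest.approx(ref["test statistic"])

    def test_rank_invariance_to_monotone_transform(self, rng):
        dm, groups = self._clustered_dm(rng, separated=True)
        dm2 = DistanceMatrix(np.sqrt(dm.data), ids=dm.ids)
        r1 = eco.anosim(dm, groups, permutations=99, seed=0)["R"]
        r2 = eco.anosim(dm2, groups, permutations=99, seed=0)["R"]
        assert r1 == pytest.approx(r2)

    def test_add_one_p_never_zero(self, rng):
        dm, groups = self._clustered_dm(rng, separated=True)
        res = eco.anosim(dm, groups, permutations=999, seed=3)
        assert 0.0 < res["p"] <= 1.0

    def test_small_group_rejected(self, rng):
        dm, groups = self._clustered_dm(rng)
        groups.iloc[:] = ["g1"] * 7 + ["g2"]
        with pytest.raises(ValueError):
            eco.anosim(dm, groups)


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2 * v + 1 for v in x]
        assert eco.pearson_test(x, y)["r"] == pytest.approx(1.0)

    def test_orthogonal(self):
        x = [-1.0, 0.0, 1.0]
        y = [1.0, -2.0, 1.0]  # symmetric around x=0: r = 0
        assert eco.pearson_test(x, y)["r"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_formula(self, rng):
        x = rng.normal(size=25)
        y = 0.4 * x + rng.normal(size=25)
        res = eco.pearson_test(x, y)
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        tstat = r * np.sqrt((len(x) - 2) / (1 - r**2))
        p = 2 * t_dist.sf(abs(tstat), df=len(x) - 2)
        assert res["r"] == pytest.approx(r, abs=1e-12)
        assert res["p"] == pytest.approx(p, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            eco.pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
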
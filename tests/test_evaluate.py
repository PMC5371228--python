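import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from methclock import cluster_heatmap, compare_treatments, pca_clock_sites
from methclock.clock import PredictionResult
from methclock.core import DAYS_PER_MONTH

from conftest import make_meta


def predictions_from_months(epi_months, age_months, samples=None):
    samples = samples or [f"s{i}" for i in range(len(epi_months))]
    epi = np.asarray(epi_months, dtype=float)
    age = np.asarray(age_months, dtype=float)
    table = pd.DataFrame(
        {
            "epigenetic_age_days": epi * DAYS_PER_MONTH,
            "epigenetic_age_months": epi,
            "age_days": age * DAYS_PER_MONTH,
            "age_months": age,
            "residual_months": epi - age,
        },
        index=samples,
    )
    return PredictionResult(table=table)


class TestTreatmentComparison:
    def meta_for(self, pred, treatments):
        return make_meta(
            list(pred.table.index),
            list(pred.table["age_days"]),
            treatment=list(treatments),
        )

    def test_identical_groups_give_zero_reduction_and_p_one(self):
        vals = [22, 23, 21, 22] * 2
        pred = predictions_from_months(vals, [22] * 8)
        meta = self.meta_for(pred, ["none"] * 4 + ["dwarf"] * 4)
        comp = compare_treatments(pred, meta)
        row = comp.per_group.iloc[0]
        assert row["reduction_months"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_toy_reduction_matches_hand_computed_t(self):
        control, treated = [22.0, 23.0, 21.0, 22.0], [12.0, 13.0, 11.0, 12.0]
        pred = predictions_from_months(control + treated, [22] * 8)
        meta = self.meta_for(pred, ["none"] * 4 + ["dwarf"] * 4)
        comp = compare_treatments(pred, meta)
        row = comp.per_group.iloc[0]
        assert row["reduction_months"] == pytest.approx(10.0)
        # pooled-variance two-sample t with equal n
        sp2 = (np.var(control, ddof=1) + np.var(treated, ddof=1)) / 2
        t_hand = 10.0 / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert row["t"] == pytest.approx(t_hand, abs=1e-12)

    def test_reduction_is_antisymmetric_under_label_swap(self):
        pred = predictions_from_months([20, 21, 19, 13, 12, 14], [22] * 6)
        meta_a = self.meta_for(pred, ["none"] * 3 + ["dwarf"] * 3)
        meta_b = self.meta_for(pred, ["dwarf"] * 3 + ["none"] * 3)
        a = compare_treatments(pred, meta_a).per_group.iloc[0]["reduction_months"]
        b = compare_treatments(pred, meta_b).per_group.iloc[0]["reduction_months"]
        assert a == pytest.approx(-b)

    def test_two_group_anova_f_equals_t_squared(self):
        pred = predictions_from_months([20, 21, 19, 22, 13, 12, 14, 11], [22] * 8)
        meta = self.meta_for(pred, ["none"] * 4 + ["dwarf"] * 4)
        comp = compare_treatments(pred, meta, anova_group="22m")
        row = comp.per_group.iloc[0]
        assert comp.anova_F == pytest.approx(row["t"] ** 2, rel=1e-10)

    def test_treated_group_without_controls_rejected(self):
        pred = predictions_from_months([20, 21, 13, 12], [22] * 4)
        meta = self.meta_for(pred, ["rapamycin"] * 2 + ["dwarf"] * 2)
        with pytest.raises(ValueError, match="matched controls"):
            compare_treatments(pred, meta)


class TestPCA:
    def age_dominant_data(self, n=30, g=40, seed=1):
        rng = np.random.default_rng(seed)
        age = np.linspace(30, 700, n)
        loadings = rng.normal(0, 1, g)
        X = np.log2(age)[:, None] * loadings[None, :] * 0.05
        X += rng.normal(0, 0.01, (n, g))
        frac = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                            columns=[f"1:{j}" for j in range(g)])
        meta = make_meta(list(frac.index), list(age))
        return frac, meta

    def test_pc1_tracks_the_planted_age_axis(self):
        frac, meta = self.age_dominant_data()
        res = pca_clock_sites(frac, meta)
        r = stats.pearsonr(res.scores["PC1"], meta["age_days"])[0]
        assert r > 0.9  # oriented positively by convention

    def test_duplicated_samples_share_scores(self):
        frac, meta = self.age_dominant_data(n=10)
        dup = pd.concat([frac, frac.rename(index=lambda s: s + "_copy")])
        meta_dup = pd.concat([meta, meta.rename(index=lambda s: s + "_copy")])
        res = pca_clock_sites(dup, meta_dup)
        a = res.scores.loc[frac.index].to_numpy()
        b = res.scores.loc[[s + "_copy" for s in frac.index]].to_numpy()
        assert np.allclose(a, b)

    def test_feature_sign_flip_keeps_pc1_orientation(self):
        frac, meta = self.age_dominant_data()
        res_pos = pca_clock_sites(frac, meta)
        res_neg = pca_clock_sites(-frac, meta)
        r_pos = stats.pearsonr(res_pos.scores["PC1"], meta["age_days"])[0]
        r_neg = stats.pearsonr(res_neg.scores["PC1"], meta["age_days"])[0]
        assert r_pos > 0.9 and r_neg > 0.9

    def test_full_rank_scores_reconstruct_the_data(self):
        frac, meta = self.age_dominant_data(n=12, g=8)
        res = pca_clock_sites(frac, meta, n_components=8)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centered = frac.to_numpy() - frac.to_numpy().mean(axis=0)
        assert np.abs(recon - centered).max() < 1e-8

    def test_pc1_regression_detects_treatment_offset(self):
        frac, meta = self.age_dominant_data(n=40)
        meta = meta.copy()
        treated = list(meta.index[:20])
        meta.loc[treated, "treatment"] = "dwarf"
        offset = frac.loc[treated] - 0.3 * frac.std(axis=0)
        frac2 = pd.concat([offset, frac.drop(index=treated)]).loc[frac.index]
        res = pca_clock_sites(frac2, meta)
        term = res.pc1_regressions.query("term.str.contains('treatment')")
        assert not term.empty


class TestClustering:
    def test_two_planted_groups_split_at_the_top(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.2, 0.01, (6, 10))
        b = rng.normal(0.8, 0.01, (6, 10))
        frac = pd.DataFrame(np.vstack([a, b]),
                            index=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
                            columns=[f"1:{j}" for j in range(10)])
        res = cluster_heatmap(frac, sites=list(frac.columns))
        labels = hierarchy.fcluster(res.linkage, t=2, criterion="maxclust")
        groups = {tuple(sorted(np.flatnonzero(labels == k))) for k in (1, 2)}
        assert groups == {tuple(range(6)), tuple(range(6, 12))}

    def test_identical_samples_merge_at_zero_height(self):
        frac = pd.DataFrame(
            [[0.1, 0.9], [0.1, 0.9], [0.7, 0.2]],
            index=["a", "b", "c"], columns=["1:1", "1:2"],
        )
        res = cluster_heatmap(frac, sites=["1:1", "1:2"])
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_average_linkage_heights_match_hand_computation(self):
        # 1-d points where average-linkage merge heights are easy by hand
        pts = np.array([0.0, 0.1, 1.0, 1.1, 5.0])[:, None]
        frac = pd.DataFrame(pts, index=list("abcde"), columns=["1:1"])
        res = cluster_heatmap(frac, sites=["1:1"], scale="zscore")
        sd = pts.std(ddof=1)
        scaled = (pts - pts.mean()) / sd
        from scipy.spatial.distance import pdist

        expected = hierarchy.linkage(pdist(scaled), method="average")
        assert np.allclose(res.linkage, expected)
        # first two merges join the tight pairs at distance 0.1/sd
        assert res.linkage[0, 2] == pytest.approx(0.1 / sd, rel=1e-10)

    def test_zero_range_site_dropped_with_warning(self):
        frac = pd.DataFrame(
            [[0.5, 0.1], [0.5, 0.9], [0.5, 0.4]],
            index=["a", "b", "c"], columns=["1:1", "1:2"],
        )
        with pytest.warns(UserWarning, match="zero-range"):
            res = cluster_heatmap(frac, sites=["1:1", "1:2"])
        assert res.sites == ["1:2"]

    def test_top_variable_selection_uses_designated_samples(self):
        frac = pd.DataFrame(
            {
                "1:1": [0.0, 1.0, 0.5, 0.5],
                "1:2": [0.4, 0.5, 0.0, 1.0],
            },
            index=["w1", "w2", "t1", "t2"],
        )
        from methclock.evaluate import top_variable_sites

        assert top_variable_sites(frac, 1, samples=["w1", "w2"]) == ["1:1"]
        assert top_variable_sites(frac, 1, samples=["t1", "t2"]) == ["1:2"]

    def test_sample_order_invariance_up_to_tie_breaks(self):
        rng = np.random.default_rng(4)
        frac = pd.DataFrame(rng.random((8, 5)),
                            index=[f"s{i}" for i in range(8)],
                            columns=[f"1:{j}" for j in range(5)])
        res1 = cluster_heatmap(frac, sites=list(frac.columns))
        res2 = cluster_heatmap(frac.iloc[::-1], sites=list(frac.columns))
        heights1 = sorted(res1.linkage[:, 2])
        heights2 = sorted(res2.linkage[:, 2])
        assert np.allclose(heights1, heights2)
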
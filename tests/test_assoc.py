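import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methclock import (
    CohortSpec,
    bh_fdr,
    entropy,
    entropy_values,
    replicate_associations,
    simulate_cohort,
)
from methclock.assoc import test_age_association as age_association
from methclock.design import build_design

from conftest import make_meta


def rss_oracle(X, y):
    beta = np.linalg.pinv(X.T @ X) @ X.T @ y
    r = y - X @ beta
    return float(r @ r)


def drop_one_oracle(meta, covariates, y):
    """Independent F-test via explicit normal equations."""
    Xf = build_design(meta, [*covariates, "age"], age_transform=None).to_numpy()
    Xr = build_design(meta, list(covariates), age_transform=None).to_numpy()
    rf, rr = rss_oracle(Xf, y), rss_oracle(Xr, y)
    df = len(y) - Xf.shape[1]
    F = (rr - rf) / (rf / df)
    return F, float(stats.f.sf(F, 1, df))


class TestDropOneFTest:
    def test_near_deterministic_signal_is_overwhelming(self):
        rng = np.random.default_rng(0)
        ages = np.linspace(30, 600, 20)
        meta = make_meta([f"s{i}" for i in range(20)], ages)
        y = 0.01 * ages / 30.4 + rng.normal(0, 1e-6, 20)
        frac = pd.DataFrame({"1:1": y}, index=meta.index)
        res = age_association(frac, meta, covariates=["sex"])
        assert res.table["p"].iloc[0] < 1e-10

    def test_small_instance_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 8
        meta = make_meta(
            [f"s{i}" for i in range(n)],
            rng.uniform(30, 700, n),
            sex=list(np.where(rng.random(n) < 0.5, "male", "female")),
            treatment=list(np.where(rng.random(n) < 0.5, "none", "dwarf")),
        )
        y = rng.random(n)
        frac = pd.DataFrame({"1:1": y}, index=meta.index)
        res = age_association(frac, meta, covariates=["sex", "treatment"])
        F, p = drop_one_oracle(meta, ["sex", "treatment"], y)
        assert res.table["F"].iloc[0] == pytest.approx(F, abs=1e-10)
        assert res.table["p"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(2)
        n, g = 40, 800
        meta = make_meta([f"s{i}" for i in range(n)], rng.uniform(30, 700, n))
        frac = pd.DataFrame(
            rng.random((n, g)), index=meta.index, columns=[f"1:{i}" for i in range(g)]
        )
        res = age_association(frac, meta, covariates=["sex"])
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 1e-3

    def test_too_few_samples_rejected(self):
        meta = make_meta(["a", "b", "c"], [10, 20, 30])
        frac = pd.DataFrame({"1:1": [0.1, 0.2, 0.3]}, index=meta.index)
        with pytest.raises(ValueError, match="too few samples"):
            age_association(frac, meta, covariates=["sex"])

    def test_collinear_covariates_named_in_error(self):
        meta = make_meta(["a", "b", "c", "d", "e", "f"], [10, 20, 30, 40, 50, 60],
                         sex=["male"] * 6, treatment=["none"] * 3 + ["dwarf"] * 3,
                         strain=["x"] * 3 + ["y"] * 3)
        frac = pd.DataFrame({"1:1": np.linspace(0, 1, 6)}, index=meta.index)
        with pytest.raises(ValueError, match="rank deficient"):
            age_association(frac, meta, covariates=["treatment", "strain"])


class TestBH:
    def test_worked_four_value_example(self):
        q = bh_fdr(pd.Series([0.01, 0.02, 0.03, 0.9]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.9])
        assert (q <= 0.05).sum() == 3

    def test_all_zero_pvalues_all_rejected(self):
        q = bh_fdr(np.zeros(5))
        assert (q == 0).all()

    def test_single_pvalue_passes_through(self):
        assert bh_fdr(pd.Series([0.04])).iloc[0] == pytest.approx(0.04)

    def test_empty_input_gives_empty_output(self):
        assert len(bh_fdr(pd.Series([], dtype=float))) == 0

    def test_agrees_with_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            _, q_sm, *_ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_fdr(p).to_numpy(), q_sm, atol=1e-12)

    def test_null_rejection_rate_controlled(self):
        rng = np.random.default_rng(5)
        rates = [
            (bh_fdr(rng.random(200)) <= 0.01).mean() for _ in range(200)
        ]
        assert np.mean(rates) <= 0.01 + 3 * np.std(rates) / np.sqrt(len(rates))


class TestReplication:
    def make_cohort(self, seed, n_age):
        spec = CohortSpec(n_samples=50, n_sites=100, n_age_sites=n_age,
                          slope_scale=0.06, noise_sd=0.01, missing_rate=0.0,
                          mean_depth=60, seed=seed)
        matrix, meta, truth = simulate_cohort(spec)
        return matrix.fraction, meta, truth

    def test_signal_in_both_cohorts_is_retained(self):
        frac1, meta1, truth = self.make_cohort(31, 20)
        primary = age_association(frac1, meta1, covariates=["sex"])
        hits = set(primary.significant)
        assert hits  # planted signal detected
        replicated = replicate_associations(primary, frac1, meta1, covariates=["sex"])
        assert set(replicated) <= hits

    def test_signal_absent_in_replication_is_dropped(self):
        frac1, meta1, truth = self.make_cohort(32, 20)
        primary = age_association(frac1, meta1, covariates=["sex"])
        # null replication cohort: no age drift anywhere
        frac_null, meta_null, _ = self.make_cohort(33, 0)
        replicated = replicate_associations(primary, frac_null, meta_null, covariates=["sex"])
        assert len(replicated) <= max(1, int(0.1 * len(primary.significant)))

    def test_no_candidates_in_replication_rejected(self):
        frac1, meta1, _ = self.make_cohort(34, 20)
        primary = age_association(frac1, meta1, covariates=["sex"])
        renamed = frac1.rename(columns=lambda s: "99:" + s.split(":")[1])
        with pytest.raises(ValueError, match="no primary candidate"):
            replicate_associations(primary, renamed, meta1)


class TestEntropy:
    def frame(self, values):
        arr = np.atleast_2d(values)
        return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                            columns=[f"1:{j}" for j in range(arr.shape[1])])

    def test_half_methylated_sites_give_maximal_entropy(self):
        assert entropy_values(self.frame([0.5, 0.5, 0.5])).iloc[0] == pytest.approx(1.0)

    def test_fully_determined_sites_give_zero_entropy(self):
        assert entropy_values(self.frame([0.0, 1.0, 0.0, 1.0])).iloc[0] == pytest.approx(0.0)

    def test_single_site_quarter_methylated(self):
        expected = (0.25 * np.log(0.25) + 0.75 * np.log(0.75)) / np.log(0.5)
        val = entropy_values(self.frame([0.25])).iloc[0]
        assert val == pytest.approx(0.8113, abs=1e-4)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_logarithm_base_invariance(self):
        rng = np.random.default_rng(6)
        mf = rng.random(30)
        base_e = entropy_values(self.frame(mf)).iloc[0]
        term = mf * np.log2(mf) + (1 - mf) * np.log2(1 - mf)
        base_2 = term.sum() / (len(mf) * np.log2(0.5))
        assert base_e == pytest.approx(base_2, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10),
        st.integers(0, 9),
        st.floats(0.01, 0.99),
    )
    def test_moving_a_fraction_toward_half_never_decreases_entropy(self, mfs, idx, step):
        idx = idx % len(mfs)
        before = entropy_values(self.frame(mfs)).iloc[0]
        moved = list(mfs)
        moved[idx] = moved[idx] + step * (0.5 - moved[idx])
        after = entropy_values(self.frame(moved)).iloc[0]
        assert after >= before - 1e-12

    def test_empty_site_set_rejected(self):
        with pytest.raises(ValueError, match="at least one site"):
            entropy_values(pd.DataFrame(index=["s"], columns=[]))

    def test_entropy_rises_with_age_when_drift_planted(self):
        positive = 0
        for seed in range(5):
            spec = CohortSpec(n_samples=60, n_sites=200, n_age_sites=60,
                              entropy_drift=0.04, missing_rate=0.0, mean_depth=50,
                              seed=seed)
            matrix, meta, truth = simulate_cohort(spec)
            frac = matrix.fraction[truth.age_site_ids].clip(0, 1)
            series = entropy(frac.fillna(frac.mean()), meta)
            positive += series.pearson_r > 0
        assert positive >= 4
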
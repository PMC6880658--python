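import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from lldnet.data_io import CohortTable, split_by_anxiety
from lldnet.matching import (
    MatchConfig,
    MatchingError,
    fit_propensity,
    match,
    match_cohort,
    matched_tables,
)
from lldnet.synthetic import generate_cohort, preset_lld

from conftest import make_cohort_df


def labeled_cohort(df_low, df_high):
    df_low = df_low.copy()
    df_high = df_high.copy()
    df_low["group"] = "low_anxiety"
    df_high["group"] = "high_anxiety"
    df_high["subject_id"] = ["H" + s for s in df_high["subject_id"]]
    return CohortTable(pd.concat([df_low, df_high], ignore_index=True))


class TestPropensity:
    def test_identical_covariates_give_prevalence(self):
        df = make_cohort_df(n=60, seed=1)
        cohort = labeled_cohort(df, df)
        p = fit_propensity(cohort)
        assert np.allclose(p, 0.5, atol=1e-6)

    def test_shifted_covariate_discriminates(self):
        rng = np.random.default_rng(2)
        df_low = make_cohort_df(n=400, seed=3)
        df_high = make_cohort_df(n=400, seed=4)
        df_low["age"] = rng.normal(70, 5, 400).round(1)
        df_high["age"] = rng.normal(80, 5, 400).round(1)  # 2-SD shift
        cohort = labeled_cohort(df_low, df_high)
        p = fit_propensity(cohort, MatchConfig(covariates=("age",)))
        y = (cohort.df["group"] == "high_anxiety").astype(int)
        assert roc_auc_score(y, p) > 0.9

    def test_matches_grid_search_oracle(self):
        """Logistic MLE on one covariate vs exhaustive likelihood grid."""
        rng = np.random.default_rng(5)
        df = make_cohort_df(n=20, seed=6)
        df["age"] = np.linspace(60, 80, 20)
        df["group"] = ["low_anxiety"] * 10 + ["high_anxiety"] * 10
        df.loc[rng.permutation(20)[:4], "group"] = "high_anxiety"
        cohort = CohortTable(df)
        p = fit_propensity(cohort, MatchConfig(covariates=("age",)))

        y = (cohort.df["group"] == "high_anxiety").to_numpy(dtype=float)
        x = (cohort.df["age"].to_numpy(dtype=float))

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))

        b0g = np.linspace(-40, 40, 401)
        b1g = np.linspace(-0.8, 0.8, 401)
        lls = np.array([[loglik(a, b) for b in b1g] for a in b0g])
        i, j = np.unravel_index(np.argmax(lls), lls.shape)
        eta_hat = np.log(p / (1 - p)).to_numpy()
        eta_grid = b0g[i] + b1g[j] * x
        # compare on the fitted-probability scale (grid resolution limited)
        assert np.max(np.abs(1 / (1 + np.exp(-eta_grid)) - p.to_numpy())) < 0.02

    def test_perfect_separation_raises(self):
        df = make_cohort_df(n=30, seed=7)
        df["age"] = np.arange(30, dtype=float) + 60
        df["group"] = ["low_anxiety"] * 15 + ["high_anxiety"] * 15
        cohort = CohortTable(df)
        with pytest.raises(MatchingError):
            fit_propensity(cohort, MatchConfig(covariates=("age",)))


class TestMatch:
    def hand_cohort(self, treated_p, control_p):
        n = len(treated_p) + len(control_p)
        df = make_cohort_df(n=n, seed=8)
        df["group"] = ["high_anxiety"] * len(treated_p) + ["low_anxiety"] * len(control_p)
        prop = pd.Series(list(treated_p) + list(control_p),
                         index=df["subject_id"].to_numpy())
        return CohortTable(df), prop

    def test_hand_enumerated_pairs(self):
        cohort, prop = self.hand_cohort([0.8, 0.6], [0.79, 0.61, 0.2])
        res = match(cohort, prop, MatchConfig(caliper=10.0))
        got = {(prop[a], prop[b]) for a, b in res.pairs}
        assert got == {(0.8, 0.79), (0.6, 0.61)}

    def test_caliper_discards_distant_treated(self):
        cohort, prop = self.hand_cohort([0.95, 0.6], [0.61, 0.55])
        res = match(cohort, prop, MatchConfig(caliper=0.5, caliper_scale="raw"))
        assert res.n_matched == 1
        assert {prop[a] for a, _ in res.pairs} == {0.6}

    def test_caliper_bound_holds_for_every_pair(self, confounded_cohort):
        table, _ = confounded_cohort
        low, high = split_by_anxiety(table)
        pooled = CohortTable(pd.concat([low.df, high.df], ignore_index=True))
        res = match_cohort(pooled)
        lg = np.log(res.propensity / (1 - res.propensity))
        for a, b in res.pairs:
            assert abs(lg[a] - lg[b]) <= res.caliper_logit + 1e-12
        assert res.n_matched <= min(low.n, high.n)
        flat = [s for pair in res.pairs for s in pair]
        assert len(flat) == len(set(flat))

    def test_balance_improves_on_confounded_preset(self):
        ok = 0
        reps = 15
        before_sum = None
        after_sum = None
        for seed in range(reps):
            table, _ = generate_cohort(preset_lld("confounded_anxiety"), seed=100 + seed)
            low, high = split_by_anxiety(table)
            pooled = CohortTable(pd.concat([low.df, high.df], ignore_index=True))
            res = match_cohort(pooled)
            bal = res.balance.set_index("covariate")
            before_sum = bal["smd_before"].abs() if before_sum is None else before_sum + bal["smd_before"].abs()
            after_sum = bal["smd_after"].abs() if after_sum is None else after_sum + bal["smd_after"].abs()
            ok += abs(bal.loc["madrs_sum", "smd_after"]) < 0.1
        # seed-averaged balance never worsens for the matched covariates
        assert (after_sum / reps <= before_sum / reps + 0.02).all()
        assert ok >= 0.9 * reps

    def test_matched_tables_align_pairs(self, confounded_cohort):
        table, _ = confounded_cohort
        low, high = split_by_anxiety(table)
        pooled = CohortTable(pd.concat([low.df, high.df], ignore_index=True))
        res = match_cohort(pooled)
        mlow, mhigh = matched_tables(pooled, res)
        assert mlow.n == mhigh.n == res.n_matched
        assert list(mhigh.df["subject_id"]) == [a for a, _ in res.pairs]
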
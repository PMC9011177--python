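"""Logistic burden machinery: MLE correctness against independent
oracles, design semantics, gating, and the age-at-diagnosis shift."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

import pvburden as pv
from pvburden.burden import fit_logistic, GATE_MIN_CARRIERS


def neg_loglik(beta, X, y):
    eta = X @ beta
    return -(y * eta - np.log1p(np.exp(eta))).sum()


def random_dataset(rng, n=120, with_cov=True):
    carrier = rng.random(n) < rng.uniform(0.1, 0.4)
    age = rng.normal(60, 10, n)
    logit = -1.0 + rng.normal(0, 0.8) * carrier + rng.normal(0, 0.02) * (age - 60)
    y = rng.random(n) < special.expit(logit)
    cov = pd.DataFrame({"age": age}) if with_cov else None
    return y.astype(float), carrier.astype(float), cov


class TestLogisticFit:
    def test_no_covariate_or_equals_cross_product(self):
        y = np.r_[np.ones(100), np.zeros(200)]
        carrier = np.r_[np.ones(10), np.zeros(90), np.ones(5), np.zeros(195)]
        fit = fit_logistic(y, carrier)
        assert np.exp(fit.beta[1]) == pytest.approx(10 * 195 / (90 * 5), abs=1e-9)

    def test_null_carrier_effect_is_zero(self):
        y = np.r_[np.ones(200), np.zeros(200)]
        carrier = np.r_[np.ones(20), np.zeros(180), np.ones(20), np.zeros(180)]
        fit = fit_logistic(y, carrier)
        assert abs(fit.beta[1]) < 1e-8

    def test_matches_direct_likelihood_maximisation(self, rng):
        """IRLS solution's log-likelihood agrees with a generic numeric
        optimiser on small printed-size datasets."""
        for _ in range(20):
            y, carrier, cov = random_dataset(rng)
            if y.min() == y.max() or len(set(carrier[y == 1])) < 2 \
                    or len(set(carrier[y == 0])) < 2:
                continue
            fit = fit_logistic(y, carrier, cov)
            X = np.column_stack([np.ones_like(y), carrier, cov["age"]])
            res = optimize.minimize(neg_loglik, np.zeros(3), args=(X, y),
                                    method="BFGS",
                                    options={"gtol": 1e-10, "maxiter": 500})
            assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        y, carrier, cov = random_dataset(rng, n=400)
        fit = fit_logistic(y, carrier, cov)
        X = sm.add_constant(np.column_stack([carrier, cov["age"]]))
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)), ref.bse, rtol=1e-4)

    def test_age_location_invariance(self, rng):
        y, carrier, cov = random_dataset(rng, n=300)
        fit1 = fit_logistic(y, carrier, cov)
        fit2 = fit_logistic(y, carrier, cov + 1000.0)
        assert fit1.beta[1] == pytest.approx(fit2.beta[1], abs=1e-6)

    def test_complete_separation_is_flagged_not_raised(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        carrier = np.r_[np.ones(10), np.zeros(90)]   # no carrier controls
        fit = fit_logistic(y, carrier)
        assert "separation" in fit.flags and not fit.converged

    def test_one_hot_categorical_covariate(self, rng):
        y, carrier, cov = random_dataset(rng, n=300)
        cov["region"] = pd.Categorical(rng.choice(["a", "b", "c"], 300))
        fit = fit_logistic(y, carrier, cov)
        assert fit.converged
        assert sum(n.startswith("region") for n in fit.names) == 2


def make_assoc_cohort(n_cases=400, n_controls=2000, carriers_cases=20,
                      carriers_controls=10, seed=5):
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    df = pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(n)],
        "sex": rng.choice(["female", "male"], n),
        "region": rng.choice(["a", "b"], n),
        "age_registration": rng.integers(40, 80, n).astype(float),
        "status": ["case"] * n_cases + ["control"] * n_controls,
        "case_c1": [1] * n_cases + [0] * n_controls,
        "fh_c1": 0,
    })
    df["agedx_c1"] = np.where(df["case_c1"] == 1,
                              rng.integers(35, 75, n).astype(float), np.nan)
    carrier = np.zeros(n, bool)
    carrier[:carriers_cases] = True
    carrier[n_cases:n_cases + carriers_controls] = True
    carr = pd.DataFrame({"individual_id": df["individual_id"],
                         "carrier_G1": carrier})
    return df, carr


class TestRunAssociation:
    def test_all_patients_design_withholds_estimates(self):
        cohort, carr = make_assoc_cohort()
        res = pv.run_association(cohort, carr, "G1", "c1", "all_patients")
        assert res.p is not None and res.odds_ratio is None and res.beta is None
        assert "withheld" in res.note

    def test_no_family_history_design_reports_or_with_ci(self):
        cohort, carr = make_assoc_cohort()
        res = pv.run_association(cohort, carr, "G1", "c1", "no_family_history")
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert res.odds_ratio == pytest.approx(np.exp(res.beta))

    def test_fh_cases_are_excluded_from_risk_design(self):
        cohort, carr = make_assoc_cohort()
        cohort.loc[cohort.index[:100], "fh_c1"] = 1   # first 100 cases report FH
        res = pv.run_association(cohort, carr, "G1", "c1", "no_family_history")
        assert res.n_cases == 300

    def test_two_carrier_fixture_is_gated_without_estimates(self):
        cohort, carr = make_assoc_cohort(carriers_cases=2)
        res = pv.run_association(cohort, carr, "G1", "c1", "no_family_history")
        assert res.gated and "carrier count < 3" in res.gate_reason
        assert res.beta is None and res.odds_ratio is None and res.p is None

    def test_unknown_design_and_cancer_rejected(self):
        cohort, carr = make_assoc_cohort()
        with pytest.raises(ValueError, match="design"):
            pv.run_association(cohort, carr, "G1", "c1", "matched")
        with pytest.raises(ValueError, match="cancer"):
            pv.run_association(cohort, carr, "G1", "nope")

    def test_bonferroni_preserves_p_ordering(self, demo_sim, demo_carriers):
        cohort, _, _ = demo_sim
        table = pv.run_all_associations(cohort, demo_carriers,
                                        designs=("no_family_history",))
        sub = table[table["p"].notna()]
        order_raw = sub.sort_values("p")["cancer"].tolist()
        order_adj = sub.sort_values("p_bonferroni", kind="stable")["cancer"].tolist()
        assert order_raw == order_adj


class TestAgeShift:
    def test_equal_age_distributions_give_zero_difference(self):
        cohort, carr = make_assoc_cohort()
        cohort["agedx_c1"] = np.where(cohort["case_c1"] == 1, 60.0, np.nan)
        res = pv.age_at_diagnosis_shift(cohort, carr, "G1", "c1")
        assert res.difference == pytest.approx(0.0, abs=1e-12)

    def test_injected_shift_recovered(self):
        rng = np.random.default_rng(0)
        cohort, carr = make_assoc_cohort(n_cases=5000, n_controls=100,
                                         carriers_cases=500, seed=1)
        merged = pv.attach_carriers(cohort, carr)
        is_case = merged["case_c1"] == 1
        ages = rng.normal(60, 8, int(is_case.sum()))
        ages[merged.loc[is_case, "carrier_G1"].to_numpy()] -= 5.7
        cohort.loc[is_case, "agedx_c1"] = ages
        res = pv.age_at_diagnosis_shift(cohort, carr, "G1", "c1")
        assert res.difference == pytest.approx(-5.7, abs=0.5)
        assert res.ci_low < res.difference < res.ci_high
        assert res.p < 1e-10 and res.p_welch < 1e-10

    def test_single_carrier_is_gated(self):
        cohort, carr = make_assoc_cohort(carriers_cases=1)
        res = pv.age_at_diagnosis_shift(cohort, carr, "G1", "c1")
        assert res.gated and res.difference is None
        assert res.n_carrier_cases < GATE_MIN_CARRIERS
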
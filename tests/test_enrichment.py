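"""Regional heterogeneity, family-history trend/cross-tabulation and
cohort summaries, checked against closed forms and exact enumeration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pvburden as pv
from pvburden.enrichment import fh_trend
from conftest import make_calls


def region_cohort(counts):
    """counts: {region: (n, n_carriers)} -> (cohort, carrier table, calls)."""
    rows, carr_rows, call_rows = [], [], []
    k = 0
    for region, (n, nc) in counts.items():
        for i in range(n):
            iid = f"i{k}"
            k += 1
            rows.append({"individual_id": iid, "sex": "female", "region": region,
                         "age_registration": 60.0, "status": "case",
                         "case_c1": 1, "agedx_c1": 55.0, "fh_c1": 0})
            is_car = i < nc
            carr_rows.append({"individual_id": iid, "carrier_G1": is_car})
            if is_car:
                vid = "G1_founder" if region == "r0" else f"G1_v{k}"
                call_rows.append((iid, "G1", vid, "P", int(region == "r0")))
    return (pd.DataFrame(rows), pd.DataFrame(carr_rows), make_calls(call_rows))


class TestRegionalChisq:
    def test_equal_proportions_give_null_statistic(self):
        cohort, carr, _ = region_cohort({f"r{i}": (200, 10) for i in range(4)})
        chi2, dof, p = pv.regional_chisq(cohort, carr, "G1")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert dof == 3 and p == pytest.approx(1.0)

    def test_two_by_two_matches_classical_formula(self):
        cohort, carr, _ = region_cohort({"x": (120, 18), "y": (250, 9)})
        chi2, dof, _ = pv.regional_chisq(cohort, carr, "G1")
        a, b, c, d = 18, 102, 9, 241
        n = a + b + c + d
        expected = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        assert dof == 1 and chi2 == pytest.approx(expected, rel=1e-12)

    def test_founder_exclusion_removes_regional_signal(self):
        counts = {f"r{i}": (700, 7) for i in range(1, 7)}
        counts["r0"] = (700, 35)   # founder-driven 5x excess in one region
        cohort, carr, calls = region_cohort(counts)
        _, _, p = pv.regional_chisq(cohort, carr, "G1")
        assert p < 0.001
        _, _, p_excl = pv.regional_chisq(cohort, carr, "G1", calls=calls,
                                         exclude_founders=True)
        assert p_excl > 0.1

    def test_invariant_to_region_relabelling(self):
        counts = {"r0": (300, 12), "r1": (200, 3), "r2": (150, 9)}
        cohort, carr, _ = region_cohort(counts)
        chi2a, _, _ = pv.regional_chisq(cohort, carr, "G1")
        cohort2 = cohort.assign(region=cohort["region"].map(
            {"r0": "zz", "r1": "aa", "r2": "mm"}))
        chi2b, _, _ = pv.regional_chisq(cohort2, carr, "G1")
        assert chi2a == pytest.approx(chi2b, rel=1e-12)

    def test_fold_difference_reported(self):
        cohort, carr, _ = region_cohort({"x": (1000, 50), "y": (1000, 10)})
        bd = pv.regional_breakdown(cohort, carr, "G1")
        assert bd.attrs["fold_difference"] == pytest.approx(5.0)


def exact_trend_p(r_i, n_i, scores=(0, 1, 2)):
    """Exact conditional two-sided p for the trend statistic: enumerate all
    2x3 tables with the observed margins under the multivariate
    hypergeometric null and sum the probabilities of tables whose absolute
    trend score displacement is at least the observed one."""
    r, n = sum(r_i), sum(n_i)
    obs = abs(sum(s * x for s, x in zip(scores, r_i))
              - r * sum(s * m for s, m in zip(scores, n_i)) / n)
    total_ways = math.comb(n, r)
    p = 0.0
    for a in range(0, min(r, n_i[0]) + 1):
        for b in range(0, min(r - a, n_i[1]) + 1):
            c = r - a - b
            if c < 0 or c > n_i[2]:
                continue
            disp = abs(sum(s * x for s, x in zip(scores, (a, b, c)))
                       - r * sum(s * m for s, m in zip(scores, n_i)) / n)
            if disp >= obs - 1e-9:
                p += (math.comb(n_i[0], a) * math.comb(n_i[1], b)
                      * math.comb(n_i[2], c)) / total_ways
    return p


class TestFhTrend:
    def test_flat_proportions_give_zero_statistic(self):
        car = np.r_[np.ones(10), np.zeros(90), np.ones(10), np.zeros(90),
                    np.ones(10), np.zeros(90)].astype(bool)
        cat = np.repeat([0, 1, 2], 100)
        res = fh_trend(car, cat)
        assert res.z == pytest.approx(0.0, abs=1e-12) and res.p == pytest.approx(1.0)

    def test_strong_gradient_detected(self):
        rng = np.random.default_rng(4)
        cat = np.r_[np.zeros(1000, int), np.ones(300, int), np.full(50, 2)]
        prob = np.select([cat == 0, cat == 1], [0.01, 0.05], 0.20)
        car = rng.random(len(cat)) < prob
        res = fh_trend(car, cat)
        assert res.p < 0.001 and res.z > 0

    def test_matches_exact_permutation_enumeration_at_small_n(self):
        car = np.array([1] * 2 + [0] * 38 + [1] * 4 + [0] * 16 + [1] * 5 + [0] * 5,
                       bool)
        cat = np.r_[np.zeros(40, int), np.ones(20, int), np.full(10, 2)]
        res = fh_trend(car, cat)
        r_i = [2, 4, 5]
        n_i = [40, 20, 10]
        p_exact = exact_trend_p(r_i, n_i)
        assert res.p == pytest.approx(p_exact, abs=0.02)

    def test_reversing_category_order_flips_sign(self):
        rng = np.random.default_rng(1)
        cat = rng.integers(0, 3, 500)
        car = rng.random(500) < (0.02 + 0.05 * cat)
        a = fh_trend(car, cat)
        b = fh_trend(car, 2 - cat)
        assert a.z == pytest.approx(-b.z, rel=1e-9)
        assert a.p == pytest.approx(b.p, rel=1e-9)

    def test_reduces_to_two_sample_proportion_z_without_third_category(self):
        car = np.r_[np.ones(12), np.zeros(188), np.ones(30), np.zeros(170)].astype(bool)
        cat = np.r_[np.zeros(200, int), np.ones(200, int)]
        res = fh_trend(car, cat)
        p1, p2, n1, n2 = 12 / 200, 30 / 200, 200, 200
        pp = (12 + 30) / 400
        z = (p2 - p1) / math.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        assert abs(res.z) == pytest.approx(abs(z), rel=1e-9)

    def test_all_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fh_trend(np.array([], bool), np.array([], int))


class TestFhCrossTab:
    @staticmethod
    def fh_cohort():
        n = 210
        df = pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(n)],
            "sex": "female", "region": "a", "age_registration": 60.0,
            "status": "case", "case_c1": 1, "agedx_c1": 55.0,
            "fh_c1": [1] * 10 + [0] * 200,
            "fh_c2": 0, "case_c2": 0, "agedx_c2": np.nan,
        })
        carrier = np.zeros(n, bool)
        carrier[:3] = True           # 3 of 10 FH-positive carry
        carrier[10:20] = True        # 10 of 200 FH-negative carry
        carr = pd.DataFrame({"individual_id": df["individual_id"],
                             "carrier_G1": carrier})
        return df, carr

    def test_fisher_p_matches_hypergeometric_sum(self):
        df, carr = self.fh_cohort()
        out = pv.fh_cross_tab(df, carr, "G1", ["c1"])
        row = out[(out["case_cancer"] == "c1") & (out["fh_cancer"] == "c1")].iloc[0]
        assert (row["carriers_fh"], row["n_fh"]) == (3, 10)
        # two-sided Fisher p by direct enumeration of the hypergeometric
        k_obs, n_fh, k_tot, n = 3, 10, 13, 210
        probs = [stats.hypergeom.pmf(k, n, k_tot, n_fh) for k in range(k_tot + 1)]
        p_exact = sum(p for k, p in enumerate(probs)
                      if p <= probs[k_obs] * (1 + 1e-9))
        assert row["fisher_p"] == pytest.approx(p_exact, rel=1e-9)

    def test_grid_bonferroni_factor_is_cell_count(self):
        df, carr = self.fh_cohort()
        out = pv.fh_cross_tab(df, carr, "G1", ["c1", "c2"])
        assert len(out) == 4 and out.attrs["bonferroni_factor"] == 4
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_carriers_without_fh_yield_zero_proportion(self):
        df, carr = self.fh_cohort()
        out = pv.fh_cross_tab(df, carr, "G1", ["c1"], ["c2"])
        assert out.iloc[0]["prop_fh"] != out.iloc[0]["prop_fh"] or \
            out.iloc[0]["carriers_fh"] == 0


class TestSummaries:
    def test_multiplicity_fraction_to_one_decimal(self):
        n, n_multi = 65108, 4128
        df = pd.DataFrame({
            "individual_id": range(n), "sex": "female", "region": "a",
            "age_registration": 60.0, "status": "case",
            "case_c1": 1, "agedx_c1": 55.0, "fh_c1": 0,
            "case_c2": [1] * n_multi + [0] * (n - n_multi),
            "agedx_c2": 58.0, "fh_c2": 0,
        })
        s = pv.summarize_cohort(df)
        assert s["multi_primary_fraction_pct"] == 6.3
        assert s["n_patients"] == n and s["n_cases_total"] == n + n_multi

    def test_single_individual_sd_is_missing(self):
        df = pd.DataFrame({"individual_id": ["i1"], "sex": ["male"],
                           "region": ["a"], "age_registration": [70.0],
                           "status": ["case"], "case_c1": [1],
                           "agedx_c1": [64.0], "fh_c1": [0]})
        s = pv.summarize_cohort(df)
        assert s["per_cancer"]["c1"]["agedx_sd"] is None
        assert s["per_cancer"]["c1"]["agedx_mean"] == 64.0

    def test_hand_computed_aggregates(self):
        df = pd.DataFrame({
            "individual_id": [f"i{k}" for k in range(5)],
            "sex": ["female", "male", "female", "male", "female"],
            "region": "a", "age_registration": 60.0,
            "status": ["case", "case", "case", "control", "control"],
            "case_c1": [1, 1, 1, 0, 0],
            "agedx_c1": [50.0, 60.0, 70.0, np.nan, np.nan],
            "fh_c1": [1, 0, 0, 0, 0],
        })
        s = pv.summarize_cohort(df)
        c1 = s["per_cancer"]["c1"]
        assert c1["n_female"] == 2 and c1["n_male"] == 1
        assert c1["agedx_mean"] == pytest.approx(60.0)
        assert c1["agedx_sd"] == pytest.approx(10.0)
        assert c1["pct_fh_same_type"] == 33.3
        assert s["n_controls"] == 2

    def test_age_band_proportions_conserve_counts(self, demo_sim, demo_carriers):
        cohort, _, _ = demo_sim
        out = pv.age_band_carrier_proportions(cohort, demo_carriers,
                                              "BRCA2", "gastric")
        merged = pv.attach_carriers(cohort, demo_carriers)
        cases = merged[(merged["case_gastric"] == 1)
                       & merged["agedx_gastric"].notna()]
        overall = cases["carrier_BRCA2"].mean()
        weighted = (out["proportion"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(overall, abs=1e-12)
        assert out["n"].sum() == len(cases)
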
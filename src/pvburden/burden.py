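"""Age-adjusted dominant-model burden association between carrier status
and each cancer type.

The core model is a logistic regression of case status on collapsed
carrier status with age as a covariate — age at diagnosis for cases and
age at registration for controls.  Two primary designs mirror the
two-stage analysis of registry case-control studies with
family-history-free controls:

``all_patients``
    every case of the cancer type versus every control; because the
    family-history-free control pool biases risk estimates upward, this
    design reports the association p-value only and withholds OR/CI.
``no_family_history``
    cases restricted to patients reporting no family history of cancer,
    versus controls (family-history-free by construction); reports the
    OR with a 95% Wald CI.

Two sensitivity designs are included: ``region_adjusted`` (region as a
categorical covariate) and ``single_cancer_only`` (cases with exactly
one cancer type).  Any analysis in which cases or controls contain
fewer than 3 carriers is *gated*: the result carries counts and the
reason, but no estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DESIGNS",
    "BURDEN_ALPHA",
    "LogisticFit",
    "AssociationResult",
    "AgeShiftResult",
    "fit_logistic",
    "run_association",
    "run_all_associations",
    "age_at_diagnosis_shift",
    "attach_carriers",
]

DESIGNS = ("all_patients", "no_family_history", "region_adjusted", "single_cancer_only")
#: genome-wide style significance threshold for the burden test
BURDEN_ALPHA = 1e-4
#: minimum carrier count per category (cases; controls) below which
#: estimates are suppressed
GATE_MIN_CARRIERS = 3

Z95 = 1.959964


# ---------------------------------------------------------------------------
# IRLS logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    names: list[str]
    flags: list[str] = field(default_factory=list)


def _design_matrix(carrier, covariates):
    cols = [np.ones(len(carrier)), np.asarray(carrier, float)]
    names = ["intercept", "carrier"]
    if covariates is not None:
        cov = covariates if isinstance(covariates, pd.DataFrame) \
            else pd.DataFrame(np.asarray(covariates))
        for c in cov.columns:
            col = cov[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=str(c), drop_first=True)
                for d in dummies.columns:
                    cols.append(dummies[d].to_numpy(float))
                    names.append(str(d))
            else:
                cols.append(col.to_numpy(float))
                names.append(str(c))
    return np.column_stack(cols), names


def fit_logistic(outcome, carrier, covariates=None,
                 max_iter: int = 100, score_tol: float = 1e-10,
                 ll_tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares.

    The design matrix is [intercept, carrier, covariates]; categorical
    covariate columns are one-hot encoded with the first level as
    reference.  Convergence when the maximum absolute score falls below
    ``score_tol`` or the relative log-likelihood change falls below
    ``ll_tol``, within ``max_iter`` iterations.  Non-convergence and
    complete separation (an empty carrier-by-outcome cell) are flagged on
    the result, never raised.
    """
    y = np.asarray(outcome, float)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X, names = _design_matrix(carrier, covariates)
    flags: list[str] = []

    car = np.asarray(carrier, bool)
    cells = [(y[car] == 1).sum(), (y[car] == 0).sum(),
             (y[~car] == 1).sum(), (y[~car] == 0).sum()]
    if min(cells) == 0:
        p = len(names)
        return LogisticFit(np.full(p, np.nan), np.full((p, p), np.nan),
                           np.nan, False, 0, names, ["separation"])

    beta = np.zeros(X.shape[1])
    # start the intercept at the empirical logit
    pbar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    beta[0] = math.log(pbar / (1 - pbar))
    ll_old = -np.inf
    converged = False
    rel_ll_ok = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        score = X.T @ (y - mu)
        w = mu * (1 - mu)
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        max_score = float(np.max(np.abs(score)))
        rel_ll_ok = np.isfinite(ll_old) and abs(ll - ll_old) <= ll_tol * abs(ll_old)
        if max_score < score_tol:
            converged = True
            ll_old = ll
            break
        xtwx = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        # step-halving guards against overshoot on quasi-separated data
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            mu_c = np.clip(1.0 / (1.0 + np.exp(-(X @ cand))), 1e-12, 1 - 1e-12)
            ll_c = float(np.sum(y * np.log(mu_c) + (1 - y) * np.log1p(-mu_c)))
            if ll_c >= ll or step < 1e-6:
                break
            step *= 0.5
        beta = beta + step * delta
        ll_old = ll
    if not converged and rel_ll_ok:
        # the likelihood stalled below the relative tolerance: accept as
        # converged even though the score never crossed its threshold
        converged = True
    if not converged:
        flags.append("non_convergence")
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    xtwx = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    return LogisticFit(beta, cov, ll, converged, it, names, flags)


# ---------------------------------------------------------------------------
# association designs
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    gene: str
    cancer: str
    design: str
    sex: str | None
    n_cases: int
    n_controls: int
    carriers_cases: int
    carriers_controls: int
    beta: float | None = None
    se: float | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    gated: bool = False
    gate_reason: str | None = None
    converged: bool = True
    flags: tuple[str, ...] = ()
    significant_burden: bool | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["flags"] = ",".join(self.flags)
        return d


def attach_carriers(cohort: pd.DataFrame, carrier_table: pd.DataFrame) -> pd.DataFrame:
    """Left-join the collapsed carrier flags onto the cohort table;
    individuals without a carrier row are noncarriers."""
    merged = cohort.merge(carrier_table, on="individual_id", how="left")
    for col in carrier_table.columns:
        if col.startswith("carrier_"):
            merged[col] = merged[col].fillna(False).astype(bool)
    return merged


def _cancer_names(cohort: pd.DataFrame) -> list[str]:
    return [c[len("case_"):] for c in cohort.columns if c.startswith("case_")]


def _select_rows(cohort: pd.DataFrame, cancer: str, design: str,
                 sex: str | None, fh_scope: str):
    case_col = f"case_{cancer}"
    if case_col not in cohort.columns:
        raise ValueError(f"unknown cancer {cancer!r}")
    cases = cohort[cohort[case_col] == 1]
    controls = cohort[cohort["status"] == "control"]
    if sex is not None:
        cases = cases[cases["sex"] == sex]
    case_sexes = cases["sex"].unique()
    if len(case_sexes) == 1:
        # sex-restricted cancer (or explicit split): compare against the
        # relevant sex only
        controls = controls[controls["sex"] == case_sexes[0]]
    if design in ("no_family_history", "region_adjusted", "single_cancer_only"):
        fh_cols = [c for c in cohort.columns if c.startswith("fh_")] \
            if fh_scope == "any" else [f"fh_{cancer}"]
        cases = cases[cases[fh_cols].sum(axis=1) == 0]
    if design == "single_cancer_only":
        n_types = cases[[f"case_{c}" for c in _cancer_names(cohort)]].sum(axis=1)
        cases = cases[n_types == 1]
    return cases, controls


def run_association(cohort: pd.DataFrame, carrier_table: pd.DataFrame | None,
                    gene: str, cancer: str, design: str = "no_family_history",
                    sex: str | None = None, fh_scope: str = "any") -> AssociationResult:
    """Run one (gene, cancer, design) burden analysis.

    ``cohort`` may already carry ``carrier_<gene>`` columns (pass
    ``carrier_table=None``), otherwise the carrier table is joined on
    ``individual_id``.  ``fh_scope`` controls the no-family-history case
    filter: ``"any"`` excludes cases reporting a family history of any
    cancer type (default, stricter), ``"same"`` only of the analysed type.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    flag_col = f"carrier_{gene}"
    if carrier_table is not None:
        cohort = attach_carriers(cohort, carrier_table)
    if flag_col not in cohort.columns:
        raise ValueError(f"unknown gene {gene!r}")
    cases, controls = _select_rows(cohort, cancer, design, sex, fh_scope)

    age_cases = cases[f"agedx_{cancer}"]
    cases = cases[age_cases.notna()]
    controls = controls[controls["age_registration"].notna()]
    cc_cases = int(cases[flag_col].sum())
    cc_controls = int(controls[flag_col].sum())
    res = AssociationResult(gene=gene, cancer=cancer, design=design, sex=sex,
                            n_cases=len(cases), n_controls=len(controls),
                            carriers_cases=cc_cases, carriers_controls=cc_controls)
    if min(cc_cases, cc_controls) < GATE_MIN_CARRIERS:
        res.gated = True
        res.gate_reason = (f"carrier count < {GATE_MIN_CARRIERS} "
                           f"(cases: {cc_cases}, controls: {cc_controls})")
        return res
    if len(cases) == 0 or len(controls) == 0:
        res.gated = True
        res.gate_reason = "empty case or control set"
        return res

    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    carrier = np.concatenate([cases[flag_col].to_numpy(),
                              controls[flag_col].to_numpy()]).astype(float)
    cov = pd.DataFrame({
        "age": np.concatenate([cases[f"agedx_{cancer}"].to_numpy(float),
                               controls["age_registration"].to_numpy(float)])})
    if design == "region_adjusted":
        cov["region"] = pd.Categorical(
            np.concatenate([cases["region"].to_numpy(), controls["region"].to_numpy()]))
    fit = fit_logistic(y, carrier, cov)
    res.converged = fit.converged
    res.flags = tuple(fit.flags)
    if not fit.converged:
        res.note = "model did not converge; estimates withheld"
        return res
    j = fit.names.index("carrier")
    beta = float(fit.beta[j])
    se = float(math.sqrt(fit.cov[j, j]))
    res.p = float(2 * stats.norm.sf(abs(beta / se)))
    res.significant_burden = res.p < BURDEN_ALPHA
    if design == "all_patients":
        res.note = ("association test only; risk estimates withheld because "
                    "family-history-free controls bias them upward")
        return res
    res.beta, res.se = beta, se
    res.odds_ratio = math.exp(beta)
    res.ci_low = math.exp(beta - Z95 * se)
    res.ci_high = math.exp(beta + Z95 * se)
    return res


def run_all_associations(cohort: pd.DataFrame, carrier_table: pd.DataFrame,
                         genes: Sequence[str] | None = None,
                         cancers: Sequence[str] | None = None,
                         designs: Sequence[str] = ("all_patients", "no_family_history"),
                         split_by_sex: Sequence[str] = ("breast",),
                         fh_scope: str = "any") -> pd.DataFrame:
    """All (gene, cancer, design) analyses as one tidy table.

    Cancer types listed in ``split_by_sex`` whose cases include both sexes
    are analysed separately per sex, mirroring the sex-split convention for
    breast cancer.
    """
    merged = attach_carriers(cohort, carrier_table)
    genes = list(genes) if genes is not None else \
        [c[len("carrier_"):] for c in merged.columns if c.startswith("carrier_")]
    cancers = list(cancers) if cancers is not None else _cancer_names(cohort)
    rows = []
    for cancer in cancers:
        case_sexes = merged.loc[merged[f"case_{cancer}"] == 1, "sex"].unique()
        sexes = list(case_sexes) if (cancer in split_by_sex and len(case_sexes) > 1) \
            else [None]
        for sex in sorted(sexes, key=str):
            for gene in genes:
                for design in designs:
                    rows.append(run_association(merged, None, gene, cancer,
                                                design, sex, fh_scope).to_dict())
    out = pd.DataFrame(rows)
    if "p" in out.columns:
        m = out.groupby("design")["p"].transform(lambda s: max(int(s.notna().sum()), 1))
        out["p_bonferroni"] = (out["p"] * m).clip(upper=1.0)
    return out


# ---------------------------------------------------------------------------
# age-at-diagnosis shift
# ---------------------------------------------------------------------------


@dataclass
class AgeShiftResult:
    gene: str
    cancer: str
    n_carrier_cases: int
    n_noncarrier_cases: int
    difference: float | None = None   # mean carrier age minus noncarrier age
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    p_welch: float | None = None
    gated: bool = False
    gate_reason: str | None = None


def age_at_diagnosis_shift(cohort: pd.DataFrame, carrier_table: pd.DataFrame | None,
                           gene: str, cancer: str,
                           sex: str | None = None) -> AgeShiftResult:
    """Difference in mean age at diagnosis between carrier and noncarrier
    cases of one cancer type, by linear regression of diagnosis age on
    carrier status (a Welch two-sample p-value is reported alongside).
    Gated below 3 carrier cases."""
    import statsmodels.api as sm

    if carrier_table is not None:
        cohort = attach_carriers(cohort, carrier_table)
    flag_col = f"carrier_{gene}"
    cases = cohort[(cohort[f"case_{cancer}"] == 1) & cohort[f"agedx_{cancer}"].notna()]
    if sex is not None:
        cases = cases[cases["sex"] == sex]
    car = cases[flag_col].to_numpy(bool)
    ages = cases[f"agedx_{cancer}"].to_numpy(float)
    res = AgeShiftResult(gene=gene, cancer=cancer,
                         n_carrier_cases=int(car.sum()),
                         n_noncarrier_cases=int((~car).sum()))
    if car.sum() < GATE_MIN_CARRIERS or (~car).sum() < GATE_MIN_CARRIERS:
        res.gated = True
        res.gate_reason = f"carrier count < {GATE_MIN_CARRIERS}"
        return res
    X = sm.add_constant(car.astype(float))
    ols = sm.OLS(ages, X).fit()
    res.difference = float(ols.params[1])
    res.ci_low, res.ci_high = (float(v) for v in ols.conf_int()[1])
    res.p = float(ols.pvalues[1])
    res.p_welch = float(stats.ttest_ind(ages[car], ages[~car], equal_var=False).pvalue)
    return res
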
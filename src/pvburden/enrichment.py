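"""Descriptive and categorical analyses: regional carrier-frequency
heterogeneity with founder-variant stratification, family-history trend
and cross-tabulation, and cohort characteristic summaries.

Founder pathogenic variants concentrate in single geographic regions and
can dominate the between-region variation in carrier frequency; the
regional chi-square is therefore offered both as-is and with founder
carriers recounted as noncarriers, so that founder-driven structure can
be isolated from residual regional differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .burden import attach_carriers

__all__ = [
    "regional_breakdown",
    "regional_chisq",
    "fh_profile",
    "fh_trend",
    "fh_cross_tab",
    "summarize_cohort",
    "age_band_carrier_proportions",
    "TrendResult",
]


# ---------------------------------------------------------------------------
# regional structure
# ---------------------------------------------------------------------------


def _carrier_flags_excluding_founders(cohort, calls, gene):
    """Carrier flags recomputed with founder-flagged variants removed."""
    qual = calls[(calls["gene"] == gene) & calls["class"].isin(("P", "LP"))
                 & (calls.get("founder", 0) == 0)]
    keep = set(qual["individual_id"])
    return cohort["individual_id"].isin(keep).to_numpy()


def regional_breakdown(cohort: pd.DataFrame, carrier_table: pd.DataFrame,
                       gene: str, cases_only: bool = True,
                       calls: pd.DataFrame | None = None,
                       exclude_founders: bool = False) -> pd.DataFrame:
    """Per-region carrier counts and proportions for one gene, with the
    max/min fold difference attached as ``.attrs['fold_difference']``.

    With ``exclude_founders`` (requires ``calls`` with a ``founder``
    column), carriers whose only qualifying variants are founder-flagged
    count as noncarriers.
    """
    df = attach_carriers(cohort, carrier_table)
    if cases_only:
        df = df[df["status"] == "case"]
    if exclude_founders:
        if calls is None:
            raise ValueError("exclude_founders requires the variant-call table")
        flags = _carrier_flags_excluding_founders(df, calls, gene)
    else:
        flags = df[f"carrier_{gene}"].to_numpy(bool)
    out = (pd.DataFrame({"region": df["region"].to_numpy(), "carrier": flags})
           .groupby("region").agg(n=("carrier", "size"), n_carriers=("carrier", "sum"))
           .reset_index())
    out["proportion"] = out["n_carriers"] / out["n"]
    nz = out.loc[out["proportion"] > 0, "proportion"]
    out.attrs["fold_difference"] = float(out["proportion"].max() / nz.min()) \
        if len(nz) else float("nan")
    return out


def regional_chisq(cohort: pd.DataFrame, carrier_table: pd.DataFrame, gene: str,
                   cases_only: bool = True, calls: pd.DataFrame | None = None,
                   exclude_founders: bool = False):
    """Pearson chi-square (no continuity correction) on the
    regions x {carrier, noncarrier} table.  Returns (chi2, df, p)."""
    bd = regional_breakdown(cohort, carrier_table, gene, cases_only,
                            calls, exclude_founders)
    if len(bd) < 2:
        raise ValueError("need at least 2 regions")
    if (bd["n"] == 0).any():
        raise ValueError("every region must contain at least one individual")
    table = np.column_stack([bd["n_carriers"], bd["n"] - bd["n_carriers"]])
    if table.sum(axis=0).min() == 0:
        # degenerate table (no carriers at all, or everyone a carrier):
        # no between-region variation to test
        return 0.0, len(bd) - 1, 1.0
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# family history
# ---------------------------------------------------------------------------


def fh_profile(cohort: pd.DataFrame, cancer_types: list[str]) -> pd.Series:
    """Per-individual count category — 0, 1 or 2 (meaning >= 2) — of the
    given associated cancer types reported in relatives."""
    cols = [f"fh_{c}" for c in cancer_types]
    missing = set(cols) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks family-history columns: {sorted(missing)}")
    counts = cohort[cols].sum(axis=1)
    return counts.clip(upper=2).astype(int)


@dataclass(frozen=True)
class TrendResult:
    z: float
    p: float
    counts: tuple[tuple[int, int], ...]  # (carriers, total) per ordered category


def fh_trend(carrier_flags, categories, scores=(0, 1, 2)) -> TrendResult:
    """Cochran-Armitage test for trend in carrier proportion across ordered
    family-history categories (none / 1 / >= 2 reported cancer types).

    Standard 2 x k trend statistic with fixed scores; two-sided p from the
    normal reference.  Empty categories are allowed; an all-empty table
    raises.
    """
    car = np.asarray(carrier_flags, bool)
    cat = np.asarray(categories, int)
    if car.size == 0:
        raise ValueError("empty table")
    scores = np.asarray(scores, float)
    n_i = np.array([(cat == j).sum() for j in range(len(scores))], float)
    r_i = np.array([car[cat == j].sum() for j in range(len(scores))], float)
    n, r = n_i.sum(), r_i.sum()
    if n == 0 or r == 0 or r == n:
        return TrendResult(0.0, 1.0, tuple(zip(r_i.astype(int), n_i.astype(int))))
    num = float((scores * (r_i - n_i * r / n)).sum())
    pbar = r / n
    sbar = float((scores * n_i).sum() / n)
    var = pbar * (1 - pbar) * float((n_i * (scores - sbar) ** 2).sum())
    if var <= 0:
        return TrendResult(0.0, 1.0, tuple(zip(r_i.astype(int), n_i.astype(int))))
    z = num / np.sqrt(var)
    return TrendResult(float(z), float(2 * stats.norm.sf(abs(z))),
                       tuple(zip(r_i.astype(int), n_i.astype(int))))


def fh_cross_tab(cohort: pd.DataFrame, carrier_table: pd.DataFrame, gene: str,
                 case_cancers: list[str], fh_cancers: list[str] | None = None
                 ) -> pd.DataFrame:
    """Carrier proportion among cases of each cancer type, split by reported
    family history of each (associated) cancer type, with a Fisher exact p
    per (case-cancer, family-history-cancer) cell and Bonferroni correction
    across the grid."""
    fh_cancers = fh_cancers if fh_cancers is not None else case_cancers
    df = attach_carriers(cohort, carrier_table)
    flag = f"carrier_{gene}"
    rows = []
    for cc in case_cancers:
        cases = df[df[f"case_{cc}"] == 1]
        for fc in fh_cancers:
            fh = cases[f"fh_{fc}"] == 1
            a = int((cases[flag] & fh).sum())        # carriers with FH
            b = int((~cases[flag] & fh).sum())
            c = int((cases[flag] & ~fh).sum())
            d = int((~cases[flag] & ~fh).sum())
            p = float(stats.fisher_exact([[a, b], [c, d]])[1])
            rows.append({"case_cancer": cc, "fh_cancer": fc,
                         "n_fh": a + b, "carriers_fh": a,
                         "prop_fh": a / (a + b) if a + b else np.nan,
                         "n_no_fh": c + d, "carriers_no_fh": c,
                         "prop_no_fh": c / (c + d) if c + d else np.nan,
                         "fisher_p": p})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = (out["fisher_p"] * m).clip(upper=1.0)
    out.attrs["bonferroni_factor"] = m
    return out


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------


def summarize_cohort(cohort: pd.DataFrame, carrier_table: pd.DataFrame | None = None
                     ) -> dict:
    """Registry-style characteristics table: per-cancer case counts by sex,
    mean (SD) diagnosis age, percent with same-type family history; control
    counts; and the multiple-primary fraction among patients.  Percentages
    are rounded to 1 decimal; an SD over fewer than 2 values is emitted as
    missing (None)."""
    cancers = [c[len("case_"):] for c in cohort.columns if c.startswith("case_")]
    per_cancer = {}
    for c in cancers:
        cases = cohort[cohort[f"case_{c}"] == 1]
        ages = cases[f"agedx_{c}"].dropna()
        per_cancer[c] = {
            "n_female": int((cases["sex"] == "female").sum()),
            "n_male": int((cases["sex"] == "male").sum()),
            "n_total": len(cases),
            "agedx_mean": float(ages.mean()) if len(ages) else None,
            "agedx_sd": float(ages.std(ddof=1)) if len(ages) > 1 else None,
            "pct_fh_same_type": round(100.0 * float((cases[f"fh_{c}"] == 1).mean()), 1)
            if len(cases) else None,
        }
    is_case = cohort["status"] == "case"
    n_types = cohort[[f"case_{c}" for c in cancers]].sum(axis=1)
    n_patients = int(is_case.sum())
    summary = {
        "per_cancer": per_cancer,
        "n_patients": n_patients,
        "n_cases_total": int(n_types[is_case].sum()),
        "n_controls": int((cohort["status"] == "control").sum()),
        "multi_primary_fraction_pct": round(
            100.0 * float((n_types[is_case] >= 2).mean()), 1) if n_patients else None,
    }
    if carrier_table is not None:
        df = attach_carriers(cohort, carrier_table)
        genes = [c[len("carrier_"):] for c in df.columns if c.startswith("carrier_")]
        summary["carriers"] = {g: int(df[f"carrier_{g}"].sum()) for g in genes}
    return summary


def age_band_carrier_proportions(cohort: pd.DataFrame, carrier_table: pd.DataFrame,
                                 gene: str, cancer: str, band_width: int = 10
                                 ) -> pd.DataFrame:
    """Carrier proportion among cases of one cancer type by diagnosis-age
    band.  The band-size-weighted mean of the proportions equals the
    overall carrier proportion (conservation of counts)."""
    df = attach_carriers(cohort, carrier_table)
    cases = df[(df[f"case_{cancer}"] == 1) & df[f"agedx_{cancer}"].notna()]
    band = (cases[f"agedx_{cancer}"] // band_width * band_width).astype(int)
    out = (pd.DataFrame({"age_band": band,
                         "carrier": cases[f"carrier_{gene}"].to_numpy(bool)})
           .groupby("age_band").agg(n=("carrier", "size"),
                                    n_carriers=("carrier", "sum"))
           .reset_index())
    out["proportion"] = out["n_carriers"] / out["n"]
    return out
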
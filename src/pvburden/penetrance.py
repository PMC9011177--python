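"""Lifetime cumulative-risk (penetrance) estimation for carriers and
noncarriers from an odds ratio, a population carrier frequency, and
age-band population incidence.

Population incidence in each age band is a carrier-frequency-weighted
mixture of the carrier and noncarrier hazards.  Treating the odds ratio
as a relative risk (rare-disease assumption; carrier frequencies here
are at most a few percent) and taking it constant across age bands, the
mixture constraint pins both hazards down exactly:

    lambda_n(t) = lambda_pop(t) / (1 + p (rr - 1))
    lambda_c(t) = rr * lambda_n(t)
    p * lambda_c(t) + (1 - p) * lambda_n(t) = lambda_pop(t)

Cumulative risk to age ``a`` follows the piecewise-exponential survival
form ``F(a) = 1 - prod_b exp(-lambda_b * width_b)`` over bands ending by
``a``, with no competing-mortality deflation (a cumulative-incidence
presentation; flagged in output metadata).

The 95% CI for the terminal risk propagates the log-OR sampling
distribution by simulation: log-OR draws from Normal(beta, SE^2) are
each pushed through the partition, and the interval is the normal
approximation on the *risk* scale, ``F_hat +/- 1.959964 * SD(draws)``.
That construction can produce negative lower bounds for small risks
with wide CIs — as published penetrance intervals sometimes do — so a
percentile interval is emitted alongside for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RiskCurve",
    "partition_hazard",
    "cumulative_risk",
    "risk_curve",
    "risk_ci",
    "validate_incidence",
]

Z95 = 1.959964
RISK_HORIZON = 85.0


def validate_incidence(incidence: pd.DataFrame, to_age: float = RISK_HORIZON) -> pd.DataFrame:
    """Check one (cancer, sex) block of an incidence table: columns
    ``age_lo, age_hi, rate``, contiguous non-overlapping bands covering
    [0, to_age), nonnegative rates.  Returns the block sorted by band."""
    missing = {"age_lo", "age_hi", "rate"} - set(incidence.columns)
    if missing:
        raise ValueError(f"incidence table missing columns: {sorted(missing)}")
    inc = incidence.sort_values("age_lo").reset_index(drop=True)
    if (inc["rate"] < 0).any():
        raise ValueError("incidence rates must be >= 0")
    if inc.loc[0, "age_lo"] > 0 or inc["age_hi"].iloc[-1] < to_age:
        raise ValueError(f"age bands must cover [0, {to_age})")
    prev_hi = inc.loc[0, "age_lo"]
    for lo, hi in zip(inc["age_lo"], inc["age_hi"]):
        if lo != prev_hi or hi <= lo:
            raise ValueError("gap or overlap in age-band coverage")
        prev_hi = hi
    return inc


def partition_hazard(incidence: pd.DataFrame, p: float, rr: float) -> pd.DataFrame:
    """Split population incidence into noncarrier and carrier hazards.

    ``p`` is the population carrier frequency (``0 <= p < 1``), ``rr`` the
    carrier relative risk (> 0).  Returns the incidence rows with added
    ``lam_n`` and ``lam_c`` columns satisfying the mixture identity
    exactly.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"carrier frequency must be in [0, 1), got {p}")
    if not rr > 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    inc = validate_incidence(incidence)
    lam_n = inc["rate"].to_numpy(float) / (1.0 + p * (rr - 1.0))
    out = inc.copy()
    out["lam_n"] = lam_n
    out["lam_c"] = rr * lam_n
    return out


def cumulative_risk(bands: pd.DataFrame, rate_col: str = "rate",
                    to_age: float = RISK_HORIZON) -> np.ndarray:
    """Cumulative risk at each band end up to ``to_age`` from band hazards,
    ``F(a) = 1 - prod exp(-lambda * width)`` over bands ending <= a."""
    block = bands[["age_lo", "age_hi", rate_col]].rename(columns={rate_col: "rate"})
    inc = validate_incidence(block, to_age)
    keep = inc["age_lo"] < to_age
    inc = inc[keep]
    width = np.minimum(inc["age_hi"].to_numpy(float), to_age) - inc["age_lo"].to_numpy(float)
    cumhaz = np.cumsum(inc["rate"].to_numpy(float) * width)
    return -np.expm1(-cumhaz)


@dataclass
class RiskCurve:
    """Band-wise hazard partition and cumulative risks for one
    (gene, cancer, sex) combination."""

    gene: str
    cancer: str
    sex: str
    p: float
    rr: float
    bands: pd.DataFrame                 # age_lo, age_hi, rate, lam_n, lam_c, F_n, F_c
    terminal_age: float = RISK_HORIZON
    f_n: float = 0.0                    # cumulative risk to terminal age, noncarriers
    f_c: float = 0.0                    # …carriers
    ci_normal: tuple[float, float] | None = None      # CI for f_c, risk scale
    ci_percentile: tuple[float, float] | None = None
    ci_normal_n: tuple[float, float] | None = None    # CI for f_n
    meta: dict = field(default_factory=dict)


def risk_curve(incidence: pd.DataFrame, p: float, rr: float,
               gene: str = "", cancer: str = "", sex: str = "",
               to_age: float = RISK_HORIZON) -> RiskCurve:
    """Point-estimate risk curve: hazard partition plus cumulative risks."""
    part = partition_hazard(incidence, p, rr)
    part = part[part["age_lo"] < to_age].reset_index(drop=True)
    part["F_n"] = cumulative_risk(part, "lam_n", to_age)
    part["F_c"] = cumulative_risk(part, "lam_c", to_age)
    return RiskCurve(gene=gene, cancer=cancer, sex=sex, p=p, rr=rr,
                     bands=part, terminal_age=to_age,
                     f_n=float(part["F_n"].iloc[-1]), f_c=float(part["F_c"].iloc[-1]),
                     meta={"competing_mortality": "ignored",
                           "or_as_rr": "rare-disease assumption"})


def risk_ci(beta: float, se: float, incidence: pd.DataFrame, p: float,
            n_draws: int = 10_000, seed: int | None = 0,
            to_age: float = RISK_HORIZON, gated: bool = False):
    """Simulation CI for the terminal cumulative risks given a fitted
    log-OR ``beta`` with standard error ``se``.

    Draws log-OR ~ Normal(beta, se^2), recomputes the carrier and
    noncarrier terminal risks per draw, and reports for each the normal
    approximation on the risk scale (point estimate +/- 1.959964 x SD of
    draws; the lower bound may be negative) plus a 2.5/97.5 percentile
    interval.  Raises if the source association was gated.
    """
    if gated:
        raise ValueError("association result is gated; no estimates to propagate")
    if se < 0:
        raise ValueError("se must be >= 0")
    rng = np.random.default_rng(seed)
    curve = risk_curve(incidence, p, math.exp(beta), to_age=to_age)
    draws_rr = np.exp(beta + se * rng.standard_normal(n_draws))
    inc = validate_incidence(incidence, to_age)
    keep = inc["age_lo"] < to_age
    width = (np.minimum(inc["age_hi"][keep].to_numpy(float), to_age)
             - inc["age_lo"][keep].to_numpy(float))
    lam_pop = inc["rate"][keep].to_numpy(float)
    cum_pop = float((lam_pop * width).sum())
    denom = 1.0 + p * (draws_rr - 1.0)
    f_n_draws = -np.expm1(-cum_pop / denom)
    f_c_draws = -np.expm1(-cum_pop * draws_rr / denom)
    sd_c, sd_n = float(f_c_draws.std(ddof=1)), float(f_n_draws.std(ddof=1))
    curve.ci_normal = (curve.f_c - Z95 * sd_c, curve.f_c + Z95 * sd_c)
    curve.ci_normal_n = (curve.f_n - Z95 * sd_n, curve.f_n + Z95 * sd_n)
    curve.ci_percentile = tuple(float(q) for q in
                                np.percentile(f_c_draws, [2.5, 97.5]))
    curve.meta["n_draws"] = n_draws
    return curve
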
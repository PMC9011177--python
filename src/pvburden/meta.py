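"""Between-gene heterogeneity of odds ratios: Cochran Q, I², and
DerSimonian-Laird random-effects pooling, computed from ORs and their
95% CIs alone.

Printed Wald CIs are symmetric on the log scale, so the log-OR standard
error is recovered by CI inversion, ``SE = (ln hi - ln lo) / (2 z)``
with ``z = 1.959964`` (the exact normal 97.5% quantile; spelled out for
determinism even though the difference from 1.96 is below printed
precision).  Heterogeneity across k effect estimates then follows the
standard inverse-variance machinery:

    w_i = 1 / SE_i^2,   theta_bar = sum(w theta) / sum(w)
    Q = sum w (theta - theta_bar)^2,   df = k - 1
    I^2 = max(0, (Q - df) / Q) * 100
    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w))

with the random-effects pooled estimate using weights
``1 / (SE_i^2 + tau^2)``.  The heterogeneity p-value is the upper tail
of a central chi-square with k-1 degrees of freedom; no small-k
corrections are applied (the gene-pair use case has k = 2 throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z95",
    "EffectEstimate",
    "HetResult",
    "se_from_ci",
    "heterogeneity",
    "heterogeneity_table",
    "load_published_pairs",
]

Z95 = 1.959964


@dataclass(frozen=True)
class EffectEstimate:
    """One effect on the log-odds scale."""

    label: str
    theta: float
    se: float

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"SE must be positive, got {self.se}")


def se_from_ci(odds_ratio: float, lo: float, hi: float,
               label: str = "") -> EffectEstimate:
    """Invert a printed OR with 95% CI to a log-odds effect estimate."""
    if not (0 < lo < odds_ratio < hi):
        raise ValueError(
            f"require 0 < lo < OR < hi, got OR={odds_ratio}, CI=({lo}, {hi})")
    return EffectEstimate(label=label, theta=math.log(odds_ratio),
                          se=(math.log(hi) - math.log(lo)) / (2 * Z95))


@dataclass(frozen=True)
class HetResult:
    q: float
    df: int
    p: float
    i2: float          # percent, floored at 0
    tau2: float        # DerSimonian-Laird, floored at 0
    pooled_theta: float
    pooled_se: float
    pooled_or: float
    pooled_ci_low: float
    pooled_ci_high: float

    @property
    def i2_rounded(self) -> float:
        return round(self.i2, 1)


def heterogeneity(effects: Sequence[EffectEstimate]) -> HetResult:
    """Cochran Q / I² heterogeneity and DL random-effects pooling over
    ``k >= 2`` effect estimates."""
    k = len(effects)
    if k < 2:
        raise ValueError(f"need at least 2 effect estimates, got {k}")
    theta = np.array([e.theta for e in effects])
    se = np.array([e.se for e in effects])
    w = 1.0 / se**2
    theta_bar = float((w * theta).sum() / w.sum())
    q = float((w * (theta - theta_bar) ** 2).sum())
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= df else 100.0 * (q - df) / q
    c = float(w.sum() - (w**2).sum() / w.sum())
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float((w_re * theta).sum() / w_re.sum())
    pooled_se = float(1.0 / math.sqrt(w_re.sum()))
    return HetResult(q=q, df=df, p=p, i2=i2, tau2=tau2,
                     pooled_theta=pooled, pooled_se=pooled_se,
                     pooled_or=math.exp(pooled),
                     pooled_ci_low=math.exp(pooled - Z95 * pooled_se),
                     pooled_ci_high=math.exp(pooled + Z95 * pooled_se))


def heterogeneity_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-cancer heterogeneity report from a long table of printed ORs.

    ``pairs`` needs columns ``cancer, gene, or, lo, hi``; every cancer with
    at least two gene rows yields one output row with Q, p, I² (1 decimal,
    floored at 0), tau², and the random-effects pooled OR with CI.
    """
    missing = {"cancer", "gene", "or", "lo", "hi"} - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    rows = []
    for cancer, grp in pairs.groupby("cancer", sort=True):
        if len(grp) < 2:
            continue
        effects = [se_from_ci(r["or"], r["lo"], r["hi"], label=r["gene"])
                   for _, r in grp.sort_values("gene").iterrows()]
        h = heterogeneity(effects)
        rows.append({"cancer": cancer, "k": len(effects), "q": h.q,
                     "p_het": h.p, "i2": h.i2_rounded, "tau2": h.tau2,
                     "pooled_or": h.pooled_or, "pooled_ci_low": h.pooled_ci_low,
                     "pooled_ci_high": h.pooled_ci_high})
    return pd.DataFrame(rows)


def load_published_pairs() -> pd.DataFrame:
    """The shipped fixture of published gene-specific OR (95% CI) pairs
    from a nationwide biobank case-control study of two DNA-repair genes
    across cancer types (no-family-history design), as printed."""
    with resources.files("pvburden.data").joinpath("published_or_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
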
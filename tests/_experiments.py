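"""Frozen study conditions for the simulation experiments.

One-cancer, one-gene cohorts with a registry-like adult-onset hazard
shape (zero before 30, doubling per decade).  Carrier frequencies and
lifetime baseline risks are fixed so that expected carrier-case counts
sit in the tens, comparable to the common-cancer strata of a nationwide
biobank; the calibration (null) endpoint is a deliberately common
composite phenotype so the null rejection rate is informative.
"""

from __future__ import annotations

import numpy as np

from pvburden.sim import SimConfig, CancerSpec, adult_onset_hazard

GENE = "GENE1"
CANCER = "stomach"

#: lifetime baseline risk of the composite calibration endpoint
NULL_LIFETIME_RISK = 0.50
NULL_CARRIER_FREQ = 0.02
#: rare-cancer conditions for CI-coverage and penetrance recovery
RARE_LIFETIME_RISK = 0.045
COVERAGE_CARRIER_FREQ = 0.015
COVERAGE_RR = 10.0
E2E_CARRIER_FREQ = 0.004
E2E_RR = 11.0


def one_cancer_config(n: int, seed: int, rr: float, carrier_freq: float,
                      lifetime_risk: float) -> SimConfig:
    hz = adult_onset_hazard(lifetime_risk)
    return SimConfig(
        n_individuals=n,
        regions={"east": 0.5, "west": 0.5},
        genes=(GENE,),
        cancers=(CancerSpec(CANCER, {"female": hz, "male": hz}),),
        background_rate={GENE: carrier_freq},
        true_or={(GENE, CANCER): rr},
        fh_background_rate={CANCER: 0.05},
        fh_carrier_multiplier=1.0,   # genuine null for calibration purposes
        seed=seed,
    ).validate()


def null_config(seed: int, n: int = 20_000) -> SimConfig:
    return one_cancer_config(n, seed, 1.0, NULL_CARRIER_FREQ, NULL_LIFETIME_RISK)


def coverage_config(seed: int, n: int = 20_000) -> SimConfig:
    return one_cancer_config(n, seed, COVERAGE_RR, COVERAGE_CARRIER_FREQ,
                             RARE_LIFETIME_RISK)


def e2e_config(seed: int, n: int = 100_000) -> SimConfig:
    return one_cancer_config(n, seed, E2E_RR, E2E_CARRIER_FREQ, RARE_LIFETIME_RISK)


def true_carrier_risk(rr: float, lifetime_risk: float = RARE_LIFETIME_RISK,
                      to_age: float = 85.0) -> float:
    """Generative carrier cumulative risk to ``to_age`` under the band model."""
    from pvburden.sim import DEFAULT_AGE_BANDS

    hz = np.array(adult_onset_hazard(lifetime_risk))
    widths = np.array([hi - lo for lo, hi in DEFAULT_AGE_BANDS])
    keep = np.array([lo < to_age for lo, _ in DEFAULT_AGE_BANDS])
    return float(-np.expm1(-rr * float((hz * widths)[keep].sum())))
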
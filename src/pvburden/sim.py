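"""Synthetic biobank-style case-control cohort generator.

Emulates the data structure of a nationwide hospital-based registry in
which patients with any of several cancer types and cancer-free,
family-history-free controls were sequenced for two cancer-predisposition
genes: region-structured founder variants, rare background pathogenic
variants, age-dependent onset with genotype relative risks, multiple
primary cancers in a minority of patients, and first/second-degree
family-history reporting.  Every downstream stage of the pipeline
(carrier collapsing, burden regression, heterogeneity, penetrance,
enrichment) can therefore be tested against known ground truth without
any real data.

The generative model, per individual:

* sex, region and registration age are drawn independently;
* per gene, carrier status is the union of region-specific founder
  variants and a region-independent background variant (all classified
  pathogenic / likely pathogenic); benign and VUS decoy calls are added
  that must never confer carrier status;
* per cancer type, onset is sampled from discrete age-band hazards
  (geometric within band), with the carrier hazard equal to the relative
  risk times the baseline; an onset is observed only if it precedes the
  registration age;
* family-history flags are marginal Bernoulli draws, enriched among
  carriers by a configurable multiplier;
* individuals with no observed cancer and no family history form the
  control pool, mirroring the registry's control definition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "FounderVariant",
    "CancerSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_incidence_table",
    "default_config",
    "write_table",
    "read_cohort_table",
    "read_variant_calls",
    "read_incidence_table",
    "write_variant_calls_vcf",
]

#: closed set of variant classification labels, most to least severe
CLASSIFICATIONS = ("P", "LP", "VUS", "LB", "B")
#: labels that confer carrier status under the dominant model
PATHOGENIC_CLASSES = frozenset({"P", "LP"})

SEXES = ("female", "male")
AGE_MIN, AGE_MAX = 20, 99
RISK_HORIZON = 85
DEFAULT_AGE_BANDS = tuple((float(lo), float(lo + 5)) for lo in range(0, 85, 5))


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FounderVariant:
    """A pathogenic variant at elevated frequency in one region."""

    gene: str
    variant_id: str
    region: str
    frequency: float


@dataclass(frozen=True)
class CancerSpec:
    """One cancer type: which sexes it affects and its per-band baseline
    hazard (events per person-year) for each sex.

    ``hazard`` maps sex to either a scalar (constant across bands) or a
    sequence with one rate per age band.
    """

    name: str
    hazard: Mapping[str, object]
    sexes: tuple[str, ...] = SEXES

    def hazard_array(self, sex: str, n_bands: int) -> np.ndarray:
        if sex not in self.sexes:
            return np.zeros(n_bands)
        h = self.hazard.get(sex, 0.0)
        arr = np.broadcast_to(np.asarray(h, dtype=float), (n_bands,)).copy() \
            if np.ndim(h) == 0 else np.asarray(h, dtype=float)
        if arr.shape != (n_bands,):
            raise ConfigError(
                f"cancers[{self.name}].hazard[{sex}]: expected scalar or "
                f"{n_bands} per-band rates, got shape {arr.shape}")
        return arr


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic cohort.

    Frequencies and probabilities live in [0, 1], hazards are
    nonnegative per-person-year rates, relative risks are positive, and
    region weights sum to one.  ``validate`` enforces all of this and
    raises :class:`ConfigError` naming the offending field.
    """

    n_individuals: int
    regions: dict[str, float]
    genes: tuple[str, ...]
    cancers: tuple[CancerSpec, ...]
    founder_variants: tuple[FounderVariant, ...] = ()
    background_rate: dict[str, float] = field(default_factory=dict)
    true_or: dict[tuple[str, str], float] = field(default_factory=dict)
    fh_background_rate: dict[str, float] = field(default_factory=dict)
    fh_carrier_multiplier: float = 1.0
    multi_primary_target: float = 0.0
    female_fraction: float = 0.5
    #: ("truncnorm", mean, sd, lo, hi) or ("uniform", lo, hi); the source
    #: study does not report its control registration-age distribution,
    #: so it is exposed here rather than fixed.
    registration_age: tuple = ("truncnorm", 60.0, 13.0, 20.0, 90.0)
    decoy_rate: float = 0.0
    age_bands: tuple[tuple[float, float], ...] = DEFAULT_AGE_BANDS
    seed: int = 0

    # -- validation ----------------------------------------------------

    def validate(self) -> "SimConfig":
        if not isinstance(self.n_individuals, (int, np.integer)) or self.n_individuals <= 0:
            raise ConfigError(f"n_individuals: must be a positive integer, got {self.n_individuals!r}")
        if not self.regions:
            raise ConfigError("regions: at least one region is required")
        w = np.array(list(self.regions.values()), float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("regions: weights must be nonnegative and sum to 1 within 1e-9")
        if not self.genes:
            raise ConfigError("genes: at least one gene is required")
        if not self.cancers:
            raise ConfigError("cancers: at least one cancer type is required")
        names = [c.name for c in self.cancers]
        if len(set(names)) != len(names):
            raise ConfigError("cancers: duplicate cancer names")
        self._check_bands()
        nb = len(self.age_bands)
        for c in self.cancers:
            for s in c.sexes:
                if s not in SEXES:
                    raise ConfigError(f"cancers[{c.name}].sexes: unknown sex {s!r}")
                if (c.hazard_array(s, nb) < 0).any():
                    raise ConfigError(f"cancers[{c.name}].hazard[{s}]: rates must be >= 0")
        for fv in self.founder_variants:
            if fv.gene not in self.genes:
                raise ConfigError(f"founder_variants[{fv.variant_id}].gene: unknown gene {fv.gene!r}")
            if fv.region not in self.regions:
                raise ConfigError(f"founder_variants[{fv.variant_id}].region: unknown region {fv.region!r}")
            if not 0.0 <= fv.frequency <= 1.0:
                raise ConfigError(f"founder_variants[{fv.variant_id}].frequency: must be in [0, 1]")
        for g, r in self.background_rate.items():
            if g not in self.genes:
                raise ConfigError(f"background_rate[{g}]: unknown gene")
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"background_rate[{g}]: must be in [0, 1]")
        for (g, c), rr in self.true_or.items():
            if g not in self.genes:
                raise ConfigError(f"true_or[{g}, {c}]: unknown gene {g!r}")
            if c not in names:
                raise ConfigError(f"true_or[{g}, {c}]: unknown cancer {c!r}")
            if not rr > 0:
                raise ConfigError(f"true_or[{g}, {c}]: relative risk must be > 0")
        for c, p in self.fh_background_rate.items():
            if c not in names:
                raise ConfigError(f"fh_background_rate[{c}]: unknown cancer")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"fh_background_rate[{c}]: must be in [0, 1]")
        if self.fh_carrier_multiplier < 0:
            raise ConfigError("fh_carrier_multiplier: must be >= 0")
        if not 0.0 <= self.multi_primary_target <= 1.0:
            raise ConfigError("multi_primary_target: must be in [0, 1]")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction: must be in [0, 1]")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ConfigError("decoy_rate: must be in [0, 1]")
        self._check_age_dist()
        return self

    def _check_bands(self) -> None:
        bands = self.age_bands
        if not bands:
            raise ConfigError("age_bands: empty")
        lo0, hi_last = bands[0][0], bands[-1][1]
        if lo0 != 0.0 or hi_last < RISK_HORIZON:
            raise ConfigError(f"age_bands: must cover [0, {RISK_HORIZON})")
        for (lo, hi), (lo2, _hi2) in zip(bands, bands[1:]):
            if hi != lo2 or hi <= lo:
                raise ConfigError("age_bands: bands must be contiguous half-open [lo, hi)")
        if bands[-1][1] <= bands[-1][0]:
            raise ConfigError("age_bands: bands must be contiguous half-open [lo, hi)")

    def _check_age_dist(self) -> None:
        ra = tuple(self.registration_age)
        if ra and ra[0] == "truncnorm" and len(ra) == 5:
            _, _mu, sd, lo, hi = ra
            ok = sd > 0 and AGE_MIN <= lo < hi <= AGE_MAX
        elif ra and ra[0] == "uniform" and len(ra) == 3:
            _, lo, hi = ra
            ok = AGE_MIN <= lo < hi <= AGE_MAX
        else:
            ok = False
        if not ok:
            raise ConfigError(
                "registration_age: expected ('truncnorm', mean, sd, lo, hi) or "
                f"('uniform', lo, hi) with bounds in [{AGE_MIN}, {AGE_MAX}], got {ra!r}")

    # -- derived quantities --------------------------------------------

    def cancer(self, name: str) -> CancerSpec:
        for c in self.cancers:
            if c.name == name:
                return c
        raise KeyError(name)

    def rr(self, gene: str, cancer: str) -> float:
        return float(self.true_or.get((gene, cancer), 1.0))

    def region_carrier_frequency(self, gene: str, region: str) -> float:
        """P(carrier of ``gene``) for an individual in ``region``."""
        q = 1.0 - self.background_rate.get(gene, 0.0)
        for fv in self.founder_variants:
            if fv.gene == gene and fv.region == region:
                q *= 1.0 - fv.frequency
        return 1.0 - q

    def carrier_frequency(self, gene: str) -> float:
        """Region-weight-averaged population carrier frequency."""
        return float(sum(w * self.region_carrier_frequency(gene, r)
                         for r, w in self.regions.items()))

    def config_digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    # -- (de)serialisation ---------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cancers"] = [
            {"name": c.name, "sexes": list(c.sexes),
             "hazard": {s: (float(h) if np.ndim(h) == 0 else [float(v) for v in h])
                        for s, h in c.hazard.items()}}
            for c in self.cancers]
        d["founder_variants"] = [dataclasses.asdict(fv) for fv in self.founder_variants]
        d["true_or"] = [{"gene": g, "cancer": c, "rr": v} for (g, c), v in self.true_or.items()]
        d["age_bands"] = [list(b) for b in self.age_bands]
        d["registration_age"] = list(self.registration_age)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        try:
            d["cancers"] = tuple(
                CancerSpec(name=c["name"], hazard=dict(c["hazard"]),
                           sexes=tuple(c.get("sexes", SEXES)))
                for c in d["cancers"])
            d["founder_variants"] = tuple(
                FounderVariant(**fv) for fv in d.get("founder_variants", ()))
            d["true_or"] = {(e["gene"], e["cancer"]): float(e["rr"])
                            for e in d.get("true_or", ())}
            d["genes"] = tuple(d["genes"])
            if "age_bands" in d:
                d["age_bands"] = tuple(tuple(map(float, b)) for b in d["age_bands"])
            if "registration_age" in d:
                d["registration_age"] = tuple(d["registration_age"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed configuration: {exc}") from exc
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Latent quantities realised during generation, for parameter-recovery
    testing: per-individual carrier status, per-region carrier frequencies,
    and the relative risks used.  Bit-for-bit reproducible from
    (config, seed)."""

    carrier: pd.DataFrame               # index individual_id, one bool column per gene
    rr: dict[tuple[str, str], float]
    region_carrier_freq: pd.DataFrame   # index region, one float column per gene
    seed: int
    config_digest: str


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_registration_age(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    ra = cfg.registration_age
    if ra[0] == "uniform":
        ages = rng.uniform(ra[1], ra[2], n)
    else:  # truncnorm via inverse CDF so the stream stays a single uniform draw
        from scipy.stats import truncnorm
        _, mu, sd, lo, hi = ra
        a, b = (lo - mu) / sd, (hi - mu) / sd
        ages = truncnorm.ppf(rng.random(n), a, b, loc=mu, scale=sd)
    return np.floor(ages)


def _sample_onsets(rng: np.random.Generator, bands, lam: np.ndarray) -> np.ndarray:
    """Sample one onset age per row of ``lam`` (rows: individuals, columns:
    bands) from the discrete band-hazard model: survive band b with
    probability exp(-lam*width), and given an event, the year within the
    band is geometric with per-year rate lam.  Returns NaN for no event
    before the end of the last band."""
    n, nb = lam.shape
    onset = np.full(n, np.nan)
    alive = np.ones(n, bool)
    for b, (lo, hi) in enumerate(bands):
        width = hi - lo
        lam_b = lam[:, b]
        p_event = -np.expm1(-lam_b * width)
        event = alive & (rng.random(n) < p_event)
        # truncated-geometric year offset within the band
        v = rng.random(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.floor(np.log1p(-v * -np.expm1(-lam_b * width)) / -lam_b)
        k = np.where(np.isfinite(k), k, 0.0)
        k = np.clip(k, 0, max(width - 1, 0))
        onset[event] = lo + k[event]
        alive &= ~event
    return onset


def simulate_cohort(config: SimConfig):
    """Generate a cohort.

    Returns ``(cohort, calls, truth)`` where ``cohort`` is the per-individual
    phenotype table (sex, region, registration age, per-cancer case flags and
    diagnosis ages, family-history flags, case/control status), ``calls`` is
    the per-individual variant-call table including non-pathogenic decoy
    calls, and ``truth`` is the :class:`GroundTruth` record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    bands = config.age_bands
    nb = len(bands)

    ids = np.array([f"I{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    labels = list(config.regions)
    region = rng.choice(labels, size=n, p=np.array(list(config.regions.values()), float))
    age_reg = _draw_registration_age(config, rng, n)

    # --- carrier status and variant calls ---
    carrier = {g: np.zeros(n, bool) for g in config.genes}
    call_rows: list[tuple[str, str, str, str, int]] = []

    def add_calls(mask, gene, vid, cls, founder):
        for i in np.nonzero(mask)[0]:
            call_rows.append((ids[i], gene, vid, cls, founder))

    for gene in config.genes:
        for fv in config.founder_variants:
            if fv.gene != gene:
                continue
            hit = (rng.random(n) < fv.frequency) & (region == fv.region)
            carrier[gene] |= hit
            add_calls(hit, gene, fv.variant_id, "P", 1)
        bg = config.background_rate.get(gene, 0.0)
        if bg > 0:
            hit = rng.random(n) < bg
            pool = rng.integers(0, 20, n)          # 20 synthetic background alleles
            is_lp = rng.random(n) < 0.4
            carrier[gene] |= hit
            for i in np.nonzero(hit)[0]:
                call_rows.append((ids[i], gene, f"{gene}_b{pool[i]:03d}",
                                  "LP" if is_lp[i] else "P", 0))
    if config.decoy_rate > 0:
        hit = rng.random(n) < config.decoy_rate
        gidx = rng.integers(0, len(config.genes), n)
        pool = rng.integers(0, 40, n)
        cls = rng.choice(["VUS", "LB", "B"], size=n, p=[0.7, 0.15, 0.15])
        for i in np.nonzero(hit)[0]:
            g = config.genes[gidx[i]]
            call_rows.append((ids[i], g, f"{g}_d{pool[i]:03d}", cls[i], 0))

    carrier_any = np.zeros(n, bool)
    for g in config.genes:
        carrier_any |= carrier[g]

    # --- onsets ---
    sex_is_f = sex == "female"
    case = {}
    agedx = {}
    for c in config.cancers:
        base = np.empty((n, nb))
        base[sex_is_f] = c.hazard_array("female", nb)
        base[~sex_is_f] = c.hazard_array("male", nb)
        mult = np.ones(n)
        for g in config.genes:
            rr = config.rr(g, c.name)
            if rr != 1.0:
                mult = mult * np.where(carrier[g], rr, 1.0)
        onset = _sample_onsets(rng, bands, base * mult[:, None])
        observed = np.isfinite(onset) & (onset < age_reg)
        case[c.name] = observed
        agedx[c.name] = np.where(observed, onset, np.nan)

    # --- multi-primary top-up ---
    names = [c.name for c in config.cancers]
    n_types = np.zeros(n, int)
    for c in names:
        n_types += case[c]
    if config.multi_primary_target > 0 and len(names) > 1:
        _promote_multi_primary(config, rng, sex, age_reg, case, agedx, n_types)
        n_types = np.zeros(n, int)
        for c in names:
            n_types += case[c]

    # --- family history ---
    fh = {}
    for c in config.cancers:
        p0 = config.fh_background_rate.get(c.name, 0.0)
        p = np.where(carrier_any, p0 * config.fh_carrier_multiplier, p0)
        fh[c.name] = rng.random(n) < np.clip(p, 0.0, 1.0)

    fh_any = np.zeros(n, bool)
    for c in names:
        fh_any |= fh[c]
    is_case = n_types > 0
    status = np.where(is_case, "case", np.where(fh_any, "excluded", "control"))
    # the control definition forbids any personal or family history of cancer
    for c in names:
        fh[c] &= status != "control"  # no-op by construction; keep explicit

    cohort = pd.DataFrame({"individual_id": ids, "sex": sex, "region": region,
                           "age_registration": age_reg, "status": status})
    for c in names:
        cohort[f"case_{c}"] = case[c].astype(int)
        cohort[f"agedx_{c}"] = agedx[c]
        cohort[f"fh_{c}"] = fh[c].astype(int)

    calls = pd.DataFrame(call_rows,
                         columns=["individual_id", "gene", "variant_id", "class", "founder"])
    calls = calls.sort_values(["individual_id", "gene", "variant_id"], kind="stable",
                              ignore_index=True)

    carrier_df = pd.DataFrame({g: carrier[g] for g in config.genes},
                              index=pd.Index(ids, name="individual_id"))
    reg_freq = pd.DataFrame(
        {g: [carrier[g][region == r].mean() if (region == r).any() else np.nan
             for r in labels] for g in config.genes},
        index=pd.Index(labels, name="region"))
    truth = GroundTruth(carrier=carrier_df,
                        rr={(g, c): config.rr(g, c) for g in config.genes for c in names},
                        region_carrier_freq=reg_freq,
                        seed=config.seed, config_digest=config.config_digest())
    return cohort, calls, truth


def _promote_multi_primary(config, rng, sex, age_reg, case, agedx, n_types):
    """Top up the multi-primary fraction by giving randomly chosen
    single-cancer patients a second, carrier-independent primary."""
    names = [c.name for c in config.cancers]
    n_patients = int((n_types > 0).sum())
    if n_patients == 0:
        return
    deficit = config.multi_primary_target - (n_types >= 2).sum() / n_patients
    n_extra = int(round(deficit * n_patients))
    if n_extra <= 0:
        return
    singles = np.nonzero(n_types == 1)[0]
    if singles.size == 0:
        return
    chosen = rng.choice(singles, size=min(n_extra, singles.size), replace=False)
    share = {c.name: max(1, sum(case[c.name])) for c in config.cancers}
    for i in chosen:
        current = next(c for c in names if case[c][i])
        options = [c for c in config.cancers
                   if c.name != current and sex[i] in c.sexes]
        if not options:
            continue
        w = np.array([share[c.name] for c in options], float)
        pick = options[rng.choice(len(options), p=w / w.sum())].name
        first = agedx[current][i]
        case[pick][i] = True
        agedx[pick][i] = float(rng.integers(int(first), int(age_reg[i]) + 1))


# ---------------------------------------------------------------------------
# population incidence implied by the configuration
# ---------------------------------------------------------------------------


def simulate_incidence_table(config: SimConfig) -> pd.DataFrame:
    """Exact population incidence implied by the configuration, as a
    band-wise hazard mixture over genotypes:

        lambda_pop(t) = lambda_0(t) * sum_r w_r * prod_g (1 - p_gr + p_gr * rr_g)

    which for a single gene reduces to
    ``p * rr * lambda_0 + (1 - p) * lambda_0``.  One row per
    (cancer, sex, age band); stands in for a national registry incidence
    table when feeding the penetrance stage from synthetic data.
    """
    config.validate()
    nb = len(config.age_bands)
    rows = []
    for c in config.cancers:
        for s in c.sexes:
            base = c.hazard_array(s, nb)
            mix = sum(
                w * float(np.prod([
                    1.0 - config.region_carrier_frequency(g, r)
                    + config.region_carrier_frequency(g, r) * config.rr(g, c.name)
                    for g in config.genes]))
                for r, w in config.regions.items())
            for b, (lo, hi) in enumerate(config.age_bands):
                rows.append((c.name, s, lo, hi, base[b] * mix))
    return pd.DataFrame(rows, columns=["cancer", "sex", "age_lo", "age_hi", "rate"])


# ---------------------------------------------------------------------------
# file I/O (TSV with header row; minimal VCF dialect)
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline table as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"individual_id", "sex", "region", "age_registration", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def read_variant_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"individual_id", "gene", "variant_id", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"variant-call table missing columns: {sorted(missing)}")
    if "founder" not in df.columns:
        df["founder"] = 0
    return df


def read_incidence_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"cancer", "sex", "age_lo", "age_hi", "rate"} - set(df.columns)
    if missing:
        raise ValueError(f"incidence table missing columns: {sorted(missing)}")
    return df


def write_variant_calls_vcf(calls: pd.DataFrame, individuals: Sequence[str], path) -> None:
    """Write calls as a minimal VCF: one record per distinct (gene, variant),
    one sample column per individual (GT 0/1 dominant coding), INFO keys
    GENE, CLASS (P/LP/VUS/LB/B) and FOUNDER."""
    import pysam

    header = pysam.VariantHeader()
    genes = sorted(calls["gene"].unique())
    contigs = {g: f"ctg{k + 1}" for k, g in enumerate(genes)}
    for g in genes:
        header.contigs.add(contigs[g], length=10_000_000)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CLASS", 1, "String", "Clinical classification (P/LP/VUS/LB/B)")
    header.info.add("FOUNDER", 0, "Flag", "Regional founder variant")
    header.formats.add("GT", 1, "String", "Genotype")
    individuals = list(individuals)
    for ind in individuals:
        header.add_sample(ind)
    idx = {ind: k for k, ind in enumerate(individuals)}

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        pos = {g: 0 for g in genes}
        for (gene, vid), grp in calls.groupby(["gene", "variant_id"], sort=True):
            pos[gene] += 100
            rec = vf.new_record(contig=contigs[gene], start=pos[gene] - 1,
                                alleles=("A", "T"), id=vid)
            rec.info["GENE"] = gene
            rec.info["CLASS"] = grp["class"].iloc[0]
            if int(grp["founder"].max()) > 0:
                rec.info["FOUNDER"] = True
            for ind in individuals:
                rec.samples[ind]["GT"] = (0, 0)
            for ind in grp["individual_id"]:
                rec.samples[ind]["GT"] = (0, 1)
            _ = idx  # sample order fixed by header
            vf.write(rec)


# ---------------------------------------------------------------------------
# hazard helpers and demonstration configuration
# ---------------------------------------------------------------------------


def adult_onset_hazard(lifetime_risk: float,
                       bands: Sequence[tuple[float, float]] = DEFAULT_AGE_BANDS,
                       onset_floor: float = 30.0,
                       doubling_years: float = 10.0) -> tuple[float, ...]:
    """Per-band hazards with a registry-like adult-onset shape: zero below
    ``onset_floor``, then rising exponentially (doubling every
    ``doubling_years``), scaled so the cumulative risk over the bands is
    ``lifetime_risk``."""
    if not 0.0 <= lifetime_risk < 1.0:
        raise ConfigError(f"lifetime_risk must be in [0, 1), got {lifetime_risk}")
    mids = np.array([(lo + hi) / 2 for lo, hi in bands])
    widths = np.array([hi - lo for lo, hi in bands])
    shape = np.where(mids < onset_floor, 0.0, 2.0 ** ((mids - 75.0) / doubling_years))
    total = float((shape * widths).sum())
    scale = -math.log1p(-lifetime_risk) / total if total > 0 else 0.0
    return tuple(float(v) for v in scale * shape)


def default_config(n_individuals: int = 20_000, seed: int = 0) -> SimConfig:
    """A two-gene, 14-cancer configuration emulating the scale and structure
    of a nationwide biobank study: region-weighted sampling over seven
    regions, founder variants at 0.2-0.6% in single regions, rare background
    carriers, relative risks concentrated in the classically associated
    cancers, and a multi-primary fraction of 6.3%."""
    regions = {"hokkaido": 0.05, "tohoku": 0.08, "kanto": 0.33, "chubu": 0.17,
               "kinki": 0.18, "kyushu": 0.15, "okinawa": 0.04}
    genes = ("BRCA1", "BRCA2")
    founders = (
        FounderVariant("BRCA1", "BRCA1_f001", "tohoku", 0.006),
        FounderVariant("BRCA1", "BRCA1_f002", "kanto", 0.002),
        FounderVariant("BRCA2", "BRCA2_f001", "kinki", 0.008),
        FounderVariant("BRCA2", "BRCA2_f002", "kyushu", 0.003),
    )
    # lifetime (to 85) baseline risks with an adult-onset rising hazard
    # shape, roughly ordered like East Asian registry incidence
    # (common: gastric/colorectal/lung; rare: biliary); breast uses an
    # earlier onset floor and a large female-male asymmetry
    lifetime = {
        "biliary_tract": 0.010, "colorectal": 0.065, "esophageal": 0.013,
        "gastric": 0.060, "liver": 0.022, "lung": 0.045,
        "lymphoma": 0.010, "pancreatic": 0.012, "kidney": 0.008,
    }
    cancers = [CancerSpec(name, {s: adult_onset_hazard(f) for s in SEXES})
               for name, f in lifetime.items()]
    cancers += [
        CancerSpec("breast", {"female": adult_onset_hazard(0.07, onset_floor=25.0,
                                                           doubling_years=20.0),
                              "male": adult_onset_hazard(0.0005)}),
        CancerSpec("cervical", {"female": adult_onset_hazard(0.012, onset_floor=20.0,
                                                             doubling_years=30.0)},
                   sexes=("female",)),
        CancerSpec("endometrial", {"female": adult_onset_hazard(0.012)},
                   sexes=("female",)),
        CancerSpec("ovarian", {"female": adult_onset_hazard(0.010)},
                   sexes=("female",)),
        CancerSpec("prostate", {"male": adult_onset_hazard(0.095)},
                   sexes=("male",)),
    ]
    true_or = {
        ("BRCA1", "ovarian"): 17.0, ("BRCA1", "breast"): 10.0,
        ("BRCA1", "biliary_tract"): 10.0, ("BRCA1", "gastric"): 4.0,
        ("BRCA1", "pancreatic"): 8.0, ("BRCA1", "lymphoma"): 5.0,
        ("BRCA2", "breast"): 9.0, ("BRCA2", "ovarian"): 8.0,
        ("BRCA2", "gastric"): 4.0, ("BRCA2", "pancreatic"): 8.0,
        ("BRCA2", "prostate"): 4.0, ("BRCA2", "esophageal"): 5.0,
    }
    fh_rate = {"biliary_tract": 0.01, "colorectal": 0.07, "esophageal": 0.03,
               "gastric": 0.12, "liver": 0.05, "lung": 0.07, "lymphoma": 0.012,
               "pancreatic": 0.04, "kidney": 0.013, "breast": 0.06,
               "cervical": 0.015, "endometrial": 0.012, "ovarian": 0.02,
               "prostate": 0.04}
    return SimConfig(
        n_individuals=n_individuals, regions=regions, genes=genes,
        cancers=tuple(cancers), founder_variants=founders,
        background_rate={"BRCA1": 0.002, "BRCA2": 0.004},
        true_or=true_or, fh_background_rate=fh_rate,
        fh_carrier_multiplier=2.0, multi_primary_target=0.063,
        decoy_rate=0.03, seed=seed,
    ).validate()
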
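"""Dominant-model carrier collapsing and carrier-frequency summaries.

A variant call is a classified observation of one variant in one gene of
one individual, with classification in {P, LP, VUS, LB, B}.  Pathogenic
and likely pathogenic calls are pooled: under the dominant model an
individual is a carrier for a gene iff they have at least one P or LP
call in that gene, regardless of zygosity or how many qualifying
variants they carry.  Variant identifiers are opaque strings; no
nomenclature parsing is attempted, classification arrives as a label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sim import CLASSIFICATIONS, PATHOGENIC_CLASSES

__all__ = [
    "collapse_carriers",
    "carrier_frequency",
    "proportion_ci",
    "pathogenic_variant_fraction",
    "CarrierFrequency",
    "read_carrier_table",
    "read_variant_calls_vcf",
]

_SEVERITY = {c: i for i, c in enumerate(CLASSIFICATIONS)}  # P=0 most severe


def _validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    required = {"individual_id", "gene", "variant_id", "class"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"variant calls missing columns: {sorted(missing)}")
    bad = ~calls["class"].isin(CLASSIFICATIONS)
    if bad.any():
        row = calls.index[bad][0]
        raise ValueError(
            f"unknown classification {calls.loc[row, 'class']!r} at row {row}; "
            f"expected one of {CLASSIFICATIONS}")
    return calls


def collapse_carriers(calls: pd.DataFrame, genes: Sequence[str],
                      roster: Iterable[str] | None = None,
                      strict: bool = False) -> pd.DataFrame:
    """Collapse classified calls to per-gene dominant carrier status.

    Parameters
    ----------
    calls
        Variant-call table with columns ``individual_id, gene, variant_id,
        class`` (and optionally ``founder``).  Duplicate
        (individual, gene, variant) entries are deduplicated keeping the
        most severe classification (P > LP > VUS > LB > B).
    genes
        Genes to report flags for; calls in other genes are ignored.
    roster
        Full list of sequenced individuals.  Individuals on the roster with
        no calls are reported as noncarriers (everyone was sequenced); with
        ``strict=True`` they must appear in ``calls`` and an error is raised
        otherwise.

    Returns
    -------
    DataFrame with one row per individual: ``individual_id``, one boolean
    ``carrier_<gene>`` column and one ``variants_<gene>`` column holding the
    comma-joined qualifying variant ids per gene.
    """
    if not list(genes):
        raise ValueError("genes must be non-empty")
    calls = _validate_calls(calls)

    calls = calls.assign(_sev=calls["class"].map(_SEVERITY))
    calls = (calls.sort_values("_sev", kind="stable")
                  .drop_duplicates(["individual_id", "gene", "variant_id"], keep="first"))

    ids_in_calls = pd.Index(calls["individual_id"].unique())
    if roster is not None:
        roster = pd.Index(roster)
        if strict:
            absent = ids_in_calls.difference(roster).tolist() or None
            missing = roster.difference(ids_in_calls)
            if len(missing):
                raise ValueError(
                    f"strict mode: {len(missing)} roster individuals have no "
                    f"calls (first: {missing[0]!r}); expected explicit "
                    "wild-type rows")
            if absent:
                raise ValueError(f"calls for individuals not on roster: {absent[:5]}")
        index = roster.union(ids_in_calls, sort=False)
    else:
        index = ids_in_calls
    index = pd.Index(np.sort(np.asarray(index)), name="individual_id")

    out = pd.DataFrame(index=index)
    qual = calls[calls["class"].isin(PATHOGENIC_CLASSES)]
    for gene in genes:
        sub = qual[qual["gene"] == gene].sort_values("variant_id", kind="stable")
        vlists = sub.groupby("individual_id")["variant_id"].agg(",".join)
        out[f"carrier_{gene}"] = out.index.isin(vlists.index)
        out[f"variants_{gene}"] = vlists.reindex(index).fillna("")
    return out.reset_index()


def read_carrier_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    if "individual_id" not in df.columns:
        raise ValueError("carrier table missing column individual_id")
    for col in df.columns:
        if col.startswith("carrier_"):
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df


def read_variant_calls_vcf(path) -> pd.DataFrame:
    """Read the minimal VCF dialect written by the simulator back into the
    TSV call-table layout (individual_id, gene, variant_id, class, founder)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            gene = rec.info["GENE"]
            cls = rec.info["CLASS"]
            founder = int(bool(rec.info.get("FOUNDER", False)))
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt and any(a == 1 for a in gt if a is not None):
                    rows.append((s, gene, rec.id, cls, founder))
    return pd.DataFrame(rows, columns=["individual_id", "gene", "variant_id",
                                       "class", "founder"])


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CarrierFrequency:
    n_carriers: int
    n_total: int
    proportion: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return round(100.0 * self.proportion, 1)


def proportion_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval via the beta
    quantile representation."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def carrier_frequency(carrier_flags, alpha: float = 0.05) -> CarrierFrequency:
    """Carrier proportion with exact binomial CI for a group of individuals.

    ``carrier_flags`` is a boolean array-like: the ``carrier_<gene>`` column
    restricted to the group of interest (e.g. cases of one cancer type).
    """
    flags = np.asarray(carrier_flags, bool)
    n = flags.size
    if n == 0:
        raise ValueError("empty group")
    k = int(flags.sum())
    lo, hi = proportion_ci(k, n, alpha)
    return CarrierFrequency(k, n, k / n, lo, hi)


def pathogenic_variant_fraction(calls: pd.DataFrame) -> CarrierFrequency:
    """Fraction of *distinct* variants classified P or LP, with exact CI.

    Duplicated (gene, variant) rows count once; a variant observed with
    several classifications counts by its most severe one.
    """
    calls = _validate_calls(calls)
    sev = (calls.assign(_sev=calls["class"].map(_SEVERITY))
                .groupby(["gene", "variant_id"])["_sev"].min())
    flags = sev <= _SEVERITY["LP"]
    return carrier_frequency(flags.to_numpy())
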
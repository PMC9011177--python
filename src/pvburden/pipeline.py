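"""End-to-end orchestration: simulate -> collapse -> associate ->
heterogeneity -> penetrance -> report, as one reproducible run.

All stage outputs are pure functions of the configuration and seed;
machine-readable files are written unrounded, and a manifest captures
the configuration digest, seed, package version and SHA-256 digests of
every output file so that a run can be verified byte-for-byte.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .sim import SimConfig, simulate_cohort, simulate_incidence_table, write_table
from .carriers import collapse_carriers
from .burden import BURDEN_ALPHA, run_all_associations, age_at_diagnosis_shift
from .meta import heterogeneity_table, load_published_pairs
from .penetrance import risk_ci
from .enrichment import (regional_breakdown, regional_chisq, fh_profile,
                         fh_trend, summarize_cohort)

__all__ = ["run_pipeline", "published_pairs_report", "PipelineError"]

log = logging.getLogger("pvburden")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(outdir / "run.log")):
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)


def published_pairs_report(pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Heterogeneity report for the shipped (or a user-supplied) table of
    published gene-specific OR pairs, sorted by cancer."""
    if pairs is None:
        pairs = load_published_pairs()
    return heterogeneity_table(pairs)


def run_pipeline(config: SimConfig | str | Path, outdir: str | Path) -> dict:
    """Run every stage on a synthetic cohort and write all outputs under
    ``outdir``.  ``config`` is a :class:`SimConfig` or a path to its YAML
    form.  Returns the run manifest (also written as ``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)

    if not isinstance(config, SimConfig):
        path = Path(config)
        if not path.exists():
            raise PipelineError(f"config: file not found: {path}")
        config = SimConfig.from_yaml(path)
    config.validate()
    log.info("run starts: n=%d seed=%d digest=%s",
             config.n_individuals, config.seed, config.config_digest())

    stage = "simulate"
    try:
        cohort, calls, truth = simulate_cohort(config)
        incidence = simulate_incidence_table(config)
        write_table(cohort, outdir / "cohort.tsv")
        write_table(calls, outdir / "variant_calls.tsv")
        write_table(incidence, outdir / "incidence.tsv")

        stage = "collapse"
        carr = collapse_carriers(calls, config.genes,
                                 roster=cohort["individual_id"])
        write_table(carr, outdir / "carriers.tsv")
        log.info("collapse: %d carriers across %d genes",
                 int(carr[[f"carrier_{g}" for g in config.genes]].any(axis=1).sum()),
                 len(config.genes))

        stage = "associate"
        assoc = run_all_associations(cohort, carr,
                                     designs=("all_patients", "no_family_history"))
        write_table(assoc, outdir / "associations.tsv")
        shifts = []
        for _, row in assoc[(assoc["design"] == "no_family_history")
                            & ~assoc["gated"]].iterrows():
            shifts.append(age_at_diagnosis_shift(
                cohort, carr, row["gene"], row["cancer"], row["sex"]).__dict__)
        if shifts:
            write_table(pd.DataFrame(shifts), outdir / "age_shift.tsv")

        stage = "heterogeneity"
        ungated = assoc[(assoc["design"] == "no_family_history") & ~assoc["gated"]]
        pairs = ungated.rename(columns={"odds_ratio": "or", "ci_low": "lo",
                                        "ci_high": "hi"})
        pairs = pairs[pairs.groupby(["cancer", "sex"], dropna=False)["gene"]
                      .transform("nunique") >= 2]
        het = heterogeneity_table(pairs[["cancer", "gene", "or", "lo", "hi"]]) \
            if len(pairs) else pd.DataFrame()
        write_table(het, outdir / "heterogeneity.tsv")

        stage = "penetrance"
        risks = _penetrance_stage(config, cohort, carr, incidence, ungated)
        write_table(risks, outdir / "risk.tsv")

        stage = "report"
        report = {"summary": summarize_cohort(cohort, carr), "regional": {},
                  "fh_trend": {}}
        cases = cohort[cohort["status"] == "case"]
        assoc_cancers = sorted(set(ungated.loc[ungated["significant_burden"] == True,  # noqa: E712
                                               "cancer"])) or \
            [c.name for c in config.cancers[:1]]
        for gene in config.genes:
            chi2, dof, p = regional_chisq(cohort, carr, gene)
            chi2x, _, px = regional_chisq(cohort, carr, gene, calls=calls,
                                          exclude_founders=True)
            bd = regional_breakdown(cohort, carr, gene)
            report["regional"][gene] = {
                "chi2": chi2, "df": dof, "p": p,
                "chi2_excluding_founders": chi2x, "p_excluding_founders": px,
                "fold_difference": bd.attrs["fold_difference"]}
            profile = fh_profile(cases, assoc_cancers)
            tr = fh_trend(cases.merge(carr, on="individual_id", how="left")
                          [f"carrier_{gene}"].fillna(False).to_numpy(bool),
                          profile.to_numpy())
            report["fh_trend"][gene] = {"z": tr.z, "p": tr.p,
                                        "counts": [list(map(int, c)) for c in tr.counts]}
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": config.config_digest(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": {p.name: _digest(p) for p in sorted(outdir.iterdir())
                    if p.suffix in (".tsv", ".json") and p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %d output files", len(manifest["outputs"]))
    return manifest


def _penetrance_stage(config, cohort, carr, incidence, ungated) -> pd.DataFrame:
    """Cumulative risk to 85 for every significant, ungated gene-cancer
    association, with carrier frequency taken from controls."""
    from .burden import attach_carriers

    merged = attach_carriers(cohort, carr)
    controls = merged[merged["status"] == "control"]
    rows = []
    sig = ungated[(ungated["significant_burden"] == True)  # noqa: E712
                  & ungated["beta"].notna()]
    for _, row in sig.iterrows():
        gene, cancer = row["gene"], row["cancer"]
        spec = config.cancer(cancer)
        sexes = [row["sex"]] if row["sex"] else list(spec.sexes)
        for sex in sexes:
            inc = incidence[(incidence["cancer"] == cancer) & (incidence["sex"] == sex)]
            ctrl = controls[controls["sex"] == sex] if len(spec.sexes) == 1 or row["sex"] \
                else controls
            p_carrier = float(ctrl[f"carrier_{gene}"].mean())
            if not len(inc) or p_carrier >= 1.0:
                continue
            curve = risk_ci(row["beta"], row["se"], inc, p_carrier,
                            seed=config.seed)
            rows.append({
                "gene": gene, "cancer": cancer, "sex": sex,
                "carrier_freq_controls": p_carrier, "odds_ratio": row["odds_ratio"],
                "f_noncarrier_85": curve.f_n, "f_carrier_85": curve.f_c,
                "f_carrier_ci_low": curve.ci_normal[0],
                "f_carrier_ci_high": curve.ci_normal[1],
                "f_carrier_pct_low": curve.ci_percentile[0],
                "f_carrier_pct_high": curve.ci_percentile[1]})
    return pd.DataFrame(rows, columns=[
        "gene", "cancer", "sex", "carrier_freq_controls", "odds_ratio",
        "f_noncarrier_85", "f_carrier_85", "f_carrier_ci_low",
        "f_carrier_ci_high", "f_carrier_pct_low", "f_carrier_pct_high"])
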
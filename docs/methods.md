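# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the known limitations of
`pvburden`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Burden association model

Carrier status is dominant: an individual carries a gene's burden iff
they have ≥1 variant classified Pathogenic or Likely pathogenic in that
gene; the two classes are pooled and zygosity is ignored. VUS, Likely
benign and Benign calls never contribute. Duplicate calls for the same
(individual, gene, variant) are deduplicated keeping the most severe
classification (P > LP > VUS > LB > B) — conservative for carrier
assignment. Individuals on the sequencing roster with no calls are
noncarriers (everyone was sequenced); a `strict` mode instead requires
explicit wild-type rows. Carriers of pathogenic variants in both genes
count in both gene-specific analyses; they are identifiable in the
carrier table through the per-gene qualifying-variant lists.

The association model is a logistic regression of case status on
carrier status with age entered linearly in years — age at diagnosis
for cases, age at registration for controls; rows with missing age are
dropped. Fitting is by Newton/IRLS with step-halving; convergence when
the maximum absolute score falls below 1e-10 (with a relative
log-likelihood stall below 1e-10 accepted as a fallback verdict), at
most 100 iterations. Complete separation — an empty carrier-by-outcome
cell — is detected up front and flagged, never raised; non-convergence
likewise yields a flagged result without estimates. With no covariates
the fitted OR equals the 2×2 cross-product ratio to better than 1e-9
(verified against a direct likelihood optimiser in the tests). Tests
and CIs are Wald (`z = 1.959964`), matching the log-symmetric geometry
of published CI columns; likelihood-ratio or Firth corrections are out
of scope.

Two primary designs: `all_patients` reports the p-value only, because
controls screened to be free of personal *and family* history of cancer
bias risk estimates upward; `no_family_history` restricts cases to
patients reporting no family history and reports OR with CI. The case
filter defaults to family history of *any* cancer type (the stricter
reading; a `fh_scope="same"` flag restricts to the analysed type only —
the looser alternative is exposed because the source design is ambiguous
on this point). Controls need no filtering: they are family-history-free
by construction. Sensitivity designs: `region_adjusted` adds region as a
one-hot categorical covariate; `single_cancer_only` drops cases with
more than one primary cancer. Breast cancer is analysed separately by
sex; sex-restricted cancers automatically compare against same-sex
controls.

**Gating.** Any analysis with fewer than 3 carriers among cases or
among controls is suppressed: the result carries the counts and the
reason but no estimates. The "category" in the fewer-than-3 rule is
interpreted as carrier count within cases and within controls
separately; the gate reason string records both counts so the
interpretation is auditable.

Multiple testing: a Bonferroni-adjusted p (factor = number of non-gated
analyses per design) and the burden-test significance threshold
p < 1×10⁻⁴ are reported as separate labelled columns; neither silently
filters rows.

The age-at-diagnosis shift for carriers is the carrier coefficient of an
OLS regression of diagnosis age on carrier status among cases (95% CI
from the regression), with a Welch two-sample p-value alongside; the
same <3-carrier gate applies.

## Heterogeneity

Between-gene heterogeneity per cancer type is computed from the
published-style (OR, 95% CI) pairs alone. CI inversion uses
SE = (ln hi − ln lo)/(2z) with z = 1.959964 — the exact 97.5% normal
quantile, spelled out for determinism although the difference from 1.96
is below printed precision. With inverse-variance weights wᵢ = 1/SEᵢ²:
Q = Σwᵢ(θᵢ − θ̄)², df = k−1, p from the upper central χ² tail,
I² = max(0, (Q−df)/Q)·100 reported to one decimal and floored at zero,
τ² by DerSimonian-Laird floored at zero, and the random-effects pooled
estimate with weights 1/(SEᵢ² + τ²). No small-k corrections are applied
(k = 2 throughout the gene-pair use case). The implementation is
cross-checked in the tests against frozen reference values from an
independent meta-analysis package (R metafor, method "DL").

**Precision limit of printed inputs.** Recomputing I² from ORs printed
to one decimal place is exact for pairs whose effects are well away
from 1, but an OR printed as 1.1 with a CI bound of 0.3 carries roughly
one significant figure; for such pairs the recomputed I² can sit a few
percentage points from the value computed from unrounded estimates.
This is a property of the rounded inputs, not of the formulas, and the
affected fixture rows are annotated with the published values for
comparison.

## Penetrance

The hazard-partition estimator treats the fitted OR as a relative risk
(rare-disease assumption; carrier frequencies here are ≤ a few percent)
and as constant across age bands — age-specific ORs are not estimable
from a single registration-based case-control pass. Population
incidence per (cancer, sex, 5-year band) is split exactly:

    λ_n(t) = λ_pop(t) / (1 + p·(RR − 1)),   λ_c(t) = RR·λ_n(t)

so the carrier-frequency mixture identity p·λ_c + (1−p)·λ_n = λ_pop
holds to machine precision per band. The carrier frequency p defaults to
the control-group estimate (family-history-free controls), and is
configurable. Cumulative risk is piecewise exponential,
F(a) = 1 − Π exp(−λ·Δt) over bands ending by a (85 by default; band
width configurable). Competing mortality is deliberately ignored — the
output is a cumulative incidence to 85, flagged as such in the curve
metadata.

The 95% CI for the terminal risks propagates log-OR uncertainty by
simulation: 10 000 draws from Normal(β, SE²), each pushed through the
partition; the reported interval is the *normal approximation on the
risk scale* (point estimate ± 1.959964 × SD of draws). That choice can
produce negative lower bounds for small risks with wide CIs — published
penetrance intervals show exactly this signature, which rules out
percentile or logit constructions as the primary interval; a percentile
interval is emitted alongside for comparison. Absolute published risk
figures are not reproduction targets: they are functions of national
age-specific incidence tables (external data), so this module's
validation is property-based — conservation, monotonicity in RR,
round-trip recovery of the generative baseline hazard, and end-to-end
recovery of the generative carrier risk on synthetic cohorts.

## Enrichment statistics

Regional heterogeneity is a Pearson χ² (no continuity correction) on
the regions × {carrier, noncarrier} table, computed per gene on carrier
status (not variant counts — the plausible alternative reading).
With founder exclusion, individuals whose only qualifying variants are
founder-flagged are recounted as noncarriers, isolating founder-driven
structure from residual regional differences. A degenerate table (no
carriers at all) returns χ² = 0, p = 1. The family-history trend is the
standard Cochran-Armitage statistic on the 2×3 table with fixed scores
0/1/2 for none/1/≥2 associated cancer types reported in relatives
(two-sided normal p; alternative scores deliberately not exposed),
verified against exact conditional enumeration in the tests.
Family-history cross-tabulation uses Fisher's exact test per
(case-cancer, family-history-cancer) cell with Bonferroni correction
across the full grid. Family history pools first- and second-degree
relatives as a single flag — the cohort format does not distinguish
degree.

## Synthetic cohorts

The generator emulates the structure of a nationwide hospital-registry
case-control resource: per individual it draws sex, region (weighted
categorical over 7 regions in the demonstration configuration) and
registration age; carrier status per gene as the union of
region-confined founder variants and region-independent background
variants; cancer onsets from discrete per-band hazards (survive a band
with exp(−λ·width); given an event, a geometric year within the band),
with the carrier hazard equal to RR × baseline and multiplicative
combination across genes; and marginal Bernoulli family-history flags,
enriched among carriers by a configurable multiplier. An onset is
observed only if it precedes registration; individuals with no observed
cancer and no family-history flag form the control pool, mirroring the
control definition of such registries. Benign/VUS decoy calls are
injected and must never confer carrier status. A single seeded NumPy
generator drives the whole run; outputs are bit-identical for identical
(config, seed).

Hazard shapes in the demonstration configuration are adult-onset:
zero before an onset floor (30 years by default), then doubling every
decade, scaled to a specified lifetime (to-85) risk — the registry-like
alternative to a constant hazard, which would produce childhood onsets
and an unrealistically wide gap between case diagnosis ages and control
registration ages. Registration age defaults to a truncated normal
(mean 60, SD 13, bounds 20–90) and is configurable because the source
design does not pin it down.

Two structural realism mechanisms deserve note because they interact
with estimation:

* **Multiple primaries.** Independent per-cancer onsets underproduce
  patients with ≥2 cancer types, so the generator tops up to the
  configured multi-primary fraction by promoting randomly chosen
  single-cancer patients with a second, carrier-independent primary.
  The promoted cases slightly dilute the OR of the receiving cancer
  type; estimator-calibration configurations therefore use a single
  cancer type, where the mechanism is inert.
* **Control selection.** Because carriers report family history more
  often (multiplier > 1) and controls must be family-history-free,
  carriers are depleted from the control pool — reproducing the risk
  overestimation that motivates withholding estimates in the
  all-patients design. Null-calibration configurations set the
  multiplier to 1 so that the null is genuinely null.

What the generator does **not** emulate: linkage disequilibrium and
haplotypes, pedigree structure (family history is marginal, not
transmitted), sequencing error, somatic variation, competing mortality,
and secular or regional trends in incidence. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to these real-data features.

## Experiment sizes and conditions

The simulation experiments in the test suite use conditions chosen to
keep expected carrier-case counts in the tens, comparable to the
common-cancer strata of a large biobank, at tractable problem sizes:

* Type-I calibration: one gene at 2% carrier frequency, a composite
  common endpoint with 50% lifetime baseline risk, true RR = 1,
  n = 20 000 per run, 500 seeds.
* Wald CI coverage: 1.5% carrier frequency, 4.5% lifetime baseline
  risk, true RR = 10, n = 20 000 per run, 500 seeds.
* End-to-end penetrance recovery: 0.4% carrier frequency, 4.5% lifetime
  baseline risk, true RR = 11, n = 100 000 per run, 100 seeds; the
  estimated OR and the control-group carrier frequency are pushed
  through the hazard partition and compared against the generative
  carrier cumulative risk.

## Known limitations

* OR-as-RR breaks down for genuinely common outcomes; the partition is
  then an approximation and the carrier risk is overstated.
* Wald inference is first-order; with carrier counts near the gate
  threshold the CI undercovers slightly.
* The normal-approximation risk CI is honest about its negative lower
  bounds; consumers wanting a bounded interval should use the
  percentile interval that is always emitted alongside.
* Variant classification is consumed as a label; the classification
  criteria themselves, structural variants, and histological-subtype
  analyses are out of scope.
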
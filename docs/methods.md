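# Methods

## Model and assumptions

A DRI value is a hazard-quotient-style ratio: the pesticide intake from one
serving of food divided by the maximum acceptable chronic daily intake for
that pesticide.  With the acceptable intake expressed as a chronic reference
dose cRfD (mg per kg body weight per day), body weight BW (kg) and serving
mass Serv (g), the reference concentration in food is
cRfC = (cRfD × BW) / Serv, in ppm (mg pesticide per kg food).  The three
scores are DRI-M = Mean/cRfC (mean of positives), FS-DRI = DRI-M × NP/N
(all-samples average), and the single-sample DRI = concentration/cRfC.
Because all three are ratios of concentrations, they are dimensionless,
additive across independent contributions, linear in concentrations, and
inverse-linear in the dose limit.  The package treats those four properties
as testable invariants rather than documentation.

Assumptions inherited from the scoring model:

- **Chronic, deterministic, single-serving.**  Risk is indexed by annual
  mean residues against a chronic threshold.  No probabilistic (Monte
  Carlo) exposure assessment, no acute percentile-consumption modelling, no
  consumption-survey weighting.
- **Additivity across pesticides** in aggregate and per-sample scores is a
  bookkeeping convention, not a common-mechanism cumulative risk assessment.
- **Positives are quantifiable residues**: concentration ≥ LOQ.  Trace
  values between LOD and LOQ are non-detects.  Non-detects contribute to
  FS-DRI only through the NP/N factor; no LOQ/2 imputation is performed (an
  imputation mode is deliberately out of scope).
- **Thresholds are point values.**  A published cPAD or cADI is entered as
  `crfd` with `fqpa_factor = 1`; an FQPA factor > 1 divides the effective
  limit.  One arithmetic path, two entry styles.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| body weight | 16 | kg | ~4-year-old child, 50th percentile growth charts; children eat less diverse diets and more food per body weight |
| serving | 2/3 × RACC | g | child serving as a fraction of the general-population Reference Amount Customarily Consumed |
| positive cut-off | LOQ | ppm | both monitoring programs report quantifiable residues |
| Rule-of-10 floor | 10 | samples | combinations with N < 10 are dropped when the rule is invoked; N = 10 is retained |
| risk zones (DRI-M) | 0.01 / 0.1 | — | deminimus below 0.01; possibly significant above 0.1; boundaries closed on the left, and exactly 0.1 stays in the moderate zone |
| level of concern (sample DRI) | 1 | — | one serving delivering a full acceptable daily intake |
| concentration unit | ppm (mg/kg) | — | readers convert µg/kg files via a dialect flag |

Both body weight and serving are overridable per food so subpopulation DRI
values can be computed.

## Data handling conventions

- **N is per food × analyte**, not per food: lab panels differ, so analyte
  rows within one food may carry different N (the 1996 peach table has
  N = 168 for phosmet against 198 for most analytes).  Absence of a
  determination means "not analyzed" and is excluded from N; non-detects
  must be explicit zero-concentration rows carrying their LOQ.
- **UK quarterly files** are combined by calendar year of sampling.  The
  crop-year/test-year mismatch for stored crops is unresolvable from the
  files and no correction is attempted; a year covered by fewer than four
  quarters gets a low-coverage warning.
- **Nomenclature maps** are user-supplied tables.  Metabolites and moieties
  mapped to one canonical analyte within a sample are combined as a
  weighted sum of concentrations (default weight 1); the combined LOQ is
  the minimum of the component LOQs.  Unmapped analyte labels are excluded
  from DRI computation and enumerated in the ingest report; unmapped food
  labels are kept under their source label and enumerated.  Mapping is
  idempotent and merges measurements, never samples.
- **"Conventional" = every sample whose claim is not organic**, so IPM and
  pesticide-free samples fall in the conventional set.
- **Banned organochlorines** (DDT group including DDE/DDD, aldrin,
  dieldrin, heptachlor and its epoxide, chlordane, mirex, toxaphene) can be
  excluded as a selection switch; endosulfan and methoxychlor remain in
  use and are never on the default list.  The list is a configurable set
  keyed on canonical analyte ids.
- **Rule-of-10 granularity** is the food × form × analyte combination
  within the selection's origin/claim stratum — per food form, the more
  conservative reading when a food has multiple forms.  Because the rule
  conditions only on counts, applying it before or after summarisation is
  equivalent (tested).

## Reports

Rows are ranked by FS-DRI descending with deterministic tie-breaking
(descending DRI-M, then lexicographic label) so reruns are byte-identical.
Percent shares are computed from unrounded values; summary rows equal
column sums at full float precision; rounding (3 significant figures,
half-up; 1-decimal percents) happens only at rendering, with a
full-precision mode for pipelines.  Two summary conventions follow the
published layouts: food reports print the *average* per-analyte N and
residues-per-sample = positives / average N; pesticide reports print the
*total* sample count and divide by it.  The by-food-group report mirrors
the all-foods layout grouped by a food-group column.  Stratum comparisons
(domestic vs imported, conventional vs organic) emit two totals rows plus
an elementwise ratio row; a ratio element is absent, with a warning, when
its denominator is zero.

## Printed-table fixtures and the reconciliation rule

The packaged fixtures transcribe published report tables (N, NP, mean,
cRfC, serving per row) so the full report path can be tested on real
numbers without agency archives.  A few printed cRfC cells contradict the
same row's printed DRI-M (e.g. a cRfC printed for a neighbouring serving
size).  Since the DRI-M column is the system's own computed output, the
fixture constructor treats it as authoritative: when the printed DRI-M is
not the half-up rounding of mean/cRfC at the DRI-M's printed significant
digits, the effective cRfC is back-computed as mean/DRI-M; otherwise the
printed cRfC is used at full precision.  The rule is mechanical and
uniform.  With it, every tested aggregate lands on the printed value at
printed precision; remaining one-ulp drifts (the peach aggregate DRI-M) are
propagation of the source's own per-row rounding, and quantities whose raw
samples were never published are held to a 2% envelope instead of printed
precision.

## Synthetic data

The generator emulates the statistical structure of monitoring data: per
food × analyte × stratum, a Bernoulli detection with probability %P and a
positive-concentration model.  Positives are lognormal by default — heavy
right tails with p99 up to ~11× the mean are the lognormal signature in
the published distribution tables — with log-sd defaulting to 0.8, the
middle of the 0.6–1.0 range that reproduces published p95/mean ratios of
~2.5–4; a fixed-list mode exists for exact tests.  The default scenario
uses ~300 samples per food (the US program's typical panel), detection
frequencies of 5–60% and mean concentrations taken from published
food–pesticide combinations.  Draws below the LOQ are clipped up to it so a
drawn positive stays a positive; the default LOQ of 1e-4 ppm makes this a
< 10⁻¹² probability event at default parameters.  The generator does not
model lab measurement error, between-lab LOQ heterogeneity, or censoring
beyond the LOQ rule — so passing tests demonstrate pipeline correctness on
idealised data, not robustness to real-world lab artefacts.  Every run is
reproducible from its seed and returns a manifest of realised counts and
closed-form moments; the test suite checks the generate → write → read →
summarize loop against the manifest exactly, and parameter recovery at
n = 10,000 within 3 Monte-Carlo standard errors.

## Numerical choices

- Percentiles use linear interpolation between order statistics, validated
  against a brute-force sort-based oracle (the published percentile method
  is unstated and its values are not reproducible without raw sample
  lists, so the estimator is oracle-validated rather than table-validated).
- All internal arithmetic is double precision; %P is always computed from
  counts, never from a rounded percentage — the published tables only check
  out under this convention.
- Exceedance fractions carry a Wilson score interval.
- Degenerate inputs fail loudly: non-positive doses, servings or body
  weights, duplicate (sample, analyte) determinations, quarters outside
  1–4, and summaries whose mean is present without positives (or absent
  with them) all raise typed errors; summaries with zero positives are
  omitted from reports and counted in diagnostics, as are analytes without
  thresholds.

## Known limitations

- Scores are only as good as the thresholds: cRfD/cADI values are single
  no-adverse-effect point estimates and carry no endpoint diversity.
- Composite samples blend produce from multiple fields, so per-sample
  residue counts overstate what any single farm applied.
- The by-food-group report requires a food-group mapping the user supplies;
  no canonical food taxonomy is bundled.
- Printed-table fixtures inherit the source tables' rounding; aggregates
  recomputed from them can differ from the printed bottom rows by about one
  unit in the last printed digit.
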
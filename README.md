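# dietrisk

Chronic pesticide dietary-risk scoring from residue-monitoring data.

Government residue-monitoring programs — the US Pesticide Data Program
(US-PDP) and the UK Food Standards Agency (UK-FSA) program — publish, for
every tested food and pesticide, the number of samples tested (N), the
number with a quantifiable residue (NP), and the mean concentration of the
positive samples.  `dietrisk` turns those summaries (or the underlying
sample-level files) into Dietary Risk Index (DRI) scores that are comparable
across foods, pesticides, years, countries of origin and production systems,
and emits the system's ranked report family and risk-distribution analyses.
It is written for exposure scientists, food-policy analysts and anyone who
wants to rank food–pesticide combinations by measured chronic dietary risk
rather than by tolerance levels.

## The model

For a pesticide with chronic reference dose cRfD (mg per kg body weight per
day; divided by an FQPA children's safety factor when one applies, giving
the cPAD), a consumer of body weight BW eating a serving of mass Serv can
tolerate a residue concentration of

```
cRfC = (cRfD × BW) / Serv        [ppm]
```

— the *chronic reference concentration*: one serving at exactly cRfC
delivers exactly the acceptable daily intake.  Three dimensionless ratios
follow:

```
DRI-M      = Mean / cRfC                 mean of positive samples
FS-DRI     = DRI-M × %P                  all-samples (food-supply) average
sample DRI = concentration / cRfC        one sample, one analyte
```

where %P = NP/N is the exact positive fraction.  Values are additive: across
pesticides within a food, across foods for a pesticide, across everything
tested in a year, and across the residues in a single sample.  A sample DRI
of 1 marks the regulatory "level of concern".  Defaults follow the published
analyses: a 16-kg child and servings of 2/3 of the general-population RACC,
both overridable for subpopulation analyses.

Selection criteria reproduce the system's report variants: seven
country-of-origin options, three market-claim options (conventional = all
non-organic), the Rule of 10 (combinations with fewer than 10 tested samples
are ignored), and optional exclusion of long-banned organochlorines.  Four
origin options apply to US data and six to UK data, so with 8 standard
report kinds the variant matrix is 8 × 4 × 3 × 4 + 8 × 6 × 3 × 4 = 960
reports.

## Worked example

Rebuild the 1996 US-grown conventional peach report from its published
inputs and inspect the leading rows:

```python
import dietrisk as dr

table = dr.table_fixtures()["peaches_1996"]   # printed N/NP/mean/cRfC inputs
report = table.report()                        # ranked food report
print(report.rounded().head(5).to_string(index=False))
```

```
      analyte_id   n  np  mean_ppm  crfc_ppm  dri_m  fs_dri  pct_fs_dri
parathion-methyl 198  82    0.0562     0.032 1.7600  0.7270        69.5
       iprodione 198 155    0.9230     8.000 0.1150  0.0903         8.6
         phosmet 168  53    0.2170     0.960 0.2260  0.0713         6.8
        dicloran 198 102    0.3940     4.000 0.0986  0.0508         4.9
        carbaryl 198  32    0.4120     1.600 0.2570  0.0416         4.0
```

Methyl parathion was found in 82 of 198 samples at a mean of 0.0562 ppm
against a cRfC of 0.032 ppm, so the average *positive* peach carried 1.76
acceptable daily intakes per serving (DRI-M), the average peach overall
0.727 (FS-DRI) — 69.5% of that year's aggregate peach risk.  The summary
row gives the aggregates across all 23 detected pesticides:

```python
print(report.summary)
# aggregate_dri_m 4.09..., aggregate_fs_dri 1.046..., total_positives 591,
# residues_per_sample 3.03..., n_analytes 23
```

The same machinery runs on raw sample files.  A synthetic monitoring year
end to end from the shell:

```
dri simulate --seed 9 --out-dir data/
dri report data/samples_pdp.csv --kind 5 \
    --thresholds thresholds.csv --servings servings.csv --out-dir out/
dri variants --program us_pdp        # the 48 US selection variants
```

Risk-zone language follows the published continuum: DRI-M below 0.01 is
deminimus, above 0.1 possibly significant
(`dr.classify_risk(0.005)` → `"deminimus"`), and
`dr.classify_risk(15.6, basis="sample")` flags a sample past the level of
concern.

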
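# Methods

## System and design

The package models a dark, 25 deg C jar incubation of a calcareous silty
loam (8.9 g/kg SOC, pH 7.9) developed under long-term C4 (maize) cropping,
amended in a 2 x 2 factorial: wheat straw at 0 or 10 g per kg dry soil and
wood ash at 0 or 12 g per kg, three replicate jars of 0.25 kg soil per
treatment, uniform mineral fertilization (159 mg N, 185 mg P2O5 per kg).
Respired CO2 is captured in NaOH traps exchanged on days
2, 3, 4, 5, 7, 10, 15, 20, 25, 35, 45, 65, 95 and 118; destructive pool
measurements and 16S profiling happen once, at day 118.

## Isotope partition model

Two-end-member linear mixing on the VPDB delta-13C scale:

    f_new = (d_a - d_b) / (d_m - d_b)

with `d_a` the carbonate-free bulk SOC delta-13C after incubation, `d_b`
the baseline soil signature (-19.5 permil) and `d_m` the amendment
signature. Assumptions, and the choices made where the procedure was
genuinely open:

* The delta of a two-pool mixture is the C-mass-weighted arithmetic mean
  of the pool deltas — the standard small-delta linearization; no Suess or
  concentration-dependent correction is applied.
* No isotopic fractionation during decomposition: the amendment-derived C
  remaining in soil is assumed to keep the amendment's signature.
* For the straw+ash treatment, `d_m` mixes straw (-27.5 permil, 456.1 g
  organic C per kg) and ash (-26.4 permil, 3.2 g organic C per kg) weighted
  by dose x organic-C content; ash carbonate C (432 mg C per kg soil at the
  12 g/kg dose) is inorganic and excluded from the organic mixing pool.
  At the study doses the ash contributes under 1% of amendment C, so
  `d_m(SW) = -27.49` permil, barely distinguishable from straw alone.
* The baseline `d_b` is the bulk pre-incubation soil value; whether a
  carbonate-free baseline would differ is unknowable from the available
  description, and the parameter is configurable (`EndMembers.delta_soc_b`).
* `SOC_b` in the sequestration difference defaults to the pre-incubation
  soil (8.9 g/kg), not the post-incubation control, and is configurable —
  the two conventions differ by the control's own drift.
* `f_new` outside [0, 1] (possible with noisy deltas) is returned raw with
  a warning; it is clamped only where mass accounting requires a physical
  fraction, never silently.

The bookkeeping identities `newly = f_new * SOC_a`,
`sequestered = SOC_a - SOC_b`, `native mineralized = newly - sequestered`
hold exactly by construction; the test suite asserts the conservation
identity and the closed-form round trip (mix at f*, invert, recover f* to
1e-12).

## Trap stoichiometry

The alkali-trap calculation is the classical one: CO2 + 2 NaOH -> Na2CO3,
BaCl2 precipitates the carbonate, back-titration with HCl against a
soil-free blank gives Delta mol HCl, and mol CO2 = Delta mol HCl / 2;
12 g/mol converts to carbon mass, normalized per kg dry soil. Because the
trap is continuous between exchanges, cumulative mineralization is the
plain running sum of interval values; the first record covers day 0 to the
first exchange and no interpolation is ever applied. A sample titration
volume exceeding the blank is physically impossible and raises.

## Pool arithmetic

* MBC = (extractable C fumigated - unfumigated) / kEC with kEC = 0.45, the
  conventional fumigation-extraction efficiency (configurable; a negative
  flush warns rather than raises, since swapped extracts are a real
  bench error worth surfacing).
* Net newly formed SIC = 1000 x (SIC_ashed - SIC_reference) - ash-carbonate
  input, in mg C per kg; negative values mean net carbonate dissolution.
* Percent changes are plain 100 x (treated - reference)/reference on
  treatment means; group contrasts compare group means the same way.

## Statistics

Two complementary views of the balanced 2 x 2 x 3 design, because the
report format uses both: a two-way ANOVA with interaction (fitted by OLS
via statsmodels; the test suite cross-checks it against an explicit
sum-of-squares decomposition) for the factor p-value columns, and a
one-way ANOVA across the four cells whose mean square error feeds Fisher's
protected LSD, LSD = t(1-alpha/2, df_err) sqrt(2 MSE / n). Letters are
assigned from the largest mean downward; since the
"not-significantly-different" relation is a threshold on ordered means,
the maximal letter groups are exactly the maximal runs of consecutive
means spanning no more than the LSD (ties broken by declaration order).
If the omnibus F is not significant, every treatment shares "a" —
"protected" means no pairwise comparisons are attempted. A constant
response is reported as F = 0, p = 1 (no evidence of effects) rather than
the numerically meaningless 0/0.

Pearson correlation matrices use the exact t transform for two-tailed
p-values, flagged at 0.05 and 0.01. No multiple-testing correction is
applied across the many pairs — deliberate, to match how such summary
tables are conventionally reported; treat individual flags accordingly.

Calibration: under a 2,000-run null simulation (iid Gaussian response,
fixed seed) each effect's rejection rate at alpha = 0.05 must land in
[0.04, 0.06], roughly a two-binomial-SE band around the nominal level.

## Diversity estimators

Shannon entropy uses log base 2 (bits), the convention of the QIIME2 alpha
stack this emulates (configurable to any base). Chao1 uses the
bias-corrected form S_obs + F1(F1-1)/(2(F2+1)), finite even with no
doubletons; Good's coverage is 1 - F1/N. All three are computed on raw
integer counts — no rarefaction by default, because none is part of the
emulated workflow; an even-depth subsampler with an explicit seed exists
for sensitivity analysis. Venn regions use presence = summed count > 0
over a group's replicates. "ASV" and "OTU" tables are treated as the same
abstraction. Estimator implementations are delegated to scikit-bio; the
tests pin them to hand-computed toy values.

## Synthetic generator

The generator exists so the full chain has ground truth. What it emulates,
and its defaults:

* **Pool means** default to the study's day-118 treatment means (e.g. MBC
  180/205/364/438 mg/kg for Control/W/S/SW), with MBC realized as
  fumigated/unfumigated extract pairs (unfumigated 160 mg/kg, flush =
  0.45 x target) so the fumigation arithmetic is exercised, not bypassed.
* **Measurement noise** is iid Gaussian per variable; default SDs are the
  study's reported standard errors scaled by sqrt(3) (SE -> SD at n = 3),
  averaged over treatments. These are derived, not author-stated, values.
  delta-13C noise defaults to 0.1 permil, a typical IRMS repeatability.
* **delta-13C** per sample is the exact linear mixture at a configurable
  `true_fraction_new` (defaults 0.25 for S, 0.267 for SW, chosen once so
  newly formed SOC is ~2.4 and ~2.6 g C/kg — the observed ~9% relative
  increase under added ash — at the study SOC levels).
* **CO2 kinetics** follow a two-pool first-order decay (fast fraction
  0.45, k_fast 0.25/d, k_slow 0.05/d) — a generator convenience, not an
  inference target, since the accounting layer never fits kinetics. Totals
  of 900/700/5000/4700 mg C/kg make day-118 cumulative values land on the
  study's 0.9/0.7/5.0/4.7 g/kg (the decay is >99% complete by day 118).
  Interval noise is truncated at zero, so traps never titrate impossibly.
* **Community counts** are Dirichlet-multinomial (concentration 200,
  depth 20,000) around phylum-structured profiles: Proteobacteria
  dominant everywhere, Bacteroidetes/Actinobacteriota tilted up under ash,
  Acidobacteriota up under straw alone, Firmicutes up in the control —
  the qualitative pattern reported for these soils.

What it does **not** emulate: temporal pool dynamics (pools are generated
only at day 118), spatial or temperature structure, correlated measurement
errors across variables, priming feedbacks between straw and native SOC
(the generated delta and SOC values are independent draws), compositional
read-depth artifacts beyond multinomial sampling, and sequence-level
features (no FASTQ). Passing tests therefore demonstrate that the
*accounting* is correct and calibrated under the stated error model — not
that the error model captures every feature of real incubation data.

All stochastic draws flow from a single `numpy.random.Generator` seeded by
one integer: identical seeds give bit-identical datasets, and the
end-to-end pipeline is a pure function of config + seed.

## Numerical choices and degenerate inputs

* Equal amendment and baseline deltas make the mixing model singular and
  raise; zero amendment organic C likewise.
* Constant ANOVA responses short-circuit to F = 0, p = 1; zero-variance
  variables are rejected from correlation matrices by name.
* LSD letters require balanced replication (the design of interest always
  is; unbalanced data would need a different standard error per pair).
* Validation errors name the offending file and column; the CLI maps
  validation, I/O and numerical failures to exit codes 2, 3 and 4.

## Problem sizes

The test suite and the acceptance script use: 1,000-draw round-trip and
stoichiometry oracle checks, 500 noisy-recovery simulations at n = 3,
2,000 null ANOVA runs, and single synthetic datasets of 168 titration
records, 12 pool/delta samples and a 12 x ~120 ASV table — sizes chosen to
estimate the stochastic quantities to well inside their acceptance bands
while keeping a full run in tens of seconds.
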
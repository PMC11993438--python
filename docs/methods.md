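# Methods

## Statistical model

The pipeline performs frequentist disproportionality analysis on
spontaneous adverse-event reports.  Reports carry a suspected drug, a set of
MedDRA-style preferred terms (PTs), demographic fields and FAERS seriousness
outcome codes.  For an index drug g and event category k, reports (or term
occurrences) are cross-classified against a *within-class comparator* — the
pooled other drugs of the same class, not the whole database — giving cell
counts a (index, in category), b (index, other), c (comparator, in
category), d (comparator, other).

Estimators:

- ROR = (a·d)/(b·c); 95% CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )
  (Woolf variance of the log odds ratio).
- PRR = [a/(a+b)] / [c/(c+d)]; 95% CI =
  exp( ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)) ).
- Pearson chi-square with 1 df: n(ad − bc)²/((a+b)(c+d)(a+c)(b+d)); Yates
  continuity correction available but off by default; p-value from the
  chi-square survival function.

Signal rules, applied verbatim: the count criterion a ≥ 3 gates everything;
the ROR rule additionally requires the lower 95% bound to exceed 1; the PRR
rule requires the point estimate to be ≥ 2 (no chi-square clause — the
classic Evans criterion's chi² ≥ 4 is deliberately not added).  Flags mark
reporting disproportion, a hypothesis-generating device; spontaneous data
support no causal or incidence claims.

Assumptions worth keeping in mind: cells are treated as independent counts
(no within-case correlation model); a report may contribute to several
category tables (the multi-category question is resolved permissively); no
stratification, adjustment or multiplicity correction is applied.

## Conventions and numerical choices

- **Counting unit** defaults to `event` (PT occurrences); `report` counts
  each report at most once per category.  Back-calculation from published
  within-class analyses of this drug class shows report-level denominators
  are inconsistent with the printed ratio tables, so event-level is the
  presumed convention; both are supported and the unit is recorded in every
  output row and the run manifest.
- **Zero cells**: estimates are returned as undefined (`defined=False`,
  NaN fields) rather than corrected; the Haldane–Anscombe +0.5 correction is
  available by flag.  Undefinedness is a value, not an error, so downstream
  tables always render.
- **CI level** is fixed at 95% (z = 1.96) and not configurable, to avoid
  silent divergence from the published convention.
- **Rounding**: percentages half-up to 2 decimals, ratio estimates to 4
  decimals in rendered tables; full precision is kept internally.
  Percentages are computed in exact decimal arithmetic from integer counts
  before quantizing, so printed values are reproducible from printed counts.
- **Deduplication** keeps the highest case version, ties broken by latest
  file order (the FAERS caseversion convention); drug-name resolution runs
  first so a case reported under brand and generic names collapses to one
  record.  Records naming two or more distinct study drugs are excluded and
  counted — the within-class comparator is undefined for them.
- **Windowing** is inclusive on both calendar-year bounds; the year is taken
  from the DEMO-style table's year field.
- **Term matching** is exact on normalized case/whitespace, never substring,
  to avoid PT collisions; the PT → category mapping is configuration (YAML),
  with a small documented stand-in dictionary shipped for simulation and
  testing.  Arthralgia is a separate single-term category, disjoint from
  musculoskeletal, mirroring how this drug class's safety tables report it.

## Synthetic-data generator

The generator emulates the *structure* of FAERS-like data with exactly known
statistics.  Per drug it draws: sex from a categorical mix; age from a
normal truncated to [18, 100] years (an adult rheumatoid-arthritis cohort);
receipt year uniform over the study window; category mentions as independent
Bernoulli draws; one uniformly chosen preferred term per mentioned category;
outcome codes as independent Bernoulli draws per code.  A configured
fraction of cases is re-emitted as follow-up versions (version + 1, same
case id and drug, perturbed age) to exercise deduplication.

Effects act on odds: with base rate p and multiplier m the mention
probability becomes p′ = m·p/(1 − p + m·p), so odds(p′)/odds(p) = m exactly
and a two-arm design with a null comparator has true ROR = m.  This is the
recovery oracle used throughout the tests.  Note that in a three-drug
within-class analysis the comparator pool carries its own multipliers, so
configured per-drug multipliers map to within-class RORs only qualitatively.

Defaults are the study conditions of the JAK-inhibitor comparison: report
volumes 227,144 / 9,305 / 37,208 down-sampled 100-fold (tofacitinib /
baricitinib / upadacitinib); sex mixes (75.68 / 18.04 / 6.28)%,
(62.34 / 30.95 / 6.71)%, (72.46 / 22.19 / 5.35)% (female/male/unknown); ages
57.5 (6.15), 60.14 (2.96), 58.5 (1.31) years (mean, SD); window 2012–2022;
outcome-code rates derived from the published outcome counts (e.g.
hospitalization 0.121, death 0.042); default odds multipliers set to the
published within-class RORs; duplicate fraction 0.05.  Category base rates
(cardiovascular 0.05, cancer 0.04, respiratory 0.08, gastrointestinal 0.07,
musculoskeletal 0.35, arthralgia 0.10) are plausible invented plumbing — the
published analysis does not report per-category baselines.

What the generator does **not** emulate: reporting latency and the Weber
effect, stimulated reporting around label changes, drug–drug interaction
reports, within-report term correlation, indication-based selection, or
free-text drug-name noise beyond brand/generic synonyms.  Passing tests
therefore demonstrate correctness of the computation and calibration of the
statistics under idealized reporting — not robustness to the biases of real
spontaneous data.

## Validation design and problem sizes

- Estimator correctness: 1,000 random tables (cells 1–500) against an
  independent brute-force arithmetic oracle, agreement to 12 significant
  digits; worked small-table examples frozen by hand arithmetic.
- Interval calibration: 5,000 independent-row tables (n = 200, p = 0.1);
  the ROR interval covers the null in 93–97% of replicates.
- Effect recovery: odds multipliers {0.5, 2, 4} at 10⁵ reports per arm,
  100 replicate seeds each; the 95% interval contains the truth in ≥ 90
  replicates (observed ~91–95%; the Woolf interval is mildly
  anti-conservative).
- Null calibration: 1,000 three-drug datasets (500 reports per drug, six
  categories, all multipliers 1); per-pair ROR-signal rate ~2.5–2.9%
  against the 7.5% bound (nominal one-sided 2.5%).
- Round trips: both I/O dialects write-then-read to equal records;
  duplicate injection followed by deduplication recovers the original
  case-id set across 100 random configurations; pipeline reruns are
  byte-identical for a fixed config and seed.

## Known limitations

- Exact reproduction of a published ratio table requires the original PT →
  category dictionary and full extract; with the stand-in dictionary the
  pipeline reproduces table *shapes*, printed demographic percentages and
  effect directions, not the published ROR/PRR values themselves.
- The Woolf and PRR intervals are Wald-type on the log scale: undefined at
  zero cells and slightly anti-conservative at small counts.
- One preferred term per mentioned category means event- and report-unit
  counts coincide in purely synthetic single-mention data; real data
  separate them.
- The flat demographic model (year-independent volumes and mixes) makes the
  yearly table a uniform partition rather than the growth curves real
  launch-cohort data show.
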
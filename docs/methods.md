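# Methods

## The assay and what the pipeline computes

An in vitro batch culture incubates a weighed substrate (0.5 g dry matter)
in 20 mL of strained rumen fluid plus 40 mL of buffer (60 mL liquid total)
at 39 °C for 72 h. Gas is read with glass syringes at 3, 6, 9, 12, 24, 48,
and 72 h; the CH4 fraction of each reading comes from gas chromatography.
Substrate-free blank bottles track the inoculum's own gas production. At
72 h each bottle yields end-point chemistry (pH, six VFA, NH3-N, microbial
protein, residue weight), a hydrolysed amino-acid panel, qPCR counts of
four microbial groups, and optionally a 16S OTU count table.

The pipeline chains: blank correction and cumulation → replicate rejection
→ hydrogen balance → chemistry and amino-acid summaries → qPCR
quantification → diversity → treatment comparison.

## Gas model and conventions

* **Net gas**: gross syringe reading minus the arithmetic mean of the blank
  readings at the same timepoint, per run. Negative nets are *kept* (with a
  warning) so that the sum of interval nets always equals the final
  cumulative value; clipping would silently break that conservation.
* **CH4 volume**: interval net gas × measured CH4 fraction of the interval.
  The field reports both net- and gross-based CH4; both are implemented
  (`ch4_basis="net"|"gross"`, default net) because published totals rarely
  state the convention.
* **Replicate rejection**: a bottle is dropped when its 72-h cumulative net
  total deviates more than 10 % (configurable) from the mean of its
  (treatment, run) group — computed in a single pass against the mean of
  all bottles, since the common bench rule does not define an iterative
  variant. If every bottle fails, the group is reported as degenerate
  rather than silently emptied.
* **Experimental unit**: the mean of the retained bottles within each run.
  With two runs this gives n = 2 units per treatment, which is what the
  pooled SEMs below refer to.

## Hydrogen balance

Amounts are in mmol throughout. Concentrations (mmol/L) are converted with
the 60 mL liquid volume; this convention reproduces the published
produced-hydrogen values exactly from the published concentrations, which
is why 0.06 L is the fixed default. CH4 gas volume is converted with a
configurable molar volume (22.4 L/mol STP default; 25.6 L/mol at 39 °C
offered) — but note that published utilized-hydrogen values generally
cannot be regenerated from published CH4 volumes under any standard molar
volume, because the per-bottle CH4 amounts behind them were never printed.
The hydrogen stage therefore prefers a measured `ch4_mmol` column when the
chemistry table provides one and falls back to gas-derived CH4 otherwise.
The synthetic presets carry per-bottle CH4 amounts back-solved from the
published utilized values (e.g. 0.748 mmol for the control), making the
zero-noise pipeline reproduce the full published hydrogen block.

Isobutyrate appears in no hydrogen term; lactate, formate, and succinate
are outside the balance by construction.

## Chemistry and amino acids

TVFA is the plain sum of the six acids; molar proportions divide by it; the
A/P ratio requires positive propionate. DMD is
`(1 − residue/substrate) × 100`; values below zero (residue gain) are
flagged, not clipped. The colorimetric assays (microbial protein, NH3-N)
are modelled as linear standard curves only — no reagent-specific math is
assumed. The amino-acid panel groups 8 essential and 12 non-essential
analytes; **histidine is counted as non-essential**, following the source
panel's grouping rather than the textbook assignment, because fidelity to
the published table layout wins. Printed panel totals were computed by the
original authors from unrounded inputs, so aggregate comparisons against
printed totals use a 0.5 % relative tolerance.

## qPCR

Standard copy numbers use the 660 g/mol/bp double-stranded convention with
Avogadro's number. Curves are least-squares fits of Ct on log10(copies);
efficiency is `10^(−1/slope) − 1`. An r² below 0.999 or an efficiency
outside (0, 1.1] is a logged QC warning, not a failure. Reaction-to-sample
scaling is one multiplicative dilution factor (default 1e5 in the
generator) since extraction/elution volumes vary by lab. The per-g vs
per-mL unit label is carried through without conversion.

## Diversity

Alpha indices use the Mothur formulations (Shannon in nats; Simpson as the
unbiased dominance `Σ n(n−1)/(N(N−1))`; Chao1 with the bias-corrected form
when no doubletons exist; ACE with rare cutoff 10, falling back to Chao1
when all rare taxa are singletons; Good's coverage `1 − F1/N`). Rarefaction
is available (seeded) but off by default — raw counts are analysed unless
the user opts in. Bray–Curtis comes from `scipy.spatial.distance.pdist`.
PERMANOVA uses Anderson's pseudo-F on squared distances with seeded label
permutations and the `(count + 1)/(n_permutations + 1)` p-value, so the
smallest attainable p is `1/(n_permutations + 1)`; the default permutation
count is 999 and is a flag. The Venn presence rule is "group-summed count
≥ 1", configurable.

## Group statistics

One-way ANOVA on the experimental units; pooled SEM is `sqrt(MSE/n)` (with
the harmonic mean n under mild imbalance). Compact letters come from
pairwise Tukey HSD (studentized-range p-values; Tukey–Kramer for unbalanced
groups) through the insert-and-absorb algorithm, with letter classes
ordered by descending member means so "a" marks the top group; unprotected
LSD is available as a flag. At n = 2 units per treatment letter recovery is
power-limited — the package supports bottle-level analysis as an
alternative, at the cost of treating pseudo-replicates as units.
Correlation screens use Spearman rank correlation with average ranks for
ties and the star convention `* 0.01 < p ≤ 0.05`, `** 0.001 < p ≤ 0.01`,
`*** p ≤ 0.001`, gated on |rho| > 0.1, with **no** multiple-testing
correction (matching field practice for these heatmaps).

## Synthetic generator

The generator is first-class, tested code that defines the study
conditions:

* **Design**: 4 treatments × 5 bottles × 2 runs, 3 blanks per run,
  timepoints {3, 6, 9, 12, 24, 48, 72} h, 0.5 g substrate, 60 mL liquid.
* **Gas**: single-pool saturating curves `V(t) = A(1 − e^(−kt))` — the
  simplest monotone saturating family consistent with the observed
  cumulation shape. Asymptotes are the published 72-h totals × 0.5 g;
  rate constants are 0.15/h (control, cysteamine) and 0.10/h (nitrate
  groups), chosen once to reproduce the slower early rise under nitrate.
  Interval noise is multiplicative lognormal (unit mean, CV 0.05 by
  default) to preserve positivity; blanks follow their own saturating curve
  (asymptote 8 mL) and enter bottle readings additively.
* **End-points**: Normal(mean, sd) truncated at zero. Published tables give
  pooled SEMs over n = 2 run-average units, so per-bottle SDs are
  back-derived as `SEM × √2` — a flagged convention, not the original
  authors'; it makes run-average dispersion match the printed SEM while
  leaving per-bottle dispersion underdetermined.
* **qPCR plates**: a true curve at 100 % efficiency (slope −3.3219,
  intercept 38) emits standards over 10³–10⁸ copies/reaction and unknown
  Cts from the treatment log10 means, with Normal Ct noise (sd 0.1).
* **OTU tables**: Dirichlet-multinomial around per-treatment genus
  compositions (15 published genera plus an "Other" remainder),
  concentration 200, depth 10 000 by default; `overdispersion=inf` gives
  pure multinomial sampling.
* **Seeding**: one global seed spawns an independent substream per table,
  so regenerating or adding one table never perturbs another — and the
  whole experiment is bit-reproducible under a fixed seed.

What the generator does **not** emulate: sequencing error and chimeras,
compositional correlations between taxa beyond the Dirichlet, run-level
(week) batch effects, nitrate-reduction kinetics, or within-bottle temporal
correlation of measurement error. Passing tests therefore demonstrate that
the analysis recovers known parameters under the stated noise model — not
that the model captures every feature of real bench data.

## Numerical and testing choices

Zero-variance groups are handled deterministically (identical groups →
p = 1, shared letter; distinct means with zero MSE → p = 0, distinct
letters) instead of propagating NaNs from F ratios. Simulation-based test
sizes were chosen to keep the default suite in the tens of seconds:
PERMANOVA type-I calibration uses 1000 null datasets of 2 × 5 samples at
depth 500 with 199 permutations; the Spearman null uses 2000 draws at
n = 8; noisy parameter recovery uses 60 seeded regenerations of the full
endpoint table. Cross-checks against independent implementations
(scikit-bio alpha indices and PERMANOVA pseudo-F, statsmodels Tukey HSD)
are tests, not dependencies of the computation path.

## Known limitations

* Published per-bottle raw data are unavailable, so published significance
  letters cannot be regenerated; letter logic is validated on synthetic
  data only.
* The generator treats runs as exchangeable; real week-to-week inoculum
  variation would add a random effect the ANOVA here does not model (mixed
  models are out of scope).
* Amino-acid and VFA concentrations are taken as given — chromatographic
  peak integration and internal-standard response factors are upstream of
  this package.
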
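# Methods

This note documents the models, numerical choices and limitations behind
`farmclock`. It is written for users who want to know exactly what the
package computes, and why, before applying it to their own herds.

## The problem

DNA methylation at a modest panel of CpG sites changes with age in a
strikingly reproducible way across mammals, and sparse linear models on
methylation beta values ("epigenetic clocks") predict chronological age
with correlations above 0.9 in many species. `farmclock` builds such
clocks for ruminant livestock — deer, cattle, goat and sheep — either per
species or pooled into a single multi-species *farm clock*, and estimates
their out-of-sample accuracy honestly, including transfer to species
absent from training.

## Age transformations

Regressing methylation on raw age is a poor model: methylation changes
fast through development and slowly in adulthood, and raw age is not
comparable between a goat and a deer. Each clock therefore predicts a
*transformed* age, anchored on three species constants in days —
gestation length GT, age at sexual maturity ASM, and maximum lifespan
MaxAge — vendored from the AnAge longevity database:

| species | MaxAge (years) | ASM (days) | GT (days) |
|---------|---------------|------------|-----------|
| deer    | 31.5          | 791        | 245       |
| cattle  | 20            | 548        | 277       |
| goat    | 20.8          | 545.5      | 155       |
| sheep   | 22.8          | 731        | 146       |

All internal ages are in days; lifespans tabulated in years are converted
with the Julian year (365.25 d). Every transform offsets age by 2 GT,
which regularizes the logarithm near birth and leaves room for prenatal
samples in later extensions. With natural logs:

* **Clock 1 (log age)** — `y = ln(Age + 2GT)`, inverse
  `exp(y) − 2GT`. Species-specific; not meaningful pooled across species
  with different lifespans.
* **Clock 2 (log-log relative age)** —
  `RelativeAge = (Age + 2GT)/(MaxAge + 2GT)` in (0, 1], then
  `y = −ln(−ln(RelativeAge))`, inverse
  `exp(−exp(−y))(MaxAge + 2GT) − 2GT`. Lifespan-normalized, the preferred
  scale for multi-species clocks.
* **Clock 3 (log-linear age)** — `r = (Age + 2GT)/(ASM + 2GT)`;
  `y = ln r` below sexual maturity and `r − 1` above, continuously
  differentiable at ASM. Uses ASM, which is far better recorded in
  livestock than true maximum lifespan.

All three are strictly increasing with exact closed-form inverses; the
test suite verifies round trips to 1e-6 days over the full age range.
One deliberate design choice: the published form of clock 3's
sub-maturity inverse subtracts the constant 1.5 rather than 2 GT. That
constant is not the algebraic inverse of the forward transform and is
dimensionally inconsistent with day units (the post-maturity branch *is*
the exact inverse), so the package defaults to the exact inverse
`exp(y)(ASM + 2GT) − 2GT` and offers the published form behind a
`printed_inverse` compatibility flag.

Clock 2 diverges as age approaches MaxAge. By default the forward
transform raises there; at prediction time the evaluation routines enable
a clamp (RelativeAge capped at 1 − 1e-6) so a long-lived outlier degrades
gracefully instead of crashing a cross-validation run.

## Preprocessing and QC

Beta values are `M/(M + U + a)` with offset `a = 100` by default,
stabilizing the ratio when both intensities are small. The package
accepts externally normalized beta matrices or raw intensity pairs; probe
chemistry normalization (pOOBAH/SeSAMe and kin) is out of scope and
expected upstream. A generic detection-p mask (default threshold 0.05)
marks failed entries; probes masked in more than half the samples are
dropped, the rest mean-imputed per probe — within species for species
clocks, globally for the farm clock — because the penalized regression
needs complete predictors. These masking defaults are declared
conventions, not values inherited from any particular array pipeline.

Sample QC mirrors array practice: average-linkage hierarchical
clustering on 1 − Pearson correlation between sample profiles (the
convention of the WGCNA ecosystem), cut at the number of species, to
surface species structure and batch problems; and a sex check that
predicts each sample's sex by nearest sex-centroid on a user-supplied
list of sex-informative probes, flagging samples whose recorded binary
sex disagrees. Flagged samples are excluded with an explicit logged
reason, never silently; samples recorded as other/unknown are never
excluded by the sex check.

## Clock fitting

The clock solves the elastic-net problem

    min_b0,b  (1/2n) Σᵢ (yᵢ − b0 − xᵢ·b)² + λ [ α‖b‖₁ + (1−α)/2 ‖b‖₂² ]

with mixing α = 0.5 by default. Predictors are standardized internally
(coefficient estimates are returned on the original beta scale;
without standardization the λ selection would depend on arbitrary probe
scalings). The λ grid has 100 log-spaced values from λ_max — the
smallest penalty with an all-zero solution, `max|Xᵀy|/(nα)` on the
standardized data — down to λ_max × 1e-4. λ is chosen as *lambda.min*:
the grid value minimizing the mean of per-fold MSEs over seeded internal
cross-validation (10 folds by default, assigned by seeded permutation and
stratified by species in pooled fits so no fold loses a species
entirely). The final model is refit on all samples at the selected λ,
warm-starting down the path. The coordinate-descent path solver is
scikit-learn's `enet_path`; everything around it (grid, folds,
standardization, selection, back-scaling) is this package.

The farm clock pools all species, with each sample's response computed
from its own species' life history; only clocks 2 and 3 are offered
pooled, since log chronological age is not commensurate across lifespans.
Selected sites are summarized by the sign of their *marginal* Pearson
correlation with chronological age in the training data (not the
coefficient sign, which is conditional on the other selected sites); an
exactly-zero correlation counts as positive and is logged. Cross-clock
CpG sharing is reported as the full Venn decomposition of selected-site
sets.

Clock files are plain CSV with metadata header lines; floats are
serialized with `repr` so a write → read round trip reproduces
predictions bit-for-bit.

## Validation

* **LOOCV** refits the entire clock, internal λ selection included, on
  every n−1 subset (n full fits). Each refit draws its own internal
  folds, seeded deterministically from (seed, fold index) — repeated
  cross-validated fits are independent draws, and reusing one fold split
  everywhere would make the null degenerate (an intercept-only model's
  leave-one-out predictions are the training means, which correlate −1
  with the held-out responses by construction). A `fast` mode reusing a
  single full-data λ is provided for exploration and labelled as the
  deviation it is.
* **LOSO** (farm clocks only) holds out each species entirely; the
  held-out species' own constants drive both its true transformed ages
  and the back-transformation, since life history is a property of the
  sample, not of the training set.
* **Metrics**: Pearson r on the transformed scale (where the model is
  linear); MAE as the *median* absolute error between back-transformed
  DNAm age and chronological age, in days (divide by 30.4375 for months).
  For LOSO, per-species fold correlations and their median (med.corr)
  accompany the pooled r computed across all held-out predictions on the
  commensurate transformed scale.

## The synthetic generator

Defaults emulate a four-herd study: 96 samples per species, uniform ages
over herd-like ranges (about a month to 7–14 years depending on species),
3000 probes, 60 causal sites per species of which 5 are shared across all
species, 60% of causal sites gaining methylation with age, ~75% female
samples, chips of 96. A causal probe's mean beta is
`baseline + sign·slope·z(age)` where z is the clock-2 transformed age
standardized against the pooled sampling design — linear on the
relative-age scale with one species-invariant mapping, so the shared
sites carry a signal that genuinely transfers between species (a
within-species standardization would make the same methylation level mean
different relative ages in different species, capping cross-species
accuracy well below what conserved age-CpGs show in practice).
Shared sites use identical signs and slopes everywhere; species-specific
causal sites are disjoint between species. Background probes get
species-specific baseline offsets (sd 0.08), which is what makes samples
cluster by species. Baselines follow a bimodal mixture concentrated near
0.1 and 0.9 (imitating array beta marginals) except causal and sex probes,
which are drawn mid-range so their effects are expressible within [0, 1]
after clamping. Gaussian noise (sd 0.04) is added and values clamped to
[0, 1]; with the default effect scale (0.11 beta-range per ±√3 of z) the
per-site |r| with age sits near 0.6, the regime in which elastic net
selects a few dozen sites per clock. Sex probes are shifted +0.2 in
males — far above noise, as true sex-linked probes are.

What the generator does *not* emulate: probe-probe correlation blocks
(CpG islands), heteroskedastic beta noise near the boundaries, batch
effects with real structure, breed substructure, age-skewed herd
demographics (a right-skew option exists but is off by default), or any
array chemistry. Passing tests therefore demonstrate that the pipeline
recovers the structure it models, at realistic sizes and noise — not that
any particular accuracy will be achieved on real arrays.

## Problem sizes and numerical notes

The study-scale checks use the default 4 × 96 × 3000 configuration; full
LOOCV at that size is ~100 internal-CV fits per clock and runs in a few
minutes per clock on one core, which is why the acceptance script
evaluates LOOCV on one representative species and LOSO on the pooled
data. Degenerate inputs fail loudly: exactly-constant responses,
non-finite transformed ages, masked entries reaching the solver, clock-2
ages at or beyond MaxAge (unless clamped), fewer samples than folds.
Equality checks on constant vectors use exact range (`ptp == 0`) rather
than a variance epsilon. The elastic-net active set can occasionally
shrink by a site between adjacent path points as correlated predictors
trade places; monotone growth of the active set holds in the overwhelming
majority of steps but is not asserted step-by-step.

## Known limitations

* Raw IDAT parsing, pOOBAH and array normalization are upstream concerns.
* No batch-effect correction is applied (none was needed in the data
  regime the package targets; the QC clustering makes batch structure
  visible so the user can decide).
* No confidence intervals on correlations, and no age-acceleration
  residual phenotypes — the evaluation reports point accuracy only.
* AnAge life-history constants may sit outside what particular farming
  systems record; custom constants can be supplied via config, and the
  relative-age transforms are robust to proportional disagreement across
  species.
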
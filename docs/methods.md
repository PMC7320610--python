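# Methods

## Problem and labeling model

The package discriminates two recurrence-defined classes of somatic SNVs
from tumour catalogs: *highly recurrent* variants (`r >= ρ`), used as a
proxy for positively selected drivers, and *singleton* variants (`r = 1`),
used as a proxy for neutral passengers. The recurrence count `r` is taken
as given in the input VCF (INFO key, default `CNT`); no patient-level
deduplication is attempted.

Because recurrent and rare variants can occupy systematically different
genomic neighbourhoods, negatives are *window-matched*: a singleton is
retained only if it lies within `w` nucleotides (boundary-inclusive,
position-to-position distance) of some positive on the same chromosome.
Defaults bind per region mode: `ρ = 7`, `w = 10 000` for coding and
`ρ = 8`, `w = 1000` for non-coding variants, where "coding" means the
position overlaps an annotated CDS interval. Variants with `1 < r < ρ` are
excluded from training but cached so the recurrence-threshold sweep can
relabel without re-reading inputs.

Dataset rows are canonically ordered by (chromosome, position, alt), so the
same catalog produces the identical dataset whether it arrives in memory or
through files.

## Features

Seven per-variant feature groups:

| Group | Content | Default parameters |
|---|---|---|
| Conservation | value of each conservation-type track at the position | input bedGraph tracks |
| Uniqueness | value of each sequence-uniqueness-type track | input bedGraph tracks |
| GC | G+C fraction of a centred window | window 100 bp |
| LocalMutFreq | count of other catalog variants within ±window/2 | window 1000 bp, self-excluded |
| GeneProximity | distance to nearest TSS / splice site / TFBS | log1p-transformed |
| Spectrum | normalized k-mer frequencies of a centred window | k = 3, window 100 bp |
| FunctionalElements | overlap indicator per element class | classes from input BED |

Conservation and uniqueness are consumed as pre-computed tracks, never
recomputed from alignments. Missing values (position absent from a track,
no interval of a kind on the chromosome, all-N windows) use a NaN sentinel
and are imputed with training-row column means at assembly time; a column
missing in every training row imputes to 0. The spectrum window is read as
a window of total width `w` centred on the variant; the mutation-frequency
"region of 1000 positions" likewise means ±500 around the variant, with
the query variant itself excluded. These conventions are frozen here so the
extractors are exactly testable against brute-force scans.

## Classifier

The learner is a support-vector machine with an RBF kernel (linear
selectable) on the column-concatenated feature groups:

* **Standardization** (default on): training-fold column means and
  population SDs; constant columns map to zero (SD stored as 1).
* **Bandwidth**: median heuristic — `γ = 1/(2 m²)` with `m` the median
  pairwise Euclidean distance over (a seeded subsample of ≤500)
  standardized training rows. Regularization `C = 1`.
* **Calibration**: a Platt-style sigmoid `p = σ(a·f + b)` fitted by
  logistic regression on the training decision values `f`. The slope is
  clamped at `a >= 0` so the map is monotone non-decreasing; in the clamped
  (signal-free) case the intercept encodes the training positive rate, so a
  degenerate model scores everything at its base rate rather than
  inventing structure.
* **Decision rule**: label `+` iff score `>= 0.5` (ties positive).

All train-side statistics — imputation values, standardization, kernel
state, calibration — are estimated from training rows only; the test suite
verifies that perturbing held-out rows leaves the fitted state bit-identical.

## Validation

Leave-one-chromosome-out cross-validation over the autosomes present in
the data (chr1–chr22; X, Y and MT never appear on either side). Training
folds are balanced by subsampling up to `n_per_class` examples per class
(default 4000, the full class when smaller) with a dedicated seeded
generator; all examples of the held-out chromosome are scored. Pooled
metrics over all out-of-fold predictions are primary; per-fold metrics are
also reported. Metrics with zero denominators are reported as missing,
never as 0.

Cautious classification thresholds the score's distance from 0.5: an
example is high-confidence iff its score is `>= τ` or `<= 1 − τ`
(`τ ∈ (0.5, 1]`, default 0.91); coverage is the confident fraction and
cautious metrics are computed over confident examples only. Coverage is
non-increasing in τ by construction.

The two-sample distribution test (class-conditional feature comparisons)
is Kolmogorov–Smirnov by default, Mann–Whitney by option. p-values below
the floating-point floor are reported as an explicit upper bound using the
KS tail inequality `p <= 2·exp(−2 D² nm/(n+m))`, never as 0.

## Forward feature-group selection

Singleton groups are ranked by mean cross-validated balanced accuracy
(ties broken by group name; an all-missing group ranks last). Starting
from the top singleton, each round evaluates adding every remaining group
as one concatenated kernel, under the same folds and training subsamples
(paired comparison), and accepts the best addition only if it improves
significantly.

"Significantly" is genuinely underdetermined, and with a handful of folds
most fold-level tests are either underpowered or uncalibrated, so three
rules are provided:

* `example_permutation` (default): paired sign-flip permutation on pooled
  per-example balanced-accuracy contributions, **aggregated within 10 kb
  genomic blocks** before flipping. Nearby variants share feature windows
  (mutation density, GC, track bins), so their paired differences are
  dependent; flipping them independently demonstrably understates p and
  admits spurious groups. Candidate evaluations are additionally averaged
  over 3 balanced-subsample repeats to damp training-side noise. One-sided
  α = 0.05 with Bonferroni correction over the round's candidates.
* `stderr`: accept when the mean per-fold paired improvement exceeds one
  standard error of the per-fold differences. Simple, but with f folds the
  null acceptance rate per candidate is roughly `P(t_{f−1} > 1) ≈ 0.2`, so
  it over-selects with few folds.
* `fold_permutation`: sign-flip permutation over per-fold differences;
  note that with f folds the smallest attainable p is `2^{−f}`, so it
  cannot reject at α = 0.05 below 5 folds.

The trace records, for every evaluated candidate, the per-fold balanced
accuracies, the mean and pooled balanced accuracy, the p-value and the
accept decision; accepted steps strictly increase the mean balanced
accuracy, and re-evaluating any step's group set under the same seed
reproduces its recorded numbers.

## Synthetic-data generator

The generator emulates the structure the method assumes, not the scale or
composition of real tumour catalogs. Defaults: 4 autosomes of 200 kb,
uniform base composition, 20 mutation hotspots, 300 driver variants with
truncated-geometric recurrence on [8, 20], 3000 passengers (`r = 1`; 70%
within ±800 bp of a hotspot, 30% uniform), 8 genes and 10 TFBS per
chromosome, two functional-element classes, and three score tracks
(PhastCons-like on [0, 1], PhyloP-like unbounded, uniqueness-like) drawn
per 100 bp bin.

Class-conditional effects are planted with per-group effect sizes in SD
units of the baseline feature distribution:

* **Conservation / Uniqueness** — track values at exact driver positions
  are drawn from the baseline shifted by the effect (clipping of bounded
  tracks slightly attenuates large shifts).
* **GC / Spectrum** — sequence around drivers rewritten with shifted G+C
  probability (0.05 per SD of a 100 bp window) or nucleotide
  autocorrelation. Because driver windows overlap passenger windows inside
  a hotspot cloud, composition effects are partially diluted.
* **LocalMutFreq** — extra `r = 2` "clutter" variants around drivers
  (≈4 per SD unit); they raise local density but the labeling rule keeps
  them out of training.
* **GeneProximity** — a fraction of drivers relocated next to a TSS.
* **FunctionalElements** — elements planted over a fraction of drivers.
* **effect_vs_r** — optional extra conservation shift per recurrence unit,
  giving recurrence-graded signal for threshold sweeps.

Drivers and near-hotspot passengers share the same spatial law, so with
all effects at zero every feature is identically distributed across
classes — an exact null (a few percent of retained far-passengers deviate
negligibly). Default effect sizes (Conservation 1.0, Uniqueness 0.75,
LocalMutFreq 0.75, GC 0.5, GeneProximity 0.5, FunctionalElements 0.25,
Spectrum 0) reflect the qualitative pattern that recurrent somatic
variants concentrate in constrained, mutation-dense regions, with milder
composition and annotation effects. An optional germline-like cohort
(uniformly placed, conservation shifted −1 SD by default) supports
germline-versus-somatic distribution comparisons.

What passing tests on these cohorts shows: that the pipeline recovers
planted class-conditional shifts of known size, is calibrated at the null,
selects exactly the informative groups, and leaks nothing across folds.
What it does not show: performance on real catalogs, whose feature
correlations, mutational signatures, patient structure and genome-scale
heterogeneity the generator deliberately does not model.

## Problem sizes and numerical choices

Simulated evaluations use ~2000–2500-example datasets over 4 autosomes and
up to 300 training examples per class per fold — sizes chosen so the whole
suite and the acceptance script run in minutes on one CPU while keeping
per-fold test sets in the hundreds. Determinism: every stochastic step
(simulation, subsampling, bandwidth subsample, permutations) draws from
its own seeded generator; identical inputs and seeds reproduce reports and
prediction files byte-identically. Coordinates are 0-based half-open
internally; VCF/GFF3 convert at the I/O boundary. bedGraph serialization
uses shortest round-trip float representation so fixtures re-parse
bit-identically.

## Known limitations

* Recurrence thresholds stand in for functional driver status; the model
  learns recurrence correlates, which on real data include mutational
  hotspot processes unrelated to selection.
* The exact learner and confidence measure of deployed recurrence
  classifiers vary; the RBF-SVM with clamped Platt calibration and the
  score-distance-from-0.5 confidence used here are conventional,
  documented realizations of the [0, 1]-score contract, not claims about
  any particular production system.
* The fold-level permutation stop rule is unusable below 5 folds (see
  above); the default block-permutation rule assumes block size covers the
  dependence range of the features (10 kb covers all default windows).
* Window matching measures position-to-position distance; matching to
  region boundaries around recurrent sites is not implemented.
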
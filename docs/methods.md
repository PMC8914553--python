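# Methods

This note documents the models, statistical procedures and design choices
behind `matscale`: what each stage computes, which parameters matter, what
the synthetic observer model does and does not emulate, and the numerical
conventions used throughout.

## Data model

One CSV row is one trial. A session has up to three blocks: *free*
(free-text material description), *choice* (one of 26 material categories,
with a 1–7 confidence rating), and — in the unbiased design only —
*distance* (a measurement unit from {micrometer, millimeter, centimeter,
meter, kilometer} plus a metric value). Category labels are matched
case-insensitively after trimming and stored lower-case, which removes a
silent failure mode in hand-edited files. Validation enforces the block
structure (a choice row needs a category, a distance row needs unit and
value), the design structure (distance fields only in the unbiased
experiment; group labels must match their experiment), and the value ranges.

Distance analyses operate on the **ordinal** unit scale. Converting
estimates to a common unit produces a distribution spanning many orders of
magnitude and extremely skewed, so converted centimeters
(`to_centimeters`, factors 1e-4 / 1e-1 / 1 / 1e2 / 1e5) are exposed for
descriptive summaries only.

The default 26-label choice vocabulary covers the material categories a
surface-photograph study of this kind uses (bark, stone, water, sand,
plant, carpet, marble, …). It is a first-class parameter of every
operation: a reanalysis of deposited data would substitute the deposited
category list without touching any code. The free-text side admits a
larger set of single-word descriptors, disjoint from the choice list, plus
the sink term `none`.

## Free-text normalization

Free descriptions are reduced to single terms by a deterministic rule
chain driven by an editable YAML lexicon: typo correction → translation →
compound reduction (keep the head noun: explicit map first, last-token
fallback second) → synonym resolution → vocabulary check. Anything
unresolved or non-material maps to `none`. Two conventions matter:

- Phrase-level synonyms ("frozen water" → "ice") take precedence over
  compound reduction, which would otherwise strip them to the wrong head
  noun ("water"). Compound reduction therefore skips any phrase that is a
  synonym key or already an allowed multiword term.
- The published studies performed this reduction manually; the lexicon
  chain trades fidelity to unrecorded manual edits for reproducibility.
  The shipped lexicon seeds every documented example mapping and a small
  German translation table; it is meant to be extended per dataset.

Normalization is total and idempotent: outputs are always in the allowed
vocabulary (or `none`), and normalizing an output returns it unchanged.
Task agreement between free and choice blocks is the Spearman rank
correlation (midrank ties) of term frequencies over the terms common to
both maps, excluding `none`; at least 3 common terms are required.

## Pair counts and the MSA statistic

Responses for one image are partitioned *near*/*far* — by distance unit
(micrometer/millimeter/centimeter vs meter/kilometer) in the unbiased
design, by manipulation group (instructed-near / small object vs
instructed-far / large object) otherwise. The directional pair-count
matrix is the Cartesian product of the two response multisets:
`C[a, b] = n_near(a) · n_far(b)`, rows = near category, columns = far
category (the one coordinate convention, used everywhere). Images whose
responses all fall in one group yield no pairs and are flagged
*degenerate*; they are excluded from per-image rankings and summaries and
counted in the logs. Responses from different images are never paired.

MSA is the RMSE between corresponding cells of the lower and upper
triangles of `C`, diagonal excluded. Defaults, both exposed as options:

- **Pair set** (`full_vocab`): average over all C(26, 2) = 325 unordered
  vocabulary pairs, including never-chosen categories. This keeps the
  denominator identical across images, making per-image scores
  comparable; `observed_only` restricts to categories with any response.
- **Count scale** (`raw`): raw pair counts, not per-image frequencies.
  With 24 participants split roughly 12/12, raw counts put the mean score
  in the low units rather than inside [0, 1]; `normalized` divides by
  near_total · far_total.

Because `C` is always a rank-one outer product `u vᵀ` of the per-category
count vectors, the triangle sum collapses to
`‖u‖²‖v‖² − (u·v)²`, giving a closed form used on the permutation hot
path (`msa_from_vectors`); the generic triangle computation
(`msa_from_counts`) handles aggregated or filtered matrices and the
non-default options, and the two are cross-checked in the tests.

Properties relied on (and property-tested): MSA ≥ 0 with equality iff `C`
is symmetric; invariance under transposition and under relabeling applied
to both axes; homogeneity of degree 1 in the counts.

## Permutation chance levels

Chance MSA for an image is the arithmetic mean of MSA over 1000 random
permutations (default `n_permutations`, seeded) that break the association
between category and scale grouping:

- **Unbiased design** — permute the distance units across the image's
  responses at the *response* level. The unit multiset (hence the near/far
  split sizes) is preserved, so no permutation is degenerate if the
  original image was not.
- **Manipulated designs** — permute participants' group membership at the
  *participant* level: each participant's full response set moves between
  groups together, preserving within-participant dependence and the fixed
  group sizes.

An image counts as *above chance* when its observed MSA exceeds its
permutation mean. Note that the null distribution of MSA is right-skewed,
so even under a true null the probability of exceeding the null *mean* is
below one half; the calibration tests account for this by estimating the
false-positive expectation from the permutation draws themselves, and use
randomized empirical p-values (uniform by construction for exchangeable
draws from a discrete null) when testing uniformity.

## Experiment summaries and inference

Per experiment: means of observed and chance MSA with 95% percentile
bootstrap CIs (10,000 resamples, seeded; no analytic CI is implied by the
reporting convention), a two-sided Wilcoxon signed-rank test on the paired
per-image differences — zero differences dropped, `T` = the smaller
signed-rank sum, exact null up to 25 non-zero pairs and the normal
approximation with continuity correction above — and the paired effect
size `d = mean(diff) / sd(diff)`. Images are ranked by observed MSA
descending (mean across experiments when combining), ties broken by image
id for determinism.

Supporting statistics:

- `chance_accuracy(n)` = 1/n; with 26 options this is 3.85%, reported as 4%.
- `binomial_exceed_chance(x, n, α)`: exact (Clopper–Pearson) one-sided
  lower 1−α confidence bound for a binomial proportion, the Beta quantile
  `Beta(α; x, n−x+1)`; for x = n it reduces to `α^(1/n)`. Applied to the
  count of participants individually exceeding chance accuracy; `n` is a
  parameter. The bound is one-sided by construction even though the other
  tests are two-sided — the two conventions coexist deliberately.
- Cohen's *g* for a one-sample proportion: the raw difference
  observed − reference.
- Spearman correlations use midranks; Mann–Whitney U (confidence
  comparison, attribute contrasts) is reported with a pooled-SD Cohen's d
  on the per-unit means, matching the field's reporting style.

## Synthetic observer model

Each simulated participant adopts a latent *reading* of each image — near
with probability `p_near` (default 0.5), far otherwise — then draws a
category from a reading-conditional distribution. A per-image asymmetry
parameter λ ∈ [0, 1] interpolates linearly between a shared base
distribution (default: ½/½ on a designated confusable category pair, e.g.
bark↔stone) and point masses on the pair:

```
near_dist(λ) = (1−λ)·base + λ·δ(pair_near)
far_dist(λ)  = (1−λ)·base + λ·δ(pair_far)
```

so λ = 0 gives identical conditionals (symmetric confusions in
expectation, the null case) and λ = 1 a fully directional confusion.
Defaults mirror the emulated study design: 24 participants (unbiased),
12 per group (manipulated), 87 images, 26 categories.

The unbiased simulation emits all three blocks; the distance unit is drawn
consistently with the reading (near: 0.15/0.35/0.5 over
micrometer/millimeter/centimeter; far: 0.7/0.3 over meter/kilometer) with
a log-uniform metric value in 1–99 of the unit — descriptive-only
downstream, so the exact ranges are unconstrained. Free text is the
category label, 30% of the time prefixed with a modifier ("scratched",
"desert", …) so the normalization chain is exercised end-to-end.
Confidence is a discretized normal (mean 5, sd 1, clipped to 1–7).

Manipulated designs shift the reading probability by ±δ (default 0.4) per
group; the familiar-objects modality attenuates δ by 0.5 and lowers mean
confidence by 0.2, emulating a weaker, less trusted scale cue. A
ground-truth ledger (per-trial λ and reading) accompanies every simulated
dataset for recovery tests. `attribute_table` generates synthetic
per-image appearance ratings and self-similarity values — stand-ins for
pilot ratings, which the exploratory analyses consume as precomputed
numbers.

What the simulator does **not** emulate: real images' heterogeneous
response entropy (real responses spread over many more categories than a
single confusable pair, which is why simulated MSA magnitudes exceed
those typical of real data at the same design size), participant-level
response biases and lapses, free-text noise beyond the modifier scheme,
and any dependence of confidence on image difficulty. Passing tests
therefore demonstrate correctness and calibration of the *pipeline*, not
quantitative agreement with any particular dataset.

## Exploratory analyses

- **Modal distance group** per image: the most frequent selected unit,
  mapped near/far; ties between units break toward the smaller (nearer)
  unit.
- **Attributes by distance**: Mann–Whitney U + pooled-SD d per appearance
  attribute, comparing images whose modal unit is near vs far.
- **Organic split**: categories rated strictly above the median
  organic/natural rating are "organic" (a category at exactly the median
  is inorganic — the below-or-equal rule); the analysis reports the
  fraction of near- and far-group choice responses falling in the organic
  set.
- **MSA classifier protocol**: target = median split of per-image MSA (at
  the median → low). For each of 1000 (default) random stratified 75/25
  train/test partitions, a fresh RBF-kernel SVM is fit with C and gamma
  grid-searched on the training data (logarithmic 10⁻³…10³ grid, 3-fold
  inner CV, features standardized); the result is the mean test accuracy.
  Split ratio, grid and backend are configurable; splits leaving one
  class in either partition are re-drawn. The train/test ratio and grid
  are choices this package fixes as defaults, since no single convention
  exists for the protocol.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; pipeline commands
derive per-image seeds from the master seed via a seeded generator, and
identical seeds yield byte-identical CSV/JSON artifacts. The test suite
runs its simulations at reduced but statistically meaningful sizes (8–200
images, 200–300 permutations, 50,000 draws where a sampling mean is
checked against exhaustive enumeration within 1%); the acceptance script
runs the full 87-image design with 1000 permutations. Degenerate inputs
(single-group images, all-zero differences, constant rank inputs) raise
typed errors rather than returning NaN.

## Known limitations

- The lexicon ships with a seed vocabulary; real free-text corpora will
  need per-dataset lexicon extensions (the CLI accepts an override file).
- The exact pair-set/count-scale combination used by any given published
  analysis may differ from the defaults; both are options precisely so a
  reanalysis can match the deposited analysis code.
- The classifier protocol's mean accuracy depends on the unstated split
  ratio and grid; comparisons across studies should fix these explicitly.
- Aggregated confusion matrices are exported as tables; chord-diagram and
  word-cloud rendering is left to downstream tools.
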
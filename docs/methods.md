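# Methods

`vertdescent` implements a comparative analysis of how arboreal mammals
descend vertical supports: gait kinematics quantified from footfall
events, descent-strategy statistics, morphological correlates,
phylogenetic signal, imputation of descent behavior for fossil taxa,
and trait-evolution model comparison. This note records the models, the
choices made where the design was genuinely open, and the limits of
what the synthetic-data tests demonstrate.

## Gait quantification and classification

A stride cycle is four limb contact cycles (touchdown, lift-off, next
touchdown per limb), with times in seconds (frame counts divide by the
recording fps on read). Derived quantities, all in percent:

- **Duty factor**: contact duration over stride duration, per limb; the
  mean duty factor averages the four limbs.
- **Reference stride duration**: the verbal definition of "total stride
  duration" names no limb; we use the arithmetic mean of the four
  per-limb stride durations, which is symmetric in the limbs and robust
  to per-limb timing noise. This is a fixed convention, not an option.
- **Girdle lag**: left-to-right lag of contact midpoints within a
  girdle, modulo the stride duration. Computed left→right; the
  symmetry window [40, 60] is mirror-stable, so the direction choice is
  inconsequential.
- **Limb phase**: hindlimb-to-ipsilateral-forelimb delay, computed from
  contact-interval *midpoints* (not touchdowns), left and right phases
  averaged.
- **Stance period**: minimal circular separation of a girdle's two
  contact midpoints, as a percentage of the pair's **mean** contact
  duration. "Pair total contact duration" is ambiguous (mean, sum, or
  per-limb); the mean is used because it keeps the 0–100 scale of the
  per-limb convention and is symmetric. With the summed convention all
  values would halve; the 10% classification cut would then sit at 5%.

Classification: symmetrical when both girdle lags lie in [40, 60]%
(closed interval); symmetrical strides split by mean limb phase into
LSLC [0, 25), LSDC [25, 50), DSDC [50, 75), DSLC [75, 100]
(inclusive upper end). Asymmetrical strides split by stance periods:
bound when both ≤ 10, half-bound when exactly one ≤ 10, gallop
otherwise. The ≤ and ≥ rules overlap at exactly 10%; bound is
evaluated first, then half-bound, then gallop, making the ordering
total and deterministic. Exact ties are practically unreachable from
measured event times in floating point; the rule matters for
constructed inputs.

## Ethogram statistics

Strategy proportions are two-stage: per-individual event proportions
first, then an unweighted average across the species' individuals, so
heavily sampled individuals do not dominate. Cells with no descent
events are absent (NA).

Support-diameter effects per species are tested on bootstrap resamples:
individuals are drawn with replacement first, then events within each
drawn individual (default 10 × 10 per support). The response unit is
the per-resampled-individual strategy-proportion vector. With two
strategies in the species' repertoire the proportions are
complementary and a one-way ANOVA is used; with three or more, a Wilks
MANOVA on all but one proportion column. Post hoc pairwise support
comparisons are run when the omnibus is significant, BH-corrected.

Ascent/descent kinematic contrasts bootstrap 20 events per direction
and use a two-sided Mann-Whitney U test; the percent change is
100·(mean descent − mean ascent)/mean ascent on the bootstrapped
samples, so the reported change and the test share the same resample.
Symmetrical-gait-fraction contrasts draw 100 bootstrap species, sample
10 ascent and 10 descent events each, and apply a two-sided Wilcoxon
signed-rank test to the paired fractions (p = 1 when all differences
are zero).

**Calibration caveat.** Resampling *up to* fixed counts from small
pools creates duplicated sampling units that a subsequent rank or
variance-ratio test treats as independent. The type-I calibration
properties in the test suite therefore evaluate each wrapper under its
own asymptotic sampling null (well-populated pools: tens of
individuals with ~100 events, species pools of hundreds of events);
there the empirical type-I error is within 2 percentage points of the
nominal 5%. With pools at the scale of a sparse observational study
(2–3 individuals, ≤10 events per cell) the same wrappers are
measurably anticonservative (we observed ~13% for the bootstrap
MANOVA with 10 individuals × 30 events, and ~20% for the Wilcoxon
wrapper with 10 species × 50 events). Conclusions driven by p-values
near the threshold under such designs should be treated with caution;
this is a property of the resampling design itself, faithfully
reproduced here.

Family-wise control is Benjamini-Hochberg step-up, applied over
whatever family the pipeline assembles (species for support tests,
support × strategy × variable for contrasts, group × support for gait
fractions). BH is order-invariant and never lowers a p-value; note the
step-up transform is *not* idempotent in general (only flat adjusted
sets are fixed points).

Gait-repertoire similarity between phylogenetic groups uses PCA
(centered, not scaled — frequencies are already commensurate) on
individual-on-support gait-frequency rows, keeping the smallest
leading set of components whose cumulative explained variance reaches
95%, followed by a Wilks MANOVA with BH-corrected pairwise post hocs.
A single retained component routes to a one-way ANOVA.

## Morphometrics

Eight body proportions follow the standard limb-proportion formulas
(tail/body, forelimb/body, hindlimb/body, intermembral index =
100 × forelimb-without-hand / hindlimb-without-foot, hand and foot
relative to the limb without its autopod, pollex/hand, hallux/foot).
All are scale-invariant in the raw lengths; missing raw cells (fossil
rows) propagate to NA ratios rather than erroring.

EQ uses the Jerison reference allometry E[brain g] = 0.12 · (body g)^(2/3);
both constants are arguments, so a 0.75-exponent reference can be
swapped in. Endocranial volume converts to brain mass at 1.0 g/cm³
(standard paleoneurology convention, also configurable). Brain–body
allometry within a data set is checked by major-axis orthogonal
regression on natural-log masses: the slope is the leading eigenvector
of the 2×2 covariance (base-invariant; the intercept is on the
natural-log scale), with significance from the Pearson correlation at
n − 2 df.

## Trees

Trees are rooted, with branch lengths in millions of years; rescaling
to unit height happens only inside model fitting. The majority-rule
consensus retains rooted clades present in >50% of the input trees
(strict consensus available), with branch lengths averaged over the
trees containing each clade — the consensus flavor is configurable
because tree-set summaries differ between tools. Forced
ultrametricity extends terminal branches to the maximal tip depth,
leaving internal branches untouched. Fossil tips attach on the stem
branch of a named clade at a stem age; when the literature gives only
a tip age and a topological position, the stem age defaults to the
midpoint of the permissible interval on that branch. Grafting
preserves all pre-existing pairwise distances; extinct tips end above
the present, so the full tree is non-ultrametric while extant tips
remain contemporaneous.

## Phylogenetic signal

Blomberg's K is the observed MSE ratio (tip variance around the
phylogenetic GLS mean over phylogenetically corrected variance)
divided by its Brownian-motion expectation on the same tree. p-values
come from tip-label permutations with (b + 1)/(B + 1) smoothing
(default 50,000 iterations); the effect size is the observed statistic
standardized by the raw permutation distribution (a log-scale option
exists because conventions differ across implementations). K_mult
replaces sums of squares by Frobenius norms of the (optionally
PCA-reduced, 95% variance) trait matrix and reduces exactly to K for
one trait. Species-mean gait frequencies are the intended multivariate
input.

## Multiple imputation

Missing cells (fossil descent proportions and unpreserved morphology)
are handled under a single multivariate-normal model. EM provides the
mode of the observed-data likelihood (monotone log-likelihood,
ridge-stabilized on singular updates). Data augmentation then
alternates I-steps (missing cells from their conditional normal) and
P-steps (parameters from the normal–inverse-Wishart posterior under a
Jeffreys prior) for 50 steps, independently 5000 times by default;
each chain contributes its final completed draw. Point predictions are
means over chains, clamped to [0, 100] *after* averaging; intervals
are 2.5/97.5 percentiles. The response stays on the raw percent scale
(no logit), matching how such proportions are reported; predictors are
not standardized (the MVN model is equivariant to affine predictor
changes), except that body mass enters as log10. The head-first model
uses six predictors (log10 body mass, EQ, relative forelimb, hindlimb
and tail lengths, intermembral index); the side-descent variant
restricts extant rows to primates and uses relative hallux length
alone. Rows with no observed predictor are still predicted, from the
marginals, and flagged low-confidence. The procedure is deliberately
non-phylogenetic.

## Trait-evolution models

Five Gaussian models are fitted to a tip trait on the (possibly
fossil-bearing, non-ultrametric) tree: BM, early burst (rate decaying
as exp(r t), r ∈ [−10/height, 0]), single-optimum OU, two-rate BMM and
two-optimum OUM on a regime painting (a clade from its stem versus the
background). OU-family covariances use the exact patristic-distance
form, valid off-ultrametric trees; OUM tip expectations weight the
optima by the exponential occupancy of each regime along the
root-to-tip path.

**Root treatment.** The default fixes the root state at the root
regime's optimum ("theta" root, the convention of the standard
multivariate fitting tools). This choice nests BM exactly as
alpha → 0 and keeps the parameter counts BM 2, EB 3, OU 3, BMM 3,
OUM 4. A "stationary" root (root drawn from the stationary
distribution; same counts) and a "free" root (one extra parameter:
OU 4, OUM 5) are available. A genuinely stationary root does **not**
converge to BM as alpha → 0 — the diverging stationary variance along
the shared direction is penalized by the likelihood — which is why it
is not the default.

Fitting profiles the mean parameters and the scale analytically,
leaving a single structural parameter (EB rate, OU/OUM alpha on the
log scale with alpha ∈ [1e−4, 1e3]/height, BMM log rate ratio)
optimized by bounded L-BFGS-B from five grid points plus ten seeded
random restarts; the convergence flag reports the optimizer's own
status for the best start. Models are compared by AIC = 2k − 2lnL with
ΔAIC against the best; the phylogenetic half-life ln(2)/alpha is
reported for OU-family fits, conventionally after rescaling the tree
to unit height.

## Synthetic data

The generators emit every input format the pipeline reads, with ground
truth returned alongside, and defaults at the emulated study's design:
21 extant species in six phylogenetic groups (6 + 5 + 1 + 3 + 3 + 3),
3 individuals per species, up to 10 events per individual × support ×
direction, three support classes, 13 fossil tips (34 tips total).

- **Footfall events** realize each of the seven gait archetypes by
  construction: stride duration fixed, hindlimb midpoints placed,
  forelimb midpoints from the target limb phase (or girdle separations
  for asymmetrical gaits: stance targets 4% and 16%, clear of the 10%
  cut), contact widths from the duty factor (55/65/75% levels —
  climbing duty factors are high), then uniform jitter on the *event
  times* (default 1.5% of stride duration) and rounding to integer
  frames at 120 fps.
- **Bout tables** hold species-level strategy probabilities (primate
  groups split across side/tail-first; other groups head-first
  descenders), a descent/ascent speed ratio of 0.7 (descending
  head-first is slower by roughly a third in this literature), and
  direction-specific symmetrical-gait probabilities (0.65 ascending,
  0.35 descending).
- **Trees** are birth–death simulations (λ = 0.08, μ = 0.03/My,
  rescaled to 75 My height) conditioned on the extant tip count; the
  simulation stops at a speciation event, so every terminal branch is
  extended by a tenth of the height before the present to avoid a
  singular covariance. Fossils are grafted at random valid stem
  positions with positive tip ages.
- **Morphology matrices** draw the six predictors from a correlated
  Gaussian (limb lengths mutually correlated and with EQ, hindlimb
  with tail) and map a weighted predictor combination through a
  sigmoid onto 0–100%, plus percent-scale noise (SD 8). Signs follow
  the biology: heavier, larger-headed, longer-limbed and longer-tailed
  species avoid head-first descents. Fossil rows mask the response and
  apply a per-fossil template ("complete", "cranial-only",
  "postcranial-only").

What the synthetic data do **not** emulate: biomechanical dynamics,
within-individual correlation of successive strides, support-diameter
effects on kinematics, measurement error in lengths, and
phylogenetically structured morphology (predictors are drawn
independently of the tree). Passing tests therefore demonstrate the
correctness and calibration of the *procedures*, not that real
morphology predicts real behavior.

## Problem sizes in the standard checks

The packaged checks run at the study's scale where that is what is
being claimed (34-tip trees for signal calibration and OUM recovery;
21 + 13 morphology rows for imputation), and at asymptotic scale where
the claim is the calibration of a sampling procedure (type-I nulls,
above). Counts per check: 500 Brownian simulations for the K
calibration; 100 OUM replicates; 200 imputation replicates with 30
chains × 8 steps each (the 5000 × 50 default is a production setting —
the pooled mean stabilizes far earlier, and chains are embarrassingly
independent); 1000 replicates per type-I null; ~1000 jittered strides
per gait archetype.

## Known limitations

- The bootstrap wrappers are anticonservative at sparse-study scale
  (see above); no small-sample correction is attempted.
- EQ comparisons inherit the reference-allometry choice; within-sample
  brain–body slopes can be much shallower than the 2/3 reference, so
  EQ differences between distantly related groups conflate grade and
  allometry.
- The MI model is jointly Gaussian; strongly skewed predictors (hence
  the log10 body mass) and responses near 0/100% violate it, and
  clamping after averaging introduces a small bias toward the
  interior at the boundaries.
- Regime paintings are fixed hypotheses; no regime-discovery search is
  performed, and imputation uncertainty in fossil trait values is not
  propagated into the evolutionary-model comparison (point predictions
  are used).
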
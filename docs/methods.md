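# Methods

## The decomposition model

A 24-2 visual field is represented by its 54 total-deviation (TD) values
in dB on a canonical right-eye-oriented lattice (row-major from the
superior-temporal corner; left-eye fields are reflected about the vertical
midline at load, which on the stored vector is a within-row reversal and
an involution). The two locations overlying the physiologic blind spot,
(15°, ±3°), are kept in the vector by default: blind-spot enlargement is a
cardinal papilledema pattern and removing those points would erase it. A
52-location mode that drops them is available.

Archetypal analysis factorizes the cohort matrix X (n × 54) as X ≈ αZ with
Z = βX, where the rows of α (per-field loadings) and β (archetype
compositions) lie on the probability simplex. Archetypes are therefore
convex combinations of observed fields — extreme yet realizable TD maps on
the data's convex hull — and every field is a convex combination of
archetypes, reported as percentages summing to 100.

### Optimization

Both simplex-constrained least-squares subproblems are solved by the
classical penalty device: a constraint row with multiplier M = 200 × the
data scale is appended to the design and the problem passed to
non-negative least squares; solutions are renormalized to sum exactly to
one (the penalty leaves a deviation of order 1/M²). The many-fields
loading step uses a vectorized block-principal-pivoting NNLS on the normal
equations; columns whose Gram submatrices are rank-deficient fall back to
scipy's Lawson–Hanson solver, which is also used directly for the
(underdetermined) archetype-update projection.

The alternating fit performs exact coordinate minimization. The α-step is
an exact solve per field. The Z-step updates one archetype at a time: with
R_j the residual excluding slot j, the identity
‖R_j − α_j z‖² = ‖R_j‖² + ‖α_j‖²(‖z − v_j‖² − ‖v_j‖²) with
v_j = α_jᵀR_j/‖α_j‖² shows that projecting v_j onto the convex hull of the
data rows is the exact minimizer over β_j. Both half-steps are therefore
nonincreasing in the objective, and the per-iteration RSS trace is asserted
monotone (to 1e-6 relative, the penalty/renormalization tolerance) in
every test fit. An archetype whose loading column collapses to zero is
reseeded at the worst-fit field.

Initialization: furthest-sum seeding for the first restart; uniformly
random row subsets for later restarts (furthest-sum is deterministic given
its single random anchor, so repeating it explores almost nothing — on
small instances this mattered for reaching the global optimum). Defaults:
5 restarts, 200 iterations, relative-RSS tolerance 1e-6. Same seed ⇒
bit-identical model.

Fitted archetypes are ordered by relative weight (mean loading over the
fitted fields) descending; ties break by average TD descending, then by
index. Weights are kept at full precision; any rounding is display-only.

## Model-order selection

Training RSS and 10-fold cross-validated RSS are computed for each k
(default 2–20). The CV figure accumulates held-out RSS over the folds —
every row is held out exactly once — so it is directly comparable to the
training RSS; a per-fold mean would differ only by the constant factor
`folds` but would break that comparability. The default elbow rule
normalizes both axes to [0, 1] and picks the k furthest from the chord
joining the curve's endpoints (scale-free); a relative-drop rule (first k
improving by less than 5%) is the alternative. Selection uses the CV
curve; both curves are always exported. Degenerate curves (flat or exactly
linear) return the smallest k with a warning.

## Control calibration of the meaningful-weight threshold

All fields from a healthy-control cohort are decomposed against the
disease model. Statistics are computed across eyes, not visits: each eye's
weights are first averaged over its visits so repeated testing cannot
shrink the intervals. The per-eye weight change is the mean absolute
difference between each follow-up visit and the eye's first visit
(baseline-anchored; consecutive-visit differences are available).
Confidence intervals are normal-approximation mean ± 1.96·SE across eyes,
with a seeded percentile bootstrap (2000 resamples) as an option.

Archetypes with average TD ≥ −1 dB are classed "normal" and excluded from
the threshold maximum (an explicit list can override). The threshold is
ceil(largest abnormal upper 95% CI, pooling weight and change intervals)
plus a margin, default 2 percentage points — the margin absorbs the
multiplicity of testing ~14 archetypes at once, so a control cohort whose largest abnormal upper CI is 7% yields the
conservative ≥9% rule used in practice.

## Scoring

Meaningful archetypes are those with weight ≥ threshold (boundary
inclusive); a dominant archetype carries ≥ 50% (an exact 50/50 tie is no
dominant archetype). The AT Sum composite assigns +1 to the half of the
archetypes with higher average TD (median split; odd k puts the median on
the positive side; an explicit partition can override) and −1 to the rest,
then sums the signed percentages, giving a score in [−100, 100] with lower
values = worse field function. Expert-label matching compares small
feature-tag sets (controlled vocabulary) as exact / partial (nonempty
intersection) / different; archetype→tag maps are user configuration,
since tagging is a clinical judgment. Cohort reports use Spearman
correlations (average ranks for ties, t-approximation p-values), Wilcoxon
rank-sum tests between two groups, and a χ² test on the 2×k
above-threshold frequency table; p-values are raw by default with an
optional Holm adjustment.

## Cohort curation

Reliability follows the trial cutoffs: fixation losses < 33% and false
positives < 15%; unreliable fields are dropped. Replicates at one visit
are averaged pointwise. Treatment failure is a confirmed MD drop from
baseline: ≥2 dB when baseline MD ≤ −3.5 dB, else ≥3 dB, confirmed when the
next available test shows the same-magnitude drop. (The two strata are
stated overlappingly in the source literature; this reading is the one
consistent with its worked numbers.) Curation to the six-month outcome
window drops later visits; for treatment failures the failure-visit field
is substituted forward through month 6 and post-confirmation tests are
excluded; for performance failures only reliable (confirmatory) fields are
retained — the unreproduced worsening tests are exactly the unreliable
ones in this data model.

MD and PSD for synthetic or averaged fields are surrogates: the unweighted
mean and the sample SD of the 52 non-blind-spot TD values. The
instrument's proprietary variance-weighted indices down-weight the
variable periphery; the surrogates do not, so absolute MD values are
comparable only within this package.

## Synthetic data: what it emulates and what it does not

The generator composes each eye's fields as Dirichlet(0.3) mixtures over
eight hand-authored prototypes (normal, mild uniform −3 dB depression,
severe eccentricity-graded −16…−24 dB depression, blind-spot enlargement,
superior/inferior arcuate respecting the horizontal midline, nasal step,
temporal hemianopia) plus iid Gaussian noise (default SD 1.5 dB per
location, clipped to [−40, +10] dB). The severe-depression gradient keeps
the library affinely independent (two uniform maps would be parallel), so
noiseless mixtures are exactly identifiable. The surrogate MD is linear in
the mixing weights, so baseline severity is set by blending the drawn
weights toward a corrective prototype in closed form until the target MD —
drawn inside the trial inclusion window of −7 to −2 dB — is met, noise
included, for every baseline replicate.

The visit schedule follows the trial: two baseline tests, one test at
months 1–5, two at month 6. Controls are 61 eyes × 9 visits ≈ the real
control dataset's size, all normal-prototype + noise. Most trial eyes
improve (weights decay toward the normal prototype at a per-eye rate drawn
from U(0.05, 0.30) per month); 4% of eyes instead worsen linearly toward
severe depression steeply enough (target drop = stratum threshold
+ 0.8 dB, ~3σ of the measured-MD noise) to trip the confirmed failure
rule; 2.5% of fields carry failing reliability indices (≈ the source
trial's unreliable fraction).

Not emulated: spatially correlated test-retest noise, eccentricity- or
severity-dependent variance, learning/fatigue effects, demographics, or
acuity. Passing tests therefore demonstrate correctness of the estimation
machinery under an idealized noise model, not clinical performance on real
perimetry.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale chosen as realistic for
the statistics involved: recovery experiments use 300–500 fields from 4
planted prototypes; the model-order experiment uses 80-field cohorts,
k = 2–8, 10 folds, 20 independent seeds; calibration uses 61 control eyes.
Cross-validation fold fits use 1 restart and a capped iteration budget
(the curve's shape, not its converged floor, drives the elbow). The
bundled analysis study uses 120 trial eyes (~1100 fields) and k = 2–12.

Degenerate inputs: k = n is allowed (archetypes are the data rows) with a
warning; k > n, non-finite data, empty cohorts, single-eye calibration,
and fold sizes below one row raise validation errors. Decomposition is
deterministic and seed-free.

## Known limitations

- The alternating fit finds local optima; restarts mitigate but do not
  guarantee global optimality beyond the tiny instances where it is
  verified exhaustively.
- The threshold's +2 margin is a configurable default, not a derived
  multiplicity correction.
- Surrogate MD/PSD differ from the instrument's weighted indices (above).
- The χ² frequency-table test counts eyes once per archetype, as reported
  in the field; it is a descriptive comparison, not a strictly valid
  contingency test.
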
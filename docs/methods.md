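# Methods

## Task model

The search task is modeled as a belief MDP.  The hidden state is the target
location; the prior `P_T` is uniform (1/N) over the N grid cells inside the
shape, or proportional to the soft cell membership of a foveated shape.  An
action is a fixation location; a cell is *covered* when its Euclidean
distance to a fixation is strictly below the search radius (6.5° of visual
angle; the strict inequality is kept as specified).  Detection probability
is the belief mass of the union of covered cells, and the probability of a
correct present/absent response is affine in it
(`prevalence·DP + (1−prevalence)` for the "respond present iff detected"
rule), so all argmax policies are unaffected by the proportionality
constant.

The per-step reward is `r = 100·DP − α·amplitude` with the cost weight α in
% detection performance per degree and amplitude in degrees.  The discount
γ is fixed at 1: the horizon is finite (at most two fixations) and nothing
in the task motivates discounting.  Planning is open loop — the horizon-2
policy is the joint argmax of the expected total reward over ordered
fixation pairs; termination on detection only matters for target-present
trials, which the behavioral pipeline removes.

## Solvers

Fixation candidates are lattice points at the solver resolution within one
search radius of the shape support, plus the exact start location.  A cell
outside that set covers zero mass and is weakly dominated by staying at the
start (reward ≥ 0 there versus < 0 for any α > 0; at α = 0 the tie resolves
to the start by the amplitude tie-break), so pruning does not change the
argmax; the test suite checks the solvers against a full-bounding-box
exhaustive enumeration on small grids.

Default resolution is a coarse 1.0° candidate grid followed by a local
0.25° refinement within a ±1° window around the coarse optimum (fitting
uses a 0.5° grid with the same refinement; stimulus screening uses the
coarse grid alone).  The prior is aggregated onto the solver lattice by
mass summation; refinement re-evaluates coverage against the full-resolution
prior.

Ties are broken deterministically: maximal score, then minimal (total)
saccade amplitude, then — for fixation pairs — maximal first-fixation
coverage, then row-major (y, x) order taken in the *task frame* (x running
away from the start side), which makes tie resolution commute with
mirroring the display.  The early-coverage stage exists because detection
after the first fixation already ends the search: of two equally rewarding,
equally long scanpaths, the one covering more mass first is behaviorally
prior.  Without it, a shape fully coverable by one fixation admits a
degenerate optimum ("stay at the start, then saccade") of equal amplitude.

The MAP searcher fixates the cell of maximal posterior mass (ties: distance
to current gaze, then row-major order) and renormalizes the posterior to
uncovered cells before its second step.

## Foveation

The contrast threshold `CT(f, e) = CT0·exp(α_c·f·(e + e2)/e2)` with
CT0 = 1/75, α_c = 0.106, e2 = 2.3° yields the cut-off frequency
`f_c(e) = e2·ln(CT_max/CT0)/(α_c(e + e2))` at contrast ceiling
CT_max = 1.  Rendering uses a Gaussian pyramid whose level k has
half-amplitude frequency `f_max/2^k` (f_max ≈ 40.73 cycles/deg, the foveal
cut-off); each cell is interpolated linearly between the two levels
bracketing its local cut-off.  The blur-width conversion is the Gaussian
half-amplitude relation σ = 0.1874/f_c (degrees).  Note that at the default
0.25° grid the implied blur is sub-cell for eccentricities inside a typical
display — foveation perturbs the prior only near shape boundaries and only
weakly, which is the physically expected magnitude.

The foveated values feed the policies as target-location prior weight; this
is a modeling choice (the mechanism by which degraded shape knowledge
enters the reward is underdetermined) and is isolated behind
`target_prior`.  For the second fixation of a two-saccade trial the shape
is re-foveated at the executed first landing in simulation mode, or at the
empirical mean first landing in data-fitting mode.

Undershoot is a post-hoc transform: planned targets are chosen without
compensation and executed landings shrink each saccade by the factor
(1 − u), the second saccade launching from the executed first landing.  An
aim-beyond compensation mode exists behind `ModelSpec.compensate_undershoot`
but is off by default.

## Stimuli

Shapes follow the experimental recipe: five points uniform in a centered
23.24° square, an interpolating closed (periodic) cubic B-spline through
them (chord-length parameterization; degree and parameterization are
choices, as the recipe states neither), rasterization by an even-odd
point-in-polygon rule (so self-intersecting outlines produce two-lobed
shapes; nonzero winding is available), upscaling by 1.5 about the bounding
box center, and centering on the screen.  The white-noise fill is cosmetic
metadata (a stored seed); only the mask drives computation.  Mirroring is
x-negation on a grid built symmetric about both axes, so a double mirror is
bit-exact.

Model-driven selection screens every candidate at the 1.0° solver
resolution and ranks divergent shapes by descending greedy-vs-planned
first-fixation distance and coincident shapes by ascending *whole-scanpath*
distance; ranked finalists are then re-solved at the 0.5° + refinement
resolution and accepted only if the category survives.  The two-stage check
matters: agreement of first fixations at a coarse resolution does not imply
agreement of full scanpaths at the resolution the analyses use, and only
whole-scanpath agreement makes a shape genuinely uninformative about
planning.  An area-similarity filter (±35% of the category median) is
applied within each category, because coincident shapes are systematically
smaller — agreement is easiest when one or two fixations cover everything.
Coincidence is a property of the base (cost-free) models; large saccade
costs can re-split policies on a nominally coincident shape.

## Behavioral pipeline

Trial filters run in a fixed order with telescoping counts: (1) trials
whose gaze never entered the shape, (2) trials with the wrong number of
fixations for their condition (1 short / 2 long), (3) target-present trials
regardless of outcome.  Stage percentages use the preceding stage's
denominator.  Strategy clustering (full-covariance Gaussian mixtures,
k ≤ 3 selected by BIC, only the most frequent component kept) is applied
only to shapes flagged multimodal — by default those with two 4-connected
lobes — and separately per shape *and condition*: strategy modes are
alternative scanpaths under the same task demand, and pooling conditions
would mistake a genuine short-vs-long difference for a strategy split.

Subject summaries reflect mirrored trials to the canonical orientation,
then average within subject per (shape, condition, fixation index) slot.
The condition contrast is the two-sample Hotelling T² on bivariate means
with pooled covariance, `F = T²(n1+n2−p−1)/(p(n1+n2−2))`, p = 2.

## Fitting and model comparison

Observations are the per-subject mean fixation vectors per slot.  Error
covariances are estimated per slot from the subject means once
(ridge-regularized by 1e-6) and shared across models; they are not counted
as free parameters — only α and u are — so BIC differences are driven by
policy structure.  Parameter search is a deterministic grid (α ∈ [0, 2]
step 0.05; u ∈ [0, 0.10] step 0.005) with no stochastic restarts.  The
likelihood is piecewise constant in α (the discrete argmax changes only at
switch points), so the α estimate is the midpoint of the maximizing
plateau; u enters the predictions continuously and is polished by bounded
scalar minimization.  Estimates on a grid boundary are flagged as pinned.
An optional third parameter, the search radius, is implemented behind the
"radius" extension and off by default.

The ladder's floor is the saturated lower bound: slot means taken directly
from the data, two free parameters per slot.  ΔBIC > 4.6 is flagged
decisive.  BICs are only compared across fits with identical observation
sets.

## Synthetic experiments

`SimConfig` defaults encode the study design: 16 subjects, four 100-trial
blocks ordered SSLL or LLSS (alternating across subjects), target
prevalence 0.5, mirrored layouts at random, nuisance rates 0.23% (gaze
never on shape) and 17% (wrong fixation count), generating policy =
planning observer with α = 0.3 and u = 0.03.  Scatter magnitudes are
declared assumptions, not reconstructions: isotropic 1.0° SD per-trial
noise and 0.5° SD per-subject offsets (applied in the canonical frame, so a
subject's bias follows the shape layout under mirroring).  Fixation
timestamps are schematic (onsets 130 + 250k ms, 200 ms durations).

Target-present trials draw the target uniformly from the shape's cells and
score detection against the trial's noisy fixations.  When a long-condition
trial finds the target on the first fixation the search terminates; the
trial records the gaze capture on the target as its second fixation.  This
keeps the wrong-fixation-count filter's measured rate equal to the planted
nuisance rate (a truncated trial would otherwise be misclassified as a
count failure), and the affected trials are target-present and leave the
analysis at the next filter stage anyway.

What passing the recovery tests shows — and what it does not: the synthetic
generator shares the solver family with the fitted models, so recovery
demonstrates the internal consistency and identifiability of the pipeline
(given divergent stimuli, α to roughly the plateau width, u to ~0.01,
policy identity decisively), not that real human data would be fit equally
well.  Real gaze data contain oculomotor structure the generator omits:
saccade latencies and durations, corrective saccades, endpoint variability
growing with amplitude, drift, and condition-dependent strategy shifts
beyond the two-component mixture.

## Problem sizes

Default analysis sizes were chosen to keep every study a desk computation:
stimulus selection screens ~120 candidates (growing adaptively if a
category cannot be filled); fitting solves on a 0.5° grid with 0.25°
refinement; the recovery study runs 20 seeds of the full 6400-trial design
on the two divergent shapes; the Hotelling calibration uses 2000 null
replicates at n = 16 per group.  Coverage geometry is cached per shape, so
repeated fits re-use the pairwise structures.

## Known limitations

* Open-loop planning only; closed-loop observation branching and horizons
  beyond two fixations are out of scope, as is fixation-event detection
  from raw gaze samples.
* The α estimate is interval-identified by construction; its reported value
  is a plateau midpoint and its precision is limited by the solver
  resolution, not by data volume.
* Foveation of the white-noise texture (as opposed to the mask boundary) is
  not modeled; neither are luminance or color.
* The headline fitted quantities of the original experiment can only be
  recomputed on the deposited behavioral dataset;
  `fitting.evaluate_external_dataset` runs the ladder when such a file is
  supplied and refuses cleanly otherwise.  Exact BIC values additionally
  depend on the parameter-counting convention documented above, which is
  applied uniformly inside this package's ladder.
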
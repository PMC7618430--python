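# Methods

## The scientific setting

`gridmapnav` studies how a *grid map* navigation mechanism can emerge through
learning. A navigator senses two scalar environmental gradients (think
magnetic intensity and inclination, or two odourant concentrations) whose
values jointly specify position relative to a goal. Small feedforward
networks are trained online to output the compass direction of a fixed goal
from the two sensed values, and at successive training checkpoints their
orientation errors over a test grid are compared against the error patterns
predicted by nine analytic navigational models. The question is not whether
the networks learn (they do), but *which mechanism* their behaviour matches
at each stage of learning.

## Environments

Every environment pairs the fixed linear field `A = (x − k1)/k2` with one of
seven second fields:

| case | raw form        | geometry vs A                  |
|------|-----------------|--------------------------------|
| B1   | `y`             | linear, orthogonal             |
| B2i  | `x − y`         | linear, oblique                |
| B2ii | `x − 2y`        | linear, oblique                |
| B3i  | `x − (y−1)²`    | curved, oblique at the goal    |
| B3ii | `x − 0.2(y+2)²` | curved, oblique at the goal    |
| B4i  | `e^y`           | curved, orthogonal             |
| B4ii | `(6 − y)³`      | curved, orthogonal             |

The B4 fields vary along y: the defining property of this family is that the
direction of variation is everywhere orthogonal to field A (which is what
makes the approximate and correct combination rules coincide there, and the
directional model insensitive to the extrapolation rule).

**Normalization constants.** For each field, `k1` is chosen so the field is
exactly zero at the goal (the origin), and `k2` so that every field spans the
same range as field A over a normalization region — by default the
[−5, 5]² test square, with the training disc available as a config option.
These are the package's own choices for constants that are otherwise only
constrained to "standardise the range" of the fields; they are recorded in
every run manifest.

**Geometry.** Training locations form a polar grid: 160 distances
(0.025 to 4.000 in steps of 0.025) × 90 directions (every 4° clockwise from
the +y axis) = 14 400 points, denser near the goal by construction. Test
locations form a 101 × 101 Cartesian grid over [−5, 5]² at 0.1 spacing,
built by exact integer-index stepping so the endpoints carry no
floating-point drift. The goal gridpoint (0, 0) is flagged and excluded
from every angular-error aggregate (its direction is undefined).

**Angle convention.** All directions are compass angles: measured from +y,
increasing clockwise, in [0, 2π). Signed errors are
`wrap(heading − true direction)` in (−π, π], so a positive signed error is a
clockwise deviation. The convention lives in a single utility module
(`angles.py`) and can be changed in one place.

## Navigational models

A model is a pair (combination rule, extrapolation rule). Writing
ΔF = F(p) − F(goal) for the sensed offset in one field and g for that
field's extrapolation gradient:

* **Displacement estimate** per field: `d = ΔF · g / |g|²` — the
  displacement along g that accounts for the sensed offset.
* **APPROX** combines the two per-field displacements by vector addition and
  heads along `−(d_A + d_B)`. Exact when the fields are linear and
  orthogonal; predictably biased in oblique grids.
* **DIRECTIONAL** uses only directions: heads along
  `−(sign(ΔA)·ĝ_A + sign(ΔB)·ĝ_B)`. A field on its goal isopleth
  (ΔF = 0) contributes nothing.
* **CORRECT** solves the 2 × 2 linear system `G·D = (ΔA, ΔB)` (rows of G are
  the two gradients) and heads along `−D`. Exact for truly linear fields;
  undefined when the gradients are near-parallel (condition number above
  10⁸ → the location is marked missing rather than producing an
  astronomically amplified heading).

Extrapolation fixes where g is taken: at the goal (**target-based**), at the
current location (**release-based**), or as the component-wise mean gradient
over all training locations (**training-based**; raw vectors, not unit
vectors, are averaged — the average vector along which the field varies).
ΔF itself always uses the true, possibly non-linear field values; only the
conversion of ΔF into a spatial displacement is linearized.

Two structural facts the test suite pins down:

* In linear environments the three extrapolations are identical, and CORRECT
  reproduces the true goal direction everywhere.
* The polar training grid is symmetric about y = 0, so for the B3 fields
  (quadratic in y) the mean training gradient equals the goal gradient:
  target- and training-based extrapolation coincide *exactly* there. The
  comparator set is therefore built by numerical deduplication of the nine
  maps — only models with unique, non-zero predictions are kept, with
  collapsed labels such as `APPROX-Ta/Tr` or `APPROX/CORRECT-Tr`.

## Learners

Both implementations are multilayer perceptrons with 2 inputs (the two field
values), hidden layers 10-100-200-500-200-100 with ReLU, and sigmoid
outputs, trained with batch size one for a single epoch (each training
location seen at most once — a deliberately constrained, biologically
conservative regime).

* **Implementation 1** (regression): one output unit encoding goal direction
  in turns (degrees/360) relative to a per-network random baseline
  direction; loss is the squared *circular* difference (the raw output −
  target difference wrapped to [−0.5, 0.5] before squaring, with the
  gradient taken through the chosen branch); optimizer is plain gradient
  descent with learning rate 0.001 and Nesterov momentum 0.9. An unwrapped
  variant of the loss is available behind `wrap_loss=False`; the wrapped
  form is the default because a directional error is circular and an
  unwrapped loss would penalize near-identical directions across the 0/1
  seam — the very bias the random baseline direction exists to control.
* **Implementation 2** (classification): 20 output units, one per equal
  circular sector in a per-network randomly rotated frame; summed binary
  cross-entropy; Adam with standard defaults (lr 0.001, β₁ 0.9, β₂ 0.999,
  ε 10⁻⁷). Decoding takes the argmax sector's centre angle (ties to the
  lowest index); a circular-expectation decoder is available behind config.

Weight initialization is Glorot-uniform (the standard fan-balanced scheme),
fully seeded. The forward/backward passes and both optimizers are
implemented directly on numpy arrays; backpropagated gradients are checked
against central finite differences on a reduced architecture in the test
suite.

**Population trainer.** Replicates are independent (own seed, own baseline
direction, own shuffled data order) but architecturally identical, so the
experiment layer trains them in lockstep on stacked (replicate, fan-in,
fan-out) float32 tensors. This is an execution strategy, not a model change:
the lockstep path is tested to reproduce the per-network float64 reference
path to float32 precision. Checkpoint evaluation is a pure forward pass over
the test grid and cannot perturb training state.

## Scoring and statistics

At each checkpoint (0, 100, 250, 500, 1000, 2000, 4000, 8000, 14000
datapoints) each network's headings over the test grid are reduced to a mean
absolute angular difference against each comparator: `PERFECT` (the true
goal directions) and every distinct navigational model. Differences are
wrapped, absolute values lie in [0, π], and undefined map locations are
excluded pairwise (a warning fires if fewer than 90% of locations remain).

The comparator fits are compared with the mixed model

    mean_abs_diff ~ comparator + (1 | network_id)

The fit table is balanced by construction, so the REML solution is computed
in closed form from the two-way layout: fixed-effect comparator means are
the cell means; σ²_resid = MS_residual with (n−1)(k−1) degrees of freedom;
σ²_network = (MS_network − MS_residual)/k truncated at zero (at the boundary
the model collapses to OLS and the residual pools the network sum of
squares, flagged in the result). A contrast between two comparators is a
within-network comparison whose variance involves only σ²_resid, so
Satterthwaite's degrees of freedom reduce exactly to the residual degrees of
freedom; with two comparators the whole procedure reproduces the paired
t-test, which the suite asserts to 1e−6. The closed form is additionally
cross-checked against a numerically fitted mixed model (statsmodels MixedLM)
on simulated tables. Tests are two-sided at the 5% level with no
multiple-testing correction (matching the reporting convention the package
reproduces); per-checkpoint summaries report each comparator's mean
difference relative to the PERFECT baseline plus two significance
annotations: best model vs the baseline, and best model vs the next best.

## Problem sizes and defaults

The full-scale study design is 100 replicates per environment and
implementation (200 in B3i/B3ii, which have the most models to
distinguish); this is available as the `paper` scale preset. The default
`desk` preset uses 20 replicates, which is enough for the qualitative
ontogeny (the approximate model's transient advantage in oblique
environments is reported at p < 0.001 at full scale and remains clearly
detectable at n = 20). The acceptance script and test suite run at desk
scale; the learning-rate-ordering check (simplest environment learned
fastest) uses 8 replicates truncated to 2000 datapoints, where the ordering
is already unambiguous.

## What the generator does and does not emulate

The environments are noiseless, stationary analytic fields sensed with
perfect accuracy, and the training order is a uniform shuffle — there is no
exploration trajectory, no sensory noise, no wind/current/compass
disturbance, and no anomaly-bearing gradients. Passing tests therefore show
that the learning-and-comparison machinery behaves as specified under ideal
sensing, not that real animals (whose cue fields are noisy, drifting and
explored along autocorrelated paths) would produce equally clean model
signatures. The per-replicate random baseline direction is the one
implementation bias the design deliberately randomizes and averages over.

## Numerical choices

* Wrapping maps differences to (−π, π] with the half-turn assigned to +π.
* CORRECT solves are rejected above condition number 10⁸ (missing value).
* Sigmoid outputs are clamped to [10⁻⁷, 1−10⁻⁷] inside cross-entropy.
* `sign(0)` contributes a zero vector in DIRECTIONAL (no cue from a field
  on its goal isopleth); if both cues vanish the heading is undefined.
* Map deduplication uses 10⁻⁹ rad tolerances; extrapolation-invariance in
  linear environments holds to 10⁻¹².
* Per-replicate seeds derive from the master seed via `SeedSequence`
  spawning; every derived seed is logged in the run manifest.

## Known limitations

* The lockstep trainer holds all replicate weights in memory
  (~10 MB/replicate in float32); hundreds of replicates are fine, thousands
  are not.
* The closed-form mixed model requires a balanced fit table; unbalanced
  data (e.g. after dropping a failed replicate) must be rebalanced first.
* Only two gradients and a single goal are supported; anomaly-bearing or
  time-varying fields are out of scope.
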
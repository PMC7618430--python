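# gridmapnav

How could *grid map* navigation — homing by reading two intersecting
environmental gradients, as proposed for birds, turtles and other
long-distance navigators — arise through learning, and which mechanism does
a learner actually use at each stage? `gridmapnav` is a simulation package
for asking that question in silico. It provides:

* **Seven two-gradient environments**: a fixed linear field `A = (x−k₁)/k₂`
  paired with a second field that varies linearly-orthogonally (B1),
  linearly-obliquely (B2i, B2ii), non-linearly and obliquely (B3i, B3ii) or
  non-linearly and orthogonally (B4i, B4ii), all normalized to zero at the
  goal and to a common range. The goal sits at the origin; training
  locations form a dense polar grid (14 400 points within radius 4), test
  locations a 101 × 101 Cartesian grid over [−5, 5]².
* **Nine analytic navigational models** — three rules for combining the two
  cues into a heading crossed with three rules for linearly extrapolating a
  field's spatial structure. Writing ΔF = F(p) − F(goal) and g for the
  extrapolation gradient, each field yields a displacement estimate
  d = ΔF·g/|g|², and the heading is the direction of −(d_A + d_B)
  (**approximate**), of −(sign ΔA·ĝ_A + sign ΔB·ĝ_B) (**directional**,
  magnitudes ignored), or of −D where G·D = (ΔA, ΔB) is solved conjointly
  (**correct**). The gradient g is taken at the goal (**target-based**), at
  the current location (**release-based**), or as the mean over experienced
  locations (**training-based**).
* **Two online-learning perceptron navigators** (hidden layers
  10-100-200-500-200-100, ReLU; batch size 1, single epoch): a regression
  network with one sigmoid output encoding direction in turns against a
  random per-network baseline (squared circular error, SGD with Nesterov
  momentum), and a classification network with 20 sigmoid sector outputs in
  a randomly rotated frame (binary cross-entropy, Adam).
* **A mixed-effects comparison** of which comparator — perfect performance
  or any distinct navigational model — best fits the population of learners
  at each checkpoint: `mean_abs_diff ~ comparator + (1 | network)`, with
  Satterthwaite t-tests at the 5% level.

## Worked example

Train 20 regression networks in the oblique linear environment B2i and ask,
checkpoint by checkpoint, which comparator fits them best:

```python
from gridmapnav import (NetworkConfig, TrainingSchedule, make_environment,
                        run_population, score_population, test_locations)
from gridmapnav.stats import compare_across_checkpoints

env, loc, sch = make_environment("B2i"), test_locations(), TrainingSchedule()
headings, seeds = run_population(env, NetworkConfig(implementation=1), sch,
                                 master_seed=1, n_replicates=20, locset=loc)
table = score_population(headings, env, loc, sch, implementation=1)
for r in compare_across_checkpoints(table):
    print(r.checkpoint, "best:", r.best_model,
          {k: round(v, 3) for k, v in r.comparator_means.items()},
          "p vs perfect %.2g" % r.p_best_vs_perfect)
```

prints (about 10 minutes on one CPU):

```
0     best: APPROX  {'APPROX': 1.583, 'DIRECTIONAL': 1.584, 'PERFECT': 1.583} p vs perfect 0.93
100   best: APPROX  {'APPROX': 1.461, 'DIRECTIONAL': 1.464, 'PERFECT': 1.47}  p vs perfect 0.046
250   best: APPROX  {'APPROX': 1.291, 'DIRECTIONAL': 1.3,   'PERFECT': 1.31}  p vs perfect 0.0017
500   best: APPROX  {'APPROX': 1.013, 'DIRECTIONAL': 1.042, 'PERFECT': 1.082} p vs perfect 1.5e-05
1000  best: APPROX  {'APPROX': 0.632, 'DIRECTIONAL': 0.707, 'PERFECT': 0.766} p vs perfect 1.3e-07
2000  best: APPROX  {'APPROX': 0.614, 'DIRECTIONAL': 0.695, 'PERFECT': 0.677} p vs perfect 0.00025
4000  best: PERFECT {'APPROX': 0.626, 'DIRECTIONAL': 0.678, 'PERFECT': 0.533} p vs perfect 2.6e-07
8000  best: PERFECT {'APPROX': 0.588, 'DIRECTIONAL': 0.619, 'PERFECT': 0.374} p vs perfect 1.8e-10
14000 best: PERFECT {'APPROX': 0.564, 'DIRECTIONAL': 0.575, 'PERFECT': 0.286} p vs perfect 7.9e-15
```

Each number is a population mean absolute angular difference (radians, in
[0, π]) between network headings and a comparator's predictions over the
test grid. Untrained networks sit at chance (≈ π/2 ≈ 1.571 against
everything). During intermediate training (500–2000 datapoints) the
networks' *errors* match the approximate model's predicted errors better
than they match perfect performance — the learners have adopted the
approximate mechanism, biases included. With further training they improve
past it: by 14 000 datapoints perfect performance fits best. That
transient adoption, and its eventual abandonment, is the package's central
reproducible result.

A command-line surface wraps the same pipeline:

```bash
gridmapnav maps -e B2i -o results/maps          # analytic error maps (CSV)
gridmapnav train -e B2i -i 1 -r 20 -s 1 -o run  # fit table + manifest
gridmapnav compare run/fit_table.csv -o run     # best model per checkpoint
```

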
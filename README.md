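# ivjoint

Identification of a lumped-parameter intervertebral-joint (IVJ) model from
tracked spine-segment kinematics, with a full joint-pose sensitivity
pipeline.

## The problem

Multibody models of the spine represent everything between two vertebrae —
disc, ligaments, facets — as a single 6-DoF *bushing* joint: uncoupled
linear springs and dampers acting along and about the joint's axes. Two
ingredients must be personalised from experiment: the **joint pose** (centre
of rotation and axis orientation, usually derived from virtually palpated
anatomical landmarks) and the **stiffnesses**. Given measured vertebral
motion under a known load, the stiffnesses can be found by optimisation —
but the joint pose is only known up to inter-operator palpation scatter
(resultant SD ≈ 2.9 mm), and the identified stiffness turns out to be
highly sensitive to it.

`ivjoint` implements that identification loop end-to-end for a potted
L1–L4 lumbar segment under an eccentric compressive ramp load (54 N over
1 s), plus the sensitivity machinery around it, driven entirely by a
synthetic-data generator so every stage is testable without experimental
data:

- **kinematics** — rigid-transform algebra, least-squares (SVD/Kabsch)
  registration of labelled point sets, motion re-expressed about a joint
  (`T_local = J⁻¹ T J`, intrinsic Z–X–Y Euler angles);
- **frames** — ISB-style vertebral frames and joint poses from four
  landmarks; Latin-Hypercube sampling of palpation-perturbed landmark sets;
- **model** — rigid-body chain with bushing joints; mesh inertia by
  signed-tetrahedron decomposition; quasi-static equilibrium (root-find)
  and transient dynamics (ramp loading);
- **identify** — the weighted cost
  `cf = Σ wᵢ (pᵢ − mᵢ)²` over 8 DoF (AP/axial/RL translation + FE rotation
  of L2 and L3, in mm and degrees, weights 10/100/1/1), minimised over
  log₁₀ of (k_ap, k_is, k_fe) within literature-derived bounds, with
  success / local-minimum / outlier classification (1 % and 10× rules);
- **study** — pose-sensitivity population runs, the *reduced dataset*
  filter, two-factor (pose × stiffness) grids, bootstrap over initial
  parameters, summary tables;
- **stats** — chi-squared/KS normality screening, Spearman / Kendall tau-b
  with Bonferroni correction, Friedman blocked test, pruned regression-tree
  importance (pose block vs stiffness block), Bland–Altman;
- **synthetic** — the generator for geometry, ground-truth poses and
  stiffnesses, and simulated DIC-like measurements at 25 Hz.

See `docs/methods.md` for model details, conventions, defaults and
limitations.

## Worked example

```python
from ivjoint import make_synthetic_spine, simulate_experiment, optimise_stiffness
from ivjoint.study import ForwardEvaluator, measured_about_poses

truth = make_synthetic_spine(seed=1)                  # L1-L4 chain + ground truth
exp = simulate_experiment(truth, "quasistatic", seed=2)
measured = measured_about_poses(exp.measured_transforms, truth.joint_poses)
forward = ForwardEvaluator(truth, truth.joint_poses)
res = optimise_stiffness(forward, measured)
print(res.classification, round(res.final_cost.total, 5))
print({d: round(getattr(res.k_opt, d), 1) for d in ("k_ap", "k_is", "k_fe")})
```

prints

```
success 0.00027
{'k_ap': 25223.1, 'k_is': 442006.2, 'k_fe': 30.0}
```

i.e., starting from the literature initial guess (24,600 / 110,000 N/m,
37 N·m/rad) the optimiser recovers the generator's ground-truth stiffnesses
(25,000 / 440,000 N/m, 30 N·m/rad) to well within 1 % despite the injected
measurement noise; the residual weighted cost of 3e-4 corresponds to
sub-micrometre and milli-degree kinematic errors. Re-running the same
identification with joint poses rebuilt from palpation-perturbed landmarks
(resultant SD 2.9 mm) scatters the identified stiffnesses by an order of
magnitude — the package's central sensitivity result:

```
ivjoint --seed 7 --n-samples 50 --out results/sens sensitivity
```

writes `models.csv` (one row per perturbed-pose model: identified
stiffnesses, per-DoF kinematic errors in mm/degrees, classification) and
summary tables of medians, IQRs and pose dispersion.

The `ivjoint` CLI exposes the stages as subcommands — `synth`, `simulate`,
`identify`, `sensitivity`, `twofactor`, `bootstrap`, `stats`, `report` —
each writing a results directory with a reproducibility manifest; all
randomness is routed through `--seed`.

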
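# Methods

## The model

A cadaveric lumbar spine segment (L1–L4, caudal vertebra potted and fixed,
cranial vertebra merged with the loading pot) is represented as an open chain
of rigid bodies connected by lumped intervertebral joints (IVJs). Each IVJ is
a 6-DoF *bushing*: six uncoupled linear spring–damper elements, coincident
and aligned with the joint frame, so no kinematic constraint is imposed — all
six degrees of freedom are elastic. Axes follow the ISB convention used
throughout the package: X anterior, Y superior, Z right; flexion–extension
(FE) is rotation about Z, lateral bending (LB) about X, axial rotation (AR)
about Y.

The bushing law on joint axes is

```
F_i   = −k_i d_i − c_t ḋ_i        (i = AP, IS, RL translations)
τ_j   = −k_j θ_j − c_r θ̇_j        (j = LB, AR, FE rotations)
```

with the rotations θ taken from an intrinsic Z–X–Y Euler decomposition
(FE first, the dominant experimental motion, then LB, then AR) of the
relative rotation across the joint, conjugated into the joint frame
(`T_local = J⁻¹ T J`). Translational displacements are the joint-origin
displacement expressed in joint axes. Using Euler angles as the torque
conjugates is exact only to first order, which is adequate in the
small-rotation regime (< 5°) the pipeline enforces.

**Joint frames.** A vertebral anatomical frame is built from four virtually
palpated landmarks (superior/inferior endplate centres, left/right pedicle
bases): origin at the endplate-centre midpoint, Y from inferior to superior
centre, provisional Z from left to right pedicle base, X = Ŷ×Ẑ,
Z re-orthogonalised. A joint's centre of rotation (CoR) is the midpoint of
the two facing endplate centres and its orientation the geodesic mean of the
adjacent vertebral frames — a symmetric convention adopted because the
original guideline leaves the joint-level construction open.

**Equilibrium.** Quasi-static response is found by a direct root-find on the
net generalized forces (gravity, external load, bushing wrenches), with the
configuration parameterised per body as a rotation vector plus the CoM
displacement. Damping is irrelevant at steady state, so the transient
integrator (quaternion rigid-body dynamics, LSODA) is retained only for
ramp-loading comparisons and for the dynamic loading mode. The integrator
runs in 0.25 s segments and stops early once its own state is at equilibrium
(force residual < 1e-5 N, torque < 1e-6 N·m, kinetic energy < 1e-12 J —
a held state then deviates from the exact equilibrium by well under a
nanometre and a tenth of a microradian); this avoids burning steps on
sub-nanometre numerical chatter around the settled state. Convergence
requires the stacked force residual < 1e-6 N and torque residual
< 1e-8 N·m. The solver uses MINPACK's hybrid method with a homotopy over the
total applied force as fallback; inside parameter sweeps a Newton iteration
reuses one LU-factorised finite-difference Jacobian across nearby solves and
refreshes it when the iteration stalls.

A mechanical subtlety worth knowing: the compressive load acts as a
*follower load* (the application point rides on the cranial body), which
softens the effective rotational stiffness by roughly P·h (load times height
of the load point above a joint, here ≈ 7–9 N·m/rad). Below ~10 N·m/rad of
flexion-extension stiffness the chain buckles into a large-rotation branch.
Equilibria whose body rotations exceed 0.35 rad are outside the linear
bushing model's validity and are treated as forward-solve failures during
identification.

## Identification

Three stiffnesses — anterior-posterior (k_ap), axial (k_is) and
flexion-extension (k_fe) — are identified, shared by all three joints
(level-independence assumption). The cost is

```
cf = Σ_i w_i (p_i − m_i)²,   n = 8 terms
```

over AP, IS, RL translation and FE rotation of the two free middle vertebrae
(L2, L3), translations in **mm** and rotations in **degrees** — the unit
system in which the weights w = (10, 100, 1, 1) put every term on a common
order of magnitude given motions of ~0.3 mm and ~1.5°. Predicted and
measured motions are both expressed about the same candidate joint poses
(measured rigid transforms are re-conjugated per candidate pose).

The search runs over log10-stiffness (ranges span orders of magnitude)
within bounds equal to published per-DoF ranges widened by ×0.5/×2, using a
trust-region interior-point minimiser with central finite-difference
gradients (relative step 1e-3 in log space) and per-parameter-vector caching
of forward solves. A bounded trust radius matters here: the landscape has a
genuine low-cost trap on the post-buckling branch near the soft k_fe bound,
and unbounded first steps of quasi-Newton line searches can vault into it.

Runs are classified: **failed_local** if *all* three optimised stiffnesses
changed ≤ 1 % from their initial values (the 1 %/jointly reading was chosen
because the alternative per-DoF reading would mark nearly every run failed);
**outlier** if *any* exceeds 10× its initial value (physiologically
implausible); otherwise **success**. Successful runs form the *reduced
dataset*.

## Synthetic data

The generator stands in for the study's CT/DIC data. Vertebrae are schematic
solids (elliptic cylinder, half-axes 17.5 mm AP × 21 mm RL, height 28 mm,
plus a posterior block) stacked with 10 mm disc gaps and a small seeded
rigid jitter (SD 1° / 0.5 mm) so joint poses are non-trivial; landmarks are
placed analytically, and the true joint poses derive from them through the
same frame construction the pipeline uses, so generator and pipeline are
consistent by construction. Bone density is 1.14 g/cm³; mesh inertia is
computed by signed-tetrahedron decomposition.

Loading mirrors the flexion experiment: an eccentric compressive ramp
(54 N over 1 s, then held), applied at a point 4 mm anterior of the
top-pot marker centroid — 10 % of the vertebral-body AP dimension, the
protocol's eccentricity rule. The top assembly is a 1 kg point mass with a
small diagonal inertia (1e-4 kg·m²); its CoM sits on the marker-centroid
axis by default (a pre-settled specimen carries no standing gravity moment;
the offset is configurable). The anterior-posterior force component is
identically zero (the experimental ball joint rode on low-friction AP
bearings), and the measured uniaxial force is decomposed into axial and
right-left components by the top-pot orientation.

Ground-truth stiffnesses default to k_ap = 25,000 N/m, k_is = 440,000 N/m,
k_fe = 30 N·m/rad — the order of the experimentally identified values, with
k_ap placed at the scale of the pose-study median and k_fe far enough above
the ~10 N·m/rad buckling threshold that default-load rotations stay within
the linear regime (< 5°). Non-optimised DoF default to the literature
initial estimates (k_rl = 13,500 N/m, k_lb = 64, k_ar = 268 N·m/rad,
damping 1000 N/(m/s) and 1.4 N·m/(rad/s)), so the noiseless identification
problem closes exactly.

Measurements: surface points sampled from each vertebra mesh and pot markers
are propagated through the forward solution at 25 Hz; per-vertebra rigid
transforms are corrupted with translation noise at the experimentally
reported uncertainties (0.0013 mm AP, 8.1e-4 mm axial; RL reuses the AP
value) and a rotational SD of 0.005° — a placeholder, since no rotational
uncertainty was reported. Palpation scatter is an isotropic trivariate
normal per landmark, resultant SD 2.9 mm (per-axis 2.9/√3 mm), sampled by
per-coordinate Latin-Hypercube stratification from one seeded stream in a
fixed coordinate order. The quasi-static trajectory's first frame is the
reference (pre-release) configuration — the state the model geometry is
registered to — so registration of the point trajectories recovers the
recorded transforms identically.

What the generator does *not* emulate: real vertebral geometry and
segmentation error, DIC speckle/correlation error structure (noise enters at
the transform level by default), CoR migration, nonlinear or coupled joint
behaviour, and specimen-to-specimen variability. Passing tests therefore
demonstrate the pipeline's internal correctness and its sensitivity
behaviour under controlled conditions, not accuracy on any real specimen.

## Studies

*Pose sensitivity*: n landmark-set draws (500 in the original design; the
test suite and examples use 50, which already resolves the effect) → three
candidate joint poses each → measured motion re-expressed → identification →
classification. *Two-factor*: every reduced-dataset pose crossed with the
stiffness sets of the 10 best models (lowest final cost, ties by model
index), one forward solve per cell. *Bootstrap*: initial stiffness vectors
sampled log-uniformly from the published literature ranges (the damping
space defaults bracket the nominal coefficients by ×0.1/×10, as the original
damping table is not available); each set re-optimised. Summary metrics use
linear-interpolation quantiles; CoR positions are reported relative to the
bottom pot's upper-surface centre.

## Statistics

Normality: chi-squared goodness of fit against a fitted normal with √n
equal-probability bins and df = bins − 3, falling back to one-sample
Kolmogorov–Smirnov when any expected count < 5 or the sample is degenerate;
rejection at p < 0.05. Correlation: Spearman, switching to tie-corrected
Kendall tau-b when ties are present; Bonferroni adjustment min(1, m·p) with
the family size always an explicit argument. Friedman rank-sum test for
unreplicated blocked data (average ranks for ties; the fully tied matrix is
defined as statistic 0, p 1). Tree regression: variance-reduction splits,
minimum leaf 5, cost-complexity pruning at the 1-SE rule under 10-fold CV;
importance is normalised impurity reduction, summed into an 18-feature pose
block and a 3-feature stiffness block. Bland–Altman: bias ± 1.96 SD of
differences.

## Numerical choices and limitations

- Internal units SI (m, N, rad); file and table units mm, degrees, N/m,
  N·m/rad with unit-suffixed column names.
- Euler decomposition near gimbal lock (middle angle within 1e-6 of ±π/2):
  first angle set to 0, flag raised.
- Registration uses the Kabsch SVD solution with the determinant correction,
  so reflections are never returned; collinear point sets are rejected.
- The dynamic mode is substantially slower and, started from the reference
  pose, shows the gravitational-settling artefact (early motion dominated by
  gravity rather than the ramp); the quasi-static mode is the default.
- Identification accuracy is bounded by the optimiser tolerances (~0.05 %
  in the noiseless closure), far below the pose-uncertainty effects under
  study.
- All randomness flows through explicit integer seeds; studies are
  reproducible bitwise in classifications and to 1e-9 in floats.
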
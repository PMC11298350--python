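"""Study orchestration: pose-sensitivity, two-factor and bootstrap analyses.

Reproduces the shape of the original investigation on synthetic data: a
Latin-Hypercube population of palpation-perturbed landmark sets defines a
population of candidate joint poses; the measured rigid motion is
re-expressed about each candidate pose, stiffnesses are re-identified per
pose, runs are filtered into the *reduced dataset* (successful, non-outlier
optimisations), the best-performing stiffness sets are crossed with every
reduced-dataset pose in a two-factor forward-simulation grid, and summary
metrics are tabulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, IVJointError, InputError
from .frames import JointPose, LandmarkSet, build_chain_poses
from .identify import (
    COST_DOFS,
    COST_VERTEBRAE,
    OptimizationConfig,
    OptimizationResult,
    literature_stiffness_ranges,
    result_csv_row,
)
from .kinematics import MotionSixDoF, RigidTransform, motion_about_joint
from .model import BushingParams, simulate_dynamic, predicted_motion
from .synthetic import SyntheticTruth, perturb_palpation

__all__ = [
    "StudyConfig",
    "StudyRecord",
    "StudyResults",
    "TwoFactorGrid",
    "run_pose_sensitivity",
    "select_best_models",
    "run_two_factor",
    "summarize_metrics",
    "run_bootstrap",
]

log = logging.getLogger("ivjoint.study")


@dataclass
class StudyConfig:
    """Configuration of the pose-sensitivity study."""

    n_samples: int = 500
    seed: int = 0
    palpation_resultant_mm: float = 2.9
    loading: str = "quasistatic"  # or "dynamic"
    n_best: int = 10
    optimization: OptimizationConfig = field(default_factory=OptimizationConfig)

    def __post_init__(self):
        if self.n_samples < 1:
            raise InputError("n_samples must be >= 1")
        if self.loading not in ("quasistatic", "dynamic"):
            raise InputError(f"unknown loading mode {self.loading!r}")


@dataclass
class StudyRecord:
    """One perturbed-pose model: its poses, measured motion, optimisation."""

    index: int
    joint_poses: list[JointPose]
    measured: dict[str, MotionSixDoF]
    result: OptimizationResult | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.result is not None

    @property
    def reduced(self) -> bool:
        return self.ok and self.result.classification == "success"


@dataclass
class StudyResults:
    config: StudyConfig
    records: list[StudyRecord]
    control: "StudyResults | None" = None

    @property
    def reduced_indices(self) -> list[int]:
        return [r.index for r in self.records if r.reduced]

    def to_frame(self) -> pd.DataFrame:
        """models.csv shape: one row per sample."""
        rows = []
        for r in self.records:
            if not r.ok:
                rows.append(
                    {"model_index": r.index, "classification": "solve_failed",
                     "status": "error", "note": r.error}
                )
                continue
            row = result_csv_row(r.result, r.index)
            row["in_reduced_dataset"] = r.reduced
            for p in r.joint_poses:
                tag = p.joint_id.replace("-", "_")
                for ax, name in zip(range(3), ("ap", "is", "rl")):
                    row[f"cor_{tag}_{name}_mm"] = p.cor[ax] * 1e3
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class TwoFactorGrid:
    """Per-DoF kinematic errors on the (pose model) x (stiffness set) grid."""

    pose_indices: list[int]
    stiffness_indices: list[int]
    errors: pd.DataFrame  # columns pose_index, stiffness_index, err_{vert}_{dof}
    failures: list[tuple[int, int, str]]


# ---------------------------------------------------------------------------
# forward evaluation
# ---------------------------------------------------------------------------

class ForwardEvaluator:
    """Model-under-load evaluator with warm-started equilibrium solves.

    Maps BushingParams -> predicted MotionSixDoF per vertebra under the
    study load, for a fixed set of candidate joint poses.
    """

    #: solutions whose body rotations exceed this are outside the linear
    #: bushing model's validity (post-buckling branch) -> treated as failures
    rotation_guard_rad: float = 0.35

    def __init__(
        self,
        truth: SyntheticTruth,
        joint_poses: Sequence[JointPose] | None = None,
        loading: str = "quasistatic",
    ):
        self.truth = truth
        self.joint_poses = list(joint_poses) if joint_poses is not None else None
        self.loading = loading
        self._warm = None
        self._mech = None
        self._model = None
        self._solved_once = False
        self._collapse_hits = 0

    def _max_rotation(self, q: np.ndarray) -> float:
        return float(max(
            np.linalg.norm(q[6 * i: 6 * i + 3]) for i in range(len(q) // 6)
        ))

    def __call__(self, params: BushingParams) -> dict[str, MotionSixDoF]:
        from .model import _Mechanics, _solve_static, _solve_static_fast
        from .errors import SingularJointError

        if self.loading != "dynamic":
            if np.any(np.concatenate([params.k_translation(),
                                      params.k_rotation()]) == 0.0):
                raise SingularJointError("zero stiffness in a loaded DoF")
            if self._mech is None:
                self._model = self.truth.build_model(self.joint_poses, params)
                self._mech = _Mechanics(self._model, self.truth.load_case)
            else:
                self._mech.set_bushing(params)
            state = _solve_static_fast(self._mech, 1.0, self._warm)
            if state is None and self._warm is not None:
                # a poisoned warm start: retry the cheap path cold
                state = _solve_static_fast(self._mech, 1.0, None)
            if state is None:
                # during a sustained streak of confirmed collapses the
                # robust retry is pointless — fail fast with the penalty
                if self._collapse_hits >= 3:
                    raise ConvergenceError(
                        "equilibrium left the linear regime "
                        "(post-buckling collapse)"
                    )
                try:
                    state = _solve_static(self._mech, 1.0, None,
                                          light=self._solved_once)
                except ConvergenceError:
                    self._warm = None
                    raise
            if self._max_rotation(state.q) > self.rotation_guard_rad:
                self._warm = None
                self._collapse_hits += 1
                raise ConvergenceError(
                    "equilibrium left the linear regime "
                    "(post-buckling collapse)"
                )
            self._solved_once = True
            self._collapse_hits = 0
            self._warm = state.q
            return predicted_motion(state, self._model)

        model = self.truth.build_model(self.joint_poses, params)
        load = self.truth.load_case
        frames = simulate_dynamic(
            model, load, dt=0.04,
            t_end=load.duration + self.truth.config.hold_time_s,
            rtol=1e-6, atol=1e-9,
        )
        transforms = frames[-1].transforms
        return {
            j.child: motion_about_joint(transforms[j.child], j.pose)
            for j in model.joints
        }


def measured_about_poses(
    measured_raw: Mapping[str, RigidTransform], joint_poses: Sequence[JointPose]
) -> dict[str, MotionSixDoF]:
    """Re-express raw per-vertebra transforms about candidate joint poses.

    Each vertebra is paired with its adjacent inferior joint by id
    (vertebra Lk with joint Lk-L(k+1))."""
    by_upper = {p.joint_id.split("-")[0]: p for p in joint_poses}
    out = {}
    for vert, t in measured_raw.items():
        if vert in by_upper:
            out[vert] = motion_about_joint(t, by_upper[vert])
    return out


# ---------------------------------------------------------------------------
# pose sensitivity study
# ---------------------------------------------------------------------------

def run_pose_sensitivity(
    truth: SyntheticTruth,
    measured_raw: Mapping[str, RigidTransform],
    cfg: StudyConfig,
) -> StudyResults:
    """The pose-sensitivity experiment on one synthetic specimen.

    For each of ``cfg.n_samples`` Latin-Hypercube palpation perturbations:
    build the three candidate joint poses, re-express the measured rigid
    motion about them, identify the stiffnesses, classify the run.  Records
    whose forward solves fail irrecoverably are kept with their error rather
    than aborting the study.
    """
    samples = perturb_palpation(
        truth, cfg.palpation_resultant_mm / 1e3, cfg.n_samples, cfg.seed
    )
    records = []
    for i, lm_sets in enumerate(samples):
        records.append(
            _run_one_model(truth, measured_raw, lm_sets, i, cfg)
        )
        if records[-1].ok:
            log.info(
                "model %d: %s cost=%.4g", i,
                records[-1].result.classification,
                records[-1].result.final_cost.total,
            )
        else:
            log.warning("model %d failed: %s", i, records[-1].error)
    n_success = sum(r.reduced for r in records)
    log.info("%d (of %d) successful", n_success, len(records))
    return StudyResults(cfg, records)


def _run_one_model(
    truth: SyntheticTruth,
    measured_raw: Mapping[str, RigidTransform],
    lm_sets: Sequence[LandmarkSet],
    index: int,
    cfg: StudyConfig,
) -> StudyRecord:
    from .identify import optimise_stiffness

    try:
        poses = build_chain_poses(lm_sets)
        measured = measured_about_poses(measured_raw, poses)
        forward = ForwardEvaluator(truth, poses, cfg.loading)
        result = optimise_stiffness(forward, measured, cfg.optimization)
        return StudyRecord(index, poses, measured, result)
    except IVJointError as exc:
        return StudyRecord(index, poses if "poses" in dir() else [], {}, None,
                           error=str(exc))


def select_best_models(results: StudyResults, n_best: int | None = None) -> list[int]:
    """Reduced-dataset model indices ranked by final cost (ties: lower index)."""
    n_best = n_best if n_best is not None else results.config.n_best
    reduced = [r for r in results.records if r.reduced]
    if not reduced:
        raise InputError("reduced dataset is empty")
    ranked = sorted(reduced, key=lambda r: (r.result.final_cost.total, r.index))
    if len(ranked) < n_best:
        log.warning(
            "reduced dataset has only %d models (requested %d best)",
            len(ranked), n_best,
        )
    return [r.index for r in ranked[:n_best]]


def run_two_factor(
    truth: SyntheticTruth, results: StudyResults, cfg: StudyConfig | None = None
) -> TwoFactorGrid:
    """Cross every reduced-dataset pose with the n-best stiffness sets.

    Each cell is one forward solve (no optimisation loop); per-DoF absolute
    errors are taken against that pose's measured motion.  Cell failures are
    recorded, not fatal.
    """
    cfg = cfg or results.config
    best = select_best_models(results, cfg.n_best)
    by_index = {r.index: r for r in results.records}
    rows, failures = [], []
    for rec in results.records:
        if not rec.reduced:
            continue
        forward = ForwardEvaluator(truth, rec.joint_poses, cfg.loading)
        for b in best:
            k_set = by_index[b].result.k_opt
            try:
                predicted = forward(k_set)
            except IVJointError as exc:
                failures.append((rec.index, b, str(exc)))
                continue
            row = {"pose_index": rec.index, "stiffness_index": b}
            for vert in COST_VERTEBRAE:
                p, m = predicted[vert], rec.measured[vert]
                for dof in COST_DOFS:
                    d = getattr(p, dof) - getattr(m, dof)
                    err = abs(d) * 1e3 if dof.startswith("t_") else abs(np.degrees(d))
                    row[f"err_{vert}_{dof}"] = err
            rows.append(row)
    return TwoFactorGrid(
        pose_indices=[r.index for r in results.records if r.reduced],
        stiffness_indices=best,
        errors=pd.DataFrame(rows),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# summary metrics
# ---------------------------------------------------------------------------

def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    return float(q3 - q1)


def _col_summary(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    return {
        "median": float(np.median(x)),
        "iqr": _iqr(x),
        "range": float(x.max() - x.min()),
    }


def summarize_metrics(
    results: StudyResults | None = None,
    grid: TwoFactorGrid | None = None,
    reference_point: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Median / IQR / range tables per DoF and vertebra, pose-dispersion
    summaries (per-model average joint orientation per rotational DoF and
    average CoR distance from the mean CoR), and CoR positions relative to a
    named reference point (the bottom pot's upper-surface centre)."""
    out: dict[str, pd.DataFrame] = {}
    if results is not None:
        reduced = [r for r in results.records if r.reduced]
        if not reduced:
            raise InputError("no successful records to summarise")
        # error and stiffness summaries over the reduced dataset
        err_rows = []
        for vert in COST_VERTEBRAE:
            for dof in COST_DOFS:
                vals = np.array(
                    [r.result.per_dof_errors[(vert, dof)] for r in reduced]
                )
                unit = "mm" if dof.startswith("t_") else "deg"
                err_rows.append(
                    {"vertebra": vert, "dof": dof, "unit": unit,
                     **_col_summary(vals)}
                )
        out["errors"] = pd.DataFrame(err_rows)

        k_rows = []
        for dof in results.config.optimization.optimized_dofs:
            vals = np.array([getattr(r.result.k_opt, dof) for r in reduced])
            k_rows.append({"stiffness": dof, **_col_summary(vals)})
        out["stiffness"] = pd.DataFrame(k_rows)

        # pose dispersion: per-model average orientation / CoR distance
        from .kinematics import euler_decompose

        ori_rows, cor_rows = [], []
        all_cors = {}
        for r in results.records:
            if not r.ok:
                continue
            for p in r.joint_poses:
                all_cors.setdefault(p.joint_id, []).append(p.cor)
        mean_cor = {jid: np.mean(np.vstack(v), axis=0) for jid, v in all_cors.items()}
        for r in results.records:
            if not r.ok:
                continue
            angs = []
            dists = []
            for p in r.joint_poses:
                a, _ = euler_decompose(p.orientation, "ZXY")
                angs.append(np.degrees([a[1], a[2], a[0]]))  # lb, ar, fe
                dists.append(np.linalg.norm(p.cor - mean_cor[p.joint_id]))
            angs = np.mean(np.vstack(angs), axis=0)
            ori_rows.append(
                {"model_index": r.index, "mean_lb_deg": angs[0],
                 "mean_ar_deg": angs[1], "mean_fe_deg": angs[2],
                 "mean_cor_dist_mm": float(np.mean(dists)) * 1e3,
                 "in_reduced_dataset": r.reduced}
            )
        out["pose_dispersion"] = pd.DataFrame(ori_rows)

        # CoR relative to the reference point, per joint (complete + reduced)
        if reference_point is not None:
            rows = []
            for subset, pred in (("complete", lambda r: r.ok),
                                 ("reduced", lambda r: r.reduced)):
                per_joint: dict[str, list] = {}
                for r in results.records:
                    if not pred(r):
                        continue
                    for p in r.joint_poses:
                        per_joint.setdefault(p.joint_id, []).append(
                            (p.cor - reference_point) * 1e3
                        )
                for jid, vals in per_joint.items():
                    vals = np.vstack(vals)
                    row = {"model_set": subset, "joint": jid}
                    for ax, name in zip(range(3), ("ap", "is", "rl")):
                        row[f"median_{name}_mm"] = float(np.median(vals[:, ax]))
                        row[f"iqr_{name}_mm"] = _iqr(vals[:, ax])
                    rows.append(row)
            out["cor_positions"] = pd.DataFrame(rows)

    if grid is not None and len(grid.errors):
        rows = []
        for col in grid.errors.columns:
            if not col.startswith("err_"):
                continue
            _, vert, *dof = col.split("_")
            rows.append(
                {"vertebra": vert, "dof": "_".join(dof),
                 **_col_summary(grid.errors[col].to_numpy())}
            )
        out["grid_errors"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# bootstrap over initial parameters
# ---------------------------------------------------------------------------

def run_bootstrap(
    truth: SyntheticTruth,
    measured_raw: Mapping[str, RigidTransform],
    n_sets: int,
    seed: int = 0,
    mode: str = "quasistatic",
    space: Mapping[str, tuple[float, float]] | None = None,
    damping_space: Mapping[str, tuple[float, float]] | None = None,
    base_config: OptimizationConfig | None = None,
) -> dict:
    """Bootstrap the identification over random initial parameters.

    ``space`` gives per-DoF stiffness ranges (defaults: the published
    literature ranges); initial vectors are sampled log-uniformly within
    them.  ``damping_space`` optionally samples the two damping coefficients
    the same way (defaults bracket the nominal 1000 N/(m/s) and
    1.4 N*m/(rad/s) by x0.1 / x10 when requested).  Only optimisations that
    classify as success are flagged for analysis.
    """
    from .identify import optimise_stiffness

    if n_sets < 1:
        raise InputError("n_sets must be >= 1")
    space = dict(space) if space is not None else literature_stiffness_ranges()
    for name, (lo, hi) in space.items():
        if not (0 < lo < hi):
            raise InputError(f"empty or invalid range for {name}")
    rng = np.random.default_rng(seed)
    base_config = base_config or OptimizationConfig()

    poses = truth.joint_poses
    measured = measured_about_poses(measured_raw, poses)

    results, successes = [], 0
    for i in range(n_sets):
        kw = {
            name: float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
            for name, (lo, hi) in space.items()
        }
        if damping_space:
            for name, (lo, hi) in damping_space.items():
                kw[name] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        initial = BushingParams.literature_initial().with_values(**kw)
        bounds = {
            d: (
                min(base_config.bounds[d][0], getattr(initial, d) * 0.5),
                max(base_config.bounds[d][1], getattr(initial, d) * 2.0),
            )
            for d in base_config.optimized_dofs
        }
        cfg = OptimizationConfig(
            optimized_dofs=base_config.optimized_dofs,
            weights=dict(base_config.weights),
            initial=initial,
            bounds=bounds,
        )
        forward = ForwardEvaluator(truth, poses, loading=mode)
        try:
            res = optimise_stiffness(forward, measured, cfg)
        except IVJointError as exc:
            results.append({"set_index": i, "error": str(exc), "initial": initial})
            continue
        successes += res.classification == "success"
        results.append({"set_index": i, "initial": initial, "result": res})
    return {"results": results, "n_success": successes, "n_sets": n_sets}
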
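"""YAML configuration loading with schema validation.

I/O units follow the reporting convention: lengths in mm, angles in degrees,
stiffnesses in N/m and N*m/rad; they are converted to SI at this boundary.
Unknown keys are rejected and all problems are reported together.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .identify import DEFAULT_WEIGHTS, OptimizationConfig
from .model import BushingParams
from .study import StudyConfig
from .synthetic import NoiseModel, SyntheticConfig

__all__ = ["RunConfig", "load_config", "dump_config"]

#: YAML key -> (SyntheticConfig field, scale into SI)
_SYNTH_KEYS = {
    "body_half_ap_mm": ("body_half_ap", 1e-3),
    "body_half_rl_mm": ("body_half_rl", 1e-3),
    "body_height_mm": ("body_height", 1e-3),
    "disc_gap_mm": ("disc_gap", 1e-3),
    "pedicle_halfwidth_mm": ("pedicle_halfwidth", 1e-3),
    "jitter_rot_deg": ("jitter_rot_deg", 1.0),
    "jitter_trans_mm": ("jitter_trans_mm", 1.0),
    "density_kg_m3": ("density_kg_m3", 1.0),
    "load_axial_n": ("load_axial_n", 1.0),
    "load_rl_n": ("load_rl_n", 1.0),
    "load_eccentricity_ap_mm": ("load_eccentricity_ap_m", 1e-3),
    "ramp_duration_s": ("ramp_duration_s", 1.0),
    "hold_time_s": ("hold_time_s", 1.0),
    "top_mass_kg": ("top_mass_kg", 1.0),
    "top_com_offset_ap_mm": ("top_com_offset_ap_m", 1e-3),
    "top_inertia_kg_m2": ("top_inertia_kg_m2", 1.0),
    "n_surface_points": ("n_surface_points", 1),
    "gravity_on": ("gravity_on", None),
}

_STIFFNESS_KEYS = ("k_ap", "k_is", "k_rl", "k_lb", "k_ar", "k_fe",
                   "c_trans", "c_rot")
_NOISE_KEYS = ("sd_trans_ap_mm", "sd_trans_is_mm", "sd_trans_rl_mm",
               "sd_rot_deg", "palpation_resultant_mm")
_STUDY_KEYS = ("n_samples", "seed", "palpation_resultant_mm", "loading",
               "n_best")
_OPT_KEYS = ("weights", "initial", "bounds", "max_iterations")


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    study: StudyConfig = field(default_factory=StudyConfig)


def _check_number(value, key, problems, allow_bool=False):
    if isinstance(value, bool) and not allow_bool:
        problems.append(f"{key}: expected a number, got a boolean")
        return False
    if not isinstance(value, (int, float)):
        problems.append(f"{key}: expected a number, got {type(value).__name__}")
        return False
    return True


def _parse_stiffness(raw: dict, prefix: str, problems: list,
                     base: BushingParams | None = None) -> BushingParams:
    base = base or BushingParams.literature_initial()
    kw = {}
    for key, value in raw.items():
        if key not in _STIFFNESS_KEYS:
            problems.append(f"{prefix}.{key}: unknown key")
            continue
        if _check_number(value, f"{prefix}.{key}", problems):
            if value < 0:
                problems.append(f"{prefix}.{key}: must be >= 0")
            else:
                kw[key] = float(value)
    try:
        return base.with_values(**kw)
    except Exception as exc:  # noqa: BLE001 - collected into the report
        problems.append(f"{prefix}: {exc}")
        return base


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration; raises ConfigError with an
    itemised list of every problem found."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    problems: list[str] = []

    known_top = {"synthetic", "study", "optimization"}
    for key in raw:
        if key not in known_top:
            problems.append(f"{key}: unknown top-level section")

    synth_kw = {}
    noise_kw = {}
    stiffness = None
    for key, value in (raw.get("synthetic") or {}).items():
        if key == "true_stiffness":
            stiffness = _parse_stiffness(value or {}, "synthetic.true_stiffness",
                                         problems,
                                         SyntheticConfig().true_stiffness)
        elif key == "noise":
            for nk, nv in (value or {}).items():
                if nk not in _NOISE_KEYS:
                    problems.append(f"synthetic.noise.{nk}: unknown key")
                elif _check_number(nv, f"synthetic.noise.{nk}", problems):
                    noise_kw[nk] = float(nv)
        elif key in _SYNTH_KEYS:
            fieldname, scale = _SYNTH_KEYS[key]
            if scale is None:
                if not isinstance(value, bool):
                    problems.append(f"synthetic.{key}: expected a boolean")
                else:
                    synth_kw[fieldname] = value
            elif _check_number(value, f"synthetic.{key}", problems):
                synth_kw[fieldname] = type(scale)(value * scale)
        else:
            problems.append(f"synthetic.{key}: unknown key")

    study_kw = {}
    for key, value in (raw.get("study") or {}).items():
        if key not in _STUDY_KEYS:
            problems.append(f"study.{key}: unknown key")
        elif key == "loading":
            if value not in ("quasistatic", "dynamic"):
                problems.append(f"study.loading: must be quasistatic or dynamic")
            else:
                study_kw[key] = value
        elif _check_number(value, f"study.{key}", problems):
            study_kw[key] = int(value) if key != "palpation_resultant_mm" else float(value)

    opt_kw = {}
    opt_raw = raw.get("optimization") or {}
    for key, value in opt_raw.items():
        if key not in _OPT_KEYS:
            problems.append(f"optimization.{key}: unknown key")
    weights = dict(DEFAULT_WEIGHTS)
    for key, value in (opt_raw.get("weights") or {}).items():
        if key not in weights:
            problems.append(f"optimization.weights.{key}: unknown key")
        elif _check_number(value, f"optimization.weights.{key}", problems):
            if value <= 0:
                problems.append(f"optimization.weights.{key}: must be > 0")
            else:
                weights[key] = float(value)
    initial = BushingParams.literature_initial()
    if "initial" in opt_raw:
        initial = _parse_stiffness(opt_raw["initial"] or {}, "optimization.initial",
                                   problems)
    bounds = None
    if "bounds" in opt_raw:
        bounds = {}
        for key, value in (opt_raw["bounds"] or {}).items():
            if not (isinstance(value, (list, tuple)) and len(value) == 2):
                problems.append(
                    f"optimization.bounds.{key}: expected [lower, upper]"
                )
                continue
            lo, hi = value
            if not (isinstance(lo, (int, float)) and isinstance(hi, (int, float))):
                problems.append(f"optimization.bounds.{key}: non-numeric bound")
            elif lo < 0 or hi < 0:
                problems.append(f"optimization.bounds.{key}: bounds must be >= 0")
            elif not lo < hi:
                problems.append(f"optimization.bounds.{key}: lower must be < upper")
            else:
                bounds[key] = (float(lo), float(hi))
    if "max_iterations" in opt_raw:
        if _check_number(opt_raw["max_iterations"], "optimization.max_iterations",
                         problems):
            opt_kw["max_iterations"] = int(opt_raw["max_iterations"])

    if problems:
        raise ConfigError(problems)

    noise = NoiseModel(**noise_kw)
    if "palpation_resultant_mm" in study_kw:
        noise = dataclasses.replace(
            noise, palpation_resultant_mm=study_kw["palpation_resultant_mm"]
        )
    synth_cfg = SyntheticConfig(
        **synth_kw,
        noise=noise,
        **({"true_stiffness": stiffness} if stiffness is not None else {}),
    )
    opt_cfg_kw = dict(weights=weights, initial=initial, **opt_kw)
    if bounds is not None:
        opt_cfg_kw["bounds"] = bounds
    try:
        opt_cfg = OptimizationConfig(**opt_cfg_kw)
        study_cfg = StudyConfig(**study_kw, optimization=opt_cfg)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(synthetic=synth_cfg, study=study_cfg)


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> dict:
    """Serialise a RunConfig back to the YAML schema (mm / degree units)."""
    s = cfg.synthetic
    inv = {}
    for yaml_key, (fieldname, scale) in _SYNTH_KEYS.items():
        value = getattr(s, fieldname)
        if scale is None or isinstance(value, bool):
            inv[yaml_key] = value
        elif isinstance(scale, int):
            inv[yaml_key] = int(value)
        else:
            inv[yaml_key] = float(value / scale)
    inv["true_stiffness"] = s.true_stiffness.to_dict()
    inv["noise"] = dataclasses.asdict(s.noise)
    st = cfg.study
    opt = st.optimization
    payload = {
        "synthetic": inv,
        "study": {
            "n_samples": st.n_samples,
            "seed": st.seed,
            "palpation_resultant_mm": st.palpation_resultant_mm,
            "loading": st.loading,
            "n_best": st.n_best,
        },
        "optimization": {
            "weights": dict(opt.weights),
            "initial": opt.initial.to_dict(),
            "bounds": {k: list(v) for k, v in opt.bounds.items()},
            "max_iterations": opt.max_iterations,
        },
    }
    if path is not None:
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
    return payload
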
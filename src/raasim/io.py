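"""Configuration loading, fixture generation, and result serialization.

Run configurations are YAML or JSON documents validated against a strict
schema; unknown keys are rejected with a nearest-valid-key hint, and every
default traces back to a field of the shipped parameter files.
"""

from __future__ import annotations

import difflib
import json
import logging
from pathlib import Path
from typing import Any, Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .drug import DoseEvent, get_study_subject, load_drug_parameters
from .errors import ConfigurationError, DomainError
from .kinetics import HORMONES, RAASParameters, load_raas_parameters
from .physiology import SubjectParams, build_reference_body
from .simulator import (DrugBundle, SimOptions, assemble_system, simulate,
                        solve_steady_state)

logger = logging.getLogger("raasim.io")

__all__ = [
    "RunConfig",
    "load_config",
    "build_run",
    "generate_fixtures",
    "write_trajectory_csv",
    "write_summary_json",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SolverConfig(_StrictModel):
    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-12


class DoseConfig(_StrictModel):
    time_min: float = 1500.0
    amount_mg: float = 10.0
    route: Literal["oral", "intravenous"] = "oral"
    compound: Literal["Ena", "Enaat"] = "Ena"


class SubjectConfig(_StrictModel):
    study_label: str = "default"
    dose_mg: float | None = None
    body_weight_kg: float | None = None
    vmax_liv: float | None = None
    renal_clearance_ena: float | None = None
    renal_clearance_enaat: float | None = None
    ace_c_ref: float | None = None
    v_liver: float | None = None
    fasted: bool | None = None


class RunConfig(_StrictModel):
    """Validated run description for the CLI and `build_run`."""

    scenario: Literal["steady_state", "oral_ena", "iv_enaat", "custom"] = (
        "steady_state")
    study: str | None = None
    subject: SubjectConfig = Field(default_factory=SubjectConfig)
    doses: list[DoseConfig] = Field(default_factory=list)
    dose_time_min: float = 1500.0
    horizon_min: float = 3000.0
    grid_min: float = 5.0
    hematocrit: float = 0.47
    complex_source: Literal["whole_body", "kidney"] = "whole_body"
    ace_binding: bool = True
    solver: SolverConfig = Field(default_factory=SolverConfig)
    parameter_overrides: dict[str, float] = Field(default_factory=dict)
    physiology_overrides: dict[str, dict[str, float]] = Field(default_factory=dict)
    out_dir: str = "."
    seed: int | None = None


def _known_keys(model: type[BaseModel], prefix: str = "") -> list[str]:
    keys = []
    for name, f in model.model_fields.items():
        keys.append(prefix + name)
        ann = f.annotation
        if isinstance(ann, type) and issubclass(ann, BaseModel):
            keys += _known_keys(ann, prefix + name + ".")
    return keys


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys raise :class:`ConfigurationError` naming the nearest
    valid key; defaults reproduce the packaged parameterisation exactly.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    try:
        config = RunConfig.model_validate(raw)
    except ValidationError as exc:
        known = _known_keys(RunConfig)
        msgs = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            if err["type"] == "extra_forbidden":
                hint = difflib.get_close_matches(loc, known, n=1)
                extra = f"; did you mean {hint[0]!r}?" if hint else ""
                msgs.append(f"unknown key {loc!r}{extra}")
            else:
                msgs.append(f"{loc}: {err['msg']}")
        raise ConfigurationError("; ".join(msgs)) from None
    # overrides must resolve against the packaged parameter table
    params = load_raas_parameters()
    for dotted in config.parameter_overrides:
        params.get(dotted)
    if config.study is not None:
        get_study_subject(config.study)
    return config


def canonical_serialization(config: RunConfig) -> str:
    """Stable JSON form; write -> load -> write round-trips identically."""
    return json.dumps(config.model_dump(), sort_keys=True, indent=2)


def _resolve_subject(config: RunConfig) -> SubjectParams:
    if config.study is not None:
        base = get_study_subject(config.study)
    else:
        base = SubjectParams(study_label=config.subject.study_label)
    upd = {k: v for k, v in {
        "dose_mg": config.subject.dose_mg,
        "body_weight": config.subject.body_weight_kg,
        "vmax_liv": config.subject.vmax_liv,
        "renal_clearance_ena": config.subject.renal_clearance_ena,
        "renal_clearance_enaat": config.subject.renal_clearance_enaat,
        "ace_c_ref": config.subject.ace_c_ref,
        "v_liver": config.subject.v_liver,
        "fasted": config.subject.fasted,
    }.items() if v is not None}
    if upd:
        from dataclasses import replace
        base = replace(base, **upd)
    return base


def build_run(config: RunConfig):
    """Materialise (system, doses, horizon, grid) from a validated config."""
    subject = _resolve_subject(config)
    body = build_reference_body(subject, hematocrit=config.hematocrit,
                                overrides=config.physiology_overrides or None)
    params = load_raas_parameters()
    if config.parameter_overrides:
        params = params.with_overrides(config.parameter_overrides)
    options = SimOptions(method=config.solver.method, rtol=config.solver.rtol,
                         atol=config.solver.atol,
                         complex_source=config.complex_source,
                         ace_binding=config.ace_binding)
    system = assemble_system(body, params, DrugBundle.for_subject(subject),
                             options)
    if config.scenario == "steady_state":
        doses: list[DoseEvent] = []
    elif config.scenario == "oral_ena":
        doses = [DoseEvent(time=config.dose_time_min, amount=subject.dose_mg,
                           route="oral", compound="Ena")]
    elif config.scenario == "iv_enaat":
        doses = [DoseEvent(time=config.dose_time_min, amount=subject.dose_mg,
                           route="intravenous", compound="Enaat")]
    else:
        doses = [DoseEvent(time=d.time_min, amount=d.amount_mg, route=d.route,
                           compound=d.compound) for d in config.doses]
    return system, doses, config.horizon_min, config.grid_min


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

#: Ranges spanned by the published study populations (subjects fixture).
_SUBJECT_RANGES = {
    "body_weight": (56.0, 80.0),
    "vmax_liv": (131.88, 194.36),
    "renal_clearance_ena": (4.51e-3, 6.53e-3),
    "renal_clearance_enaat": (2.99e-4, 8.01e-4),
    "ace_c_ref": (1.30, 4.32),
    "v_liver": (1.35, 1.57),
}

#: Generating values of the pk_curves fixture (packaged defaults).
PK_CURVE_TRUE_PARAMS = {"ka": 0.03, "f_abs": 0.6}


def generate_fixtures(kind: Literal["subjects", "pk_curves", "raas_targets"],
                      n: int = 1, seed: int = 0, *,
                      noise_cv: float = 0.15,
                      subject: SubjectParams | None = None,
                      times_min: np.ndarray | None = None,
                      lloq_umol_per_L: float = 1e-3) -> pd.DataFrame:
    """Deterministic synthetic datasets for exercising the package.

    ``subjects``: virtual subjects sampled uniformly within the ranges
    spanned by the published study populations.  ``pk_curves``: simulated
    oral-enalapril concentration-time curves for a subject, sampled at
    clinical-like times with multiplicative lognormal noise (CV
    ``noise_cv``; 0 disables noise); samples whose noise-free value falls
    below ``lloq_umol_per_L`` are dropped, emulating an assay's lower
    limit of quantification.  ``raas_targets``: the reference venous
    steady-state concentrations, optionally perturbed.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)

    if kind == "subjects":
        rows = []
        for i in range(n):
            draw = {k: rng.uniform(*rng_) for k, rng_ in _SUBJECT_RANGES.items()}
            rows.append({"subject_id": i, "dose_mg": float(rng.choice([10.0, 20.0])),
                         "fasted": bool(rng.integers(0, 2)), **draw})
        return pd.DataFrame(rows)

    if kind == "pk_curves":
        from .identification import DEFAULT_PK_TIMES_MIN, absorption_curve_predictor
        times = np.asarray(times_min if times_min is not None
                           else DEFAULT_PK_TIMES_MIN, float)
        predict = absorption_curve_predictor(
            subject=subject, times_ena=times, times_enaat=times)
        clean = predict(PK_CURVE_TRUE_PARAMS)
        n_t = len(times)
        rows = []
        for i in range(n):
            noise = (np.exp(rng.normal(0.0, noise_cv, size=clean.shape))
                     if noise_cv > 0 else np.ones_like(clean))
            noisy = clean * noise
            for sp, block, ref in (("Ena", noisy[:n_t], clean[:n_t]),
                                   ("Enaat", noisy[n_t:], clean[n_t:])):
                keep = ref >= lloq_umol_per_L
                rows.append(pd.DataFrame({
                    "curve_id": i, "time_min": times[keep], "species": sp,
                    "concentration_umol_per_L": block[keep],
                }))
        out = pd.concat(rows, ignore_index=True)
        out.attrs["true_params"] = dict(PK_CURVE_TRUE_PARAMS)
        return out

    if kind == "raas_targets":
        params = load_raas_parameters()
        ref = params.reference_concentrations()
        rows = []
        for i in range(n):
            noise = (np.exp(rng.normal(0.0, noise_cv, size=len(ref)))
                     if noise_cv > 0 else np.ones(len(ref)))
            rows.append(pd.DataFrame({
                "replicate": i, "species": list(ref),
                "concentration_umol_per_L": np.array(list(ref.values())) * noise,
            }))
        return pd.concat(rows, ignore_index=True)

    raise ConfigurationError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_trajectory_csv(trajectory, path: str | Path,
                         species=None, compartments=None) -> Path:
    path = Path(path)
    frame = trajectory.to_frame(species=species, compartments=compartments)
    frame.to_csv(path, index=False)
    logger.info("wrote trajectory (%d rows) to %s", len(frame), path)
    return path


def write_summary_json(path: str | Path, payload: Mapping[str, Any]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    logger.info("wrote summary to %s", path)
    return path
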
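"""Parent-metabolite pharmacokinetics of oral enalapril.

Enalapril (Ena) is an inactive ethyl-ester prodrug absorbed from the gut;
hepatic carboxylesterases hydrolyse it to enalaprilat (Enaat), the active
ACE inhibitor.  The model tracks both compounds over the same plasma
compartment graph as the hormones, with

* a first-order gut depot feeding liver-inflow plasma (oral route),
* a liver intracellular pool (site of Eq.-style Michaelis-Menten
  conversion and of linear hepatic clearance of Ena),
* study-specific linear renal clearance of both compounds from kidney
  plasma, and
* reversible Enaat binding to endothelial ACE in every expressing organ;
  bound Enaat neither clears nor degrades, which produces the drug's
  prolonged terminal phase.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Any, Literal, Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError
from .physiology import SubjectParams

__all__ = [
    "DrugSpec",
    "CarboxylesteraseParams",
    "DoseEvent",
    "AbsorptionParams",
    "load_drug_parameters",
    "load_study_subjects",
    "hepatic_conversion_rate",
    "renal_clearance_rate",
    "oral_absorption_rate",
]

KM_LIV_UMOL_PER_L = 710.0


@dataclass
class DrugSpec:
    """Physicochemical and clearance properties of one compound."""

    name: Literal["Ena", "Enaat"]
    molecular_weight: float                  # g/mol
    log_p: float
    pka: tuple[float, ...] = ()
    plasma_protein_binding_pct: float = 0.0  # metadata; rates use total conc
    hepatic_clearance: float = 0.0           # ml/min, Ena only
    renal_clearance_per_kg: float = 0.0      # L/min/kg, study-specific
    partition_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise DomainError("molecular weight must be > 0")
        if not 0.0 <= self.plasma_protein_binding_pct <= 100.0:
            raise DomainError("protein binding must lie in [0, 100]%")
        if self.hepatic_clearance < 0 or self.renal_clearance_per_kg < 0:
            raise DomainError("clearances must be >= 0")
        if any(k <= 0 for k in self.partition_coefficients.values()):
            raise DomainError("partition coefficients must be > 0")

    def k_org(self, organ: str) -> float:
        """Tissue:plasma partition coefficient (default 1.0)."""
        return self.partition_coefficients.get(organ, 1.0)


@dataclass
class CarboxylesteraseParams:
    """Hepatic Ena -> Enaat hydrolysis kinetics (Vmax study-specific)."""

    vmax_liv: float                 # umol/min/L
    km_liv: float = KM_LIV_UMOL_PER_L

    def __post_init__(self):
        if self.vmax_liv <= 0 or self.km_liv <= 0:
            raise DomainError("carboxylesterase parameters must be > 0")


@dataclass(frozen=True)
class DoseEvent:
    """One administration: oral Ena reaches the gut depot, IV doses the
    venous pool directly."""

    time: float                     # min
    amount: float                   # mg
    route: Literal["oral", "intravenous"] = "oral"
    compound: Literal["Ena", "Enaat"] = "Ena"

    def __post_init__(self):
        if self.amount <= 0:
            raise DomainError("dose amount must be > 0")
        if self.time < 0:
            raise DomainError("dose time must be >= 0")


@dataclass
class AbsorptionParams:
    """First-order oral absorption: rate constant and absorbable fraction."""

    ka: float = 0.03                # 1/min
    f_abs: float = 0.6              # fraction of dose ever absorbed

    def __post_init__(self):
        if self.ka < 0:
            raise DomainError("ka must be >= 0")
        if not 0.0 <= self.f_abs <= 1.0:
            raise DomainError("f_abs must lie in [0, 1]")


def _load_yaml() -> dict[str, Any]:
    ref = importlib.resources.files("raasim.data") / "drug_parameters.yaml"
    with importlib.resources.as_file(ref) as path:
        return yaml.safe_load(path.read_text())


def load_drug_parameters(
    subject: SubjectParams | None = None,
) -> tuple[DrugSpec, DrugSpec, AbsorptionParams]:
    """Packaged Ena/Enaat specs, with study-specific renal clearances taken
    from the subject when given."""
    raw = _load_yaml()
    subject = subject or SubjectParams()
    ena = DrugSpec(
        name="Ena",
        molecular_weight=float(raw["enalapril"]["molecular_weight_g_per_mol"]),
        log_p=float(raw["enalapril"]["log_p"]),
        pka=tuple(raw["enalapril"]["pka"]),
        plasma_protein_binding_pct=float(
            raw["enalapril"]["plasma_protein_binding_pct"]),
        hepatic_clearance=float(raw["enalapril"]["hepatic_clearance_ml_per_min"]),
        renal_clearance_per_kg=subject.renal_clearance_ena,
    )
    enaat = DrugSpec(
        name="Enaat",
        molecular_weight=float(raw["enalaprilat"]["molecular_weight_g_per_mol"]),
        log_p=float(raw["enalaprilat"]["log_p"]),
        pka=tuple(raw["enalaprilat"]["pka"]),
        plasma_protein_binding_pct=float(
            raw["enalaprilat"]["plasma_protein_binding_pct"]),
        renal_clearance_per_kg=subject.renal_clearance_enaat,
    )
    absorption = AbsorptionParams(
        ka=float(raw["absorption"]["ka_per_min"]),
        f_abs=float(raw["absorption"]["f_abs"]),
    )
    return ena, enaat, absorption


def load_study_subjects() -> dict[str, SubjectParams]:
    """Subject parameterisations of the published study populations."""
    raw = _load_yaml()
    subjects = {}
    for label, block in raw["studies"].items():
        subjects[label] = SubjectParams(
            study_label=label,
            n_individuals=int(block["n_individuals"]),
            dose_mg=float(block["dose_mg"]),
            fasted=bool(block["fasted"]),
            body_weight=float(block["body_weight_kg"]),
            vmax_liv=float(block["vmax_liv_umol_per_min_L"]),
            renal_clearance_ena=float(block["renal_clearance_ena_L_per_min_kg"]),
            renal_clearance_enaat=float(block["renal_clearance_enaat_L_per_min_kg"]),
            ace_c_ref=float(block["ace_c_ref_umol_per_L"]),
            v_liver=float(block["v_liver_L"]),
        )
    return subjects


def get_study_subject(label: str) -> SubjectParams:
    subjects = load_study_subjects()
    try:
        return subjects[label]
    except KeyError:
        import difflib
        hint = difflib.get_close_matches(label, subjects, n=1)
        suffix = f"; did you mean {hint[0]!r}?" if hint else ""
        raise ConfigurationError(f"unknown study label {label!r}{suffix}") from None


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def hepatic_conversion_rate(p: CarboxylesteraseParams, v_liver, c_ena_cell):
    """Carboxylesterase-mediated Ena -> Enaat hydrolysis in hepatocytes
    (umol/min): r = Vmax_liv * V_liver * C_Ena / (C_Ena + Km_liv).
    Removes Ena and produces Enaat 1:1 in the liver intracellular pool."""
    if np.any(np.asarray(c_ena_cell) < 0) or np.any(np.asarray(v_liver) < 0):
        raise DomainError("concentration and volume must be >= 0")
    return p.vmax_liv * v_liver * c_ena_cell / (c_ena_cell + p.km_liv)


def renal_clearance_rate(cl_per_kg, body_weight, c_kidney_plasma):
    """Irreversible renal elimination from kidney plasma (umol/min):
    r = CL_per_kg * BW * C_kidney."""
    if (np.any(np.asarray(cl_per_kg) < 0) or np.any(np.asarray(body_weight) < 0)
            or np.any(np.asarray(c_kidney_plasma) < 0)):
        raise DomainError("all arguments must be >= 0")
    return cl_per_kg * body_weight * c_kidney_plasma


def oral_absorption_rate(ka, f_abs, gut_amount):
    """First-order transfer from the gut depot into liver-inflow plasma
    (umol/min).  The depot is charged with ``f_abs * dose`` at dose time;
    the remaining fraction is never absorbed."""
    if np.any(np.asarray(ka) < 0) or np.any(np.asarray(gut_amount) < 0):
        raise DomainError("ka and gut amount must be >= 0")
    if not 0.0 <= f_abs <= 1.0:
        raise DomainError("f_abs must lie in [0, 1]")
    return ka * gut_amount
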
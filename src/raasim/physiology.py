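"""Reduced whole-body physiology for the circulating RAAS.

The body is a compartment graph of plasma pools: an arterial pool feeding
15 organ compartments in parallel, their effluent collecting in a venous
pool which perfuses the lung before returning to the arterial pool.  The
lung therefore sees total cardiac output, which is what gives its
endothelial ACE (100% relative expression) its dominant role in
angiotensin conversion.

Per-organ plasma volumes and blood flows come from a packaged
reference-human table (70 kg adult, ~3 L total plasma) and scale linearly
with body weight.  Membrane-bound targets (ACE, AT1) are distributed over
organs via relative expression percentages; absolute concentrations follow
from a subject-level reference concentration, C0 = C_Ref * E_Ref / 100.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

__all__ = [
    "OrganCompartment",
    "BodyModel",
    "SubjectParams",
    "ORGAN_NAMES",
    "BLOOD_POOLS",
    "load_reference_physiology",
    "build_reference_body",
    "expressed_concentration",
]

#: The 15 organs carrying expression data, in canonical order.
ORGAN_NAMES = (
    "Brain", "Fat", "Gonads", "Heart", "Kidney", "Large Intestine", "Liver",
    "Lung", "Muscle", "Pancreas", "Plasma", "Skin", "Spleen",
    "Small Intestine", "Stomach",
)

#: Central blood pools (no expression, pure transit volumes).
BLOOD_POOLS = ("Arterial Blood", "Venous Blood")

REFERENCE_BODY_WEIGHT_KG = 70.0
DEFAULT_HEMATOCRIT = 0.47
DEFAULT_V_LIVER_L = 1.5
V_KIDNEY_CELL_L = 0.24


@dataclass(frozen=True)
class OrganCompartment:
    """One plasma compartment of the body graph.

    ``blood_flow`` is whole-blood flow (L/min); multiply by (1 - HCT) for
    the plasma-perfusing flow.  ``intracellular_volume`` is only nonzero
    for organs with an intracellular pool in the model (kidney, liver).
    """

    name: str
    plasma_volume: float
    blood_flow: float
    ace_expression_pct: float = 0.0
    at1_expression_pct: float = 0.0
    intracellular_volume: float = 0.0

    def __post_init__(self):
        if self.plasma_volume < 0 or self.blood_flow < 0:
            raise DomainError(f"{self.name}: volumes and flows must be >= 0")
        for pct in (self.ace_expression_pct, self.at1_expression_pct):
            if not 0.0 <= pct <= 100.0:
                raise DomainError(
                    f"{self.name}: expression percentage {pct} outside [0, 100]"
                )


@dataclass
class BodyModel:
    """Reduced whole-body compartment model.

    Topology: arterial pool -> organs (parallel) -> venous pool -> lung ->
    arterial pool.  ``compartments`` holds the two blood pools followed by
    the 15 organs; the lung participates in the series loop, not the
    parallel set.
    """

    compartments: list[OrganCompartment]
    hematocrit: float = DEFAULT_HEMATOCRIT
    subject: "SubjectParams | None" = None

    def __post_init__(self):
        if not 0.0 < self.hematocrit < 1.0:
            raise DomainError("hematocrit must lie in (0, 1)")
        self._index = {c.name: i for i, c in enumerate(self.compartments)}
        if self.total_plasma_volume <= 0:
            raise DomainError("total plasma volume must be > 0")

    # -- lookups -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigurationError(f"unknown compartment {name!r}") from None

    def __getitem__(self, name: str) -> OrganCompartment:
        return self.compartments[self.index(name)]

    @property
    def plasma_volumes(self) -> np.ndarray:
        return np.array([c.plasma_volume for c in self.compartments])

    @property
    def total_plasma_volume(self) -> float:
        return float(self.plasma_volumes.sum())

    @property
    def cardiac_output(self) -> float:
        """Whole-blood cardiac output (L/min) = lung perfusion."""
        return self["Lung"].blood_flow

    def expression(self, target: str) -> np.ndarray:
        """Relative expression (%) per compartment, target in {'ACE','AT1'}."""
        attr = {"ACE": "ace_expression_pct", "AT1": "at1_expression_pct"}[target]
        return np.array([getattr(c, attr) for c in self.compartments])

    # -- flow graph --------------------------------------------------------
    def flow_matrix(self) -> np.ndarray:
        """Plasma flow operator F (L/min): dA/dt|transport = F @ (A / V).

        Row i collects plasma inflows minus outflows of compartment i;
        every column sums to zero, so convective transport conserves mass
        exactly for any plasma-borne species.
        """
        n = len(self.compartments)
        f = np.zeros((n, n))
        pf = 1.0 - self.hematocrit
        i_art = self.index("Arterial Blood")
        i_ven = self.index("Venous Blood")
        i_lung = self.index("Lung")
        co = self.cardiac_output * pf
        for i, c in enumerate(self.compartments):
            if i in (i_art, i_ven, i_lung):
                continue
            q = c.blood_flow * pf
            f[i, i_art] += q
            f[i, i] -= q
            f[i_ven, i] += q
        f[i_ven, i_ven] -= co
        f[i_lung, i_ven] += co
        f[i_lung, i_lung] -= co
        f[i_art, i_lung] += co
        f[i_art, i_art] -= co
        return f

    def check_flow_balance(self, rtol: float = 1e-9) -> None:
        """Raise unless inflow equals outflow at every node."""
        f = self.flow_matrix()
        col = np.abs(f.sum(axis=0))
        scale = np.abs(f).max()
        if np.any(col > rtol * scale):
            raise ConfigurationError("flow balance violated in body topology")


@dataclass(frozen=True)
class SubjectParams:
    """Subject/study-level parameters (population properties plus the
    study-specific identified values: hepatic carboxylesterase Vmax, renal
    clearances, ACE reference concentration, intracellular liver volume)."""

    study_label: str = "default"
    n_individuals: int = 1
    dose_mg: float = 10.0
    fasted: bool = True
    body_weight: float = REFERENCE_BODY_WEIGHT_KG
    vmax_liv: float = 160.0            # umol/min/L
    renal_clearance_ena: float = 5.4e-3    # L/min/kg
    renal_clearance_enaat: float = 5.6e-4  # L/min/kg
    ace_c_ref: float = 2.59            # umol/L
    v_liver: float = DEFAULT_V_LIVER_L

    def __post_init__(self):
        positive = {
            "dose_mg": self.dose_mg,
            "body_weight": self.body_weight,
            "vmax_liv": self.vmax_liv,
            "ace_c_ref": self.ace_c_ref,
            "v_liver": self.v_liver,
        }
        for key, value in positive.items():
            if value <= 0:
                raise DomainError(f"SubjectParams.{key} must be > 0")
        if self.renal_clearance_ena < 0 or self.renal_clearance_enaat < 0:
            raise DomainError("renal clearances must be >= 0")


def load_reference_physiology() -> pd.DataFrame:
    """Load the packaged reference-human physiology table (70 kg)."""
    ref = importlib.resources.files("raasim.data") / "reference_physiology.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def build_reference_body(
    subject: SubjectParams | None = None,
    *,
    hematocrit: float = DEFAULT_HEMATOCRIT,
    physiology: pd.DataFrame | None = None,
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> BodyModel:
    """Assemble the reduced whole-body model for a subject.

    Volumes and flows scale linearly with body weight relative to the
    70-kg reference table.  ``overrides`` maps organ name to column
    overrides (e.g. ``{"Kidney": {"blood_flow_L_per_min": 1.2}}``).
    """
    subject = subject or SubjectParams()
    table = (physiology if physiology is not None else load_reference_physiology()).copy()
    table = table.set_index("organ")

    expected = set(BLOOD_POOLS) | set(ORGAN_NAMES)
    if set(table.index) != expected:
        missing = expected - set(table.index)
        extra = set(table.index) - expected
        raise ConfigurationError(
            f"physiology table organ set mismatch (missing {sorted(missing)}, "
            f"unexpected {sorted(extra)})"
        )

    if overrides:
        for organ, cols in overrides.items():
            if organ not in table.index:
                raise ConfigurationError(
                    f"unknown organ {organ!r} in physiology overrides"
                )
            for col, value in cols.items():
                if col not in table.columns:
                    raise ConfigurationError(f"unknown physiology column {col!r}")
                table.loc[organ, col] = value

    scale = subject.body_weight / REFERENCE_BODY_WEIGHT_KG
    comps: list[OrganCompartment] = []
    for name in (*BLOOD_POOLS, *ORGAN_NAMES):
        row = table.loc[name]
        icv = 0.0
        if name == "Kidney":
            icv = V_KIDNEY_CELL_L * scale
        elif name == "Liver":
            icv = subject.v_liver
        comps.append(
            OrganCompartment(
                name=name,
                plasma_volume=float(row["plasma_volume_L"]) * scale,
                blood_flow=float(row["blood_flow_L_per_min"]) * scale,
                ace_expression_pct=float(row["ace_expression_pct"]),
                at1_expression_pct=float(row["at1_expression_pct"]),
                intracellular_volume=icv,
            )
        )
    body = BodyModel(compartments=comps, hematocrit=hematocrit, subject=subject)
    body.check_flow_balance()
    return body


def expressed_concentration(c_ref: float, e_ref_pct: float) -> float:
    """Absolute target concentration in an organ from relative expression.

    C0 = C_Ref * E_Ref / 100, with E_Ref the organ's expression as a
    percentage of the maximally expressing organ.
    """
    if c_ref < 0:
        raise DomainError("reference concentration must be >= 0")
    if not 0.0 <= e_ref_pct <= 100.0:
        raise DomainError("expression percentage must lie in [0, 100]")
    return c_ref * e_ref_pct / 100.0
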
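"""Rate laws of the circulating renin-angiotensin-aldosterone cascade.

All rate laws are pure functions of concentrations and kinetic constants,
written to accept scalars or numpy arrays.  Conventions:

* concentrations in umol/L, volumes in L, times in min;
* rates carrying a volume factor (convection, Michaelis-Menten conversion,
  prorenin activation, secretion, aldosterone synthesis) are in umol/min;
* per-litre rates (degradation, receptor binding) are in umol/min/L and are
  multiplied by the compartment plasma volume by the caller.

The cascade: hepatically secreted angiotensinogen (AGT) is cleaved by
circulating renin to angiotensin 1, which membrane-bound ACE converts to
angiotensin 2.  Ang2 binds the AT1 receptor; the receptor complex drives
aldosterone secretion and feedback-inhibits the renal activation of
prorenin to renin.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError

__all__ = [
    "SpeciesSpec",
    "MMKinetics",
    "BindingParams",
    "SecretionParams",
    "ProreninActivation",
    "RAASParameters",
    "load_raas_parameters",
    "OPTIMIZED_PARAMETERS",
    "convective_transport_rate",
    "secretion_rate",
    "prorenin_activation_rate",
    "degradation_rate",
    "mm_conversion_rate",
    "binding_rate",
    "aldosterone_synthesis_rate",
]

LN2 = float(np.log(2.0))

#: Circulating species integrated per plasma compartment, canonical order.
HORMONES = ("AGT", "renin", "prorenin", "Ang1", "Ang2", "aldosterone")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSpec:
    """One circulating RAAS actor and its systemic properties."""

    name: str
    molecular_weight: float               # kDa
    half_life: float | None = None        # min; None for non-degrading targets
    plasma_only: bool = True
    reference_plasma_conc: float = 0.0    # venous, pre-administration steady state
    log_p: float | None = None
    protein_binding_pct: float | None = None

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise DomainError(f"{self.name}: molecular weight must be > 0")
        if self.half_life is not None and self.half_life <= 0:
            raise DomainError(f"{self.name}: half-life must be > 0")
        if self.reference_plasma_conc < 0:
            raise DomainError(f"{self.name}: reference concentration must be >= 0")


@dataclass
class MMKinetics:
    """Michaelis-Menten constants of an enzymatic conversion."""

    kcat: float        # 1/min
    km: float          # umol/L
    enzyme: str
    substrate: str

    def __post_init__(self):
        if self.kcat < 0 or self.km <= 0:
            raise DomainError("require kcat >= 0 and Km > 0")


@dataclass
class BindingParams:
    """Association/dissociation constants of a reversible binding step."""

    k_on: float        # L/umol/min
    k_off: float       # 1/min

    def __post_init__(self):
        if self.k_on < 0 or self.k_off < 0:
            raise DomainError("binding constants must be >= 0")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant (umol/L)."""
        if self.k_on == 0:
            raise DomainError("Kd undefined for k_on = 0")
        return self.k_off / self.k_on


@dataclass
class SecretionParams:
    """First-order cellular secretion, optionally with a zero-order floor
    (aldosterone's constitutive production)."""

    k_secretion: float             # L/min
    k_production: float = 0.0      # umol/min, aldosterone only
    source_organ: str = ""

    def __post_init__(self):
        if self.k_secretion < 0 or self.k_production < 0:
            raise DomainError("secretion parameters must be >= 0")


@dataclass
class ProreninActivation:
    """Renal prorenin -> renin activation, feedback-inhibited by Ang2."""

    vmax_kid: float                    # umol/min/L
    km_kid: float                      # umol/L
    k_inhibition: float                # umol/L
    intracellular_prorenin_ref: float  # umol/L

    def __post_init__(self):
        for name in ("vmax_kid", "km_kid", "k_inhibition",
                     "intracellular_prorenin_ref"):
            if getattr(self, name) <= 0:
                raise DomainError(f"ProreninActivation.{name} must be > 0")


#: Dotted paths of the parameters obtained by optimization (the default
#: free set of the steady-state identification workflow).
OPTIMIZED_PARAMETERS = (
    "AGT.t_half", "AGT.k_secretion",
    "renin.kcat", "renin.km", "renin.t_half",
    "ACE.kcat", "ACE.km",
    "Ang1.t_half",
    "Ang2.k_inhibition",
    "AT1.c_ref", "AT1.k_on", "AT1.k_off",
    "aldosterone.k_production", "aldosterone.k_secretion", "aldosterone.t_half",
    "prorenin.intracellular_ref", "prorenin.vmax_kid", "prorenin.km_kid",
    "prorenin.k_secretion", "prorenin.t_half",
)


@dataclass
class RAASParameters:
    """Complete kinetic parameterisation of the hormone cascade.

    Parameters are addressable by dotted path (``"renin.kcat"``,
    ``"AT1.c_ref"``) for overrides and identification.
    """

    species: dict[str, SpeciesSpec]
    renin_mm: MMKinetics
    ace_mm: MMKinetics
    at1_binding: BindingParams
    ace_binding: BindingParams
    agt_secretion: SecretionParams
    prorenin_secretion: SecretionParams
    aldosterone_secretion: SecretionParams
    prorenin_activation: ProreninActivation
    at1_c_ref: float                   # umol/L
    v_kidney_cell: float = 0.24        # L, intracellular kidney volume
    km_liv: float = 710.0              # umol/L, carboxylesterase Km

    # -- dotted-path parameter access -------------------------------------
    def _resolve(self, path: str):
        group, _, attr = path.partition(".")
        table: dict[str, tuple[Any, str]] = {
            "AGT.t_half": (self.species["AGT"], "half_life"),
            "AGT.k_secretion": (self.agt_secretion, "k_secretion"),
            "renin.kcat": (self.renin_mm, "kcat"),
            "renin.km": (self.renin_mm, "km"),
            "renin.t_half": (self.species["renin"], "half_life"),
            "ACE.kcat": (self.ace_mm, "kcat"),
            "ACE.km": (self.ace_mm, "km"),
            "ACE.k_on": (self.ace_binding, "k_on"),
            "ACE.k_off": (self.ace_binding, "k_off"),
            "Ang1.t_half": (self.species["Ang1"], "half_life"),
            "Ang2.t_half": (self.species["Ang2"], "half_life"),
            "Ang2.k_inhibition": (self.prorenin_activation, "k_inhibition"),
            "AT1.c_ref": (self, "at1_c_ref"),
            "AT1.k_on": (self.at1_binding, "k_on"),
            "AT1.k_off": (self.at1_binding, "k_off"),
            "aldosterone.k_production": (self.aldosterone_secretion, "k_production"),
            "aldosterone.k_secretion": (self.aldosterone_secretion, "k_secretion"),
            "aldosterone.t_half": (self.species["aldosterone"], "half_life"),
            "prorenin.intracellular_ref": (
                self.prorenin_activation, "intracellular_prorenin_ref"),
            "prorenin.vmax_kid": (self.prorenin_activation, "vmax_kid"),
            "prorenin.km_kid": (self.prorenin_activation, "km_kid"),
            "prorenin.k_secretion": (self.prorenin_secretion, "k_secretion"),
            "prorenin.t_half": (self.species["prorenin"], "half_life"),
        }
        if path not in table:
            import difflib
            hint = difflib.get_close_matches(path, table, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigurationError(f"unknown parameter path {path!r}{suffix}")
        return table[path]

    def get(self, path: str) -> float:
        obj, attr = self._resolve(path)
        return float(getattr(obj, attr))

    def set(self, path: str, value: float) -> None:
        obj, attr = self._resolve(path)
        setattr(obj, attr, float(value))

    def with_overrides(self, overrides: Mapping[str, float]) -> "RAASParameters":
        new = copy.deepcopy(self)
        for path, value in overrides.items():
            new.set(path, value)
        return new

    def reference_concentrations(self) -> dict[str, float]:
        """Printed pre-administration venous steady-state concentrations."""
        return {name: self.species[name].reference_plasma_conc for name in HORMONES}


def _value(node: Any) -> float:
    """Unwrap ``{value: x, optimized: true}`` blocks of the parameter file."""
    if isinstance(node, Mapping):
        return float(node["value"])
    return float(node)


def load_raas_parameters(source: str | None = None) -> RAASParameters:
    """Load the cascade parameterisation from the packaged default file or
    a user-supplied YAML with the same species-block layout."""
    if source is None:
        ref = importlib.resources.files("raasim.data") / "raas_parameters.yaml"
        with importlib.resources.as_file(ref) as path:
            raw = yaml.safe_load(path.read_text())
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)

    def spec(name: str, block: Mapping[str, Any], **extra) -> SpeciesSpec:
        return SpeciesSpec(
            name=name,
            molecular_weight=_value(block["molecular_weight_kDa"]),
            half_life=_value(block["t_half_min"]) if "t_half_min" in block else None,
            plasma_only=bool(block.get("plasma_only", True)),
            reference_plasma_conc=_value(
                block.get("plasma_concentration_umol_per_L", 0.0)),
            log_p=(float(block["log_p"]) if "log_p" in block else None),
            protein_binding_pct=(
                float(block["protein_binding_pct"])
                if "protein_binding_pct" in block else None),
            **extra,
        )

    try:
        species = {name: spec(name, raw[name])
                   for name in ("AGT", "renin", "prorenin", "Ang1", "Ang2",
                                "aldosterone")}
        params = RAASParameters(
            species=species,
            renin_mm=MMKinetics(
                kcat=_value(raw["renin"]["kcat_per_min"]),
                km=_value(raw["renin"]["km_umol_per_L"]),
                enzyme="renin", substrate="AGT"),
            ace_mm=MMKinetics(
                kcat=_value(raw["ACE"]["kcat_per_min"]),
                km=_value(raw["ACE"]["km_umol_per_L"]),
                enzyme="ACE", substrate="Ang1"),
            at1_binding=BindingParams(
                k_on=_value(raw["AT1"]["k_on_L_per_umol_min"]),
                k_off=_value(raw["AT1"]["k_off_per_min"])),
            ace_binding=BindingParams(
                k_on=_value(raw["ACE"]["k_on_L_per_umol_min"]),
                k_off=_value(raw["ACE"]["k_off_per_min"])),
            agt_secretion=SecretionParams(
                k_secretion=_value(raw["AGT"]["k_secretion_L_per_min"]),
                source_organ="Liver"),
            prorenin_secretion=SecretionParams(
                k_secretion=_value(raw["prorenin"]["k_secretion_L_per_min"]),
                source_organ="Kidney"),
            aldosterone_secretion=SecretionParams(
                k_secretion=_value(raw["aldosterone"]["k_secretion_L_per_min"]),
                k_production=_value(raw["aldosterone"]["k_production_umol_per_min"]),
                source_organ="Venous Blood"),
            prorenin_activation=ProreninActivation(
                vmax_kid=_value(raw["prorenin"]["vmax_kid_umol_per_min_L"]),
                km_kid=_value(raw["prorenin"]["km_kid_umol_per_L"]),
                k_inhibition=_value(raw["Ang2"]["k_inhibition_umol_per_L"]),
                intracellular_prorenin_ref=_value(
                    raw["prorenin"]["renal_intracellular_umol_per_L"])),
            at1_c_ref=_value(raw["AT1"]["c_ref_umol_per_L"]),
            v_kidney_cell=_value(raw["prorenin"]["v_kidney_L"]),
            km_liv=_value(raw["carboxylesterase"]["km_liv_umol_per_L"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing parameter field: {exc}") from exc
    return params


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def _check_nonneg(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise DomainError(f"{name} must be >= 0")


def convective_transport_rate(q_organ, hct, c_pls_organ):
    """Convective plasma transport out of an organ (umol/min).

    r = Q_organ * (1 - HCT) * C_pls_organ: blood flow restricted to the
    plasma fraction carries the dissolved species.
    """
    _check_nonneg(q_organ=q_organ, hct=hct, c_pls_organ=c_pls_organ)
    if np.any(np.asarray(hct) >= 1.0):
        raise DomainError("hematocrit must be < 1")
    return q_organ * (1.0 - hct) * c_pls_organ


def secretion_rate(p: SecretionParams, c_cellular):
    """First-order endocrine secretion from an intracellular pool
    (umol/min), proportional to the intracellular concentration.  The
    zero-order ``k_production`` floor does not enter here; it belongs to
    aldosterone synthesis only."""
    _check_nonneg(c_cellular=c_cellular)
    return p.k_secretion * c_cellular


def prorenin_activation_rate(p: ProreninActivation, v_kidney,
                             c_prorenin_cell, c_ang2_renal_plasma):
    """Renal prorenin -> renin activation-and-secretion (umol/min).

    A competitive-inhibition Michaelis-Menten form in the intracellular
    prorenin concentration, with renal plasma Ang2 raising the apparent Km
    (the cascade's negative feedback):

        r = Vmax_kid * V_kidney * C_pro / (C_pro + Km_kid * (1 + C_Ang2/K_i))

    The single rate removes intracellular prorenin and delivers plasma
    renin in the kidney.
    """
    _check_nonneg(v_kidney=v_kidney, c_prorenin_cell=c_prorenin_cell,
                  c_ang2_renal_plasma=c_ang2_renal_plasma)
    km_app = p.km_kid * (1.0 + c_ang2_renal_plasma / p.k_inhibition)
    return p.vmax_kid * v_kidney * c_prorenin_cell / (c_prorenin_cell + km_app)


def degradation_rate(c, half_life):
    """First-order plasma degradation (umol/min/L): r = C * ln2 / t_half.

    Applied per plasma litre in every compartment holding the species.
    """
    _check_nonneg(c=c)
    if np.any(np.asarray(half_life) <= 0):
        raise DomainError("half-life must be > 0")
    return c * LN2 / half_life


def mm_conversion_rate(k: MMKinetics, v0, c_enzyme, c_prohormone):
    """Enzymatic prohormone conversion in one organ's plasma (umol/min):

        r = kcat * V0 * C_enzyme * C_pro / (C_pro + Km)

    Used for renin cleaving AGT -> Ang1 (C_enzyme = local renin) and for
    endothelial ACE converting Ang1 -> Ang2 (C_enzyme = free ACE).  The
    enzyme is catalytic, not consumed.
    """
    _check_nonneg(v0=v0, c_enzyme=c_enzyme, c_prohormone=c_prohormone)
    return k.kcat * v0 * c_enzyme * c_prohormone / (c_prohormone + k.km)


def binding_rate(b: BindingParams, c_free_target, c_ligand, c_complex):
    """Net reversible complex formation per plasma litre (umol/min/L):

        r = k_on * C_target_free * C_ligand - k_off * C_complex

    Used for Ang2 binding AT1 and for enalaprilat sequestering ACE.
    """
    _check_nonneg(c_free_target=c_free_target, c_ligand=c_ligand,
                  c_complex=c_complex)
    return b.k_on * c_free_target * c_ligand - b.k_off * c_complex


def aldosterone_synthesis_rate(p: SecretionParams, c_complex):
    """Aldosterone synthesis (umol/min), driven by the AT1-Ang2 receptor
    complex with a constitutive zero-order floor:

        r = k_secretion * C_complex + k_production
    """
    _check_nonneg(c_complex=c_complex)
    return p.k_secretion * c_complex + p.k_production
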
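"""Assembly and integration of the coupled RAAS + enalapril ODE system.

The state vector stacks, per plasma compartment, the molar amounts (umol)
of the six circulating hormones and the two drug compounds, the two
membrane-bound complexes (AT1-Ang2 and ACE-Enaat), and then a handful of
scalar pools: intracellular AGT (liver), intracellular prorenin (kidney),
the oral gut depot, liver intracellular Ena/Enaat, and cumulative mass
trackers used for balance checks.

Steady state: the hormone cascade is anchored to its printed venous
reference concentrations by two closure fluxes computed at assembly time
(zero-order synthesis of intracellular AGT and prorenin chosen so that
synthesis equals secretion plus conversion at the reference state), then
constructed by long-horizon stiff integration with a Newton root polish.

Dosing: dose events restart the integrator with a discontinuous depot
increment (oral: gut depot; IV: venous pool), which keeps event handling
exact and deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .drug import (AbsorptionParams, CarboxylesteraseParams, DoseEvent,
                   DrugSpec, load_drug_parameters)
from .errors import ConfigurationError, ConvergenceError, DomainError, SolverError
from .kinetics import HORMONES, LN2, RAASParameters
from .physiology import BodyModel, SubjectParams

__all__ = [
    "SimOptions",
    "DrugBundle",
    "SimulationState",
    "Trajectory",
    "RAASSystem",
    "assemble_system",
    "solve_steady_state",
    "simulate",
]

#: Plasma-borne species, in state-vector block order.
PLASMA_SPECIES = (*HORMONES, "Ena", "Enaat")
COMPLEX_SPECIES = ("AT1_complex", "ACE_complex")
SCALAR_STATES = (
    "AGT_cell", "prorenin_cell", "gut_Ena", "Ena_liver_cell",
    "Enaat_liver_cell", "unabsorbed_Ena", "cum_renal_Ena",
    "cum_hepatic_Ena", "cum_converted", "cum_renal_Enaat",
)
#: Scalar states that are pure accumulators (excluded from root solving).
TRACKER_STATES = ("unabsorbed_Ena", "cum_renal_Ena", "cum_hepatic_Ena",
                  "cum_converted", "cum_renal_Enaat")


@dataclass
class SimOptions:
    """Solver and model-structure options.

    ``complex_source`` selects which AT1-Ang2 complex concentration drives
    aldosterone synthesis: the plasma-volume-weighted whole-body mean or
    the kidney's local value.  ``ps_liver`` is the permeability-surface
    product (L/min) of the liver plasma/intracellular drug exchange;
    ``None`` uses the liver plasma flow (perfusion-limited uptake).
    """

    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-12
    complex_source: Literal["whole_body", "kidney"] = "whole_body"
    ace_binding: bool = True
    dynamic_raas: bool = True
    ps_liver: float | None = None
    check_negative: bool = True
    negative_threshold: float = -1e-12


@dataclass
class DrugBundle:
    """Everything the drug sub-model needs for one subject."""

    ena: DrugSpec
    enaat: DrugSpec
    absorption: AbsorptionParams
    esterase: CarboxylesteraseParams

    @classmethod
    def for_subject(cls, subject: SubjectParams) -> "DrugBundle":
        ena, enaat, absorption = load_drug_parameters(subject)
        return cls(ena=ena, enaat=enaat, absorption=absorption,
                   esterase=CarboxylesteraseParams(vmax_liv=subject.vmax_liv))


@dataclass
class SimulationState:
    """Molar amounts (umol) per named state variable at one time point."""

    time: float
    y: np.ndarray
    system: "RAASSystem"

    def amount(self, species: str, compartment: str | None = None) -> float:
        return float(self.y[self.system.state_index(species, compartment)])

    def concentration(self, species: str, compartment: str) -> float:
        """Plasma concentration (umol/L) of a plasma-borne species or
        complex in one compartment."""
        i = self.system.state_index(species, compartment)
        v = self.system.body[compartment].plasma_volume
        return float(self.y[i]) / v

    def venous_concentration(self, species: str) -> float:
        return self.concentration(species, "Venous Blood")

    def copy(self) -> "SimulationState":
        return SimulationState(self.time, self.y.copy(), self.system)


@dataclass
class Trajectory:
    """Dense simulation output on a time grid."""

    times: np.ndarray                 # (n_t,), min, strictly increasing
    values: np.ndarray                # (n_t, n_states), umol
    system: "RAASSystem"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("trajectory times must be strictly increasing")

    def state_at(self, index: int) -> SimulationState:
        return SimulationState(float(self.times[index]),
                               self.values[index].copy(), self.system)

    def amounts(self, species: str, compartment: str | None = None) -> np.ndarray:
        return self.values[:, self.system.state_index(species, compartment)]

    def concentrations(self, species: str, compartment: str) -> np.ndarray:
        v = self.system.body[compartment].plasma_volume
        return self.amounts(species, compartment) / v

    def venous_concentrations(self, species: str) -> np.ndarray:
        return self.concentrations(species, "Venous Blood")

    def to_frame(self, species: Sequence[str] | None = None,
                 compartments: Sequence[str] | None = None) -> pd.DataFrame:
        """Tidy table: time_min, species, compartment, concentration_umol_per_L."""
        species = species or (*PLASMA_SPECIES, *COMPLEX_SPECIES)
        compartments = compartments or self.system.body.names
        rows = []
        for sp in species:
            for comp in compartments:
                conc = self.concentrations(sp, comp)
                rows.append(pd.DataFrame({
                    "time_min": self.times,
                    "species": sp,
                    "compartment": comp,
                    "concentration_umol_per_L": conc,
                }))
        return pd.concat(rows, ignore_index=True)

    def content_hash(self) -> str:
        """SHA-256 over grid and states; bit-identical runs hash equal."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.times).tobytes())
        h.update(np.ascontiguousarray(self.values).tobytes())
        h.update(json.dumps(self.metadata.get("solver", {}),
                            sort_keys=True).encode())
        return h.hexdigest()

    def check_nonnegative(self, threshold: float = -1e-12) -> None:
        lowest = float(self.values.min())
        if lowest < threshold:
            i, j = np.unravel_index(self.values.argmin(), self.values.shape)
            raise SolverError(
                f"state {self.system.state_names[j]!r} reached {lowest:.3e} umol "
                f"at t = {self.times[i]:.1f} min", last_time=float(self.times[i]))


class RAASSystem:
    """The assembled right-hand side of the coupled model.

    Every derivative term is attributable to exactly one kinetics/drug
    operation; ``term_registry`` lists them with their compartments for
    introspection and testing.
    """

    def __init__(self, body: BodyModel, raas: RAASParameters,
                 drug: DrugBundle | None = None,
                 options: SimOptions | None = None):
        if not isinstance(raas, RAASParameters):
            raise ConfigurationError("raas parameters must be RAASParameters")
        for name in HORMONES:
            if name not in raas.species:
                raise ConfigurationError(f"missing species block {name!r}")
        self.body = body
        self.raas = raas
        self.options = options or SimOptions()
        self.subject = body.subject or SubjectParams()
        self.drug = drug if drug is not None else DrugBundle.for_subject(self.subject)

        n = self.n_comp = len(body.compartments)
        self.volumes = body.plasma_volumes
        self.total_plasma_volume = body.total_plasma_volume
        self.flow_operator = body.flow_matrix() @ np.diag(1.0 / self.volumes)
        self.i_art = body.index("Arterial Blood")
        self.i_ven = body.index("Venous Blood")
        self.i_kid = body.index("Kidney")
        self.i_liv = body.index("Liver")

        from .physiology import expressed_concentration
        self.ace_total = np.array([
            expressed_concentration(self.subject.ace_c_ref, c.ace_expression_pct)
            for c in body.compartments])
        self.at1_total = np.array([
            expressed_concentration(raas.at1_c_ref, c.at1_expression_pct)
            for c in body.compartments])

        self.v_kidney_cell = body["Kidney"].intracellular_volume or raas.v_kidney_cell
        self.v_liver_cell = body["Liver"].intracellular_volume
        self.ps_liver = (self.options.ps_liver
                         if self.options.ps_liver is not None
                         else body["Liver"].blood_flow * (1 - body.hematocrit))
        self.cl_hepatic_ena = self.drug.ena.hepatic_clearance / 1000.0  # L/min

        # state layout ----------------------------------------------------
        self.species_offset = {sp: i * n for i, sp in enumerate(PLASMA_SPECIES)}
        self.complex_offset = {sp: (len(PLASMA_SPECIES) + i) * n
                               for i, sp in enumerate(COMPLEX_SPECIES)}
        base = (len(PLASMA_SPECIES) + len(COMPLEX_SPECIES)) * n
        self.scalar_index = {name: base + i for i, name in enumerate(SCALAR_STATES)}
        self.n_states = base + len(SCALAR_STATES)
        self.state_names = self._build_state_names()

        self._compute_closures()
        self.term_registry = self._build_registry()
        self._sparsity: np.ndarray | None = None

    # -- bookkeeping -------------------------------------------------------
    def _build_state_names(self) -> list[str]:
        names = []
        for sp in (*PLASMA_SPECIES, *COMPLEX_SPECIES):
            names.extend(f"{sp}@{c}" for c in self.body.names)
        names.extend(SCALAR_STATES)
        return names

    def state_index(self, species: str, compartment: str | None = None) -> int:
        if species in self.scalar_index:
            return self.scalar_index[species]
        if compartment is None:
            raise ConfigurationError(
                f"{species!r} is per-compartment; a compartment is required")
        i = self.body.index(compartment)
        if species in self.species_offset:
            return self.species_offset[species] + i
        if species in self.complex_offset:
            return self.complex_offset[species] + i
        raise ConfigurationError(f"unknown species {species!r}")

    def species_slice(self, species: str) -> slice:
        off = dict(self.species_offset, **self.complex_offset)[species]
        return slice(off, off + self.n_comp)

    @property
    def raas_mask(self) -> np.ndarray:
        """Boolean mask of states entering the steady-state root solve
        (everything except the pure accumulators)."""
        mask = np.ones(self.n_states, dtype=bool)
        for name in TRACKER_STATES:
            mask[self.scalar_index[name]] = False
        return mask

    # -- closures ----------------------------------------------------------
    def _compute_closures(self) -> None:
        """Zero-order synthesis rates for the intracellular AGT and
        prorenin pools, chosen once so that the printed reference venous
        concentrations are a self-consistent steady state: synthesis equals
        secretion (plus conversion) when the intracellular pools sit at
        their reference concentrations."""
        p = self.raas
        ref = p.reference_concentrations()
        vp = self.total_plasma_volume

        # AGT: plasma losses at reference = degradation + renin conversion
        agt_loss = (ref["AGT"] * LN2 / p.species["AGT"].half_life * vp
                    + p.renin_mm.kcat * vp * ref["renin"]
                    * ref["AGT"] / (ref["AGT"] + p.renin_mm.km))
        if p.agt_secretion.k_secretion <= 0:
            raise ConfigurationError("AGT.k_secretion must be > 0")
        self.agt_cell_ref = agt_loss / p.agt_secretion.k_secretion  # umol/L
        self.agt_synthesis = agt_loss                               # umol/min

        # prorenin: intracellular losses = secretion + activation at reference
        act = p.prorenin_activation
        km_app = act.km_kid * (1.0 + ref["Ang2"] / act.k_inhibition)
        r3_ref = (act.vmax_kid * self.v_kidney_cell
                  * act.intracellular_prorenin_ref
                  / (act.intracellular_prorenin_ref + km_app))
        self.prorenin_cell_ref = act.intracellular_prorenin_ref
        self.prorenin_synthesis = (
            r3_ref + p.prorenin_secretion.k_secretion * self.prorenin_cell_ref)

    def _build_registry(self) -> list[dict]:
        names = self.body.names
        ace_organs = [c.name for c in self.body.compartments
                      if c.ace_expression_pct > 0]
        at1_organs = [c.name for c in self.body.compartments
                      if c.at1_expression_pct > 0]
        reg = [
            {"op": "convective_transport_rate", "species": list(PLASMA_SPECIES),
             "compartments": names},
            {"op": "secretion_rate", "species": "AGT", "compartments": ["Liver"]},
            {"op": "secretion_rate", "species": "prorenin",
             "compartments": ["Kidney"]},
            {"op": "prorenin_activation_rate", "species": "renin",
             "compartments": ["Kidney"]},
            {"op": "mm_conversion_rate", "enzyme": "renin",
             "substrate": "AGT", "compartments": names},
            {"op": "mm_conversion_rate", "enzyme": "ACE",
             "substrate": "Ang1", "compartments": ace_organs},
            {"op": "binding_rate", "target": "AT1", "ligand": "Ang2",
             "compartments": at1_organs},
            {"op": "aldosterone_synthesis_rate", "species": "aldosterone",
             "compartments": ["Venous Blood"]},
        ]
        reg += [{"op": "degradation_rate", "species": sp,
                 "compartments": names} for sp in HORMONES]
        reg += [
            {"op": "oral_absorption_rate", "species": "Ena",
             "compartments": ["Liver"]},
            {"op": "hepatic_conversion_rate", "species": "Ena",
             "compartments": ["Liver"]},
            {"op": "renal_clearance_rate", "species": "Ena",
             "compartments": ["Kidney"]},
            {"op": "renal_clearance_rate", "species": "Enaat",
             "compartments": ["Kidney"]},
        ]
        if self.options.ace_binding:
            reg.append({"op": "binding_rate", "target": "ACE",
                        "ligand": "Enaat", "compartments": ace_organs})
        return reg

    # -- reference / initial state ----------------------------------------
    def reference_state(self) -> SimulationState:
        """Drug-free state at the printed reference concentrations, with
        AT1 complexes pre-equilibrated and intracellular pools at their
        closure values."""
        y = np.zeros(self.n_states)
        ref = self.raas.reference_concentrations()
        for sp in HORMONES:
            y[self.species_slice(sp)] = ref[sp] * self.volumes
        kd = self.raas.at1_binding.kd
        occ = ref["Ang2"] / (ref["Ang2"] + kd)
        y[self.species_slice("AT1_complex")] = self.at1_total * occ * self.volumes
        y[self.scalar_index["AGT_cell"]] = self.agt_cell_ref * self.v_liver_cell
        y[self.scalar_index["prorenin_cell"]] = (
            self.prorenin_cell_ref * self.v_kidney_cell)
        return SimulationState(0.0, y, self)

    # -- right-hand side ---------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.raas
        opt = self.options
        n = self.n_comp
        v = self.volumes
        dy = np.zeros_like(y)

        n_plasma = len(PLASMA_SPECIES)
        plasma = y[: n_plasma * n].reshape(n_plasma, n)
        conc = plasma / v
        d_plasma = dy[: n_plasma * n].reshape(n_plasma, n)

        # convective transport (Eq.-1 form), all plasma-borne species at once
        d_plasma += plasma @ self.flow_operator.T

        i_agt, i_ren, i_pro, i_a1, i_a2, i_ald, i_ena, i_enaat = range(n_plasma)
        at1_cplx = y[self.species_slice("AT1_complex")]
        ace_cplx = y[self.species_slice("ACE_complex")]
        c_at1_cplx = at1_cplx / v
        c_ace_cplx = ace_cplx / v
        ace_free = self.ace_total - c_ace_cplx

        s = self.scalar_index
        c_agt_cell = y[s["AGT_cell"]] / self.v_liver_cell
        c_pro_cell = y[s["prorenin_cell"]] / self.v_kidney_cell
        c_ena_cell = y[s["Ena_liver_cell"]] / self.v_liver_cell
        c_enaat_cell = y[s["Enaat_liver_cell"]] / self.v_liver_cell

        if opt.dynamic_raas:
            # degradation (per litre x plasma volume = first order on amounts)
            for i, sp in enumerate(HORMONES):
                d_plasma[i] -= plasma[i] * LN2 / p.species[sp].half_life

            # AGT secretion from hepatocytes; intracellular closure
            sec_agt = p.agt_secretion.k_secretion * c_agt_cell
            d_plasma[i_agt, self.i_liv] += sec_agt
            dy[s["AGT_cell"]] += self.agt_synthesis - sec_agt

            # renin-mediated AGT -> Ang1, all plasma compartments
            r_renin = (p.renin_mm.kcat * v * conc[i_ren]
                       * conc[i_agt] / (conc[i_agt] + p.renin_mm.km))
            d_plasma[i_agt] -= r_renin
            d_plasma[i_a1] += r_renin

            # ACE-mediated Ang1 -> Ang2, organs with ACE expression
            r_ace = (p.ace_mm.kcat * v * ace_free
                     * conc[i_a1] / (conc[i_a1] + p.ace_mm.km))
            d_plasma[i_a1] -= r_ace
            d_plasma[i_a2] += r_ace

            # prorenin: secretion and feedback-inhibited activation (kidney)
            act = p.prorenin_activation
            sec_pro = p.prorenin_secretion.k_secretion * c_pro_cell
            km_app = act.km_kid * (1.0 + conc[i_a2, self.i_kid] / act.k_inhibition)
            r3 = (act.vmax_kid * self.v_kidney_cell * c_pro_cell
                  / (c_pro_cell + km_app))
            d_plasma[i_pro, self.i_kid] += sec_pro
            d_plasma[i_ren, self.i_kid] += r3
            dy[s["prorenin_cell"]] += self.prorenin_synthesis - sec_pro - r3

            # AT1 binding (per litre x V): bound Ang2 is protected
            rb = (p.at1_binding.k_on * (self.at1_total - c_at1_cplx) * conc[i_a2]
                  - p.at1_binding.k_off * c_at1_cplx) * v
            d_plasma[i_a2] -= rb
            dy[self.species_slice("AT1_complex")] += rb

            # aldosterone synthesis into the venous pool
            if opt.complex_source == "whole_body":
                c_drive = at1_cplx.sum() / self.total_plasma_volume
            else:
                c_drive = c_at1_cplx[self.i_kid]
            d_plasma[i_ald, self.i_ven] += (
                p.aldosterone_secretion.k_secretion * c_drive
                + p.aldosterone_secretion.k_production)

        # ---- drug sub-model ---------------------------------------------
        ab = self.drug.absorption
        r_abs = ab.ka * y[s["gut_Ena"]]
        dy[s["gut_Ena"]] -= r_abs
        d_plasma[i_ena, self.i_liv] += r_abs

        # liver plasma <-> intracellular exchange (perfusion-limited)
        k_org_ena = self.drug.ena.k_org("Liver")
        k_org_enaat = self.drug.enaat.k_org("Liver")
        ex_ena = self.ps_liver * (conc[i_ena, self.i_liv] - c_ena_cell / k_org_ena)
        ex_enaat = self.ps_liver * (conc[i_enaat, self.i_liv]
                                    - c_enaat_cell / k_org_enaat)
        d_plasma[i_ena, self.i_liv] -= ex_ena
        dy[s["Ena_liver_cell"]] += ex_ena
        d_plasma[i_enaat, self.i_liv] -= ex_enaat
        dy[s["Enaat_liver_cell"]] += ex_enaat

        # hepatic carboxylesterase conversion and hepatic clearance of Ena
        est = self.drug.esterase
        r_conv = (est.vmax_liv * self.v_liver_cell * c_ena_cell
                  / (c_ena_cell + est.km_liv))
        r_hep = self.cl_hepatic_ena * c_ena_cell
        dy[s["Ena_liver_cell"]] -= r_conv + r_hep
        dy[s["Enaat_liver_cell"]] += r_conv
        dy[s["cum_converted"]] += r_conv
        dy[s["cum_hepatic_Ena"]] += r_hep

        # renal clearance from kidney plasma
        bw = self.subject.body_weight
        r_ren_ena = self.drug.ena.renal_clearance_per_kg * bw * conc[i_ena, self.i_kid]
        r_ren_enaat = (self.drug.enaat.renal_clearance_per_kg * bw
                       * conc[i_enaat, self.i_kid])
        d_plasma[i_ena, self.i_kid] -= r_ren_ena
        d_plasma[i_enaat, self.i_kid] -= r_ren_enaat
        dy[s["cum_renal_Ena"]] += r_ren_ena
        dy[s["cum_renal_Enaat"]] += r_ren_enaat

        # Enaat sequestration of endothelial ACE
        if opt.ace_binding:
            rbe = (p.ace_binding.k_on * ace_free * conc[i_enaat]
                   - p.ace_binding.k_off * c_ace_cplx) * v
            d_plasma[i_enaat] -= rbe
            dy[self.species_slice("ACE_complex")] += rbe

        return dy

    # -- Jacobian sparsity (probed once, reused by the stiff solver) ------
    def jac_sparsity(self) -> np.ndarray:
        if self._sparsity is None:
            rng = np.random.default_rng(20130204)
            pattern = np.zeros((self.n_states, self.n_states), dtype=bool)
            for _ in range(2):
                y0 = rng.uniform(0.3, 1.0, self.n_states) * 1e-4
                f0 = self.rhs(0.0, y0)
                for j in range(self.n_states):
                    yj = y0.copy()
                    yj[j] *= 1.37
                    pattern[:, j] |= (self.rhs(0.0, yj) - f0) != 0.0
            pattern |= np.eye(self.n_states, dtype=bool)
            self._sparsity = pattern
        return self._sparsity

    def parameter_fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.raas).encode())
        h.update(repr(self.drug).encode())
        h.update(repr(self.subject).encode())
        h.update(repr(self.options).encode())
        h.update(self.volumes.tobytes())
        return h.hexdigest()[:16]


def assemble_system(body: BodyModel, raas_params: RAASParameters,
                    drug_params: DrugBundle | None = None,
                    options: SimOptions | None = None) -> RAASSystem:
    """Build the deterministic right-hand side of the coupled model.

    Raises :class:`ConfigurationError` naming the missing field if the
    parameterisation is incomplete.
    """
    return RAASSystem(body, raas_params, drug_params, options)


# ---------------------------------------------------------------------------
# reduced drug-only integration (fast path for absorption fitting)
# ---------------------------------------------------------------------------

def drug_only_curves(system: RAASSystem, oral_dose_umol: float,
                     times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Venous Ena/Enaat concentration-time curves after one oral dose at
    t = 0, integrating only the drug states (gut depot, plasma amounts,
    liver intracellular pools, ACE-Enaat complexes).

    The drug PK does not depend on the hormone concentrations, so this
    reduced 54-state system reproduces the full model's drug curves; it
    exists because random-search identification evaluates thousands of
    candidate curves.
    """
    n = system.n_comp
    v = system.volumes
    fop = system.flow_operator
    i_liv, i_kid = system.i_liv, system.i_kid
    ab = system.drug.absorption
    est = system.drug.esterase
    bw = system.subject.body_weight
    cl_ren_ena = system.drug.ena.renal_clearance_per_kg * bw
    cl_ren_enaat = system.drug.enaat.renal_clearance_per_kg * bw
    k_org_ena = system.drug.ena.k_org("Liver")
    k_org_enaat = system.drug.enaat.k_org("Liver")
    ps = system.ps_liver
    vcell = system.v_liver_cell
    cl_hep = system.cl_hepatic_ena
    bind = system.options.ace_binding
    kon, koff = system.raas.ace_binding.k_on, system.raas.ace_binding.k_off
    ace_total = system.ace_total

    s_ena, s_enaat = slice(0, n), slice(n, 2 * n)
    s_cplx = slice(2 * n, 3 * n)
    i_gut, i_ecell, i_acell = 3 * n, 3 * n + 1, 3 * n + 2

    def rhs(t, x):
        dx = np.empty_like(x)
        ena, enaat, cplx = x[s_ena], x[s_enaat], x[s_cplx]
        c_ena, c_enaat, c_cplx = ena / v, enaat / v, cplx / v
        d_ena = fop @ ena
        d_enaat = fop @ enaat
        r_abs = ab.ka * x[i_gut]
        dx[i_gut] = -r_abs
        c_ecell = x[i_ecell] / vcell
        c_acell = x[i_acell] / vcell
        ex_ena = ps * (c_ena[i_liv] - c_ecell / k_org_ena)
        ex_enaat = ps * (c_enaat[i_liv] - c_acell / k_org_enaat)
        r_conv = est.vmax_liv * vcell * c_ecell / (c_ecell + est.km_liv)
        r_hep = cl_hep * c_ecell
        d_ena[i_liv] += r_abs - ex_ena
        d_enaat[i_liv] -= ex_enaat
        dx[i_ecell] = ex_ena - r_conv - r_hep
        dx[i_acell] = ex_enaat + r_conv
        d_ena[i_kid] -= cl_ren_ena * c_ena[i_kid]
        d_enaat[i_kid] -= cl_ren_enaat * c_enaat[i_kid]
        if bind:
            rbe = (kon * (ace_total - c_cplx) * c_enaat - koff * c_cplx) * v
            d_enaat -= rbe
            dx[s_cplx] = rbe
        else:
            dx[s_cplx] = 0.0
        dx[s_ena] = d_ena
        dx[s_enaat] = d_enaat
        return dx

    x0 = np.zeros(3 * n + 3)
    x0[i_gut] = ab.f_abs * oral_dose_umol
    times = np.asarray(times, dtype=float)
    key = "_drug_only_sparsity"
    pattern = getattr(system, key, None)
    if pattern is None:
        rng = np.random.default_rng(20130208)
        pattern = np.zeros((x0.size, x0.size), dtype=bool)
        for _ in range(2):
            xp = rng.uniform(0.3, 1.0, x0.size)
            f0 = rhs(0.0, xp)
            for j in range(x0.size):
                xj = xp.copy()
                xj[j] *= 1.37
                pattern[:, j] |= (rhs(0.0, xj) - f0) != 0.0
        pattern |= np.eye(x0.size, dtype=bool)
        setattr(system, key, pattern)
    opt = system.options
    sol = solve_ivp(rhs, (0.0, float(times[-1])), x0, method=opt.method,
                    rtol=opt.rtol, atol=opt.atol, t_eval=times,
                    jac_sparsity=pattern)
    if not sol.success:
        raise SolverError(f"drug-only integration failed: {sol.message}")
    i_ven = system.i_ven
    return (sol.y[s_ena][i_ven] / v[i_ven], sol.y[s_enaat][i_ven] / v[i_ven])


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def _integrate(system: RAASSystem, y0: np.ndarray, t0: float, t1: float,
               t_eval: np.ndarray | None = None, dense: bool = False):
    opt = system.options
    sol = solve_ivp(system.rhs, (t0, t1), y0, method=opt.method,
                    rtol=opt.rtol, atol=opt.atol, t_eval=t_eval,
                    dense_output=dense, jac_sparsity=system.jac_sparsity())
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t0
        raise SolverError(
            f"integration failed at t = {last:.2f} min: {sol.message} "
            f"(stiff system; consider loosening rtol/atol)", last_time=last)
    return sol

def steady_state_residual(system: RAASSystem, y: np.ndarray,
                          eps: float = 1e-12) -> tuple[float, int]:
    """Max relative rate |dA/dt| / max(A, eps) over non-tracker states,
    and the index of the worst state."""
    mask = system.raas_mask
    dy = system.rhs(0.0, y)
    rel = np.abs(dy[mask]) / np.maximum(np.abs(y[mask]), eps)
    worst_local = int(np.argmax(rel))
    worst = np.flatnonzero(mask)[worst_local]
    return float(rel[worst_local]), worst


def solve_steady_state(system: RAASSystem, horizon: float | None = None,
                       y0: np.ndarray | None = None,
                       residual_tol: float = 1e-9,
                       root_polish: bool = True) -> SimulationState:
    """Construct the drug-free pre-administration steady state.

    Long-horizon stiff integration from the reference state (default
    horizon: 10x the longest half-life chain, at least 5000 min) followed
    by a Newton (hybr) root polish on the non-accumulator states.  Raises
    :class:`ConvergenceError` with the worst residual term if the relative
    rate criterion is not met.
    """
    if horizon is None:
        half_lives = [sp.half_life for sp in system.raas.species.values()
                      if sp.half_life]
        horizon = max(5000.0, 10.0 * 10.0 * max(half_lives))
    start = y0 if y0 is not None else system.reference_state().y
    sol = _integrate(system, start, 0.0, horizon)
    y = sol.y[:, -1].copy()
    if root_polish:
        y = _root_polish(system, y)
    res, worst = steady_state_residual(system, y)
    if res > residual_tol:
        raise ConvergenceError(
            f"steady state not converged: worst relative rate {res:.2e}/min "
            f"on state {system.state_names[worst]!r}")
    y[~system.raas_mask] = 0.0
    return SimulationState(0.0, y, system)


def _root_polish(system: RAASSystem, y_guess: np.ndarray) -> np.ndarray:
    mask = system.raas_mask
    fixed = y_guess[~mask]

    def fun(x):
        y = np.empty(system.n_states)
        y[mask] = x
        y[~mask] = fixed
        return system.rhs(0.0, y)[mask]

    # scale states to O(1) so hybr's step control treats them evenly
    scale = np.maximum(np.abs(y_guess[mask]), 1e-12)
    res = root(lambda z: fun(z * scale), y_guess[mask] / scale,
               method="hybr", options={"xtol": 1e-12})
    if res.success:
        y = y_guess.copy()
        y[mask] = res.x * scale
        return y
    return y_guess


def fast_steady_state(system: RAASSystem, y_guess: np.ndarray | None = None,
                      residual_tol: float = 1e-9) -> SimulationState:
    """Warm-startable steady state for inner optimisation loops: root solve
    first, long integration only as fallback."""
    start = y_guess if y_guess is not None else system.reference_state().y
    y = _root_polish(system, start)
    res, _ = steady_state_residual(system, y)
    if res > residual_tol or np.any(y[system.raas_mask] < -1e-15):
        return solve_steady_state(system, y0=start, residual_tol=residual_tol)
    y = y.copy()
    y[~system.raas_mask] = 0.0
    return SimulationState(0.0, y, system)


# ---------------------------------------------------------------------------
# dosing and simulation
# ---------------------------------------------------------------------------

def _apply_dose(system: RAASSystem, y: np.ndarray, dose: DoseEvent) -> None:
    from .units import mg_to_umol
    s = system.scalar_index
    if dose.compound == "Ena":
        mw = system.drug.ena.molecular_weight
    else:
        mw = system.drug.enaat.molecular_weight
    amount = mg_to_umol(dose.amount, mw)
    if dose.route == "oral":
        if dose.compound != "Ena":
            raise ConfigurationError("oral dosing is modelled for Ena only")
        f = system.drug.absorption.f_abs
        y[s["gut_Ena"]] += f * amount
        y[s["unabsorbed_Ena"]] += (1.0 - f) * amount
    else:
        sp = "Ena" if dose.compound == "Ena" else "Enaat"
        y[system.state_index(sp, "Venous Blood")] += amount


def simulate(system: RAASSystem, initial: SimulationState,
             doses: Sequence[DoseEvent] = (), horizon: float = 3000.0,
             grid: float | np.ndarray = 5.0) -> Trajectory:
    """Integrate the coupled model over ``horizon`` minutes with dose
    events applied as exact depot discontinuities (integrator restart).

    ``grid`` is either a spacing (min) or an explicit strictly increasing
    time array starting at the initial time.
    """
    if horizon <= 0:
        raise DomainError("horizon must be > 0")
    t0 = initial.time
    if np.isscalar(grid):
        times = np.arange(t0, t0 + horizon + 0.5 * float(grid), float(grid))
    else:
        times = np.asarray(grid, dtype=float)
        if times[0] != t0:
            raise DomainError("explicit grid must start at the initial time")
    t_end = t0 + horizon
    doses = sorted(doses, key=lambda d: d.time)
    for d in doses:
        if not t0 <= d.time <= t_end:
            raise DomainError(f"dose at t = {d.time} outside simulation horizon")

    y = initial.y.copy()
    out_t: list[np.ndarray] = [np.array([t0])]
    out_y: list[np.ndarray] = [y.copy()[None, :]]
    seg_start = t0
    pending = list(doses)
    while True:
        seg_end = pending[0].time if pending else t_end
        if seg_end > seg_start:
            sol = _integrate(system, y, seg_start, seg_end, dense=True)
            pts = times[(times > seg_start) & (times < seg_end)]
            if pts.size:
                out_t.append(pts)
                out_y.append(sol.sol(pts).T)
            y = sol.y[:, -1].copy()
            if seg_end in times or seg_end == t_end:
                out_t.append(np.array([seg_end]))
                out_y.append(y.copy()[None, :])
        while pending and pending[0].time == seg_end:
            _apply_dose(system, y, pending.pop(0))
        seg_start = seg_end
        if seg_start >= t_end:
            break

    t_all = np.concatenate(out_t)
    y_all = np.vstack(out_y)
    keep = np.concatenate(([True], np.diff(t_all) > 0))
    traj = Trajectory(
        times=t_all[keep], values=y_all[keep], system=system,
        metadata={
            "parameter_fingerprint": system.parameter_fingerprint(),
            "solver": {"method": system.options.method,
                       "rtol": system.options.rtol,
                       "atol": system.options.atol},
            "doses": [vars(d) for d in doses],
        })
    if system.options.check_negative:
        traj.check_nonnegative(system.options.negative_threshold)
    traj.metadata["content_hash"] = traj.content_hash()
    return traj
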
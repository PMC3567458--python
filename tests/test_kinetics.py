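import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import raasim
from raasim.errors import DomainError
from raasim.kinetics import (LN2, BindingParams, MMKinetics, ProreninActivation,
                             SecretionParams, aldosterone_synthesis_rate,
                             binding_rate, convective_transport_rate,
                             degradation_rate, mm_conversion_rate,
                             prorenin_activation_rate, secretion_rate)

positive = st.floats(min_value=1e-8, max_value=1e3, allow_nan=False)
conc = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def test_convective_transport_worked_example():
    assert convective_transport_rate(1.0, 0.47, 2.0) == pytest.approx(1.06)
    assert convective_transport_rate(1.0, 0.3, 0.0) == 0.0
    assert convective_transport_rate(0.0, 0.3, 5.0) == 0.0


def test_convective_transport_rejects_full_hematocrit():
    with pytest.raises(DomainError):
        convective_transport_rate(1.0, 1.0, 2.0)


def test_secretion_is_linear_in_cellular_concentration():
    p = SecretionParams(k_secretion=7.81)
    assert secretion_rate(p, 0.0) == 0.0
    assert secretion_rate(p, 1e-6) == pytest.approx(7.81e-6)
    assert secretion_rate(p, 2e-6) == pytest.approx(2 * secretion_rate(p, 1e-6))


def test_prorenin_activation_saturation_limit():
    """At saturating intracellular prorenin the rate tends to
    Vmax_kid * V_kidney = 1.62 * 0.24 umol/min."""
    p = ProreninActivation(vmax_kid=1.62, km_kid=4.68e-2, k_inhibition=1.87e-8,
                           intracellular_prorenin_ref=1.1e-4)
    rate = prorenin_activation_rate(p, 0.24, 1e15, 5.0)
    assert rate == pytest.approx(0.3888, rel=1e-6)


def test_prorenin_activation_reduces_to_mm_without_ang2():
    p = ProreninActivation(vmax_kid=1.62, km_kid=4.68e-2, k_inhibition=1.87e-8,
                           intracellular_prorenin_ref=1.1e-4)
    c = 1.1e-4
    expected = 1.62 * 0.24 * c / (c + 4.68e-2)
    assert prorenin_activation_rate(p, 0.24, c, 0.0) == pytest.approx(expected)


def test_degradation_worked_example():
    # angiotensin 2 at its reference concentration and 1.54-min half-life
    assert degradation_rate(4.84e-6, 1.54) == pytest.approx(2.18e-6, rel=1e-3)
    assert degradation_rate(0.0, 3.0) == 0.0
    assert degradation_rate(1.7, np.log(2)) == pytest.approx(1.7)


def test_mm_conversion_worked_example():
    # renin cleaving AGT, per litre of plasma
    k = MMKinetics(kcat=3.6, km=5.04e-2, enzyme="renin", substrate="AGT")
    rate = mm_conversion_rate(k, 1.0, 3.62e-7, 0.60)
    assert rate == pytest.approx(1.20e-6, rel=2e-3)
    assert mm_conversion_rate(k, 1.0, 0.0, 0.60) == 0.0


def test_mm_conversion_saturates_at_kcat_v_e():
    k = MMKinetics(kcat=2.0, km=1e-3, enzyme="e", substrate="s")
    assert mm_conversion_rate(k, 3.0, 0.5, 1e6) == pytest.approx(
        2.0 * 3.0 * 0.5, rel=1e-5)


def test_enaat_ace_dissociation_constant():
    b = BindingParams(k_on=35.16, k_off=2.15e-2)
    assert b.kd == pytest.approx(6.11e-4, rel=1e-3)


def test_binding_rate_zero_at_equilibrium():
    b = BindingParams(k_on=23.5, k_off=3.07e-2)
    c0, c2 = 0.5, 1e-4
    c_complex = b.k_on * c0 * c2 / b.k_off
    assert binding_rate(b, c0, c2, c_complex) == pytest.approx(0.0, abs=1e-18)
    assert binding_rate(b, c0, 0.0, 0.0) == 0.0


def test_aldosterone_synthesis_affine_in_complex():
    p = SecretionParams(k_secretion=7.81, k_production=1.51e-6)
    assert aldosterone_synthesis_rate(p, 0.0) == pytest.approx(1.51e-6)
    assert aldosterone_synthesis_rate(p, 1e-7) == pytest.approx(2.29e-6, rel=1e-3)
    slope = (aldosterone_synthesis_rate(p, 2e-7)
             - aldosterone_synthesis_rate(p, 1e-7)) / 1e-7
    assert slope == pytest.approx(7.81)


# ---------------------------------------------------------------------------
# oracle equivalence: each rate law vs an independent scalar evaluation of
# its printed formula, over a random parameter grid
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=200)
@given(q=positive, hct=st.floats(min_value=0.0, max_value=0.99), c=conc)
def test_convection_matches_formula(q, hct, c):
    assert convective_transport_rate(q, hct, c) == pytest.approx(
        q * (1 - hct) * c, rel=1e-12, abs=1e-300)


@settings(derandomize=True, max_examples=200)
@given(vmax=positive, km=positive, ki=positive, vk=positive,
       c_pro=conc, c_ang2=conc)
def test_prorenin_activation_matches_formula(vmax, km, ki, vk, c_pro, c_ang2):
    p = ProreninActivation(vmax_kid=vmax, km_kid=km, k_inhibition=ki,
                           intracellular_prorenin_ref=1.0)
    expected = vmax * vk * c_pro / (c_pro + km * (1 + c_ang2 / ki))
    assert prorenin_activation_rate(p, vk, c_pro, c_ang2) == pytest.approx(
        expected, rel=1e-12, abs=1e-300)


@settings(derandomize=True, max_examples=200)
@given(kcat=positive, km=positive, v0=positive, c_e=conc, c_s=conc)
def test_mm_conversion_matches_formula(kcat, km, v0, c_e, c_s):
    k = MMKinetics(kcat=kcat, km=km, enzyme="e", substrate="s")
    expected = kcat * v0 * c_e * c_s / (c_s + km)
    assert mm_conversion_rate(k, v0, c_e, c_s) == pytest.approx(
        expected, rel=1e-12, abs=1e-300)


@settings(derandomize=True, max_examples=200)
@given(kon=positive, koff=positive, c0=conc, c2=conc, cc=conc)
def test_binding_matches_formula(kon, koff, c0, c2, cc):
    b = BindingParams(k_on=kon, k_off=koff)
    assert binding_rate(b, c0, c2, cc) == pytest.approx(
        kon * c0 * c2 - koff * cc, rel=1e-12, abs=1e-300)


@settings(derandomize=True, max_examples=200)
@given(c=conc, t_half=positive)
def test_degradation_matches_formula(c, t_half):
    assert degradation_rate(c, t_half) == pytest.approx(
        c * LN2 / t_half, rel=1e-12, abs=1e-300)


@settings(derandomize=True, max_examples=200)
@given(ks=positive, kp=positive, cc=conc)
def test_aldosterone_synthesis_matches_formula(ks, kp, cc):
    p = SecretionParams(k_secretion=ks, k_production=kp)
    assert aldosterone_synthesis_rate(p, cc) == pytest.approx(
        ks * cc + kp, rel=1e-12, abs=1e-300)


# ---------------------------------------------------------------------------
# structural properties
# ---------------------------------------------------------------------------

def test_rates_vanish_at_zero_concentrations():
    """Every rate law returns 0 for all-zero concentrations, except
    aldosterone synthesis which keeps its constitutive floor."""
    assert convective_transport_rate(1.0, 0.47, 0.0) == 0.0
    assert secretion_rate(SecretionParams(k_secretion=5.0), 0.0) == 0.0
    p = ProreninActivation(vmax_kid=1.0, km_kid=1.0, k_inhibition=1.0,
                           intracellular_prorenin_ref=1.0)
    assert prorenin_activation_rate(p, 0.24, 0.0, 0.0) == 0.0
    assert degradation_rate(0.0, 1.0) == 0.0
    k = MMKinetics(kcat=1.0, km=1.0, enzyme="e", substrate="s")
    assert mm_conversion_rate(k, 1.0, 0.0, 0.0) == 0.0
    assert binding_rate(BindingParams(1.0, 1.0), 0.0, 0.0, 0.0) == 0.0
    p_ald = SecretionParams(k_secretion=1.0, k_production=1.51e-6)
    assert aldosterone_synthesis_rate(p_ald, 0.0) == pytest.approx(1.51e-6)


@settings(derandomize=True, max_examples=60)
@given(c_lo=positive, factor=st.floats(min_value=1.001, max_value=100.0))
def test_prorenin_activation_strictly_decreasing_in_ang2(c_lo, factor):
    """Higher renal Ang2 always slows prorenin activation: the negative
    feedback loop of the cascade."""
    p = ProreninActivation(vmax_kid=1.62, km_kid=4.68e-2, k_inhibition=1.87e-8,
                           intracellular_prorenin_ref=1.1e-4)
    r_lo = prorenin_activation_rate(p, 0.24, 1.1e-4, c_lo)
    r_hi = prorenin_activation_rate(p, 0.24, 1.1e-4, c_lo * factor)
    assert r_hi < r_lo


def test_table_values_against_scratch_formula_evaluation():
    """The shipped prorenin-activation parameterisation against a one-line
    independent evaluation of the inhibition equation."""
    p = ProreninActivation(vmax_kid=1.62, km_kid=4.68e-2, k_inhibition=1.87e-8,
                           intracellular_prorenin_ref=1.1e-4)
    rate = prorenin_activation_rate(p, 0.24, 1.1e-4, 4.84e-6)
    oracle = 1.62 * 0.24 * 1.1e-4 / (1.1e-4 + 4.68e-2 * (1 + 4.84e-6 / 1.87e-8))
    assert rate == pytest.approx(oracle, rel=1e-12)


def test_parameter_file_reproduces_shipped_defaults(raas_params):
    """The packaged parameter file carries the published kinetic values."""
    p = raas_params
    assert p.species["AGT"].reference_plasma_conc == pytest.approx(0.60)
    assert p.species["renin"].reference_plasma_conc == pytest.approx(3.62e-7)
    assert p.species["aldosterone"].half_life == pytest.approx(12.87)
    assert p.renin_mm.kcat == pytest.approx(3.60)
    assert p.ace_binding.k_on == pytest.approx(35.16)
    assert p.at1_c_ref == pytest.approx(7.69)
    assert p.get("prorenin.vmax_kid") == pytest.approx(1.62)
    assert p.km_liv == pytest.approx(710.0)


def test_parameter_path_misspelling_names_candidate(raas_params):
    from raasim.errors import ConfigurationError
    with pytest.raises(ConfigurationError, match="renin.kcat"):
        raas_params.get("renin.kcatt")
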
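import numpy as np
import pytest

import raasim
from raasim.drug import DoseEvent
from raasim.errors import ConvergenceError, DomainError
from raasim.kinetics import HORMONES, LN2
from raasim.simulator import (SimOptions, SimulationState, drug_only_curves,
                              fast_steady_state, steady_state_residual)
from raasim.units import mg_to_umol


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_term_registry_single_prorenin_activation_in_kidney(system):
    """Exactly one prorenin-activation term exists, located in the kidney
    (the only organ that converts and secretes renin)."""
    entries = [t for t in system.term_registry
               if t["op"] == "prorenin_activation_rate"]
    assert len(entries) == 1
    assert entries[0]["compartments"] == ["Kidney"]


def test_term_registry_covers_all_rate_laws(system):
    ops = {t["op"] for t in system.term_registry}
    assert ops >= {"convective_transport_rate", "secretion_rate",
                   "degradation_rate", "mm_conversion_rate", "binding_rate",
                   "aldosterone_synthesis_rate", "oral_absorption_rate",
                   "hepatic_conversion_rate", "renal_clearance_rate"}


def test_ace_conversion_terms_only_in_expressing_organs(system):
    entry = next(t for t in system.term_registry
                 if t["op"] == "mm_conversion_rate" and t["enzyme"] == "ACE")
    assert "Lung" in entry["compartments"]
    assert "Kidney" not in entry["compartments"]  # 0% ACE expression


def test_transport_only_conserves_mass(body, raas_params):
    """With all reactions disabled, convection rearranges but never
    creates or destroys each species."""
    opts = SimOptions(dynamic_raas=False, check_negative=False)
    system = raasim.assemble_system(body, raas_params, options=opts)
    rng = np.random.default_rng(42)
    y0 = np.zeros(system.n_states)
    for sp in HORMONES:
        y0[system.species_slice(sp)] = rng.uniform(0.1, 1.0, system.n_comp)
    traj = raasim.simulate(system, SimulationState(0.0, y0, system),
                           horizon=500.0, grid=50.0)
    for sp in HORMONES:
        totals = traj.values[:, system.species_slice(sp)].sum(axis=1)
        assert np.max(np.abs(totals / totals[0] - 1)) < 1e-8


def test_single_compartment_degradation_is_exponential(system):
    """A degradation-only species decays as the closed-form exponential."""
    from scipy.integrate import solve_ivp
    t_half = 1.54
    sol = solve_ivp(lambda t, y: -y * LN2 / t_half, (0, 10 * t_half), [1.0],
                    rtol=1e-10, atol=1e-14, dense_output=True)
    assert sol.sol(t_half)[0] == pytest.approx(0.5, rel=1e-6)
    assert sol.sol(3 * t_half)[0] == pytest.approx(0.125, rel=1e-6)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def test_steady_state_residual_criterion(system, steady_state):
    res, _ = steady_state_residual(system, steady_state.y)
    assert res < 1e-9


def test_steady_state_flux_balance_for_aldosterone(system, steady_state):
    """At steady state the aldosterone synthesis flux equals its total
    degradation flux."""
    p = system.raas
    cplx = steady_state.y[system.species_slice("AT1_complex")]
    c_drive = cplx.sum() / system.total_plasma_volume
    synthesis = (p.aldosterone_secretion.k_secretion * c_drive
                 + p.aldosterone_secretion.k_production)
    amounts = steady_state.y[system.species_slice("aldosterone")]
    degradation = amounts.sum() * LN2 / p.species["aldosterone"].half_life
    assert synthesis == pytest.approx(degradation, rel=1e-6)


def test_steady_state_invariant_to_initial_perturbation(system, steady_state):
    """Multi-start: scaled initial conditions converge to the same fixed
    point (stable, unique attractor within a 10x ball)."""
    for factor in (0.2, 5.0):
        y0 = system.reference_state().y * factor
        state = raasim.solve_steady_state(system, y0=y0)
        ref = np.array([steady_state.venous_concentration(sp)
                        for sp in HORMONES])
        got = np.array([state.venous_concentration(sp) for sp in HORMONES])
        assert np.max(np.abs(got / ref - 1)) < 1e-6


def test_fast_steady_state_matches_long_integration(system, steady_state):
    state = fast_steady_state(system)
    for sp in HORMONES:
        assert state.venous_concentration(sp) == pytest.approx(
            steady_state.venous_concentration(sp), rel=1e-6)


def test_no_dose_trajectory_stays_at_steady_state(system, steady_state):
    """Fixed-point persistence: each venous hormone concentration stays
    within 0.5% of its initial value over 3000 min without dosing."""
    traj = raasim.simulate(system, steady_state, horizon=3000.0, grid=100.0)
    for sp in HORMONES:
        c = traj.venous_concentrations(sp)
        assert np.max(np.abs(c / c[0] - 1)) < 5e-3


# ---------------------------------------------------------------------------
# dosing and trajectories
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def dosed(system, steady_state):
    doses = [DoseEvent(time=1500.0, amount=10.0, route="oral")]
    return raasim.simulate(system, steady_state, doses=doses,
                           horizon=3000.0, grid=5.0)


def test_inhibition_directionality(dosed, steady_state):
    """After the oral dose, ACE blockade lowers Ang2 and aldosterone and
    disinhibits renin (raising Ang1) relative to pre-dose levels."""
    t = dosed.times
    window = (t > 1500.0) & (t <= 1740.0)
    for sp, direction in (("renin", +1), ("Ang1", +1),
                          ("Ang2", -1), ("aldosterone", -1)):
        pre = steady_state.venous_concentration(sp)
        post = dosed.venous_concentrations(sp)[window]
        if direction > 0:
            assert np.all(post > pre), f"{sp} should rise"
        else:
            assert np.all(post < pre), f"{sp} should fall"


def test_receptor_and_enzyme_pools_conserved(dosed, system):
    """Per organ, free + complexed AT1 and free + complexed ACE equal the
    expressed totals throughout the dosed trajectory (complexes never
    exceed their pools)."""
    v = system.volumes
    for name, total in (("AT1_complex", system.at1_total),
                        ("ACE_complex", system.ace_total)):
        c = dosed.values[:, system.species_slice(name)] / v
        assert np.all(c >= -1e-12)
        assert np.all(c <= total + 1e-9)
        free = total - c
        assert np.allclose(free + c, np.broadcast_to(total, c.shape),
                           rtol=0, atol=1e-12)


def test_no_state_goes_negative(dosed):
    assert dosed.values.min() >= -1e-12


def test_dose_doubling_weakly_increases_peak_occupancy(body, raas_params):
    opts = SimOptions(dynamic_raas=False, check_negative=False)
    peaks = []
    for dose in (10.0, 20.0):
        system = raasim.assemble_system(body, raas_params, options=opts)
        y0 = SimulationState(0.0, np.zeros(system.n_states), system)
        traj = raasim.simulate(system, y0,
                               doses=[DoseEvent(time=0.0, amount=dose)],
                               horizon=720.0, grid=10.0)
        i_lung = system.body.index("Lung")
        occ = (traj.values[:, system.species_slice("ACE_complex")][:, i_lung]
               / system.body["Lung"].plasma_volume / system.ace_total[i_lung])
        peaks.append(occ.max())
    assert peaks[1] >= peaks[0]


def test_trajectory_grid_and_determinism(system, steady_state):
    doses = [DoseEvent(time=100.0, amount=10.0)]
    runs = [raasim.simulate(system, steady_state, doses=doses, horizon=300.0,
                            grid=10.0) for _ in range(2)]
    assert np.all(np.diff(runs[0].times) > 0)
    assert runs[0].metadata["content_hash"] == runs[1].metadata["content_hash"]
    assert np.array_equal(runs[0].values, runs[1].values)


def test_tolerance_halving_changes_little(body, raas_params, steady_state):
    """Halving rtol/atol moves reported venous concentrations by < 0.1%:
    the defaults are converged."""
    doses = [DoseEvent(time=200.0, amount=10.0)]
    results = []
    for factor in (1.0, 0.5):
        opts = SimOptions(rtol=1e-8 * factor, atol=1e-12 * factor)
        sys_f = raasim.assemble_system(body, raas_params, options=opts)
        ss = fast_steady_state(sys_f, y_guess=steady_state.y)
        traj = raasim.simulate(sys_f, ss, doses=doses, horizon=600.0,
                               grid=50.0)
        results.append(np.array([traj.venous_concentrations(sp)[-1]
                                 for sp in (*HORMONES, "Ena", "Enaat")]))
    scale = np.maximum(np.abs(results[0]), 1e-30)
    assert np.max(np.abs(results[0] - results[1]) / scale) < 1e-3


def test_drug_only_fast_path_matches_full_system(body, raas_params):
    """The reduced drug-only integration reproduces the full coupled
    system's drug curves (quantifiable range) at matched tolerances."""
    opts = SimOptions(dynamic_raas=False, check_negative=False)
    system = raasim.assemble_system(body, raas_params, options=opts)
    times = np.array([30.0, 60.0, 120.0, 240.0, 480.0, 1440.0, 2880.0])
    dose_umol = mg_to_umol(10.0, system.drug.ena.molecular_weight)
    ena_fast, enaat_fast = drug_only_curves(system, dose_umol, times)
    y0 = SimulationState(0.0, np.zeros(system.n_states), system)
    traj = raasim.simulate(system, y0, doses=[DoseEvent(time=0.0, amount=10.0)],
                           horizon=2880.0,
                           grid=np.concatenate([[0.0], times]))
    idx = np.searchsorted(traj.times, times)
    ena_full = traj.venous_concentrations("Ena")[idx]
    enaat_full = traj.venous_concentrations("Enaat")[idx]
    quant = ena_full > 1e-6
    assert ena_fast[quant] == pytest.approx(ena_full[quant], rel=1e-4)
    assert enaat_fast == pytest.approx(enaat_full, rel=1e-4)


def test_simulate_rejects_bad_inputs(system, steady_state):
    with pytest.raises(DomainError):
        raasim.simulate(system, steady_state, horizon=-5.0)
    with pytest.raises(DomainError):
        raasim.simulate(system, steady_state,
                        doses=[DoseEvent(time=5000.0, amount=10.0)],
                        horizon=100.0)
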
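import math

import numpy as np
import pytest
from scipy.optimize import brentq

from dcache_ai2 import (OneSiteParams, Thermogram, TitrationProtocol,
                        bound_complex, fit_one_site, injection_heats,
                        simulate_titration, subtract_dilution, wiseman_c)

STANDARD = TitrationProtocol(syringe_conc_M=700e-6, cell_conc_M=70e-6)


def bound_complex_oracle(total_sites, total_ligand, kd):
    """Independent 1-D root-finder for Kd*[PL] = (S-[PL])(L-[PL])."""
    if total_sites == 0 or total_ligand == 0:
        return 0.0
    f = lambda pl: kd * pl - (total_sites - pl) * (total_ligand - pl)
    return brentq(f, 0.0, min(total_sites, total_ligand), xtol=1e-300,
                  rtol=8.9e-16, maxiter=500)


def test_quadratic_solver_matches_root_finder_to_1e12():
    rng = np.random.default_rng(123)
    for _ in range(300):
        s = 10.0 ** rng.uniform(-9, -2)
        l = 10.0 ** rng.uniform(-9, -2)
        kd = 10.0 ** rng.uniform(-12, -2)
        pl = bound_complex(s, l, kd)
        oracle = bound_complex_oracle(s, l, kd)
        assert pl == pytest.approx(oracle, rel=1e-12)


def test_zero_enthalpy_gives_zero_heats():
    params = OneSiteParams(Kd=1e-6, dH=0.0, q_offset=0.0)
    tg = simulate_titration(STANDARD, params, 0.0)
    assert all(q == 0.0 for q in tg.heats_uJ)


def test_tight_binding_limit_heats():
    # saturating protocol: every injected ligand molecule binds until the
    # sites run out, then the heat falls to the background offset
    protocol = TitrationProtocol(syringe_conc_M=100e-6, cell_conc_M=10e-6)
    params = OneSiteParams(Kd=1e-15, n=1.0, dH=-40000.0, q_offset=5.0)
    heats = np.array(simulate_titration(protocol, params, 0.0).heats_uJ)
    v = protocol.injection_volumes_L[0]
    expected_first = params.dH * protocol.syringe_conc_M * v * 1e6 + 5.0
    assert heats[0] == pytest.approx(expected_first, rel=1e-6)
    assert heats[-1] == pytest.approx(5.0, abs=1e-6)


def test_cumulative_heat_matches_mole_balance_oracle():
    """Total heat = dH * (moles of complex in cell + moles displaced out)."""
    for kd in (1e-8, 1e-6, 1e-4):
        params = OneSiteParams(Kd=kd, n=1.3, dH=-40000.0, q_offset=0.0)
        heats = injection_heats(STANDARD, params)
        V0 = STANDARD.cell_volume_L
        M, L, pl_prev = STANDARD.cell_conc_M, 0.0, 0.0
        displaced_moles = 0.0
        for v in STANDARD.injection_volumes_L:
            displaced_moles += pl_prev * v
            d = 1 - v / V0
            M *= d
            L = L * d + STANDARD.syringe_conc_M * v / V0
            pl_prev = bound_complex_oracle(params.n * M, L, kd)
        expected_total = params.dH * (V0 * pl_prev + displaced_moles) * 1e6
        assert heats.sum() == pytest.approx(expected_total, rel=1e-9)


def test_bound_fraction_nondecreasing_without_noise():
    params = OneSiteParams(Kd=1e-6, n=1.0, dH=-40000.0)
    V0 = STANDARD.cell_volume_L
    M, L = STANDARD.cell_conc_M, 0.0
    fractions = []
    for v in STANDARD.injection_volumes_L:
        d = 1 - v / V0
        M *= d
        L = L * d + STANDARD.syringe_conc_M * v / V0
        fractions.append(bound_complex(params.n * M, L, params.Kd) / (params.n * M))
    assert all(b >= a - 1e-15 for a, b in zip(fractions, fractions[1:]))


def test_simulation_is_seed_reproducible():
    params = OneSiteParams(Kd=1e-6)
    a = simulate_titration(STANDARD, params, 2.0, seed=7)
    b = simulate_titration(STANDARD, params, 2.0, seed=7)
    c = simulate_titration(STANDARD, params, 2.0, seed=8)
    assert a.heats_uJ == b.heats_uJ
    assert a.heats_uJ != c.heats_uJ


def test_subtract_dilution_identities():
    tg = Thermogram(heats_uJ=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0))
    zeros = Thermogram(heats_uJ=(0.0,) * 6)
    assert subtract_dilution(tg, tg).heats_uJ == (0.0,) * 6
    assert subtract_dilution(tg, zeros).heats_uJ == tg.heats_uJ
    with pytest.raises(ValueError, match="injections"):
        subtract_dilution(tg, Thermogram(heats_uJ=(0.0,) * 5))


def test_dilution_correction_recovers_binding_signal():
    params = OneSiteParams(Kd=1e-6, dH=-40000.0, q_offset=8.0)
    clean = injection_heats(STANDARD, OneSiteParams(Kd=1e-6, dH=-40000.0))
    noise_sd = 2.0
    signal = simulate_titration(STANDARD, params, noise_sd, seed=11)
    control = simulate_titration(
        STANDARD, OneSiteParams(Kd=1.0, dH=0.0, q_offset=8.0),
        noise_sd, seed=12)
    corrected = np.array(subtract_dilution(signal, control).heats_uJ)
    # difference of two independent noise draws: fixed-seed realization
    # stays within a few noise s.d. of the noise-free signal per point
    assert np.max(np.abs(corrected - clean)) < 4 * noise_sd


def test_noise_free_fit_recovers_parameters_to_4sf():
    protocol = STANDARD  # c = 10 at Kd = 7 µM
    truth = OneSiteParams(Kd=7e-6, n=0.95, dH=-40000.0, q_offset=1.0)
    tg = simulate_titration(protocol, truth, 0.0)
    fit = fit_one_site(tg, protocol)
    assert fit.converged
    assert fit.params.Kd == pytest.approx(truth.Kd, rel=1e-4)
    assert fit.params.n == pytest.approx(truth.n, rel=1e-4)
    assert fit.params.dH == pytest.approx(truth.dH, rel=1e-4)
    assert fit.params.q_offset == pytest.approx(truth.q_offset, abs=1e-3)
    assert fit.stderr["Kd"] >= 0.0


def test_fix_n_clamps_stoichiometry():
    truth = OneSiteParams(Kd=7e-6, n=1.0, dH=-40000.0)
    tg = simulate_titration(STANDARD, truth, 0.0)
    fit = fit_one_site(tg, STANDARD, fix_n=1.0)
    assert fit.n_fixed and fit.params.n == 1.0
    assert fit.params.Kd == pytest.approx(truth.Kd, rel=1e-4)


def test_fit_invariant_to_unit_rescaling():
    """µJ vs µcal heats give the same Kd; dH rescales by the same factor."""
    truth = OneSiteParams(Kd=7e-6, n=1.0, dH=-40000.0)
    tg = simulate_titration(STANDARD, truth, 0.0)
    cal = Thermogram(heats_uJ=tuple(q / 4.184 for q in tg.heats_uJ))
    fit_uj = fit_one_site(tg, STANDARD)
    fit_cal = fit_one_site(cal, STANDARD)
    assert fit_cal.params.Kd == pytest.approx(fit_uj.params.Kd, rel=1e-3)
    assert fit_cal.params.dH == pytest.approx(fit_uj.params.dH / 4.184,
                                              rel=1e-3)


def test_too_few_injections_is_hard_error():
    protocol = TitrationProtocol(syringe_conc_M=700e-6, cell_conc_M=70e-6,
                                 injection_volumes_L=(10e-6,) * 5)
    tg = simulate_titration(protocol, OneSiteParams(Kd=1e-6), 0.0)
    with pytest.raises(ValueError, match="too few injections"):
        fit_one_site(tg, protocol)


def test_wiseman_c_values_and_limit():
    assert wiseman_c(TitrationProtocol(syringe_conc_M=700e-6,
                                       cell_conc_M=70e-6),
                     OneSiteParams(Kd=0.14e-6)) == pytest.approx(500.0)
    assert wiseman_c(TitrationProtocol(syringe_conc_M=13e-6,
                                       cell_conc_M=1.3e-6),
                     OneSiteParams(Kd=26e-9)) == pytest.approx(50.0)
    assert wiseman_c(STANDARD, OneSiteParams(Kd=1e6)) == pytest.approx(0.0, abs=1e-10)


def test_low_c_fit_warns():
    truth = OneSiteParams(Kd=181e-6, n=1.0, dH=-40000.0)
    tg = simulate_titration(STANDARD, truth, 0.0)
    fit = fit_one_site(tg, STANDARD, fix_n=1.0)
    assert fit.wiseman_c < 1.0
    assert any("c =" in w for w in fit.warnings)


def test_protocol_and_param_validation():
    with pytest.raises(ValueError):
        TitrationProtocol(syringe_conc_M=700e-6, cell_conc_M=70e-6,
                          injection_volumes_L=(30e-6,) * 25)  # overfills cell
    with pytest.raises(ValueError):
        OneSiteParams(Kd=0.0)
    with pytest.raises(ValueError):
        simulate_titration(STANDARD, OneSiteParams(Kd=1e-6), noise_sd_uJ=-1.0)
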
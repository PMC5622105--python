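"""Kinetic core: microrate assembly, the two mass-action schemes, stiff
integration, steady states, the closed-form divalent oracle, occupancy
curves and Hill analysis."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecmbind import (
    AGGREGATION,
    DIVALENT,
    EquilibriumRelations,
    Microrates,
    RatePair,
    Scenario,
    ValidationError,
    aggregation_rhs,
    assemble_microrates,
    divalent_rhs,
    equilibrium_divalent,
    hill_coefficient,
    occupancy_curve,
    rate_pair_to_kd,
    simulate,
    solve_steady_state,
    steady_state,
)
from ecmbind.kinetics import (
    LIGAND_WEIGHTS,
    RECEPTOR_WEIGHTS,
    _aggregation_jac,
    _divalent_jac,
)

COL_I = RatePair(k_on_per_M_s=5.6e4, k_off_per_s=1.3e-3)
FIBRONECTIN = RatePair(k_on_per_M_s=1.6e8, k_off_per_s=3.5e-1)


def _scenario(pair=COL_I, receptor=1e-4, ligand=6420.0, model=AGGREGATION, **kw):
    return Scenario(
        ligand="ligand", receptor="receptor",
        receptor_total_nM=receptor, ligand_total_nM=ligand,
        rates=pair, model=model, **kw,
    )


class TestRates:
    @pytest.mark.parametrize(
        "pair, kd_nM",
        [(COL_I, 23.21), (FIBRONECTIN, 2.19), (RatePair(1e5, 0.0), 0.0)],
    )
    def test_kd(self, pair, kd_nM):
        assert rate_pair_to_kd(pair) == pytest.approx(kd_nM, abs=5e-3)

    def test_assembly_constants(self):
        rates = assemble_microrates(COL_I)
        assert rates.ki == pytest.approx(23.214, abs=1e-2)
        assert rates.kc == pytest.approx(0.2321, abs=1e-3)
        assert rates.ka == pytest.approx(232.14, abs=1e-1)

    def test_no_cooperativity_relation(self):
        rates = assemble_microrates(COL_I, EquilibriumRelations(kc_over_ki=1.0))
        assert rates.k4 == pytest.approx(rates.k2, rel=1e-12)

    @given(
        k_on=st.floats(1e3, 1e9),
        k_off=st.floats(1e-5, 10.0),
        kc=st.floats(1e-3, 10.0),
        ka=st.floats(0.1, 100.0),
        kp=st.floats(1.0, 1e3),
        kpx=st.floats(1.0, 1e3),
    )
    def test_ratio_invariants(self, k_on, k_off, kc, ka, kp, kpx):
        """Every assembled set satisfies the five equilibrium-ratio
        relations to 1e-12 relative."""
        rel = EquilibriumRelations(kc, ka, kp, kpx)
        r = assemble_microrates(RatePair(k_on, k_off), rel)
        ki = r.k2 / r.k1
        assert r.ki == pytest.approx(ki, rel=1e-12)
        assert r.kc == pytest.approx(kc * ki, rel=1e-12)
        assert r.ka == pytest.approx(ka * ki, rel=1e-12)
        assert r.kp == pytest.approx(kp * ki, rel=1e-12)
        assert r.kx == pytest.approx(kp * ki / kpx, rel=1e-12)


def _random_states(n, scale=10.0, seed=42):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, scale, size=(n, 9))


class TestRhs:
    def test_zero_state(self):
        rates = assemble_microrates(COL_I)
        assert np.all(divalent_rhs(np.zeros(9), rates) == 0)
        assert np.all(aggregation_rhs(np.zeros(9), rates) == 0)

    def test_divalent_sign_structure(self):
        rates = assemble_microrates(COL_I)
        y = np.zeros(9)
        y[0], y[1] = 1.0, 5.0  # I, E only
        d = divalent_rhs(y, rates)
        assert d[0] < 0 and d[2] > 0

    def test_divalent_rhs_vanishes_at_oracle(self):
        rates = assemble_microrates(COL_I)
        y = equilibrium_divalent(0.05, 840.0, rates.ki, rates.kc)
        d = divalent_rhs(y, rates)
        assert np.linalg.norm(d) < 1e-10 * np.linalg.norm(y)

    def test_aggregation_conservation_random_states(self):
        """Receptor- and ligand-weighted derivative sums cancel identically
        (to 1e-14 of the gross flux) at arbitrary non-negative states."""
        rates = assemble_microrates(COL_I)
        for y in _random_states(200):
            d = aggregation_rhs(y, rates)
            gross = np.abs(d).sum() + 1e-300
            assert abs(RECEPTOR_WEIGHTS @ d) < 1e-14 * gross
            assert abs(LIGAND_WEIGHTS @ d) < 1e-14 * gross

    def test_printed_amd_variant_breaks_receptor_conservation(self):
        """The published Amd balance carries spurious factors of E on the k8
        exchange terms; it violates receptor conservation whenever E != 1."""
        rates = assemble_microrates(COL_I)
        y = np.array([1.0, 5.0, 0.5, 0.5, 0.1, 0.1, 0.1, 0.2, 0.3])
        d = aggregation_rhs(y, rates, printed_amd_form=True)
        gross = np.abs(d).sum()
        assert abs(RECEPTOR_WEIGHTS @ d) > 1e-6 * gross

    def test_reduces_to_divalent_when_no_aggregation(self):
        rates = assemble_microrates(COL_I).replace(k5=0.0)
        y = np.zeros(9)
        y[0], y[1], y[2], y[3] = 0.3, 7.0, 0.2, 0.1
        np.testing.assert_allclose(
            aggregation_rhs(y, rates), divalent_rhs(y, rates), rtol=1e-14
        )

    @pytest.mark.parametrize("model", [DIVALENT, AGGREGATION])
    def test_jacobian_matches_finite_differences(self, model):
        rates = assemble_microrates(COL_I)
        k = rates.as_array()
        rhs = divalent_rhs if model == DIVALENT else aggregation_rhs
        jac = _divalent_jac if model == DIVALENT else _aggregation_jac
        for y in _random_states(5, seed=7):
            J = jac(y, k)
            num = np.zeros((9, 9))
            h = 1e-6
            for j in range(9):
                up, dn = y.copy(), y.copy()
                up[j] += h
                dn[j] -= h
                num[:, j] = (rhs(up, rates) - rhs(dn, rates)) / (2 * h)
            np.testing.assert_allclose(J, num, rtol=1e-5, atol=1e-7)


class TestSimulate:
    def test_zero_ligand_is_constant(self):
        sc = _scenario(ligand=0.0)
        traj = simulate(sc, t_end=1e4)
        np.testing.assert_allclose(traj.states[:, 0], sc.receptor_total_nM, rtol=1e-12)
        assert np.all(traj.states[:, 1:] == 0)

    def test_saturating_collagen_scenario(self):
        """Excess collagen over a trace receptor pool drives Cd to the full
        receptor total (ligand 6420 nM >> Ki 23.2 nM >> Kc)."""
        sc = _scenario(model=DIVALENT)
        state, converged = solve_steady_state(sc)
        assert converged
        assert state[3] == pytest.approx(sc.receptor_total_nM, rel=1e-3)

    def test_doubling_horizon_after_convergence(self):
        sc = _scenario(model=DIVALENT)
        y1, _ = solve_steady_state(sc, t_end=1e6)
        y2, _ = solve_steady_state(sc, t_end=2e6)
        np.testing.assert_allclose(y1[:4], y2[:4], rtol=1e-9, atol=1e-18)

    def test_steady_state_flag_on_constant_trajectory(self):
        sc = _scenario(ligand=0.0)
        traj = simulate(sc, t_end=10.0)
        state, converged = steady_state(traj)
        assert converged
        np.testing.assert_allclose(state, traj.states[0])

    def test_stiff_fibronectin_conserves(self):
        """The fastest published on-rate (1.6e8 s^-1M^-1) integrates without
        conservation drift beyond 1e-6 relative."""
        sc = _scenario(pair=FIBRONECTIN, receptor=0.05, ligand=470.0)
        traj = simulate(sc)
        cons = traj.conservation_error()
        assert max(cons.values()) < 1e-6

    def test_aggregation_equals_divalent_without_pairing(self):
        """With k5 = 0 and an aggregate-free start the aggregation scheme is
        the divalent scheme; trajectories agree to 1e-8 relative."""
        sc = _scenario(pair=COL_I, receptor=0.05, ligand=840.0)
        rates = assemble_microrates(sc.rates, sc.relations).replace(k5=0.0)
        t_eval = np.geomspace(1e-2, 1e5, 40)
        traj_a = simulate(sc, model=AGGREGATION, microrates=rates,
                          t_eval=t_eval, t_end=1e5)
        traj_d = simulate(sc, model=DIVALENT, microrates=rates,
                          t_eval=t_eval, t_end=1e5)
        np.testing.assert_allclose(
            traj_a.states, traj_d.states, rtol=1e-8,
            atol=1e-12 * sc.receptor_total_nM,
        )


class TestDivalentOracle:
    def test_zero_ligand(self):
        y = equilibrium_divalent(2.0, 0.0, 10.0, 1.0)
        assert y[0] == 2.0 and y[1:].sum() == 0

    def test_saturation_limit(self):
        y = equilibrium_divalent(1e-3, 1e6, 10.0, 0.1)
        assert y[3] / 1e-3 > 0.999

    def test_invalid_constants(self):
        with pytest.raises(ValidationError):
            equilibrium_divalent(1.0, 1.0, 0.0, 1.0)

    def test_integrator_matches_oracle_random_scenarios(self):
        """Divalent steady states from the ODE path agree with the
        closed-form equilibrium to 1e-6 relative (25-scenario spot check;
        the acceptance suite runs 100)."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            ki = 10 ** rng.uniform(-1, 4)
            kc = 10 ** rng.uniform(-2, 3)
            R = 10 ** rng.uniform(-4, 1)
            L = 10 ** rng.uniform(-1, 5)
            pair = RatePair(1e5, ki * 1e5 * 1e-9)
            rel = EquilibriumRelations(kc_over_ki=kc / ki)
            sc = _scenario(pair=pair, receptor=R, ligand=L,
                           model=DIVALENT, relations=rel)
            sim, converged = solve_steady_state(sc)
            oracle = equilibrium_divalent(R, L, ki, kc)
            assert converged
            np.testing.assert_allclose(
                sim, oracle, rtol=1e-6, atol=1e-9 * max(R, L)
            )


class TestOccupancy:
    def test_zero_grid_point(self):
        curve = occupancy_curve(_scenario(model=DIVALENT), [0.0])
        assert curve["frac_cd"].iloc[0] == 0.0

    def test_divalent_curve_strictly_increasing(self):
        sc = _scenario(model=DIVALENT, receptor=1e-4)
        ki = sc.microrates().ki
        grid = np.geomspace(0.01 * ki, 100 * ki, 30)
        curve = occupancy_curve(sc, grid)
        assert np.all(np.diff(curve["frac_cd"]) > 0)

    def test_ode_and_analytic_paths_agree(self):
        sc = _scenario(model=DIVALENT, receptor=0.05)
        grid = [10.0, 100.0, 1000.0]
        analytic = occupancy_curve(sc, grid, method="analytic")
        ode = occupancy_curve(sc, grid, method="ode")
        np.testing.assert_allclose(
            analytic["frac_cd"], ode["frac_cd"], rtol=1e-6
        )


class TestHill:
    def test_one_to_one_reference(self):
        L = np.geomspace(0.01, 100.0, 60)
        y = L / (L + 1.0)
        assert hill_coefficient(L, y) == pytest.approx(1.0, abs=0.01)

    def test_cooperative_divalent_curve(self):
        """With the second-site affinity switch (Kc = 0.01 Ki) the fully
        occupied fraction is strongly sigmoidal; the dilute closed form
        x^2/(1 + 100x + x^2) gives a logit slope of 1.878 over the 5–95%
        band."""
        sc = _scenario(model=DIVALENT, receptor=1e-6)
        ki = sc.microrates().ki
        grid = np.geomspace(0.01 * ki, 100 * ki, 50)
        curve = occupancy_curve(sc, grid)
        n_h = hill_coefficient(curve["ligand_nM"], curve["frac_cd"])
        assert n_h > 1.0
        assert n_h == pytest.approx(1.878, abs=0.05)

    def test_equal_stepwise_constants_retain_ladder_steepness(self):
        """Setting Kc = Ki removes the cooperative enhancement but the fully
        occupied fraction of a sequential two-site receptor keeps a logit
        slope above one (dilute closed form x^2/(1+x+x^2): 1.331 over the
        5–95% band; the limiting slopes are 2 at low and 1 at high ligand)."""
        sc = _scenario(model=DIVALENT, receptor=1e-6,
                       relations=EquilibriumRelations(kc_over_ki=1.0))
        ki = sc.microrates().ki
        grid = np.geomspace(0.01 * ki, 100 * ki, 50)
        curve = occupancy_curve(sc, grid)
        n_h = hill_coefficient(curve["ligand_nM"], curve["frac_cd"])
        assert n_h == pytest.approx(1.331, abs=0.05)

    def test_too_few_points(self):
        with pytest.raises(ValidationError, match=">= 5"):
            hill_coefficient([1.0, 10.0], [0.4, 0.6])


class TestDiluteAggregationLinearity:
    def test_ka_scaling_in_dilute_regime(self, scenario_for):
        """When aggregates hold <1e-3 of the receptor pool, the saturated
        aggregate pair scales inversely with the aggregation constant:
        dividing Ka by 10 multiplies steady-state Add by 10 within 1%."""
        sc = scenario_for("Col 1a1", "ccl4")
        rates = sc.microrates()
        base, _ = solve_steady_state(sc, microrates=rates)
        assert 2 * base[4:].sum() < 1e-3 * sc.receptor_total_nM
        tenth = rates.replace(k6=rates.k6 * 0.1)
        pert, _ = solve_steady_state(sc, microrates=tenth)
        assert pert[8] / base[8] == pytest.approx(10.0, rel=0.01)
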
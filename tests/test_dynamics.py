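"""Steady-state solver and time-course integration."""

import numpy as np
import pytest

import thermoglyc as tg
from thermoglyc.dynamics import STEADY_STATE_TOL


def _balance_residual(model, result):
    s_free = model.stoichiometric_matrix(model.free_species)
    v = np.array([result.fluxes[r.name] for r in model.reactions])
    return float(np.max(np.abs(s_free @ v)))


class TestSteadyState:
    def test_residual_below_tolerance(self, ssol_base_model,
                                      ssol_base_steady):
        assert ssol_base_steady.converged
        assert ssol_base_steady.max_residual < STEADY_STATE_TOL
        assert _balance_residual(ssol_base_model, ssol_base_steady) \
            < STEADY_STATE_TOL

    def test_concentrations_non_negative(self, ssol_base_steady):
        assert all(c >= 0 for c in ssol_base_steady.concentrations.values())

    def test_fluxes_recomputed_from_concentrations_match(
            self, ssol_base_model, ssol_base_steady):
        recomputed = ssol_base_model.rates(ssol_base_steady.concentrations)
        for name, flux in ssol_base_steady.fluxes.items():
            assert recomputed[name] == flux  # bit-exact by construction

    def test_internal_node_balance_with_branching(self, ssol_gapn_model,
                                                  ssol_gapn_steady):
        """At 3PG: influx through PGK + GAPN + BPG decay equals the mutase
        efflux (the published 16.82 - 0.23 = 16.59 self-consistency)."""
        f = ssol_gapn_steady.fluxes
        influx = f["PGK"] + f["GAPN"] + f["BPG_degradation"]
        assert influx == pytest.approx(f["PGMA"], abs=1e-9)

    def test_boundary_species_keep_their_values(self, ssol_base_model,
                                                ssol_base_steady):
        for s in ssol_base_model.species:
            if s.is_boundary:
                assert ssol_base_steady.concentrations[s.name] == \
                    s.concentration

    def test_warm_start_reaches_the_same_state(self, ssol_base_model,
                                               ssol_base_steady):
        warm = {n: ssol_base_steady.concentrations[n] * 1.3
                for n in ssol_base_model.free_species}
        again = tg.find_steady_state(ssol_base_model, initial=warm)
        assert again.fluxes["GAPDH"] == pytest.approx(
            ssol_base_steady.fluxes["GAPDH"], rel=1e-9)


class TestMultistart:
    def test_fluxes_reproducible_from_random_starts(self, ssol_gapn_model):
        """Ten uniform-random initial vectors converge to one flux set
        (monostability check to 6 significant digits)."""
        results = tg.multistart_steady_state(ssol_gapn_model, n_starts=10)
        reference = results[0].fluxes["GAPN"]
        for res in results:
            assert res.fluxes["GAPN"] == pytest.approx(reference, rel=1e-6)

    def test_adenylate_moiety_respected_in_multistart(self):
        model = tg.build_model("sulfolobus", "with_atpase", k_atpase=0.1)
        results = tg.multistart_steady_state(model, n_starts=3)
        for res in results:
            total = res.concentrations["ATP"] + res.concentrations["ADP"]
            assert total == pytest.approx(3.84, rel=1e-8)


class TestTimeCourse:
    def test_all_zero_state_stays_identically_zero(self, ssol_base_model):
        model = ssol_base_model
        for name in model.boundary_species:
            model = model.with_boundary(name, 0.0)
        trajectory = tg.simulate_time_course(model, t_end=5.0, n_points=20)
        assert np.all(trajectory.concentrations.to_numpy() == 0.0)

    def test_adenylate_moiety_conserved_along_trajectory(self):
        """ATP(t) + ADP(t) = 3.84 mM at every output point."""
        model = tg.build_model("sulfolobus", "with_atpase", k_atpase=1.0)
        trajectory = tg.simulate_time_course(model, 50.0, n_points=100)
        total = (trajectory.concentrations["ATP"]
                 + trajectory.concentrations["ADP"])
        assert np.max(np.abs(total - 3.84)) / 3.84 < 1e-8
        assert trajectory.moiety_residual() < 1e-8

    def test_boundary_columns_constant(self, ssol_base_model):
        trajectory = tg.simulate_time_course(ssol_base_model, 10.0,
                                             n_points=30)
        for name in ssol_base_model.boundary_species:
            column = trajectory.concentrations[name]
            assert column.nunique() == 1

    def test_long_run_matches_steady_state_solver(self, ssol_base_model,
                                                  ssol_base_steady):
        """Terminal fluxes of a doubling-until-converged time course agree
        with the algebraic steady state to 0.1%."""
        t_end, previous = 250.0, None
        for _ in range(20):
            final = tg.simulate_time_course(
                ssol_base_model, t_end, n_points=5).final_state()
            flux = ssol_base_model.rates(final)["PGMA"]
            if previous is not None and \
                    abs(flux - previous) <= 1e-3 * abs(previous):
                break
            previous, t_end = flux, t_end * 2
        assert flux == pytest.approx(ssol_base_steady.fluxes["PGMA"],
                                     rel=1e-3)

    def test_t_end_must_be_positive(self, ssol_base_model):
        with pytest.raises(ValueError):
            tg.simulate_time_course(ssol_base_model, -1.0)


def test_equilibrium_state_is_a_fixed_point(ssol_gapn_model):
    """A state with every reversible reaction at equilibrium and every
    irreversible substrate at zero has exactly zero residual."""
    pgma_keq = ssol_gapn_model.get_reaction("PGMA").parameters["Keq"]
    eno_keq = ssol_gapn_model.get_reaction("ENO").parameters["Keq"]
    state = {"GAP": 0.0, "NADP": 1.0, "NADPH": 0.5, "Pi": 10.0,
             "BPG": 0.0, "ATP": 0.0, "ADP": 0.0, "PYR": 0.0,
             "3PG": 0.5, "2PG": 0.5 * pgma_keq,
             "PEP": 0.5 * pgma_keq * eno_keq}
    rates = ssol_gapn_model.rates(state)
    # exact zeros except for the one ratio that round-trips through Keq
    assert all(abs(rate) < 1e-15 for rate in rates.values())
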
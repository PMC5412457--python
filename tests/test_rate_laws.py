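"""Rate-law semantics: printed examples, thermodynamic zero-crossings,
homogeneity in Vmax, and agreement with the independent symbolic
transcriptions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermoglyc as tg
from thermoglyc.pathway import KEQ_GAPDH_SSOL_MM
from thermoglyc.rate_laws import RATE_LAWS
from thermoglyc.symbolic import SYMBOLIC_LAWS, lambdified_law


def _reaction(model, name):
    return model.get_reaction(name)


class TestPointValues:
    def test_gapn_half_saturated_gives_quarter_vmax(self, ssol_gapn_model):
        """Both substrates at their Km: v = Vm/4 (here 20/4 = 5 mM/min)."""
        rxn = _reaction(ssol_gapn_model, "GAPN")
        state = {"GAP": rxn.parameters["KmGAP"],
                 "NADP": rxn.parameters["KmNADP"]}
        assert tg.evaluate_rate(rxn, state) == pytest.approx(5.0, abs=1e-12)

    def test_bpg_degradation_is_first_order(self, ssol_base_model):
        """1 mM BPG at the 70 degC constant decays at 1.058 mM/min."""
        rxn = _reaction(ssol_base_model, "BPG_degradation")
        assert tg.evaluate_rate(rxn, {"BPG": 1.0}) == pytest.approx(1.058)

    def test_atpase_is_mass_action(self):
        model = tg.build_model("sulfolobus", "with_atpase", k_atpase=2.5)
        rxn = _reaction(model, "ATPase")
        assert tg.evaluate_rate(rxn, {"ATP": 2.0}) == pytest.approx(5.0)

    def test_archaeal_gapdh_vanishes_at_equilibrium(self, ssol_base_model):
        """The reversible law is zero exactly where the mass-action ratio
        [BPG][NADPH]/([GAP][NADP][Pi]) equals the equilibrium constant."""
        rxn = _reaction(ssol_base_model, "GAPDH")
        state = {"GAP": 0.5, "NADP": 0.8, "Pi": 10.0, "NADPH": 0.39}
        state["BPG"] = (KEQ_GAPDH_SSOL_MM * state["GAP"] * state["NADP"]
                        * state["Pi"] / state["NADPH"])
        assert tg.evaluate_rate(rxn, state) == pytest.approx(0.0, abs=1e-15)

    def test_pgk_matches_symbolic_oracle_at_reference_state(
            self, ssol_base_model):
        """The PGK evaluator agrees with an independently written symbolic
        transcription at a glycolytic reference state."""
        rxn = _reaction(ssol_base_model, "PGK")
        state = {"BPG": 0.01, "ADP": 1.32, "ATP": 2.52, "3PG": 0.5}
        oracle = lambdified_law("PGK_shared")({**state, **rxn.parameters})
        assert tg.evaluate_rate(rxn, state) == pytest.approx(
            oracle, rel=1e-14)


class TestErrors:
    def test_missing_species_names_the_symbol(self, ssol_base_model):
        rxn = _reaction(ssol_base_model, "GAPDH")
        with pytest.raises(tg.ConfigurationError, match="NADP"):
            tg.evaluate_rate(rxn, {"GAP": 1.0, "Pi": 10.0, "BPG": 0.0,
                                   "NADPH": 0.1})

    def test_missing_parameter_names_the_symbol(self):
        with pytest.raises(tg.ConfigurationError, match="KmNADP"):
            tg.ReactionSpec("broken", {"GAP": -1}, "GAPN",
                            {"Vm": 20.0, "KmGAP": 0.02})

    def test_negative_concentration_is_a_domain_error(self, ssol_base_model):
        rxn = _reaction(ssol_base_model, "BPG_degradation")
        with pytest.raises(tg.DomainError):
            tg.evaluate_rate(rxn, {"BPG": -0.1})


# every reversible law bracketed around its equilibrium through one pivot
# species; ``pivot_role`` says whether raising the pivot drives the rate
# backward ("product") or forward ("substrate")
_REVERSIBLE = [
    ("sulfolobus", "GAPDH",
     {"GAP": 0.4, "NADP": 1.0, "Pi": 10.0, "NADPH": 0.5}, "BPG", "product",
     lambda p, s: p["Keq"] * s["GAP"] * s["NADP"] * s["Pi"] / s["NADPH"]),
    ("yeast", "GAPDH",
     {"GAP": 0.4, "NAD": 1.0, "Pi": 10.0, "NADH": 0.5}, "BPG", "product",
     lambda p, s: (p["Keq"] / p["KmPi"]) * s["GAP"] * s["NAD"] * s["Pi"]
     / s["NADH"]),
    ("sulfolobus", "PGK",
     {"ADP": 1.0, "ATP": 2.0, "3PG": 1.5}, "BPG", "substrate",
     lambda p, s: s["ATP"] * s["3PG"] / (p["Keq"] * s["ADP"])),
    ("sulfolobus", "PGMA", {"2PG": 0.12}, "3PG", "substrate",
     lambda p, s: s["2PG"] / p["Keq"]),
    ("sulfolobus", "ENO", {"PEP": 0.7}, "2PG", "substrate",
     lambda p, s: s["PEP"] / p["Keq"]),
    ("sulfolobus", "PYK",
     {"ADP": 1.0, "ATP": 2.0, "PYR": 5.0}, "PEP", "substrate",
     lambda p, s: s["ATP"] * s["PYR"] / (p["Keq"] * s["ADP"])),
]


@pytest.mark.parametrize(
    "organism, name, state, pivot, pivot_role, equilibrium",
    _REVERSIBLE, ids=[f"{o}-{n}" for o, n, *_ in _REVERSIBLE])
def test_reversible_laws_change_sign_at_equilibrium(organism, name, state,
                                                    pivot, pivot_role,
                                                    equilibrium):
    """Each reversible law vanishes exactly where the mass-action ratio
    equals K_eq and changes sign when the pivot species is moved across
    its equilibrium value."""
    model = tg.build_model(organism, "base")
    rxn = model.get_reaction(name)
    pivot_eq = equilibrium(rxn.parameters, state)
    at_eq = dict(state, **{pivot: pivot_eq})
    below = dict(state, **{pivot: 0.5 * pivot_eq})
    above = dict(state, **{pivot: 2.0 * pivot_eq})
    sign = 1.0 if pivot_role == "product" else -1.0
    assert tg.evaluate_rate(rxn, at_eq) == pytest.approx(0.0, abs=1e-12)
    assert sign * tg.evaluate_rate(rxn, below) > 0
    assert sign * tg.evaluate_rate(rxn, above) < 0


@settings(derandomize=True, max_examples=30, deadline=None)
@given(factor=st.floats(0.01, 100.0), seed=st.integers(0, 10_000))
def test_rates_are_homogeneous_in_vmax(factor, seed):
    """Doubling (or any scaling of) Vmax scales the rate exactly."""
    rng = np.random.default_rng(seed)
    model = tg.build_model("sulfolobus", "with_gapn")
    for rxn in model.reactions:
        symbol = "Vmr" if "Vmr" in rxn.parameters else \
            "Vm" if "Vm" in rxn.parameters else None
        if symbol is None:
            continue
        law = RATE_LAWS[rxn.rate_law_id]
        state = {s: float(rng.uniform(0.0, 5.0)) for s in law.species}
        base = tg.evaluate_rate(rxn, state)
        scaled = tg.evaluate_rate(
            tg.build_model("sulfolobus", "with_gapn")
            .with_parameter(rxn.name, symbol,
                            rxn.parameters[symbol] * factor)
            .get_reaction(rxn.name), state)
        assert scaled == pytest.approx(factor * base, rel=1e-12)


def test_dual_transcriptions_agree_to_twelve_digits():
    """The numeric evaluators and the independently written symbolic
    transcriptions of every law agree to 12 significant digits at 100
    random non-negative states."""
    rng = np.random.default_rng(20170420)
    for law_id, law in RATE_LAWS.items():
        oracle = lambdified_law(law_id)
        params = _random_parameters(law_id, rng)
        for _ in range(100 // len(RATE_LAWS) + 10):
            state = {s: float(rng.uniform(0.0, 4.0)) for s in law.species}
            v_main = law(state, params)
            v_oracle = oracle({**state, **params})
            assert v_main == pytest.approx(v_oracle, rel=1e-12, abs=1e-300)


def _random_parameters(law_id, rng):
    law = RATE_LAWS[law_id]
    return {p: float(rng.uniform(0.05, 5.0)) for p in law.parameters}


def test_every_rate_law_has_a_symbolic_twin():
    assert set(SYMBOLIC_LAWS) == set(RATE_LAWS)


def test_rates_finite_guard():
    rxn = tg.ReactionSpec("chain", {"X0": -1, "X1": 1}, "MASS_ACTION_REV",
                          {"kf": math.inf, "kr": 0.0},
                          species_map={"S": "X0", "P": "X1"})
    with pytest.raises(tg.DomainError, match="finite"):
        tg.evaluate_rate(rxn, {"X0": 1.0, "X1": 0.0})
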
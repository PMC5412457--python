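"""Symbolic (sympy) transcriptions of the rate laws.

These expressions are written independently of :mod:`thermoglyc.rate_laws`
— a second, separate transcription of the published formulas. They serve
two purposes: they are the MathML source for SBML export, and they act as
the cross-check oracle against the numeric evaluators (the two
transcriptions are required to agree to twelve significant digits at
random states).

Symbols are named exactly like the rate-law species/parameter slots;
``3PG``/``2PG`` appear as ``_3PG``/``_2PG`` because sympy symbols (and
SBML ids) cannot start with a digit.
"""

from __future__ import annotations

import sympy as sp

__all__ = ["SYMBOLIC_LAWS", "symbolic_rate", "lambdified_law"]


def _syms(names):
    # keyed by the sanitized symbol name ("3PG" -> "_3PG")
    return {("_" + n if n[0].isdigit() else n):
            sp.Symbol("_" + n if n[0].isdigit() else n) for n in names}


def _build():
    laws = {}

    s = _syms(["GAP", "NAD", "Pi", "BPG", "NADH", "Vm", "KmGAP", "KmNAD",
               "KmNADH", "KmBPG", "KmPi", "Keq"])
    laws["GAPDH_yeast"] = (
        s["Vm"]
        * (s["GAP"] * s["NAD"] * s["Pi"]
           / (s["KmGAP"] * s["KmNAD"] * s["KmPi"])
           - s["BPG"] * s["NADH"] / (s["Keq"] * s["KmGAP"] * s["KmNAD"]))
        / (((1 + s["GAP"] / s["KmGAP"]) * (1 + s["Pi"] / s["KmPi"])
            + s["BPG"] / s["KmBPG"])
           * (1 + s["NAD"] / s["KmNAD"] + s["NADH"] / s["KmNADH"])))

    s = _syms(["GAP", "NADP", "Pi", "BPG", "NADPH", "Vm", "KmGAP", "KmNADP",
               "KmNADPH", "KmBPG", "KmPi", "Keq"])
    laws["GAPDH_ssol"] = (
        s["Vm"]
        * (s["GAP"] * s["NADP"] * s["Pi"]
           / (s["KmGAP"] * s["KmNADP"] * s["KmPi"])
           - s["BPG"] * s["NADPH"]
           / (s["Keq"] * s["KmPi"] * s["KmGAP"] * s["KmNADP"]))
        / (((1 + s["GAP"] / s["KmGAP"]) * (1 + s["Pi"] / s["KmPi"])
            + s["BPG"] / s["KmBPG"])
           * (1 + s["NADP"] / s["KmNADP"] + s["NADPH"] / s["KmNADPH"])))

    s = _syms(["BPG", "ADP", "3PG", "ATP", "Vmr", "KmADP", "KmATP", "KmBPG",
               "Km3PG", "KiADP", "Keq"])
    pgk_num = (s["Vmr"]
               * (s["Keq"] * s["ADP"] * s["BPG"] - s["ATP"] * s["_3PG"])
               / (s["KmATP"] * s["Km3PG"]))
    laws["PGK_shared"] = pgk_num / (
        (1 + s["ADP"] / s["KiADP"])
        * (1 + s["_3PG"] / s["Km3PG"] * (1 + s["ATP"] / s["KmATP"])
           + s["BPG"] / s["KmBPG"] * (1 + s["ADP"] / s["KmADP"])))
    laws["PGK_printed"] = pgk_num / (
        (1 + s["ADP"] / s["KiADP"])
        * (1 + s["_3PG"] / s["Km3PG"] * (1 + s["ATP"] / s["KmATP"])
           + s["BPG"] / s["KmBPG"] + 1 + s["ADP"] / s["KmADP"]))

    s = _syms(["3PG", "2PG", "Vm", "Km3PG", "Km2PG", "Keq"])
    laws["PGMA"] = (
        s["Vm"] / s["Km3PG"] * (s["_3PG"] - s["_2PG"] / s["Keq"])
        / (1 + s["_3PG"] / s["Km3PG"] + s["_2PG"] / s["Km2PG"]))

    s = _syms(["2PG", "PEP", "Vm", "Km2PG", "KmPEP", "Keq"])
    laws["ENO"] = (
        s["Vm"] / s["Km2PG"] * (s["_2PG"] - s["PEP"] / s["Keq"])
        / (1 + s["_2PG"] / s["Km2PG"] + s["PEP"] / s["KmPEP"]))

    s = _syms(["ADP", "PEP", "ATP", "PYR", "Vm", "KmADP", "KmATP", "KmPEP",
               "KmPYR", "Keq"])
    laws["PYK"] = (
        s["Vm"]
        * (s["ADP"] * s["PEP"] / (s["KmADP"] * s["KmPEP"])
           - s["ATP"] * s["PYR"] / (s["KmADP"] * s["Keq"] * s["KmPEP"]))
        / ((1 + s["ADP"] / s["KmADP"] + s["ATP"] / s["KmATP"])
           * (1 + s["PEP"] / s["KmPEP"] + s["PYR"] / s["KmPYR"])))

    s = _syms(["GAP", "NADP", "Vm", "KmGAP", "KmNADP"])
    laws["GAPN"] = (
        s["Vm"] * s["GAP"] * s["NADP"] / (s["KmGAP"] * s["KmNADP"])
        / ((1 + s["GAP"] / s["KmGAP"]) * (1 + s["NADP"] / s["KmNADP"])))

    s = _syms(["BPG", "KdBPG"])
    laws["BPG_degradation"] = s["KdBPG"] * s["BPG"]

    s = _syms(["ATP", "k"])
    laws["ATPase"] = s["k"] * s["ATP"]

    s = _syms(["S", "P", "kf", "kr"])
    laws["MASS_ACTION_REV"] = s["kf"] * s["S"] - s["kr"] * s["P"]

    return laws


SYMBOLIC_LAWS = _build()


def _symbol_name(name: str) -> str:
    return "_" + name if name[0].isdigit() else name


def symbolic_rate(law_id: str) -> sp.Expr:
    return SYMBOLIC_LAWS[law_id]


def lambdified_law(law_id: str):
    """Callable(state_dict, param_dict) -> float from the symbolic form."""
    expr = SYMBOLIC_LAWS[law_id]
    symbols = sorted(expr.free_symbols, key=lambda x: x.name)
    func = sp.lambdify(symbols, expr, modules="math")

    def evaluate(values: dict) -> float:
        args = [values[sym.name.lstrip("_") if sym.name.startswith("_")
                       else sym.name] for sym in symbols]
        return func(*args)

    return evaluate
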
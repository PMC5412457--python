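"""Equilibrium constants and Gibbs energies of the GAPDH and PGK reactions.

The equilibrium constant of an enzymatic reaction follows from its kinetic
constants through the Briggs-Haldane relation

    K_eq = (Vm_f * prod Km_products) / (Vm_r * prod Km_substrates),

which carries a unit of M^-1 when the substrate side has one more Michaelis
constant than the product side (the phosphate term of the phosphorylating
GAPDH). Standard Gibbs energies follow as dG0' = -RT ln K_eq with K_eq
expressed in M-based units. Because intracellular phosphate sits far below
the 1 M standard state, an *effective* standard Gibbs energy

    dG0'' = dG0' + RT ln(1/Pi)        (Pi in M)

absorbs the fixed phosphate concentration; at Pi = 1 M it coincides with
dG0' exactly, and it falls by RT ln 10 per decade of phosphate. The actual
reaction Gibbs energy at given concentrations is
dG = dG0'' + RT ln(prod products / prod substrates), with the phosphate
imbalance already inside dG0''.

Unrounded equilibrium constants are propagated throughout; rounding to the
reported precision (1 decimal in kJ/mol) happens only in the table writer.

Default temperatures are the exact Kelvin conversions of 70 and 30 degC
(343.15 / 303.15 K); these reproduce the published Gibbs-energy table,
whereas the 347/307 K quoted alongside it do not. T stays exposed as a
parameter so either convention can be evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DomainError

__all__ = [
    "R_GAS",
    "T_HOT",
    "T_COLD",
    "ThermoContext",
    "ThermoResult",
    "keq_briggs_haldane",
    "keq_from_apparent",
    "standard_gibbs",
    "effective_gibbs",
    "reaction_gibbs",
    "keq_gapdh_ssol",
    "keq_pgk_ssol",
    "keq_gapdh_yeast",
    "KEQ_PGK_YEAST",
    "table1",
]

R_GAS = 8.314  # J K^-1 mol^-1
T_HOT = 343.15  # K, 70 degC (archaeal growth condition)
T_COLD = 303.15  # K, 30 degC (yeast growth condition)


@dataclass(frozen=True)
class ThermoContext:
    """Temperature and phosphate context for Gibbs-energy calculations."""

    T: float = T_HOT  # K
    R: float = R_GAS  # J K^-1 mol^-1
    Pi: float = 0.010  # M, for effective corrections

    def __post_init__(self):
        if self.T <= 0:
            raise DomainError(f"temperature must be positive, got {self.T}")
        if self.Pi <= 0:
            raise DomainError(f"phosphate must be positive, got {self.Pi}")

    @property
    def rt_kj(self) -> float:
        """R*T in kJ/mol."""
        return self.R * self.T / 1000.0


@dataclass(frozen=True)
class ThermoResult:
    """Equilibrium constant and Gibbs energies with their context."""

    reaction: str
    keq: float
    keq_units: str  # "" (dimensionless) or "M^-1"
    dg0_prime: float  # kJ/mol, standard
    dg0_double_prime: float  # kJ/mol, effective at ctx.Pi
    ctx: ThermoContext
    dg: float | None = None  # kJ/mol at given concentrations, optional


def keq_briggs_haldane(vm_forward: float, km_products: Sequence[float],
                       vm_reverse: float, km_substrates: Sequence[float],
                       ) -> tuple[float, str]:
    """Equilibrium constant from forward/reverse Vmax and Michaelis constants.

    Returns ``(value, units)`` with the value in M-based units: when the
    substrate side carries exactly one extra Km (all Km in mM), the mM^-1
    result is converted to M^-1 and tagged accordingly; with balanced sides
    the constant is dimensionless.
    """
    inputs = [vm_forward, vm_reverse, *km_products, *km_substrates]
    if any(x <= 0 for x in inputs):
        raise DomainError("all Briggs-Haldane inputs must be positive")
    value = (vm_forward * math.prod(km_products)) / \
        (vm_reverse * math.prod(km_substrates))
    excess = len(km_substrates) - len(km_products)
    if excess == 0:
        return value, ""
    if excess == 1:
        return value * 1000.0, "M^-1"  # mM^-1 -> M^-1
    raise DomainError(
        f"unsupported Km imbalance of {excess}; expected 0 or 1")


def keq_from_apparent(keq_apparent: float, k_pi: float) -> float:
    """Phosphate-inclusive K_eq (M^-1) from an apparent, Pi-free constant.

    ``k_pi`` is the phosphate Michaelis constant in M.
    """
    if keq_apparent <= 0 or k_pi <= 0:
        raise DomainError("inputs must be positive")
    return keq_apparent / k_pi


def standard_gibbs(keq: float, ctx: ThermoContext) -> float:
    """dG0' = -RT ln(K_eq) in kJ/mol (K_eq numeric in M-based units)."""
    if keq <= 0:
        raise DomainError(f"K_eq must be positive, got {keq}")
    return -ctx.rt_kj * math.log(keq)


def effective_gibbs(dg0_prime: float, pi_molar: float,
                    ctx: ThermoContext) -> float:
    """dG0'' = dG0' + RT ln(1/Pi) in kJ/mol, Pi in M."""
    if pi_molar <= 0:
        raise DomainError(f"Pi must be positive, got {pi_molar}")
    return dg0_prime + ctx.rt_kj * math.log(1.0 / pi_molar)


def reaction_gibbs(dg0_double_prime: float, products: Sequence[float],
                   substrates: Sequence[float], ctx: ThermoContext) -> float:
    """dG at given concentrations (mM enter as ratios) in kJ/mol.

    The phosphate imbalance is already inside dG0'', so products and
    substrates must be passed without the Pi term.
    """
    if any(c <= 0 for c in (*products, *substrates)):
        raise DomainError("all concentrations must be positive")
    ratio = math.prod(products) / math.prod(substrates)
    return dg0_double_prime + ctx.rt_kj * math.log(ratio)


# -- the published constants, computed from their kinetic inputs -------------

def keq_pgk_ssol() -> float:
    """K_eq of archaeal PGK (dimensionless) from its assayed kinetics."""
    value, _ = keq_briggs_haldane(
        vm_forward=37.96, km_products=[9.309, 0.567],
        vm_reverse=17.212, km_substrates=[0.374, 0.0082])
    return value


def keq_gapdh_ssol() -> float:
    """K_eq of archaeal GAPDH in M^-1 (unrounded; prints as 0.18)."""
    value, units = keq_briggs_haldane(
        vm_forward=35.551, km_products=[0.09445, 0.0895],
        vm_reverse=23.6115, km_substrates=[0.204, 3.1091, 108.32])
    assert units == "M^-1"
    return value


def keq_gapdh_yeast() -> float:
    """K_eq of yeast GAPDH in M^-1 from the apparent constant 0.0054."""
    return keq_from_apparent(0.0054, 0.0015)


KEQ_PGK_YEAST = 3200.0  # dimensionless, taken from the source yeast model


def analyse(reaction: str, keq: float, keq_units: str,
            ctx: ThermoContext, pi_dependent: bool = True) -> ThermoResult:
    """Bundle dG0' and dG0''(ctx.Pi) for one reaction."""
    dg0 = standard_gibbs(keq, ctx)
    if pi_dependent:
        dg0pp = effective_gibbs(dg0, ctx.Pi, ctx)
    else:
        dg0pp = dg0
    return ThermoResult(reaction=reaction, keq=keq, keq_units=keq_units,
                        dg0_prime=dg0, dg0_double_prime=dg0pp, ctx=ctx)


def table1(pi_values_mm=(1.0, 10.0, 100.0, 1000.0)) -> pd.DataFrame:
    """Effective standard Gibbs energies of GAPDH and PGK at 70 and 30 degC.

    One row per phosphate level (mM), one column per (reaction,
    temperature); PGK has no phosphate dependence so its column is flat.
    Values in kJ/mol, unrounded.
    """
    columns = {
        ("GAPDH", 70): (keq_gapdh_ssol(), True, ThermoContext(T=T_HOT)),
        ("PGK", 70): (keq_pgk_ssol(), False, ThermoContext(T=T_HOT)),
        ("GAPDH", 30): (keq_gapdh_yeast(), True, ThermoContext(T=T_COLD)),
        ("PGK", 30): (KEQ_PGK_YEAST, False, ThermoContext(T=T_COLD)),
    }
    rows = {}
    for pi_mm in pi_values_mm:
        row = {}
        for (name, temp), (keq, pi_dep, ctx) in columns.items():
            dg0 = standard_gibbs(keq, ctx)
            if pi_dep:
                row[f"{name}_{temp}C"] = effective_gibbs(
                    dg0, pi_mm / 1000.0, ctx)
            else:
                row[f"{name}_{temp}C"] = dg0
        rows[pi_mm] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "Pi_mM"
    return frame
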
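"""Enzyme rate laws for the lower glycolytic pathway (GAP -> pyruvate).

Each law is a pure function of a concentration mapping (mM) and a parameter
mapping, returning a signed net rate in mM/min; positive means the glycolytic
direction as the reaction is written (for PGK: BPG + ADP -> 3PG + ATP).

Conventions
-----------
* Concentrations are in mM, maximal rates in mM/min, first-order rate
  constants in 1/min.
* Reversible laws are written so that the net rate vanishes exactly where the
  mass-action ratio equals the reaction's equilibrium constant.  For the
  archaeal (NADP-linked, phosphorylating) GAPDH that constant includes the
  phosphate term and is therefore carried in mM^-1; for the yeast GAPDH the
  apparent (Pi-free) constant ``Keq`` is used together with ``Pi/KmPi``
  scaling, so the thermodynamic constant is ``Keq/KmPi``.
* The phosphoglycerate kinase (PGK) law is parameterised by the *reverse*
  maximal rate ``Vmr`` (the direction assayed in cell extract); the Haldane
  relation then fixes the forward capacity.  Two denominator variants are
  provided, see :data:`PGK_DENOMINATOR_FORMS`.
"""

from __future__ import annotations

import math
from typing import Callable, Mapping

from .errors import ConfigurationError, DomainError

__all__ = [
    "RATE_LAWS",
    "RateLaw",
    "evaluate_rate",
    "rate_law",
]


class RateLaw:
    """A named rate law with declared species and parameter symbols."""

    def __init__(self, name: str, species: tuple, parameters: tuple,
                 func: Callable[..., float]):
        self.name = name
        self.species = species
        self.parameters = parameters
        self.func = func

    def __call__(self, concentrations: Mapping[str, float],
                 parameters: Mapping[str, float]) -> float:
        c = []
        for s in self.species:
            try:
                value = concentrations[s]
            except KeyError:
                raise ConfigurationError(
                    f"rate law {self.name!r} needs species {s!r} "
                    "which is absent from the state") from None
            if value < 0:
                raise DomainError(
                    f"negative concentration {value} mM for species {s!r}")
            c.append(value)
        p = []
        for symbol in self.parameters:
            try:
                p.append(parameters[symbol])
            except KeyError:
                raise ConfigurationError(
                    f"rate law {self.name!r} needs parameter {symbol!r} "
                    "which is missing") from None
        return self.func(*c, *p)

    def __repr__(self):  # pragma: no cover
        return f"RateLaw({self.name!r})"


RATE_LAWS: dict[str, RateLaw] = {}


def rate_law(name: str, species: tuple, parameters: tuple):
    def register(func):
        RATE_LAWS[name] = RateLaw(name, species, parameters, func)
        return func
    return register


# -- glyceraldehyde-3-phosphate dehydrogenase, NAD-linked (yeast) ------------
# GAP + NAD + Pi <-> BPG + NADH.  ``Keq`` is the apparent, Pi-free constant
# (0.0054); the thermodynamic constant is Keq/KmPi = 3.6 M^-1.

@rate_law("GAPDH_yeast",
          species=("GAP", "NAD", "Pi", "BPG", "NADH"),
          parameters=("Vm", "KmGAP", "KmNAD", "KmNADH", "KmBPG", "KmPi", "Keq"))
def gapdh_nad(gap, nad, pi, bpg, nadh,
              vm, km_gap, km_nad, km_nadh, km_bpg, km_pi, keq):
    num = vm * (gap * nad * pi / (km_gap * km_nad * km_pi)
                - bpg * nadh / (keq * km_gap * km_nad))
    den = (((1 + gap / km_gap) * (1 + pi / km_pi) + bpg / km_bpg)
           * (1 + nad / km_nad + nadh / km_nadh))
    return num / den


# -- glyceraldehyde-3-phosphate dehydrogenase, NADP-linked (S. solfataricus) -
# GAP + NADP + Pi <-> BPG + NADPH.  ``Keq`` is the full thermodynamic
# constant in mM^-1 (Briggs-Haldane, phosphate included), so the net rate is
# zero exactly at [BPG][NADPH]/([GAP][NADP][Pi]) = Keq.

@rate_law("GAPDH_ssol",
          species=("GAP", "NADP", "Pi", "BPG", "NADPH"),
          parameters=("Vm", "KmGAP", "KmNADP", "KmNADPH", "KmBPG", "KmPi",
                      "Keq"))
def gapdh_nadp(gap, nadp, pi, bpg, nadph,
               vm, km_gap, km_nadp, km_nadph, km_bpg, km_pi, keq):
    num = (vm * (gap * nadp * pi - bpg * nadph / keq)
           / (km_gap * km_nadp * km_pi))
    den = (((1 + gap / km_gap) * (1 + pi / km_pi) + bpg / km_bpg)
           * (1 + nadp / km_nadp + nadph / km_nadph))
    return num / den


# -- phosphoglycerate kinase -------------------------------------------------
# BPG + ADP <-> 3PG + ATP, reverse-Vmax parameterisation.  The denominator
# has two published readings (see module docstring); the grouped
# ternary-complex form is the default because it reproduces the reference
# steady states, the literal transcription is kept for sensitivity analysis.

def _pgk_numerator(bpg, adp, pg3, atp, vmr, km_atp, km_3pg, keq):
    return vmr * (keq * adp * bpg - atp * pg3) / (km_atp * km_3pg)


@rate_law("PGK_shared",
          species=("BPG", "ADP", "3PG", "ATP"),
          parameters=("Vmr", "KmADP", "KmATP", "KmBPG", "Km3PG", "KiADP",
                      "Keq"))
def pgk_grouped(bpg, adp, pg3, atp,
                vmr, km_adp, km_atp, km_bpg, km_3pg, ki_adp, keq):
    num = _pgk_numerator(bpg, adp, pg3, atp, vmr, km_atp, km_3pg, keq)
    den = ((1 + adp / ki_adp)
           * (1 + pg3 / km_3pg * (1 + atp / km_atp)
              + bpg / km_bpg * (1 + adp / km_adp)))
    return num / den


@rate_law("PGK_printed",
          species=("BPG", "ADP", "3PG", "ATP"),
          parameters=("Vmr", "KmADP", "KmATP", "KmBPG", "Km3PG", "KiADP",
                      "Keq"))
def pgk_printed(bpg, adp, pg3, atp,
                vmr, km_adp, km_atp, km_bpg, km_3pg, ki_adp, keq):
    # literal transcription of the published expression, dangling
    # "+(1+ADP/KmADP)" term included as an additive constant
    num = _pgk_numerator(bpg, adp, pg3, atp, vmr, km_atp, km_3pg, keq)
    den = ((1 + adp / ki_adp)
           * (1 + pg3 / km_3pg * (1 + atp / km_atp) + bpg / km_bpg
              + (1 + adp / km_adp)))
    return num / den


PGK_DENOMINATOR_FORMS = ("PGK_shared", "PGK_printed")


# -- phosphoglycerate mutase -------------------------------------------------

@rate_law("PGMA",
          species=("3PG", "2PG"),
          parameters=("Vm", "Km3PG", "Km2PG", "Keq"))
def pgma(pg3, pg2, vm, km_3pg, km_2pg, keq):
    return (vm / km_3pg * (pg3 - pg2 / keq)
            / (1 + pg3 / km_3pg + pg2 / km_2pg))


# -- enolase -----------------------------------------------------------------

@rate_law("ENO",
          species=("2PG", "PEP"),
          parameters=("Vm", "Km2PG", "KmPEP", "Keq"))
def eno(pg2, pep, vm, km_2pg, km_pep, keq):
    return (vm / km_2pg * (pg2 - pep / keq)
            / (1 + pg2 / km_2pg + pep / km_pep))


# -- pyruvate kinase ---------------------------------------------------------

@rate_law("PYK",
          species=("ADP", "PEP", "ATP", "PYR"),
          parameters=("Vm", "KmADP", "KmATP", "KmPEP", "KmPYR", "Keq"))
def pyk(adp, pep, atp, pyr, vm, km_adp, km_atp, km_pep, km_pyr, keq):
    num = vm * (adp * pep / (km_adp * km_pep)
                - atp * pyr / (km_adp * keq * km_pep))
    den = ((1 + adp / km_adp + atp / km_atp)
           * (1 + pep / km_pep + pyr / km_pyr))
    return num / den


# -- non-phosphorylating GAP dehydrogenase (GAPN) ----------------------------
# Irreversible two-substrate law, GAP + NADP -> 3PG + NADPH.

@rate_law("GAPN",
          species=("GAP", "NADP"),
          parameters=("Vm", "KmGAP", "KmNADP"))
def gapn(gap, nadp, vm, km_gap, km_nadp):
    return (vm * gap * nadp / (km_gap * km_nadp)
            / ((1 + gap / km_gap) * (1 + nadp / km_nadp)))


# -- non-enzymatic BPG hydrolysis --------------------------------------------

@rate_law("BPG_degradation", species=("BPG",), parameters=("KdBPG",))
def bpg_degradation(bpg, kd):
    return kd * bpg


# -- lumped ATP hydrolysis (mass action) -------------------------------------

@rate_law("ATPase", species=("ATP",), parameters=("k",))
def atpase(atp, k):
    return k * atp


# -- reversible first-order step (synthetic linear chains) -------------------

@rate_law("MASS_ACTION_REV",
          species=("S", "P"), parameters=("kf", "kr"))
def mass_action_reversible(s, p, kf, kr):
    return kf * s - kr * p


def evaluate_rate(reaction, state: Mapping[str, float]) -> float:
    """Net rate (mM/min) of ``reaction`` at the concentrations in ``state``.

    ``reaction`` is a :class:`~thermoglyc.pathway.ReactionSpec` (anything
    with ``rate_law_id``, ``parameters`` and, for mass-action chain steps,
    a ``species_map``).  Species named by the law are looked up in ``state``
    directly, or through the reaction's ``species_map`` when the law uses
    generic roles (substrate ``S`` / product ``P``).
    """
    try:
        law = RATE_LAWS[reaction.rate_law_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown rate law {reaction.rate_law_id!r}; "
            f"known laws: {sorted(RATE_LAWS)}") from None
    species_map = getattr(reaction, "species_map", None)
    if species_map:
        state = {role: state[name] for role, name in species_map.items()}
    rate = law(state, reaction.parameters)
    if not math.isfinite(rate):
        raise DomainError(
            f"rate of {reaction.name!r} is not finite at the given state")
    return rate
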
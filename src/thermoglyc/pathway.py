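"""Executable pathway models of lower glycolysis (GAP -> pyruvate).

The module defines the domain containers (:class:`SpeciesState`,
:class:`ReactionSpec`, :class:`PathwayModel`, :class:`FluxTable`) and the
:func:`build_model` factory that assembles the published model variants for
*Saccharomyces cerevisiae* (30 degC) and *Sulfolobus solfataricus* (70 degC).

The archaeal pathway differs from the yeast one in two respects: it carries
the non-phosphorylating bypass GAPN (GAP + NADP -> 3PG + NADPH, no ATP), and
its thermolabile intermediate 1,3-bisphosphoglycerate (BPG) hydrolyses
spontaneously to 3PG with a first-order rate constant of 1.058/min at 70 degC.

All kinetic parameters are the published cell-extract values; no temperature
scaling of the kinetics is applied (temperature enters only through which
parameter set is used and through the thermodynamics module).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError
from .rate_laws import RATE_LAWS, evaluate_rate

__all__ = [
    "SpeciesState",
    "ReactionSpec",
    "PathwayModel",
    "FluxTable",
    "build_model",
    "KEQ_GAPDH_SSOL_MM",
    "ORGANISMS",
    "VARIANTS",
    "ADENYLATE_TOTAL_MM",
]

# Thermodynamic equilibrium constant of the archaeal GAPDH reaction
# (GAP + NADP + Pi <-> BPG + NADPH) in mM^-1: the unrounded Briggs-Haldane
# value 0.185 M^-1 divided by 1000. Rounded only at report time.
KEQ_GAPDH_SSOL_MM = (35.551 * 0.09445 * 0.0895) / (23.6115 * 0.204 * 3.1091
                                                   * 108.32)

# ATP + ADP conserved total (mM) when the adenylates are freed (2.52 + 1.32).
ADENYLATE_TOTAL_MM = 3.84

ORGANISMS = ("yeast", "sulfolobus")
VARIANTS = ("base", "gapdh_x1000", "with_gapn", "with_atpase", "hyp2_base",
            "hyp2_boosted", "catabolic", "anabolic", "anabolic_text")


@dataclass(frozen=True)
class SpeciesState:
    """A metabolite with its initial concentration.

    Boundary species are clamped: their concentration is held fixed during
    integration and steady-state solving.
    """

    name: str
    concentration: float  # mM
    is_boundary: bool = False

    def __post_init__(self):
        if self.concentration < 0:
            raise DomainError(
                f"species {self.name!r}: concentration must be >= 0, "
                f"got {self.concentration}")


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction: signed stoichiometry, a rate-law id and its parameters."""

    name: str
    stoichiometry: dict  # species name -> signed integer
    rate_law_id: str
    parameters: dict  # symbol -> value
    species_map: dict | None = None  # law role -> species name (chains only)

    def __post_init__(self):
        law = RATE_LAWS.get(self.rate_law_id)
        if law is None:
            raise ConfigurationError(
                f"reaction {self.name!r}: unknown rate law "
                f"{self.rate_law_id!r}")
        missing = [s for s in law.parameters if s not in self.parameters]
        if missing:
            raise ConfigurationError(
                f"reaction {self.name!r}: rate law {self.rate_law_id!r} "
                f"is missing parameters {missing}")

    def rate(self, state) -> float:
        return evaluate_rate(self, state)


@dataclass
class PathwayModel:
    """Species, reactions and conserved moieties of one model variant."""

    organism: str
    species: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    moieties: list = field(default_factory=list)  # (frozenset, total mM)
    temperature_label: float | None = None  # degC, annotation only
    name: str = ""

    # -- lookups -------------------------------------------------------------

    @property
    def species_names(self):
        return [s.name for s in self.species]

    @property
    def free_species(self):
        return [s.name for s in self.species if not s.is_boundary]

    @property
    def boundary_species(self):
        return [s.name for s in self.species if s.is_boundary]

    @property
    def reaction_names(self):
        return [r.name for r in self.reactions]

    def get_species(self, name: str) -> SpeciesState:
        for s in self.species:
            if s.name == name:
                return s
        raise ConfigurationError(f"no species named {name!r}")

    def get_reaction(self, name: str) -> ReactionSpec:
        for r in self.reactions:
            if r.name == name:
                return r
        raise ConfigurationError(f"no reaction named {name!r}")

    def initial_state(self) -> dict:
        return {s.name: s.concentration for s in self.species}

    # -- editing (copy-on-write) ---------------------------------------------

    def with_parameter(self, reaction: str, symbol: str,
                       value: float) -> "PathwayModel":
        """Copy of the model with one rate-law parameter replaced."""
        new = copy.deepcopy(self)
        for i, r in enumerate(new.reactions):
            if r.name == reaction:
                if symbol not in r.parameters:
                    raise ConfigurationError(
                        f"reaction {reaction!r} has no parameter {symbol!r}")
                params = dict(r.parameters)
                params[symbol] = value
                new.reactions[i] = replace(r, parameters=params)
                return new
        raise ConfigurationError(f"no reaction named {reaction!r}")

    def with_boundary(self, species: str, concentration: float
                      ) -> "PathwayModel":
        """Copy of the model with one boundary concentration replaced."""
        new = copy.deepcopy(self)
        for i, s in enumerate(new.species):
            if s.name == species:
                if not s.is_boundary:
                    raise ConfigurationError(
                        f"species {species!r} is not a boundary species")
                new.species[i] = replace(s, concentration=concentration)
                return new
        raise ConfigurationError(f"no species named {species!r}")

    # -- structure -----------------------------------------------------------

    def stoichiometric_matrix(self, species=None) -> np.ndarray:
        """Signed stoichiometric matrix, rows = species, cols = reactions."""
        if species is None:
            species = self.species_names
        mat = np.zeros((len(species), len(self.reactions)))
        index = {name: i for i, name in enumerate(species)}
        for j, rxn in enumerate(self.reactions):
            for name, coeff in rxn.stoichiometry.items():
                if name in index:
                    mat[index[name], j] = coeff
        return mat

    def rates(self, state) -> dict:
        return {r.name: r.rate(state) for r in self.reactions}

    def validate(self):
        """Check the structural invariants; raise ConfigurationError if bad.

        The conserved-moiety totals must equal the sums of their members'
        initial concentrations, and each moiety indicator vector must lie in
        the left null space of the stoichiometric matrix restricted to free
        species.
        """
        names = set(self.species_names)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - names
            if unknown:
                raise ConfigurationError(
                    f"reaction {rxn.name!r} references unknown species "
                    f"{sorted(unknown)}")
        free = self.free_species
        s_free = self.stoichiometric_matrix(free)
        index = {name: i for i, name in enumerate(free)}
        for members, total in self.moieties:
            missing = [m for m in members if m not in index]
            if missing:
                raise ConfigurationError(
                    f"moiety {sorted(members)}: members {missing} are not "
                    "free species")
            init = sum(self.get_species(m).concentration for m in members)
            if not math.isclose(init, total, rel_tol=1e-12):
                raise ConfigurationError(
                    f"moiety {sorted(members)}: total {total} != sum of "
                    f"initial concentrations {init}")
            indicator = np.zeros(len(free))
            for m in members:
                indicator[index[m]] = 1.0
            if np.max(np.abs(indicator @ s_free)) > 1e-12:
                raise ConfigurationError(
                    f"moiety {sorted(members)} is not conserved by the "
                    "stoichiometry")
        return self


@dataclass
class FluxTable:
    """Per-reaction signed net fluxes (mM/min), glycolytic direction > 0."""

    fluxes: dict

    def __getitem__(self, name):
        return self.fluxes[name]

    def __contains__(self, name):
        return name in self.fluxes

    def items(self):
        return self.fluxes.items()

    def as_dict(self):
        return dict(self.fluxes)


# ---------------------------------------------------------------------------
# Published parameter sets (cell-extract kinetics; mM, mM/min, 1/min)
# ---------------------------------------------------------------------------

_GAPDH_YEAST = dict(Vm=1859.0, KmGAP=0.21, KmNAD=0.09, KmNADH=0.06,
                    KmBPG=0.0098, KmPi=1.5, Keq=0.0054)
_GAPDH_SSOL = dict(Vm=66.0, KmGAP=3.10, KmNADP=0.20, KmNADPH=0.094,
                   KmBPG=0.089, KmPi=108.52, Keq=KEQ_GAPDH_SSOL_MM)
# Yeast PGK: no ADP inhibition constant is published; KiADP = inf makes the
# (1 + ADP/KiADP) factor exactly 1.
_PGK_YEAST = dict(Vmr=2670.0, KmADP=0.2, KmATP=0.3, KmBPG=0.003, Km3PG=0.53,
                  KiADP=math.inf, Keq=3200.0)
_PGK_SSOL = dict(Vmr=73.0, KmADP=0.374, KmATP=9.303, KmBPG=0.008,
                 Km3PG=0.567, KiADP=1.14, Keq=3793.0)
_PGMA = dict(Km3PG=1.2, Km2PG=0.08, Keq=0.19)
_ENO = dict(Km2PG=0.04, KmPEP=0.5, Keq=6.7)
_PYK = dict(KmADP=0.53, KmATP=1.5, KmPEP=0.14, KmPYR=21.0, Keq=6500.0)
_VM = {  # organism-specific maximal rates, mM/min
    "yeast": dict(PGMA=856.0, ENO=357.0, PYK=559.0),
    "sulfolobus": dict(PGMA=56.0, ENO=20.5, PYK=76.0),
}
_GAPN = dict(Vm=20.0, KmGAP=0.02, KmNADP=0.09)
KDEG_70C = 1.058  # 1/min, non-enzymatic BPG -> 3PG at 70 degC

# Boundary presets (mM). "catabolic" doubles as the baseline condition for
# the steady-state/control-analysis runs; phosphate baseline is 10 mM.
_CATABOLIC = dict(GAP=0.15, NADox=1.2, NADred=0.39, ADP=1.32, ATP=2.52,
                  Pi=10.0, PYR=0.0)
# Gluconeogenic preset from the published results-table caption.
_ANABOLIC = dict(GAP=0.0015, NADox=0.1, NADred=1.49, ADP=0.1, ATP=3.74,
                 Pi=10.0, PYR=0.0, PEP=0.7)
# Alternate gluconeogenic preset from the methods text (conflicting print).
_ANABOLIC_TEXT = dict(GAP=0.015, NADox=0.1, NADred=1.49, ADP=1.32, ATP=2.52,
                      Pi=10.0, PYR=0.0, PEP=0.7)


def _species_list(organism, preset, free_adenylates=False):
    nad_ox, nad_red = ("NAD", "NADH") if organism == "yeast" else \
        ("NADP", "NADPH")
    species = [
        SpeciesState("GAP", preset["GAP"], True),
        SpeciesState(nad_ox, preset["NADox"], True),
        SpeciesState(nad_red, preset["NADred"], True),
        SpeciesState("Pi", preset["Pi"], True),
        SpeciesState("PYR", preset["PYR"], True),
        SpeciesState("ATP", preset["ATP"], not free_adenylates),
        SpeciesState("ADP", preset["ADP"], not free_adenylates),
        SpeciesState("BPG", 0.0, False),
        SpeciesState("3PG", 0.0, False),
        SpeciesState("2PG", 0.0, False),
    ]
    if "PEP" in preset:
        species.append(SpeciesState("PEP", preset["PEP"], True))
    else:
        species.append(SpeciesState("PEP", 0.0, False))
    return species


def _core_reactions(organism, pgk_form):
    nad_ox, nad_red = ("NAD", "NADH") if organism == "yeast" else \
        ("NADP", "NADPH")
    gapdh_law = "GAPDH_yeast" if organism == "yeast" else "GAPDH_ssol"
    gapdh_params = _GAPDH_YEAST if organism == "yeast" else _GAPDH_SSOL
    pgk_params = _PGK_YEAST if organism == "yeast" else _PGK_SSOL
    vm = _VM[organism]
    reactions = [
        ReactionSpec("GAPDH",
                     {"GAP": -1, nad_ox: -1, "Pi": -1, "BPG": 1, nad_red: 1},
                     gapdh_law, dict(gapdh_params)),
        ReactionSpec("PGK",
                     {"BPG": -1, "ADP": -1, "3PG": 1, "ATP": 1},
                     pgk_form, dict(pgk_params)),
        ReactionSpec("PGMA", {"3PG": -1, "2PG": 1},
                     "PGMA", dict(_PGMA, Vm=vm["PGMA"])),
        ReactionSpec("ENO", {"2PG": -1, "PEP": 1},
                     "ENO", dict(_ENO, Vm=vm["ENO"])),
        ReactionSpec("PYK",
                     {"PEP": -1, "ADP": -1, "PYR": 1, "ATP": 1},
                     "PYK", dict(_PYK, Vm=vm["PYK"])),
    ]
    if organism == "sulfolobus":
        reactions.append(
            ReactionSpec("BPG_degradation", {"BPG": -1, "3PG": 1},
                         "BPG_degradation", dict(KdBPG=KDEG_70C)))
    return reactions


def _gapn_reaction():
    return ReactionSpec("GAPN",
                        {"GAP": -1, "NADP": -1, "3PG": 1, "NADPH": 1},
                        "GAPN", dict(_GAPN))


def _atpase_reaction(k=1.0):
    return ReactionSpec("ATPase", {"ATP": -1, "ADP": 1}, "ATPase", dict(k=k))


def build_model(organism: str, variant: str = "base", *,
                pgk_form: str = "PGK_shared",
                k_deg: float | None = None,
                k_atpase: float = 1.0,
                with_gapn: bool | None = None) -> PathwayModel:
    """Assemble a fully parameterised :class:`PathwayModel`.

    Parameters
    ----------
    organism : {"yeast", "sulfolobus"}
    variant : str
        ``base``
            GAPDH + PGK + lower chain (and, for the archaeon, spontaneous
            BPG hydrolysis); no GAPN. Catabolic boundary concentrations.
        ``gapdh_x1000``
            base with the GAPDH maximal rate multiplied by 1000
            (archaeon only).
        ``with_gapn`` / ``catabolic``
            full archaeal model including GAPN (``catabolic`` maps to
            ``base`` for yeast, whose pathway has no GAPN).
        ``with_atpase`` / ``hyp2_base``
            base topology plus a lumped mass-action ATPase; ATP and ADP
            become free with a conserved sum of 3.84 mM.
        ``hyp2_boosted``
            as ``hyp2_base`` but with thermodynamically relieved GAPDH:
            Vmax x10, GAP and Pi boundaries x10, NADPH 0.1 mM,
            NADP 1.59 mM (archaeon only).
        ``anabolic`` / ``anabolic_text``
            full model under gluconeogenic boundary conditions (high PEP
            and reduced cofactor, low GAP); the two presets reflect two
            conflicting published prints of the condition.
    pgk_form : {"PGK_shared", "PGK_printed"}
        Denominator variant of the PGK law.
    k_deg : float, optional
        Override for the BPG hydrolysis rate constant (1/min); default is
        the 70 degC value 1.058 (archaeon only).
    k_atpase : float
        ATPase rate constant (1/min) for the variants that include it.
    with_gapn : bool, optional
        Force GAPN in or out of the ``hyp2_*`` variants (default: absent).
    """
    if organism not in ORGANISMS:
        raise ConfigurationError(
            f"unknown organism {organism!r}; valid: {list(ORGANISMS)}")
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; valid: {list(VARIANTS)}")
    if pgk_form not in ("PGK_shared", "PGK_printed"):
        raise ConfigurationError(
            f"unknown PGK form {pgk_form!r}; valid: PGK_shared, PGK_printed")
    ssol = organism == "sulfolobus"
    if not ssol and variant in ("gapdh_x1000", "with_gapn", "hyp2_boosted"):
        raise ConfigurationError(
            f"variant {variant!r} is defined for the archaeal model only")

    free_adenylates = variant in ("with_atpase", "hyp2_base", "hyp2_boosted")
    if variant == "anabolic":
        preset = dict(_ANABOLIC)
    elif variant == "anabolic_text":
        preset = dict(_ANABOLIC_TEXT)
    else:
        preset = dict(_CATABOLIC)
    if variant == "hyp2_boosted":
        preset["GAP"] *= 10
        preset["Pi"] *= 10
        preset["NADox"] = 1.59
        preset["NADred"] = 0.1

    reactions = _core_reactions(organism, pgk_form)
    if variant == "gapdh_x1000":
        gapdh = reactions[0]
        params = dict(gapdh.parameters)
        params["Vm"] *= 1000
        reactions[0] = replace(gapdh, parameters=params)
    if variant == "hyp2_boosted":
        gapdh = reactions[0]
        params = dict(gapdh.parameters)
        params["Vm"] *= 10
        reactions[0] = replace(gapdh, parameters=params)

    gapn_in = variant in ("with_gapn", "anabolic", "anabolic_text") or \
        (variant == "catabolic" and ssol)
    if variant in ("with_atpase", "hyp2_base", "hyp2_boosted") and with_gapn:
        gapn_in = True
    if gapn_in and ssol:
        reactions.append(_gapn_reaction())
    if free_adenylates:
        reactions.append(_atpase_reaction(k_atpase))
    if k_deg is not None:
        if not ssol:
            raise ConfigurationError(
                "k_deg applies to the archaeal model only")
        for i, r in enumerate(reactions):
            if r.name == "BPG_degradation":
                reactions[i] = replace(r, parameters=dict(KdBPG=k_deg))

    species = _species_list(organism, preset, free_adenylates)
    moieties = []
    if free_adenylates:
        moieties.append((frozenset({"ATP", "ADP"}),
                         preset["ATP"] + preset["ADP"]))
    model = PathwayModel(
        organism=organism,
        species=species,
        reactions=reactions,
        moieties=moieties,
        temperature_label=70.0 if ssol else 30.0,
        name=f"{organism}_{variant}",
    )
    return model.validate()
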
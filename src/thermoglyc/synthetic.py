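"""Synthetic kinetic networks with closed-form answers, and randomized
perturbations of the published parameter set.

The linear first-order chains exercise the steady-state solver and the
control analysis against exact algebra: for a chain of reversible
mass-action steps v_i = kf_i c_{i-1} - kr_i c_i between a clamped source
c_0 and sink c_n, the steady flux is

    J = (c_0 prod kf_i  -  c_n prod kr_i) / D,
    D = sum_j  prod_{l<j} kr_l  *  prod_{l>j} kf_l,

and the scaled flux control coefficient of step j (scaling kf_j and kr_j
together, as an enzyme-amount change would) is exactly C_j = D_j / D with
D_j the j-th denominator term. For n identical irreversible steps this
gives the textbook C_j = 1/n.

Parameter perturbations are multiplicative log-normal on every maximal rate
and Michaelis constant - positive and scale-aware - while equilibrium
constants stay untouched, so the thermodynamic zero-crossings of every
reversible law are preserved by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError
from .pathway import PathwayModel, ReactionSpec, SpeciesState

__all__ = ["OracleModel", "make_linear_chain", "perturb_parameters"]


@dataclass
class OracleModel:
    """A linear-chain PathwayModel with its analytic solution attached."""

    model: PathwayModel
    analytic_flux: float  # mM/min, common to every step
    analytic_concentrations: dict  # free species -> mM
    analytic_control: dict  # reaction name -> C^J

    def balance_residual(self) -> float:
        """Infinity norm of the balance equations at the analytic state."""
        state = {s.name: s.concentration
                 for s in self.model.species if s.is_boundary}
        state.update(self.analytic_concentrations)
        rates = self.model.rates(state)
        s_free = self.model.stoichiometric_matrix(self.model.free_species)
        v = np.array([rates[r.name] for r in self.model.reactions])
        if len(self.model.free_species) == 0:
            return 0.0
        return float(np.max(np.abs(s_free @ v)))


def make_linear_chain(n_steps: int, k_forward, k_reverse,
                      source: float = 1.0, sink: float = 0.0) -> OracleModel:
    """Reversible first-order chain X0 -> X1 -> ... -> Xn with clamped ends.

    ``k_forward`` and ``k_reverse`` are per-step rate constants (1/min),
    scalars or length-``n_steps`` sequences; ``source``/``sink`` are the
    clamped boundary concentrations (mM). Reverse constants may be zero
    (irreversible steps); forward constants must be positive.
    """
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    kf = np.broadcast_to(np.asarray(k_forward, dtype=float),
                         (n_steps,)).copy()
    kr = np.broadcast_to(np.asarray(k_reverse, dtype=float),
                         (n_steps,)).copy()
    if np.any(kf <= 0) or np.any(kr < 0):
        raise DomainError("rate constants must be positive (kf) and "
                          "non-negative (kr)")
    if source < 0 or sink < 0:
        raise DomainError("boundary concentrations must be >= 0")

    names = [f"X{i}" for i in range(n_steps + 1)]
    species = [SpeciesState(names[0], source, True)]
    species += [SpeciesState(n, 0.0, False) for n in names[1:-1]]
    species.append(SpeciesState(names[-1], sink, True))
    reactions = []
    for i in range(n_steps):
        reactions.append(ReactionSpec(
            f"step{i + 1}",
            {names[i]: -1, names[i + 1]: 1},
            "MASS_ACTION_REV",
            dict(kf=float(kf[i]), kr=float(kr[i])),
            species_map={"S": names[i], "P": names[i + 1]}))
    model = PathwayModel(organism="synthetic", species=species,
                         reactions=reactions,
                         name=f"chain_{n_steps}").validate()

    # closed-form flux and control coefficients
    d_terms = np.array([np.prod(kr[:j]) * np.prod(kf[j + 1:])
                        for j in range(n_steps)])
    denominator = float(d_terms.sum())
    flux = float((source * np.prod(kf) - sink * np.prod(kr)) / denominator)
    control = {f"step{j + 1}": float(d_terms[j] / denominator)
               for j in range(n_steps)}

    # interior concentrations from the tridiagonal balance system
    interior = names[1:-1]
    concentrations = {}
    if interior:
        m = len(interior)
        a = np.zeros((m, m))
        b = np.zeros(m)
        for idx in range(m):
            # balance of X_{idx+1}: kf[idx] c_idx - (kr[idx]+kf[idx+1])
            #   c_{idx+1} + kr[idx+1] c_{idx+2} = 0
            a[idx, idx] = -(kr[idx] + kf[idx + 1])
            if idx > 0:
                a[idx, idx - 1] = kf[idx]
            else:
                b[idx] -= kf[0] * source
            if idx < m - 1:
                a[idx, idx + 1] = kr[idx + 1]
            else:
                b[idx] -= kr[n_steps - 1] * sink
        solution = np.linalg.solve(a, b)
        concentrations = dict(zip(interior, solution))
    return OracleModel(model=model, analytic_flux=flux,
                       analytic_concentrations=concentrations,
                       analytic_control=control)


# parameters multiplied by a log-normal factor; equilibrium and first-order
# decay constants are left untouched
_PERTURBED_PREFIXES = ("Vm", "Vmr", "Km", "Ki")


def perturb_parameters(model: PathwayModel, sigma: float,
                       seed: int) -> PathwayModel:
    """Multiplicative log-normal jitter on every Vmax and Michaelis constant.

    Each eligible parameter is multiplied by exp(N(0, sigma^2)) with an
    independent draw from a generator seeded by ``seed`` (deterministic:
    equal seeds give bit-identical models). Equilibrium constants are not
    touched, so every reversible law keeps its thermodynamic
    zero-crossing.
    """
    if sigma < 0:
        raise DomainError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    reactions = []
    for rxn in model.reactions:
        params = {}
        for symbol, value in rxn.parameters.items():
            if sigma > 0 and symbol.startswith(_PERTURBED_PREFIXES) \
                    and np.isfinite(value):
                params[symbol] = value * float(
                    np.exp(rng.normal(0.0, sigma)))
            else:
                params[symbol] = value
        reactions.append(replace(rxn, parameters=params))
    perturbed = PathwayModel(
        organism=model.organism,
        species=list(model.species),
        reactions=reactions,
        moieties=list(model.moieties),
        temperature_label=model.temperature_label,
        name=f"{model.name}_perturbed" if sigma > 0 else model.name,
    )
    return perturbed
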
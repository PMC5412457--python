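# Methods

`thermoglyc` models the lower glycolytic pathway — glyceraldehyde
3-phosphate (GAP) to pyruvate — of the hyperthermoacidophilic archaeon
*Sulfolobus solfataricus* (growing at ~70 °C) and, as a mesophilic control,
of *Saccharomyces cerevisiae* (30 °C). The scientific question is why many
(hyper)thermophilic archaea carry GAPN, a non-phosphorylating GAP
dehydrogenase (GAP + NADP⁺ → 3PG + NADPH) that bypasses the canonical
GAPDH + PGK couple and thereby forfeits one substrate-level ATP per triose.
Three candidate explanations are examined entirely in silico: (1) at 70 °C
the GAPDH reaction is thermodynamically too far uphill for GAPDH + PGK to
carry useful flux; (2) spontaneous hydrolysis of the thermolabile
intermediate 1,3-bisphosphoglycerate (BPG) erodes the ATP yield of the
canonical route below that of the bypass; (3) GAPDH + PGK are retained for
the gluconeogenic direction, which the irreversible GAPN cannot serve.

## Kinetic model

Both organisms share the backbone GAP → BPG → 3PG → 2PG → PEP → pyruvate
with reactions GAPDH (reversible, explicit phosphate:
GAP + NAD(P)⁺ + Pi ⇌ BPG + NAD(P)H), PGK (BPG + ADP ⇌ 3PG + ATP), the
mutase (PGMA), enolase (ENO) and pyruvate kinase (PYK). The archaeal model
additionally carries GAPN (irreversible two-substrate Michaelis–Menten) and
a first-order non-enzymatic BPG → 3PG decay, k_deg = 1.058 min⁻¹ at 70 °C
(assumed ×10 per +10 °C for the 80/90 °C scenarios: 10.58 and 105.8 min⁻¹).
All kinetic constants are literature cell-extract values carried in mM and
mM/min; temperature is not Arrhenius-scaled — it enters only through which
parameter set is used and through the thermodynamic formulas.

Two transcription choices deserve note:

* **GAPDH equilibrium constants.** The archaeal (NADP-linked) law carries
  the full thermodynamic constant K_eq = 1.85259 × 10⁻⁴ mM⁻¹ (the
  unrounded Briggs–Haldane value; it prints as 0.18–0.19 M⁻¹), so the net
  rate is zero exactly at [BPG][NADPH]/([GAP][NADP][Pi]) = K_eq. The yeast
  law uses the apparent, phosphate-free constant 0.0054 together with
  Pi/K_mPi scaling; its thermodynamic zero-crossing is 0.0054/1.5 mM =
  3.6 M⁻¹. Unrounded constants are propagated everywhere and rounded only
  in report writers.
* **PGK denominator.** The literature prints the PGK law with a dangling
  "+(1+ADP/K_mADP)" term — typographically ambiguous. We implement the
  grouped ternary-complex reading
  `(1+ADP/K_iADP)·(1 + 3PG/K_m3PG·(1+ATP/K_mATP) + BPG/K_mBPG·(1+ADP/K_mADP))`
  as the default (`PGK_shared`): it reproduces every published steady
  state we can test against (base flux 0.137 vs 0.136 mM/min, BPG
  6.75 × 10⁻⁶ vs 6.9 × 10⁻⁶ mM, 1000×-GAPDH flux 7.45 vs 7.4, yeast 239
  vs 236, the phosphate experiment and the scan ratios), whereas the
  literal additive reading (kept as `PGK_printed` for sensitivity
  analysis) misses the BPG level ~3.7-fold. No ADP inhibition constant is
  published for yeast PGK, so its (1+ADP/K_iADP) factor is fixed at 1
  (K_i → ∞); the archaeal K_iADP is 1.14 mM.

Boundary (clamped) species define each scenario. The glycolytic preset
fixes GAP 0.15, NAD(P)⁺ 1.2, NAD(P)H 0.39, ADP 1.32, ATP 2.52, Pi 10
(100 in the phosphate experiment), pyruvate 0 mM; BPG, 3PG, 2PG and PEP
evolve from 0. Pyruvate is clamped at 0 because the chain would otherwise
have no steady state; with K_mPYR = 21 mM and K_eqPYK = 6500 the neglected
product back-pressure is negligible. The gluconeogenic preset fixes GAP
0.0015, NAD(P)⁺ 0.1, NAD(P)H 1.49, PEP 0.7, ADP 0.1, ATP 3.74 mM. (The
source text prints a second, conflicting version of that preset — GAP
0.015, ADP 1.32, ATP 2.52; it ships as the `anabolic_text` variant. We
default to the caption preset because it annotates the published result
rows.) For the ATP-yield scans ATP and ADP become free with a conserved
sum of 3.84 mM, closed by a lumped mass-action ATPase v = k·[ATP] — the
simplest law consistent with "a parameter scan over the ATPase rate
constant"; GAPN is absent from the scan models by default (the hypothesis
concerns the GAPDH + PGK route) and NADP/NADPH stay clamped, both
toggleable.

## Thermodynamics

Equilibrium constants come from the Briggs–Haldane relation
K_eq = (V_f Π K_m,products)/(V_r Π K_m,substrates); one excess substrate-side
K_m (the phosphate term) leaves a unit of M⁻¹. Then
ΔG°′ = −RT ln K_eq, and the *effective* standard Gibbs energy
ΔG°′′ = ΔG°′ + RT ln(1/Pi) (Pi in M) absorbs the fixed sub-molar phosphate;
ΔG°′′(Pi = 1 M) ≡ ΔG°′ and ΔG°′′ falls by RT ln 10 per decade of Pi.
Actual reaction energies use ΔG = ΔG°′′ + RT ln(Π products/Π substrates)
with steady-state concentrations. R = 8.314 J K⁻¹ mol⁻¹; T defaults to
343.15 K and 303.15 K (exact conversions of 70/30 °C) because those values
reproduce the published Gibbs-energy table, while the 347/307 K quoted in
the source text do not; T remains a parameter.

## Numerics

* **Steady states.** Stiff integration (LSODA, rtol 1e-10, atol 1e-14,
  BDF fallback) over doubling time windows, with a damped-Newton polish
  (moieties substituted out) attempted after each window; the first
  polished point whose free-species balance residual falls below
  1 × 10⁻⁹ mM/min (infinity norm) is accepted. The tolerance sits far
  below the ~10⁻⁶ mM turnover of BPG. Pure Newton from a 0 mM start
  diverges for this system. A residual that plateaus while Newton keeps
  failing is reported as "no steady state" — a real possibility here,
  since the archaeal chain runs close to its saturable enolase capacity.
  Warm starts (Newton first) are used along parameter scans. Monostability
  is checked, not assumed: ten seeded uniform-random initial vectors must
  agree to six significant digits or the spread is raised as an error.
* **Flux control coefficients.** C^J_E = (e/J)(ΔJ/Δe) by central finite
  difference on each step's activity (V_max; the rate constants for the
  BPG decay and ATPase steps, so the summation theorem can be checked on
  every topology), default ±1 %, warm-started re-solves. "3PG production
  flux" is operationalised as the mutase flux — at steady state 3PG
  production equals consumption and PGMA is its unique consumer in every
  variant. The estimate at ±1 % and ±0.5 % agrees to three digits.
* **ATPase scans.** At steady state k·[ATP] = J_PGK + J_PYK, so the scan
  is parameterised by [ATP]: clamping the adenylates reduces the problem
  to the well-conditioned metabolite subsystem and yields the unique k
  that closes the adenylate balance; 200 log-spaced k values across the
  ATP/ADP ∈ [1, 4] window are then solved by Brent root-finding on [ATP].
  This avoids the adenylate-starved corners of the free problem, which
  genuinely lack steady states at high BPG-decay rates. The summary
  statistic for each scan is the mean of J_ATPase/J_PYK over the window
  (with min/max reported); mid-window points agree with direct
  free-adenylate solves.

## Synthetic oracles

Reversible first-order chains with clamped ends have closed-form steady
states: J = (c₀ Π k_f − c_n Π k_r)/D with D = Σ_j Π_{l<j} k_r,l Π_{l>j}
k_f,l, interior concentrations from the tridiagonal balance system, and
scaled control coefficients exactly D_j/D (scaling k_f and k_r together,
as an enzyme-amount change would; for an irreversible chain this puts all
control on the entry step). These oracles validate the solver to eight and
the control analysis to three significant digits. Random perturbations of
the pathway models are multiplicative log-normal on every V_max and
Michaelis/inhibition constant — positive and scale-aware — with
equilibrium constants untouched, so thermodynamic zero-crossings are
preserved by construction. What the synthetic layer does *not* emulate:
enzyme-assay noise, channelling, crowding, or temperature dependence of
the constants; passing tests certify the numerics and the qualitative
robustness of the flux comparison, not in-vivo quantitative accuracy.

## Problem sizes and runtimes

Every steady-state solve is sub-second (4–7 free species). The shipped
analyses use 200-point scan windows, 100 perturbation draws at σ = 0.2
(seeded), and 10 multistart vectors; the full test suite runs in about
half a minute and `scripts/acceptance.py` in a few seconds.

## Known limitations

* With the printed GAPN V_max = 20 mM/min the glycolytic-condition GAPN
  flux is analytically fixed at 16.42 mM/min (GAP and NADP are clamped),
  vs the published 16.82; consequently the small GAPDH/PGK back-fluxes
  under that condition come out −0.18 instead of the published −0.23
  mM/min (they are hypersensitive to the 3PG level the GAPN flux sets).
  V_max = 20.5 — the same cell-extract scaling value as the archaeal
  enolase — would reproduce all three numbers almost exactly, suggesting a
  transcription slip in the published parameter table; we nevertheless
  keep the printed value and the corresponding two test expectations fail,
  by design.
* The published 70 °C Gibbs-energy column is an internally rounded ladder
  (steps of exactly 6.5 kJ/mol); computing exactly from the unrounded
  K_eq gives 4.81/11.38/17.95/24.52 kJ/mol, so the Pi = 1 mM entry
  (printed 24.4) cannot be matched to ±0.1 under any consistent (T, K_eq)
  choice. The corresponding test expectation is likewise left failing.
* Glucose-1-phosphate modulation of GAPN, the upper Entner–Doudoroff
  branch, and any growth-rate interpretation are outside the model.
* SBML export is one-way and structurally validated in-repo; it has not
  been round-tripped through an external SBML simulator.
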
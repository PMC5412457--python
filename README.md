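# thermoglyc

Kinetic and thermodynamic analysis of the lower glycolytic pathway —
glyceraldehyde 3-phosphate (GAP) to pyruvate — in the hyperthermophilic
archaeon *Sulfolobus solfataricus* (70 °C) compared with *Saccharomyces
cerevisiae* (30 °C).

Many (hyper)thermophilic archaea express GAPN, a non-phosphorylating GAP
dehydrogenase (GAP + NADP⁺ → 3PG + NADPH) that bypasses the canonical
GAPDH + PGK couple and gives up one substrate-level ATP per triose. This
package builds executable kinetic models of both organisms' pathways and
tests, in silico, three explanations for why the bypass exists:

1. **Thermodynamics** — at 70 °C the phosphorylating GAPDH reaction
   (GAP + NADP⁺ + Pi ⇌ BPG + NADPH, K_eq ≈ 0.185 M⁻¹) is so far uphill
   that GAPDH + PGK alone carry almost no flux;
2. **ATP yield** — spontaneous hydrolysis of the thermolabile intermediate
   1,3-bisphosphoglycerate (k_deg = 1.058 min⁻¹ at 70 °C) erodes the
   ATP-per-pyruvate ratio of the canonical route;
3. **Bidirectionality** — GAPDH + PGK are kept for gluconeogenesis, which
   the irreversible GAPN cannot serve.

The toolkit provides the ten rate laws and both organisms' parameter sets,
a stiff hybrid (integrate-then-Newton) steady-state solver with conserved
moieties, finite-difference metabolic control analysis
(C^J_E = (e/J)·dJ/de, summation theorem checked), Briggs–Haldane
equilibrium constants and effective standard Gibbs energies
(ΔG°′′ = −RT ln K_eq + RT ln(1/Pi)), scenario drivers for the three
hypothesis tests, synthetic linear-chain models with closed-form oracles,
YAML model configs, SBML Level 3 export and a `glyco` command line.

## Worked example

Steady state of the archaeal GAPDH+PGK-only pathway at 70 °C:

```python
>>> import thermoglyc as tg
>>> model = tg.build_model("sulfolobus", "base")
>>> steady = tg.find_steady_state(model)
>>> round(steady.fluxes["GAPDH"], 4)
0.1372
>>> float(f"{steady.concentrations['BPG']:.3g}")
6.75e-06
>>> control = tg.flux_control_coefficients(model)
>>> round(control["GAPDH"], 2), round(control.total(), 3)
(0.99, 1.0)
```

The pathway crawls at 0.137 mM/min with BPG pinned at 6.8 nM — three
orders below the PGK Michaelis constant — and GAPDH holds essentially all
flux control (C^J = 0.99): the canonical couple is thermodynamically
stalled. Adding the GAPN bypass (`variant="with_gapn"`) raises the GAP
depletion flux about 120-fold to ~16.4 mM/min, and boosting GAPDH 1000×
instead (`variant="gapdh_x1000"`) buys only 7.5 mM/min.

The ATP-yield scan (hypothesis 2) frees ATP/ADP against a lumped ATPase
and averages the ATP-production : pyruvate-production flux ratio over the
physiological ATP/ADP ∈ [1, 4] window:

```python
>>> scan = tg.run_atpase_scan("hyp2_boosted", k_deg=1.058)
>>> round(scan.mean_flux_ratio, 2)
1.99
>>> round(tg.run_atpase_scan("hyp2_boosted", k_deg=105.8).mean_flux_ratio, 2)
0.81
```

At the measured 70 °C decay constant the canonical route still yields
nearly 2 ATP per pyruvate; only a hundredfold faster BPG decay (a 90 °C
scenario) pushes the yield below the bypass's 1.

The same models run from the shell:

```bash
glyco hyp1 --out results/        # fluxes, BPG, control coefficients
glyco thermo --out results/      # equilibrium constants & Gibbs energies
glyco hyp2 --kdeg 105.8 --out results/
glyco hyp3 --condition anabolic --out results/
glyco export-sbml --variant with_gapn --out results/
```

Each run writes CSV/JSON plus a provenance record (config hash, seed,
package version).

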
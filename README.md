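# pnpaging

Quantitative analysis of the multistep inactivation of hexameric purine
nucleoside phosphorylase (PNP): multi-site equilibrium ligand-binding models
with an incompetent receptor fraction fitted globally to fluorescence
titrations and ITC isotherms, a runs-test/AIC model-discrimination ladder, a
weighted multiphase activity-decay model catalogue, and the total /
ligand-binding / catalytic concentration bookkeeping — plus seeded synthetic
generators so every stage runs without external data.

## The scientific problem

Hexameric bacterial PNP (a trimer of dimers) does not die in one step. As
purified *E. coli* PNP ages, its specific activity vs. inosine decays in
several distinct phases, and intermediates accumulate that still **bind**
ligands but no longer **catalyse** phosphorolysis of natural substrates.
Three quantitative signatures of this picture are modelled here:

1. **Binding heterogeneity.** Titrations of the enzyme (trimer
   concentration *P*) with ligand *L* are described by up to three
   nonequivalent independent site classes with macroscopic dissociation
   constants *K*<sub>d1..3</sub>. Free ligand follows the mass balance

   *L*<sub>tot</sub> = *L*<sub>free</sub> + *P*<sub>active</sub> Σᵢ
   *L*<sub>free</sub>/(*K*<sub>dᵢ</sub> + *L*<sub>free</sub>),

   with *P*<sub>active</sub> = *P*<sub>tot</sub>(1 − *f*<sub>inc</sub>),
   where the *incompetent fraction* *f*<sub>inc</sub> (a local, per-curve
   parameter) is the part of the protein not binding ligand at all.
   Fluorescence curves use the signal model *F* = *i*₀(1 + (1 −
   *f*<sub>inc</sub>) Σᵢ αᵢθᵢ); ITC isotherms use the perfusion-cell
   displacement model for the normalized differential heat per injection
   (NDH, kcal/mol injectant) with per-site enthalpies ΔHᵢ.

2. **Model discrimination.** Candidate models are fitted globally, simplest
   first; the Wald–Wolfowitz runs test on residual signs decides whether a
   richer model is warranted (α = 0.05, exact enumeration for < 20
   residuals), with the least-squares AIC/AICc recorded for every candidate
   and disagreements flagged.

3. **Multiphase decay.** Activity-vs-time series are fitted by inverse-
   variance-weighted least squares (w = 1/SD²) to a catalogue of decay
   shapes: linear, bi-exponential + offset, exponential + linear, and sums
   of one to three generalized-logistic (Richards) phases
   *A*(t) = *A*<sub>∞</sub> + (*A*₀ − *A*<sub>∞</sub>) Σ pₖ / (1 +
   10^((t<sub>k</sub> − t)h<sub>k</sub>)), reporting per-phase half-times.

4. **Fraction bookkeeping.** For each sample: total concentration from UV
   absorbance (ε¹% = 2.7 (mg/mL)⁻¹cm⁻¹, trimer MW 3 × 25 950 Da),
   ligand-binding = total × (1 − *f*<sub>inc</sub>), catalytic = total ×
   SA/117 U/mg. Binding exceeding catalytic is the quantitative signature
   of binding-competent, catalytically dead intermediates.

## Worked example

```python
import numpy as np
from pnpaging import (BindingSystem, ItcDesign, NoiseModel,
                      generate_itc_experiments, fit_itc_global)

# three-site system: Kd in µM, dH in kcal/mol
system = BindingSystem(kd=(16.52, 154.24, 79.67), dh=(-5.36, -0.13, -1.34))
designs = [ItcDesign(cell_conc0=c, syringe_conc=c * 60, experiment_id=f"e{c}")
           for c in (43.98, 144.87, 699.90)]           # µM trimer
exps = generate_itc_experiments(designs, system, NoiseModel(scale=0.0))
fit = fit_itc_global(exps, n_sites=3, seed=1)
print({k: round(v, 2) for k, v in fit.params.items() if k.startswith("kd")})
```

prints

```
{'kd1': 16.52, 'kd2': 79.67, 'kd3': 154.24}
```

— the three dissociation constants recovered from the simulated
three-concentration isotherm set (site classes are reported sorted by
ascending *K*<sub>d</sub>; `fit.params["dh1"]` etc. carry the matching
enthalpies, and `finc_0..2`/`offset_0..2` the per-experiment incompetent
fractions and dilution-heat baselines).

The numbered drivers under `analysis/` run the full pipeline on synthetic
data (simulate → ITC global fit → titration discrimination ladder → decay
model ranking → fraction table) and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_itc_global_fit.py
...
```

A thin `pnpaging` CLI exposes the same stages on CSV files
(`pnpaging simulate|fit-titration|fit-itc|fit-decay|select-model|fractions`).

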
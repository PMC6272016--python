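# stdepitope

Quantitative analysis of saturation transfer difference (STD) NMR for
protein–ligand complexes: build-up curve fitting, binding-epitope
mapping, relaxation-matrix ("CORCEMA-style") prediction of STD
intensities from a 3-D complex structure, and NOE R-factor scoring of
experiment against prediction.

It is written for NMR spectroscopists and structural modellers who
measure STD build-ups for a small-molecule ligand binding a protein
(e.g. dinucleotide coenzymes on a flavoenzyme) and want to (1) turn
per-proton intensities into an unbiased epitope map and (2) test a
candidate complex structure by back-calculating its STD response.

## The model

**Build-up and epitope.** The fractional STD of ligand proton *k* is
η<sub>STD</sub> = (I₀ − I<sub>sat</sub>)/I₀ × 100.  Its growth with
saturation time follows

    STD(t_sat) = STD_max · (1 − exp(−k_sat · t_sat))

and the relaxation/rebinding-free epitope descriptor is the initial
slope STD₀ = STD_max · k_sat.  The binding epitope is the set of STD₀
values normalized to 100 % at the largest one; protons with high
relative STD sit closest to the protein surface in the bound state.

**Prediction.** Given a protonated complex structure, two-site exchange
kinetics (K_d or k_on/k_off, total concentrations) and NMR parameters
(τ_c bound/free, spectrometer frequency), the engine builds the Solomon
dipolar relaxation matrix (σ, ρ ∝ r⁻⁶ through spectral densities
J(ω) = τ_c/(1+ω²τ_c²)), couples bound and free ligand magnetization
with population-balanced exchange, clamps the saturated protein protons
at zero z-magnetization, and propagates the system in closed form to
give S<sub>calc,k</sub>(t) = (I₀ₖ − Iₖ(t))·100/I₀ₖ.  Exchangeable
(N/O/S-bonded) hydrogens are excluded (D₂O conditions) and the protein
basis is truncated at a ligand-proton cutoff (default 8 Å).

**Scoring.** Experiment vs prediction is summarized by the NOE R-factor
r = √(Σ(STDᵉˣᵖ − STDᶜᵃˡᶜ)²/Σ(STDᵉˣᵖ)²): 0 is a perfect match, 1 the
score of an all-zero prediction.

## Worked example

```python
import numpy as np
from stdepitope import (DEFAULT_TSAT_GRID, ToySpec, make_toy_complex,
                        predict_for_structure, fit_buildup, epitope_map,
                        simulate_noisy_buildup, noe_r_factor)

# 1. fit a noisy build-up and map the epitope
fit = fit_buildup(simulate_noisy_buildup(50.0, 0.8, DEFAULT_TSAT_GRID,
                                         noise_sd=1.0, seed=3))
print(round(fit.std_max, 2), round(fit.k_sat, 3), round(fit.std0, 1))
# 49.02 0.813 39.9        (truth: 50, 0.8, 40)

emap = epitope_map({"A2": 30.0, "A8": 3.9})
print(emap.values)        # {'A2': 100.0, 'A8': 13.0}  reference proton A2

# 2. predict STD for a toy complex (3 ligand protons in a chain,
#    protein cluster next to the first one) and check the ranking
ps, model = make_toy_complex(ToySpec(n_ligand_protons=3,
                                     n_protein_protons=3, seed=1))
pred = predict_for_structure(ps, model, cutoff=50.0)
print(pred.values[2.0].round(3))
# LIG1    10.819
# LIG2     0.540
# LIG3     0.078   <- STD decays with distance from the saturated cluster
```

The fitted `(std_max, k_sat)` recover the generating parameters within
noise, the epitope map reproduces the 100/13 normalization convention,
and the predicted S_calc at 2 s decreases steeply with ligand-proton
distance from the saturation source, exactly the r⁻⁶-driven contrast
epitope mapping relies on.

Packaged experimental reference epitopes for six FNR–dinucleotide
complexes are available via `stdepitope.load_table("table1"|"table2"|"table3")`.

A CLI mirrors the library: `stdepitope protons|fit|predict|compare|simulate --help`.

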
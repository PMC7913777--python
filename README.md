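# assemblink

Thermodynamic and hydrodynamic analysis of linked protein assembly:
sedimentation-equilibrium modeling and global fitting, pH-linkage analysis of
self-association constants, reaction-coupled Lamm-equation simulation with a
c(s)-style distribution analysis, and ITC isotherm fitting — built around the
*E. coli* RecO/RecR recombination-mediator system.

## The scientific problem

RecR, the partner of the recombination mediator RecO, populates a
pH-dependent dimer–tetramer equilibrium

    2 R₂ ⇌ R₄,   L_obs = [R₄]/[R₂]²

whose constant drops by orders of magnitude between pH 6.4 and 9 because
tetramer formation takes up protons (Wyman linkage):

    L_obs(pH) = L₀ · P_tet / P_di²,   P_tet = 1 + (k_tet[H⁺])^m,
                                      P_di = (1 + k_di[H⁺])^n

RecO binds the tetramer in two steps (R₄ + O ⇌ R₄O, K₃; R₄O + O ⇌ R₄O₂, K₄),
and binding of the SSB C-terminal acidic-tip peptide (P15) to RecO switches
the cooperativity of those steps — an allosteric effect visible as a shift of
the sedimenting complex boundary. The package implements the complete
quantitative chain used to establish this picture:

* **`hydro`** — molar-mass/v̄ additivity, buoyant factors M(1 − v̄ρ), Svedberg
  diffusion coefficients, s₂₀,w corrections, glycerol-buffer properties;
* **`sedeq`** — equilibrium profile models (multi-species and
  dimer–tetramer), global multi-speed/multi-loading NLLS fitting, species
  fractions;
* **`linkage`** — binding polynomials, the L_obs(pH) model, proton-uptake
  slopes, NLLS fitting with upper-limit handling;
* **`svel`** — Scheme speciation, mass-action kinetics, a conservative
  finite-volume Lamm solver for the reacting system, a regularized c(s)
  analyzer and a transport-method weight-average-s oracle;
* **`itc`** — n-identical-site isotherms, displacement-corrected differential
  heats, (n, K, ΔH) fitting;
* **`synthgen`** — seeded generators reproducing the study designs, so every
  fitting stage has ground-truth inputs;
* **`io`/`cli`** — scan CSV / fixture YAML / result JSON formats
  (`docs/formats.md`) and the `assemblink` command-line tool.

## Worked example

Generate a synthetic sedimentation-equilibrium dataset at the pH 8 design
(4/8/12 µM RecR monomer at 20/25/30 krpm, 0.005 AU noise, ground truth
L_obs = 2.16×10⁵ M⁻¹), refit it globally, and fit the pH-linkage model to
the shipped L_obs(pH) table:

```bash
$ assemblink gen --fixture recr_ph8_se --seed 1 --out data
wrote SE dataset to data

$ assemblink fit-se data/*.csv --out fit
L_obs = 2.154e+05 M^-1

$ assemblink fit-linkage table1_50mM.csv --out linkfit
k_tet = 7.24e+09 M^-1, k_di = 3.51e+07 M^-1, slope(8-9) = -2.54
```

Reading the numbers: the global fit recovers the generating tetramerization
constant within 0.3 % (2.154 vs 2.16 ×10⁵ M⁻¹ — nine noisy scans carry that
much information). The linkage fit says protonation of three cooperative
tetramer sites (association constant k_tet ≈ 7.2×10⁹ M⁻¹, pK ≈ 9.9) against
two independent dimer sites per dimer (k_di ≈ 3.5×10⁷ M⁻¹, pK ≈ 7.5)
describes the pH dependence, and the mean slope of log₁₀L_obs between pH 8
and 9 of −2.54 means a net uptake of two to three protons accompanies
tetramer formation in that range.

The same library calls are available in Python:

```python
import numpy as np
from assemblink import (FixtureSpec, gen_se, fit_global, btp_buffer,
                        species_fractions)
from assemblink.synthgen import se_model_spec_for

scans, truth = gen_se(FixtureSpec(kind="SE", noise_sd=0.005, seed=1))
result = fit_global(scans, se_model_spec_for(), btp_buffer())
print(result.parameters["L_obs"])      # 215390.0...
print(species_fractions(2.16e5, 4e-6)) # (0.525, 0.475) at 8 uM monomer
```

For the velocity side, `simulate_lamm` + `fit_cs` reproduce the diagnostic
c(s) signature of the allosteric switch: with free-RecO constants the
RecOR complex peak sits near 2.5 S, and switching to the P15-bound constants
(K₃ = 2.5×10⁸, K₄ = 1×10⁷ M⁻¹) lowers the complex-boundary weight-average s
— the negative-cooperativity shift toward the 1:1 complex.

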
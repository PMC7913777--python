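# Methods

`assemblink` models the linked self-association and hetero-association
equilibria of the *E. coli* RecO/RecR recombination-mediator system as
measured by analytical ultracentrifugation (AUC) and isothermal titration
calorimetry (ITC). This note records the models, the numerical choices, and
the reasoning behind design decisions that were genuinely open.

## Sedimentation equilibrium

At equilibrium in a sector-shaped cell spinning at angular velocity ω, each
ideal species contributes an exponential in r²:

    A(r) = Σᵢ A₀ᵢ · exp[ Mᵢ(1 − v̄ᵢρ) ω²/(2RT) · (r² − r₀²) ] + b

with M in kg/mol, v̄ the partial specific volume (ml/g), ρ the solvent
density. For the dimer–tetramer self-association of RecR with
L_obs = [R₄]/[R₂]² the tetramer term is slaved to the dimer term: its
amplitude is L_obs·c₂₀² and its exponent exactly twice the dimer exponent.
Absorbance conversion gives the tetramer twice the dimer's extinction (same
chromophores per mole of dimer-equivalents).

Fitting choices:

* Reference radius r₀ defaults to each channel's meniscus, so amplitudes are
  the (physically interpretable) meniscus concentrations.
* The baseline is one floated constant per scan. No radial form is imposed.
* Thermodynamic parameters (floated molar masses, log₁₀ L_obs) are global
  across speeds and loadings; amplitudes and baselines are local per scan.
* Parameters spanning decades (L_obs, amplitudes, masses) are fitted as
  log₁₀ to enforce positivity without active constraints; trust-region least
  squares with analytic-free Jacobians; eight multistarts perturb log₁₀ L_obs
  uniformly over ±2 decades (seeded), lowest objective wins. Standard errors
  are asymptotic, from the Jacobian at the optimum with the delta method for
  log-fitted parameters.
* Scans are weighted uniformly.
* A mass-conservation mode penalizes unequal sector integrals
  ∫A·r dr across rotor speeds within a channel (weight configurable,
  off by default); the per-scan amplitudes otherwise absorb loading.

Species mass fractions for the dimer–tetramer system solve
2·L_obs·[R₂]² + [R₂] = R_tot (R_tot in dimer units) in closed form and are
reported as mass fractions f₂ = [R₂]/R_tot, f₄ = 2L_obs[R₂]²/R_tot, which sum
to one. (The number-fraction convention [R₄]/R_tot does not normalize when
R_tot is in dimer units; we use mass fractions throughout.)

## pH linkage

Tetramerization is linked to protonation. With binding polynomials
P = (1 + k[H⁺])^sites for identical independent sites and
P = 1 + (k[H⁺])^sites for fully cooperative sites,

    L_obs(pH) = L₀ · P_tet / P_di²,

and the pointwise slope ∂log₁₀L_obs/∂pH equals the net proton uptake Δn_H⁺ on
forming a tetramer from two dimers (analytic form: −m·θ_tet + 2n·θ_di with θ
the site occupancies). The default model is three cooperative tetramer sites
(m = 3) and two independent dimer sites per dimer (n = 2); all four
cooperativity variants and alternative site counts can be ranked by fit RMSD
(`rank_site_models`).

**Identifiability convention.** When every measured point lies on the
protonation-saturated side of the tetramer transition — true for the shipped
pH 6.4–8.5 table — the data constrain only the product L₀·k_tet^m (and k_di):
the three-parameter likelihood has an exactly flat ridge in (L₀, k_tet), and
the asymptotic SE of log₁₀ k_tet diverges. `fit_linkage_auto` detects this
(SE > 1 decade) and refits with the unprotonated reference constant pinned at
L₀ = 1 M⁻¹, making k_tet the reported, interpretable quantity. Under this
convention the shipped table yields k_tet ≈ 7.2×10⁹ M⁻¹ and
k_di ≈ 3.5×10⁷ M⁻¹ with finite standard errors; L₀ itself is then a
convention, not an estimate. Upper-limit rows (flagged in the input) are
excluded from the residuals; weighting by the tabulated standard errors is
available but off by default.

## Reacting-system sedimentation velocity

The reaction network couples four reversible steps:

    2 R₂ ⇌ R₄ (L_obs);  R₂+O ⇌ R₂O (K₂);  R₄+O ⇌ R₄O (K₃);  R₄O+O ⇌ R₄O₂ (K₄)

with forward rates K·k_off and reverse rates k_off (default 0.01 s⁻¹ each).
Step-wise constants are applied in mass action exactly as given; an optional
flag applies the 2×/½ site-statistics conversion for the two tetramer sites.
Default constants: L_obs = 2.16×10⁵ M⁻¹, K₂ = 10 M⁻¹ (the dimer–RecO complex
is unpopulated), and either K₃ = 5×10⁵ / K₄ = 4×10⁸ M⁻¹ (free RecO;
positively cooperative) or K₃ = 2.5×10⁸ / K₄ = 1×10⁷ M⁻¹ (RecO bound to the
SSB-Ct peptide; negatively cooperative).

Equilibrium speciation solves free-RecO root finding (Brent) nested with the
closed-form free-dimer quadratic; the system is monotone so the positive root
is unique, verified against a brute-force nested-bisection oracle to 1e-8.

The Lamm equation

    ∂cᵢ/∂t = (1/r) ∂/∂r[ r(Dᵢ ∂cᵢ/∂r − sᵢω²r²cᵢ) ] + fᵢ(c)

is solved on a conservative finite-volume radial grid (default 400 cells)
with zero-flux ends:

* **Transport**: Crank–Nicolson in time; first-order upwind advection and
  central diffusion in space. The cell Péclet number at the default grids is
  ≲ 0.2, so upwinding adds ≪ 10 % numerical diffusion while keeping
  diffusion-free fronts monotone. The discrete sector integral Σcᵢrᵢ·Δr is
  conserved to machine precision by construction (conservation diagnostics
  use this FV measure; trapezoidal quadrature over cell centers under-weights
  the boundary cell where material accumulates and is *not* conserved).
* **Reactions**: Strang splitting with a backward-Euler substep solved by a
  batched Newton iteration (analytic 6×6 Jacobian per cell, tolerance 1e-12
  of the largest concentration). Backward Euler preserves both linear
  conservation laws exactly and is robust for on-rates up to at least
  4×10⁹ M⁻¹s⁻¹ (the instantaneous-equilibrium limit is reached: raising all
  k_off from 10 to 100 s⁻¹ changes the weight-average s by < 0.1 %). If
  Newton stalls, the step is halved automatically, with a hard error at a
  1 ms floor.
* Species diffusion coefficients come from the Svedberg relation
  D = sRT/(M(1 − v̄ρ)) applied to each species' buffer s.

Default species (mass kDa / v̄ ml/g / s in buffer / ε₂₃₀ M⁻¹cm⁻¹): RecO
27.4/0.734/0.8/1.55×10⁵; R₂ 43.9/0.711/1.2; R₄ 87.8/0.711/1.7; R₂O
71.3/0.720/1.4; R₄O 115.2/0.716/1.9; R₄O₂ 142.6/0.720/2.5; RecR monomer ε₂₃₀
= 5.3×10⁴ scales with stoichiometry. Complex v̄ by mass-weighted additivity.

### Kinetic regime and the shape of c(s)

At k_off = 0.01 s⁻¹ every reaction relaxes in 25–100 s — fast relative to
boundary separation — so free dimer and tetramer co-sediment as one reaction
boundary (appearing at ≈1.5–1.6 S rather than as isolated 1.2 S and 1.7 S
peaks) next to the complex boundary at ≈2.5 S. Slower k_off moves the free-R
feature toward 1.2–1.4 S. The simulation is therefore *not* insensitive to
k_off in this solver; the shipped fixtures keep the 0.01 s⁻¹ default, and the
tests assert the resolved free-R feature within the 1.0–1.7 S dimer–tetramer
window plus the complex peak near 2.5 S.

### c(s)-style distribution

Scans are fitted as a nonnegative superposition of single-species Lamm
solutions on an s grid with second-difference Tikhonov smoothing (absolute
penalty weight, default λ = 0.1 AU — roughly the influence of the 0.005 AU
scan noise, chosen so the penalty does not bias peak positions) and D(s) from
a scalar frictional ratio via
f = (6πη·f/f₀)^{3/2}·(3v̄s/4π(1−v̄ρ))^{1/2}, D = k_BT/f. The fit range
excludes 0.1 cm at the base (back-diffusion/accumulation) and 0.01 cm at the
meniscus, following standard practice. Because the species table spans
Svedberg-equivalent f/f₀ 1.35–1.70, no single f/f₀ is exact for all species;
`optimize_fr` selects the scalar from a coarse grid by smallest residual
(the full nonlinear f/f₀ refinement and maximum-entropy regularization of
dedicated c(s) software are out of scope). Weight-average s over a range is
∫s·c(s)ds / ∫c(s)ds.

An independent, model-free weight-average s (`transport_sw`) comes from the
transport method: in a plateau, dQ/dt = −sω²r_p²c_p for
Q = ∫_m^{r_p} A·r dr, so s is obtained by regressing Q against the cumulative
plateau exposure −ω²r_p²∫c_p dt (exact under radial dilution, noise-averaged
across all scans, FV quadrature). The two routes agree within 2 % on
simulated data and serve as mutual cross-checks.

## ITC

Cumulative heat for ligand X binding n identical independent sites on M:

    Q = V₀·ΔH·M_tot·nKx/(1 + Kx),

with free x the stable root of the binding quadratic (verified against
bisection to 1e-12). Differential heats include the heat carried out of the
overflow cell: ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2. Cell concentrations
follow the standard displacement bookkeeping — per injection both solutes
dilute by (1 − dV/2V₀)/(1 + dV/2V₀) and the syringe delivers
X_syr·(dV/V₀)/(1 + dV/2V₀). Defaults: V₀ = 1.4 ml (VP-ITC class cell),
28 × 10 µl injections, 50 µM syringe into 2 µM cell. Fitting is NLLS over
(n, log₁₀K, ΔH) with the c-value K·M_tot·n reported and flagged outside
[1, 1000].

**Replicate protocol.** At the default design (c ≈ 24, 0.1 µcal injection
noise) the Cramér–Rao bound for a single titration is σ(K)/K ≈ 23 % — single
runs cannot beat that. The package's reporting protocol therefore averages
three replicate titrations generated with independent seeds, the standard
experimental practice; ΔH is determined far more precisely (≈ 2 %).

## Hydrodynamic conversions

Buoyant molar mass M(1 − v̄ρ); s₂₀,w correction
s·(η_b/η₂₀,w)·(1 − v̄ρ)₂₀,w/(1 − v̄ρ)_b with ρ₂₀,w = 0.99823 g/ml and η₂₀,w =
1.002 cP fixed in one constants table. Solvent density and viscosity of
glycerol–water buffers come from an embedded grid compiled from standard
published tables (0–50 % v/v, 15–40 °C) with bilinear interpolation; NaCl
adds a linear density increment (0.0414 g·ml⁻¹·M⁻¹) and its viscosity
contribution is neglected (≤ 200 mM). Out-of-range requests raise rather
than extrapolate. Note that buoyant masses computed with the mass-weighted
additive v̄ are exactly additive over components for *any* component v̄
values — additivity fails only for a non-mass-weighted (naive mean) v̄.

## Synthetic data

The generators emulate the study designs: equilibrium profiles at 4/8/12 µM
monomer loadings and 20/25/30 krpm in short (3 mm) channels with amplitudes
chosen so the sector-average concentration equals the loading at every speed
(conservation across speeds then holds by construction); velocity scans at
42,000 rpm between 6.14 and 7.2 cm (60 scans, 60 s apart by default); ITC
titrations per the heat model with a constant dilution blank (shipped blanks
are smoothed, i.e. noise-free). Gaussian noise (SD 0.005 AU for AUC,
0.1 µcal for ITC) is drawn from per-scan child seeds split from one fixture
seed, so extending a design never changes earlier scans' noise.

What the generators do **not** emulate: time-invariant and radially invariant
systematic noise, meniscus/bottom mislocation, finite optical resolution,
buffer-component gradients (e.g. the glycerol self-gradient), nonideality
(hydrodynamic or thermodynamic), and aggregation. Passing round-trip tests
therefore demonstrates correctness of the estimators under the stated noise
model, not robustness to real-instrument artifacts.

## Problem sizes

Tests run reduced designs chosen for CI practicality: 150–200 radial cells
and 15–30 scans for velocity simulations (400 cells for the analytic
transport check), 50–75-point s grids, 20-replicate recovery studies for the
equilibrium and ITC fits. The acceptance script uses the full shipped
equilibrium design (9 scans, ~900 points) and triplicate ITC titrations.

## Known limitations

* The c(s) implementation is a simplified regularized inversion; peak areas
  (not positions) depend on the scalar f/f₀ compromise, and closely spaced
  species (1.2 vs 1.7 S under 2.2 cP viscosity) merge.
* Kinetic rate constants are forward-simulation inputs, never fitted.
* The linkage L₀ is reported under the unit-reference convention when the
  data do not reach the high-pH plateau (see above).
* No treatment of a minor (<2 %) faster species seen at some pH values in
  real data, and no nonideality terms.
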
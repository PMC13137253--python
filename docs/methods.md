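# Methods

This note documents the models, conventions, numerical choices and known
limitations of `hydralk`. Units throughout: energy kJ/mol, length nm,
temperature K; k_B = 0.0083144621 kJ/(mol·K).

## Hydration decomposition and well-depth reparameterization

The working decomposition is ΔG_hyd = ΔG_cavity + ΔH_att. Cavity free
energies are consumed as inputs (they come from dedicated cavity
studies and are treated as temperature-independent over 290–350 K);
`hydralk` never computes them. The attraction enthalpy is identified
with the alkane–water Lennard–Jones interaction energy, which for a
small perturbation of the cross well depth ε is linear in ε (frozen
local solvent structure). Two fitting rules for the global scale
s are provided:

* `mean_ratio` (default): unweighted mean of the per-alkane ratios
  ΔH_att^exp/ΔH_att^model. This choice reproduces the packaged
  reference table's updated columns within 0.02 kJ/mol and the updated
  well depths within 0.0005 kJ/mol, and is therefore the default; the
  exact rule behind the published updated values is not stated anywhere,
  so this remains an inference.
* `weighted_ls`: the least-squares slope Σ(ΔH^exp·ΔH^model)/Σ(ΔH^model)²,
  which weights long alkanes more. Both rules land in [1.045, 1.065] on
  the packaged data.

Rows lacking a model value are carried through untouched — never imputed.
σ is deliberately not refit: the cavity term depends strongly on σ, and
changing it would invalidate the cavity inputs.

### Shipped parameters

TraPPE-UA: ε/k_B = 148, 98, 46 K and σ = 0.373, 0.375, 0.395 nm for CH4,
CH3, CH2. Water-oxygen LJ sites are shipped with their original-source
precision; note that SPC/E's ε must be taken as 0.1553 kcal/mol
(= 0.6497752 kJ/mol), not the commonly rounded 0.650 kJ/mol, for the
mixed CH4:O well depth to reproduce the reference value 0.8942 at four
decimals. The HH-alkane file carries pair well depths only; its σ values
("thermal radius" construction) are not available here and must be
user-supplied when a geometry is needed.

## FEP estimator

The per-window increment is the volume-weighted exponential average
(NPT form); with NVT samples the volume weights cancel exactly and the
estimator reduces to the Zwanzig average — this reduction is tested, as
is invariance under uniform volume rescaling. All exponential averages
go through log-sum-exp, so arbitrarily large gaps cannot overflow.
The printed NPT estimator is implemented exactly as given; no separate
P·ΔV work term is added.

Closed-form anchor: for Gaussian gaps dU ~ N(μ, s²) at constant volume
the increment is μ − s²/(2k_BT); the synthetic-gap generator
(`gaussian_gap_samples`) exists to pin this.

Uncertainties: per-window standard errors come from ten contiguous
block averages (absorbing serial correlation at the block scale) and are
summed in quadrature over windows. Replicate summaries use the sample
standard deviation (n−1) over independent seeds, mirroring the
three-replicate protocol; the λ=0→1 forward total is the hydration free
energy, and forward+reverse totals give the signed hysteresis.

## Toy Monte Carlo simulator

NVT Metropolis MC of one rigid all-trans united-atom chain (C–C bond
0.154 nm, backbone angle 114°, no torsional sampling) in a neutral LJ
solvent, with soft-core cross interactions (α = 0.5, n = 2) applied only
to solute–solvent pairs; solvent–solvent interactions are λ-independent.
An optional NPT mode (logarithmic volume moves, acceptance
exp(−β(ΔU + PΔV) + (N+1)ln V'/V)) exercises the volume-weighted
estimator. All randomness flows from a single seed through numpy
substreams; identical seeds give bit-identical output. Energy
bookkeeping is re-anchored at every window boundary and the accumulated
drift against full recomputation is reported (≤1e-8 kJ/mol in tests).
The inner sweep is numba-jitted when numba is importable; the pure-numpy
fallback consumes the same random draws in the same order.

### What the toy solvent emulates — and what it does not

The solvent is a charge-free LJ fluid: ε = 0.4 kJ/mol, σ = 0.34 nm,
ρ = 8 nm⁻³, T = 300 K (ρσ³ ≈ 0.31, ε/k_BT ≈ 0.16 — a weakly structured
dense gas whose g(r) is within ±0.1 of 1 beyond the first shell, the
regime the analytic corrections assume). The default cross pair is
CH4:O-like (ε = 0.9 kJ/mol, σ = 0.35 nm). Cutoffs are independently
configurable per interaction class; toy defaults are 0.9 nm
(solvent–solvent) and 1.0–1.2 nm (solute–solvent), scaled down from the
conventional 1.0/1.4 nm so that 200-particle boxes satisfy the
minimum-image requirement.

What passing the toy cross-validations shows: the estimator, sampling,
shift/tail corrections and their sign conventions are mutually
consistent on a system with the assumed statistical structure. What it
does not show: anything about real water — hydrogen bonding,
electrostatics, the temperature dependence of cavity formation, or
force-field accuracy. Those enter only through the packaged reference
table.

### Cross-validation triangle (study protocol)

Single LJ solute in 200 solvent particles; 40 windows (Δλ = 0.025);
per window 30 burn-in + 300 sampling sweeps; three independent
replicates forward and reverse; Widom insertion on a separate
pure-solvent run (400 sweeps, 5000 insertions/frame, identical truncated
Hamiltonian, no tail). Forward FEP, negated reverse FEP and Widom agree
within combined 3σ. The dilute-limit check uses an ideal solvent
(ε_ss = 0) at ρ = 0.5 nm⁻³ against the closed form
k_BT·ρ·∫(1−e^{−βu})4πr²dr (adaptive quadrature; exact to first order in
density). These problem sizes keep each experiment in the minutes range
on one CPU while leaving the 3σ bands a factor ≳2 above the observed
discrepancies.

## Shift and tail corrections

For a pair potential shifted by its cutoff value, every in-range
solute–solvent pair is offset by −u(r_c). Three routes to the mean
effect ⟨ΔE⟩ are implemented:

1. exact from an RDF: N ρ u(r_c) ∫₀^{r_c} w r² g(r) dr (trapezoid);
2. analytic step-g approximation:
   N ρ u(r_c) (w/3)[(r_c − σ)³ − (Ñ − 1)σ³], where Ñ counts chain
   united atoms within r_c of a reference atom (the excluded-volume
   term);
3. brute force: per-frame difference of shifted vs plain cross energies.

`w` is the prefactor convention: the default `half` (w = 2π, and
8πεσ³ in the tail term) follows the convention the correction formulas
are usually quoted with in this decomposition; `full` (w = 4π, 16πεσ³)
counts each solute–solvent pair once and is the convention under which
the brute-force route closes identically. The switch is global and
shared with `forcefield.tail_correction`; consistency tests run under
both, and the end-to-end experiments use `full`.

Sign conventions, fixed by first-order perturbation theory and verified
end to end on the toy system: ⟨ΔE⟩ is negative for an attractive u(r_c);
the shifted-potential coupling is less attractive, so the shifted-run
free energy sits above the truncated one by −⟨ΔE⟩, and the corrected
value is ΔG_corrected = ΔG_shifted + ⟨ΔE⟩ + ⟨E_tail⟩.

Two caveats, documented deliberately:

* The step-g bracket uses (r_c − σ)³ as printed in the source formula;
  the literal step-function integral would give (r_c³ − σ³)/... , so the
  approximation is reliable only for σ ≪ r_c (relative error ≈ 3σ/r_c).
  Tests exercise it in that regime; the exact-from-RDF route should be
  preferred whenever a g(r) is available.
* The geometric Ñ of an all-trans C20 chain at r_c = 1.4 nm is 15.5
  (per-site average), not the canonical 11 quoted for conformationally
  averaged chains; `count_within_cutoff` computes the geometric count
  and callers may override Ñ explicitly.

## Temperature dependence

ΔG_hyd(T) = ΔG(T₀) + (C^ex − S^ex(T₀))(T − T₀) − C^ex·T·ln(T/T₀).
For fixed T₀ this is linear in (ΔG(T₀), C^ex − S^ex, C^ex), so the fit
is plain linear least squares and recovers generated parameters to
machine precision. Over narrow temperature windows the −T ln(T/T₀)
regressor is nearly collinear with (T − T₀); a warning fires when the
design-matrix condition number exceeds 1e4 (a 60 K window sits near 100;
a 0.2 K window near 2e5). kT-unit conversion uses per-temperature
normalization, ΔG/(k_B T).

## Degenerate inputs and tie-breaks

Zero solvent particles give identically zero gaps and a zero FEP total.
λ = 0 contributes exactly zero cross energy (the λ^n prefactor), so
decoupled-state sampling is pure solvent. RDF self-pairs are excluded by
a 1e-12 distance threshold; r_max beyond half the box edge is rejected.
The λ-schedule constructor requires 1/Δλ integral to 1e-9 so windows
land exactly on λ = 1. Reference tables are checksum-pinned
(sha256) and fail hard on mismatch.

## Known limitations

* The toy solvent is not water; quantitative agreement with the
  reference ΔG_hyd values is out of reach by design and not claimed.
* Exponential-averaging (Zwanzig) estimation carries a finite-sample
  bias ~var/(2k_BT·n_eff) per window; BAR/MBAR would reduce it but are
  deliberately out of scope.
* NPT volume moves recompute the total energy (O(N²)) and are intended
  for small boxes only.
* The half/full prefactor ambiguity means absolute shift-correction
  magnitudes depend on the convention chosen; within-package consistency
  is guaranteed, cross-package comparisons must state the convention.
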
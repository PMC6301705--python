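# Methods

## The model

Oxidative dimerization of a 2-aminophenol-type monomer (2AP, L-3HOK, 3HAA,
or carboxylate-ionized 3HAAi) to a phenoxazinone (D10; xanthommatin beyond
D10 for L-3HOK) is a six-electron oxidation: three pairs of H-atom
abstractions interleaved with conjugation, tautomerization, cyclization and
protonation steps. The package encodes the process as 26 registered
half-reactions (a YAML registry, editable) over named species forms, and
treats every energy question as arithmetic over species Gibbs free energies:

* species free energy: `G = E_T + G_corr` — the single-point total energy
  (or total free energy in solution) plus the harmonic thermal correction,
  both supplied as inputs in kcal/mol (hartree accepted with the conversion
  627.509474);
* stage free energy: `ΔG = ΣG(products) − ΣG(reactants)`;
* pathway total: multiplicity-weighted stage sum;
* redox descriptors: adiabatic `IP = G₊ − G₀`, `EA = G₀ − G₋`,
  `χ = (IP+EA)/2`;
* O₂ coupling: oxidation-stage ΔG plus the matching O₂ reduction ΔG, with
  H-atom bookkeeping enforced (1 H* for HO₂•, 2 for H₂O₂, 6 for full
  reduction to water);
* kinetics: conventional TST with a Wigner tunneling factor (below).

Assumptions inherited from the input data: H-atom transfer is treated as a
single proton-coupled electron-transfer event; ions unstable in the gas
phase are optimized in water (a provenance flag on the record, not a
correction); D1/D6-type chirality is ignored (conjugation is not
stereospecific); all temperatures are 298.15 K.

## Conventions and parameters

| Parameter | Default | Why |
|---|---|---|
| T | 298.15 K | temperature of all thermal corrections and rates |
| R | 1.987204 cal·mol⁻¹·K⁻¹ | barriers held in kcal/mol (×1000 internally) |
| standard-state factor | 24.3 | converts a bimolecular rate from the 1 atm ideal-gas standard state to 1 M; the literature-printed value is kept (exact: 24.465, ~0.7% on k) |
| Wigner coefficient | 1.44 cm·K | printed value kept (exact hc/k_B = 1.43877; ≲0.2% on k) |
| G(H⁺) | −6.28 (gas), −272.18 (water) kcal/mol | literature proton free energies; **no heptane value exists** — protonation stages in heptane are only defined as summed pairs (N7+8, N13+14) where the proton cancels, and requesting one singly is an error, never a silent zero |
| BDG stage set | N1, N2, N5, N6, N11, N12, N16, N17, N19, N21, N22 (×4 compounds, n=44) | N24 excluded: the D6′→D10 collapse is a spin-forbidden biradical recombination, not an H abstraction |
| Hess tolerance | 1e-6 kcal/mol (species-derived), 0.01 (printed fixtures) | printed values carry 3 decimals |
| BSSE corrections | stored with the printed negative sign | applied once per stage: conjugation ΔG raised by \|c\| (dimerization less favorable), H-abstraction ΔG lowered (X–H BDG smaller); double application is an error |

The "±" on BDG summaries is a t-based 95% CI half-width
(`t₀.₉₇₅,₄₃·SD/√44`), verified bit-for-bit for the gas phase; the SD is
reported alongside because the source annotation is unlabeled.

The final xanthommatin stage (N26, L-3HOK only) is registered in both
printed product variants. ROS coupling uses the ammonium variant, encoded
as `D10 → XAN⁻ + NH₄⁺ + 2H*` — the only charge-conserving stoichiometry
compatible with a heptane value existing (no free proton in heptane) — and
only that variant reproduces the printed feasibility lists; the NH₃ variant
is available for stage arithmetic.

## Kinetics

`k(T) = I·(k_B T/h)·exp(−ΔG‡·1000/(R_cal·T))·f_std·A(T)` with
`A(T) = 1 + (1/24)(c·ν_i/T)²`, ν_i the magnitude of the imaginary frequency
in cm⁻¹ (stored positive). Forward rates use the reactant-side barrier
`ΔG‡_R = G_TS − G_R`, reverse rates `ΔG‡_P = G_TS − G_P`; detailed balance
`k_f/k_r = exp(−ΔG_{P−R}/RT)` is exact because all prefactors cancel.
Negative barriers are accepted (barrierless limit) with a logged warning.

**Reproduction limit.** Recomputing the reference rate table from its
*printed* barriers and frequencies agrees with the printed rates to at most
~0.7% relative (36 of 60 cells differ in the third significant digit): the
printed inputs are rounded to 3 decimals while the original rates were
evidently computed from unrounded energies. The reproduction tests
therefore assert 1% relative agreement — one unit in the third significant
digit — which is the attainable printed-precision limit, not a fitted
tolerance.

## ROS classification

For each phase, HO₂• feasibility scans all eleven single H-abstraction
stages; H₂O₂ feasibility scans the sterically motivated stage pairs
(N1+2, N5+6, N11+12, N19+22) plus N26; full reduction couples each
compound's complete pathway sum; superoxide feasibility is
`IP + ΔG(O₂→O₂•⁻) < 0` per species (strict, with a ±0.5 kcal/mol "marginal"
tag). Where the printed reference membership disagrees with its own
arithmetic — in the gas phase 3HAAi-D4 is listed as an O₂•⁻ donor at
ΔG = +6.475, and 3HAAi-D6 is exergonic (−1.471) yet unlisted — the
classifier reports both cells as discrepancies rather than suppressing
either source (a likely 4↔6 typesetting slip).

## Statistics

Pearson r and OLS come from scipy. The two-sided randomization test uses
\|Δmean\| as the default (pluggable) statistic: all C(n, n_a) label
assignments are enumerated when there are at most 20,000 (p is then exact
and never zero, since the observed assignment is counted), otherwise
seeded Monte-Carlo with the add-one correction. p is invariant under group
relabeling and under adding a constant to all values. Batch normalization
divides each value by its batch mean before merging, preserving
within-batch ratios.

## Synthetic data

The generator emulates the *summary output* of a quantum-thermochemistry
study under stated conditions: stage-ΔG targets drawn from the observed
ranges of the reference network (H abstraction 19–77 kcal/mol, conjugation
−5–58, tautomerization −17–7, cyclization 2–37, protonation split by phase),
barriers 5–40 kcal/mol, imaginary frequencies 1000–2500 cm⁻¹, and a
two-theory-level linear relation (slope 0.977, intercept −0.916, σ = 1
kcal/mol, n = 36) matching the reported level-II/level-III regression.
Species free energies are built *constructively* — monomer G sampled, every
derived species placed to meet its stage target — so Hess
route-independence, charge conservation and H* bookkeeping hold exactly by
design rather than by rejection sampling; any subset of stage targets can
be pinned to reference values for fixture/species cross-validation.

What the generator does **not** emulate: electronic-structure error
(functional/basis bias, solvation-model artifacts), conformational
multiplicity, or any structure–energy correlation. A green test on
synthetic data therefore establishes the correctness of the bookkeeping
and statistics, not the chemistry of any real compound.

## Numerical choices and degenerate inputs

Energies are float64 kcal/mol throughout; registry magnitudes (~3×10⁵)
leave ~1e-10 kcal/mol of cancellation noise, far below every tolerance
used. Ranking sorts are stable with species-id tie-breaks. Correlation and
regression reject constant series (undefined r / vertical line). BDG
summaries of fewer than two values report NaN spread statistics rather
than failing. Registry readers reject duplicate (species, phase, level)
keys, unknown phases, and non-numeric energies with row-level error
listings; decimal commas are normalized with a logged warning.

## Known limitations

* The package never computes `E_T`, `G_corr` or frequencies from molecular
  structure; the registry format is the boundary.
* The heptane BDG summary printed in the reference (51.032 ± 5.365) does
  not recompute from the printed stage cells (50.963 ± 5.381); gas and
  water reproduce exactly. The package reports the recomputed values.
* Metal-ion modulation of redox properties and enzyme mechanism are out of
  scope (no equations exist for them in the source data).
* Kinetic accessibility of electron transfer is not modeled; the
  superoxide classification is purely thermodynamic.
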
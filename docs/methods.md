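# Methods

This note documents the models implemented in `evbcat`, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.

## Two-state EVB model and free-energy profiles

The reactive step is represented by two diabatic states with per-frame
energies ε₁ (reactant force field) and ε₂ (product force field).  The
gas-phase origin shift α is applied **once**, additively, to the raw
product diabat before anything else (ε₂ = ε₂_raw + α); `WindowLog` stores
the shifted value, and validates on construction that the stored mapping
energy regenerates from (1−λ)ε₁ + λε₂ to 1e-6 kcal/mol.  The adiabatic
ground state is the lower eigenvalue of the 2×2 Hamiltonian,
E_g = ½(ε₁+ε₂) − ½√((ε₁−ε₂)² + 4H₁₂²), evaluated in closed form.

Defaults for the enzyme-scale constants are H₁₂ = 44.28 kcal/mol and
α = 103.94 kcal/mol at T = 300 K, with a uniform 51-window λ schedule
(Δλ = 0.02).  The gas constant is R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹.
Units are fixed repository-wide: kcal/mol, Å, K, elementary charge.

**FEP accumulation.** Window free energies use the forward Zwanzig
estimator between adjacent windows, ΔG = −RT ln⟨exp(−Δε/RT)⟩ with
Δε = ε_{m+1} − ε_m evaluated on window m's frames, accumulated from λ = 0
and stabilized with log-sum-exp.  A double-ended variant was considered
and not made default; for the harmonic test systems the forward estimator
is unbiased well within the reported SEMs, and the estimator choice is
invisible to the rest of the pipeline.

**Umbrella recombination.** The profile along X = ε₁ − ε₂ uses, per bin,

    ΔG(bin) = ΔG_m − RT · ln[ (1/N_m) Σ_{frames of window m in bin} exp(−(E_g − ε_m)/RT) ],

where window m is the window contributing the most frames to the bin
(ties broken toward lower λ) and N_m is that window's total frame count.
The 1/N_m normalization over *all* of the window's frames — not only those
in the bin — carries the bin-occupancy weight; with a bin-conditional
average instead, the recombined profile would not converge to the exact
adiabatic curve.  This estimator is checked directly against the grid
oracle (below).

**Binning and extraction.** Default 50 uniform bins over the observed X
range; bins whose dominant window contributes fewer than `min_count = 10`
frames are omitted, and the reported per-bin count is the dominant
window's.  The transition state is the global maximum among interior bins
that have a strictly lower value on both sides; the reactant minimum is
the lowest bin on the negative-X side of it, the product minimum the
lowest on the other side.  Profiles are shifted so the reactant minimum is
zero.  A monotone profile raises "no transition state" on explicit
extraction; `build_free_energy_profile` then reports the shape with
`barrier = None` so partially converged runs remain inspectable.  Binning
smooths the sharp crossing cusp of uncoupled (H₁₂ = 0) systems: at the
default bin width the symmetric toy barrier reads ~0.2 kcal/mol low, and
recovering the Marcus value to better than 0.1 kcal/mol needs ~200 bins.
Coupled systems are smooth at the crossing and unaffected.

**Replicas.** The per-replica barrier is extracted from each replica's own
profile and then averaged (mean, SEM = s/√n, flagged undefined for n = 1);
pooling frames across replicas before extraction is deliberately not done,
so the SEM reflects true replica-to-replica scatter.

## Eyring–Polanyi kinetics

k = (k_B T/h)·exp(−ΔG‡/RT) with k_B/h = 2.08366 × 10¹⁰ s⁻¹ K⁻¹ and a
transmission coefficient fixed at 1.  All conversions default to 300 K,
which maps the measured WT turnover of 67.4 min⁻¹ to 17.5 kcal/mol;
minute-based rates convert with an exact factor of 60.  Fold-changes use
the prefactor-free ratio form.  No tunnelling, variational, or isotope
corrections are applied.

## Charge-embedding ON/OFF decomposition

Snapshots hold a reacting moiety (positions, per-state charges) and an
environment of point charges grouped into residues.  An `EnergyBackend` is
any deterministic map (snapshot, active-charge subset) → energy whose
empty-subset value is the isolated-moiety energy; the quantum engines used
at production scale satisfy this contract.  The shipped `CoulombBackend`
surrogate evaluates a configured per-state internal constant, an optional
harmonic term in the moiety coordinates, and the bare Coulomb interaction
E = Σ C q_i q_j / r_ij with C = 332.0636 kcal·Å·mol⁻¹·e⁻², no cutoff and
no periodicity.  Coincident atom pairs raise an error naming the pair.

Barriers are differences of unweighted arithmetic means over snapshots
(ΔE‡ = ⟨E_TS⟩ − ⟨E_R⟩), computed with charges off and on;
ΔΔE‡_ON−OFF = ΔE‡_ON − ΔE‡_OFF is the catalytic effect, negative when the
environment stabilizes the transition state more than the reactants.  The
default ensemble size is 100 R + 100 TS snapshots.  No outlier pruning is
applied before averaging.  The combined SEM of the catalytic effect is the
quadrature sum of the four state-mean SEMs.

Because the surrogate is linear in the environment charges, the ON−OFF
difference of any snapshot is exactly the sum of single-residue terms.
This additivity is the module's key internal oracle (checked to 1e-8
relative); polarizable quantum engines break it, which is a physical
feature of those engines, not a bug of the decomposition algebra.

## Per-residue scan, classification, geometry

A residue's contribution is the decomposition restricted to its charges.
Classification threshold: |contribution| < 0.1 kcal/mol is negligible;
≤ −0.1 catalytic; ≥ +0.1 anticatalytic.  The scan planner reports the
single-point job count (residues × snapshots × variants, e.g.
512 × 200 × 4 = 409,600 at production scale) before executing.

Residue–moiety distances use unweighted centroids over *all* atoms
(hydrogens included, no mass weighting), the Euclidean distance per
snapshot, averaged over the combined R+TS ensemble by default (a per-state
option exists).  Differential profiles report per-residue
(variant − reference) changes in contribution and distance over the shared
residue set.  "Sequence domains" are reported as contiguous residue runs
with |Δcontribution| ≥ 0.25 kcal/mol — a stated convention of this
package, chosen at half the scale of the typical non-negligible
contribution, since no numeric rule exists for the shaded regions in the
original figures.

## Synthetic generators

**Toy diabats.** Two harmonic wells with a shared force constant k
(default 2 kcal/mol/Å², minima 4 Å apart, giving λ_reorg = ½kd² = 16
kcal/mol — a reorganization energy on the scale typical of enzymatic
charge-transfer steps).  Equal force constants make X linear in q, so the
exact profile is available by dense-grid evaluation of E_g
(`exact_profile_oracle`, default 4001 points padded 4σ beyond the minima)
and, for H₁₂ = 0, in the Marcus closed form (λ_reorg + ΔG₀)²/(4λ_reorg).
The pipeline's toy variants default to H₁₂ = 1.0 kcal/mol: the
enzyme-calibrated 44.28 kcal/mol exceeds this system's λ_reorg/2 and would
leave a single barrierless well, so the toy coupling is a property of the
toy diabats, configured alongside them.

**Window sampler.** Metropolis Monte Carlo on the 1D coordinate under ε_m:
each recorded frame is the endpoint of its own independent chain
(initialized uniformly within ±3σ of the window's minimum), so frames are
uncorrelated and SEM formulas apply directly.  Proposal steps are tuned
during burn-in (8 rounds of 25 steps) into a 30–60% acceptance band,
followed by 150 production steps per chain; zero acceptance raises an
error advising a step-size change.  Everything is reproducible from the
seed.

**Synthetic enzymes.** Six moiety atoms near the origin with distinct R
and TS charge sets (net charge conserved, distribution shifted — a
hydride-transfer-like polarization); residues of a few point charges each
on a 6–20 Å shell, carrying a net monopole of roughly ±1 e like charged
side chains.  With a planted catalytic effect, per-residue targets are
drawn (default 60% below the negligible threshold, the remainder ~3:1
catalytic:anticatalytic), corrected to sum exactly to the planted value,
rank-matched to the residues' base Coulomb couplings (so rescaling factors
stay moderate and close residues carry the large contributions), and each
residue's charges are scaled so its exact contribution at the mean
geometry equals its target.  The 60% negligible default is a desk-scale
choice: at ~20 residues, the >90% fraction observed for a real 500-residue
enzyme would leave only one or two active residues and no useful
classification statistics.  Mutations replace one residue's charge set and
displace every residue's mean position by isotropic Gaussian noise
(default 0.2 Å — the "subtle, delocalized" structural-response regime;
most real mutation-induced shifts stay below 0.5 Å).  Thermal snapshot
ensembles jitter every atom by 0.1 Å by default.  R and TS share the mean
geometry so the planted signal is purely electrostatic.

What the generators do **not** emulate: real enzyme geometry or residue
identity, force-field energetics, moiety polarization or charge transfer,
correlated (collective) thermal motion, and R/TS geometry differences.
Passing tests therefore validate the estimators, the decomposition
algebra, and the statistical machinery — not force fields or quantum
chemistry.

## Problem sizes and numerical details

The test suite and the acceptance script run the profile oracle check at
51 windows × 20,000 frames (mean absolute deviation from the grid oracle
is ~0.03 kcal/mol, asserted ≤ 0.15), the Gaussian FEP identity at 10⁶
samples with block-estimated standard errors, and planted-effect recovery
at 100 + 100 snapshots with 0.1 Å jitter; smaller unit tests use 21–51
windows × 500–8,000 frames.  Exponentials are guarded with log-sum-exp or
clipping at −700; float comparisons in file round-trips respect PDB column
precision (1e-3 Å).  Sub-seeds for independent random streams derive from
`numpy.random.SeedSequence` and stay below 2³¹.

## Limitations

- The Coulomb surrogate has no moiety polarization, charge transfer, or
  solvent screening; it is the analysis-layer stand-in that the backend
  contract lets a quantum engine replace.
- The dominant-window rule uses one window per bin rather than a
  multi-window (WHAM-like) combination; with 51 windows the overlap is
  ample and the oracle check bounds the resulting error.
- Barrier extraction assumes a single interior maximum flanked by two
  minima; multi-barrier profiles report only the global transition state.
- The negligible/catalytic classification is threshold-based and inherits
  the sampling noise of the per-residue contributions near ±0.1 kcal/mol.
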
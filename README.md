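# evbcat

Tools for quantifying how point mutations impair enzyme catalysis through
electrostatics, built around the workflow used to study monoamine oxidase A
(MAO-A) variants linked to Brunner syndrome (WT, C266F, V244I, E446K).  The
package covers four connected analyses:

1. **EVB free-energy profiles.** The rate-limiting hydride transfer is
   described by two diabatic states — reactant-like (ε₁) and product-like
   (ε₂, origin-shifted by a gas-phase calibration constant α) — coupled by a
   constant off-diagonal element H₁₂.  Sampling driven by the mapping
   potential ε_m = (1−λ)ε₁ + λε₂ over a schedule of λ windows is converted
   into a free-energy profile along the energy-gap coordinate X = ε₁ − ε₂
   by free-energy perturbation between adjacent windows plus umbrella
   reweighting onto the adiabatic ground state
   E_g = ½(ε₁+ε₂) − ½√((ε₁−ε₂)² + 4H₁₂²).  Barriers are averaged over
   replicas with their SEM.
2. **Eyring–Polanyi kinetics.** k = (k_B T/h)·exp(−ΔG‡/RT) converts
   barriers to rate constants; the WT/mutant fold-change
   k_WT/k_MUT = exp((ΔG‡_MUT − ΔG‡_WT)/RT) is prefactor-free.
3. **Enzyme ON/OFF barrier decomposition.** Reactant and transition-state
   snapshot ensembles are evaluated with the environment point charges
   active (ON) and removed (OFF); ΔΔE‡_ON−OFF = ΔE‡_ON − ΔE‡_OFF measures
   the catalytic effect of the enzyme's electrostatic preorganization.
   The energy engine is pluggable; a fixed-charge Coulomb surrogate ships
   with the package.
4. **Per-residue scans and geometry.** Repeating the decomposition with a
   single residue's charges classifies residues as catalytic,
   anticatalytic, or negligible (|contribution| < 0.1 kcal/mol), and
   centroid distance profiles plus WT-vs-mutant differentials localize the
   structural response to a mutation.

Synthetic generators (toy diabats with an exact grid/Marcus oracle,
point-charge enzymes with planted catalytic effects) make every stage
testable on a desk, without molecular-dynamics or quantum-chemistry runs.
Audience: computational enzymologists and method developers who want the
analysis layer of this workflow as a tested, scriptable library.

## Worked example

```python
from evbcat import (EVBParams, MappingSchedule, ToyDiabaticSystem,
                    build_free_energy_profile, rate_ratio)
from evbcat.embedding import CoulombBackend, decompose_barrier
from evbcat.synthetic_data import (exact_profile_oracle, generate_snapshots,
                                   make_synthetic_enzyme, sample_windows)

# Toy diabats: k = 2 kcal/mol/Å², minima 4 Å apart -> λ_reorg = 16 kcal/mol.
system = ToyDiabaticSystem(force_constant=2.0, q1=0.0, q2=4.0, dg0=0.0)
params = EVBParams(off_diagonal=1.0, gas_shift=0.0)
logs = sample_windows(system, MappingSchedule.uniform(51), params,
                      n_frames=5000, seed=1)
profile = build_free_energy_profile(logs, params)
oracle = exact_profile_oracle(system, params)
print(f"sampled barrier  {profile.barrier:.2f} kcal/mol")
print(f"oracle barrier   {oracle.barrier:.2f} kcal/mol")

# Synthetic enzyme with a planted -14.4 kcal/mol electrostatic effect.
enzyme = make_synthetic_enzyme(n_residues=20, planted_effect=-14.4, seed=1)
ens = (generate_snapshots(enzyme, "R", 100, 0.1, seed=2)
       + generate_snapshots(enzyme, "TS", 100, 0.1, seed=3))
backend = CoulombBackend(state_energies={"R": 0.0, "TS": 30.0})
dec = decompose_barrier(ens, backend)
print(f"catalytic effect {dec.catalytic_effect:.2f} "
      f"+/- {dec.sem_catalytic_effect:.2f} kcal/mol")
print(f"fold change for +3.4 kcal/mol: {rate_ratio(17.1, 20.5):.0f}")
```

prints

```
sampled barrier  3.01 kcal/mol
oracle barrier   3.06 kcal/mol
catalytic effect -15.03 +/- 0.52 kcal/mol
fold change for +3.4 kcal/mol: 300
```

The sampled barrier reproduces the exact grid evaluation of the adiabatic
surface (λ_reorg/4 − H₁₂ + H₁₂²/λ_reorg ≈ 3.06 kcal/mol) to within the
Monte Carlo noise; the ON/OFF decomposition recovers the planted
−14.4 kcal/mol effect within its ensemble SEM; and a 3.4 kcal/mol barrier
elevation — the V244I-scale change — corresponds to a ~300-fold slowdown
at 300 K.  The same conversions give 17.5 kcal/mol for the measured WT
turnover of 67.4 min⁻¹:

```bash
$ evbcat kinetics --rate 67.4/min
barrier = 17.4958 kcal/mol at 300.0 K
```

The `evbcat` command also exposes `synth`, `evb-profile`, `decompose`,
`residue-scan`, `distances` and `run` (the full pipeline driven by a YAML
configuration; see `docs/methods.md`).

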
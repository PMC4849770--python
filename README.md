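# pmhcdyn

Comparative analysis of conformational ensembles of peptide-presenting
immune complexes — peptide-MHC (p-HLA) binary complexes, their ternary
complexes with a T-cell receptor, and the free molecules — built for the
question: *why do complexes with near-identical structures trigger such
different T-cell responses?*  The package quantifies the dynamic
differences that crystal structures hide: per-residue flexibility, the
network of salt bridges and how it rewires between antigen variants, and
the conformational-entropy cost of receptor binding.

It operates on any conformational ensemble (multi-model PDB, or a binary
trajectory via MDAnalysis) and ships a synthetic-ensemble generator with
closed-form ground truth, so every stage is testable without running
molecular dynamics.

## What it computes

**Stability statistics.** Per-frame RMSD after Kabsch superposition, its
OLS drift (pm/ns), and the mass-weighted radius of gyration

    R_G = sqrt( Σᵢ mᵢ |rᵢ − r_CoM|² / Σᵢ mᵢ )

whose stability over time indicates the complex neither unfolds nor
dissociates.

**Fluctuation profiles.** Iteratively fitted average structures,
per-residue RMSF (mass-weighted over backbone or all atoms), difference
maps between species, per-residue RMSD maps, and paired/Welch t-tests on
whole profiles.

**Salt-bridge networks.** Ion pairs (sidechain carboxylate O vs sidechain
N of Asp/Glu vs Lys/Arg) detected with an 8 Å cutoff on the per-frame
minimum O–N distance, assembled into a weighted adjacency matrix of
time-averaged inverse distances,

    a_ij = (1/T) Σₜ 1 / d_ij(t)      [Å⁻¹],

counted as *formed* when the O–N distance stays below 3.2 Å in at least
half the frames.  Patterns from different species are compared through the
Frobenius inner product Tr(A·Bᵀ) and the normalized Frobenius distance
‖A/‖A‖_F − B/‖B‖_F‖_F — a proper metric on bridge patterns that ignores
overall interaction strength (0 for identical patterns, √2 for disjoint
ones).  Intermolecular submatrices isolate the presenter/peptide–receptor
interface.

**Quasi-harmonic entropy and the binding cycle.** The mass-weighted
covariance matrix C = ⟨Δq Δqᵀ⟩ (q = √m·r) is diagonalized; each retained
eigenvalue λ defines an oscillator ω = √(k_B T/λ) and the vibrational
entropy is the quantum harmonic-oscillator sum

    S = k_B Σᵢ [ xᵢ/(e^{xᵢ}−1) − ln(1−e^{−xᵢ}) ],   xᵢ = ħωᵢ/k_B T,

reported as −T·S (kJ/mol).  The thermodynamic cycle

    −TΔS_binding = (−TS)_ternary − (−TS)_free_receptor − (−TS)_binary

gives the entropic cost of receptor binding, compared across antigen
variants relative to a reference species.

## Worked example

`examples/` holds one short script per capability.  The end-to-end demo
(`examples/06_demo_pipeline.py`, or `pmhcdyn demo --out demo_out --seed 1`)
builds a paired synthetic comparison — a "reactive" species with three
extra scheduled salt bridges and a stiff binary complex, and a floppier
"non-reactive" species — and runs every stage:

```
counted bridges per species:
  reactive-ternary       10 formed / 35 candidates
  reactive-binary         5 formed / 22 candidates
  nonreactive-ternary     7 formed / 32 candidates
  nonreactive-binary      5 formed / 20 candidates
  free-receptor           0 formed /  4 candidates

normalized Frobenius distance, ternary complexes:
                     reactive-ternary  nonreactive-ternary
reactive-ternary                 0.00                 0.61
nonreactive-ternary              0.61                 0.00

entropic binding cycle (kJ/mol):
  nonreactive  -T dS_binding =    999.2, ddG_entropy vs reference = +339.3
  reactive     -T dS_binding =    659.9, ddG_entropy vs reference = +0.0
```

Reading the numbers: the reactive ternary complex keeps three more formed
salt bridges than the non-reactive one (10 vs 7); the two bridge patterns
sit at normalized Frobenius distance 0.61 (identical patterns would give
0, the diagonal); and because the non-reactive species fluctuates more
when free, it loses 339 kJ/mol more conformational entropy on receptor
binding — the entropic signature separating the two species.  The full
report bundle (summary table, RMSF profiles and t-tests, labeled bridge
matrices, distance traces, entropy table and cycle) is written as
deterministic CSV/JSON under `demo_out/report/`.

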
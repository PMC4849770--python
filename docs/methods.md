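# Methods

This note records the models, conventions and numerical choices behind
each analysis, what the synthetic generator does and does not emulate, and
the known limitations.

## Coordinate conventions and superposition

Coordinates are handled in Å throughout, masses in atomic mass units
(standard atomic weights assigned from the element), and atoms are indexed
0-based internally while residue identifiers from the source file are
preserved for reporting, so outputs use author numbering.  HETATM records
(solvent, ions) are skipped by default; alternate locations other than
blank or `A` are dropped for deterministic parsing.

Superposition is the unweighted Kabsch least-squares fit over a chosen
selection (default backbone: atoms named N, CA, C, O), restricted to
proper rotations.  Mass weighting of the fit is deliberately not used —
fits are geometric, matching the common default of trajectory-analysis
suites — while per-residue aggregation of fluctuations *is* mass-weighted
for consistency with the mass-weighted covariance used for entropy.  Fits
across a trajectory use a batched 3×3 SVD, so fitting 10⁴–10⁵ frames is
cheap.  Degenerate (collinear) fit selections are rejected; the inertia
tensor, by contrast, is well defined for collinear atom sets, so principal
frames accept them and only flag spherical degeneracy.

## RMSD series, average structures, RMSF

The RMSD series fits every frame to a reference over the fit selection and
measures over a possibly different selection.  Drift is the ordinary
least-squares slope of RMSD against time, converted from Å/ps to pm/ns
(1 Å/ps = 10⁵ pm/ns), reported with its standard error; a slope
indistinguishable from zero indicates a stationary ensemble.

The average structure is computed iteratively — fit all frames to the
current mean, re-average, repeat until the mean moves < 10⁻⁶ Å RMS
(at most 10 iterations) — because the mean depends on the alignment and
vice versa.  RMSF is the per-atom root-mean-square deviation about this
fitted mean; residue values are the mass-weighted mean over the residue's
backbone or all atoms.  Note that removing six rigid-body degrees of
freedom during fitting absorbs a small fraction (~6/3N) of the apparent
fluctuation; parameter-recovery tests therefore fit on a rigid scaffold
when they compare against the analytic expectation.

Profile comparisons default to a paired two-sided t-test across residues
(each residue contributes one difference); Welch's unpaired variant is
available by flag.  A zero-variance difference vector is reported as a
degenerate result (NaN p) rather than an error.

## Salt-bridge networks

A salt bridge is operationally a contact between a sidechain carboxylate
oxygen of Asp/Glu and a sidechain nitrogen of Lys/Arg.  Histidine and
chain-terminal amino/carboxylate groups are excluded from the default
catalog (none of the bridges this analysis targets involve them), but the
catalog is a plain mapping and can be extended.  The pair distance is the
per-frame *minimum* over all member-atom O–N combinations, which keeps the
definition symmetric across the Arg guanidinium nitrogens.

Two thresholds are deliberately separate: a generous 8 Å *detection*
cutoff (a pair is a candidate if its minimum distance ever reaches it)
that fixes the matrix support, and a strict 3.2 Å *contact* criterion with
a 50% occupancy threshold that counts bridges actually formed.  Matrix
entries are time-averaged inverse distances (Å⁻¹), proportional to the
mean Coulomb interaction strength of the pair; normalized weights divide
by 1/2.8 Å⁻¹ ≈ 0.357, the practical ceiling set by a permanent tight
contact, mapping weights to ≈[0, 1].

Pattern comparison: the Frobenius inner product Tr(A·Bᵀ) is exposed as
the primitive, but distances between species use unit-Frobenius-normalized
matrices, d(A,B) = ‖Â − B̂‖_F = √(2 − 2⟨Â,B̂⟩).  This is a proper metric
(zero self-distance, symmetry, triangle inequality — property-tested on
1000 random triples), is invariant to overall interaction strength and to
a common relabeling, and is bounded by √2.  Matrices over different bridge
sets are first re-indexed on the union of labels with zeros for absent
pairs.  A zero matrix is left unnormalized and two zero matrices are at
distance zero (flagged degenerate).

## Quasi-harmonic entropy and the binding cycle

The mass-weighted covariance C = ⟨Δq Δqᵀ⟩ with q = √m·r (units amu·Å²)
is accumulated after superposing frames onto the iteratively fitted
average structure (the fit is optional so that free-oscillator analyses
can retain rigid-body motion).  The sample (ddof = 1) estimator is used;
at the frame counts involved the distinction from 1/T is negligible.

Eigenvalues λ map to oscillator frequencies ω = √(k_B T/λ); unit chain:
λ[kg·m²] = λ[amu·Å²]·(1.66054×10⁻²⁷ kg)·(10⁻²⁰ m²), constants from CODATA
2018 via scipy.  The entropy is the quantum harmonic-oscillator sum
(per mole, via R = k_B·N_A), reported as −T·S in kJ/mol at a default
298 K.  High-frequency (stiff) modes contribute → 0 and are evaluated
overflow-safely; the 6 smallest eigenvalues are dropped by default
(quasi-null rigid-body modes of a superposed ensemble) along with any
λ < 10⁻⁸ amu·Å².  The estimator is additive over independent blocks and
strictly increasing under covariance scaling — both property-tested.

The binding cycle is pure arithmetic on −T·S values at a common
temperature: binding = ternary − free_receptor − binary, with ΔΔ values
relative to a reference species.  Absolute single-species entropies
depend strongly on sampling and mode retention and should only be
compared within a consistent protocol; the cycle and ΔΔ differences are
the meaningful quantities.

## Synthetic generator

The generator emulates the *statistics* the analyses assume, not
dynamics: no force field, no integrator, no solvent, and frames are
independent draws (no autocorrelation).  Three ingredients:

- **Harmonic fluctuations** — per-residue isotropic Gaussian displacement
  with amplitude σ about a fixed mean structure, giving analytic
  expectations RMSF = √3·σ and covariance eigenvalues m·σ² (three per
  fluctuating atom), hence a closed-form entropy oracle in the
  schedule-free regime.
- **Scheduled bridges** — a two-state (formed/broken) distance schedule
  per charged pair, realized by rigidly translating the basic group's
  member atoms along the mean inter-group axis.  The leading-block
  pattern realizes round(f·T)/T exactly; the Bernoulli pattern draws per
  frame.  Noise-free, the scheduled minimum O–N distance is exact as long
  as the controlling atom pair remains the closest (true for the shipped
  toy geometries, and verified by test); with noise the endpoints add
  ~√2·σ jitter.  Expected adjacency weight: f/d_formed + (1−f)/d_broken.
- **Toy complex topology** — three chains with presenter/peptide/receptor
  roles, schematic residue geometry (not stereochemically accurate), a
  seeded deterministic subset of residues made Asp/Lys/Glu/Arg with
  correctly named sidechain O/N atoms.

Random streams for atomic noise and schedule switching are split from one
seed, so changing one leaves the other unchanged.  Identical spec + seed
is bit-reproducible.

Passing the recovery tests on this generator demonstrates correctness of
the estimators under their stated assumptions; it does not demonstrate
robustness to features of real trajectories the generator omits —
autocorrelated frames, anharmonic and multi-basin motion, correlated
inter-residue fluctuations, or conformational exchange coupled to bridge
formation.

## Pipeline and problem sizes

The end-to-end comparison writes all outputs at fixed precision
(%.6g CSV, sorted-key JSON) so repeated runs are byte-identical; inputs
are checksummed into a manifest.  Output is staged and renamed only on
success, so a failed stage leaves no partial bundle.  The shipped demo
uses 240-frame ensembles of a ~130-atom complex and completes in seconds.

Test-suite problem sizes were chosen as the smallest at which the
statistical tolerances are comfortably met: entropy convergence at
T = 50000 frames of a ~110-atom system (sampling error ≈ 0.1%), RMSF
recovery at T = 10000 over 50 seeds of a 45-atom system, occupancy and
adjacency recovery at T = 5000 with σ = 0.1 Å, and 1000-replicate null
calibration of the profile t-test.

## Known limitations

- Single-chain PDB conventions only (no mmCIF, no insertion codes); chain
  identifiers are single characters.
- The entropy estimator assumes the quasi-harmonic picture; it
  overestimates entropy for multi-basin landscapes and ignores
  supralinear mode coupling.
- The t-test treats residues as independent observations; spatial
  correlation along the chain makes the effective sample size smaller
  than the residue count, so p-values on real structures are
  anti-conservative.
- Bridge detection is purely geometric; no hydrogen-bond geometry,
  π-cation interactions, or electrostatic screening.
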
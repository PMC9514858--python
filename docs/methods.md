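# Methods

## The synthetic ensemble model

Real binding-site ensembles of single-domain antibodies come from
microsecond enhanced-sampling MD. This package replaces them with the
simplest generative model that reproduces their analysis-relevant
structure — metastable interconversion between a small number of loop
conformations:

- **Hidden chain.** A discrete-time Markov chain over `n` macrostates with
  a row-stochastic transition matrix `T`. Scenario matrices are built as
  Metropolis kernels with uniform proposals targeting a prescribed
  stationary vector π, so detailed balance (`πᵢTᵢⱼ = πⱼTⱼᵢ`) and the exact
  stationary masses hold by construction. The first state of every
  trajectory is a stationary draw, so no burn-in handling is needed
  downstream.
- **Emissions.** Given the state, each backbone torsion is drawn
  independently from a von Mises distribution (circular mean per state and
  dihedral, concentration κ). Defaults: 5 paratope residues (tagged CDR1,
  HV2, CDR3), φ and ψ each (10 dihedrals), per-state means spaced 360°/n
  apart on every dihedral, κ = 20 (angular spread ≈ 13°), i.e. well
  separated, clearly metastable basins.
- **Time scale.** One frame nominally spans 0.1 ns; lags quoted in ns map
  onto frames through this declared convention (it is a convention of the
  generator, not a measured quantity). The Metropolis kernel is globally
  rescaled so the slowest implied timescale is 100 frames (10 ns nominal):
  comparable to the tICA lag, below the MSM lag, and fast enough that a
  5 × 10⁵-frame trajectory samples the stationary vector to a few tenths
  of a percentage point. Slower kinetics would be just as realistic but
  would leave the stationary masses statistically unrecoverable at this
  trajectory length; the choice is part of the study conditions and is not
  tuned per run.
- **Humanization scenario.** Parent and variant share all emission
  geometry and differ only in π: the binding-competent state (index 0)
  holds 0.92 of the mass in the parent and 0.16 in the variant, the
  remainder spread evenly (defaults; both configurable). 5 × 10⁵ frames
  per system.

What the generator does **not** emulate: continuous-time dynamics,
within-state diffusive relaxation (emissions are conditionally i.i.d., so
all intra-basin correlation vanishes after one frame), correlated
dihedrals within a state, solvent or energetics, and any coupling between
loop geometry and kinetics. Passing tests therefore demonstrate that the
analysis machinery recovers known ensemble structure; they do not validate
force fields or sampling of real antibodies.

### Toy structures

`build_toy_peptide` places N, CA, C, O (and CB for non-Gly) by sequential
internal-to-Cartesian (NeRF) construction with ideal geometry (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω = 180°); recomputing φ/ψ from the
coordinates returns the inputs to < 0.5°. For typed-contact fixtures, one
labeled functional atom per charged/polar residue (e.g. LYS NZ, GLU OE1)
is extended along the CA→CB axis at a residue-specific distance. These are
caricatures adequate for geometric rule testing, not stereochemically
complete side chains.

## Analysis stages and parameter choices

| Stage | Parameter | Default | Why |
| --- | --- | --- | --- |
| featurize | feature map | (sin θ, cos θ) per dihedral, unit weights | periodicity-respecting standard dihedral features; ψ-only mode mirrors the collective-variable convention for loop sampling |
| tICA | lag | 10 ns (100 frames) | the slow-coordinate lag of the protocol |
| tICA | estimator | symmetrized (reversible) | equilibrium surfaces presuppose reversibility; a non-reversible option exists |
| tICA | ridge ε | 1e-8 · tr(C₀)/dim | regularizes the collinearity inherent in sin/cos pairs; reported on the model |
| FES | grid | 100 × 100 bins, 5% margin, histogram | bin count is a display choice; KDE smoothing deliberately omitted (a smoothed surface hides sampling gaps); empty bins are NaN, never 0 |
| MSM | microstates | k-means, k = 100, k-means++ seeding, fixed seed | standard discretization of the protocol |
| MSM | lag | 15 ns (150 frames) | the protocol's MSM lag |
| MSM | estimator | reversible MLE (fixed point on symmetric edge weights, tol 1e-10) | detailed balance exactly; symmetrized-count fallback for tiny data |
| MSM | connectivity | largest strongly connected count-graph component | probabilities are only defined on a communicating set; the fraction of states kept is reported |
| PCCA+ | m | largest relative spectral gap (override available) | the protocol does not fix m; the gap criterion picks the number of resolved metastable sets, and degenerate spectra trigger a warning |
| CK test | factors | 1–5, trajectory-chunk bootstrap (50 resamples) for SEs | pass/fail at 3 SE |
| entropy | bandwidth | solve-the-equation plug-in (Sheather–Jones family, binned fixed-point form), Silverman fallback, 0.5° floor | plug-in selection with a robust fallback; the bandwidth used is reported per dihedral |
| entropy | convention | degree measure, nats | uniform angle → ln 360 ≈ 5.886, a memorable, testable bound; radians differ by −ln(180/π); optional scaling by R |
| contacts | salt bridge | opposite formal charges ≤ 4.0 Å | heavy-atom rules in the spirit of standard contact tools; all cutoffs configurable |
| contacts | hydrogen bond | donor–acceptor heavy atoms ≤ 3.5 Å, donor-antecedent angle ≥ 110° | heavy-atom proxy since toy ensembles carry no hydrogens |
| contacts | vdW | distance ≤ r₁ + r₂ + 0.5 Å | fallback type; types disjointly prioritized salt bridge > H-bond > vdW |
| contacts | counting | residue-pair events per frame (atom-level toggle) | matches residue-level frequency tables; per-frame histograms use bin width 2 |
| fingerprint | cutoff | 0.5 retention, average linkage on frequency vectors | pairs below cutoff in all systems dropped; deterministic scipy leaf order |
| surface | SASA | Shrake–Rupley, golden-spiral lattice, 960 points, probe 1.4 Å | deterministic lattice for bit-reproducibility |
| surface | scale | Wimley–White interface (octanol shipped) | both published tables ship as data; the choice is recorded in the output |
| surface | surface flag | relative SASA ≥ 0.2 of Gly-X-Gly maxima | common exposure convention |
| clustering | ensemble RMSD cut | average linkage, 1.3 Å | the trajectory-clustering criterion of the protocol; metric is superposed (Kabsch) RMSD |

## Numerical choices and degenerate inputs

- **Torsions:** φ(i) from C(i−1), N(i), CA(i), C(i); ψ(i) from N(i),
  CA(i), C(i), N(i+1); terminal residues yield only the definable angle;
  missing atoms or collinear geometry yield an *absent* (NaN-flagged)
  dihedral, never zero.
- **Kabsch:** SVD with determinant sign correction, so the rotation is
  always proper; < 3 atoms is an error.
- **Periodic KDE:** the sample is binned at 0.1° resolution and circularly
  convolved with a wrapped Gaussian (FFT), which is exactly the ±360°
  replication construction; entropy by composite Simpson on the 3601-point
  closed grid after renormalization. Bandwidth selection centers the
  sample at its circular mean first, making the result invariant under
  circular shifts to ~1e-15. Zero-variance samples get the 0.5° floor and
  a flag; < 50 samples flag the estimate unreliable.
- **PCCA+:** memberships from the first m right eigenvectors (computed via
  the π-symmetrized matrix, so the spectrum is real) and the inner-simplex
  vertex search; after the simplex transform, small negative entries are
  clipped and rows renormalized; crisp states by argmax with ties to the
  lower index.
- **SASA lattice noise:** with 960 points the per-residue SASA varies by
  up to ~1% under rigid rotation (and converges under lattice refinement:
  960 → 3840 points changes values < 2%, 2000 → 4000 < 1%). Analyses that
  need tighter rotation invariance should raise `n_sphere_points`.
- **MFPT:** linear solve of `m = 1 + T m` with m = 0 on the target;
  unreachable targets report ∞. Reported per macrostate pair in lag units
  and nominal ns.
- **Implied timescales:** negative eigenvalues are flagged and enter by
  magnitude; degenerate unit eigenvalues report ∞.

## Design choices where the design was open

- The MSM features use φ and ψ (the "backbone torsions" convention); ψ-only
  embedding is available for emulating the scalar collective variable.
- Macrostate identity across systems (for the parent-vs-variant
  comparison) is established by clustering the *pooled* tICA projections,
  so both systems share microstate definitions, and matching macrostates
  through their stationary-weighted microstate overlap. Against generator
  data, macrostates are mapped to ground-truth states by majority overlap
  of frames.
- Ensemble-clustering atom selection defaults to all atoms of the supplied
  models; a mask argument restricts to e.g. paratope backbone atoms.
  Region numbering is taken as author-supplied sequential labels and never
  renumbered.
- Error estimation: the CK test uses a trajectory-chunk bootstrap; state
  probabilities carry no analytic error bars — re-running with different
  seeds is the supported way to gauge sampling spread.

## Problem sizes

The shipped study conditions are 5 × 10⁵ frames per system (five
macrostates, 10 dihedrals). The full pipeline on one such system — tICA,
100-microstate k-means, reversible MSM, PCCA+ — takes ~20–30 s on one CPU;
the analysis drivers and the acceptance script each finish in well under
five minutes. Test fixtures use 2 × 10⁴–2 × 10⁵ frames, chosen so each
test's tolerance comfortably exceeds its sampling noise.

## Known limitations

- The generator's i.i.d. within-state emissions make every non-stationary
  eigenvalue of the *microstate* dynamics inside a basin vanish at lag 1;
  real trajectories have intra-basin relaxation that can mix with slow
  interstate modes.
- Typed contact rules are heavy-atom geometric proxies; they approximate,
  but do not reproduce, hydrogen-placement-aware tools. π-stacking,
  cation-π and water-mediated contacts are out of scope.
- Sequence accounting treats region ranges as alignment-free author
  numbering of the first sequence; for insertions/deletions a global
  alignment is applied and gap columns count as differences, with the
  denominator reported so any convention mismatch is visible.
- No mmCIF input; multi-model PDB and plain torsion tables are the two
  ensemble formats.
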
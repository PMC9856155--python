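# Methods

## The analysis model

### Combined PCA

Given trajectories of several homologous systems of equal construct length,
the preprocessing chain is: reduce to Cα atoms → split multi-chain
(dimeric) trajectories into single-subunit trajectories → concatenate all
subunit trajectories into one (frames tagged with their source system) →
iteratively align every frame to the running ensemble mean by rigid-body
least squares. The combined PCA then diagonalises the population covariance
of the aligned Cα coordinates. Because a *single* eigenbasis is estimated
from the pooled ensemble, per-system projection statistics are directly
comparable; this is what distinguishes combined PCA from fitting one PCA
per system.

Assumptions worth stating: all systems must map residue-for-residue onto a
common atom set (the identity map is the default; a two-column TSV supplies
anything else); subunits of a homodimer are treated as exchangeable samples
of the same conformational ensemble; and alignment uses uniform weights on
all Cα atoms (no mass weighting, no core selection — a selection mask can
be supplied).

Interpretation rules implemented as code contracts: the mean of the
projections of the full combined trajectory on any PC is zero by
construction; differences in per-system *average projection* indicate
different average structures along that PC; differences in per-system
*r.m.s.f. in projection* indicate different dynamics. The r.m.s.f. is the
standard deviation of the projection about the **system's own mean**, not
the RMS about the global zero. This choice keeps the two diagnostics
independent: a pure mean shift leaves the r.m.s.f. untouched and vice
versa. (The RMS-about-zero alternative would mix the two.)

### Numerical choices

* Covariance uses 1/F (population) normalisation, so each eigenvalue equals
  the variance of its projection series exactly — an identity the tests
  assert at 1e-8 relative.
* The decomposition is computed by thin SVD of the centred F × 3N
  coordinate matrix rather than assembling the 3N × 3N covariance; a dense
  covariance eigendecomposition serves as the independent test oracle. Thin
  SVD returns min(F, 3N) eigenpairs; trailing zero-variance pairs of the
  dense spectrum are not materialised.
* Eigenvector signs are arbitrary; each is oriented so its
  largest-magnitude component is positive. Ties in eigenvalue order are
  broken stably (sorted by descending λ with a stable sort).
* Alignment reference: the iteratively updated ensemble mean (not frame 1,
  not a crystal structure), tolerance 1e-4 Å mean-shift RMSD, max 20
  iterations; non-convergence is logged and the best iterate returned.
  Degenerate (collinear) point sets raise; the reflection branch of the
  Kabsch SVD solution is always corrected to det(R) = +1.
* Pseudo-trajectory span defaults to the observed projection range of the
  combined trajectory (the sampled extent of the motion); a symmetric
  ±k·√λ span is available. A zero-variance PC has no observed span and
  raises rather than emitting a degenerate trajectory.

### Titration model

The combined CSP is `√((Δδ_H W_H)² + (Δδ_N W_N)²)` with W_H = 1 and
W_N = 0.154 (the conventional scaling of nitrogen shifts to the proton
dispersion). Binder selection uses a *strict* threshold (CSP > cutoff, so a
residue exactly at the cutoff is excluded), evaluated at a ligand point
that must lie on the titration grid.

The binding model is the exact one-site isotherm with ligand depletion —
appropriate because protein concentration (0.4–0.7 mM in the motivating
experiments) is comparable to millimolar K_D values, where the hyperbolic
approximation `L/(L+K_D)` is biased. The weak-binding check in the test
suite quantifies this: for K_D ≥ 20·P the two forms agree within 1% of the
saturation amplitude (pointwise relative error at L → 0 is bounded by P/K_D
instead, which is why the comparison is made on the amplitude scale).

The global fit shares one K_D across binders with one Δ₀ per binder,
minimised by Levenberg–Marquardt on raw (unnormalised) CSPs; normalising by
Δ₀ is done only for display, where points are averaged over binders with
one-standard-deviation error bars. Without an initial guess the fit
multi-starts from seven log-spaced K_D values between 0.01 and 100 mM and
keeps the lowest-cost solution; with mM-scale data this surface is benign
and all starts typically coincide. Uncertainties: asymptotic standard
errors from the Jacobian covariance, plus an optional seeded residual
bootstrap — two estimators because reported "±" values in the literature
rarely state their provenance. Protein concentration is fixed input, never
fitted.

## The synthetic-data generator

The generator exists because studies of this type typically deposit neither
trajectories nor titration tables; every quantitative claim the pipeline
makes is therefore validated by recovering planted ground truth.

**Scaffold.** A self-avoiding random walk with 3.8 Å Cα–Cα steps confined
to a sphere of radius 4.5·N^(1/3) Å (collapsed-polymer scaling — realistic
compactness without real structures). A dimer is two identical chains
related by a rigid translation.

**Modes.** Planted mode vectors are defined on **one subunit**: random
superpositions of the five lowest sinusoidal frequencies along the residue
index (so displacement varies smoothly along the backbone, like genuine
collective motions), with the six rigid-body modes projected out before QR
orthonormalisation. Rigid-free modes are essential: alignment removes
rigid-body components from every frame, so a planted mode with a rigid
component would be partially destroyed by the pipeline's own preprocessing
and ground-truth recovery would not be well defined. For multi-chain
structures the same mode pattern acts on every chain with independent
per-chain amplitude draws — each subunit samples the same collective
motions independently, which is exactly the exchangeability the
subunit-splitting analysis assumes, and it makes the planted (μ_k, a_k)
the literal truth for the subunit-level combined PCA. For single-chain
structures the generator reduces to the plain form
`x_t = x_ref + Σ_k (μ_k + a_k z_tk) v_k + ε_t`.

**Default study conditions** (the `codyn run` demonstration and the
acceptance script): 4 systems × 2 chains × 1000 frames × 100 residues per
chain; 3 modes with amplitudes (3, 2, 1) Å; isotropic coordinate noise
0.2 Å; mean shifts ±2 Å on mode 1 splitting the systems two-and-two; one
system with a doubled mode-2 amplitude. These sizes exercise every branch
in seconds while keeping Monte-Carlo error well inside the recovery
tolerances (e.g. the standard error of a mean projection at a = 3 Å,
F = 2000 frames is 3/√2000 ≈ 0.07 Å against a 0.2 Å recovery band).

**Titrations.** Ligand grid 0, 0.25, 0.5, 1, 2, 4, 8 mM; protein 0.5 mM;
per-residue Δ₀ uniform in a configurable range with optional "silent"
(Δ₀ = 0) residues; a per-residue split angle θ ∈ [0, π/2] distributes the
combined CSP between the ¹H and ¹⁵N dimensions (component-wise shifts are
rarely reported, so a uniform angle is the least-informative choice), with
the identity that the noise-free combined CSP reproduces the isotherm at
machine precision. Gaussian noise is added per shift dimension, never at
L = 0 (the reference spectrum has zero shift by definition). Distance
fixtures are normal draws truncated at zero.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no anharmonicity or multi-basin kinetics (frames
are i.i.d., so no autocorrelation and no convergence questions), no
solvent or periodic-boundary artefacts, no sequence divergence between
homologues (systems share one scaffold), no peak overlap, exchange
broadening or assignment errors in the titrations, and Gaussian noise
only. The tests establish that the *analysis* is correct and
well-conditioned at realistic scales, not that 0.5 μs of sampling suffices
for any particular protein.

## Known limitations

* Multi-model PDB is the only trajectory format (binary formats raise with
  a pointer to external conversion); PDB coordinate precision is 1e-3 Å,
  which bounds round-trip fidelity.
* Residue correspondence across homologues must be length-preserving after
  mapping; insertions/deletions require the user-supplied map.
* The titration module fits a single binding site; multi-site or
  exchange-regime line-shape models are out of scope.
* `system_stats` reports PCs 1-based (as figures do) while the library API
  indexes PCs 0-based.
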
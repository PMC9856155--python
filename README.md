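# codyn

Comparative conformational dynamics of homologous proteins: **combined
principal component analysis** of multi-system Cα trajectories, plus **NMR
chemical-shift-perturbation (CSP) titration analysis** with a global
one-site K_D fit.

## Who this is for

Structural biologists and molecular modellers who want to ask, for a family
of homologous constructs (e.g. mesophilic/thermophilic enzyme domains and
their chimeras): *do these systems differ in their average structures, or
in their collective dynamics, along shared collective coordinates — and do
those differences track ligand-binding affinity measured by NMR titration?*

## What it computes

**Combined PCA.** Each system's trajectory is reduced to Cα atoms, split
into single-subunit trajectories, concatenated across systems into one
trajectory with per-frame provenance tags, and aligned by iterative
rigid-body least-squares (Kabsch) superposition onto the ensemble mean.
Diagonalising the population covariance `C = (1/F) Σ_t (x_t − x̄)(x_t − x̄)ᵀ`
of the combined coordinates yields one common eigenbasis `{λ_i, v_i}` for
all systems. Two per-system diagnostics follow from the projection series
`p_t = (x_t − x̄)·v_i`:

* **average projection** ⟨p⟩ per system — differences mean different
  *average structures* along that PC;
* **r.m.s.f. in projection** (sd of `p` about the system's own mean) —
  differences mean different *dynamics* within that collective motion.

Eigenvector pseudo-trajectories (frames `x̄ + s·v_i` over the observed
projection range, with start/end structures and per-residue mode r.m.s.f.
`√λ_i · |v_i,residue|` written into the PDB B-factor column) visualise each
mode. A contact module tracks interatomic distance series and left-closed
right-open histograms, pooled frame-weighted over systems.

**Titration.** Per-residue amide shift changes are combined as
`CSP = √((Δδ_H·W_H)² + (Δδ_N·W_N)²)` with `W_H = 1, W_N = 0.154`. Residues
with CSP strictly above a cutoff (default 0.05 ppm at 2 mM ligand) are fit
simultaneously with the ligand-depletion one-site isotherm

    CSP(L) = Δ₀ · [P + L + K_D − √((P + L + K_D)² − 4PL)] / (2P)

sharing one K_D across residues with one saturation amplitude Δ₀ per
residue (nonlinear least squares, multi-start over a log-spaced K_D grid,
Jacobian standard errors, optional residual bootstrap).

**Synthetic ground truth.** Because this kind of study rarely deposits raw
trajectories or titration tables, the package ships a generator that plants
known collective modes (smooth, orthonormal, rigid-body-free) with
per-system mean shifts and amplitudes into toy Cα scaffolds, and titration
tables with known K_D — so the entire pipeline is validated by
ground-truth recovery, not by eyeballing.

## Worked example

```bash
codyn run --seed 1 --out runs/demo
```

generates four systems (2 chains × 100 residues × 1000 frames each) with
three planted modes of amplitudes (3, 2, 1) Å and 0.2 Å coordinate noise —
systems A/B shifted +2 Å and C/D −2 Å along mode 1, system D with a
doubled mode-2 amplitude — plus a synthetic titration (K_D = 0.6 mM,
10 binders, 5 silent residues, 0.005 ppm noise), then runs the full
analysis. The manifest reports:

```
"n_subunit_trajectories": 8,
"n_combined_frames": 8000,
"kd_mM": 0.5931142237706438,
"kd_stderr_mM": 0.01174660041214387,
"n_binders": 10,
"kd_true_mM": 0.6
```

and `runs/demo/projection_stats.tsv` begins:

```
system  pc  avg_proj_A  rmsf_A    n_frames
sysA    1   2.055009    2.949930  2000
sysA    2   0.034663    2.041105  2000
sysA    3   0.018603    1.063975  2000
sysA    4   -0.007590   0.232093  2000
```

Reading this the way a comparative-dynamics study would: on PC 1 systems
A/B sit near +2 Å and C/D near −2 Å (different average structures along
that mode, matching the planted ±2 Å), every system has r.m.s.f. ≈ 3 Å
there (same dynamics); on the PC matching planted mode 2, system D's
r.m.s.f. is about twice everyone else's (a collective motion present in D
but quenched in the others); PCs beyond the planted three collapse to the
0.2 Å noise floor. The fitted K_D of 0.59 ± 0.01 mM recovers the planted
0.6 mM from the 10 binder residues.

Subcommands `simulate`, `preprocess`, `pca`, `contacts`, `titrate` and
`report` expose the stages individually; `--config` takes a YAML run
configuration (see `codyn.pipeline`).

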
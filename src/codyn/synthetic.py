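"""Synthetic trajectories and titrations with planted ground truth.

No experimental trajectories or titration tables accompany the analysis
this package implements, so every downstream stage is validated against
synthetic data whose answer is known by construction:

* **Trajectories** — a compact self-avoiding C-alpha scaffold (two
  identical chains, mimicking a homodimer) is perturbed along a small set
  of smooth, orthonormal collective modes.  Each system gets its own mean
  displacement mu_k and fluctuation amplitude a_k per mode, plus isotropic
  coordinate noise:

      x_t = x_ref + sum_k (mu_k + a_k z_tk) v_k + eps_t,   z, eps ~ N(0, 1)

  so the combined-PCA pipeline must recover the planted subspace, the
  per-system average projections (mu_k) and r.m.s.f. (a_k).
* **Titrations** — per-residue shift tables following the one-site
  ligand-depletion isotherm with a known K_D and per-residue saturation
  amplitudes, split between the 1H and 15N dimensions by a per-residue
  angle so that the noise-free combined CSP reproduces the isotherm
  exactly.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .titration import DEFAULT_WEIGHTS, CSPWeights, TitrationSet, isotherm_csp
from .trajectory import Trajectory

__all__ = [
    "ToyStructure",
    "ModeSet",
    "TitrationGroundTruth",
    "make_toy_structure",
    "make_mode_set",
    "simulate_system_trajectory",
    "make_titration_truth",
    "simulate_titration_set",
    "simulate_distance_series",
    "DEFAULT_LIGAND_GRID_MM",
]

# default titration schedule (mM)
DEFAULT_LIGAND_GRID_MM = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0])

_STEP = 3.8  # Calpha-Calpha virtual bond, Angstrom
_MIN_NONBONDED = 3.0  # self-avoidance cutoff, Angstrom


@dataclass
class ToyStructure:
    """C-alpha-only scaffold: atom table plus one coordinate set (Angstrom)."""

    atoms: pd.DataFrame  # chain_id, resid, name, element
    coords: np.ndarray  # (N, 3)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def flat(self) -> np.ndarray:
        return self.coords.reshape(-1)


@dataclass
class ModeSet:
    """Orthonormal planted collective modes with per-system parameters.

    ``vectors`` has orthonormal columns of dimension 3N, where N is the
    atom count of one subunit (chain).  For a multi-chain structure the
    same mode pattern acts on every chain, each chain drawing its own
    amplitudes — the subunits of the homodimer sample the same collective
    motions independently, which is exactly what a subunit-split combined
    analysis assumes.  ``system_params`` maps a system tag to (mu, a):
    per-mode mean displacement and fluctuation amplitude in Angstrom.
    ``sigma_noise`` is the isotropic per-coordinate noise sd in Angstrom.
    """

    vectors: np.ndarray  # (3N, K), N = atoms per chain
    sigma_noise: float = 0.0
    system_params: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    def with_system(self, tag: str, mu, a) -> "ModeSet":
        """Register planted (mu_k, a_k) for one system; returns self."""
        mu = np.asarray(mu, dtype=float)
        a = np.asarray(a, dtype=float)
        if mu.shape != (self.n_modes,) or a.shape != (self.n_modes,):
            raise ValueError(f"mu and a must have {self.n_modes} entries")
        self.system_params[tag] = (mu, a)
        return self


@dataclass
class TitrationGroundTruth:
    """Planted parameters of a synthetic titration.

    ``theta`` assigns each residue's combined CSP to the 1H/15N dimensions:
    ddH = CSP cos(theta)/W_H, ddN = CSP sin(theta)/W_N.
    """

    kd: float  # mM
    d0: np.ndarray  # (R,) ppm, saturation CSP per residue
    theta: np.ndarray  # (R,) rad, in [0, pi/2]
    protein: float  # mM
    ligand: np.ndarray  # (L,) mM, strictly increasing from >= 0
    noise_sd: float  # ppm
    residues: np.ndarray = None  # (R,) ids; defaults to 1..R

    def __post_init__(self):
        self.d0 = np.asarray(self.d0, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.ligand = np.asarray(self.ligand, dtype=float)
        if self.kd <= 0:
            raise ValueError("K_D must be positive")
        if self.protein <= 0:
            raise ValueError("protein concentration must be positive")
        if np.any(self.d0 < 0):
            raise ValueError("saturation CSPs must be non-negative")
        if np.any(self.ligand < 0) or np.any(np.diff(self.ligand) <= 0):
            raise ValueError("ligand grid must be non-negative, strictly increasing")
        if self.residues is None:
            self.residues = np.arange(1, self.d0.size + 1)


def _grow_chain(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding 3.8 A-step walk confined to a compact sphere."""
    # radius cap scales like a collapsed polymer, Rg ~ N^(1/3)
    r_cap = 4.5 * n ** (1.0 / 3.0)
    while True:  # restart on dead ends (rare at this density)
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            for _attempt in range(200):
                step = rng.normal(size=3)
                step *= _STEP / np.linalg.norm(step)
                cand = pts[-1] + step
                # soft inward bias once outside the cap
                if np.linalg.norm(cand) > r_cap:
                    continue
                d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1) if len(pts) > 1 else np.array([np.inf])
                if d.min() >= _MIN_NONBONDED:
                    pts.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            arr = np.asarray(pts)
            return arr - arr.mean(axis=0)


def make_toy_structure(
    n_residues_per_chain: int, n_chains: int, seed: int
) -> ToyStructure:
    """Compact self-avoiding C-alpha scaffold; identical chains, translated.

    Chains are labelled A, B, ... and related by a rigid x-translation wide
    enough to avoid inter-chain clashes.  Deterministic per seed.
    """
    if n_residues_per_chain < 4 or n_chains < 1:
        raise ValueError(
            "need n_residues_per_chain >= 4 and n_chains >= 1 "
            f"(got {n_residues_per_chain}, {n_chains})"
        )
    rng = np.random.default_rng(seed)
    chain = _grow_chain(n_residues_per_chain, rng)
    extent = chain[:, 0].max() - chain[:, 0].min()
    offset = extent + 10.0
    coords = []
    records = []
    for c in range(n_chains):
        cid = chr(ord("A") + c)
        shifted = chain + np.array([c * offset, 0.0, 0.0])
        coords.append(shifted)
        for i in range(n_residues_per_chain):
            records.append((cid, i + 1, "CA", "C"))
    atoms = pd.DataFrame(records, columns=["chain_id", "resid", "name", "element"])
    return ToyStructure(atoms=atoms, coords=np.concatenate(coords, axis=0))


def _rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes at ``coords``."""
    n = coords.shape[0]
    centred = coords - coords.mean(axis=0)
    basis = []
    for ax in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        basis.append(v.ravel())
    for ax in range(3):  # infinitesimal rotations about the centroid
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, centred).ravel())
    q, _ = np.linalg.qr(np.column_stack(basis))
    return q


def _chain_indices(structure: ToyStructure) -> list[np.ndarray]:
    chains = structure.atoms["chain_id"].to_numpy()
    idx = [np.flatnonzero(chains == cid) for cid in pd.unique(chains)]
    if len({i.size for i in idx}) != 1:
        raise ValueError("all chains must have the same atom count")
    return idx


def make_mode_set(
    structure: ToyStructure,
    n_modes: int,
    seed: int,
    sigma_noise: float = 0.0,
) -> ModeSet:
    """Random smooth orthonormal mode vectors over one subunit.

    Each mode is a superposition of low-frequency sinusoids along the
    residue index (so displacements vary slowly along the backbone, like
    genuine collective motions, not white noise).  The 6 rigid-body modes
    of the subunit are projected out before orthonormalisation so the
    planted motion is purely internal and survives rigid-body alignment.
    """
    idx = _chain_indices(structure)
    n_atoms = idx[0].size
    n3 = 3 * n_atoms
    if n_modes < 1 or n_modes > n3 - 6:
        raise ValueError(
            f"n_modes must be in [1, {n3 - 6}] for {n_atoms} atoms per chain "
            f"(got {n_modes})"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n_atoms) / max(n_atoms - 1, 1)
    raw = np.zeros((n3, n_modes))
    for k in range(n_modes):
        disp = np.zeros((n_atoms, 3))
        for ax in range(3):
            coeff = rng.normal(size=5)
            phase = rng.uniform(0, 2 * np.pi, size=5)
            freqs = np.arange(1, 6)
            disp[:, ax] = sum(
                c * np.sin(np.pi * f * t + p)
                for c, f, p in zip(coeff, freqs, phase)
            )
        raw[:, k] = disp.ravel()
    rigid = _rigid_body_basis(structure.coords[idx[0]])
    raw -= rigid @ (rigid.T @ raw)
    q, r = np.linalg.qr(raw)
    # sign-fix for determinism across BLAS implementations
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    vectors = q * signs
    return ModeSet(vectors=vectors, sigma_noise=sigma_noise)


def simulate_system_trajectory(
    structure: ToyStructure,
    modes: ModeSet,
    system_tag: str,
    n_frames: int,
    seed: int,
) -> Trajectory:
    """Generate one system's trajectory from the planted modes.

    For each chain c, frame t is

        x_ref,c + sum_k (mu_k + a_k z_tck) v_k + eps_tc

    with z standard normal per frame, chain and mode and eps isotropic
    with sd sigma_noise per coordinate: every subunit samples the same
    planted collective motions with its own draws.  Frames carry
    ``system_tag``; the output is deterministic per seed.
    """
    if system_tag not in modes.system_params:
        raise ConfigError(
            f"no planted (mu, a) parameters registered for system {system_tag!r}"
        )
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    idx = _chain_indices(structure)
    if 3 * idx[0].size != modes.vectors.shape[0]:
        raise ConfigError(
            f"mode dimension {modes.vectors.shape[0]} does not match "
            f"{idx[0].size} atoms per chain"
        )
    mu, a = modes.system_params[system_tag]
    rng = np.random.default_rng(seed)
    coords = np.repeat(structure.coords[None, :, :], n_frames, axis=0)
    for chain_idx in idx:
        z = rng.standard_normal((n_frames, modes.n_modes))
        amplitudes = mu[None, :] + a[None, :] * z  # (F, K)
        disp = (amplitudes @ modes.vectors.T).reshape(n_frames, chain_idx.size, 3)
        coords[:, chain_idx, :] += disp
    if modes.sigma_noise > 0:
        coords = coords + rng.normal(scale=modes.sigma_noise, size=coords.shape)
    return Trajectory(
        atoms=structure.atoms.copy(),
        coords=coords,
        system=np.full(n_frames, system_tag, dtype=object),
    )


def make_titration_truth(
    n_residues: int,
    kd: float,
    seed: int,
    protein: float = 0.5,
    d0_range: tuple = (0.1, 0.5),
    n_silent: int = 0,
    ligand=None,
    noise_sd: float = 0.0,
) -> TitrationGroundTruth:
    """Draw a ground truth: d0 uniform in ``d0_range`` for binders, zero for
    ``n_silent`` non-binders appended after them; theta uniform in [0, pi/2]."""
    rng = np.random.default_rng(seed)
    d0 = np.concatenate(
        [rng.uniform(*d0_range, size=n_residues), np.zeros(n_silent)]
    )
    theta = rng.uniform(0.0, np.pi / 2.0, size=d0.size)
    grid = DEFAULT_LIGAND_GRID_MM if ligand is None else np.asarray(ligand, float)
    return TitrationGroundTruth(
        kd=kd, d0=d0, theta=theta, protein=protein, ligand=grid, noise_sd=noise_sd
    )


def simulate_titration_set(
    truth: TitrationGroundTruth,
    seed: int,
    weights: CSPWeights = DEFAULT_WEIGHTS,
) -> TitrationSet:
    """Emit per-residue shift tables whose noise-free combined CSP equals
    the planted isotherm exactly.

    The planted combined CSP c is split as ddH = c cos(theta)/W_H and
    ddN = c sin(theta)/W_N, then Gaussian noise of sd ``truth.noise_sd`` is
    added to each shift dimension independently (never at L = 0, which is
    the reference spectrum and has zero shift by definition).
    """
    rng = np.random.default_rng(seed)
    c = isotherm_csp(
        truth.protein, truth.ligand[None, :], truth.kd, truth.d0[:, None]
    )
    ddh = c * np.cos(truth.theta)[:, None] / weights.w_h
    ddn = c * np.sin(truth.theta)[:, None] / weights.w_n
    if truth.noise_sd > 0:
        nonzero = truth.ligand > 0
        ddh[:, nonzero] += rng.normal(scale=truth.noise_sd, size=ddh[:, nonzero].shape)
        ddn[:, nonzero] += rng.normal(scale=truth.noise_sd, size=ddn[:, nonzero].shape)
    return TitrationSet(
        protein=truth.protein,
        ligand=truth.ligand.copy(),
        residues=truth.residues.copy(),
        ddh=ddh,
        ddn=ddn,
    )


def simulate_distance_series(
    mean: float, sd: float, n_frames: int, seed: int, system: str = ""
):
    """I.i.d. normal distance draws truncated at zero; deterministic per seed."""
    from .contacts import DistanceSeries

    if mean <= 0:
        raise ValueError("mean distance must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    if sd == 0:
        values = np.full(n_frames, float(mean))
    else:
        from scipy.stats import truncnorm

        a = (0.0 - mean) / sd
        values = truncnorm.rvs(
            a, np.inf, loc=mean, scale=sd, size=n_frames, random_state=rng
        )
    return DistanceSeries(
        values=values, system=np.full(n_frames, system, dtype=object)
    )


def write_ground_truth_sidecar(truth: TitrationGroundTruth, path) -> None:
    """Plain-text key-value sidecar for test harnesses."""
    with open(path, "w") as fh:
        fh.write(f"kd_mM\t{truth.kd!r}\n")
        fh.write(f"protein_mM\t{truth.protein!r}\n")
        fh.write(f"noise_sd_ppm\t{truth.noise_sd!r}\n")
        fh.write("ligand_mM\t" + ",".join(repr(x) for x in truth.ligand) + "\n")
        for r, d0, th in zip(truth.residues, truth.d0, truth.theta):
            fh.write(f"residue\t{r}\t{d0!r}\t{th!r}\n")
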
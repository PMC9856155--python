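"""Combined principal component analysis of concatenated trajectories.

A *combined* PCA diagonalises the C-alpha coordinate covariance of one
trajectory built by concatenating the aligned trajectories of several
homologous systems.  All systems are thereby projected onto a single common
eigenbasis, which makes two per-system diagnostics directly comparable:

* the **average projection** on a PC — systems that differ here have
  different average structures along that collective coordinate;
* the **r.m.s.f. in projection** — the fluctuation of the projection about
  the system's own mean; systems that differ here have different dynamics
  within that collective motion, e.g. a breathing mode present in one
  complex but quenched in another.

The module also builds eigenvector pseudo-trajectories (frames interpolated
along one PC about the mean, with designated start and end structures) and
residue-resolved mode r.m.s.f. values for colour-gradient rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentStateError, DegenerateSpanError
from .trajectory import Trajectory

__all__ = [
    "CombinedPCAModel",
    "ProjectionSeries",
    "PseudoTrajectory",
    "fit_pca",
    "project",
    "system_stats",
    "pseudo_trajectory",
    "residue_rmsf_in_mode",
]


def _orient(vectors: np.ndarray) -> np.ndarray:
    """Fix eigenvector signs: largest-magnitude component made positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


@dataclass
class CombinedPCAModel:
    """Eigendecomposition of the combined C-alpha coordinate covariance.

    ``eigenvectors`` holds orthonormal columns of dimension 3N; eigenvalues
    are in Angstrom^2, descending, from the population (1/F) covariance.
    ``proj_min``/``proj_max`` record the observed projection range of the
    training trajectory per PC (the default pseudo-trajectory span).
    """

    mean: np.ndarray  # (3N,)
    eigenvalues: np.ndarray  # (K,), descending
    eigenvectors: np.ndarray  # (3N, K)
    total_variance: float
    frame_systems: np.ndarray  # provenance of contributing frames
    atoms: pd.DataFrame
    proj_min: np.ndarray = field(default=None)
    proj_max: np.ndarray = field(default=None)

    @property
    def n_atoms(self) -> int:
        return self.mean.size // 3

    @property
    def rank(self) -> int:
        return self.eigenvalues.size


@dataclass
class ProjectionSeries:
    """Per-frame scalar projections onto selected PCs, with system tags."""

    pcs: list  # 0-based PC indices
    values: np.ndarray  # (n_frames, len(pcs)), Angstrom
    system: np.ndarray  # (n_frames,)

    def for_pc(self, pc: int) -> np.ndarray:
        return self.values[:, self.pcs.index(pc)]


@dataclass
class PseudoTrajectory:
    """Synthetic frames along one eigenvector about the mean structure."""

    pc: int
    displacements: np.ndarray  # (n_frames,) scalar s_j, Angstrom
    frames: np.ndarray  # (n_frames, N, 3)
    residue_rmsf: np.ndarray  # (N,), Angstrom
    atoms: pd.DataFrame

    @property
    def start(self) -> np.ndarray:
        return self.frames[0]

    @property
    def end(self) -> np.ndarray:
        return self.frames[-1]


def fit_pca(traj: Trajectory) -> CombinedPCAModel:
    """Diagonalise the coordinate covariance of an aligned trajectory.

    The covariance is taken about the combined mean with population (1/F)
    normalisation, so eigenvalues equal the variances of the corresponding
    projection series exactly.  Computed via thin SVD of the centred
    coordinate matrix; eigenpairs are sorted by descending eigenvalue with
    a deterministic tie-break, and eigenvector signs follow the
    largest-component-positive convention.
    """
    if not traj.aligned:
        raise AlignmentStateError(
            "fit_pca requires an aligned trajectory (run align_to_mean first)"
        )
    f = traj.n_frames
    if f < 2:
        raise ValueError("PCA needs at least 2 frames")
    x = traj.coords.reshape(f, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / f
    order = np.argsort(-eigenvalues, kind="stable")
    eigenvalues = eigenvalues[order]
    vectors = _orient(vt[order].T)
    total = float(np.sum(xc**2) / f)
    model = CombinedPCAModel(
        mean=mean,
        eigenvalues=eigenvalues,
        eigenvectors=vectors,
        total_variance=total,
        frame_systems=traj.system.copy(),
        atoms=traj.atoms.copy(),
    )
    proj = xc @ vectors
    model.proj_min = proj.min(axis=0)
    model.proj_max = proj.max(axis=0)
    return model


def project(
    traj: Trajectory, model: CombinedPCAModel, pcs: list[int]
) -> ProjectionSeries:
    """Project every frame onto the selected PCs: (frame - mean) . v_i."""
    x = traj.coords.reshape(traj.n_frames, -1)
    if x.shape[1] != model.mean.size:
        raise ValueError(
            f"trajectory dimension {x.shape[1]} does not match model "
            f"dimension {model.mean.size}"
        )
    for pc in pcs:
        if not 0 <= pc < model.rank:
            raise ValueError(f"PC index {pc} outside model rank {model.rank}")
    values = (x - model.mean) @ model.eigenvectors[:, list(pcs)]
    return ProjectionSeries(pcs=list(pcs), values=values, system=traj.system.copy())


def system_stats(series: ProjectionSeries) -> pd.DataFrame:
    """Average projection and r.m.s.f. in projection, per system and PC.

    The r.m.s.f. is the population standard deviation of the projection
    about the *system's own* mean, so the two statistics are independent:
    average projection reports average-structure differences, r.m.s.f.
    reports dynamical differences.
    """
    rows = []
    tags = list(dict.fromkeys(series.system))
    for tag in tags:
        mask = series.system == tag
        for j, pc in enumerate(series.pcs):
            vals = series.values[mask, j]
            rows.append(
                {
                    "system": tag,
                    "pc": pc + 1,  # 1-based in reports
                    "avg_proj_A": float(vals.mean()),
                    "rmsf_A": float(vals.std(ddof=0)),
                    "n_frames": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def pseudo_trajectory(
    model: CombinedPCAModel,
    pc: int,
    n_frames: int = 2,
    span: str | tuple = "observed",
) -> PseudoTrajectory:
    """Frames equally spaced along eigenvector ``pc`` about the mean.

    ``span`` is either ``"observed"`` (the projection range of the training
    trajectory), a ``("std", k)`` pair for mean +/- k*sqrt(lambda), or an
    explicit ``(lo, hi)`` pair in Angstrom.  The first frame is the start
    (minimum displacement) and the last the end (maximum displacement).
    """
    if not 0 <= pc < model.rank:
        raise ValueError(f"PC index {pc} outside model rank {model.rank}")
    if n_frames < 2:
        raise ValueError("a pseudo-trajectory needs at least 2 frames")
    if span == "observed":
        lo, hi = float(model.proj_min[pc]), float(model.proj_max[pc])
    elif isinstance(span, tuple) and len(span) == 2 and span[0] == "std":
        k = float(span[1])
        half = k * float(np.sqrt(model.eigenvalues[pc]))
        lo, hi = -half, half
    else:
        lo, hi = float(span[0]), float(span[1])
    if hi - lo <= 0:
        raise DegenerateSpanError(
            f"span for PC {pc + 1} is degenerate ([{lo}, {hi}]); "
            "the PC has no observed variance"
        )
    s = np.linspace(lo, hi, n_frames)
    v = model.eigenvectors[:, pc]
    frames = (model.mean[None, :] + s[:, None] * v[None, :]).reshape(
        n_frames, model.n_atoms, 3
    )
    return PseudoTrajectory(
        pc=pc,
        displacements=s,
        frames=frames,
        residue_rmsf=residue_rmsf_in_mode(model, pc),
        atoms=model.atoms.copy(),
    )


def residue_rmsf_in_mode(model: CombinedPCAModel, pc: int) -> np.ndarray:
    """Per-residue r.m.s.f. within one eigenvector.

    For residue r with eigenvector components (v_x, v_y, v_z), the value is
    sqrt(lambda_pc) * sqrt(v_x^2 + v_y^2 + v_z^2): how much of the mode's
    fluctuation amplitude that residue carries.
    """
    if not 0 <= pc < model.rank:
        raise ValueError(f"PC index {pc} outside model rank {model.rank}")
    comps = model.eigenvectors[:, pc].reshape(model.n_atoms, 3)
    return np.sqrt(model.eigenvalues[pc]) * np.linalg.norm(comps, axis=1)
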
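"""Rigid-body least-squares superposition (Kabsch) and trajectory alignment.

Before a covariance analysis, overall translation and rotation must be
removed so that only internal motion remains.  Each frame is superposed
onto an iteratively refined ensemble mean with uniform weights — standard
essential-dynamics practice.  The reflection branch of the SVD solution is
corrected so the returned rotation is always proper (det = +1): a mirror
image can never be superposed by a physical rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .trajectory import Trajectory

__all__ = ["RigidTransform", "kabsch", "align_to_mean"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile onto reference."""

    rotation: np.ndarray  # (3, 3), orthogonal, det = +1
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float  # Angstrom, after transformation

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Uniform weights; both inputs are (n, 3) with n >= 3 and must not be
    collinear.  Returns the transform minimising the RMSD, with the
    reflection branch corrected to a proper rotation.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point count mismatch: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise np.linalg.LinAlgError(
            "degenerate geometry: points are (nearly) collinear"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mob_c
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


def _superpose_frames(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Batched Kabsch of every frame onto one reference (no degeneracy checks)."""
    ref_c = reference.mean(axis=0)
    ref0 = reference - ref_c
    frame_c = coords.mean(axis=1, keepdims=True)
    x0 = coords - frame_c
    h = np.einsum("fni,nj->fij", x0, ref0)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fji,fkj->fik", vt, u))
    corr = np.repeat(np.eye(3)[None], coords.shape[0], axis=0)
    corr[:, 2, 2] = np.where(det < 0, -1.0, 1.0)
    # rot[f] = V @ corr @ U.T  for  h[f] = U S Vt
    rot = np.einsum("fji,fjk,flk->fil", vt, corr, u)
    aligned = np.einsum("fni,fji->fnj", x0, rot) + ref_c
    return aligned


def align_to_mean(
    traj: Trajectory, tolerance: float = 1e-4, max_iter: int = 20
) -> Trajectory:
    """Iteratively superpose every frame onto the running ensemble mean.

    Converged when the mean structure moves by less than ``tolerance``
    (RMSD, Angstrom) between iterations.  Non-convergence is logged as a
    warning; the best result is still returned.  The converged reference is
    stored on the returned trajectory (``.reference``) and the ``aligned``
    flag is set.
    """
    if traj.n_frames < 1:
        raise ValueError("cannot align an empty trajectory")
    coords = np.asarray(traj.coords, dtype=float)
    reference = coords.mean(axis=0)
    converged = False
    for iteration in range(max_iter):
        coords = _superpose_frames(coords, reference)
        new_ref = coords.mean(axis=0)
        shift = float(
            np.sqrt(np.mean(np.sum((new_ref - reference) ** 2, axis=1)))
        )
        reference = new_ref
        log.debug("alignment iteration %d: mean shift %.2e A", iteration + 1, shift)
        if shift < tolerance:
            converged = True
            break
    if not converged:
        log.warning(
            "alignment did not converge in %d iterations (last shift %.3e A)",
            max_iter,
            shift,
        )
    return replace(
        traj, coords=coords, aligned=True, reference=reference
    )
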
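"""Trajectory container and multi-model PDB I/O.

The preprocessing chain for a combined essential-dynamics analysis is:
reduce each system's trajectory to C-alpha atoms, split the dimer into
single-subunit trajectories, and concatenate everything into one trajectory
whose frames remember which system they came from.  The :class:`Trajectory`
container implemented here carries that frame provenance explicitly, which
is what makes per-system statistics on a common PC basis possible
downstream.

Coordinates are in Angstrom throughout.  Multi-model PDB (MODEL/ENDMDL) is
the interchange format; parsing and formatting are delegated to biotite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .errors import (
    MappingError,
    SelectionError,
    StructuralError,
    TrajectoryParseError,
)

__all__ = [
    "Trajectory",
    "ResidueMap",
    "read_trajectory",
    "write_trajectory",
    "select_calpha",
    "split_chains",
    "concatenate",
    "read_residue_map",
]


@dataclass
class Trajectory:
    """Ordered coordinate frames over a labelled atom table.

    Parameters
    ----------
    atoms:
        DataFrame with columns ``chain_id``, ``resid`` (1-based),
        ``name`` and ``element``; one row per atom.
    coords:
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    system:
        Per-frame provenance label, shape ``(n_frames,)``.
    aligned:
        Set by the superposition stage; PCA refuses unaligned input.
    reference:
        Alignment reference coordinates ``(n_atoms, 3)`` once aligned.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    system: np.ndarray
    aligned: bool = False
    reference: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"atom table length {len(self.atoms)}"
            )
        self.system = np.asarray(self.system, dtype=object)
        if self.system.shape != (self.coords.shape[0],):
            raise ValueError("system tags must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def with_system(self, tag: str) -> "Trajectory":
        """Return a copy with every frame tagged ``tag``."""
        return replace(
            self, system=np.full(self.n_frames, tag, dtype=object)
        )

    def tags(self) -> list:
        """Distinct system tags in first-appearance order."""
        seen: dict = {}
        for t in self.system:
            seen.setdefault(t, None)
        return list(seen)


@dataclass
class ResidueMap:
    """Bijective residue-id correspondence between a system and the reference.

    Homologous constructs of equal length map residue-for-residue by
    default (the identity map); a curated correspondence can be supplied
    for inserted/deleted positions.
    """

    mapping: dict[int, int] | None = None  # source resid -> reference resid

    def apply(self, resids: np.ndarray) -> np.ndarray:
        if self.mapping is None:
            return np.asarray(resids)
        values = list(self.mapping.values())
        if len(set(values)) != len(values):
            raise MappingError("residue map is not bijective")
        try:
            return np.array([self.mapping[int(r)] for r in resids])
        except KeyError as exc:
            raise MappingError(f"residue id {exc.args[0]} has no mapping") from exc


def read_residue_map(path) -> ResidueMap:
    """Read a two-column tab-separated residue correspondence table."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None)
    if table.shape[1] != 2:
        raise MappingError(f"{path}: expected exactly two columns")
    return ResidueMap(dict(zip(table[0].astype(int), table[1].astype(int))))


def _atoms_from_array(arr: struc.AtomArray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain_id": arr.chain_id.astype(str),
            "resid": arr.res_id.astype(int),
            "name": arr.atom_name.astype(str),
            "element": arr.element.astype(str),
        }
    )


def read_trajectory(path, fmt: str = "pdb", system: str = "") -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Every MODEL record becomes one frame, in file order.  All frames are
    tagged with ``system`` (often the construct name; empty by default).
    """
    if fmt != "pdb":
        raise NotImplementedError(
            f"format {fmt!r} is not supported; use multi-model PDB "
            "(convert binary trajectories externally)"
        )
    try:
        pdb_file = pdb.PDBFile.read(path)
        stack = pdb_file.get_structure()
    except Exception as exc:
        msg = str(exc)
        if "same number of atoms" in msg or "inconsistent" in msg.lower():
            raise StructuralError(f"{path}: {msg}") from exc
        raise TrajectoryParseError(f"{path}: {msg}") from exc
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise TrajectoryParseError(f"{path}: no atom records found")
    atoms = _atoms_from_array(stack[0])
    coords = np.asarray(stack.coord, dtype=float)
    tags = np.full(coords.shape[0], system, dtype=object)
    return Trajectory(atoms=atoms, coords=coords, system=tags)


def _to_atom_array_stack(traj: Trajectory, bfactor=None) -> struc.AtomArrayStack:
    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = traj.atoms["chain_id"].to_numpy(dtype="U4")
    arr.res_id = traj.atoms["resid"].to_numpy(dtype=int)
    arr.atom_name = traj.atoms["name"].to_numpy(dtype="U6")
    arr.res_name = np.full(n, "ALA", dtype="U5")  # placeholder residue type
    arr.element = traj.atoms["element"].to_numpy(dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    if bfactor is not None:
        stack.set_annotation(
            "b_factor", np.asarray(bfactor, dtype=float)
        )
    return stack


def write_trajectory(traj: Trajectory, path, fmt: str = "pdb", bfactor=None) -> None:
    """Write a trajectory as multi-model PDB (one MODEL per frame).

    ``bfactor`` optionally fills the B-factor column (one value per atom,
    shared by all models), e.g. with per-residue mode r.m.s.f. for
    colour-gradient rendering.
    """
    if fmt != "pdb":
        raise NotImplementedError(f"format {fmt!r} is not supported for writing")
    if traj.n_frames == 0:
        raise ValueError("refusing to write a zero-frame trajectory")
    stack = _to_atom_array_stack(traj, bfactor=bfactor)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


def select_calpha(traj: Trajectory) -> Trajectory:
    """Restrict the atom table and all frames to C-alpha atoms, order kept."""
    mask = (traj.atoms["name"] == "CA").to_numpy()
    if not mask.any():
        raise SelectionError("trajectory contains no CA atoms")
    atoms = traj.atoms.loc[mask].reset_index(drop=True)
    return replace(traj, atoms=atoms, coords=traj.coords[:, mask, :])


def split_chains(traj: Trajectory) -> list[Trajectory]:
    """One trajectory per chain id (chain-id order), each keeping all frames."""
    out = []
    for cid in sorted(traj.atoms["chain_id"].unique()):
        mask = (traj.atoms["chain_id"] == cid).to_numpy()
        atoms = traj.atoms.loc[mask].reset_index(drop=True)
        out.append(replace(traj, atoms=atoms, coords=traj.coords[:, mask, :]))
    return out


def concatenate(
    trajs: list[Trajectory], residue_map: ResidueMap | None = None
) -> Trajectory:
    """Append trajectories frame-wise into one combined trajectory.

    Frames keep their source system tags; the atom table is taken from the
    first input with its residue ids mapped through ``residue_map`` (identity
    by default).  All inputs must present the same mapped atom count and the
    same mapped residue-id sequence.
    """
    if not trajs:
        raise ValueError("no trajectories to concatenate")
    rmap = residue_map or ResidueMap()
    ref_atoms = trajs[0].atoms.copy()
    ref_resids = rmap.apply(ref_atoms["resid"].to_numpy())
    ref_atoms["resid"] = ref_resids
    for i, t in enumerate(trajs[1:], start=2):
        resids = rmap.apply(t.atoms["resid"].to_numpy())
        if len(resids) != len(ref_resids) or not np.array_equal(
            np.asarray(resids), np.asarray(ref_resids)
        ):
            extra = sorted(set(resids.tolist()) ^ set(ref_resids.tolist()))
            raise MappingError(
                f"input {i} maps to a different residue set than input 1; "
                f"unmatched ids: {extra[:10]}"
            )
    coords = np.concatenate([t.coords for t in trajs], axis=0)
    system = np.concatenate([t.system for t in trajs])
    return Trajectory(atoms=ref_atoms, coords=coords, system=system)
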
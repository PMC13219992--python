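"""Rigid superposition (Kabsch), ligand RMSD, and C-alpha RMSF.

Ligand RMSD follows the pose-evaluation convention: the complex is first
superposed on the protein (default fit: C-alpha atoms), then the RMSD is
taken over ligand heavy atoms in absolute coordinates WITHOUT re-fitting
the ligand itself, so a ligand that drifted inside a well-aligned pocket
scores its true displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CorrespondenceError, SuperpositionError
from .io import Structure, Trajectory
from .selection import AtomSelection, select_atoms


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation: x -> R @ x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), A

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rotation+translation mapping mobile onto target.

    Standard SVD construction with the determinant sign fix that excludes
    reflections.
    """
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    P = mobile - mob_center
    Q = target - tgt_center
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt_center - R @ mob_center
    return RigidTransform(R, t)


def superpose(
    mobile: Structure, target: Structure, fit_selection: AtomSelection
) -> RigidTransform:
    """Optimal rigid fit of ``mobile`` onto ``target`` over the fit atoms.

    Requires at least three non-collinear fit atoms; the same selection is
    applied to both structures (they must share a topology layout).
    """
    idx = fit_selection.indices
    if len(idx) < 3:
        raise SuperpositionError(f"need >= 3 fit atoms, got {len(idx)}")
    mob = mobile.coords[idx]
    tgt = target.coords[idx]
    # collinearity check: rank of the centered cloud must be >= 2
    if np.linalg.matrix_rank(mob - mob.mean(axis=0), tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) fit geometry")
    return _kabsch(mob, tgt)


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two aligned point sets."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ligand_rmsd(
    structure: Structure,
    reference: Structure,
    ligand_sel: AtomSelection,
    fit_selection: AtomSelection | None = None,
) -> float:
    """Ligand heavy-atom RMSD after protein superposition.

    ``fit_selection`` defaults to protein C-alpha atoms. The two structures
    must have matching ligand atom identities (name and residue), enforced
    so the per-atom correspondence is meaningful.
    """
    topo_a, topo_b = structure.topology, reference.topology
    if fit_selection is None:
        fit_selection = select_atoms(topo_a, "protein and name CA")
    l_idx = ligand_sel.indices
    l_idx = l_idx[~topo_a.is_hydrogen[l_idx]]
    if len(l_idx) == 0:
        raise CorrespondenceError("empty ligand heavy-atom selection")
    for i in l_idx:
        if (
            str(topo_a.names[i]) != str(topo_b.names[i])
            or topo_a.residue_key(int(i)) != topo_b.residue_key(int(i))
        ):
            raise CorrespondenceError(
                f"ligand atom {int(i)} identity mismatch between structures"
            )
    transform = superpose(structure, reference, fit_selection)
    moved = transform.apply(structure.coords[l_idx])
    return rmsd_between(moved, reference.coords[l_idx])


def rmsf(
    traj_windowed: Trajectory,
    representative: Structure,
    fit_selection: AtomSelection | None = None,
) -> pd.DataFrame:
    """Per-residue C-alpha RMSF about the time-mean position.

    Every frame is least-squares aligned to the representative structure on
    ``fit_selection`` (default: protein C-alpha); the fluctuation of each
    C-alpha atom is then sqrt(mean ||x_i(t) - <x_i>||^2), reported per
    residue. Residues without a C-alpha atom are omitted.

    Returns a DataFrame with columns chain, resseq, icode, resname, rmsf.
    """
    topo = traj_windowed.topology
    if traj_windowed.n_frames < 2:
        raise SuperpositionError("RMSF needs at least two frames")
    ca = select_atoms(topo, "protein and name CA")
    if fit_selection is None:
        fit_selection = ca
    aligned = np.empty((traj_windowed.n_frames, len(ca.indices), 3))
    for f in range(traj_windowed.n_frames):
        tr = superpose(traj_windowed.frame(f), representative, fit_selection)
        aligned[f] = tr.apply(traj_windowed.coords[f][ca.indices])
    mean_pos = aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
    rows = []
    for k, atom in enumerate(ca.indices):
        chain, seq, icode, name = topo.residue_key(int(atom))
        rows.append(
            {"chain": chain, "resseq": seq, "icode": icode, "resname": name, "rmsf": float(fluct[k])}
        )
    return pd.DataFrame(rows)
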
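"""Native-contact identification, distance series, and representative frames.

A native contact is a protein heavy-atom / ligand heavy-atom pair closer
than a cutoff (default 4.5 A, strict) in a chosen reference structure.
The representative frame of a trajectory is the one whose retained-pair
distance vector lies closest (Euclidean) to the ensemble-averaged vector,
where pairs are retained if their trajectory-mean distance is at most
6.75 A (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import NoNativeContactsError, WindowError
from .io import Structure, Topology, Trajectory
from .selection import AtomSelection

NATIVE_CUTOFF = 4.5  # A, strict upper bound for native contacts
RETENTION_CUTOFF = 6.75  # A, inclusive bound on the trajectory-mean distance
DEFAULT_DISCARD_FRACTION = 0.6  # equilibration portion dropped per replica


class ReferenceMode(str, Enum):
    """Which structure defines the native contacts."""

    DOCK = "dock"  # initial docking pose
    EXP = "exp"  # experimental (crystallographic) pose
    REPR = "repr"  # trajectory representative structure


@dataclass(frozen=True)
class ContactPair:
    protein_atom: int
    ligand_atom: int
    r0: float  # reference distance, A


@dataclass(frozen=True)
class ContactSet:
    """Sorted, unique native protein-ligand heavy-atom pairs."""

    pairs: tuple[ContactPair, ...]
    reference_mode: ReferenceMode
    cutoff: float
    reference_structure: Structure

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)

    @property
    def pair_indices(self) -> np.ndarray:
        """(N, 2) array of (protein_atom, ligand_atom)."""
        return np.array([(p.protein_atom, p.ligand_atom) for p in self.pairs], dtype=np.intp)

    @property
    def r0(self) -> np.ndarray:
        return np.array([p.r0 for p in self.pairs], dtype=np.float64)

    def to_frame(self, topology: Topology | None = None) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            row = {
                "protein_atom": p.protein_atom,
                "ligand_atom": p.ligand_atom,
                "r0": p.r0,
            }
            if topology is not None:
                chain, seq, icode, name = topology.residue_key(p.protein_atom)
                row["protein_residue"] = f"{chain}:{name}{seq}{icode}".rstrip()
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnalysisWindow:
    """Per-replica equilibration discard, as a fraction of frames."""

    discard_fraction: float = DEFAULT_DISCARD_FRACTION

    def __post_init__(self):
        if not 0.0 <= self.discard_fraction < 1.0:
            raise WindowError(
                f"discard_fraction must be in [0, 1), got {self.discard_fraction}"
            )


@dataclass
class DistanceSeries:
    """Per-frame distances (A) for a fixed list of atom pairs.

    ``values[f, p]`` is the distance of pair ``p`` in pooled frame ``f``.
    Frame metadata (replica ids, times) is carried over from the source
    trajectory so downstream reports can name frames.
    """

    pair_indices: np.ndarray  # (P, 2)
    values: np.ndarray  # (F, P)
    replica_ids: np.ndarray
    times: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


@dataclass
class EnsembleContactMatrix:
    """Trajectory-mean distances for candidate pairs plus the retained set."""

    candidate_pairs: np.ndarray  # (P, 2) all protein-ligand heavy pairs
    mean_distance: np.ndarray  # (P,) A
    retention_cutoff: float
    retained_mask: np.ndarray  # (P,) bool

    @property
    def retained_pairs(self) -> np.ndarray:
        return self.candidate_pairs[self.retained_mask]

    @property
    def mean_vector(self) -> np.ndarray:
        return self.mean_distance[self.retained_mask]


@dataclass
class RepresentativeResult:
    frame_global_index: int
    replica_id: int
    frame_index_in_replica: int
    structure: Structure
    euclidean_distance: float
    distances_per_frame: np.ndarray = field(repr=False, default=None)


def identify_native_contacts(
    reference: Structure,
    protein_sel: AtomSelection,
    ligand_sel: AtomSelection,
    cutoff: float = NATIVE_CUTOFF,
    reference_mode: ReferenceMode = ReferenceMode.EXP,
) -> ContactSet:
    """All protein/ligand heavy-atom pairs strictly closer than ``cutoff``.

    Hydrogens are excluded from both sides regardless of the selections.
    Raises :class:`NoNativeContactsError` when no pair qualifies, because
    every downstream stability statistic is undefined at N = 0.
    """
    topo = reference.topology
    p_idx = protein_sel.indices[~topo.is_hydrogen[protein_sel.indices]]
    l_idx = ligand_sel.indices[~topo.is_hydrogen[ligand_sel.indices]]
    if np.intersect1d(p_idx, l_idx).size:
        raise ValueError("protein and ligand selections overlap")
    diff = reference.coords[p_idx][:, None, :] - reference.coords[l_idx][None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    pi, li = np.nonzero(dist < cutoff)
    if pi.size == 0:
        raise NoNativeContactsError(
            f"no protein-ligand heavy-atom pair closer than {cutoff} A"
        )
    pairs = sorted(
        (
            ContactPair(int(p_idx[a]), int(l_idx[b]), float(dist[a, b]))
            for a, b in zip(pi, li)
        ),
        key=lambda p: (p.protein_atom, p.ligand_atom),
    )
    return ContactSet(tuple(pairs), ReferenceMode(reference_mode), cutoff, reference)


def apply_window(traj: Trajectory, window: AnalysisWindow) -> Trajectory:
    """Drop the leading equilibration fraction of each replica, then pool.

    Per replica, the first ``floor(discard_fraction * n_frames)`` frames are
    removed; surviving frames keep their within-replica order and replicas
    are concatenated in replica order.
    """
    keep_masks = []
    order = []
    for rep in traj.replica_ids_present():
        mask = traj.replica_ids == rep
        n = int(mask.sum())
        drop = int(np.floor(window.discard_fraction * n))
        if drop >= n:
            raise WindowError(f"replica {rep}: no frames left after windowing")
        idx = np.nonzero(mask)[0][drop:]
        order.append(idx)
    sel = np.concatenate(order)
    return Trajectory(
        topology=traj.topology,
        coords=traj.coords[sel],
        replica_ids=traj.replica_ids[sel],
        times=traj.times[sel],
        frame_indices=traj.frame_indices[sel],
    )


def compute_distance_series(traj: Trajectory, pairs) -> DistanceSeries:
    """Vectorized per-frame Euclidean distances for the given pairs."""
    if isinstance(pairs, ContactSet):
        pair_indices = pairs.pair_indices
    else:
        pair_indices = np.asarray(
            [
                (p.protein_atom, p.ligand_atom) if isinstance(p, ContactPair) else tuple(p)
                for p in pairs
            ],
            dtype=np.intp,
        )
    n_atoms = traj.topology.n_atoms
    if pair_indices.size and pair_indices.max() >= n_atoms:
        raise IndexError("pair atom index out of range for topology")
    diff = traj.coords[:, pair_indices[:, 0], :] - traj.coords[:, pair_indices[:, 1], :]
    values = np.linalg.norm(diff, axis=-1)
    return DistanceSeries(pair_indices, values, traj.replica_ids.copy(), traj.times.copy())


def ensemble_contact_matrix(
    traj_windowed: Trajectory,
    protein_sel: AtomSelection,
    ligand_sel: AtomSelection,
    retention_cutoff: float = RETENTION_CUTOFF,
) -> EnsembleContactMatrix:
    """Trajectory-mean distance for every protein-ligand heavy-atom pair.

    Candidate pairs are ALL heavy cross pairs; a pair is retained when its
    pooled-frame mean distance is <= ``retention_cutoff`` (inclusive).
    """
    topo = traj_windowed.topology
    p_idx = protein_sel.indices[~topo.is_hydrogen[protein_sel.indices]]
    l_idx = ligand_sel.indices[~topo.is_hydrogen[ligand_sel.indices]]
    pp, ll = np.meshgrid(p_idx, l_idx, indexing="ij")
    candidates = np.column_stack([pp.ravel(), ll.ravel()])
    series = compute_distance_series(traj_windowed, candidates)
    means = series.values.mean(axis=0)
    retained = means <= retention_cutoff
    if not np.any(retained):
        raise NoNativeContactsError(
            f"no candidate pair has mean distance <= {retention_cutoff} A"
        )
    return EnsembleContactMatrix(candidates, means, retention_cutoff, retained)


def select_representative(
    traj_windowed: Trajectory, matrix: EnsembleContactMatrix
) -> RepresentativeResult:
    """Frame minimizing the Euclidean distance to the ensemble-mean vector.

    Ties resolve to the lowest pooled frame index, making selection
    deterministic for degenerate (e.g. static) trajectories.
    """
    series = compute_distance_series(traj_windowed, matrix.retained_pairs)
    deltas = series.values - matrix.mean_vector[None, :]
    norms = np.linalg.norm(deltas, axis=1)
    best = int(np.argmin(norms))  # argmin takes the first minimum: tie-break
    return RepresentativeResult(
        frame_global_index=best,
        replica_id=int(traj_windowed.replica_ids[best]),
        frame_index_in_replica=int(traj_windowed.frame_indices[best]),
        structure=traj_windowed.frame(best),
        euclidean_distance=float(norms[best]),
        distances_per_frame=norms,
    )
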
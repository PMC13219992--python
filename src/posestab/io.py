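"""Topology, structure and trajectory containers plus file I/O.

All coordinates are stored in Angstrom (float64) regardless of the file
format they came from; unit conversion happens only at the reader
boundary (XTC stores nm, everything else already uses Angstrom).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .errors import (
    EmptyStructureError,
    IOFormatError,
    PDBParseError,
    TrajectoryError,
)

#: HETATM residue names treated as solvent/ions and dropped at load time.
DEFAULT_SOLVENT_RESNAMES = frozenset(
    {"HOH", "WAT", "NA", "CL", "SO4", "GOL", "K", "MG", "ZN", "CA", "PO4"}
)

_NM_TO_ANGSTROM = 10.0


def _infer_element(atom_name: str) -> str:
    """Best-effort element from an atom name when the element column is blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H" or atom_name.strip()[0] in "123456789" and "H" in atom_name:
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass(frozen=True)
class Topology:
    """Immutable per-atom metadata for a protein-ligand complex.

    Atom indices are implicit, 0-based and contiguous; arrays are parallel.
    ``is_ligand`` partitions the complex: every atom is either protein-side
    or ligand-side (solvent and ions are excluded at load time).
    """

    names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    res_seqs: np.ndarray
    ins_codes: np.ndarray
    chain_ids: np.ndarray
    is_ligand: np.ndarray
    is_hydrogen: np.ndarray

    def __post_init__(self):
        n = len(self.names)
        for f_ in dataclasses.fields(self):
            arr = getattr(self, f_.name)
            if len(arr) != n:
                raise ValueError(f"topology array {f_.name!r} has length {len(arr)} != {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~self.is_hydrogen

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.is_ligand

    def residue_key(self, index: int) -> tuple[str, int, str, str]:
        """Residue identity of an atom: (chain_id, res_seq, ins_code, res_name)."""
        return (
            str(self.chain_ids[index]),
            int(self.res_seqs[index]),
            str(self.ins_codes[index]),
            str(self.res_names[index]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f_.name), getattr(other, f_.name))
            for f_ in dataclasses.fields(self)
        )


@dataclass(frozen=True)
class Structure:
    """A topology plus one coordinate snapshot in Angstrom."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3) float64, Angstrom

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")


@dataclass
class Trajectory:
    """Frames sharing one topology, with per-frame replica metadata.

    ``replica_ids`` records which input file (or synthetic replica) each
    frame came from; within a replica, frames are time-ordered.
    """

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3) float64, Angstrom
    replica_ids: np.ndarray  # (n_frames,) int
    times: np.ndarray  # (n_frames,) float, ns
    frame_indices: np.ndarray = field(default=None)  # index within replica

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("trajectory coordinates must be (frames, atoms, 3)")
        self.replica_ids = np.asarray(self.replica_ids, dtype=np.intp)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frame_indices is None:
            idx = np.zeros(self.n_frames, dtype=np.intp)
            for rep in np.unique(self.replica_ids):
                mask = self.replica_ids == rep
                idx[mask] = np.arange(mask.sum())
            self.frame_indices = idx
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=np.intp)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(self.topology, self.coords[i])

    def replica_ids_present(self) -> np.ndarray:
        # preserve first-appearance order, not sorted order
        _, first = np.unique(self.replica_ids, return_index=True)
        return self.replica_ids[np.sort(first)]


# ---------------------------------------------------------------------------
# PDB reading


def _check_pdb_coordinates(path: str) -> None:
    """Pre-scan ATOM/HETATM records so parse errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path}:{lineno}: truncated record, missing coordinates"
                    )
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fld = line[lo:hi].strip()
                    if not fld:
                        raise PDBParseError(
                            f"{path}:{lineno}: missing coordinate field"
                        )
                    try:
                        float(fld)
                    except ValueError:
                        raise PDBParseError(
                            f"{path}:{lineno}: unparseable coordinate {fld!r}"
                        ) from None


def _topology_from_atom_array(arr: AtomArray, solvent_resnames) -> tuple[Topology, np.ndarray]:
    """Build a Topology from a biotite AtomArray, dropping solvent/ions.

    Returns the topology and the boolean keep-mask applied to the array.
    """
    res_names = np.asarray(arr.res_name, dtype="U5")
    keep = ~(arr.hetero & np.isin(res_names, list(solvent_resnames)))
    if not np.any(keep):
        raise EmptyStructureError("no atoms remain after solvent/ion filtering")
    arr = arr[keep]
    elements = np.array(
        [e if e else _infer_element(n) for e, n in zip(arr.element, arr.atom_name)],
        dtype="U2",
    )
    topo = Topology(
        names=np.asarray(arr.atom_name, dtype="U6"),
        elements=elements,
        res_names=np.asarray(arr.res_name, dtype="U5"),
        res_seqs=np.asarray(arr.res_id, dtype=np.intp),
        ins_codes=np.asarray(arr.ins_code, dtype="U1"),
        chain_ids=np.asarray(arr.chain_id, dtype="U4"),
        is_ligand=np.asarray(arr.hetero, dtype=bool),
        is_hydrogen=np.char.upper(elements) == "H",
    )
    return topo, keep


def read_structure(path: str, solvent_resnames=DEFAULT_SOLVENT_RESNAMES) -> Structure:
    """Read a PDB file into a Structure (first MODEL, Angstrom).

    HETATM records are flagged as ligand atoms unless their residue name is
    in ``solvent_resnames`` (waters, common ions, cryoprotectants), in which
    case they are dropped. Alternate locations keep the highest-occupancy
    conformer (ties resolve to the first, i.e. altloc 'A').
    """
    _check_pdb_coordinates(path)
    try:
        pdb = PDBFile.read(path)
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises several parse error types
        raise PDBParseError(f"{path}: {exc}") from exc
    topo, keep = _topology_from_atom_array(arr, solvent_resnames)
    # PDB stores 3 decimals; quantize so the parse is exact in float64
    coords = np.round(np.asarray(arr.coord[keep], dtype=np.float64), 3)
    return Structure(topo, coords)


def read_trajectory(
    paths,
    topology: Topology,
    solvent_resnames=DEFAULT_SOLVENT_RESNAMES,
) -> Trajectory:
    """Read one or more trajectory files and pool them as replicas.

    Formats: multi-model PDB, XTC, DCD (by extension). File position in
    ``paths`` defines ``replica_id``. XTC coordinates are converted nm to
    Angstrom; PDB and DCD are already in Angstrom. Every file must match
    the topology's atom count (PDB inputs are solvent-filtered first with
    the same drop-list used at topology load).
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    all_coords, all_reps, all_times, all_fidx = [], [], [], []
    for rep, path in enumerate(paths):
        path = os.fspath(path)
        ext = os.path.splitext(path)[1].lower()
        if ext == ".pdb":
            coords, times = _read_pdb_frames(path, solvent_resnames)
        elif ext == ".xtc":
            coords, times = _read_xtc_frames(path)
        elif ext == ".dcd":
            coords, times = _read_dcd_frames(path)
        else:
            raise IOFormatError(f"unsupported trajectory format: {path}")
        if coords.shape[1] != topology.n_atoms:
            raise TrajectoryError(
                f"{path}: {coords.shape[1]} atoms per frame, topology has "
                f"{topology.n_atoms}"
            )
        n = coords.shape[0]
        all_coords.append(coords)
        all_reps.append(np.full(n, rep, dtype=np.intp))
        all_times.append(times)
        all_fidx.append(np.arange(n, dtype=np.intp))
    return Trajectory(
        topology=topology,
        coords=np.concatenate(all_coords, axis=0),
        replica_ids=np.concatenate(all_reps),
        times=np.concatenate(all_times),
        frame_indices=np.concatenate(all_fidx),
    )


def _read_pdb_frames(path, solvent_resnames):
    _check_pdb_coordinates(path)
    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(altloc="occupancy")
    except Exception as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if isinstance(stack, AtomArray):
        stack = stack[np.newaxis, ...]
    res_names = np.asarray(stack.res_name, dtype="U5")
    keep = ~(stack.hetero & np.isin(res_names, list(solvent_resnames)))
    coords = np.round(np.asarray(stack.coord[:, keep, :], dtype=np.float64), 3)
    times = np.arange(coords.shape[0], dtype=np.float64)
    return coords, times


def _read_xtc_frames(path):
    from mdtraj.formats import XTCTrajectoryFile

    try:
        with XTCTrajectoryFile(path) as fh:
            xyz, time, step, box = fh.read()
    except Exception as exc:
        raise TrajectoryError(f"{path}: unreadable XTC frame ({exc})") from exc
    coords = np.asarray(xyz, dtype=np.float64) * _NM_TO_ANGSTROM
    times = np.asarray(time, dtype=np.float64) / 1000.0  # ps -> ns
    return coords, times


def _read_dcd_frames(path):
    from mdtraj.formats import DCDTrajectoryFile

    try:
        with DCDTrajectoryFile(path) as fh:
            xyz, cell_lengths, cell_angles = fh.read()
    except Exception as exc:
        raise TrajectoryError(f"{path}: unreadable DCD frame ({exc})") from exc
    coords = np.asarray(xyz, dtype=np.float64)  # DCD stores Angstrom
    times = np.arange(coords.shape[0], dtype=np.float64)
    return coords, times


# ---------------------------------------------------------------------------
# PDB writing


def _atom_array_from(topology: Topology, coords: np.ndarray) -> AtomArray:
    n = topology.n_atoms
    arr = AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = topology.chain_ids
    arr.res_id = topology.res_seqs
    arr.ins_code = topology.ins_codes
    arr.res_name = topology.res_names
    arr.hetero = topology.is_ligand
    arr.atom_name = topology.names
    arr.element = topology.elements
    return arr


def write_structure(structure: Structure, path: str) -> None:
    """Write a Structure as a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from(structure.topology, structure.coords))
    pdb.write(os.fspath(path))


def write_trajectory_pdb(traj: Trajectory, path: str) -> None:
    """Write a Trajectory as a multi-model PDB file (one MODEL per frame)."""
    n = traj.topology.n_atoms
    stack = AtomArrayStack(traj.n_frames, n)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.chain_id = traj.topology.chain_ids
    stack.res_id = traj.topology.res_seqs
    stack.ins_code = traj.topology.ins_codes
    stack.res_name = traj.topology.res_names
    stack.hetero = traj.topology.is_ligand
    stack.atom_name = traj.topology.names
    stack.element = traj.topology.elements
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(os.fspath(path))


# ---------------------------------------------------------------------------
# Tabular reports


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, dict):
            rows.append(rec)
        else:
            raise IOFormatError(f"unsupported record type: {type(rec).__name__}")
    return pd.DataFrame(rows)


def write_table(records, path: str, format: str = "tsv") -> None:
    """Write records (dataclasses, dicts or a DataFrame) as TSV or JSON.

    TSV uses a header row, tab delimiter and '.' decimal separator; floats
    are written with shortest-roundtrip repr so a read-back reproduces the
    values exactly. JSON is an array of objects.
    """
    df = _records_to_frame(records)
    path = os.fspath(path)
    try:
        if format == "tsv":
            with open(path, "w") as fh:
                fh.write("\t".join(map(str, df.columns)) + "\n")
                for row in df.itertuples(index=False):
                    fh.write("\t".join(_cell(v) for v in row) + "\n")
        elif format == "json":
            with open(path, "w") as fh:
                json.dump(df.to_dict(orient="records"), fh, indent=1, sort_keys=False)
                fh.write("\n")
        else:
            raise IOFormatError(f"unknown table format: {format!r}")
    except OSError as exc:
        raise IOFormatError(f"cannot write {path}: {exc}") from exc


def _cell(v) -> str:
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return repr(v)
    return str(v)


def read_table(path: str, format: str = "tsv") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    path = os.fspath(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise IOFormatError(f"unknown table format: {format!r}")
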
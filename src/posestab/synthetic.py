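"""Synthetic fixtures with planted ground truth.

Two generator tiers stand in for real MD output:

- a distance-level emission model (``simulate_distance_series``) that draws
  each native contact independently per frame as "intact" (distance near
  its reference value) or "broken" (pushed past the sigmoid switching
  point), with a closed-form expected R-value obtained by integrating the
  emission densities through the contact sigmoid; and
- a coordinate-level generator (``simulate_trajectory``) that realizes the
  same persistence as rigid-body ligand excursions out of a toy binding
  pocket, exercising the full pipeline including superposition and
  representative-frame selection.

Exact realization of an arbitrary distance matrix in 3-D is infeasible,
hence the two tiers. All randomness flows from one seed through named
substreams, so adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import halfnorm, truncnorm

from .contacts import ContactSet, DistanceSeries
from .errors import GenerationError
from .io import Structure, Topology, Trajectory
from .stability import ContactModelParams

_SUBSTREAMS = {"complex": 0, "distances": 1, "trajectory": 2, "decoys": 3, "jitter": 4}

_PROTEIN_ATOM_NAMES = ["CA", "CB", "CG", "CD", "CE", "CZ", "CH", "CI"]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SUBSTREAMS[stream]])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for all synthetic fixtures.

    Defaults emulate, at toy scale, a multi-replica high-temperature MD
    ensemble: several independent replicas whose pooled analysis window
    carries a few hundred frames, sub-0.1-A bound-state distance noise, and
    broken contacts displaced well past the sigmoid switching point.
    """

    n_residues: int = 8
    atoms_per_residue: int = 3
    n_ligand_atoms: int = 6
    n_frames: int = 100  # per replica
    n_replicas: int = 3
    persistence: float | np.ndarray = 0.9  # per-contact or scalar, in [0, 1]
    bound_noise_sigma: float = 0.05  # A
    broken_offset: float = 4.0  # A beyond Lambda*r0 when a contact breaks
    excursion_offset: float = 10.0  # A, coordinate-level out-of-pocket shift
    include_hydrogens: bool = False
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.persistence, dtype=np.float64)
        if np.any(p < 0) or np.any(p > 1):
            raise GenerationError("persistence must lie in [0, 1]")
        if self.bound_noise_sigma < 0:
            raise GenerationError("bound_noise_sigma must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, reproducible from config+seed."""

    persistence: np.ndarray = None
    expected_r: float = None
    intact_mask: np.ndarray = None  # (frames, contacts) or (frames,) bool
    planted_rmsd: np.ndarray = None  # per decoy pose, A
    planted_labels: list = field(default_factory=list)


def make_toy_complex(config: GeneratorConfig = GeneratorConfig()) -> Structure:
    """A pocket of pseudo-residues enclosing a pseudo-ligand.

    Ligand heavy atoms sit on a small inner sphere, protein residues on an
    outer shell (evenly spread directions plus seeded jitter), so cross
    distances land between ~2 and ~7 A: several native contacts at the
    4.5 A cutoff are guaranteed by construction and verified before
    returning. Coordinates are rounded to PDB precision (1e-3 A) so a
    write/read round trip is exact.
    """
    if min(config.n_residues, config.atoms_per_residue, config.n_ligand_atoms) < 1:
        raise GenerationError("all atom/residue counts must be >= 1")
    if config.atoms_per_residue > len(_PROTEIN_ATOM_NAMES):
        raise GenerationError(
            f"atoms_per_residue > {len(_PROTEIN_ATOM_NAMES)} not supported"
        )
    rng = _rng(config.seed, "complex")

    lig = 1.2 * _fibonacci_sphere(config.n_ligand_atoms)
    lig += rng.normal(0.0, 0.05, lig.shape)

    directions = _fibonacci_sphere(config.n_residues)
    prot = []
    for d in directions:
        center = 4.2 * d + rng.normal(0.0, 0.05, 3)
        # place residue atoms on a short arc tangent to the shell
        tangent = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(tangent) < 1e-6:
            tangent = np.array([1.0, 0.0, 0.0])
        tangent /= np.linalg.norm(tangent)
        for k in range(config.atoms_per_residue):
            prot.append(center + 0.8 * k * tangent + rng.normal(0.0, 0.05, 3))
    prot = np.array(prot)

    names = []
    elements = []
    res_names = []
    res_seqs = []
    chains = []
    is_lig = []
    is_h = []
    coords = [prot]
    for i in range(config.n_residues):
        for k in range(config.atoms_per_residue):
            names.append(_PROTEIN_ATOM_NAMES[k])
            elements.append("C")
            res_names.append("ALA")
            res_seqs.append(i + 1)
            chains.append("A")
            is_lig.append(False)
            is_h.append(False)
    for j in range(config.n_ligand_atoms):
        names.append(f"C{j + 1}")
        elements.append("C")
        res_names.append("LIG")
        res_seqs.append(1)
        chains.append("L")
        is_lig.append(True)
        is_h.append(False)
    coords.append(lig)
    if config.include_hydrogens:
        h_pos = lig + 1.0 * (lig / np.linalg.norm(lig, axis=1, keepdims=True))
        coords.append(h_pos)
        for j in range(config.n_ligand_atoms):
            names.append(f"H{j + 1}")
            elements.append("H")
            res_names.append("LIG")
            res_seqs.append(1)
            chains.append("L")
            is_lig.append(True)
            is_h.append(True)

    topo = Topology(
        names=np.array(names, dtype="U6"),
        elements=np.array(elements, dtype="U2"),
        res_names=np.array(res_names, dtype="U5"),
        res_seqs=np.array(res_seqs, dtype=np.intp),
        ins_codes=np.full(len(names), "", dtype="U1"),
        chain_ids=np.array(chains, dtype="U4"),
        is_ligand=np.array(is_lig, dtype=bool),
        is_hydrogen=np.array(is_h, dtype=bool),
    )
    xyz = np.round(np.concatenate(coords, axis=0), 3)
    structure = Structure(topo, xyz)

    heavy_p = xyz[: config.n_residues * config.atoms_per_residue]
    dist = np.linalg.norm(heavy_p[:, None, :] - lig[None, :, :], axis=-1)
    if not np.any(dist < 4.5):
        raise GenerationError("toy complex has no native contact at 4.5 A")
    return structure


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spread unit vectors (deterministic)."""
    if n == 1:
        return np.array([[1.0, 0.0, 0.0]])
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / (n - 1)
    z = np.clip(z, -1.0, 1.0)
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def expected_contact_term(
    p: float,
    r0: float,
    sigma: float,
    broken_offset: float,
    params: ContactModelParams = ContactModelParams(),
) -> float:
    """E[sigmoid term] under the emission model, by numerical integration.

    Intact: distance ~ Normal(r0, sigma) truncated to (0, inf). Broken:
    distance = Lambda*r0 + broken_offset + |Normal(0, sigma)|. The
    expectation integrates the contact sigmoid against each density.
    """
    beta, lam = params.beta, params.lam
    if sigma == 0.0:
        intact = expit(beta * (lam * r0 - r0))
        broken = expit(-beta * broken_offset)
    else:
        a = (0.0 - r0) / sigma
        intact = quad(
            lambda d: expit(beta * (lam * r0 - d))
            * truncnorm.pdf(d, a, np.inf, loc=r0, scale=sigma),
            max(0.0, r0 - 10 * sigma),
            r0 + 10 * sigma,
        )[0]
        broken = quad(
            lambda u: expit(-beta * (broken_offset + u)) * halfnorm.pdf(u, scale=sigma),
            0.0,
            10 * sigma,
        )[0]
    return float(p * intact + (1.0 - p) * broken)


def simulate_distance_series(
    config: GeneratorConfig,
    contacts: ContactSet,
    params: ContactModelParams = ContactModelParams(),
) -> tuple[DistanceSeries, PlantedTruth]:
    """Per-contact Bernoulli intact/broken emission with planted truth.

    Each frame and contact is drawn independently: with probability p the
    contact is intact (distance = r0 + Normal(0, sigma), truncated
    positive), otherwise broken (distance = Lambda*r0 + broken_offset +
    |Normal(0, sigma)|). ``expected_r`` in the returned truth is the
    closed-form expectation of the trajectory R-value for these contacts.
    """
    rng = _rng(config.seed, "distances")
    n_contacts = contacts.n_contacts
    n_frames = config.n_frames * config.n_replicas
    p = np.broadcast_to(
        np.asarray(config.persistence, dtype=np.float64), (n_contacts,)
    )
    r0 = contacts.r0
    sigma = config.bound_noise_sigma
    intact = rng.random((n_frames, n_contacts)) < p[None, :]
    noise = rng.normal(0.0, sigma if sigma > 0 else 1.0, (n_frames, n_contacts))
    intact_d = r0[None, :] + (noise if sigma > 0 else 0.0)
    # truncate at a small positive floor (resampling is overkill at these sigmas)
    intact_d = np.maximum(intact_d, 1e-6)
    broken_noise = np.abs(
        rng.normal(0.0, sigma if sigma > 0 else 1.0, (n_frames, n_contacts))
    )
    broken_d = params.lam * r0[None, :] + config.broken_offset + (
        broken_noise if sigma > 0 else 0.0
    )
    values = np.where(intact, intact_d, broken_d)
    replica_ids = np.repeat(np.arange(config.n_replicas), config.n_frames)
    times = np.tile(np.arange(config.n_frames, dtype=np.float64) * 0.1, config.n_replicas)
    series = DistanceSeries(contacts.pair_indices, values, replica_ids, times)
    expected = float(
        np.mean(
            [
                expected_contact_term(p[c], r0[c], sigma, config.broken_offset, params)
                for c in range(n_contacts)
            ]
        )
    )
    truth = PlantedTruth(persistence=p.copy(), expected_r=expected, intact_mask=intact)
    return series, truth


def simulate_trajectory(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[Trajectory, PlantedTruth]:
    """Coordinate-level trajectory: rigid ligand jitter plus excursions.

    The protein stays at its reference position. Per frame the ligand is,
    with probability ``persistence`` (scalar), in-pocket (reference pose
    plus an isotropic rigid translation of scale ``bound_noise_sigma``),
    otherwise displaced ``excursion_offset`` A out of the pocket along a
    fixed direction. The fraction of in-pocket frames realizes the planted
    persistence; truth records the per-frame mask.
    """
    base = make_toy_complex(config)
    rng = _rng(config.seed, "trajectory")
    p = float(np.asarray(config.persistence, dtype=np.float64).mean())
    lig_mask = base.topology.is_ligand
    n_frames_total = config.n_frames * config.n_replicas
    coords = np.repeat(base.coords[None, :, :], n_frames_total, axis=0)
    in_pocket = rng.random(n_frames_total) < p
    # fixed escape direction: away from the pocket center through the ligand
    lig_center = base.coords[lig_mask].mean(axis=0)
    direction = lig_center - base.coords[~lig_mask].mean(axis=0)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    for f in range(n_frames_total):
        shift = rng.normal(0.0, config.bound_noise_sigma, 3)
        if not in_pocket[f]:
            shift = shift + config.excursion_offset * direction
        coords[f, lig_mask, :] += shift
    traj = Trajectory(
        topology=base.topology,
        coords=coords,
        replica_ids=np.repeat(np.arange(config.n_replicas), config.n_frames),
        times=np.tile(
            np.arange(config.n_frames, dtype=np.float64) * 0.1, config.n_replicas
        ),
        frame_indices=np.tile(np.arange(config.n_frames), config.n_replicas),
    )
    truth = PlantedTruth(
        persistence=np.array([p]), intact_mask=in_pocket, expected_r=None
    )
    return traj, truth


def jittered_trajectory(
    base: Structure, n_frames: int, sigma: float, seed: int = 0
) -> Trajectory:
    """All-atom isotropic Gaussian jitter around a base structure.

    A minimal fluctuation fixture: each coordinate gets independent
    Normal(0, sigma) noise per frame, so every atom's expected RMSF is
    sigma * sqrt(3).
    """
    rng = _rng(seed, "jitter")
    coords = base.coords[None, :, :] + rng.normal(
        0.0, sigma, (n_frames, base.topology.n_atoms, 3)
    )
    return Trajectory(
        topology=base.topology,
        coords=coords,
        replica_ids=np.zeros(n_frames, dtype=np.intp),
        times=np.arange(n_frames, dtype=np.float64) * 0.1,
    )


def make_decoy_poses(
    reference: Structure, offsets, direction=(1.0, 0.0, 0.0)
) -> tuple[list[Structure], PlantedTruth]:
    """Decoy poses with exactly planted ligand RMSD.

    Pose k translates every ligand atom rigidly by ``offsets[k]`` A along
    ``direction`` (protein fixed), so the post-superposition ligand RMSD
    equals the offset exactly.
    """
    offsets = np.asarray(offsets, dtype=np.float64)
    if np.any(offsets < 0):
        raise GenerationError("offsets must be >= 0")
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    lig_mask = reference.topology.is_ligand
    poses = []
    for off in offsets:
        coords = reference.coords.copy()
        coords[lig_mask] += off * d
        poses.append(Structure(reference.topology, coords))
    truth = PlantedTruth(planted_rmsd=offsets.copy())
    return poses, truth
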
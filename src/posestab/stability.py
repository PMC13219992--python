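"""Contact-persistence (R-value) scoring and its decompositions.

The R-value of a configuration X against a reference with native contacts
{(i, j)} is the mean over pairs of a smoothed step function,

    R = (1/N) * sum_ij 1 / (1 + exp(beta * (r_ij^X - Lambda * r_ij^0))),

with the smoothing parameter beta = 5.0 A^-1 and the contact-fluctuation
parameter Lambda = 1.8 by default. Each term is ~1 while a contact stays
within Lambda times its reference distance and decays to ~0 once it
breaks, so the trajectory average measures how persistently the reference
contact network survives the dynamics. The trajectory R-value is the
unweighted mean of per-frame values over the pooled analysis window.

Per-residue and per-ligand-atom decompositions regroup the same
frame-by-pair sigmoid terms: the per-residue R-value is the mean term over
that residue's contacts, its contribution is that mean times the contact
count (so contributions sum to N * R), and %Contribution normalizes the
contributions to 100 across residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .contacts import ContactSet, DistanceSeries, ReferenceMode
from .errors import ComparabilityError, DomainError, NoNativeContactsError
from .io import Topology

DEFAULT_BETA = 5.0  # A^-1, smoothing parameter
DEFAULT_LAMBDA = 1.8  # dimensionless contact-fluctuation parameter
STABLE_THRESHOLD = 0.85  # atom-map category bounds (three-color scheme)
LESS_STABLE_THRESHOLD = 0.70


@dataclass(frozen=True)
class ContactModelParams:
    """Parameters of the smoothed native-contact function."""

    beta: float = DEFAULT_BETA
    lam: float = DEFAULT_LAMBDA
    native_cutoff: float = 4.5

    def __post_init__(self):
        if self.beta <= 0:
            raise DomainError(f"beta must be positive, got {self.beta}")
        if self.lam < 1:
            raise DomainError(f"lambda must be >= 1, got {self.lam}")


@dataclass
class RValueResult:
    r_global: float
    per_frame_r: np.ndarray
    n_contacts: int
    reference_mode: ReferenceMode
    params: ContactModelParams


@dataclass
class ResidueStabilityMap:
    """Per-residue stability decomposition as a DataFrame.

    Columns: chain, resseq, icode, resname, r_residue, contact_count,
    contribution, pct_contribution.
    """

    table: pd.DataFrame
    n_contacts: int
    r_global: float


@dataclass
class AtomStabilityMap:
    """Per-ligand-heavy-atom stability categories.

    Columns: atom_index, atom_name, r_atom (NaN when no contacts),
    contact_count, category in {stable, less_stable, no_contact}.
    """

    table: pd.DataFrame
    thresholds: dict


def contact_term(rX, r0, params: ContactModelParams = ContactModelParams()):
    """Smoothed indicator 1 / (1 + exp(beta*(rX - Lambda*r0))), in (0, 1).

    Vectorized over ``rX``/``r0``. Uses a numerically stable sigmoid: the
    exponent can exceed 700 for unbound frames, which would overflow a
    naive ``exp``.
    """
    rX = np.asarray(rX, dtype=np.float64)
    r0 = np.asarray(r0, dtype=np.float64)
    if np.any(rX <= 0) or np.any(r0 <= 0):
        raise DomainError("distances must be positive")
    out = expit(params.beta * (params.lam * r0 - rX))
    return float(out) if out.ndim == 0 else out


def _terms_matrix(series: DistanceSeries, contacts: ContactSet, params) -> np.ndarray:
    """(frames, contacts) sigmoid terms; series must align with contacts.pairs."""
    if contacts.n_contacts == 0:
        raise NoNativeContactsError("contact set is empty")
    if series.n_pairs != contacts.n_contacts:
        raise ValueError(
            f"distance series has {series.n_pairs} pairs, contact set has "
            f"{contacts.n_contacts}"
        )
    return contact_term(series.values, contacts.r0[None, :], params)


def r_value_frame(
    frame_distances, contacts: ContactSet, params: ContactModelParams = ContactModelParams()
) -> float:
    """R-value of a single configuration: mean sigmoid term over native pairs."""
    if contacts.n_contacts == 0:
        raise NoNativeContactsError("contact set is empty")
    frame_distances = np.asarray(frame_distances, dtype=np.float64)
    if frame_distances.shape != (contacts.n_contacts,):
        raise ValueError("frame distances not aligned with contact pairs")
    return float(np.mean(contact_term(frame_distances, contacts.r0, params)))


def r_value_trajectory(
    series: DistanceSeries,
    contacts: ContactSet,
    params: ContactModelParams = ContactModelParams(),
) -> RValueResult:
    """Trajectory R-value: unweighted mean of per-frame R over pooled frames."""
    terms = _terms_matrix(series, contacts, params)
    per_frame = terms.mean(axis=1)
    return RValueResult(
        r_global=float(per_frame.mean()),
        per_frame_r=per_frame,
        n_contacts=contacts.n_contacts,
        reference_mode=contacts.reference_mode,
        params=params,
    )


def residue_stability_map(
    series: DistanceSeries,
    contacts: ContactSet,
    params: ContactModelParams,
    topology: Topology,
) -> ResidueStabilityMap:
    """Group contacts by protein residue and decompose the R-value.

    The per-residue R is the mean sigmoid term over that residue's
    (frame x pair) block; contribution = r_residue * contact_count, so the
    contributions sum exactly to N * r_global and %Contribution sums to 100.
    """
    terms = _terms_matrix(series, contacts, params)
    keys = [topology.residue_key(p.protein_atom) for p in contacts.pairs]
    order: dict[tuple, list[int]] = {}
    for col, key in enumerate(keys):
        order.setdefault(key, []).append(col)
    rows = []
    for key, cols in order.items():
        block = terms[:, cols]
        r_res = float(block.mean())
        rows.append(
            {
                "chain": key[0],
                "resseq": key[1],
                "icode": key[2],
                "resname": key[3],
                "r_residue": r_res,
                "contact_count": len(cols),
                "contribution": r_res * len(cols),
            }
        )
    df = pd.DataFrame(rows).sort_values(["chain", "resseq", "icode"], kind="stable")
    total = df["contribution"].sum()
    df["pct_contribution"] = 100.0 * df["contribution"] / total
    df = df.reset_index(drop=True)
    return ResidueStabilityMap(
        table=df, n_contacts=contacts.n_contacts, r_global=float(terms.mean())
    )


def atom_stability_map(
    series: DistanceSeries,
    contacts: ContactSet,
    params: ContactModelParams,
    topology: Topology,
    thresholds: dict | None = None,
) -> AtomStabilityMap:
    """Per-ligand-heavy-atom R-values with a three-way stability category.

    Ligand heavy atoms without any native contact get category
    ``no_contact`` and a NaN r_atom (reported as null in JSON exports).
    Threshold defaults (stable >= 0.85, less_stable >= 0.70) mirror a
    three-color stable / less-stable / unstable map and are configurable.
    """
    thresholds = dict(thresholds or {})
    stable = thresholds.setdefault("stable", STABLE_THRESHOLD)
    less = thresholds.setdefault("less_stable", LESS_STABLE_THRESHOLD)
    terms = _terms_matrix(series, contacts, params)
    by_atom: dict[int, list[int]] = {}
    for col, pair in enumerate(contacts.pairs):
        by_atom.setdefault(pair.ligand_atom, []).append(col)
    ligand_heavy = np.nonzero(topology.is_ligand & ~topology.is_hydrogen)[0]
    rows = []
    for atom in ligand_heavy:
        cols = by_atom.get(int(atom), [])
        if not cols:
            rows.append(
                {
                    "atom_index": int(atom),
                    "atom_name": str(topology.names[atom]),
                    "r_atom": float("nan"),
                    "contact_count": 0,
                    "category": "no_contact",
                }
            )
            continue
        r_atom = float(terms[:, cols].mean())
        category = "stable" if r_atom >= stable else ("less_stable" if r_atom >= less else "unstable")
        rows.append(
            {
                "atom_index": int(atom),
                "atom_name": str(topology.names[atom]),
                "r_atom": r_atom,
                "contact_count": len(cols),
                "category": category,
            }
        )
    return AtomStabilityMap(table=pd.DataFrame(rows), thresholds=thresholds)


def delta_r(analog: RValueResult, reference_compound: RValueResult) -> float:
    """Stability change of an analog relative to a reference compound.

    Both results must come from the same contact-model parameters,
    otherwise the difference is not comparable.
    """
    if analog.params != reference_compound.params:
        raise ComparabilityError("R-values computed with different parameters")
    return analog.r_global - reference_compound.r_global
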
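"""Four-way pose classification and docking-ensemble performance metrics.

A pose is judged on two axes: stability (trajectory R-value against the
threshold ``r_min``) and similarity to the experimental pose (ligand RMSD
against ``rmsd_max``). Both comparisons are strict, so boundary values
fall in the unfavorable class:

    SS  stable & similar      r > r_min  and rmsd <  rmsd_max
    SD  stable & dissimilar   r > r_min  and rmsd >= rmsd_max
    US  unstable & similar    r <= r_min and rmsd <  rmsd_max
    UD  unstable & dissimilar otherwise
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClassificationError, MetricError, SchemaError

LABELS = ("SS", "SD", "US", "UD")


@dataclass(frozen=True)
class Thresholds:
    """Stability / similarity cutoffs (defaults 0.70 and 3.0 A)."""

    r_min: float = 0.70
    rmsd_max: float = 3.0

    def __post_init__(self):
        if not 0 < self.r_min < 1:
            raise ValueError(f"r_min must be in (0, 1), got {self.r_min}")
        if self.rmsd_max <= 0:
            raise ValueError(f"rmsd_max must be positive, got {self.rmsd_max}")


@dataclass
class PoseRecord:
    system: str
    ligand: str
    pose_id: str
    r_value: float
    rmsd: float
    dock_rank: int | None = None  # 1 = docking-score top pose
    dock_rmsd: float | None = None  # initial docking RMSD to experimental pose
    label: str | None = None
    rank: int | None = None


@dataclass
class EnsembleSummary:
    system: str
    n_poses: int
    counts: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)


def classify_pose(r_value: float, rmsd: float, thresholds: Thresholds = Thresholds()) -> str:
    """Assign the SS/SD/US/UD label; strict inequalities on both axes."""
    if not (math.isfinite(r_value) and math.isfinite(rmsd)):
        raise ClassificationError(f"non-finite pose metrics: r={r_value}, rmsd={rmsd}")
    stable = r_value > thresholds.r_min
    similar = rmsd < thresholds.rmsd_max
    if stable:
        return "SS" if similar else "SD"
    return "US" if similar else "UD"


def classify_records(records: list[PoseRecord], thresholds: Thresholds = Thresholds()) -> list[PoseRecord]:
    """Label every record in place (and return the list)."""
    for rec in records:
        rec.label = classify_pose(rec.r_value, rec.rmsd, thresholds)
    return records


def rank_poses(records: list[PoseRecord]) -> list[PoseRecord]:
    """Rank poses within each ligand by R-value (descending).

    Ties break by lower RMSD, then lexicographic pose_id, so ranking is
    fully deterministic. Rank 1 is the most stable pose.
    """
    by_ligand: dict[tuple, list[PoseRecord]] = {}
    for rec in records:
        by_ligand.setdefault((rec.system, rec.ligand), []).append(rec)
    for group in by_ligand.values():
        group.sort(key=lambda r: (-r.r_value, r.rmsd, r.pose_id))
        for i, rec in enumerate(group, start=1):
            rec.rank = i
    return records


def summarize_labels(records: list[PoseRecord]) -> list[EnsembleSummary]:
    """Per-system label counts and percentages (percentages sum to 100)."""
    out = []
    by_system: dict[str, list[PoseRecord]] = {}
    for rec in records:
        if rec.label is None:
            raise ClassificationError("records must be classified first")
        by_system.setdefault(rec.system, []).append(rec)
    for system, group in by_system.items():
        counts = {lab: sum(r.label == lab for r in group) for lab in LABELS}
        n = len(group)
        pct = {lab: 100.0 * c / n for lab, c in counts.items()}
        out.append(EnsembleSummary(system=system, n_poses=n, counts=counts, percentages=pct))
    return out


def ensemble_metrics(
    records: list[PoseRecord], thresholds: Thresholds = Thresholds()
) -> dict:
    """Docking-ensemble performance per ligand, per system and globally.

    Per ligand (each ligand is one docking ensemble):

    - ``top1_hit``: the docking-score top pose (dock_rank == 1) already has
      initial RMSD < rmsd_max;
    - ``dock_success``: any pose in the ensemble has initial RMSD <
      rmsd_max (docking sampled a native-like pose somewhere);
    - ``rescued``: docking failed at top-1 but the R-value-ranked top pose
      is SS after MD — the stability criterion recovered a correct pose.

    Returns {"per_ligand": DataFrame, "per_system": DataFrame,
    "global": dict of rates in percent}.
    """
    classify_records(records, thresholds)
    rank_poses(records)
    by_ligand: dict[tuple, list[PoseRecord]] = {}
    for rec in records:
        by_ligand.setdefault((rec.system, rec.ligand), []).append(rec)
    rows = []
    for (system, ligand), group in sorted(by_ligand.items()):
        tops = [r for r in group if r.dock_rank == 1]
        if not tops:
            raise MetricError(f"ligand {ligand!r}: no pose with dock_rank == 1")
        if any(r.dock_rmsd is None for r in group):
            raise MetricError(f"ligand {ligand!r}: missing dock_rmsd values")
        top1_hit = tops[0].dock_rmsd < thresholds.rmsd_max
        dock_success = any(r.dock_rmsd < thresholds.rmsd_max for r in group)
        r_top = min(group, key=lambda r: r.rank)
        rescued = (not top1_hit) and r_top.label == "SS"
        rows.append(
            {
                "system": system,
                "ligand": ligand,
                "n_poses": len(group),
                "top1_hit": top1_hit,
                "dock_success": dock_success,
                "rescued": rescued,
                "r_top_pose": r_top.pose_id,
                "r_top_label": r_top.label,
            }
        )
    per_ligand = pd.DataFrame(rows)
    per_system = (
        per_ligand.groupby("system", sort=True)
        .agg(
            n_ligands=("ligand", "size"),
            top1_hit_rate=("top1_hit", lambda s: 100.0 * s.mean()),
            dock_success_rate=("dock_success", lambda s: 100.0 * s.mean()),
            n_rescued=("rescued", "sum"),
            n_top1_failures=("top1_hit", lambda s: int((~s).sum())),
        )
        .reset_index()
    )
    failures = int((~per_ligand["top1_hit"]).sum())
    global_rates = {
        "n_ligands": int(len(per_ligand)),
        "top1_hit_rate": 100.0 * per_ligand["top1_hit"].mean(),
        "dock_success_rate": 100.0 * per_ligand["dock_success"].mean(),
        "n_rescued": int(per_ligand["rescued"].sum()),
        "n_top1_failures": failures,
        "rescue_rate": (
            100.0 * per_ligand["rescued"].sum() / failures if failures else float("nan")
        ),
    }
    return {"per_ligand": per_ligand, "per_system": per_system, "global": global_rates}


def threshold_grid(
    records: list[PoseRecord], r_grid, rmsd_grid
) -> pd.DataFrame:
    """Sensitivity of %SS to the two thresholds.

    For each (r_min, rmsd_max) cell: the global %SS over all poses, each
    system's %SS, and delta_pct_ss = per-system %SS minus global %SS (a
    dispersion measure; its absolute value is reported alongside).

    Returns a tidy DataFrame with one row per (cell, system).
    """
    if len(r_grid) == 0 or len(rmsd_grid) == 0:
        raise ValueError("threshold grids must be non-empty")
    r_vals = np.array([r.r_value for r in records])
    rmsd_vals = np.array([r.rmsd for r in records])
    systems = np.array([r.system for r in records])
    rows = []
    for r_min in r_grid:
        for rmsd_max in rmsd_grid:
            ss = (r_vals > r_min) & (rmsd_vals < rmsd_max)
            global_pct = 100.0 * ss.mean()
            for system in sorted(set(systems)):
                mask = systems == system
                sys_pct = 100.0 * ss[mask].mean()
                rows.append(
                    {
                        "r_min": r_min,
                        "rmsd_max": rmsd_max,
                        "system": system,
                        "pct_ss_system": sys_pct,
                        "pct_ss_global": global_pct,
                        "delta_pct_ss": sys_pct - global_pct,
                        "abs_delta_pct_ss": abs(sys_pct - global_pct),
                    }
                )
    return pd.DataFrame(rows)


POSE_TSV_COLUMNS = ("system", "ligand", "pose_id", "r_value", "rmsd")


def records_from_frame(df: pd.DataFrame) -> list[PoseRecord]:
    """Build PoseRecords from a TSV-derived DataFrame; names missing columns."""
    missing = [c for c in POSE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pose table missing columns: {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PoseRecord(
                system=str(row.system),
                ligand=str(row.ligand),
                pose_id=str(row.pose_id),
                r_value=float(row.r_value),
                rmsd=float(row.rmsd),
                dock_rank=int(row.dock_rank) if hasattr(row, "dock_rank") and not pd.isna(row.dock_rank) else None,
                dock_rmsd=float(row.dock_rmsd) if hasattr(row, "dock_rmsd") and not pd.isna(row.dock_rmsd) else None,
            )
        )
    return records
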
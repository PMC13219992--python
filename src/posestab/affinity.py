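"""Affinity handling: Kd -> pKd, native-like filtering, Pearson correlation.

The stability-affinity analysis correlates trajectory R-values (computed
against experimental reference poses) with experimental dissociation
constants on the pKd = -log10(Kd [M]) scale. Complexes whose R-value falls
below the native-like threshold (0.70 by default, strict <) are excluded
first: an unstable complex does not report on the native binding mode.
IC50 and Ki measurements are not directly comparable to Kd and are only
admitted when explicitly requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SchemaError, UndefinedCorrelationError

NATIVE_LIKE_R_MIN = 0.70

#: accepted concentration units -> factor to molar
UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


@dataclass(frozen=True)
class AffinityRecord:
    ligand: str
    kd: float  # molar
    source: str = ""
    metric: str = "Kd"  # Kd | IC50 | Ki

    @property
    def pkd(self) -> float:
        return pkd_from_kd(self.kd)


@dataclass
class CorrelationResult:
    pearson_r: float
    n_used: int
    excluded: list = field(default_factory=list)  # (ligand, reason)


def pkd_from_kd(kd: float) -> float:
    """pKd = -log10(Kd in molar); strictly decreasing in Kd."""
    if kd <= 0 or not math.isfinite(kd):
        raise DomainError(f"Kd must be positive and finite, got {kd}")
    return -math.log10(kd)


def kd_to_molar(value: float, unit: str) -> float:
    """Convert a Kd in a named unit (M, mM, uM, nM, pM) to molar."""
    try:
        return value * UNIT_TO_MOLAR[unit]
    except KeyError:
        raise SchemaError(f"unknown concentration unit {unit!r}") from None


def read_affinities(df: pd.DataFrame, include_non_kd: bool = False) -> list[AffinityRecord]:
    """Build AffinityRecords from a table with columns ligand, value, unit.

    Optional columns: metric (Kd/IC50/Ki, default Kd) and source. Non-Kd
    metrics are dropped unless ``include_non_kd`` is set.
    """
    for col in ("ligand", "value", "unit"):
        if col not in df.columns:
            raise SchemaError(f"affinity table missing column: {col}")
    records = []
    for row in df.itertuples(index=False):
        metric = str(getattr(row, "metric", "Kd") or "Kd")
        if metric != "Kd" and not include_non_kd:
            continue
        records.append(
            AffinityRecord(
                ligand=str(row.ligand),
                kd=kd_to_molar(float(row.value), str(row.unit)),
                source=str(getattr(row, "source", "")),
                metric=metric,
            )
        )
    return records


def filter_native_like(
    r_values: dict[str, float], r_min: float = NATIVE_LIKE_R_MIN
) -> tuple[dict[str, float], list[tuple[str, str]]]:
    """Partition ligands into native-like and excluded (r_value < r_min).

    The exclusion is strict: a ligand at exactly the threshold is retained.
    Returns (used mapping, excluded list of (ligand, reason)).
    """
    used, excluded = {}, []
    for ligand, r in r_values.items():
        if r < r_min:
            excluded.append((ligand, f"non-native-like (R={r:.3g} < {r_min})"))
        else:
            used[ligand] = r
    return used, excluded


def correlate(x, y, excluded=None) -> CorrelationResult:
    """Sample Pearson correlation with missing-pair handling.

    Pairs with NaN on either side are dropped and recorded. Requires at
    least three complete pairs and non-zero variance on both axes.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    excluded = list(excluded or [])
    mask = np.isfinite(x) & np.isfinite(y)
    for i in np.nonzero(~mask)[0]:
        excluded.append((int(i), "missing value"))
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 complete pairs, got {len(x)}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the series")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(pearson_r=r, n_used=int(len(x)), excluded=excluded)


def affinity_correlation(
    r_values: dict[str, float],
    affinities: list[AffinityRecord],
    r_min: float = NATIVE_LIKE_R_MIN,
    exclude_ligands=(),
) -> CorrelationResult:
    """Global R-value vs pKd Pearson correlation with native-like filtering.

    ``exclude_ligands`` is a user-supplied outlier list (never automatic);
    excluded ligands are recorded with their reason.
    """
    used, excluded = filter_native_like(r_values, r_min)
    for lig in exclude_ligands:
        if lig in used:
            used.pop(lig)
            excluded.append((lig, "user-excluded"))
    pkd_by_ligand = {a.ligand: a.pkd for a in affinities if a.metric == "Kd"}
    xs, ys = [], []
    for ligand, r in sorted(used.items()):
        if ligand not in pkd_by_ligand:
            excluded.append((ligand, "no Kd measurement"))
            continue
        xs.append(r)
        ys.append(pkd_by_ligand[ligand])
    result = correlate(xs, ys)
    result.excluded = excluded + result.excluded
    return result


def per_residue_correlation(
    maps: dict[str, pd.DataFrame],
    affinities: list[AffinityRecord],
    min_ligands: int = 3,
) -> pd.DataFrame:
    """Residue-wise Pearson correlation of stability metrics against pKd.

    ``maps`` maps ligand -> per-residue stability table (columns chain,
    resseq, icode, resname, r_residue, contribution). For every residue
    present in at least ``min_ligands`` ligands with a Kd, two correlations
    are computed: r_residue vs pKd and contribution vs pKd. Residues seen
    in fewer ligands, or with zero variance, are flagged instead of
    reported as numbers.

    Returns a DataFrame with columns chain, resseq, icode, resname,
    n_ligands, pearson_r_residue, pearson_contribution, status.
    """
    pkd_by_ligand = {a.ligand: a.pkd for a in affinities if a.metric == "Kd"}
    per_residue: dict[tuple, dict[str, tuple[float, float]]] = {}
    for ligand, table in maps.items():
        if ligand not in pkd_by_ligand:
            continue
        for row in table.itertuples(index=False):
            key = (row.chain, row.resseq, row.icode, row.resname)
            per_residue.setdefault(key, {})[ligand] = (row.r_residue, row.contribution)
    rows = []
    for key in sorted(per_residue):
        entries = per_residue[key]
        row = {
            "chain": key[0],
            "resseq": key[1],
            "icode": key[2],
            "resname": key[3],
            "n_ligands": len(entries),
            "pearson_r_residue": float("nan"),
            "pearson_contribution": float("nan"),
            "status": "ok",
        }
        if len(entries) < min_ligands:
            row["status"] = "insufficient"
        else:
            ligands = sorted(entries)
            pkds = [pkd_by_ligand[l] for l in ligands]
            for metric_idx, col in ((0, "pearson_r_residue"), (1, "pearson_contribution")):
                vals = [entries[l][metric_idx] for l in ligands]
                try:
                    row[col] = correlate(vals, pkds).pearson_r
                except UndefinedCorrelationError:
                    row["status"] = "zero-variance"
        rows.append(row)
    return pd.DataFrame(rows)
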
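"""Interaction-enthalpy bookkeeping over supplied total energies.

The interaction enthalpy of a dimer structure is E_i = E(complex) − E(A) −
E(B).  Per-cluster statistics use the sample standard deviation (n−1), the
reference cluster is the one with the lowest mean E_i, and relative
enthalpies are mean differences against it.  This module consumes energies
as input numbers; producing them (e.g. by electronic-structure codes) is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnergyRecord",
    "EnthalpyStats",
    "interaction_enthalpy",
    "cluster_enthalpy_stats",
    "association_table",
    "read_energy_csv",
]


@dataclass(frozen=True)
class EnergyRecord:
    cluster_id: str
    structure_id: str
    e_complex: float  # kcal/mol
    e_a: float
    e_b: float

    def __post_init__(self) -> None:
        for v in (self.e_complex, self.e_a, self.e_b):
            if not np.isfinite(v):
                raise ValueError("energies must be finite")


@dataclass
class EnthalpyStats:
    cluster_id: str
    n_structures: int
    mean_ei: float  # kcal/mol
    sd_ei: float
    sd_percent: float | None  # 100·sd/|mean|; None when mean is 0
    relative_to_ref: float  # kcal/mol; 0 for the reference cluster


def interaction_enthalpy(r: EnergyRecord) -> float:
    """E_i = E(complex) − E(A) − E(B), kcal/mol."""
    return r.e_complex - r.e_a - r.e_b


def cluster_enthalpy_stats(records: Sequence[EnergyRecord]) -> list[EnthalpyStats]:
    """Per-cluster mean ± sd interaction enthalpy, relative to the most
    stable (lowest-mean) cluster.  Ordered by cluster id."""
    if not records:
        raise ValueError("no energy records")
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.cluster_id, []).append(interaction_enthalpy(r))
    means = {c: float(np.mean(v)) for c, v in groups.items()}
    ref_mean = min(means.values())
    stats = []
    for cid in sorted(groups):
        vals = np.asarray(groups[cid])
        mean = means[cid]
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        sd_pct = 100.0 * sd / abs(mean) if mean != 0 else None
        stats.append(
            EnthalpyStats(
                cluster_id=cid,
                n_structures=int(vals.size),
                mean_ei=mean,
                sd_ei=sd,
                sd_percent=sd_pct,
                relative_to_ref=mean - ref_mean,
            )
        )
    return stats


def association_table(
    stats: Sequence[EnthalpyStats],
    cluster_populations: Mapping[str, float],
    contact_areas: Mapping[str, float],
    delta_gs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Association-pathway summary: one row per cluster with population %,
    mean ± sd E_i, relative E_i, hydrophobic contact area and (where
    available) the PMF dissociation ΔG; ordered by relative E_i ascending.
    """
    ids = [s.cluster_id for s in stats]
    missing = [c for c in ids if c not in cluster_populations] + [
        c for c in ids if c not in contact_areas
    ]
    if missing:
        raise KeyError(f"clusters missing populations/areas: {sorted(set(missing))}")
    rows = []
    for s in stats:
        rows.append(
            {
                "cluster_id": s.cluster_id,
                "population_percent": float(cluster_populations[s.cluster_id]),
                "mean_ei_kcal_mol": s.mean_ei,
                "sd_ei_kcal_mol": s.sd_ei,
                "sd_percent": s.sd_percent,
                "relative_ei_kcal_mol": s.relative_to_ref,
                "contact_area_A2": float(contact_areas[s.cluster_id]),
                "delta_g_kcal_mol": (
                    float(delta_gs[s.cluster_id])
                    if delta_gs is not None and s.cluster_id in delta_gs
                    else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "relative_ei_kcal_mol", kind="stable", ignore_index=True
    )
    return df


def read_energy_csv(path) -> list[EnergyRecord]:
    """Input CSV columns: cluster_id, structure_id, e_complex, e_A, e_B."""
    df = pd.read_csv(path)
    required = {"cluster_id", "structure_id", "e_complex", "e_A", "e_B"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"energy CSV missing columns: {sorted(required - set(df.columns))}"
        )
    return [
        EnergyRecord(
            cluster_id=str(r["cluster_id"]),
            structure_id=str(r["structure_id"]),
            e_complex=float(r["e_complex"]),
            e_a=float(r["e_A"]),
            e_b=float(r["e_B"]),
        )
        for _, r in df.iterrows()
    ]
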
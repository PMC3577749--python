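"""Orchestration of the full ensemble analysis into a single JSON report.

The report mirrors the result set of a dimer-ensemble study: cluster table,
per-chain hydrogen-bond summaries, secondary-structure fractions, ring
orientation statistics, the shape landscape with basins, and optional
interaction-enthalpy bookkeeping.  Output is deterministic for a fixed
configuration and seed (sorted keys, no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .clustering import pairwise_rmsd_matrix, select_cutoff
from .energetics import cluster_enthalpy_stats, read_energy_csv
from .hbonds import (
    HBondCriteria,
    existence_profile,
    mean_hbonds_per_frame,
    persistent_bonds,
    secondary_structure_timeline,
)
from .landscape import (
    angle_histogram,
    density_grid,
    find_basins,
    fraction_same_side,
    place_representatives,
    ring_angle_series,
    shape_series,
)
from .trajectory import DimerSpec, Trajectory, select_atoms

__all__ = ["AnalysisConfig", "run_analysis", "write_report"]


@dataclass
class AnalysisConfig:
    cutoff_candidates: list[float] = field(default_factory=lambda: [2.0])
    max_clusters: int = 10
    max_top_fraction: float = 30.0
    cluster_stride: int = 1
    hbond_d_max: float = 3.5
    hbond_theta_max: float = 30.0
    persistence_threshold: float = 0.5
    angle_bins: int = 41
    landscape_x_bin: float = 0.05
    landscape_y_bin: float = 0.025
    basin_min_population: float = 5.0
    energetics_csv: str | None = None
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def run_analysis(
    traj: Trajectory,
    spec: DimerSpec,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run clustering → H-bonds → secondary structure → landscape →
    (optional) energetics and return the report dictionary."""
    config = config or AnalysisConfig()
    criteria = HBondCriteria(d_max=config.hbond_d_max, theta_max=config.hbond_theta_max)
    report: dict[str, Any] = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
            "n_frames": traj.n_frames,
            "n_atoms": traj.n_atoms,
        }
    }

    # --- clustering over the full-complex backbone
    backbone = np.concatenate(
        [
            select_atoms(traj, spec.chain_linear, names=spec.backbone_names),
            select_atoms(traj, spec.chain_cyclic, names=spec.backbone_names),
        ]
    )
    matrix = pairwise_rmsd_matrix(
        traj, backbone, stride=config.cluster_stride, subset_tag="complex-backbone"
    )
    cutoff, clusters = select_cutoff(
        matrix,
        config.cutoff_candidates,
        max_clusters=config.max_clusters,
        max_top_fraction=config.max_top_fraction,
    )
    report["clusters"] = {
        "cutoff_A": cutoff,
        "n_clusters": clusters.n_clusters,
        "populations_percent": clusters.populations,
        "representative_frames": clusters.representatives,
        "labels": clusters.labels,
    }

    # --- hydrogen bonds and secondary structure, per chain
    hb: dict[str, Any] = {}
    ss: dict[str, Any] = {}
    for name, chain in (
        ("linear", spec.chain_linear),
        ("cyclic", spec.chain_cyclic),
    ):
        profile = existence_profile(traj, criteria, scope=chain)
        hb[name] = {
            "mean_per_frame": mean_hbonds_per_frame(profile)
            if profile.n_frames
            else 0.0,
            "n_distinct_bonds": len(profile.keys),
            "persistent": [
                {"bond": str(k), "persistence": float(profile.persistence[profile.keys.index(k)])}
                for k in persistent_bonds(profile, config.persistence_threshold)
            ],
        }
        timeline = secondary_structure_timeline(traj, chain)
        codes, counts = np.unique(timeline, return_counts=True)
        ss[name] = {
            str(c): float(100.0 * n / timeline.size)
            for c, n in zip(codes, counts)
        }
    report["hbonds"] = hb
    report["secondary_structure_percent"] = ss

    # --- ring orientation, per chain
    rings: dict[str, Any] = {}
    for name, chain in (
        ("linear", spec.chain_linear),
        ("cyclic", spec.chain_cyclic),
    ):
        series = ring_angle_series(traj, spec, chain)
        hist = angle_histogram(series, n_bins=config.angle_bins)
        rings[name] = {
            "same_side_percent": fraction_same_side(series),
            "peak_angle_deg": float(hist.bin_centers[int(np.argmax(hist.percent))]),
            "histogram_percent": hist.percent,
            "bin_centers_deg": hist.bin_centers,
        }
    report["ring_orientation"] = rings

    # --- D_N-C vs R_g landscape of the linear chain
    series = shape_series(traj, spec, spec.chain_linear)
    grid = density_grid(
        series, x_bin=config.landscape_x_bin, y_bin=config.landscape_y_bin
    )
    basins = find_basins(grid, min_population=config.basin_min_population)
    reps = place_representatives(series, clusters)
    report["landscape"] = {
        "basins": [
            {
                "d_nc_nm": b.center[0],
                "r_g_nm": b.center[1],
                "population_percent": b.population,
            }
            for b in basins
        ],
        "representative_positions_nm": reps,
    }

    # --- optional enthalpy bookkeeping from a supplied CSV
    if config.energetics_csv is not None:
        records = read_energy_csv(config.energetics_csv)
        stats = cluster_enthalpy_stats(records)
        report["energetics"] = [
            {
                "cluster_id": s.cluster_id,
                "n_structures": s.n_structures,
                "mean_ei_kcal_mol": s.mean_ei,
                "sd_ei_kcal_mol": s.sd_ei,
                "sd_percent": s.sd_percent,
                "relative_ei_kcal_mol": s.relative_to_ref,
            }
            for s in stats
        ]
    else:
        report["energetics"] = {"skipped": "no energy CSV supplied"}
    return _jsonable(report)


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json (sorted keys) plus CSV side-products."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
        fh.write("\n")
    labels = report.get("clusters", {}).get("labels")
    if labels is not None:
        pd.DataFrame({"frame": range(len(labels)), "cluster": labels}).to_csv(
            out / "cluster_labels.csv", index=False
        )
    return path
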
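"""Umbrella-sampling analysis: self-consistent WHAM, dissociation free
energy, and the aromatic-contact vs center-of-mass-separation profile.

Windows carry harmonic (Hookean) biases w_i(ξ) = ½ k (ξ − ξ_i)².  The
weighted histogram analysis method iterates

    P(b)        = Σ_i n_i(b) / Σ_i N_i exp(−β (w_i(b) − f_i))
    exp(−β f_i) = Σ_b P(b) exp(−β w_i(b))

to self-consistency from f_i = 0, with the gauge pinned by f_1 = 0.  The
PMF is −k_B T ln P(b), shifted so its minimum over populated bins is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._tables import KB_KCAL_MOL_K
from .errors import WHAMError
from .geometry import center_of_mass, min_contact_distance
from .trajectory import DimerSpec, Trajectory, chain_indices

logger = logging.getLogger(__name__)

__all__ = [
    "UmbrellaWindow",
    "WHAMResult",
    "DissociationEstimate",
    "bias_energy",
    "wham_solve",
    "dissociation_delta_g",
    "contact_vs_com_profile",
    "pmf_rms_error",
    "read_window_metadata",
    "write_windows",
]


@dataclass
class UmbrellaWindow:
    """One biased simulation window: harmonic restraint plus its samples."""

    center: float  # Å
    k: float  # kcal/mol/Å²
    samples: np.ndarray  # reaction-coordinate values, Å
    label: str = ""

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("force constant must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 1 or not np.isfinite(self.samples).all():
            raise ValueError("window needs at least one finite sample")


@dataclass
class WHAMResult:
    bin_centers: np.ndarray  # Å
    pmf: np.ndarray  # kcal/mol; NaN on unpopulated bins
    f_i: np.ndarray  # per-window free-energy constants, kcal/mol (f_1 = 0)
    n_samples: np.ndarray  # pooled sample count per bin
    n_iter: int
    converged: bool
    temperature: float  # K

    @property
    def populated(self) -> np.ndarray:
        return self.n_samples > 0


@dataclass
class DissociationEstimate:
    delta_g: float  # kcal/mol
    plateau_value: float  # kcal/mol
    plateau_range: tuple[float, float]  # Å
    min_location: float  # Å


def bias_energy(w: UmbrellaWindow, xi: float | np.ndarray):
    """Harmonic bias ½ k (ξ − ξ₀)² in kcal/mol."""
    return 0.5 * w.k * (np.asarray(xi, dtype=float) - w.center) ** 2


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 0.05,
    temperature: float = 300.0,
    tol: float = 1e-6,
    max_iter: int = 100000,
) -> WHAMResult:
    """Combine umbrella windows into an unbiased PMF.

    Convergence is max |Δf_i| ≤ ``tol`` between sweeps; failure to converge
    is flagged, not raised.  Disjoint sampled regions (a gap of three or
    more empty bins between populated runs) raise :class:`WHAMError`.
    """
    if len(windows) < 1:
        raise WHAMError("need at least one umbrella window")
    beta = 1.0 / (KB_KCAL_MOL_K * temperature)
    allsamp = np.concatenate([w.samples for w in windows])
    lo = np.floor(allsamp.min() / bin_width) * bin_width
    hi = np.ceil(allsamp.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    centers = 0.5 * (edges[:-1] + edges[1:])
    nb = len(centers)
    nw = len(windows)

    counts = np.stack(
        [np.histogram(w.samples, bins=edges)[0] for w in windows]
    ).astype(float)  # (nw, nb)
    n_tot = counts.sum(axis=0)
    n_i = counts.sum(axis=1)  # samples per window

    occupied = n_tot > 0
    _check_islands(occupied, centers)
    for a, b in zip(windows[:-1], windows[1:]):
        occ_a = np.histogram(a.samples, bins=edges)[0] > 0
        occ_b = np.histogram(b.samples, bins=edges)[0] > 0
        if not np.any(occ_a & occ_b):
            logger.warning(
                "adjacent windows %r and %r share no bins", a.label, b.label
            )

    # bin-averaged Boltzmann factors of the bias (8-point midpoint
    # quadrature): evaluating the bias only at bin centers biases the
    # estimate wherever a window's samples sit far from its center
    quad = (np.arange(8) + 0.5) / 8.0 - 0.5
    pts = centers[None, :, None] + bin_width * quad[None, None, :]
    bias_pts = np.stack(
        [bias_energy(w, pts[0]) for w in windows]
    )  # (nw, nb, 8)
    m = (-beta * bias_pts).max(axis=2)
    log_boltz = m + np.log(
        np.mean(np.exp(-beta * bias_pts - m[:, :, None]), axis=2)
    )  # log of bin-averaged exp(-beta w), (nw, nb)
    f = np.zeros(nw)
    n_iter = 0
    converged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        for n_iter in range(1, max_iter + 1):
            # P(b) = Σ_i n_i(b) / Σ_i N_i exp(−β(w_i(b) − f_i))
            denom = np.einsum(
                "i,ib->b", n_i, np.exp(log_boltz + beta * f[:, None])
            )
            p = np.where(occupied, n_tot / denom, 0.0)
            # e^{−β f_i} = Σ_b P(b) e^{−β w_i(b)}
            z = np.einsum("b,ib->i", p, np.exp(log_boltz))
            f_new = -np.log(z) / beta
            f_new -= f_new[0]  # pin the gauge
            delta = float(np.max(np.abs(f_new - f)))
            f = f_new
            if delta <= tol:
                converged = True
                break
        p = p / p[occupied].sum()
        pmf = np.where(occupied, -np.log(np.where(occupied, p, 1.0)) / beta, np.nan)
    pmf -= np.nanmin(pmf)
    if not converged:
        logger.warning("WHAM did not converge in %d iterations", max_iter)
    return WHAMResult(
        bin_centers=centers,
        pmf=pmf,
        f_i=f,
        n_samples=n_tot,
        n_iter=n_iter,
        converged=converged,
        temperature=temperature,
    )


def _check_islands(occupied: np.ndarray, centers: np.ndarray, max_gap: int = 2):
    """Raise when populated bins split into islands separated by > max_gap
    empty bins."""
    occ_idx = np.where(occupied)[0]
    if occ_idx.size == 0:
        raise WHAMError("no populated bins")
    gaps = np.diff(occ_idx)
    bad = np.where(gaps > max_gap + 1)[0]
    if bad.size:
        i = occ_idx[bad[0]]
        j = occ_idx[bad[0] + 1]
        raise WHAMError(
            "disjoint sampling islands: no samples between "
            f"{centers[i]:.3f} Å and {centers[j]:.3f} Å"
        )


def dissociation_delta_g(
    result: WHAMResult,
    slope_tol: float = 0.05,
    tail_fraction: float = 0.2,
) -> DissociationEstimate:
    """Dissociation free energy from the plateau of the PMF.

    The plateau is the longest terminal run of populated bins within the
    last ``tail_fraction`` of the sampled range whose finite-difference
    slope magnitude stays within ``slope_tol`` kcal/mol/Å; slopes are
    measured on a lightly smoothed profile (≈0.5 Å moving average) so that
    bin-level statistical noise does not mask a genuine plateau.  ΔG is the
    plateau mean (the PMF minimum is the zero of the profile).
    """
    pop = result.populated
    if pop.sum() < 10:
        raise WHAMError("too few populated bins for a plateau estimate")
    # drop sparsely sampled edge bins: their PMF noise is not meaningful
    counts = result.n_samples[pop]
    well_sampled = counts >= 0.25 * np.median(counts)
    centers = result.bin_centers[pop][well_sampled]
    pmf = result.pmf[pop][well_sampled]
    span = centers[-1] - centers[0]
    tail_start = centers[-1] - tail_fraction * span
    bw = float(np.median(np.diff(centers)))
    win = max(3, int(round(0.5 / bw)) | 1)
    smooth = (
        pd.Series(pmf).rolling(win, center=True, min_periods=1).mean().to_numpy()
    )
    # slope from a ±0.25 Å central-difference stencil of the smoothed
    # profile: single-bin differences are dominated by counting noise
    k = max(1, int(round(0.25 / bw)))
    hi = np.minimum(np.arange(len(smooth)) + k, len(smooth) - 1)
    lo = np.maximum(np.arange(len(smooth)) - k, 0)
    slopes = (smooth[hi] - smooth[lo]) / (centers[hi] - centers[lo])
    # trim the terminal bins where the one-sided smoothing window biases
    # the slope estimate
    trim = max(k, win // 2)
    if len(pmf) > 2 * trim + 10:
        centers, pmf, slopes = centers[:-trim], pmf[:-trim], slopes[:-trim]
    flat = (np.abs(slopes) <= slope_tol) & (centers >= tail_start)
    # longest run ending at the last bin
    run_end = len(pmf)
    run_start = run_end
    for i in range(len(pmf) - 1, -1, -1):
        if flat[i]:
            run_start = i
        else:
            break
    if run_end - run_start < 3:
        raise WHAMError(
            "no terminal plateau found; extend the sampled range"
        )
    plateau = float(np.mean(pmf[run_start:run_end]))
    return DissociationEstimate(
        delta_g=plateau,
        plateau_value=plateau,
        plateau_range=(float(centers[run_start]), float(centers[-1])),
        min_location=float(centers[int(np.argmin(pmf))]),
    )


def pmf_rms_error(
    result: WHAMResult,
    reference: Callable[[np.ndarray], np.ndarray],
    min_count: int = 50,
    max_ref_pmf: float = 10.0,
) -> float:
    """RMS deviation (kcal/mol) between the recovered PMF and a reference
    PMF callable after optimal constant-offset alignment.

    Scored over bins holding at least ``min_count`` pooled samples and lying
    in the thermally accessible range (reference within ``max_ref_pmf``
    kcal/mol of its minimum): outside it the reference slope exceeds what a
    fixed-width histogram can resolve and no binned estimator is meaningful.
    """
    mask = result.n_samples >= min_count
    if mask.sum() < 2:
        raise WHAMError("too few well-sampled bins for an RMS comparison")
    ref_all = np.asarray(reference(result.bin_centers), dtype=float)
    mask &= ref_all <= np.min(ref_all[np.isfinite(ref_all)]) + max_ref_pmf
    if mask.sum() < 2:
        raise WHAMError("too few bins inside the comparison range")
    diff = result.pmf[mask] - ref_all[mask]
    diff -= diff.mean()
    return float(np.sqrt(np.mean(diff**2)))


def binned_reference_pmf(
    potential: Callable[[np.ndarray], np.ndarray],
    temperature: float = 300.0,
    oversample: int = 32,
) -> Callable[[np.ndarray], np.ndarray]:
    """Discretized Boltzmann reference: −k_BT ln of the bin-averaged
    e^{−βU}, evaluated on the same grid as the recovered PMF.  This is the
    exact large-sample limit of a histogram PMF and the right oracle for
    bin-center comparisons on steep potentials."""
    beta = 1.0 / (KB_KCAL_MOL_K * temperature)

    def ref(centers: np.ndarray) -> np.ndarray:
        centers = np.asarray(centers, dtype=float)
        if centers.size > 1:
            width = float(np.median(np.diff(np.sort(centers))))
        else:
            width = 0.05
        offsets = (np.arange(oversample) + 0.5) / oversample - 0.5
        grid = centers[:, None] + width * offsets[None, :]
        u = np.asarray(potential(grid), dtype=float)
        u0 = u.min()
        avg = np.mean(np.exp(-beta * (u - u0)), axis=1)
        return u0 - np.log(avg) / beta

    return ref


def contact_vs_com_profile(
    traj: Trajectory, spec: DimerSpec, window: int = 21
) -> pd.DataFrame:
    """Per frame: center-of-mass separation of the two chains vs minimum
    contact distance between their aromatic ring heavy atoms, plus a
    centered moving average over ``window`` points after sorting by
    separation.  Columns: com_separation_A, min_contact_A, moving_avg_A.
    """
    idx_a = chain_indices(traj.topology, spec.chain_linear)
    idx_b = chain_indices(traj.topology, spec.chain_cyclic)
    masses = traj.masses()

    def ring_atoms(chain: str) -> np.ndarray:
        residues = set(spec.ring_residues[chain])
        out = [
            i
            for i, a in enumerate(traj.topology)
            if a.chain_id == chain
            and a.res_seq in residues
            and a.name in spec.ring_atom_names.get(a.res_name, ())
        ]
        if not out:
            raise WHAMError(f"no aromatic ring atoms found in chain {chain!r}")
        return np.array(out, dtype=int)

    ring_a = ring_atoms(spec.chain_linear)
    ring_b = ring_atoms(spec.chain_cyclic)

    com_sep = np.empty(traj.n_frames)
    contact = np.empty(traj.n_frames)
    for fidx in range(traj.n_frames):
        c = traj.coords[fidx]
        com_a = center_of_mass(c[idx_a], masses[idx_a])
        com_b = center_of_mass(c[idx_b], masses[idx_b])
        com_sep[fidx] = np.linalg.norm(com_a - com_b)
        contact[fidx] = min_contact_distance(c, ring_a, ring_b)
    df = pd.DataFrame(
        {"com_separation_A": com_sep, "min_contact_A": contact}
    ).sort_values("com_separation_A", kind="stable", ignore_index=True)
    df["moving_avg_A"] = (
        df["min_contact_A"].rolling(window, center=True, min_periods=1).mean()
    )
    return df


# ---------------------------------------------------------------------------
# Window file I/O (CSV metadata + one-coordinate-per-line sample files)


def write_windows(windows: Sequence[UmbrellaWindow], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(windows):
        label = w.label or f"window_{i:03d}"
        sample_file = out / f"{label}.dat"
        np.savetxt(sample_file, w.samples, fmt="%.6f")
        rows.append(
            {
                "label": label,
                "center_A": w.center,
                "k_kcal_mol_A2": w.k,
                "samples_path": sample_file.name,
            }
        )
    meta = out / "windows.csv"
    pd.DataFrame(rows).to_csv(meta, index=False)
    return meta


def read_window_metadata(meta_path: str | Path) -> list[UmbrellaWindow]:
    meta_path = Path(meta_path)
    df = pd.read_csv(meta_path)
    required = {"label", "center_A", "k_kcal_mol_A2", "samples_path"}
    if not required.issubset(df.columns):
        raise WHAMError(
            f"window metadata missing columns: {sorted(required - set(df.columns))}"
        )
    windows = []
    for i, row in df.iterrows():
        try:
            samples = np.loadtxt(meta_path.parent / str(row["samples_path"]))
            windows.append(
                UmbrellaWindow(
                    center=float(row["center_A"]),
                    k=float(row["k_kcal_mol_A2"]),
                    samples=np.atleast_1d(samples),
                    label=str(row["label"]),
                )
            )
        except (OSError, ValueError) as exc:
            raise WHAMError(f"malformed window metadata row {i}: {exc}") from exc
    return windows
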
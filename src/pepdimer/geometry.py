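"""Core structural measures.

Optimal rigid-body superposition (Kabsch), RMSD after fitting, radius of
gyration, end-to-end distance, ring-orientation angle, centers of mass,
minimum inter-group contact distance, Shrake–Rupley solvent-accessible
surface area and buried hydrophobic interface area.

All functions are pure and operate on plain coordinate arrays (Å) plus, where
needed, the shared topology and a :class:`~pepdimer.trajectory.DimerSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._tables import BONDI_RADII, HYDROPHOBIC_RESIDUES
from .errors import DegenerateGeometryError, SelectionError
from .trajectory import Atom, DimerSpec

__all__ = [
    "Superposition",
    "SASAResult",
    "kabsch_superpose",
    "rmsd_after_fit",
    "radius_of_gyration",
    "end_to_end_distance",
    "ring_orientation_angle",
    "center_of_mass",
    "min_contact_distance",
    "shrake_rupley_sasa",
    "buried_hydrophobic_area",
    "vdw_radii",
]


@dataclass(frozen=True)
class Superposition:
    """Least-squares optimal rigid transform mapping mobile onto reference.

    Applying the transform: ``x' = rotation @ x + translation``.
    """

    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, over the fitted subset

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SASAResult:
    per_atom_area: np.ndarray  # Å² per atom
    probe_radius: float
    n_sphere_points: int

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())


def _as_points(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {x.shape}")
    return x


def kabsch_superpose(
    ref: np.ndarray, mob: np.ndarray, subset: Sequence[int] | None = None
) -> Superposition:
    """Optimal proper-rotation superposition of ``mob`` onto ``ref``.

    The fit (and the reported RMSD) uses ``subset`` indices; reflections are
    excluded by the usual determinant correction.  Fewer than three or
    collinear fit points raise :class:`DegenerateGeometryError`.
    """
    ref = _as_points(ref)
    mob = _as_points(mob)
    if ref.shape != mob.shape:
        raise ValueError("reference and mobile coordinate sets differ in shape")
    idx = np.arange(ref.shape[0]) if subset is None else np.asarray(subset, dtype=int)
    if idx.size < 3:
        raise DegenerateGeometryError("superposition needs at least 3 fit points")
    p = ref[idx]
    q = mob[idx]
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    p0 = p - pc
    q0 = q - qc
    # collinearity: second singular value of the centered reference ~ 0
    sv = np.linalg.svd(p0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("fit points are (near-)collinear")
    h = q0.T @ p0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = pc - rot @ qc
    moved = q0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p0) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=t, rmsd=rmsd)


def rmsd_after_fit(
    ref: np.ndarray,
    mob: np.ndarray,
    fit_subset: Sequence[int] | None = None,
    measure_subset: Sequence[int] | None = None,
) -> float:
    """Fit on ``fit_subset``, measure RMSD on ``measure_subset`` (defaults to
    the fit subset).  Symmetric in its arguments when the subsets coincide."""
    sup = kabsch_superpose(ref, mob, fit_subset)
    ref = _as_points(ref)
    mob = _as_points(mob)
    if measure_subset is None:
        measure_subset = fit_subset
    midx = (
        np.arange(ref.shape[0])
        if measure_subset is None
        else np.asarray(measure_subset, dtype=int)
    )
    moved = sup.apply(mob[midx])
    return float(np.sqrt(np.mean(np.sum((moved - ref[midx]) ** 2, axis=1))))


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    coords = _as_points(coords)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    return (coords * masses[:, None]).sum(axis=0) / total


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration about the center of mass (Å)."""
    coords = _as_points(coords)
    masses = np.asarray(masses, dtype=float)
    com = center_of_mass(coords, masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.sum(masses * sq) / masses.sum()))


def _atom_index(
    topology: Sequence[Atom], chain: str, res_seq: int, name: str
) -> int:
    for i, a in enumerate(topology):
        if a.chain_id == chain and a.res_seq == res_seq and a.name == name:
            return i
    raise SelectionError(f"atom {name} of residue {res_seq} chain {chain} not found")


def end_to_end_distance(
    coords: np.ndarray, topology: Sequence[Atom], spec: DimerSpec, chain: str
) -> float:
    """Distance D_N-C between the designated first-residue and last-residue
    atoms of ``chain`` (backbone N and carbonyl C by default), in Å."""
    res = sorted({a.res_seq for a in topology if a.chain_id == chain})
    if not res:
        raise SelectionError(f"chain {chain!r} not present")
    first_name, last_name = spec.terminus_atoms
    i = _atom_index(topology, chain, res[0], first_name)
    j = _atom_index(topology, chain, res[-1], last_name)
    return float(np.linalg.norm(coords[i] - coords[j]))


def ring_orientation_angle(
    coords: np.ndarray, topology: Sequence[Atom], spec: DimerSpec, chain: str
) -> float:
    """Angle (degrees, [0, 180]) between the Cα→Cγ vectors of the two
    aromatic residues of ``chain`` (Tyr63 and Phe67 by default).

    Below 90° the two rings lie on the same side of the peptide — the
    fibril-inhibiting arrangement; above 90° on opposite sides.
    """
    r1, r2 = spec.ring_residues[chain]
    vecs = []
    for r in (r1, r2):
        ca = coords[_atom_index(topology, chain, r, "CA")]
        cg = coords[_atom_index(topology, chain, r, "CG")]
        v = cg - ca
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise DegenerateGeometryError(f"zero-length Cα→Cγ vector in residue {r}")
        vecs.append(v / n)
    cosang = float(np.clip(np.dot(vecs[0], vecs[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def min_contact_distance(
    coords: np.ndarray, group_a: Sequence[int], group_b: Sequence[int]
) -> float:
    """Minimum pairwise interatomic distance between two atom groups (Å)."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("contact groups must be non-empty")
    diff = coords[a][:, None, :] - coords[b][None, :, :]
    return float(np.sqrt(np.min(np.sum(diff**2, axis=2))))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (no RNG)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def vdw_radii(topology: Sequence[Atom]) -> np.ndarray:
    """Bondi van-der-Waals radii for each atom of the topology (Å)."""
    return np.array([BONDI_RADII[a.element] for a in topology])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> SASAResult:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Each atom's extended sphere (vdW radius + probe) carries a fixed
    golden-spiral point set; points inside any neighbor's extended sphere
    are occluded.  Deterministic given ``n_points``.
    """
    coords = _as_points(coords)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    n = coords.shape[0]
    ext = radii + probe
    sphere = _golden_spiral_points(n_points)
    areas = np.empty(n)
    # neighbor prefilter: atoms further than r_i + r_j cannot occlude
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        cut = (ext[i] + ext) ** 2
        nbr = np.where((d2[i] < cut) & (np.arange(n) != i))[0]
        if nbr.size:
            pd2 = np.sum((pts[:, None, :] - coords[nbr][None, :, :]) ** 2, axis=2)
            exposed = np.all(pd2 >= (ext[nbr] ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return SASAResult(per_atom_area=areas, probe_radius=probe, n_sphere_points=n_points)


def buried_hydrophobic_area(
    coords: np.ndarray,
    topology: Sequence[Atom],
    spec: DimerSpec,
    hydrophobic_residues: Iterable[str] = HYDROPHOBIC_RESIDUES,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Hydrophobic interface area of the dimer, Å².

    (SASA_A,h + SASA_B,h − SASA_AB,h) / 2 where each term sums per-atom
    accessible areas over atoms of hydrophobic residues; the monomer terms
    are computed with the partner chain removed.  Clamped at 0.
    """
    hydro = set(hydrophobic_residues)
    radii = vdw_radii(topology)
    idx_a = np.array(
        [i for i, a in enumerate(topology) if a.chain_id == spec.chain_linear], int
    )
    idx_b = np.array(
        [i for i, a in enumerate(topology) if a.chain_id == spec.chain_cyclic], int
    )
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError("both chains of the dimer must be present")
    mask_h = np.array([a.res_name in hydro for a in topology])
    if not mask_h.any():
        raise SelectionError("hydrophobic selection is empty")

    def _h_area(indices: np.ndarray) -> float:
        res = shrake_rupley_sasa(coords[indices], radii[indices], probe, n_points)
        return float(res.per_atom_area[mask_h[indices]].sum())

    area_a = _h_area(idx_a)
    area_b = _h_area(idx_b)
    area_ab = _h_area(np.arange(len(topology)))
    return max(0.0, (area_a + area_b - area_ab) / 2.0)
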
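"""Ground-truth synthetic data generators.

Every analysis module in this package is validated against data with known
answers produced here: Metropolis samples from analytic 1D potentials
(optionally under harmonic umbrella biases) for the WHAM machinery, and
ideal-geometry peptide templates — extended, helical, hairpin and
disulfide-closed cyclic — with planted cluster memberships, hydrogen-bond
geometries, ring orientations and end-to-end distances for the structural
modules.  All generators are pure functions of their parameters and a seed.

The hairpin/cyclic builder lays the two strands out as an idealized flat
antiparallel ladder.  A planted backbone bond N-H(i)→O(j) requires the two
residues to be ladder partners (chain indices summing to n-1, the registry
real β-hairpins use); its geometry is made exact: N···O = 2.9 Å with the
hydrogen on the donor-acceptor axis.  Non-planted carbonyls and amide
hydrogens point away from the partner strand, so a geometric H-bond search
recovers exactly the planted set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from ._tables import KB_KCAL_MOL_K, ONE_TO_THREE
from .errors import ConstructionError
from .hbonds import HBondKey
from .trajectory import Atom, DimerSpec, Trajectory
from .wham import UmbrellaWindow, bias_energy

__all__ = [
    "Potential1D",
    "harmonic",
    "double_well",
    "well_plus_plateau",
    "ChainResult",
    "metropolis_sample",
    "generate_umbrella_dataset",
    "default_umbrella_centers",
    "ConformerTemplateSpec",
    "EnsembleRecipe",
    "build_template",
    "merge_structures",
    "generate_ensemble",
    "schedule_hbond_presence",
    "set_ring_angle",
    "plant_ring_angles",
    "rigid_pull_trajectory",
    "build_dimer_template",
    "default_dimer_recipe",
]


# ---------------------------------------------------------------------------
# Analytic 1D potentials and Metropolis sampling


@dataclass(frozen=True)
class Potential1D:
    """Analytic potential U(ξ) in kcal/mol over a 1D coordinate in Å."""

    kind: str
    params: dict
    fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x):
        return self.fn(np.asarray(x, dtype=float))


def harmonic(kappa: float = 5.0) -> Potential1D:
    """U(x) = ½ κ x²."""
    return Potential1D("harmonic", {"kappa": kappa}, lambda x: 0.5 * kappa * x**2)


def double_well(a: float = 2.0, b: float = 1.0) -> Potential1D:
    """U(x) = a (x² − b²)²; minima at ±b, barrier a·b⁴ at x = 0."""
    return Potential1D(
        "double_well", {"a": a, "b": b}, lambda x: a * (x**2 - b**2) ** 2
    )


def well_plus_plateau(
    depth: float = 3.0, width: float = 2.0, x0: float = 0.0
) -> Potential1D:
    """Parabolic well of given depth centered at x0, exactly 0 beyond
    |x − x0| = width.  The dissociation free energy from the well bottom to
    the plateau is ``depth``."""

    def fn(x):
        u = depth * (((x - x0) / width) ** 2 - 1.0)
        return np.where(np.abs(x - x0) <= width, u, 0.0)

    return Potential1D(
        "well_plus_plateau", {"depth": depth, "width": width, "x0": x0}, fn
    )


@dataclass
class ChainResult:
    samples: np.ndarray
    acceptance_rate: float


def metropolis_sample(
    potential: Potential1D,
    bias: UmbrellaWindow | None = None,
    n: int = 5000,
    step: float = 0.25,
    seed: int = 0,
    burn_in: int = 500,
    temperature: float = 300.0,
    x0: float | None = None,
    thin: int = 5,
) -> ChainResult:
    """Metropolis chain with Gaussian proposals targeting
    ∝ exp(−β (U + w)); the first ``burn_in`` states are discarded and the
    chain is thinned by ``thin`` (every thin-th state kept) to reduce the
    autocorrelation of the returned samples."""
    if n <= 0 or step <= 0 or thin < 1:
        raise ValueError("n, step and thin must be positive")
    beta = 1.0 / (KB_KCAL_MOL_K * temperature)

    def energy(x: float) -> float:
        e = float(potential(x))
        if bias is not None:
            e += float(bias_energy(bias, x))
        return e

    rng = np.random.default_rng(seed)
    total = n * thin + burn_in
    proposals = rng.normal(0.0, step, total)
    uniforms = rng.random(total)
    x = float(x0) if x0 is not None else (bias.center if bias is not None else 0.0)
    e = energy(x)
    out = np.empty(total)
    accepted = 0
    for i in range(total):
        xn = x + proposals[i]
        en = energy(xn)
        if en <= e or uniforms[i] < math.exp(-beta * (en - e)):
            x, e = xn, en
            accepted += 1
        out[i] = x
    return ChainResult(
        samples=out[burn_in::thin][:n], acceptance_rate=accepted / total
    )


def default_umbrella_centers(
    n_windows: int = 26, spacing: float = 0.5
) -> np.ndarray:
    """Symmetric ladder of window centers (26 windows, 0.5 Å apart by
    default, spanning −6.25 … +6.25 Å)."""
    half = spacing * (n_windows - 1) / 2.0
    return -half + spacing * np.arange(n_windows)


def generate_umbrella_dataset(
    potential: Potential1D,
    centers: Sequence[float] | None = None,
    k: float = 20.0,
    n_per_window: int = 5000,
    seed: int = 0,
    step: float = 0.25,
    burn_in: int = 500,
    temperature: float = 300.0,
    thin: int = 5,
) -> tuple[list[UmbrellaWindow], Potential1D]:
    """One Metropolis run per window (per-window seed = seed + index);
    returns the windows plus the exact potential for recovery scoring."""
    if centers is None:
        centers = default_umbrella_centers()
    centers = np.asarray(centers, dtype=float)
    if centers.size < 2:
        raise ValueError("need at least two window centers")
    windows = []
    for i, c in enumerate(centers):
        w = UmbrellaWindow(center=float(c), k=k, samples=np.zeros(1), label=f"w{i:03d}")
        chain = metropolis_sample(
            potential,
            bias=w,
            n=n_per_window,
            step=step,
            seed=seed + i,
            burn_in=burn_in,
            temperature=temperature,
            thin=thin,
        )
        w.samples = chain.samples
        windows.append(w)
    return windows, potential


# ---------------------------------------------------------------------------
# Peptide templates

# Ideal peptide scaffolding constants (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.8
_PHI_PSI = {"extended": (-135.0, 135.0), "helix": (-57.0, -47.0)}
_LADDER_RISE = 3.5  # per-residue rise along a strand
_LADDER_SEP = 4.13  # inter-strand spacing giving N···O = 2.9 Å
_CA_CG = 1.5


@dataclass
class ConformerTemplateSpec:
    """Recipe for one ideal-geometry conformer.

    ``planted_hbonds`` entries are backbone NH→O bonds given either as
    :class:`~pepdimer.hbonds.HBondKey` or as (donor_res_seq,
    acceptor_res_seq) pairs; they are only realizable in hairpin/cyclic
    templates between ladder-paired residues.  ``ring_angle`` and ``d_nc``
    are enforced exactly where geometrically possible and raise
    :class:`ConstructionError` otherwise.
    """

    kind: str  # hairpin | extended | helix | cyclic
    sequence: str  # 1-letter codes
    n_res: int | None = None
    planted_hbonds: list = field(default_factory=list)
    ring_angle: float | None = None  # degrees
    d_nc: float | None = None  # Å
    first_res_seq: int = 60
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.n_res is None:
            self.n_res = len(self.sequence)
        if self.n_res != len(self.sequence):
            raise ConstructionError("sequence length must equal n_res")
        if self.kind not in ("hairpin", "extended", "helix", "cyclic"):
            raise ConstructionError(f"unknown template kind {self.kind!r}")


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d from the three preceding atoms."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (
        -math.cos(theta) * bc
        + math.sin(theta) * math.cos(chi) * m
        + math.sin(theta) * math.sin(chi) * n
    )
    return c + d


def _rotation_about(axis: np.ndarray, theta: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    km = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(theta) * km + (1 - math.cos(theta)) * (km @ km)


def _dihedral_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0):
    """N, CA, C positions of an ideal (phi, psi) chain."""
    pos_n = [np.array([0.0, 0.0, 0.0])]
    pos_ca = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - _A_N_CA_C)
    pos_c = [pos_ca[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n_res):
        n = _place_atom(pos_n[-1], pos_ca[-1], pos_c[-1], _B_C_N, _A_CA_C_N, psi)
        ca = _place_atom(pos_ca[-1], pos_c[-1], n, _B_N_CA, _A_C_N_CA, omega)
        c = _place_atom(pos_c[-1], n, ca, _B_CA_C, _A_N_CA_C, phi)
        pos_n.append(n)
        pos_ca.append(ca)
        pos_c.append(c)
    return pos_n, pos_ca, pos_c


def _normalize_planted(spec: ConformerTemplateSpec) -> list[tuple[int, int]]:
    pairs = []
    for item in spec.planted_hbonds:
        if isinstance(item, HBondKey):
            if item.donor_group != "NH" or item.acceptor_atom != "O":
                raise ConstructionError(
                    f"only backbone NH→O bonds can be planted, got {item}"
                )
            pairs.append((item.donor_res, item.acceptor_res))
        else:
            d, a = item
            pairs.append((int(d), int(a)))
    return pairs


def build_template(spec: ConformerTemplateSpec) -> tuple[list[Atom], np.ndarray]:
    """Build an ideal-geometry conformer: backbone N, H, CA, C, O per
    residue plus a CG pseudo-atom for each of the two aromatic (Tyr/Phe)
    residues.  Returns the topology and one coordinate frame (Å)."""
    n = spec.n_res
    planted = _normalize_planted(spec)
    seq3 = []
    for ch in spec.sequence.upper():
        if ch not in ONE_TO_THREE:
            raise ConstructionError(f"unknown residue code {ch!r}")
        seq3.append(ONE_TO_THREE[ch])

    if spec.kind in ("extended", "helix"):
        if planted:
            raise ConstructionError(
                "planted H-bonds require a hairpin or cyclic template"
            )
        coords_by_res = _build_dihedral_kind(spec)
    else:
        if spec.d_nc is not None:
            raise ConstructionError(
                "a d_nc constraint conflicts with the hairpin ladder pairing"
            )
        coords_by_res = _build_ladder_kind(spec, planted)

    # ring pseudo-atoms with an exact inter-ring angle
    ring_idx = [i for i, r in enumerate(seq3) if r in ("TYR", "PHE")]
    cg: dict[int, np.ndarray] = {}
    if len(ring_idx) >= 2:
        r1, r2 = ring_idx[0], ring_idx[1]
        angle = spec.ring_angle if spec.ring_angle is not None else 0.0
        ca1 = coords_by_res[r1]["CA"]
        ca2 = coords_by_res[r2]["CA"]
        cg[r1], cg[r2] = _ring_vectors(ca1, ca2, angle)
    elif spec.ring_angle is not None:
        raise ConstructionError(
            "ring_angle requires two aromatic residues in the sequence"
        )

    topology: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    element = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O", "CG": "C"}
    for i in range(n):
        names = ["N", "H", "CA", "C", "O"]
        if i in cg:
            names.append("CG")
        for name in names:
            pos = cg[i] if name == "CG" else coords_by_res[i][name]
            topology.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element[name],
                    res_name=seq3[i],
                    res_seq=spec.first_res_seq + i,
                    chain_id=spec.chain_id,
                )
            )
            coords.append(pos)
            serial += 1
    return topology, np.array(coords)


def _ring_vectors(ca1, ca2, angle_deg):
    e = ca2 - ca1
    nrm = np.linalg.norm(e)
    if nrm < 1e-9:
        raise ConstructionError("aromatic CA atoms coincide")
    e = e / nrm
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, e)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = ref - np.dot(ref, e) * e
    u /= np.linalg.norm(u)
    w = np.cross(e, u)
    t = math.radians(angle_deg)
    v = math.cos(t) * u + math.sin(t) * w
    return ca1 + _CA_CG * u, ca2 + _CA_CG * v


def _build_dihedral_kind(spec: ConformerTemplateSpec):
    n = spec.n_res
    phi, psi = _PHI_PSI[spec.kind]
    pos_n, pos_ca, pos_c = _dihedral_backbone(n, phi, psi)
    coords_by_res = []
    for i in range(n):
        entry = {"N": pos_n[i], "CA": pos_ca[i], "C": pos_c[i]}
        entry["O"] = _place_atom(
            pos_n[i], pos_ca[i], pos_c[i], _B_C_O, _A_CA_C_O, psi + 180.0
        )
        if i == 0:
            d = pos_n[0] - pos_ca[0]
            entry["H"] = pos_n[0] + _B_N_H * d / np.linalg.norm(d)
        else:
            d1 = pos_n[i] - pos_c[i - 1]
            d2 = pos_n[i] - pos_ca[i]
            d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
            entry["H"] = pos_n[i] + _B_N_H * d / np.linalg.norm(d)
        coords_by_res.append(entry)
    if spec.d_nc is not None:
        coords_by_res = _apply_dnc_hinge(coords_by_res, spec.d_nc)
    return coords_by_res


def _apply_dnc_hinge(coords_by_res, target: float):
    """Set the N(first)–C(last) distance exactly by rotating everything
    past the middle Cα about an axis through it."""
    n = len(coords_by_res)
    m = n // 2
    pivot = coords_by_res[m]["CA"]
    t1 = coords_by_res[0]["N"] - pivot
    t2 = coords_by_res[-1]["C"] - pivot
    axis = np.cross(t1, t2)
    if np.linalg.norm(axis) < 1e-9:
        axis = np.cross(t2, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(t2, np.array([0.0, 1.0, 0.0]))
    axis /= np.linalg.norm(axis)

    def dist(theta: float) -> float:
        r = _rotation_about(axis, theta)
        return float(np.linalg.norm(t1 - r @ t2))

    thetas = np.linspace(-math.pi, math.pi, 721)
    vals = np.array([dist(t) for t in thetas])
    if not (vals.min() - 1e-9 <= target <= vals.max() + 1e-9):
        raise ConstructionError(
            f"requested d_nc = {target:.2f} Å outside the reachable range "
            f"[{vals.min():.2f}, {vals.max():.2f}] Å"
        )
    # bracket closest to the unbent chain
    best = None
    for i in range(len(thetas) - 1):
        lo, hi = vals[i] - target, vals[i + 1] - target
        if lo == 0.0:
            best = thetas[i]
            break
        if lo * hi < 0:
            theta = brentq(lambda t: dist(t) - target, thetas[i], thetas[i + 1])
            if best is None or abs(theta) < abs(best):
                best = theta
    if best is None:
        best = thetas[int(np.argmin(np.abs(vals - target)))]
    r = _rotation_about(axis, best)
    out = []
    for i, entry in enumerate(coords_by_res):
        new = {}
        for name, pos in entry.items():
            # the second arm starts after the middle residue's CA
            second = i > len(coords_by_res) // 2 or (
                i == len(coords_by_res) // 2 and name in ("C", "O")
            )
            new[name] = pivot + r @ (pos - pivot) if second else pos
        out.append(new)
    return out


def _build_ladder_kind(spec: ConformerTemplateSpec, planted):
    """Flat antiparallel two-strand ladder (hairpin and cyclic kinds)."""
    n = spec.n_res
    h = (n + 1) // 2  # strand A: 0..h-1, strand B: h..n-1
    first = spec.first_res_seq
    pairs_idx = []
    for dres, ares in planted:
        i, j = dres - first, ares - first
        if not (0 <= i < n and 0 <= j < n):
            raise ConstructionError(f"planted bond {dres}->{ares} outside chain")
        if i + j != n - 1 or i == j:
            raise ConstructionError(
                f"planted bond {dres}->{ares} does not connect ladder partners "
                f"(residue indices must sum to {n - 1})"
            )
        pairs_idx.append((i, j))

    toward_h = set(i for i, _ in pairs_idx)  # amide H points at the partner
    toward_o = set(j for _, j in pairs_idx)  # carbonyl O points at the partner

    coords_by_res = []
    for idx in range(n):
        if idx < h:
            x = _LADDER_RISE * idx
            y = 0.0
            sgn_partner = -1.0  # partner strand lies at negative y
            n_off, c_off = -1.1, 1.1
        else:
            x = _LADDER_RISE * (n - 1 - idx)
            y = -_LADDER_SEP
            sgn_partner = 1.0
            n_off, c_off = 1.1, -1.1
        ca = np.array([x, y, 0.0])
        npos = np.array([x + n_off, y, 0.0])
        cpos = np.array([x + c_off, y, 0.0])
        sh = sgn_partner if idx in toward_h else -sgn_partner
        so = sgn_partner if idx in toward_o else -sgn_partner
        coords_by_res.append(
            {
                "N": npos,
                "H": npos + np.array([0.0, sh * _B_N_H, 0.0]),
                "CA": ca,
                "C": cpos,
                "O": cpos + np.array([0.0, so * _B_C_O, 0.0]),
            }
        )
    return coords_by_res


# ---------------------------------------------------------------------------
# Assembly, ensembles, schedules


def merge_structures(
    parts: Sequence[tuple[list[Atom], np.ndarray]]
) -> tuple[list[Atom], np.ndarray]:
    """Concatenate topologies/coordinates, renumbering serials."""
    topology: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for topo, xyz in parts:
        for a, pos in zip(topo, xyz):
            topology.append(
                Atom(serial, a.name, a.element, a.res_name, a.res_seq, a.chain_id)
            )
            coords.append(np.asarray(pos, dtype=float))
            serial += 1
    return topology, np.array(coords)


def build_dimer_template(
    linear: ConformerTemplateSpec,
    cyclic: ConformerTemplateSpec,
    translation: Sequence[float] = (0.0, 12.0, 0.0),
    rotation_z_deg: float = 0.0,
) -> tuple[list[Atom], np.ndarray]:
    """Two-chain template: the cyclic chain is rotated about z and
    translated relative to the linear chain."""
    topo_a, xyz_a = build_template(linear)
    topo_b, xyz_b = build_template(cyclic)
    r = _rotation_about(np.array([0.0, 0.0, 1.0]), math.radians(rotation_z_deg))
    center = xyz_b.mean(axis=0)
    xyz_b = (xyz_b - center) @ r.T + center + np.asarray(translation, dtype=float)
    return merge_structures([(topo_a, xyz_a), (topo_b, xyz_b)])


@dataclass
class EnsembleRecipe:
    """Mixture of conformer templates with per-coordinate Gaussian noise.

    ``templates`` entries are either :class:`ConformerTemplateSpec` or
    prebuilt (topology, coords) tuples (e.g. dimer templates); all must
    share one topology.
    """

    templates: list
    weights: Sequence[float]
    noise_sigma: float = 0.3  # Å per coordinate
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.templates) != w.size or w.size == 0:
            raise ValueError("need one weight per template")
        if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("weights must be a simplex")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def generate_ensemble(recipe: EnsembleRecipe) -> tuple[Trajectory, np.ndarray]:
    """Sample frames from the template mixture; returns the trajectory and
    the planted per-frame template labels."""
    built = [
        build_template(t) if isinstance(t, ConformerTemplateSpec) else t
        for t in recipe.templates
    ]
    sig0 = [(a.name, a.res_seq, a.chain_id, a.res_name) for a in built[0][0]]
    for topo, _ in built[1:]:
        if [(a.name, a.res_seq, a.chain_id, a.res_name) for a in topo] != sig0:
            raise ConstructionError("ensemble templates must share one topology")
    rng = np.random.default_rng(recipe.seed)
    labels = rng.choice(
        len(built), size=recipe.n_frames, p=np.asarray(recipe.weights, dtype=float)
    )
    base = np.stack([xyz for _, xyz in built])[labels]
    noise = (
        rng.normal(0.0, recipe.noise_sigma, base.shape)
        if recipe.noise_sigma > 0
        else 0.0
    )
    traj = Trajectory(
        topology=built[0][0],
        coords=base + noise,
        times_ps=240.0 * np.arange(recipe.n_frames),
    )
    return traj, labels


def _bond_atom_indices(traj: Trajectory, key) -> tuple[int, int, int]:
    if isinstance(key, HBondKey):
        dchain, dres, achain, ares = (
            key.donor_chain,
            key.donor_res,
            key.acceptor_chain,
            key.acceptor_res,
        )
    else:
        (dchain, dres), (achain, ares) = key
    idx = {}
    for i, a in enumerate(traj.topology):
        if a.chain_id == dchain and a.res_seq == dres and a.name in ("N", "H"):
            idx["D" + a.name] = i
        if a.chain_id == achain and a.res_seq == ares and a.name == "O":
            idx["AO"] = i
    if set(idx) != {"DN", "DH", "AO"}:
        raise ConstructionError(f"bond atoms not found for {key}")
    return idx["DN"], idx["DH"], idx["AO"]


def schedule_hbond_presence(
    traj: Trajectory, key, fraction: float, seed: int = 0
) -> Trajectory:
    """Plant a bond's presence in an exact-count subset of frames.

    In ``round(fraction · n_frames)`` seeded-randomly chosen frames the
    acceptor O sits 2.9 Å from the donor N along the N–H axis (inside the
    geometric criteria); in the remaining frames it is parked 6 Å away
    perpendicular to the ladder plane.  Persistence is exact, not Bernoulli.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    dn, dh, ao = _bond_atom_indices(traj, key)
    f = traj.n_frames
    n_present = int(round(fraction * f))
    rng = np.random.default_rng(seed)
    present = np.zeros(f, dtype=bool)
    present[rng.permutation(f)[:n_present]] = True
    coords = traj.coords.copy()
    for fr in range(f):
        nh = coords[fr, dh] - coords[fr, dn]
        nh = nh / np.linalg.norm(nh)
        if present[fr]:
            coords[fr, ao] = coords[fr, dn] + 2.9 * nh
        else:
            coords[fr, ao] = coords[fr, dn] + np.array([0.0, 0.0, 6.0])
    return Trajectory(
        topology=traj.topology,
        coords=coords,
        times_ps=None if traj.times_ps is None else traj.times_ps.copy(),
    )


def set_ring_angle(
    coords: np.ndarray,
    topology: Sequence[Atom],
    spec: DimerSpec,
    chain: str,
    angle_deg: float,
) -> np.ndarray:
    """Reposition the two CG pseudo-atoms of ``chain`` so the Cα→Cγ
    inter-ring angle equals ``angle_deg`` exactly."""
    r1, r2 = spec.ring_residues[chain]
    pos = {}
    for i, a in enumerate(topology):
        if a.chain_id == chain and a.res_seq in (r1, r2) and a.name in ("CA", "CG"):
            pos[(a.res_seq, a.name)] = i
    for r in (r1, r2):
        if (r, "CA") not in pos or (r, "CG") not in pos:
            raise ConstructionError(f"residue {r} of chain {chain} lacks CA/CG")
    cg1, cg2 = _ring_vectors(
        coords[pos[(r1, "CA")]], coords[pos[(r2, "CA")]], angle_deg
    )
    out = coords.copy()
    out[pos[(r1, "CG")]] = cg1
    out[pos[(r2, "CG")]] = cg2
    return out


def plant_ring_angles(
    traj: Trajectory, spec: DimerSpec, chain: str, angles: Sequence[float]
) -> Trajectory:
    """Plant one exact ring-orientation angle per frame."""
    angles = np.asarray(angles, dtype=float)
    if angles.size != traj.n_frames:
        raise ValueError("need one angle per frame")
    coords = traj.coords.copy()
    for f in range(traj.n_frames):
        coords[f] = set_ring_angle(coords[f], traj.topology, spec, chain, angles[f])
    return Trajectory(
        topology=traj.topology,
        coords=coords,
        times_ps=None if traj.times_ps is None else traj.times_ps.copy(),
    )


def rigid_pull_trajectory(
    topology: Sequence[Atom],
    coords: np.ndarray,
    chain: str,
    direction: Sequence[float],
    offsets: Sequence[float],
) -> Trajectory:
    """Frames in which one chain is rigidly translated by each offset along
    ``direction`` — a synthetic dissociation series."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    mask = np.array([a.chain_id == chain for a in topology])
    frames = []
    for off in offsets:
        c = np.asarray(coords, dtype=float).copy()
        c[mask] += off * d
        frames.append(c)
    return Trajectory(topology=list(topology), coords=np.stack(frames))


# ---------------------------------------------------------------------------
# Shipped default study system


LINEAR_SEQUENCE = "MSTYTGIFTDQ"  # apoC-II(60-70), residues 60-70
CYCLIC_SEQUENCE = "CMSTYTGIFTDQC"  # flanking Cys 59/71, disulfide-closed

#: Backbone ladder registry of the cyclic peptide's persistent bonds
#: (60↔70, 62↔68, 64↔66, both directions).
CYCLIC_LADDER_BONDS = [
    (70, 60), (60, 70), (68, 62), (62, 68), (66, 64), (64, 66),
]
LINEAR_LADDER_BONDS = [(70, 60), (60, 70), (68, 62), (62, 68), (66, 64), (64, 66)]


def default_cyclic_template(ring_angle: float = 54.0) -> ConformerTemplateSpec:
    return ConformerTemplateSpec(
        kind="cyclic",
        sequence=CYCLIC_SEQUENCE,
        planted_hbonds=list(CYCLIC_LADDER_BONDS),
        ring_angle=ring_angle,
        first_res_seq=59,
        chain_id="B",
    )


def default_dimer_recipe(
    n_frames: int = 200, noise_sigma: float = 0.3, seed: int = 0
) -> EnsembleRecipe:
    """Four-state dimer mixture emulating the dominant heterodimer states:
    two open/extended linear conformers and two hairpin-like ones bound at
    different faces of the cyclic peptide, weights 0.4/0.3/0.2/0.1."""
    lin = dict(sequence=LINEAR_SEQUENCE, first_res_seq=60, chain_id="A")
    cyc = default_cyclic_template()
    templates = [
        build_dimer_template(
            ConformerTemplateSpec(kind="extended", d_nc=10.0, ring_angle=30.0, **lin),
            cyc, translation=(0.0, 12.0, 0.0), rotation_z_deg=0.0,
        ),
        build_dimer_template(
            ConformerTemplateSpec(
                kind="hairpin", planted_hbonds=list(LINEAR_LADDER_BONDS),
                ring_angle=40.0, **lin,
            ),
            cyc, translation=(5.0, -14.0, 2.0), rotation_z_deg=90.0,
        ),
        build_dimer_template(
            ConformerTemplateSpec(kind="extended", d_nc=20.0, ring_angle=120.0, **lin),
            cyc, translation=(-4.0, 13.0, -3.0), rotation_z_deg=180.0,
        ),
        build_dimer_template(
            ConformerTemplateSpec(kind="helix", ring_angle=150.0, **lin),
            cyc, translation=(8.0, 15.0, 5.0), rotation_z_deg=45.0,
        ),
    ]
    return EnsembleRecipe(
        templates=templates,
        weights=(0.4, 0.3, 0.2, 0.1),
        noise_sigma=noise_sigma,
        n_frames=n_frames,
        seed=seed,
    )
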
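"""Geometric hydrogen-bond analysis and a DSSP-like secondary-structure
classifier.

A bond is reported when the donor–acceptor heavy-atom distance is within
``d_max`` and the hydrogen–donor–acceptor angle within ``theta_max``
(defaults 3.5 Å / 30°, the conventional geometric criteria; the analysis
degrades to distance-only with a warning when the input lacks explicit
hydrogens).  Bonds are keyed by donor group and acceptor atom, so e.g.
Ser61(OG,HG)→Asp69(OD1) and →OD2 are distinct.

The secondary-structure classifier assigns per-residue codes from backbone
H-bond energies (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol, bond iff E < −0.5) using n-turn and bridge patterns with priority
H > G > I > E > B > T > C.  It substitutes for dihedral-augmented
assignment schemes and is validated on ideal templates only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._tables import SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS
from .errors import ConfigurationError
from .trajectory import Atom, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriteria",
    "HBondKey",
    "ExistenceProfile",
    "detect_hbonds",
    "existence_profile",
    "persistent_bonds",
    "mean_hbonds_per_frame",
    "assign_secondary_structure",
]

HB_ENERGY_FACTOR = 0.084 * 332.0  # kcal/mol·Å, DSSP electrostatic model
HB_ENERGY_CUTOFF = -0.5  # kcal/mol


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5  # donor–acceptor heavy-atom distance, Å
    theta_max: float = 30.0  # hydrogen–donor–acceptor angle, degrees

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0 < self.theta_max <= 90):
            raise ValueError("theta_max must be in (0, 90]")


@dataclass(frozen=True, order=True)
class HBondKey:
    """Identity of a hydrogen bond: donor group and acceptor atom."""

    donor_chain: str
    donor_res: int
    donor_group: str  # "NH" for backbone, else e.g. "OG,HG"
    acceptor_chain: str
    acceptor_res: int
    acceptor_atom: str

    def __str__(self) -> str:  # Gln70(NH)-Met60(O) style
        return (
            f"{self.donor_chain}{self.donor_res}({self.donor_group})-"
            f"{self.acceptor_chain}{self.acceptor_res}({self.acceptor_atom})"
        )


@dataclass
class ExistenceProfile:
    """Bond × frame boolean presence matrix with persistence fractions."""

    keys: list[HBondKey]
    present: np.ndarray  # (n_keys, n_frames) bool
    persistence: np.ndarray = field(init=False)  # per-key fraction of frames

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape[0] != len(self.keys):
            raise ValueError("presence matrix rows must match key count")
        self.persistence = (
            self.present.mean(axis=1)
            if self.present.size
            else np.zeros(len(self.keys))
        )

    @property
    def n_frames(self) -> int:
        return self.present.shape[1]


# ---------------------------------------------------------------------------
# Detection


def _residue_map(topology: Sequence[Atom]) -> dict[tuple[str, int], dict]:
    res: dict[tuple[str, int], dict] = {}
    for i, a in enumerate(topology):
        entry = res.setdefault(
            (a.chain_id, a.res_seq), {"res_name": a.res_name, "atoms": {}}
        )
        entry["atoms"][a.name] = i
    return res


def _donor_groups(res_name: str, atoms: dict[str, int]):
    """Yield (donor group label, heavy index, hydrogen index or None)."""
    known = {"ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS",
             "LEU", "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL",
             "TRP", "TYR"}
    if res_name not in known:
        raise ConfigurationError(f"residue {res_name!r} missing from donor table")
    if res_name != "PRO" and "N" in atoms:
        yield "NH", atoms["N"], atoms.get("H")
    for heavy, hydros in SIDECHAIN_DONORS.get(res_name, []):
        if heavy in atoms:
            present_h = [h for h in hydros if h in atoms]
            if present_h:
                for h in present_h:
                    yield f"{heavy},{h}", atoms[heavy], atoms[h]
            else:
                yield f"{heavy},{hydros[0]}", atoms[heavy], None


def _acceptor_atoms(res_name: str, atoms: dict[str, int]):
    for name in ("O", "OXT"):
        if name in atoms:
            yield name, atoms[name]
    for name in SIDECHAIN_ACCEPTORS.get(res_name, []):
        if name in atoms:
            yield name, atoms[name]


def detect_hbonds(
    coords: np.ndarray,
    topology: Sequence[Atom],
    criteria: HBondCriteria = HBondCriteria(),
    scope: str | tuple[str, str] = "A",
) -> set[HBondKey]:
    """Hydrogen bonds present in one frame.

    ``scope`` is a single chain id (intramolecular bonds of that chain) or a
    pair of chain ids (bonds across the two chains, both directions).
    Same-residue donor→acceptor pairs are never reported.
    """
    res = _residue_map(topology)
    intra = isinstance(scope, str)
    chains = {scope} if intra else set(scope)

    donors = []  # (chain, res_seq, group, heavy idx, H idx or None)
    acceptors = []  # (chain, res_seq, atom name, idx)
    for (chain, seq), entry in res.items():
        if chain not in chains:
            continue
        for group, heavy, hyd in _donor_groups(entry["res_name"], entry["atoms"]):
            donors.append((chain, seq, group, heavy, hyd))
        for name, idx in _acceptor_atoms(entry["res_name"], entry["atoms"]):
            acceptors.append((chain, seq, name, idx))

    missing_h = any(h is None for *_, h in donors)
    if missing_h and criteria.theta_max < 180:
        logger.warning(
            "explicit hydrogens missing for some donors; "
            "falling back to distance-only hydrogen-bond criteria"
        )

    found: set[HBondKey] = set()
    for dchain, dseq, group, dheavy, dhyd in donors:
        for achain, aseq, aname, aidx in acceptors:
            if intra:
                if achain != dchain:
                    continue
            else:
                if achain == dchain:
                    continue
            if dchain == achain and dseq == aseq:
                continue
            vec = coords[aidx] - coords[dheavy]
            dist = float(np.linalg.norm(vec))
            if dist > criteria.d_max or dist < 1e-6:
                continue
            if dhyd is not None:
                hvec = coords[dhyd] - coords[dheavy]
                hn = np.linalg.norm(hvec)
                if hn > 1e-9:
                    cosang = float(
                        np.clip(np.dot(hvec / hn, vec / dist), -1.0, 1.0)
                    )
                    angle = np.degrees(np.arccos(cosang))
                    if angle > criteria.theta_max:
                        continue
            found.add(
                HBondKey(dchain, dseq, group, achain, aseq, aname)
            )
    return found


def existence_profile(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    scope: str | tuple[str, str] = "A",
) -> ExistenceProfile:
    """Bond presence tracked through every frame of the trajectory."""
    per_frame = [
        detect_hbonds(traj.coords[f], traj.topology, criteria, scope)
        for f in range(traj.n_frames)
    ]
    keys = sorted(set().union(*per_frame)) if per_frame else []
    present = np.zeros((len(keys), len(per_frame)), dtype=bool)
    key_row = {k: r for r, k in enumerate(keys)}
    for f, bonds in enumerate(per_frame):
        for k in bonds:
            present[key_row[k], f] = True
    return ExistenceProfile(keys=keys, present=present)


def persistent_bonds(
    profile: ExistenceProfile, threshold: float = 0.5
) -> list[HBondKey]:
    """Keys present in at least ``threshold`` of frames, most persistent first."""
    order = np.argsort(-profile.persistence, kind="stable")
    return [
        profile.keys[i] for i in order if profile.persistence[i] >= threshold
    ]


def mean_hbonds_per_frame(profile: ExistenceProfile) -> float:
    if profile.n_frames < 1:
        raise ValueError("profile has no frames")
    return float(profile.present.sum(axis=0).mean())


# ---------------------------------------------------------------------------
# Secondary structure


def _bb_hbond_energy(o, c, n, h) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing geometry, treat as bonded
        return -9.9
    return HB_ENERGY_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(
    coords: np.ndarray, topology: Sequence[Atom], chain: str
) -> np.ndarray:
    """Per-residue codes of ``chain``: H(α), G(3-10), I(π), E(strand),
    B(bridge), T(turn), C(coil); X where backbone atoms are missing.

    Amide hydrogens are reconstructed geometrically (N–H 1.01 Å, along the
    previous residue's O→C direction) when absent — for this classifier
    only, never for the H-bond existence profile.
    """
    res = _residue_map(topology)
    seqs = sorted(s for (c, s) in res if c == chain)
    nres = len(seqs)
    bb: list[dict | None] = []
    for s in seqs:
        atoms = res[(chain, s)]["atoms"]
        if not all(name in atoms for name in ("N", "CA", "C", "O")):
            bb.append(None)
            continue
        bb.append(
            {
                "N": coords[atoms["N"]],
                "CA": coords[atoms["CA"]],
                "C": coords[atoms["C"]],
                "O": coords[atoms["O"]],
                "H": coords[atoms["H"]] if "H" in atoms else None,
            }
        )
    # reconstruct missing amide hydrogens
    for i in range(nres):
        if bb[i] is None or bb[i]["H"] is not None:
            continue
        if i > 0 and bb[i - 1] is not None:
            d = bb[i - 1]["C"] - bb[i - 1]["O"]
            nrm = np.linalg.norm(d)
            if nrm > 1e-9:
                bb[i]["H"] = bb[i]["N"] + 1.01 * d / nrm

    def hbond(i: int, j: int) -> bool:
        """C=O of residue i accepts from N-H of residue j."""
        if not (0 <= i < nres and 0 <= j < nres):
            return False
        if abs(i - j) < 2:
            return False
        bi, bj = bb[i], bb[j]
        if bi is None or bj is None or bj["H"] is None:
            return False
        return _bb_hbond_energy(bi["O"], bi["C"], bj["N"], bj["H"]) < HB_ENERGY_CUTOFF

    turns = {n: [hbond(i, i + n) for i in range(nres)] for n in (3, 4, 5)}
    helix = {n: np.zeros(nres, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(1, nres):
            if turns[n][i - 1] and turns[n][i]:
                helix[n][i : min(i + n, nres)] = True

    bridge = np.zeros(nres, dtype=bool)
    for i in range(nres):
        for j in range(i + 3, nres):
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(i - 1, j + 1) and hbond(j - 1, i + 1)
            )
            para = (hbond(i - 1, j) and hbond(j, i + 1)) or (
                hbond(j - 1, i) and hbond(i, j + 1)
            )
            if anti or para:
                bridge[i] = bridge[j] = True
    strand = bridge & (
        np.roll(bridge, 1) | np.roll(bridge, -1)
    )
    if nres:
        strand[0] = bridge[0] and (nres > 1 and bridge[1])
        strand[-1] = bridge[-1] and (nres > 1 and bridge[-2])

    in_turn = np.zeros(nres, dtype=bool)
    for n in (3, 4, 5):
        for i in range(nres):
            if turns[n][i]:
                in_turn[i + 1 : min(i + n, nres)] = True

    codes = np.full(nres, "C", dtype="<U1")
    for i in range(nres):
        if bb[i] is None:
            codes[i] = "X"
            logger.warning("residue %s%d missing backbone atoms", chain, seqs[i])
        elif helix[4][i]:
            codes[i] = "H"
        elif helix[3][i]:
            codes[i] = "G"
        elif helix[5][i]:
            codes[i] = "I"
        elif strand[i]:
            codes[i] = "E"
        elif bridge[i]:
            codes[i] = "B"
        elif in_turn[i]:
            codes[i] = "T"
    return codes


def secondary_structure_timeline(
    traj: Trajectory, chain: str
) -> np.ndarray:
    """Residue × frame code matrix for one chain."""
    cols = [
        assign_secondary_structure(traj.coords[f], traj.topology, chain)
        for f in range(traj.n_frames)
    ]
    return np.stack(cols, axis=1)
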
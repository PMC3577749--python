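"""Trajectory container, multi-model PDB I/O and atom selections.

The in-memory model is deliberately simple: an ordered topology (list of
:class:`Atom`) shared by every frame, plus a ``(n_frames, n_atoms, 3)``
coordinate array in Å.  File I/O goes through biotite's PDB reader/writer;
a light validation pass runs first so parse errors name the offending line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._tables import ATOMIC_MASSES, BACKBONE_NAMES, RING_HEAVY_ATOMS
from .errors import (
    SelectionError,
    StructuralError,
    TrajectoryFormatError,
    TrajectoryParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Trajectory",
    "DimerSpec",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "select_atoms",
]


@dataclass(frozen=True)
class Atom:
    """One atom of the shared topology (coordinates live in the frames)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element]


@dataclass
class Trajectory:
    """Ordered topology plus stacked coordinate frames (Å).

    ``times_ps`` is optional; when set it must be strictly increasing.
    ``source_tags`` optionally records per-frame provenance (e.g. which
    independent run a frame came from) and is never used in statistics.
    """

    topology: list[Atom]
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    times_ps: np.ndarray | None = None
    source_tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructuralError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise StructuralError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.topology):
            raise StructuralError(
                f"frame atom count {self.coords.shape[1]} != topology size {len(self.topology)}"
            )
        if not np.isfinite(self.coords).all():
            raise StructuralError("non-finite coordinates in trajectory")
        if self.times_ps is not None:
            self.times_ps = np.asarray(self.times_ps, dtype=float)
            if np.any(np.diff(self.times_ps) <= 0):
                raise StructuralError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.topology:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass
class DimerSpec:
    """Selections defining the two-peptide system.

    The default describes the linear chain (A, residues 60-70, sequence
    MSTYTGIFTDQ) and the disulfide-closed cyclic chain (B, the same
    sequence flanked by Cys59/Cys71).  The aromatic residues carrying the
    ring-orientation statistic are Tyr63 and Phe67 on each chain.
    """

    chain_linear: str = "A"
    chain_cyclic: str = "B"
    backbone_names: frozenset[str] = BACKBONE_NAMES
    ring_residues: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"A": (63, 67), "B": (63, 67)}
    )
    ring_atom_names: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(RING_HEAVY_ATOMS)
    )
    # (first-residue atom, last-residue atom) used for the end-to-end
    # distance D_N-C: backbone N of the first residue, carbonyl C of the last.
    terminus_atoms: tuple[str, str] = ("N", "C")

    def __post_init__(self) -> None:
        if self.chain_linear == self.chain_cyclic:
            raise ValueError("linear and cyclic chain ids must differ")
        self.backbone_names = frozenset(self.backbone_names)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DimerSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("chain_linear", "chain_cyclic"):
            if key in data:
                kwargs[key] = data[key]
        if "backbone_names" in data:
            kwargs["backbone_names"] = frozenset(data["backbone_names"])
        if "ring_residues" in data:
            kwargs["ring_residues"] = {
                str(k): tuple(v) for k, v in data["ring_residues"].items()
            }
        if "ring_atom_names" in data:
            kwargs["ring_atom_names"] = {
                str(k): tuple(v) for k, v in data["ring_atom_names"].items()
            }
        if "terminus_atoms" in data:
            kwargs["terminus_atoms"] = tuple(data["terminus_atoms"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# PDB I/O


def _validate_pdb_lines(path: Path) -> None:
    """Pre-scan ATOM/HETATM records so errors can name the bad line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldstr = line[lo:hi]
                    try:
                        float(fieldstr)
                    except ValueError:
                        raise TrajectoryParseError(
                            f"{path}:{lineno}: malformed coordinate field {fieldstr!r}"
                        ) from None


def read_pdb_trajectory(path: str | Path) -> Trajectory:
    """Read a single- or multi-model (MODEL/ENDMDL) PDB file.

    A single-model file yields a one-frame trajectory.  Models with
    inconsistent atom counts raise :class:`StructuralError`.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise TrajectoryParseError(f"no such file: {path}")
    _validate_pdb_lines(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, extra_fields=["atom_id"])
    except StructuralError:
        raise
    except Exception as exc:  # biotite raises assorted exception types
        msg = str(exc)
        if "same number of atoms" in msg or "inconsistent" in msg.lower():
            raise StructuralError(f"{path}: {msg}") from exc
        raise TrajectoryParseError(f"{path}: {msg}") from exc

    atoms = [
        Atom(
            serial=int(stack.atom_id[i]),
            name=str(stack.atom_name[i]),
            element=str(stack.element[i]).capitalize(),
            res_name=str(stack.res_name[i]),
            res_seq=int(stack.res_id[i]),
            chain_id=str(stack.chain_id[i]),
        )
        for i in range(stack.array_length())
    ]
    return Trajectory(topology=atoms, coords=np.asarray(stack.coord, dtype=float))


def write_pdb_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write MODEL/ENDMDL blocks with fixed-width %8.3f coordinates."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if np.any(np.abs(traj.coords) > 9999.999):
        raise TrajectoryFormatError(
            "coordinates exceed the PDB fixed-width field bound (|x| > 9999.999 Å)"
        )
    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.array([a.chain_id for a in traj.topology])
    arr.res_id = np.array([a.res_seq for a in traj.topology])
    arr.res_name = np.array([a.res_name for a in traj.topology])
    arr.atom_name = np.array([a.name for a in traj.topology])
    arr.element = np.array([a.element.upper() for a in traj.topology])
    arr.set_annotation("atom_id", np.array([a.serial for a in traj.topology]))
    arr.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    if traj.n_frames == 1:
        # biotite omits MODEL/ENDMDL for a single model; keep the
        # multi-model framing so readers see an explicit one-frame file
        text = Path(path).read_text()
        if "MODEL" not in text:
            if text.endswith("END\n"):
                text = text[: -len("END\n")] + "ENDMDL\nEND\n"
            else:
                text += "ENDMDL\n"
            Path(path).write_text("MODEL        1\n" + text)


# ---------------------------------------------------------------------------
# Selections


def select_atoms(
    traj: Trajectory,
    chain: str,
    res_range: tuple[int, int] | None = None,
    names: Iterable[str] | None = None,
) -> np.ndarray:
    """Indices (topology order) of atoms in ``chain``, optionally filtered
    by an inclusive residue range and a set of atom names.

    An unknown chain raises :class:`SelectionError`; an empty selection is
    allowed but logged as a warning.
    """
    chains = {a.chain_id for a in traj.topology}
    if chain not in chains:
        raise SelectionError(f"unknown chain {chain!r}; present: {sorted(chains)}")
    name_set = None if names is None else set(names)
    out = []
    for i, a in enumerate(traj.topology):
        if a.chain_id != chain:
            continue
        if res_range is not None and not (res_range[0] <= a.res_seq <= res_range[1]):
            continue
        if name_set is not None and a.name not in name_set:
            continue
        out.append(i)
    if not out:
        logger.warning(
            "empty selection: chain=%r res_range=%r names=%r", chain, res_range, names
        )
    return np.array(out, dtype=int)


def chain_indices(topology: Sequence[Atom], chain: str) -> np.ndarray:
    idx = np.array([i for i, a in enumerate(topology) if a.chain_id == chain], dtype=int)
    if idx.size == 0:
        raise SelectionError(f"chain {chain!r} not present")
    return idx
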
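"""Trajectory loading, frame iteration and PDB snapshot handling.

The unit of work throughout the package is the :class:`FrameSnapshot`: one
trajectory frame reduced to atoms with names, residue identities and
coordinates.  Ensembles (topology + one or more trajectory files) are loaded
through MDAnalysis and iterated with an optional stride; frames can be split
into contiguous per-worker ranges for parallel prediction, and written out as
single-model PDB files for file-based pKa engines.

Coordinates are only trusted to PDB precision (3 decimals, Angstrom): the PDB
file is the interchange bottleneck between this package and the external
engines, so all round-trip equality is defined at that precision.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger("pkatraj")

__all__ = [
    "ResidueKey",
    "Atom",
    "FrameSnapshot",
    "EnsembleHandle",
    "FrameRange",
    "TopologyError",
    "EmptyEnsembleError",
    "load_ensemble",
    "split_frames",
    "normalize_residue_names",
    "write_snapshot_pdb",
    "read_snapshot_pdb",
    "IONIZABLE_RESNAMES",
]


class TopologyError(ValueError):
    """Topology and trajectory disagree (e.g. atom-count mismatch)."""


class EmptyEnsembleError(ValueError):
    """An ensemble with zero frames after striding."""


#: Residues with a titratable side chain.
IONIZABLE_RESNAMES = frozenset({"ASP", "GLU", "HIS", "CYS", "TYR", "LYS", "ARG"})

#: The canonical 20 amino acids (post-normalization residue vocabulary).
CANONICAL_RESNAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Capping groups passed through untouched.
CAP_RESNAMES = frozenset({"ACE", "NME", "NMA"})

#: Protonation-state / force-field variant names mapped to the canonical
#: residue the pKa engines recognize (AMBER and CHARMM conventions).
RESNAME_NORMALIZATION = {
    "ASH": "ASP",
    "GLH": "GLU",
    "HID": "HIS",
    "HIE": "HIS",
    "HIP": "HIS",
    "HSD": "HIS",
    "HSE": "HIS",
    "HSP": "HIS",
    "CYX": "CYS",
    "CYM": "CYS",
    "LYN": "LYS",
    "ARN": "ARG",
    "TYM": "TYR",
}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue (or terminus group) within a structure."""

    chain_id: str
    resid: int
    resname: str
    terminus_tag: Optional[str] = None  # "N-TERM", "C-TERM" or None

    def label(self) -> str:
        """Column label used in CSV outputs, e.g. ``"ASP 52 A"`` or ``"N+ 1 A"``."""
        if self.terminus_tag == "N-TERM":
            return f"N+ {self.resid} {self.chain_id}"
        if self.terminus_tag == "C-TERM":
            return f"C- {self.resid} {self.chain_id}"
        return f"{self.resname} {self.resid} {self.chain_id}"

    @classmethod
    def from_label(cls, label: str) -> "ResidueKey":
        name, resid, chain = label.split()
        if name == "N+":
            return cls(chain, int(resid), "NTR", "N-TERM")
        if name == "C-":
            return cls(chain, int(resid), "CTR", "C-TERM")
        return cls(chain, int(resid), name)


@dataclass(frozen=True)
class Atom:
    name: str
    residue: ResidueKey
    x: float
    y: float
    z: float
    element: str = ""

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.upper() == "H"
        stripped = self.name.lstrip("0123456789")
        return stripped[:1].upper() == "H"


@dataclass
class FrameSnapshot:
    """One trajectory frame as a flat list of atoms.

    Atom order is meaningful (preserved through mutation and PDB writing);
    atom names are unique within each residue.
    """

    frame_index: int
    time_ps: float
    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def residues(self) -> list[ResidueKey]:
        """Residue keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.residue, None)
        return list(seen)

    def atoms_of(self, residue: ResidueKey) -> list[Atom]:
        return [a for a in self.atoms if a.residue == residue]


@dataclass(frozen=True)
class FrameRange:
    """Contiguous half-open range of sampled-frame indices for one worker."""

    start: int
    stop: int
    worker_id: int

    def __len__(self) -> int:
        return max(0, self.stop - self.start)

    def indices(self) -> range:
        return range(self.start, self.stop)


def split_frames(n_frames: int, n_workers: int) -> list[FrameRange]:
    """Partition ``0..n_frames-1`` into contiguous near-equal worker ranges.

    Earlier workers absorb the remainder; workers beyond the frame count get
    empty ranges.  Contiguous blocks (not round-robin) preserve trajectory
    locality per worker and make merge ordering trivial.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    base, rem = divmod(n_frames, n_workers)
    ranges = []
    start = 0
    for w in range(n_workers):
        size = base + (1 if w < rem else 0)
        ranges.append(FrameRange(start, start + size, w))
        start += size
    return ranges


def normalize_residue_names(snapshot: FrameSnapshot) -> FrameSnapshot:
    """Map protonation-variant residue names to engine-recognized canonical ones.

    ASH->ASP, GLH->GLU, HID/HIE/HIP/HSD/HSE/HSP->HIS, CYX/CYM->CYS, LYN->LYS,
    ARN->ARG, TYM->TYR.  Canonical names and caps pass through; unknown names
    are logged and passed through unchanged.  Coordinates are untouched and the
    operation is idempotent.
    """
    key_map: dict[ResidueKey, ResidueKey] = {}
    warned: set[str] = set()
    new_atoms = []
    for atom in snapshot.atoms:
        key = atom.residue
        if key not in key_map:
            name = key.resname
            if name in RESNAME_NORMALIZATION:
                key_map[key] = replace(key, resname=RESNAME_NORMALIZATION[name])
            else:
                if (
                    name not in CANONICAL_RESNAMES
                    and name not in CAP_RESNAMES
                    and name not in warned
                ):
                    logger.warning(
                        "unknown residue name %r passed through unchanged", name
                    )
                    warned.add(name)
                key_map[key] = key
        new_key = key_map[key]
        new_atoms.append(atom if new_key is key else replace(atom, residue=new_key))
    return FrameSnapshot(snapshot.frame_index, snapshot.time_ps, new_atoms)


# ---------------------------------------------------------------------------
# PDB snapshot I/O
# ---------------------------------------------------------------------------

_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


def _format_atom_name(name: str) -> str:
    # Standard PDB convention: names shorter than 4 chars start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def format_pdb_atom_line(
    serial: int, atom: Atom, bfactor: float = 0.0, occupancy: float = 1.0
) -> str:
    for coord in (atom.x, atom.y, atom.z):
        if not (_PDB_COORD_MIN <= coord <= _PDB_COORD_MAX):
            raise IOError(
                f"coordinate {coord:.3f} exceeds PDB fixed-column width"
            )
    res = atom.residue
    element = atom.element or atom.name.lstrip("0123456789")[:1]
    return (
        f"ATOM  {serial:5d} {_format_atom_name(atom.name)} "
        f"{res.resname:>3s} {res.chain_id:1s}{res.resid:4d}    "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
        f"{occupancy:6.2f}{bfactor:6.2f}          {element:>2s}"
    )


def write_snapshot_pdb(
    snapshot: FrameSnapshot,
    path: str | os.PathLike,
    bfactors: Optional[Sequence[float]] = None,
) -> Path:
    """Write a single-model PDB with ATOM records in input atom order.

    Coordinates are written at PDB precision (3 decimals).  ``bfactors``, when
    given, must have one value per atom and fills the temperature-factor
    column (used by structure mapping).
    """
    if len(snapshot) == 0:
        raise ValueError("cannot write an empty snapshot")
    if bfactors is not None and len(bfactors) != len(snapshot):
        raise ValueError("bfactors length must match atom count")
    path = Path(path)
    lines = []
    for i, atom in enumerate(snapshot.atoms):
        b = bfactors[i] if bfactors is not None else 0.0
        lines.append(format_pdb_atom_line(i + 1, atom, bfactor=b))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_multimodel_pdb(
    snapshots: Sequence[FrameSnapshot], path: str | os.PathLike
) -> Path:
    """Write frames as a multi-model PDB trajectory (MODEL/ENDMDL records)."""
    path = Path(path)
    lines = []
    for m, snap in enumerate(snapshots, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, atom in enumerate(snap.atoms):
            lines.append(format_pdb_atom_line(i + 1, atom))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_snapshot_pdb(
    path: str | os.PathLike, frame_index: int = 0, time_ps: float = 0.0
) -> FrameSnapshot:
    """Parse ATOM/HETATM records of a single-model PDB back to a snapshot."""
    atoms = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        key = ResidueKey(
            chain_id=line[21].strip() or "A",
            resid=int(line[22:26]),
            resname=line[17:20].strip(),
        )
        atoms.append(
            Atom(
                name=line[12:16].strip(),
                residue=key,
                x=float(line[30:38]),
                y=float(line[38:46]),
                z=float(line[46:54]),
                element=line[76:78].strip() if len(line) >= 78 else "",
            )
        )
    return FrameSnapshot(frame_index, time_ps, atoms)


def read_pdb_bfactors(path: str | os.PathLike) -> list[tuple[str, ResidueKey, float]]:
    """Per-atom (name, residue, B-factor) triples from a PDB file."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        key = ResidueKey(
            chain_id=line[21].strip() or "A",
            resid=int(line[22:26]),
            resname=line[17:20].strip(),
        )
        out.append((line[12:16].strip(), key, float(line[60:66])))
    return out


# ---------------------------------------------------------------------------
# Ensemble loading (MDAnalysis-backed)
# ---------------------------------------------------------------------------


class EnsembleHandle:
    """Topology + trajectory files opened for strided frame iteration.

    By default only protein atoms are passed downstream (waters/ions in the
    trajectory are stripped); pass ``selection="all"`` to keep everything.
    """

    def __init__(
        self,
        topology_path: str | os.PathLike,
        trajectory_paths: Sequence[str | os.PathLike],
        stride: int = 1,
        timestep_ps: Optional[float] = None,
        selection: str = "protein",
    ):
        import MDAnalysis as mda

        self.topology_path = Path(topology_path)
        self.trajectory_paths = [Path(p) for p in trajectory_paths]
        if not self.topology_path.exists():
            raise FileNotFoundError(f"topology not found: {self.topology_path}")
        for p in self.trajectory_paths:
            if not p.exists():
                raise FileNotFoundError(f"trajectory not found: {p}")
        if stride < 1:
            raise ValueError(f"stride must be >= 1, got {stride}")
        self.stride = stride
        self.timestep_ps = timestep_ps
        self.selection = selection
        try:
            self._universe = mda.Universe(
                str(self.topology_path),
                [str(p) for p in self.trajectory_paths],
            )
        except (ValueError, TypeError, IOError) as exc:  # MDAnalysis wraps the
            # atom-count mismatch in a TypeError via the chain reader
            raise TopologyError(
                f"topology/trajectory mismatch or unreadable input: {exc}"
            ) from exc
        self._atoms = self._universe.select_atoms(selection)
        if self._atoms.n_atoms == 0:  # fall back when topology lacks protein flags
            self._atoms = self._universe.atoms
        self._total_frames = len(self._universe.trajectory)
        self._frame_indices = list(range(0, self._total_frames, stride))
        if not self._frame_indices:
            raise EmptyEnsembleError("ensemble contains zero frames")

    @property
    def n_frames(self) -> int:
        """Number of sampled frames after striding."""
        return len(self._frame_indices)

    @property
    def n_atoms(self) -> int:
        return self._atoms.n_atoms

    def _frame_time(self, original_index: int) -> float:
        if self.timestep_ps is not None:
            return original_index * self.timestep_ps
        ts = self._universe.trajectory.ts
        t = float(getattr(ts, "time", original_index))
        return t if np.isfinite(t) else float(original_index)

    def get_frame(self, sample_index: int) -> FrameSnapshot:
        """The ``sample_index``-th sampled frame as a snapshot.

        ``frame_index`` on the returned snapshot is the original (unstrided)
        frame number, so stride=2 yields indices 0, 2, 4, ...
        """
        original = self._frame_indices[sample_index]
        self._universe.trajectory[original]
        ag = self._atoms
        chain_ids = _chain_ids(ag)
        elements = _elements(ag)
        time_ps = self._frame_time(original)
        atoms = []
        for i in range(ag.n_atoms):
            key = ResidueKey(
                chain_id=chain_ids[i],
                resid=int(ag.resids[i]),
                resname=str(ag.resnames[i]),
            )
            x, y, z = ag.positions[i]
            atoms.append(
                Atom(str(ag.names[i]), key, float(x), float(y), float(z), elements[i])
            )
        return FrameSnapshot(original, time_ps, atoms)

    def iter_frames(
        self, frame_range: Optional[FrameRange] = None
    ) -> Iterator[FrameSnapshot]:
        rng = frame_range.indices() if frame_range else range(self.n_frames)
        for i in rng:
            yield self.get_frame(i)


def _chain_ids(ag) -> list[str]:
    try:
        return [str(c)[:1] or "A" for c in ag.chainIDs]
    except AttributeError:
        pass
    try:
        return [str(s)[:1] if str(s) else "A" for s in ag.segids]
    except AttributeError:
        return ["A"] * ag.n_atoms


def _elements(ag) -> list[str]:
    try:
        return [str(e) for e in ag.elements]
    except AttributeError:
        return [name.lstrip("0123456789")[:1] for name in ag.names]


def load_ensemble(
    topology_path: str | os.PathLike,
    trajectory_paths: Sequence[str | os.PathLike] | str | os.PathLike,
    stride: int = 1,
    timestep_ps: Optional[float] = None,
    selection: str = "protein",
) -> EnsembleHandle:
    """Open a topology + trajectory set for strided iteration.

    Raises :class:`FileNotFoundError` for missing files, :class:`TopologyError`
    when topology and trajectory atom counts disagree, and
    :class:`EmptyEnsembleError` for zero frames.
    """
    if isinstance(trajectory_paths, (str, os.PathLike)):
        trajectory_paths = [trajectory_paths]
    return EnsembleHandle(
        topology_path, trajectory_paths, stride=stride,
        timestep_ps=timestep_ps, selection=selection,
    )
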
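"""Synthetic structures, trajectories and engine-output fixtures.

Every analysis in this package is testable without external data: this module
generates small peptides with idealized extended-chain geometry (3.8 A
consecutive CA spacing, template side-chain heavy atoms), multi-model PDB
trajectories with coherent sinusoidal motion, labelled Gaussian-blob feature
matrices for clustering tests, and text documents in the empirical engine's
output layout for parser tests.

The generators trade realism for determinism on purpose: pKa engines only
need parseable, sterically sane coordinates, and the sinusoidal motion gives
the mock engine's pKa series a periodic structure that correlation-scan tests
can exploit.  No force-field energetics, solvent or realistic rotamers are
modelled.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .clustering import FeatureMatrix
from .trajectory import (
    Atom,
    FrameSnapshot,
    ResidueKey,
    write_multimodel_pdb,
    write_snapshot_pdb,
)

__all__ = [
    "SyntheticSpec",
    "generate_peptide",
    "generate_trajectory",
    "trajectory_snapshots",
    "generate_blob_features",
    "generate_engine_output_fixture",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Side-chain heavy-atom templates: offsets from CA in Angstrom, extended
# roughly along -y/+z so consecutive side chains (3.8 A apart) do not clash.
_CB = (0.20, -1.25, 0.85)
_CG = (0.25, -2.55, 1.55)
_CD = (0.30, -3.85, 2.25)
_CE = (0.35, -5.15, 2.95)
_CZ = (0.40, -6.45, 3.65)

_SIDECHAINS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", _CB)],
    "SER": [("CB", _CB), ("OG", _CG)],
    "CYS": [("CB", _CB), ("SG", (0.25, -2.75, 1.70))],
    "THR": [("CB", _CB), ("OG1", (-0.95, -2.45, 1.50)), ("CG2", (1.45, -2.45, 1.50))],
    "VAL": [("CB", _CB), ("CG1", (-0.95, -2.45, 1.50)), ("CG2", (1.45, -2.45, 1.50))],
    "LEU": [("CB", _CB), ("CG", _CG), ("CD1", (-0.90, -3.75, 2.20)), ("CD2", (1.50, -3.75, 2.20))],
    "ILE": [("CB", _CB), ("CG1", _CG), ("CG2", (1.45, -1.95, 0.30)), ("CD1", _CD)],
    "MET": [("CB", _CB), ("CG", _CG), ("SD", (0.32, -4.05, 2.40)), ("CE", (0.37, -5.45, 3.15))],
    "PRO": [("CB", _CB), ("CG", _CG), ("CD", (-0.95, -2.25, 0.85))],
    "PHE": [
        ("CB", _CB), ("CG", _CG),
        ("CD1", (-0.95, -3.25, 1.95)), ("CD2", (1.45, -3.25, 1.95)),
        ("CE1", (-0.95, -4.55, 2.70)), ("CE2", (1.45, -4.55, 2.70)),
        ("CZ", (0.25, -5.25, 3.10)),
    ],
    "TYR": [
        ("CB", _CB), ("CG", _CG),
        ("CD1", (-0.95, -3.25, 1.95)), ("CD2", (1.45, -3.25, 1.95)),
        ("CE1", (-0.95, -4.55, 2.70)), ("CE2", (1.45, -4.55, 2.70)),
        ("CZ", (0.25, -5.25, 3.10)), ("OH", (0.25, -6.60, 3.85)),
    ],
    "TRP": [
        ("CB", _CB), ("CG", _CG),
        ("CD1", (-1.00, -3.15, 1.90)), ("CD2", (1.35, -3.25, 1.95)),
        ("NE1", (-0.75, -4.45, 2.60)), ("CE2", (0.65, -4.50, 2.65)),
        ("CE3", (2.70, -3.00, 1.85)), ("CZ2", (1.15, -5.70, 3.30)),
        ("CZ3", (3.20, -4.25, 2.50)), ("CH2", (2.45, -5.55, 3.20)),
    ],
    "ASP": [("CB", _CB), ("CG", _CG), ("OD1", (-0.85, -3.30, 2.00)), ("OD2", (1.35, -3.35, 1.95))],
    "ASN": [("CB", _CB), ("CG", _CG), ("OD1", (-0.85, -3.30, 2.00)), ("ND2", (1.35, -3.35, 1.95))],
    "GLU": [("CB", _CB), ("CG", _CG), ("CD", _CD), ("OE1", (-0.80, -4.60, 2.70)), ("OE2", (1.40, -4.65, 2.65))],
    "GLN": [("CB", _CB), ("CG", _CG), ("CD", _CD), ("OE1", (-0.80, -4.60, 2.70)), ("NE2", (1.40, -4.65, 2.65))],
    "HIS": [
        ("CB", _CB), ("CG", _CG),
        ("ND1", (-0.90, -3.30, 2.00)), ("CD2", (1.35, -3.35, 1.95)),
        ("CE1", (-0.40, -4.55, 2.70)), ("NE2", (0.95, -4.60, 2.65)),
    ],
    "LYS": [("CB", _CB), ("CG", _CG), ("CD", _CD), ("CE", _CE), ("NZ", (0.40, -6.40, 3.60))],
    "ARG": [
        ("CB", _CB), ("CG", _CG), ("CD", _CD), ("NE", (0.35, -5.10, 2.90)),
        ("CZ", _CZ), ("NH1", (-0.75, -7.15, 4.05)), ("NH2", (1.55, -7.10, 4.00)),
    ],
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic peptide ensemble.

    ``timestep_ps`` defaults to 100 ps, a typical frame-sampling interval for
    trajectory pKa tracking; ``motion_amplitude`` is the peak per-atom
    displacement in Angstrom.
    """

    sequence: str
    n_frames: int = 10
    motion_amplitude: float = 1.0
    seed: int = 0
    timestep_ps: float = 100.0

    def __post_init__(self):
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for letter in self.sequence:
            if letter.upper() not in _ONE_TO_THREE:
                raise ValueError(f"unknown amino-acid letter {letter!r}")


def generate_peptide(spec: SyntheticSpec, chain_id: str = "A") -> FrameSnapshot:
    """Extended-chain peptide with idealized geometry.

    Consecutive CA atoms are spaced 3.8 A along x; side-chain heavy atoms
    come from fixed templates.  The C-terminal residue carries an OXT.
    Deterministic: the same spec always yields identical coordinates.
    """
    atoms: list[Atom] = []
    seq = spec.sequence.upper()
    for i, letter in enumerate(seq):
        resname = _ONE_TO_THREE[letter]
        key = ResidueKey(chain_id, i + 1, resname)
        x0 = 3.8 * i
        backbone = [
            ("N", (x0 - 1.20, 0.85, 0.0), "N"),
            ("CA", (x0, 0.0, 0.0), "C"),
            ("C", (x0 + 1.20, 0.85, 0.0), "C"),
            ("O", (x0 + 1.10, 2.08, 0.0), "O"),
        ]
        for name, pos, elem in backbone:
            atoms.append(Atom(name, key, *pos, element=elem))
        for name, (dx, dy, dz) in _SIDECHAINS[resname]:
            atoms.append(
                Atom(name, key, x0 + dx, dy, dz, element=name.lstrip("0123456789")[0])
            )
        if i == len(seq) - 1:
            atoms.append(Atom("OXT", key, x0 + 2.35, 0.55, 0.0, element="O"))
    return FrameSnapshot(0, 0.0, atoms)


def trajectory_snapshots(
    reference: FrameSnapshot, spec: SyntheticSpec
) -> list[FrameSnapshot]:
    """Frames of the sinusoidal synthetic trajectory (in memory).

    Frame k displaces every atom by ``amplitude * sin(2*pi*k/n_frames)`` along
    a fixed per-atom random unit vector drawn from the seed; frame times are
    ``k * timestep_ps``.
    """
    rng = np.random.default_rng(spec.seed)
    directions = rng.normal(size=(len(reference), 3))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    directions /= norms
    ref = reference.coordinates()
    frames = []
    for k in range(spec.n_frames):
        scale = spec.motion_amplitude * np.sin(2.0 * np.pi * k / spec.n_frames)
        coords = ref + scale * directions
        atoms = [
            Atom(a.name, a.residue, *coords[j], element=a.element)
            for j, a in enumerate(reference.atoms)
        ]
        frames.append(FrameSnapshot(k, k * spec.timestep_ps, atoms))
    return frames


def generate_trajectory(
    reference: FrameSnapshot, spec: SyntheticSpec, path: str | os.PathLike
) -> Path:
    """Write the sinusoidal trajectory as a multi-model PDB file.

    Byte-reproducible for a fixed spec (same seed -> identical file).
    """
    return write_multimodel_pdb(trajectory_snapshots(reference, spec), path)


def write_topology(reference: FrameSnapshot, path: str | os.PathLike) -> Path:
    """Write the reference structure as a single-model PDB topology."""
    return write_snapshot_pdb(reference, path)


def generate_blob_features(
    n_per_cluster: int,
    k: int,
    separation_sd: float,
    n_features: int,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Isotropic unit-variance Gaussian blobs with known labels.

    Each blob center sits ``separation_sd`` standard deviations from the
    origin along its own coordinate axis (pairwise center distances are then
    at least ``separation_sd``).  The blobs are drawn directly in the
    normalized feature space — isotropic, unit variance, commensurate axes —
    so the matrix is marked normalized and feeds clustering without further
    scaling.  Returns the matrix and the ground-truth labels for ARI
    evaluation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    centers = np.zeros((k, n_features))
    for j in range(k):
        axis = j % n_features
        shell = j // n_features + 1
        centers[j, axis] = shell * separation_sd
    labels = np.repeat(np.arange(k), n_per_cluster)
    values = centers[labels] + rng.standard_normal((k * n_per_cluster, n_features))
    matrix = FeatureMatrix(
        times=np.arange(k * n_per_cluster, dtype=float),
        labels=[f"f{i}" for i in range(n_features)],
        values=values,
        state="zscored",
    )
    return matrix, labels


def generate_engine_output_fixture(
    entries: Sequence[tuple],
) -> str:
    """A document in the empirical engine's output layout.

    ``entries`` are ``(resname, resid, chain, pka, model_pka, buried_pct)``
    tuples (``buried_pct`` may be None).  The document contains a per-group
    detail section carrying the buried percentage and a summary section
    carrying pKa and model pKa, exactly as the engine's text output does.
    """
    lines = [
        "propka3.5.0                                             2026-09-24",
        "",
        "-" * 100,
        " RESIDUE    pKa   BURIED     DESOLVATION    EFFECTS",
        "-" * 100,
    ]
    for entry in entries:
        resname, resid, chain, pka, model, buried = (list(entry) + [None])[:6]
        if buried is not None:
            lines.append(
                f"   {resname:>3s} {resid:3d} {chain}   {pka:5.2f}   {buried:3.0f} %"
                "    0.00  000   0.00    0"
            )
    lines += [
        "",
        "-" * 100,
        "SUMMARY OF THIS PREDICTION",
        "       Group      pKa  model-pKa   ligand atom-type",
    ]
    for entry in entries:
        resname, resid, chain, pka, model, _buried = (list(entry) + [None])[:6]
        lines.append(f"   {resname:>3s} {resid:3d} {chain}   {pka:6.2f}     {model:6.2f}")
    lines.append("-" * 100)
    return "\n".join(lines) + "\n"
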
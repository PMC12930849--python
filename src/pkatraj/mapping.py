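"""Mapping per-residue scalars onto a 3D structure for visualization.

A :class:`ResidueValueMap` pairs a reference snapshot with one scalar per
residue (a single-frame pKa, a trajectory mean, the shift of the mean from
the model pKa, or a buried ratio).  The map is written as

* an annotated PDB whose temperature-factor (B-factor) column carries the
  residue's value on every atom of that residue, and
* a plain-text PyMOL-style command script that loads the PDB and applies a
  color spectrum over the written value range (centered at 0 for delta maps).

B-factors are written at the standard 2-decimal precision, which bounds the
representable magnitude (|v| < 1000).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .timeseries import ResidueSummary
from .trajectory import FrameSnapshot, ResidueKey, write_snapshot_pdb

logger = logging.getLogger("pkatraj")

__all__ = [
    "ResidueValueMap",
    "write_annotated_structure",
    "delta_from_model_map",
]

VALUE_KINDS = ("pka_frame", "pka_mean", "delta_model", "buried")


@dataclass
class ResidueValueMap:
    """Per-residue scalar values anchored to a reference structure.

    Residues are matched by (chain, resid); termini groups map onto their
    parent residue.  Residues without a value receive ``unmapped_fill`` (the
    value-range midpoint by default — neutral under a symmetric color
    spectrum).
    """

    snapshot: FrameSnapshot
    values: dict[ResidueKey, float]
    value_kind: str = "pka_frame"
    unmapped_fill: Optional[float] = None

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        present = {(k.chain_id, k.resid) for k in self.snapshot.residues()}
        for key in self.values:
            if (key.chain_id, key.resid) not in present:
                raise ValueError(
                    f"valued residue {key.label()} absent from reference snapshot"
                )

    def fill_value(self) -> float:
        if self.unmapped_fill is not None:
            return self.unmapped_fill
        if not self.values:
            return 0.0
        vals = np.array(list(self.values.values()), dtype=float)
        return float((vals.min() + vals.max()) / 2.0)


def _spectrum_script(pdb_name: str, vmin: float, vmax: float, centered: bool) -> str:
    if centered:
        bound = max(abs(vmin), abs(vmax)) or 1.0
        vmin, vmax = -bound, bound
    if vmin == vmax:
        vmax = vmin + 1.0
    return "\n".join(
        [
            f"load {pdb_name}",
            "hide everything",
            "show cartoon",
            "show sticks, not (name C+N+O and not resn PRO)",
            f"spectrum b, blue_white_red, minimum={vmin:.3f}, maximum={vmax:.3f}",
            "set cartoon_transparency, 0.2",
        ]
    ) + "\n"


def write_annotated_structure(
    value_map: ResidueValueMap, out_path: str | os.PathLike
) -> tuple[Path, Path]:
    """Write the annotated PDB and its companion ``.pml`` command script.

    Every atom of a valued residue gets the residue's value in the B-factor
    column; unmapped residues get the fill value.  Values with |v| >= 1000 do
    not fit the B-factor column and raise ``ValueError``.
    """
    out_path = Path(out_path)
    by_residue = {(k.chain_id, k.resid): v for k, v in value_map.values.items()}
    for v in by_residue.values():
        if abs(v) >= 1000:
            raise ValueError(f"value {v} exceeds the PDB B-factor column width")
    fill = value_map.fill_value()
    bfactors = [
        by_residue.get((a.residue.chain_id, a.residue.resid), fill)
        for a in value_map.snapshot.atoms
    ]
    write_snapshot_pdb(value_map.snapshot, out_path, bfactors=bfactors)

    written = list(by_residue.values()) or [fill]
    script_path = out_path.with_suffix(".pml")
    script_path.write_text(
        _spectrum_script(
            out_path.name,
            min(written),
            max(written),
            centered=value_map.value_kind == "delta_model",
        )
    )
    return out_path, script_path


def delta_from_model_map(
    summaries: Sequence[ResidueSummary],
    reference: FrameSnapshot,
    unmapped_fill: Optional[float] = None,
) -> ResidueValueMap:
    """Map of mean pKa minus model pKa per residue.

    Positive values mark residues whose trajectory-average pKa is upshifted
    from the isolated-amino-acid reference.  Residues whose engine reported no
    model value are left unmapped with a warning.
    """
    values: dict[ResidueKey, float] = {}
    for s in summaries:
        if not np.isfinite(s.model_pka) or not np.isfinite(s.mean):
            logger.warning(
                "residue %s has no model value; left unmapped", s.residue.label()
            )
            continue
        values[s.residue] = s.mean - s.model_pka
    return ResidueValueMap(
        snapshot=reference,
        values=values,
        value_kind="delta_model",
        unmapped_fill=unmapped_fill,
    )
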
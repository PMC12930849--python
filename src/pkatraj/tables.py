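"""Per-frame, per-residue value tables and their CSV serialization.

The central container is :class:`PkaTable`: a frames x ionizable-residues
matrix of predicted pKa values (or buried ratios), indexed by snapshot time in
picoseconds, with one column per residue labelled ``"RESNAME RESID CHAIN"``
(e.g. ``"ASP 52 A"``; termini are ``"N+ 1 A"`` / ``"C- 129 A"``).  pKa tables
additionally carry the engine-reported model pKa per residue.

CSV files are wide format: header comment lines (tool version, seed, model
pKa values), then ``time_ps`` followed by the residue columns, rows sorted by
snapshot time.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .trajectory import ResidueKey

__all__ = ["PkaTable", "BuriedTable", "write_table_csv", "read_table_csv"]


@dataclass
class PkaTable:
    """Frames x residues value matrix with per-residue model pKa.

    ``data`` has a float ``time_ps`` index (strictly increasing) and residue
    labels as columns.  ``model_pka`` is indexed by the same labels; it is
    ``None`` for tables of properties without a reference value (buried
    ratios).
    """

    data: pd.DataFrame
    model_pka: Optional[pd.Series] = None
    kind: str = "pka"

    def __post_init__(self):
        times = self.data.index.to_numpy(dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def residues(self) -> list[ResidueKey]:
        return [ResidueKey.from_label(c) for c in self.data.columns]

    def column(self, residue: ResidueKey | str) -> pd.Series:
        label = residue if isinstance(residue, str) else residue.label()
        if label not in self.data.columns:
            raise KeyError(f"residue {label!r} not in table")
        return self.data[label]

    def model_value(self, residue: ResidueKey | str) -> float:
        if self.model_pka is None:
            return float("nan")
        label = residue if isinstance(residue, str) else residue.label()
        return float(self.model_pka.get(label, float("nan")))


#: Buried-ratio tables share the container; they simply carry no model pKa.
BuriedTable = PkaTable


def write_table_csv(
    table: PkaTable, path: str | os.PathLike, meta: Optional[dict] = None
) -> Path:
    """Serialize a table to wide CSV with ``#`` header comments."""
    path = Path(path)
    lines = [f"# pkatraj {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    if table.model_pka is not None:
        pairs = "; ".join(
            f"{label}={table.model_pka[label]}" for label in table.data.columns
        )
        lines.append(f"# model_pka: {pairs}")
    buf = io.StringIO()
    out = table.data.copy()
    out.insert(0, "time_ps", table.times)
    out.to_csv(buf, index=False)
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())
    return path


def read_table_csv(path: str | os.PathLike, kind: str = "pka") -> PkaTable:
    """Read a table written by :func:`write_table_csv`."""
    text = Path(path).read_text()
    model: Optional[pd.Series] = None
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("# ")
            if stripped.startswith("model_pka:"):
                pairs = stripped[len("model_pka:"):].strip()
                values = {}
                for item in pairs.split(";"):
                    item = item.strip()
                    if item:
                        label, val = item.rsplit("=", 1)
                        values[label.strip()] = float(val)
                model = pd.Series(values)
        else:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    if "time_ps" not in df.columns:
        raise ValueError(f"{path}: missing time_ps column")
    df = df.set_index("time_ps")
    df.index = df.index.astype(float)
    return PkaTable(data=df, model_pka=model, kind=kind)
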
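"""Distributions, time evolutions and correlation scans of per-frame pKa.

All operations consume :class:`~pkatraj.tables.PkaTable` objects.  The key
analyses are

* per-residue summaries (mean/sd/min/max and the shift of the mean from the
  engine's model pKa),
* running-average time evolutions (centered window, given either in frames or
  as a time span such as 5 ns),
* pKa histograms per residue (fixed-width bins aligned at 0),
* protonation-sensitivity flagging: the fraction of frames whose pKa falls
  within a window around a reference pH, i.e. the range where both protonation
  states are expected to have significant populations,
* correlation scanning of every residue's pKa series against user-supplied
  time-dependent properties (typically principal-component projections of the
  trajectory, which this package never computes itself),
* cross-replica averaging and wild-type vs pseudo-mutant profile comparison.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tables import PkaTable
from .trajectory import ResidueKey

logger = logging.getLogger("pkatraj")

__all__ = [
    "ResidueSummary",
    "running_average",
    "window_frames_from_time",
    "summarize",
    "distribution",
    "correlation_scan",
    "flag_protonation_sensitive",
    "average_over_replicas",
    "compare_mutant_profiles",
    "MutantComparison",
    "read_property_series",
]


@dataclass
class ResidueSummary:
    residue: ResidueKey
    mean: float
    sd: float
    min: float
    max: float
    model_pka: float

    @property
    def delta_from_model(self) -> float:
        """Shift of the trajectory-average pKa from the engine's model value."""
        return self.mean - self.model_pka


def running_average(series, window_frames: int):
    """Centered moving mean; edge windows shrink, output length is preserved.

    Even windows are rounded up to the next odd number so the window stays
    symmetric around the center frame.
    """
    x = np.asarray(series, dtype=float)
    if window_frames < 1:
        raise ValueError(f"window must be >= 1, got {window_frames}")
    if window_frames % 2 == 0:
        window_frames += 1
        logger.warning("even running-average window rounded up to %d", window_frames)
    if window_frames > len(x):
        raise ValueError(
            f"window {window_frames} larger than series length {len(x)}"
        )
    out = (
        pd.Series(x)
        .rolling(window_frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index)
    return out


def window_frames_from_time(window_ps: float, timestep_ps: float) -> int:
    """Convert a time-span window (e.g. 5 ns = 5000 ps) to an odd frame count."""
    if window_ps <= 0 or timestep_ps <= 0:
        raise ValueError("window and timestep must be positive")
    n = max(1, int(round(window_ps / timestep_ps)))
    return n + 1 if n % 2 == 0 else n


def summarize(table: PkaTable) -> list[ResidueSummary]:
    """Per-residue statistics over non-missing frames.

    Standard deviation is the population sd (a single frame gives sd 0).
    All-missing columns yield NaN statistics.
    """
    if table.n_frames < 1:
        raise ValueError("cannot summarize an empty table")
    out = []
    for key in table.residues:
        col = table.column(key).dropna()
        if col.empty:
            logger.warning("residue %s has no finite frames; summary undefined", key.label())
            out.append(
                ResidueSummary(key, np.nan, np.nan, np.nan, np.nan, table.model_value(key))
            )
            continue
        out.append(
            ResidueSummary(
                residue=key,
                mean=float(col.mean()),
                sd=float(col.std(ddof=0)),
                min=float(col.min()),
                max=float(col.max()),
                model_pka=table.model_value(key),
            )
        )
    return out


def summary_frame(summaries: Sequence[ResidueSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame (one row per residue) for CSV export."""
    return pd.DataFrame(
        {
            "residue": [s.residue.label() for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
            "min": [s.min for s in summaries],
            "max": [s.max for s in summaries],
            "model_pka": [s.model_pka for s in summaries],
            "delta_from_model": [s.delta_from_model for s in summaries],
        }
    )


def distribution(table: PkaTable, bin_width: float = 0.1) -> pd.DataFrame:
    """Histogram of pKa values per residue.

    Bins are left-closed right-open, aligned at integer multiples of
    ``bin_width`` (so counts are reproducible across runs); counts per residue
    sum to that residue's non-missing frame count.  Returns a long-format
    DataFrame with columns residue, bin_left, count.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    rows = []
    for key in table.residues:
        col = table.column(key).dropna().to_numpy()
        if col.size == 0:
            continue
        idx = np.floor(col / bin_width + 1e-9).astype(int)
        for b, c in zip(*np.unique(idx, return_counts=True)):
            rows.append((key.label(), b * bin_width, int(c)))
    return pd.DataFrame(rows, columns=["residue", "bin_left", "count"])


def _match_properties(table: PkaTable, properties: pd.DataFrame) -> pd.DataFrame:
    """Align property rows to table frames.

    Same length -> matched by row order.  Otherwise a ``time_ps`` column is
    required and rows are matched by nearest time within half a timestep.
    """
    props = properties.copy()
    has_time = "time_ps" in props.columns
    if len(props) == len(table.data) and not has_time:
        props.index = table.data.index
        return props
    if not has_time:
        raise ValueError(
            f"property series length {len(props)} does not match frame count "
            f"{table.n_frames} and no time_ps column is present"
        )
    times = table.times
    tol = 0.5 * float(np.median(np.diff(times))) if len(times) > 1 else np.inf
    prop_times = props["time_ps"].to_numpy(dtype=float)
    cols = props.drop(columns=["time_ps"])
    matched = np.full((len(times), cols.shape[1]), np.nan)
    for i, t in enumerate(times):
        j = int(np.argmin(np.abs(prop_times - t)))
        if abs(prop_times[j] - t) <= tol:
            matched[i] = cols.iloc[j].to_numpy(dtype=float)
    if np.isnan(matched).all():
        raise ValueError("no property rows match the table's frame times")
    return pd.DataFrame(matched, index=table.data.index, columns=cols.columns)


def correlation_scan(
    table: PkaTable,
    properties: pd.DataFrame,
    method: str = "pearson",
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Correlation of every residue's pKa series with every property series.

    Scans all ionizable residues against user-supplied time-dependent
    properties (e.g. principal-component projections) to flag possible
    couplings between pKa and collective motions.  The coefficient is Pearson
    by default (Spearman optional), signed, and the report is sorted by
    absolute value.  Zero-variance series yield a missing (NaN) coefficient,
    never 0.  When ``threshold`` is given, pairs with |r| above it are flagged.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    props = _match_properties(table, properties)
    rows = []
    for key in table.residues:
        y = table.column(key)
        for prop_name in props.columns:
            x = props[prop_name]
            mask = y.notna() & x.notna()
            n = int(mask.sum())
            yv, xv = y[mask], x[mask]
            if n < 2 or yv.std(ddof=0) == 0 or xv.std(ddof=0) == 0:
                r = np.nan
            else:
                r = float(yv.corr(xv, method=method))
            rows.append((key.label(), str(prop_name), r, n))
    report = pd.DataFrame(
        rows, columns=["residue", "property", "correlation", "n_samples"]
    )
    report = report.sort_values(
        "correlation", key=lambda s: s.abs(), ascending=False, kind="stable"
    ).reset_index(drop=True)
    if threshold is not None:
        report["flagged"] = report["correlation"].abs() >= threshold
    return report


def flag_protonation_sensitive(
    table: PkaTable, reference_ph: float = 7.4, half_width: float = 1.0
) -> pd.DataFrame:
    """Residues whose pKa visits the window around the reference pH.

    Within ``reference_ph +/- half_width`` both protonation states have
    significant populations (the +/-1 unit default spans roughly 10-90%
    protonation), so frames in this range flag residues for which alternative
    fixed protonation states or constant-pH MD may be warranted.  Returns
    residues with a positive frame fraction, sorted descending.
    """
    if half_width <= 0:
        raise ValueError(f"half_width must be positive, got {half_width}")
    lo, hi = reference_ph - half_width, reference_ph + half_width
    rows = []
    for key in table.residues:
        col = table.column(key).dropna()
        if col.empty:
            continue
        frac = float(((col >= lo) & (col <= hi)).mean())
        if frac > 0:
            rows.append((key.label(), frac, len(col)))
    df = pd.DataFrame(rows, columns=["residue", "fraction_in_window", "n_frames"])
    return df.sort_values(
        "fraction_in_window", ascending=False, kind="stable"
    ).reset_index(drop=True)


def average_over_replicas(tables: Sequence[PkaTable]) -> pd.DataFrame:
    """Cross-replica average of per-replica mean pKa values.

    The cross-replica mean is the unweighted mean of the per-replica means.
    Residues missing from some replicas are averaged over the replicas where
    they are present and flagged in the ``partial`` column.  Replicas with
    fully disjoint residue sets raise ``ValueError``.
    """
    if not tables:
        raise ValueError("no replicas given")
    per_replica = pd.DataFrame(
        {i: t.data.mean() for i, t in enumerate(tables)}
    )
    common = per_replica.dropna(how="any")
    if len(tables) > 1 and common.empty:
        raise ValueError("replicas share no residue columns")
    out = pd.DataFrame(
        {
            "mean_pka": per_replica.mean(axis=1),
            "n_replicas": per_replica.notna().sum(axis=1),
        }
    )
    out["partial"] = out["n_replicas"] < len(tables)
    for i in per_replica.columns:
        out[f"replica_{i}_mean"] = per_replica[i]
    for key, flag in out["partial"].items():
        if flag:
            logger.warning("residue %s missing from some replicas", key)
    out.index.name = "residue"
    return out


@dataclass
class MutantComparison:
    """Wild-type vs pseudo-mutant pKa profile difference for one residue."""

    residue: ResidueKey
    delta: pd.Series  # per-frame mutant - wild
    mean_shift: float
    fluctuation_ratio: float  # sd(mutant) / sd(wild); 0 when mutant is flat


def compare_mutant_profiles(
    wild: PkaTable, mutant: PkaTable, residue: ResidueKey | str
) -> MutantComparison:
    """Compare a residue's pKa time evolution with and without a pseudo-mutation.

    A pure mean shift leaves the fluctuation ratio at 1; a neighbour that
    modulates the *shape* of the profile (e.g. by intermittent hydrogen
    bonding) changes sd(mutant)/sd(wild) as well.
    """
    if not np.array_equal(wild.times, mutant.times):
        raise ValueError("wild and mutant tables have different time axes")
    key = residue if isinstance(residue, ResidueKey) else ResidueKey.from_label(residue)
    w = wild.column(key)
    m = mutant.column(key)
    delta = m - w
    sd_w = float(w.std(ddof=0))
    sd_m = float(m.std(ddof=0))
    ratio = sd_m / sd_w if sd_w > 0 else np.nan
    return MutantComparison(
        residue=key,
        delta=delta,
        mean_shift=float(delta.mean()),
        fluctuation_ratio=ratio,
    )


def read_property_series(path: str | os.PathLike) -> pd.DataFrame:
    """Read user-supplied time-dependent properties (e.g. PC projections).

    Accepts whitespace- or comma-delimited columns with an optional header
    row; headerless files get columns named prop_0, prop_1, ...
    """
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0]
    sep = "," if "," in first else r"\s+"
    tokens = first.replace(",", " ").split()

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = None if all(_is_number(t) for t in tokens) else 0
    df = pd.read_csv(path, sep=sep, header=header, comment="#")
    if header is None:
        df.columns = [f"prop_{i}" for i in range(df.shape[1])]
    return df
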
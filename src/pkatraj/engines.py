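"""Per-structure pKa engines and the iterative prediction pipeline.

An engine predicts the pKa of every ionizable residue of a single structure.
Three implementations are registered:

``propka``
    The empirical predictor PROPKA 3, called through its Python API on a
    temporary PDB snapshot; its text output is parsed for pKa, model pKa and
    the buried ratio (%).  Requires the ``propka`` package.
``pkai``
    The deep-learning predictor pKAI, called through its Python API on a
    temporary PDB snapshot.  pKAI reports no model pKa or buried ratio.
    Requires the ``pKAI`` package.
``mock``
    A deterministic built-in engine for testing and plumbing validation: for
    each ionizable residue i, ``pka_i = model(resname) + 0.1 * d_i`` where
    ``d_i`` is the distance (A) from residue i's heavy-atom centroid to the
    structure's backbone heavy-atom centroid, and
    ``buried_i = 100 * max(0, 1 - d_i/20)`` clamped to [0, 100].  Using the
    backbone (N, CA, C, O, OXT) as reference makes the prediction for residue
    i depend only on residue i's own side chain: it is invariant both to
    rigid translation of the structure and to alanine pseudo-mutations of
    *other* residues, which is what makes the mock usable as an oracle for
    the pipeline's plumbing.

The pipeline iterates frames of an ensemble (normalize residue names ->
optional alanine pseudo-mutation -> write temporary PDB -> predict -> parse),
splits frames into contiguous worker ranges, and merges partial results into
tables sorted by snapshot time.  Output is identical for any worker count.
Temporary snapshot and engine-output files are deleted after each frame.
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mutation import MutationSpec, apply_alanine_mutation
from .tables import BuriedTable, PkaTable
from .trajectory import (
    IONIZABLE_RESNAMES,
    EnsembleHandle,
    FrameSnapshot,
    ResidueKey,
    load_ensemble,
    normalize_residue_names,
    split_frames,
    write_snapshot_pdb,
)

logger = logging.getLogger("pkatraj")

__all__ = [
    "EngineSpec",
    "PkaEntry",
    "PredictionResult",
    "EngineNotAvailableError",
    "EngineError",
    "ParseError",
    "MergeError",
    "PipelineError",
    "MockEngine",
    "PropkaEngine",
    "PkaiEngine",
    "create_engine",
    "predict_frame",
    "mock_predict",
    "parse_propka_output",
    "merge_worker_outputs",
    "run_prediction_pipeline",
    "PipelineResult",
    "MOCK_MODEL_PKA",
]


class EngineNotAvailableError(RuntimeError):
    """The requested engine package is not installed (configuration error)."""


class EngineError(RuntimeError):
    """The engine failed on one frame."""


class ParseError(ValueError):
    """Engine output document could not be parsed."""


class MergeError(ValueError):
    """Partial worker outputs overlap in frame index."""


class PipelineError(RuntimeError):
    """Every frame of a prediction run failed."""


@dataclass(frozen=True)
class PkaEntry:
    """One residue's prediction: pKa, engine model pKa, optional buried %."""

    pka: float
    model_pka: float
    buried_pct: Optional[float] = None

    def __post_init__(self):
        if self.buried_pct is not None and not (0.0 <= self.buried_pct <= 100.0):
            raise ValueError(f"buried_pct {self.buried_pct} outside [0, 100]")


@dataclass
class PredictionResult:
    frame_index: int
    time_ps: float
    entries: dict[ResidueKey, PkaEntry]


@dataclass
class EngineSpec:
    """Which engine to run and how.

    ``engine_options`` is passed to the engine constructor; the buried ratio
    is available only from the propka and mock engines.
    """

    engine_name: str = "propka"
    engine_options: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mock engine
# ---------------------------------------------------------------------------

#: Reference model pKa table of the mock engine — typical solution values of
#: the isolated amino acids; configurable via engine_options["model_table"].
MOCK_MODEL_PKA = {
    "ASP": 3.80,
    "GLU": 4.50,
    "HIS": 6.50,
    "CYS": 9.00,
    "TYR": 10.00,
    "LYS": 10.50,
    "ARG": 12.50,
}


def mock_predict(
    snapshot: FrameSnapshot, model_table: Optional[dict] = None
) -> PredictionResult:
    """Deterministic geometric mock prediction (see module docstring).

    The reference point is the backbone heavy-atom centroid, so the
    prediction for residue i depends only on its own heavy-atom centroid
    relative to a frame of reference that rigid translation and alanine
    pseudo-mutation of other residues both leave untouched.
    """
    if len(snapshot) == 0:
        raise ValueError("cannot predict on an empty snapshot")
    table = dict(MOCK_MODEL_PKA)
    if model_table:
        table.update(model_table)
    heavy = [a for a in snapshot.atoms if not a.is_hydrogen]
    if not heavy:
        raise ValueError("snapshot has no heavy atoms")
    backbone = [a for a in heavy if a.name in ("N", "CA", "C", "O", "OXT")]
    overall = np.mean([[a.x, a.y, a.z] for a in (backbone or heavy)], axis=0)
    entries: dict[ResidueKey, PkaEntry] = {}
    by_residue: dict[ResidueKey, list] = {}
    for atom in heavy:
        by_residue.setdefault(atom.residue, []).append([atom.x, atom.y, atom.z])
    for key, coords in by_residue.items():
        if key.resname not in IONIZABLE_RESNAMES:
            continue
        d = float(np.linalg.norm(np.mean(coords, axis=0) - overall))
        buried = float(np.clip(100.0 * (1.0 - d / 20.0), 0.0, 100.0))
        entries[key] = PkaEntry(
            pka=table[key.resname] + 0.1 * d,
            model_pka=table[key.resname],
            buried_pct=buried,
        )
    return PredictionResult(snapshot.frame_index, snapshot.time_ps, entries)


class MockEngine:
    name = "mock"
    supports_buried = True
    needs_pdb = False

    def __init__(self, model_table: Optional[dict] = None):
        self.model_table = dict(model_table) if model_table else None

    def predict(
        self, snapshot: FrameSnapshot, pdb_path: Optional[Path] = None
    ) -> PredictionResult:
        return mock_predict(snapshot, self.model_table)


# ---------------------------------------------------------------------------
# PROPKA output parsing
# ---------------------------------------------------------------------------

_SUMMARY_MARKER = "SUMMARY OF THIS PREDICTION"
_SUMMARY_ROW = re.compile(
    r"^\s*(N\+|C-|[A-Z][A-Z0-9]{1,2})\s+(\d+)\s+(\S)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)"
)
_DETAIL_ROW = re.compile(
    r"^\s*(N\+|C-|[A-Z][A-Z0-9]{1,2})\s+(\d+)\s+(\S)\s+(-?\d+\.\d+)\*?\s+(\d+)\s*%"
)


def _group_key(name: str, resid: int, chain: str) -> ResidueKey:
    if name == "N+":
        return ResidueKey(chain, resid, "NTR", "N-TERM")
    if name == "C-":
        return ResidueKey(chain, resid, "CTR", "C-TERM")
    return ResidueKey(chain, resid, name)


def parse_propka_output(
    text: str, frame_index: int = 0, time_ps: float = 0.0
) -> PredictionResult:
    """Parse a PROPKA ``.pka`` document into per-residue entries.

    pKa and model pKa come from the summary section; the buried percentage
    comes from the per-group detail section that precedes it.  Residues are
    keyed by (resname, resid, chain); the termini groups ``N+``/``C-`` are
    kept as separate keys.
    """
    if _SUMMARY_MARKER not in text:
        raise ParseError("missing summary section in engine output")
    detail_text, summary_text = text.split(_SUMMARY_MARKER, 1)

    buried: dict[ResidueKey, float] = {}
    for line in detail_text.splitlines():
        m = _DETAIL_ROW.match(line)
        if m:
            name, resid, chain, _pka, pct = m.groups()
            value = float(pct)
            if not (0.0 <= value <= 100.0):
                raise ParseError(f"buried percentage {value} outside [0, 100]")
            buried[_group_key(name, int(resid), chain)] = value

    entries: dict[ResidueKey, PkaEntry] = {}
    for line in summary_text.splitlines():
        m = _SUMMARY_ROW.match(line)
        if m:
            name, resid, chain, pka, model = m.groups()
            key = _group_key(name, int(resid), chain)
            entries[key] = PkaEntry(
                pka=float(pka),
                model_pka=float(model),
                buried_pct=buried.get(key),
            )
    if not entries:
        raise ParseError("summary section contains no residue rows")
    return PredictionResult(frame_index, time_ps, entries)


# ---------------------------------------------------------------------------
# External engine adapters (lazy imports; never re-implemented)
# ---------------------------------------------------------------------------


@contextmanager
def _chdir(path: Path):
    old = os.getcwd()
    os.chdir(path)
    try:
        yield
    finally:
        os.chdir(old)


class PropkaEngine:
    """PROPKA 3 through its Python API (``propka.run.single``)."""

    name = "propka"
    supports_buried = True
    needs_pdb = True

    def __init__(self, **options):
        try:
            import propka.run  # noqa: F401
        except ImportError as exc:
            raise EngineNotAvailableError(
                "the 'propka' package is not installed; "
                "install it or choose another engine"
            ) from exc
        self.options = options

    def predict(
        self, snapshot: FrameSnapshot, pdb_path: Optional[Path] = None
    ) -> PredictionResult:
        import propka.run

        if pdb_path is None:
            raise EngineError("propka engine requires a PDB snapshot file")
        pdb_path = Path(pdb_path)
        optargs = self.options.get("optargs", [])
        with _chdir(pdb_path.parent):
            propka.run.single(pdb_path.name, optargs=optargs, write_pka=True)
            pka_file = pdb_path.with_suffix(".pka")
            try:
                text = pka_file.read_text()
            finally:
                pka_file.unlink(missing_ok=True)
        return parse_propka_output(text, snapshot.frame_index, snapshot.time_ps)


class PkaiEngine:
    """pKAI through its Python API; reports no model pKa or buried ratio."""

    name = "pkai"
    supports_buried = False
    needs_pdb = True

    def __init__(self, model_name: str = "pKAI", **options):
        try:
            from pKAI.pKAI import pKAI  # noqa: F401
        except ImportError as exc:
            raise EngineNotAvailableError(
                "the 'pKAI' package is not installed; "
                "install it or choose another engine"
            ) from exc
        self.model_name = model_name
        self.options = options

    def predict(
        self, snapshot: FrameSnapshot, pdb_path: Optional[Path] = None
    ) -> PredictionResult:
        from pKAI.pKAI import pKAI

        if pdb_path is None:
            raise EngineError("pKAI engine requires a PDB snapshot file")
        raw = pKAI(str(pdb_path), model_name=self.model_name)
        entries: dict[ResidueKey, PkaEntry] = {}
        items = raw.items() if isinstance(raw, dict) else raw
        for item in items:
            if isinstance(item, tuple) and len(item) == 2:  # dict items
                (chain, resid, resname), pka = item[0], item[1]
            else:  # list of (chain, resid, resname, pka)
                chain, resid, resname, pka = item
            key = ResidueKey(str(chain), int(resid), str(resname))
            entries[key] = PkaEntry(pka=float(pka), model_pka=float("nan"))
        if not entries:
            raise ParseError("pKAI returned no ionizable residues")
        return PredictionResult(snapshot.frame_index, snapshot.time_ps, entries)


_ENGINES = {"mock": MockEngine, "propka": PropkaEngine, "pkai": PkaiEngine}


def create_engine(spec: EngineSpec):
    """Instantiate the engine named by the spec; availability is checked here,
    before any frame is processed."""
    try:
        cls = _ENGINES[spec.engine_name]
    except KeyError:
        raise ValueError(
            f"unknown engine {spec.engine_name!r}; choose from {sorted(_ENGINES)}"
        ) from None
    return cls(**spec.engine_options)


def predict_frame(snapshot: FrameSnapshot, spec: EngineSpec) -> PredictionResult:
    """Run the engine on one (already normalized) snapshot.

    File-based engines get a temporary PDB that is removed afterwards together
    with any engine output.
    """
    engine = create_engine(spec)
    return _predict_with_engine(snapshot, engine)


def _predict_with_engine(snapshot: FrameSnapshot, engine) -> PredictionResult:
    if not engine.needs_pdb:
        return engine.predict(snapshot)
    with tempfile.TemporaryDirectory(prefix="pkatraj_") as tmp:
        pdb_path = Path(tmp) / f"frame_{snapshot.frame_index}.pdb"
        write_snapshot_pdb(snapshot, pdb_path)
        return engine.predict(snapshot, pdb_path=pdb_path)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class FrameFailure:
    frame_index: int
    message: str


@dataclass
class PipelineResult:
    pka: PkaTable
    buried: Optional[BuriedTable]
    failures: list[FrameFailure]


def _sorted_keys(keys) -> list[ResidueKey]:
    # chain, resid, then side-chain group before termini for stable columns
    return sorted(keys, key=lambda k: (k.chain_id, k.resid, k.terminus_tag or "", k.resname))


def merge_worker_outputs(
    partials: Sequence[Sequence[PredictionResult]],
    include_buried: bool = True,
) -> tuple[PkaTable, Optional[BuriedTable]]:
    """Merge per-worker result lists into tables sorted by snapshot time.

    The column set is the union of residues over all frames (constant for a
    fixed topology).  Duplicate frame indices across partials raise
    :class:`MergeError`.
    """
    results: list[PredictionResult] = []
    seen: set[int] = set()
    for partial in partials:
        for res in partial:
            if res.frame_index in seen:
                raise MergeError(f"duplicate frame index {res.frame_index} in partials")
            seen.add(res.frame_index)
            results.append(res)
    if not results:
        raise MergeError("no prediction results to merge")
    results.sort(key=lambda r: (r.time_ps, r.frame_index))

    keys = _sorted_keys({k for r in results for k in r.entries})
    labels = [k.label() for k in keys]
    times = [r.time_ps for r in results]
    pka_rows = np.full((len(results), len(keys)), np.nan)
    buried_rows = np.full((len(results), len(keys)), np.nan)
    model: dict[str, float] = {}
    any_buried = False
    for i, res in enumerate(results):
        for j, key in enumerate(keys):
            entry = res.entries.get(key)
            if entry is None:
                continue
            pka_rows[i, j] = entry.pka
            model.setdefault(key.label(), entry.model_pka)
            if entry.buried_pct is not None:
                buried_rows[i, j] = entry.buried_pct
                any_buried = True

    index = pd.Index(times, name="time_ps", dtype=float)
    pka_table = PkaTable(
        data=pd.DataFrame(pka_rows, index=index, columns=labels),
        model_pka=pd.Series({lab: model.get(lab, np.nan) for lab in labels}),
        kind="pka",
    )
    buried_table = None
    if include_buried and any_buried:
        buried_table = BuriedTable(
            data=pd.DataFrame(buried_rows, index=index, columns=labels),
            model_pka=None,
            kind="buried",
        )
    return pka_table, buried_table


def _run_range(
    ensemble: EnsembleHandle,
    frame_range,
    engine,
    mutation_spec: Optional[MutationSpec],
) -> tuple[list[PredictionResult], list[FrameFailure]]:
    results: list[PredictionResult] = []
    failures: list[FrameFailure] = []
    for snapshot in ensemble.iter_frames(frame_range):
        try:
            snap = normalize_residue_names(snapshot)
            if mutation_spec is not None and mutation_spec.targets:
                snap = apply_alanine_mutation(snap, mutation_spec)
            results.append(_predict_with_engine(snap, engine))
        except Exception as exc:  # engine failure on one frame: log and continue
            logger.warning("frame %d failed: %s", snapshot.frame_index, exc)
            failures.append(FrameFailure(snapshot.frame_index, str(exc)))
    return results, failures


def _worker_entry(args) -> tuple[list[PredictionResult], list[FrameFailure]]:
    # Top-level entry for process pools: re-opens the ensemble from paths.
    (topology, trajectories, stride, timestep, selection, rng, spec, mutation) = args
    ensemble = load_ensemble(
        topology, trajectories, stride=stride,
        timestep_ps=timestep, selection=selection,
    )
    engine = create_engine(spec)
    return _run_range(ensemble, rng, engine, mutation)


def run_prediction_pipeline(
    ensemble: EnsembleHandle,
    engine_spec: EngineSpec,
    mutation_spec: Optional[MutationSpec] = None,
    n_workers: int = 1,
    parallel: bool = False,
) -> PipelineResult:
    """Predict pKa values for every sampled frame of an ensemble.

    Frames are split into ``n_workers`` contiguous ranges; each range runs the
    per-frame chain normalize -> (mutate) -> write PDB -> predict -> parse,
    and the partial outputs are merged sorted by snapshot time.  The merged
    output is identical for any worker count.  With ``parallel=True`` ranges
    run in separate processes (each re-opens the trajectory); otherwise they
    run sequentially in-process.

    Engine availability is validated before any frame is processed.  Frames on
    which the engine fails are logged and reported in ``failures``; a run in
    which every frame fails raises :class:`PipelineError`.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    if isinstance(engine_spec, EngineSpec):
        engine = create_engine(engine_spec)  # configuration errors surface here
    else:  # a pre-built engine object
        engine = engine_spec
        if parallel:
            raise ValueError("parallel execution requires an EngineSpec")
    ranges = [r for r in split_frames(ensemble.n_frames, n_workers) if len(r)]

    partials: list[list[PredictionResult]] = []
    failures: list[FrameFailure] = []
    if parallel and len(ranges) > 1:
        from concurrent.futures import ProcessPoolExecutor

        args = [
            (
                ensemble.topology_path,
                ensemble.trajectory_paths,
                ensemble.stride,
                ensemble.timestep_ps,
                ensemble.selection,
                rng,
                engine_spec,
                mutation_spec,
            )
            for rng in ranges
        ]
        with ProcessPoolExecutor(max_workers=len(ranges)) as pool:
            for results, fails in pool.map(_worker_entry, args):
                partials.append(results)
                failures.extend(fails)
    else:
        for rng in ranges:
            results, fails = _run_range(ensemble, rng, engine, mutation_spec)
            partials.append(results)
            failures.extend(fails)

    if not any(partials):
        raise PipelineError("every frame failed in the prediction pipeline")
    include_buried = getattr(engine, "supports_buried", False)
    pka_table, buried_table = merge_worker_outputs(partials, include_buried)
    return PipelineResult(pka=pka_table, buried=buried_table, failures=failures)


def write_failures(failures: Sequence[FrameFailure], path: str | os.PathLike) -> Path:
    path = Path(path)
    lines = [f"{f.frame_index}\t{f.message}" for f in failures]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
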
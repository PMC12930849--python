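"""Clustering of trajectory frames by the environment of ionizable residues.

Frames are described by a feature matrix built from pKa values of selected
residues and optionally their buried ratios and inter-residue distances
(minimum heavy-atom distance, which tracks contact formation such as salt
bridges).  Features are Z-score normalized, optionally reduced by PCA, and
clustered with one of four algorithms: k-medoids, greedy (leader), DBSCAN or
HDBSCAN.  Hyperparameters can be optimized by grid search using the mean
silhouette width; each cluster yields one representative frame that can be
written out as a PDB structure.

k-medoids is implemented in-package (seeded multi-restart alternating
assignment/update); DBSCAN, HDBSCAN, PCA, silhouette and ARI come from
scikit-learn.  Distances are Euclidean in the normalized feature space, where
Z-scoring makes features commensurate.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .tables import PkaTable
from .trajectory import EnsembleHandle, FrameSnapshot, ResidueKey, write_snapshot_pdb

logger = logging.getLogger("pkatraj")

__all__ = [
    "FeatureDescriptor",
    "FeatureMatrix",
    "ClusterResult",
    "DegenerateClusteringError",
    "GridSearchError",
    "build_feature_matrix",
    "concat_feature_matrices",
    "zscore",
    "reduce_pca",
    "cluster",
    "grid_search",
    "extract_representatives",
]

CLUSTER_METHODS = ("kmedoids", "greedy", "dbscan", "hdbscan")


class DegenerateClusteringError(RuntimeError):
    """Clustering produced no usable clusters (e.g. every frame is noise)."""


class GridSearchError(RuntimeError):
    """Every grid point failed or was degenerate."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature column: a residue's pKa or buried ratio, or a residue-pair
    minimum heavy-atom distance."""

    kind: str  # "pka" | "buried" | "distance"
    residues: tuple[ResidueKey, ...]

    def __post_init__(self):
        if self.kind not in ("pka", "buried", "distance"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        n_expected = 2 if self.kind == "distance" else 1
        if len(self.residues) != n_expected:
            raise ValueError(f"{self.kind} feature needs {n_expected} residue(s)")
        if self.kind == "distance" and self.residues[0] == self.residues[1]:
            raise ValueError("distance feature needs two distinct residues")

    def label(self) -> str:
        if self.kind == "distance":
            a, b = self.residues
            return f"dist[{a.label()}|{b.label()}]"
        return f"{self.kind}[{self.residues[0].label()}]"


@dataclass
class FeatureMatrix:
    """Frames x features values with provenance.

    ``frame_indices`` are positions into the sampled frames of the source
    ensemble(s); ``replica`` identifies the source table when matrices from
    several trajectories are concatenated for joint clustering.
    """

    times: np.ndarray
    labels: list[str]
    values: np.ndarray
    state: str = "raw"  # "raw" | "zscored" | "pca"
    frame_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    replica: Optional[np.ndarray] = None
    n_components: Optional[int] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != (len(self.times), len(self.labels)):
            raise ValueError("values shape inconsistent with times x labels")
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.times))
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _min_heavy_distance(
    snapshot: FrameSnapshot, res_a: ResidueKey, res_b: ResidueKey
) -> float:
    def coords(key: ResidueKey) -> np.ndarray:
        pts = [
            [a.x, a.y, a.z]
            for a in snapshot.atoms
            if not a.is_hydrogen
            and a.residue.chain_id == key.chain_id
            and a.residue.resid == key.resid
        ]
        if not pts:
            raise ValueError(f"residue {key.label()} not found in trajectory frame")
        return np.array(pts)

    return float(cdist(coords(res_a), coords(res_b)).min())


def build_feature_matrix(
    pka_table: PkaTable,
    descriptors: Sequence[FeatureDescriptor],
    buried_table: Optional[PkaTable] = None,
    ensemble: Optional[EnsembleHandle] = None,
) -> FeatureMatrix:
    """Assemble the clustering feature matrix, one column per descriptor.

    Distance descriptors require the ensemble (frames must correspond 1:1 to
    the table rows).  Frames with any missing value are dropped with a log
    entry so the matrix is complete.
    """
    if not descriptors:
        raise ValueError("no feature descriptors given")
    n = pka_table.n_frames
    columns = []
    for desc in descriptors:
        if desc.kind in ("pka", "buried"):
            source = pka_table if desc.kind == "pka" else buried_table
            if source is None:
                raise ValueError("buried feature requested but no buried table given")
            try:
                columns.append(source.column(desc.residues[0]).to_numpy(dtype=float))
            except KeyError as exc:
                raise ValueError(
                    f"feature descriptor references unknown residue: {exc}"
                ) from None
        else:  # distance
            if ensemble is None:
                raise ValueError("distance feature requested but no ensemble given")
            if ensemble.n_frames != n:
                raise ValueError(
                    f"ensemble frame count {ensemble.n_frames} does not match "
                    f"table frame count {n}"
                )
            a, b = desc.residues
            columns.append(
                np.array(
                    [_min_heavy_distance(s, a, b) for s in ensemble.iter_frames()]
                )
            )
    values = np.column_stack(columns)
    keep = ~np.isnan(values).any(axis=1)
    if not keep.all():
        logger.warning(
            "dropping %d frame(s) with missing feature values", int((~keep).sum())
        )
    if not keep.any():
        raise ValueError("every frame has missing feature values")
    return FeatureMatrix(
        times=pka_table.times[keep],
        labels=[d.label() for d in descriptors],
        values=values[keep],
        state="raw",
        frame_indices=np.nonzero(keep)[0],
    )


def concat_feature_matrices(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate per-replica matrices for joint clustering, keeping
    (replica, frame) provenance.  All matrices must share columns and state."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.labels != first.labels or m.state != first.state:
            raise ValueError("matrices differ in columns or normalization state")
    return FeatureMatrix(
        times=np.concatenate([m.times for m in matrices]),
        labels=list(first.labels),
        values=np.vstack([m.values for m in matrices]),
        state=first.state,
        frame_indices=np.concatenate([m.frame_indices for m in matrices]),
        replica=np.concatenate(
            [
                m.replica if m.replica is not None else np.full(m.n_frames, i)
                for i, m in enumerate(matrices)
            ]
        ),
    )


def zscore(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column to mean 0 and population sd 1.

    Constant columns carry no clustering information and are dropped with a
    warning; an all-constant matrix raises ``ValueError``.
    """
    if matrix.state != "raw":
        raise ValueError(f"zscore expects a raw matrix, got state {matrix.state!r}")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.any():
        raise ValueError("all feature columns are constant")
    for label in np.array(matrix.labels)[~keep]:
        logger.warning("dropping constant feature column %s", label)
    values = (matrix.values[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        times=matrix.times,
        labels=[l for l, k in zip(matrix.labels, keep) if k],
        values=values,
        state="zscored",
        frame_indices=matrix.frame_indices,
        replica=matrix.replica,
    )


def reduce_pca(
    matrix: FeatureMatrix,
    n_components: Optional[int] = None,
    variance_fraction: Optional[float] = None,
) -> FeatureMatrix:
    """Project the Z-scored matrix onto leading principal components.

    With ``variance_fraction`` the smallest component count whose cumulative
    explained variance reaches the fraction is retained.
    """
    from sklearn.decomposition import PCA

    if matrix.state != "zscored":
        raise ValueError("reduce_pca expects a zscored matrix")
    if (n_components is None) == (variance_fraction is None):
        raise ValueError("give exactly one of n_components / variance_fraction")
    if n_components is not None:
        if not (1 <= n_components <= matrix.n_features):
            raise ValueError(
                f"n_components {n_components} outside [1, {matrix.n_features}]"
            )
        pca = PCA(n_components=n_components, svd_solver="full")
    else:
        if not (0 < variance_fraction <= 1):
            raise ValueError("variance_fraction must be in (0, 1]")
        pca = PCA(n_components=variance_fraction, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    k = scores.shape[1]
    return FeatureMatrix(
        times=matrix.times,
        labels=[f"PC{i + 1}" for i in range(k)],
        values=scores,
        state="pca",
        frame_indices=matrix.frame_indices,
        replica=matrix.replica,
        n_components=k,
    )


@dataclass
class ClusterResult:
    """Per-frame labels plus representatives and quality score.

    Labels are contiguous from 0 for real clusters; -1 marks noise where the
    algorithm supports it.  ``representatives`` maps cluster label to a row of
    the feature matrix; ``silhouette`` is the mean silhouette width over
    non-noise frames (NaN when fewer than two clusters remain).
    """

    labels: np.ndarray
    representatives: dict[int, int]
    silhouette: float
    hyperparameters: dict
    method: str
    frame_indices: np.ndarray
    times: np.ndarray
    replica: Optional[np.ndarray] = None
    seed: Optional[int] = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0]))

    @property
    def n_noise(self) -> int:
        return int((self.labels == -1).sum())

    def labels_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "replica": self.replica
                if self.replica is not None
                else np.zeros(len(self.labels), dtype=int),
                "frame": self.frame_indices,
                "time_ps": self.times,
                "label": self.labels,
            }
        )
        return df


def _kmedoids(
    D: np.ndarray, k: int, rng: np.random.Generator,
    n_init: int = 10, max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded multi-restart alternating k-medoids on a distance matrix.

    Each restart alternates nearest-medoid assignment with exact medoid
    update (the within-cluster summed-distance minimizer), so converged
    representatives are medoid-optimal for their cluster.  The restart with
    the lowest total cost wins.
    """
    n = D.shape[0]
    best_cost, best_medoids, best_labels = np.inf, None, None
    for _ in range(n_init):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.nonzero(labels == c)[0]
                if members.size == 0:
                    # revive an empty cluster with the point farthest from all medoids
                    new_medoids[c] = int(
                        np.argmax(np.min(D[:, new_medoids], axis=1))
                    )
                else:
                    within = D[np.ix_(members, members)].sum(axis=0)
                    new_medoids[c] = int(members[np.argmin(within)])
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                medoids = new_medoids
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), medoids[labels]].sum()
        if cost < best_cost - 1e-12:
            best_cost, best_medoids, best_labels = cost, medoids, labels
    order = np.argsort(best_medoids)
    medoids = best_medoids[order]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[best_labels], medoids


def _greedy_leader(X: np.ndarray, cutoff: float) -> tuple[np.ndarray, list[int]]:
    """Leader algorithm: frames scanned in time order join the first cluster
    whose leader lies within the cutoff, else found a new cluster."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    leaders: list[int] = []
    labels = np.empty(len(X), dtype=int)
    for i, x in enumerate(X):
        for c, lead in enumerate(leaders):
            if np.linalg.norm(x - X[lead]) <= cutoff:
                labels[i] = c
                break
        else:
            leaders.append(i)
            labels[i] = len(leaders) - 1
    return labels, leaders


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Renumber non-noise labels to 0..k-1 by first appearance; keep -1."""
    out = np.full(len(labels), -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _nearest_to_mean_representatives(
    X: np.ndarray, labels: np.ndarray
) -> dict[int, int]:
    reps = {}
    for lab in sorted(set(labels[labels >= 0])):
        members = np.nonzero(labels == lab)[0]
        center = X[members].mean(axis=0)
        reps[int(lab)] = int(members[np.argmin(np.linalg.norm(X[members] - center, axis=1))])
    return reps


def _mean_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    mask = labels >= 0
    kept = labels[mask]
    if len(set(kept)) < 2 or mask.sum() <= len(set(kept)):
        return float("nan")
    return float(silhouette_score(X[mask], kept, metric="euclidean"))


def cluster(
    matrix: FeatureMatrix,
    method: str,
    hyperparameters: Optional[dict] = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster frames in normalized feature space.

    Hyperparameters per method: kmedoids ``n_clusters``; greedy ``cutoff``;
    dbscan ``eps``, ``min_samples``; hdbscan ``min_cluster_size`` (and any
    further scikit-learn options).  Representatives are the medoid frame
    (kmedoids), the leader frame (greedy), or the frame nearest the cluster's
    feature-space mean (dbscan/hdbscan).  Seeded methods are reproducible for
    a fixed seed.
    """
    if method not in CLUSTER_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {CLUSTER_METHODS}")
    if matrix.state not in ("zscored", "pca"):
        raise ValueError("cluster expects a zscored or pca feature matrix")
    params = dict(hyperparameters or {})
    X = matrix.values
    n = len(X)

    if method == "kmedoids":
        k = int(params.get("n_clusters", 2))
        if k < 1:
            raise ValueError(f"n_clusters must be >= 1, got {k}")
        if k > n:
            raise ValueError(f"requested {k} clusters from {n} frames")
        D = cdist(X, X)
        rng = np.random.default_rng(seed)
        labels, medoids = _kmedoids(D, k, rng, n_init=int(params.get("n_init", 10)))
        reps = {int(c): int(m) for c, m in enumerate(medoids)}
    elif method == "greedy":
        labels, leaders = _greedy_leader(X, float(params.get("cutoff", 1.0)))
        reps = {int(c): int(i) for c, i in enumerate(leaders)}
    elif method == "dbscan":
        from sklearn.cluster import DBSCAN

        raw = DBSCAN(
            eps=float(params.get("eps", 0.5)),
            min_samples=int(params.get("min_samples", 5)),
        ).fit_predict(X)
        labels = _relabel_contiguous(raw)
        if (labels == -1).all():
            raise DegenerateClusteringError("DBSCAN labelled every frame as noise")
        reps = _nearest_to_mean_representatives(X, labels)
    else:  # hdbscan
        from sklearn.cluster import HDBSCAN

        kwargs = {k_: v for k_, v in params.items() if k_ != "min_cluster_size"}
        raw = HDBSCAN(
            min_cluster_size=int(params.get("min_cluster_size", 5)), **kwargs
        ).fit_predict(X)
        labels = _relabel_contiguous(raw)
        if (labels == -1).all():
            raise DegenerateClusteringError("HDBSCAN labelled every frame as noise")
        reps = _nearest_to_mean_representatives(X, labels)

    return ClusterResult(
        labels=labels,
        representatives=reps,
        silhouette=_mean_silhouette(X, labels),
        hyperparameters=params,
        method=method,
        frame_indices=matrix.frame_indices,
        times=matrix.times,
        replica=matrix.replica,
        seed=seed,
    )


def _expand_grid(grid) -> list[dict]:
    if isinstance(grid, dict):
        keys = list(grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(list(grid[k]) for k in keys))
        ]
    return [dict(p) for p in grid]


def grid_search(
    matrix: FeatureMatrix,
    method: str,
    hyperparameter_grid,
    seed: int = 0,
) -> tuple[ClusterResult, pd.DataFrame]:
    """Evaluate every grid point and return the silhouette-maximizing result.

    ``hyperparameter_grid`` is either a dict of parameter -> value list
    (expanded as a product, in order) or an explicit list of parameter dicts.
    Ties are broken by fewer clusters, then grid order.  Results with more
    than 50% noise frames are kept but ranked below any non-degenerate
    result (silhouette over mostly-noise frames is not comparable).  The
    second return value is the full score table.
    """
    points = _expand_grid(hyperparameter_grid)
    if not points:
        raise ValueError("empty hyperparameter grid")
    rows = []
    candidates: list[tuple[tuple, ClusterResult]] = []
    for order, params in enumerate(points):
        try:
            result = cluster(matrix, method, params, seed=seed)
        except Exception as exc:
            rows.append({**params, "n_clusters": 0, "n_noise": len(matrix.values),
                         "silhouette": np.nan, "error": str(exc)})
            continue
        high_noise = result.n_noise > 0.5 * len(result.labels)
        rows.append(
            {
                **params,
                "n_clusters": result.n_clusters,
                "n_noise": result.n_noise,
                "silhouette": result.silhouette,
                "error": "",
            }
        )
        if np.isfinite(result.silhouette):
            candidates.append(
                ((int(high_noise), -result.silhouette, result.n_clusters, order), result)
            )
    score_table = pd.DataFrame(rows)
    if not candidates:
        detail = "; ".join(
            f"{r}" for r in score_table.to_dict("records")
        )
        raise GridSearchError(f"every grid point degenerate or failed: {detail}")
    candidates.sort(key=lambda item: item[0])
    return candidates[0][1], score_table


def extract_representatives(
    result: ClusterResult,
    ensemble: EnsembleHandle | Sequence[EnsembleHandle],
    out_dir: str | os.PathLike,
) -> list[Path]:
    """Write one PDB per non-noise cluster, named by cluster id and frame.

    With joint cross-replica clustering, pass the ensembles in replica order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ensembles = (
        list(ensemble) if isinstance(ensemble, (list, tuple)) else [ensemble]
    )
    paths = []
    for label in sorted(result.representatives):
        if label < 0:
            continue
        row = result.representatives[label]
        replica = int(result.replica[row]) if result.replica is not None else 0
        sample_index = int(result.frame_indices[row])
        snapshot = ensembles[replica].get_frame(sample_index)
        path = out_dir / f"cluster{label}_frame{snapshot.frame_index}.pdb"
        write_snapshot_pdb(snapshot, path)
        paths.append(path)
    return paths
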
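"""Feature assembly, normalization, PCA and frame clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pkatraj import (
    Atom,
    EngineSpec,
    FeatureDescriptor,
    FrameSnapshot,
    PkaTable,
    ResidueKey,
    build_feature_matrix,
    cluster,
    extract_representatives,
    generate_blob_features,
    grid_search,
    load_ensemble,
    read_snapshot_pdb,
    reduce_pca,
    run_prediction_pipeline,
    write_snapshot_pdb,
    zscore,
)
from pkatraj.clustering import (
    DegenerateClusteringError,
    FeatureMatrix,
    GridSearchError,
    concat_feature_matrices,
)
from pkatraj.trajectory import write_multimodel_pdb


def _matrix(values, state="raw") -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        times=np.arange(len(values), dtype=float),
        labels=[f"f{i}" for i in range(values.shape[1])],
        values=values,
        state=state,
    )


@pytest.fixture(scope="module")
def blobs():
    return generate_blob_features(30, 3, separation_sd=10.0, n_features=3, seed=5)


class TestBuildFeatureMatrix:
    def test_shape_pka_plus_distance(self, ensemble):
        result = run_prediction_pipeline(ensemble, EngineSpec("mock"))
        descriptors = [
            FeatureDescriptor("pka", (ResidueKey("A", 3, "ASP"),)),
            FeatureDescriptor("pka", (ResidueKey("A", 5, "GLU"),)),
            FeatureDescriptor(
                "distance", (ResidueKey("A", 5, "GLU"), ResidueKey("A", 10, "ARG"))
            ),
        ]
        matrix = build_feature_matrix(result.pka, descriptors, ensemble=ensemble)
        assert matrix.values.shape == (10, 3)
        assert matrix.state == "raw"

    def test_min_heavy_atom_distance_345(self, tmp_path):
        a = ResidueKey("A", 1, "ASP")
        b = ResidueKey("A", 2, "GLU")
        snap = FrameSnapshot(
            0, 0.0,
            [Atom("CA", a, 0.0, 0.0, 0.0, "C"), Atom("CA", b, 3.0, 4.0, 0.0, "C")],
        )
        write_multimodel_pdb([snap], tmp_path / "traj.pdb")
        write_snapshot_pdb(snap, tmp_path / "top.pdb")
        ens = load_ensemble(
            tmp_path / "top.pdb", tmp_path / "traj.pdb", timestep_ps=1.0,
            selection="all",
        )
        table = PkaTable(
            data=pd.DataFrame(
                {"ASP 1 A": [4.0]}, index=pd.Index([0.0], name="time_ps")
            )
        )
        matrix = build_feature_matrix(
            table, [FeatureDescriptor("distance", (a, b))], ensemble=ens
        )
        assert matrix.values[0, 0] == pytest.approx(5.0, abs=1e-3)

    def test_unknown_residue_raises(self, ensemble):
        result = run_prediction_pipeline(ensemble, EngineSpec("mock"))
        with pytest.raises(ValueError, match="unknown residue"):
            build_feature_matrix(
                result.pka, [FeatureDescriptor("pka", (ResidueKey("A", 77, "ASP"),))]
            )

    def test_buried_requires_table(self, ensemble):
        result = run_prediction_pipeline(ensemble, EngineSpec("mock"))
        desc = [FeatureDescriptor("buried", (ResidueKey("A", 3, "ASP"),))]
        with pytest.raises(ValueError):
            build_feature_matrix(result.pka, desc)
        matrix = build_feature_matrix(result.pka, desc, buried_table=result.buried)
        assert matrix.values.shape == (10, 1)

    def test_distance_needs_distinct_residues(self):
        key = ResidueKey("A", 1, "ASP")
        with pytest.raises(ValueError):
            FeatureDescriptor("distance", (key, key))


class TestZscore:
    def test_population_standardization(self):
        out = zscore(_matrix([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(
            out.values[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4
        )

    def test_mean_zero_sd_one_within_tolerance(self, blobs):
        matrix, _ = blobs
        out = zscore(_matrix(matrix.values))
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        assert np.abs(out.values.std(axis=0, ddof=0) - 1).max() < 1e-10

    def test_constant_column_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="pkatraj"):
            out = zscore(_matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert out.labels == ["f0"]
        assert any("constant" in r.message for r in caplog.records)

    def test_all_constant_raises(self):
        with pytest.raises(ValueError):
            zscore(_matrix([[5.0], [5.0], [5.0]]))

    def test_prestandardized_column_unchanged(self):
        col = np.array([-1.224744871391589, 0.0, 1.224744871391589])
        out = zscore(_matrix(col[:, None]))
        np.testing.assert_allclose(out.values[:, 0], col, atol=1e-10)


class TestReducePca:
    def test_rank_one_matrix_keeps_single_component(self):
        x = np.linspace(-1, 1, 20)
        matrix = zscore(_matrix(np.column_stack([x, 2 * x])))
        out = reduce_pca(matrix, variance_fraction=0.9)
        assert out.n_components == 1
        assert out.state == "pca"

    def test_full_rank_conserves_total_variance(self, blobs):
        matrix, _ = blobs
        z = zscore(_matrix(matrix.values))
        out = reduce_pca(z, n_components=z.n_features)
        assert out.values.var(axis=0, ddof=0).sum() == pytest.approx(
            z.values.var(axis=0, ddof=0).sum(), abs=1e-8
        )

    def test_too_many_components_raises(self):
        matrix = zscore(_matrix(np.random.default_rng(0).normal(size=(10, 3))))
        with pytest.raises(ValueError):
            reduce_pca(matrix, n_components=5)

    def test_requires_zscored_input(self):
        with pytest.raises(ValueError):
            reduce_pca(_matrix([[1.0, 2.0]]), n_components=1)


class TestCluster:
    def test_kmedoids_recovers_blobs_exactly(self, blobs):
        matrix, truth = blobs
        result = cluster(matrix, "kmedoids", {"n_clusters": 3}, seed=1)
        assert adjusted_rand_score(truth, result.labels) == 1.0
        assert result.silhouette > 0.8

    def test_kmedoids_representative_is_true_medoid(self, blobs):
        """Exhaustive check: each representative minimizes summed distance to
        its cluster members."""
        from scipy.spatial.distance import cdist

        matrix, _ = blobs
        result = cluster(matrix, "kmedoids", {"n_clusters": 3}, seed=1)
        D = cdist(matrix.values, matrix.values)
        for label, rep in result.representatives.items():
            members = np.nonzero(result.labels == label)[0]
            sums = D[np.ix_(members, members)].sum(axis=0)
            assert D[rep, members].sum() == pytest.approx(sums.min())

    def test_k1_representative_is_global_medoid(self, blobs):
        from scipy.spatial.distance import cdist

        matrix, _ = blobs
        result = cluster(matrix, "kmedoids", {"n_clusters": 1}, seed=3)
        D = cdist(matrix.values, matrix.values)
        assert result.representatives[0] == int(np.argmin(D.sum(axis=0)))
        assert result.n_clusters == 1
        assert np.isnan(result.silhouette)  # undefined for a single cluster

    def test_seed_reproducibility(self, blobs):
        matrix, _ = blobs
        a = cluster(matrix, "kmedoids", {"n_clusters": 3}, seed=9)
        b = cluster(matrix, "kmedoids", {"n_clusters": 3}, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_more_clusters_than_frames_raises(self):
        with pytest.raises(ValueError):
            cluster(_matrix(np.eye(3), state="zscored"), "kmedoids", {"n_clusters": 5})

    def test_dbscan_three_clusters_no_noise(self, blobs):
        matrix, truth = blobs
        result = cluster(matrix, "dbscan", {"eps": 2.5, "min_samples": 4})
        assert result.n_clusters == 3
        assert result.n_noise == 0
        assert adjusted_rand_score(truth, result.labels) == 1.0

    def test_dbscan_all_noise_degenerate(self, blobs):
        matrix, _ = blobs
        with pytest.raises(DegenerateClusteringError):
            cluster(matrix, "dbscan", {"eps": 1e-6, "min_samples": 5})

    def test_hdbscan_recovers_blob_structure(self, blobs):
        matrix, truth = blobs
        result = cluster(matrix, "hdbscan", {"min_cluster_size": 10})
        mask = result.labels >= 0
        assert result.n_clusters == 3
        assert adjusted_rand_score(truth[mask], result.labels[mask]) == 1.0

    def test_greedy_leader_clusters_blobs(self, blobs):
        matrix, truth = blobs
        result = cluster(matrix, "greedy", {"cutoff": 6.0})
        assert adjusted_rand_score(truth, result.labels) == 1.0
        # representatives are the leader (first) frames of each cluster
        for label, rep in result.representatives.items():
            assert result.labels[rep] == label
            assert rep == int(np.nonzero(result.labels == label)[0][0])

    def test_silhouette_always_in_bounds(self, blobs):
        matrix, _ = blobs
        for k in (2, 3, 5):
            result = cluster(matrix, "kmedoids", {"n_clusters": k}, seed=0)
            assert -1.0 <= result.silhouette <= 1.0


class TestGridSearch:
    def test_selects_true_blob_count(self, blobs):
        matrix, _ = blobs
        result, scores = grid_search(
            matrix, "kmedoids", {"n_clusters": [2, 3, 4, 5, 6]}, seed=1
        )
        assert result.hyperparameters["n_clusters"] == 3
        assert len(scores) == 5
        assert scores["silhouette"].idxmax() == 1  # the k=3 row

    def test_single_point_grid_identity(self, blobs):
        matrix, _ = blobs
        result, scores = grid_search(
            matrix, "kmedoids", {"n_clusters": [3]}, seed=1
        )
        assert result.hyperparameters["n_clusters"] == 3
        assert len(scores) == 1

    def test_tie_broken_by_fewer_clusters(self):
        # two identical grid points cannot differ in silhouette; the
        # fewer-clusters tie-break must pick the smaller k among equals
        matrix, _ = generate_blob_features(20, 2, 12.0, 2, seed=4)
        result, _ = grid_search(
            matrix, "kmedoids", [{"n_clusters": 2}, {"n_clusters": 2, "n_init": 10}], seed=0
        )
        assert result.hyperparameters == {"n_clusters": 2}

    def test_all_degenerate_raises_with_details(self, blobs):
        matrix, _ = blobs
        with pytest.raises(GridSearchError):
            grid_search(
                matrix, "dbscan", {"eps": [1e-8, 1e-7], "min_samples": [5]}
            )


class TestRepresentativesAndReplicas:
    def test_one_pdb_per_cluster_with_matching_coordinates(self, ensemble, tmp_path):
        result = run_prediction_pipeline(ensemble, EngineSpec("mock"))
        descriptors = [
            FeatureDescriptor("pka", (k,)) for k in result.pka.residues
        ]
        matrix = zscore(build_feature_matrix(result.pka, descriptors))
        res = cluster(matrix, "kmedoids", {"n_clusters": 2}, seed=0)
        paths = extract_representatives(res, ensemble, tmp_path / "reps")
        assert len(paths) == 2
        for label, row in res.representatives.items():
            sample = int(res.frame_indices[row])
            snap = ensemble.get_frame(sample)
            written = read_snapshot_pdb(
                tmp_path / "reps" / f"cluster{label}_frame{snap.frame_index}.pdb"
            )
            np.testing.assert_allclose(
                written.coordinates(), snap.coordinates(), atol=5e-4
            )

    def test_concat_keeps_replica_provenance(self, blobs):
        matrix, _ = blobs
        joint = concat_feature_matrices([matrix, matrix])
        assert joint.n_frames == 2 * matrix.n_frames
        assert set(joint.replica) == {0, 1}
        result = cluster(joint, "kmedoids", {"n_clusters": 3}, seed=2)
        assert len(result.labels) == joint.n_frames
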
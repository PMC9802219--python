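"""KNN linking, Jaccard co-occurrence filtering, ranked results."""

import warnings

import numpy as np
import pandas as pd
import pytest

from omixlink import (
    GCFLinkClassifier,
    LinkResult,
    LinkerConfig,
    NeighborHit,
    apply_cooccurrence_filter,
    jaccard_index,
    knn_link,
    link_dataset,
)
from omixlink.linker import write_results


def _matrix(rows, ids, columns=None):
    arr = np.asarray(rows, dtype=float)
    cols = columns or [f"G{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(ids, name="owner_id"), columns=cols)


@pytest.fixture
def small_training():
    X = _matrix(
        [
            [1.0, 0.9, 0.0, 0.0],
            [0.9, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.8],
            [0.0, 0.0, 0.8, 1.0],
            [1.0, 0.0, 0.0, 1.0],
        ],
        ["B1", "B2", "B3", "B4", "B5"],
    )
    y = ["GCF1", "GCF1", "GCF2", "GCF2", "GCF3"]
    return X, y


class TestKnnLink:
    def test_exact_training_row_found_at_distance_zero(self, small_training):
        X, y = small_training
        res = knn_link(X.iloc[2], X, y, LinkerConfig(k=1), spectrum_id="q")
        assert res.neighbors[0].bgc_id == "B3"
        assert res.neighbors[0].distance == 0.0
        assert res.ranked_gcfs == ["GCF2"]

    def test_repeated_family_labels_preserved(self, small_training):
        X, y = small_training
        res = knn_link(X.iloc[0], X, y, LinkerConfig(k=3))
        # B1 (GCF1), B2 (GCF1) are nearest; the repeated label must remain
        assert res.ranked_gcfs[:2] == ["GCF1", "GCF1"]
        assert len(res.ranked_gcfs) == 3

    def test_distance_ties_broken_by_ascending_bgc_id(self):
        X = _matrix([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]], ["B_c", "B_a", "B_b"])
        res = knn_link(np.array([0.0, 1.0]), X, ["F1", "F2", "F3"], LinkerConfig(k=3))
        assert [n.bgc_id for n in res.neighbors] == ["B_a", "B_b", "B_c"]

    def test_neighbor_distances_non_decreasing(self, small_training):
        X, y = small_training
        res = knn_link(np.array([0.5, 0.5, 0.2, 0.1]), X, y, LinkerConfig(k=5))
        d = [n.distance for n in res.neighbors]
        assert d == sorted(d)

    def test_feature_space_mismatch_names_column(self, small_training):
        X, y = small_training
        clf = GCFLinkClassifier().fit(X, y)
        bad = X.rename(columns={"G1": "H1"})
        with pytest.raises(ValueError, match="H1"):
            clf.link(bad.iloc[:1])

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "cosine-distance"])
    def test_matches_brute_force_oracle(self, metric):
        """Neighbor sets equal an exhaustive all-pairs distance sort."""
        rng = np.random.default_rng(77)
        X = _matrix(rng.uniform(0, 1, (30, 6)), [f"B{i:02d}" for i in range(30)])
        y = [f"GCF{i % 7}" for i in range(30)]
        clf = GCFLinkClassifier(n_neighbors=4, metric=metric).fit(X, y)
        for _ in range(10):
            q = rng.uniform(0, 1, 6)
            if metric == "euclidean":
                dists = [float(np.sqrt(np.sum((q - row) ** 2))) for row in X.to_numpy()]
            elif metric == "manhattan":
                dists = [float(np.sum(np.abs(q - row))) for row in X.to_numpy()]
            else:
                dists = [
                    1.0 - float(q @ row / (np.linalg.norm(q) * np.linalg.norm(row)))
                    for row in X.to_numpy()
                ]
            expected = [bid for _, bid in sorted(zip(dists, X.index))][:4]
            res = clf.link(pd.DataFrame([q], index=["q"], columns=X.columns))[0]
            assert [n.bgc_id for n in res.neighbors] == expected


class TestJaccardIndex:
    def test_identical_binarized_fingerprints(self):
        v = np.array([0.9, 0.0, 0.75, 1.0])
        assert jaccard_index(v, v) == 1.0

    def test_disjoint_patterns(self):
        assert jaccard_index(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0

    def test_hand_counted_toy_pair(self):
        # 3 shared bits, 2 private each -> 3/7
        a = np.array([1.0, 1.0, 1.0, 0.9, 0.8, 0.0, 0.0, 0.0])
        b = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.9, 0.8, 0.0])
        assert jaccard_index(a, b) == pytest.approx(3 / 7)

    def test_symmetry_and_all_zero(self):
        rng = np.random.default_rng(8)
        a, b = rng.uniform(0, 1, 10), rng.uniform(0, 1, 10)
        assert jaccard_index(a, b) == jaccard_index(b, a)
        assert jaccard_index(np.zeros(4), np.zeros(4)) == 0.0

    def test_strains_only_scope_ignores_feature_block(self):
        a = np.array([1.0, 0.0, 1.0, 0.0])  # 2 strain cols + 2 feature bits
        b = np.array([1.0, 0.0, 0.0, 1.0])
        assert jaccard_index(a, b, scope="strains-only", n_similarity_columns=2) == 1.0
        assert jaccard_index(a, b, scope="all-features", n_similarity_columns=2) == pytest.approx(1 / 3)


class TestCooccurrenceFilter:
    def _result(self, jaccards):
        hits = [
            NeighborHit(f"B{i}", f"GCF{i}", float(i), j) for i, j in enumerate(jaccards)
        ]
        return LinkResult("q", hits, retained=True)

    def test_any_neighbor_above_threshold_retains(self):
        res = apply_cooccurrence_filter(self._result([0.6, 0.72, 0.4]))
        assert res.retained
        assert res.neighbors[1].jaccard == pytest.approx(0.72)

    def test_all_below_threshold_drops(self):
        assert not apply_cooccurrence_filter(self._result([0.6, 0.5, 0.4])).retained

    def test_identical_presence_pattern_retained(self, small_training):
        X, y = small_training
        clf = GCFLinkClassifier().fit(X, y)
        res = clf.link(X.iloc[:1])[0]
        assert res.retained
        assert res.neighbors[0].jaccard == 1.0

    def test_threshold_monotonicity(self, small_training):
        """Raising the threshold never increases the retained count."""
        X, y = small_training
        rng = np.random.default_rng(5)
        queries = _matrix(rng.uniform(0, 1, (12, 4)), [f"q{i}" for i in range(12)], columns=list(X.columns))
        counts = []
        for thr in [0.0, 0.3, 0.5, 0.7, 0.9, 1.0]:
            results = link_dataset(queries, X, y, LinkerConfig(jaccard_threshold=thr))
            counts.append(sum(r.retained for r in results))
        assert counts == sorted(counts, reverse=True)

    def test_all_zero_query_not_retained_with_warning(self, small_training):
        X, y = small_training
        clf = GCFLinkClassifier().fit(X, y)
        zero = pd.DataFrame(np.zeros((1, 4)), index=["q"], columns=X.columns)
        with pytest.warns(UserWarning, match="all-zero"):
            res = clf.link(zero)[0]
        assert not res.retained


class TestLinkDataset:
    def test_empty_query_list(self, small_training):
        X, y = small_training
        assert link_dataset(X.iloc[:0], X, y) == []

    def test_results_ordered_by_spectrum_id(self, small_training):
        X, y = small_training
        rng = np.random.default_rng(2)
        queries = _matrix(
            rng.uniform(0, 1, (5, 4)), ["q3", "q1", "q5", "q2", "q4"], columns=list(X.columns)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = link_dataset(queries, X, y)
        assert [r.spectrum_id for r in results] == ["q1", "q2", "q3", "q4", "q5"]

    def test_deterministic_across_runs(self, default_sim):
        out, result = default_sim
        from omixlink.workflow import PipelineConfig, run_pipeline

        rerun = run_pipeline(PipelineConfig(base_dir=out.outdir, seed=7))
        for a, b in zip(result.results, rerun.results):
            assert a.spectrum_id == b.spectrum_id
            assert a.retained == b.retained
            assert a.ranked_gcfs == b.ranked_gcfs
            assert [n.distance for n in a.neighbors] == [n.distance for n in b.neighbors]


def test_results_tsv_has_k_rows_per_query(tmp_path, small_training):
    X, y = small_training
    results = link_dataset(X, X, y, LinkerConfig(k=3))
    path = tmp_path / "results.tsv"
    write_results(results, path)
    df = pd.read_csv(path, sep="\t")
    assert set(df.columns) == {
        "spectrum_id", "rank", "bgc_id", "gcf_label", "distance", "jaccard", "retained"
    }
    assert (df.groupby("spectrum_id")["rank"].count() == 3).all()


def test_sklearn_estimator_api(small_training):
    X, y = small_training
    clf = GCFLinkClassifier(n_neighbors=2)
    params = clf.get_params()
    assert params["n_neighbors"] == 2
    clf.set_params(n_neighbors=1).fit(X, y)
    assert clf.n_features_in_ == 4
    preds = clf.predict(X)
    assert list(preds) == y  # each row is its own nearest neighbor
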
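"""Similarity-table loading and gene cluster family assignment."""

import numpy as np
import pandas as pd
import pytest

from omixlink.network import (
    BgcRecord,
    NetworkParams,
    SimilarityTable,
    assign_gcfs,
    domain_jaccard_similarity,
    read_bgc_table,
    read_bigscape_network,
    read_gcf_labels,
)

from conftest import UnionFind


def _network_file(tmp_path, rows, name="net.network", header=("Clustername 1", "Clustername 2", "Raw distance")):
    path = tmp_path / name
    pd.DataFrame(rows, columns=list(header)).to_csv(path, sep="\t", index=False)
    return path


class TestReadBigscapeNetwork:
    def test_similarity_is_one_minus_raw_distance_symmetric(self, tmp_path):
        table = read_bigscape_network(_network_file(tmp_path, [("A", "B", 0.2)]))
        assert table.get("A", "B") == pytest.approx(0.8)
        assert table.get("B", "A") == pytest.approx(0.8)

    def test_diagonal_row_is_noop(self, tmp_path):
        table = read_bigscape_network(_network_file(tmp_path, [("A", "A", 0.0)]))
        assert table.get("A", "A") == 1.0
        assert len(table) == 0

    def test_all_pairs_match_hand_built_map(self, tmp_path):
        rng = np.random.default_rng(0)
        ids = [f"B{i}" for i in range(6)]
        rows = []
        seen = set()
        while len(rows) < 10:
            a, b = rng.choice(ids, 2, replace=False)
            if (a, b) in seen or (b, a) in seen:
                continue
            seen.add((a, b))
            rows.append((a, b, round(float(rng.uniform(0, 1)), 3)))
        table = read_bigscape_network(_network_file(tmp_path, rows))
        hand = {}
        for a, b, d in rows:
            hand[frozenset((a, b))] = 1.0 - d
        for i in range(6):
            for j in range(i + 1, 6):
                expected = hand.get(frozenset((ids[i], ids[j])), 0.0)
                assert table.get(ids[i], ids[j]) == pytest.approx(expected)

    def test_case_and_space_insensitive_headers(self, tmp_path):
        path = _network_file(
            tmp_path, [("A", "B", 0.1)], header=("clustername  1", "CLUSTERNAME 2", "raw  Distance")
        )
        assert read_bigscape_network(path).get("A", "B") == pytest.approx(0.9)

    def test_missing_column_names_it(self, tmp_path):
        path = _network_file(tmp_path, [("A", "B")], header=("Clustername 1", "Clustername 2"))
        with pytest.raises(ValueError, match="Raw distance"):
            read_bigscape_network(path)

    def test_non_numeric_distance_reports_row(self, tmp_path):
        path = _network_file(tmp_path, [("A", "B", "oops")])
        with pytest.raises(ValueError, match="row 2"):
            read_bigscape_network(path)

    def test_out_of_range_similarity_clipped_with_warning(self, tmp_path):
        path = _network_file(tmp_path, [("A", "B", -0.5)])  # similarity 1.5
        with pytest.warns(UserWarning, match="clipped"):
            table = read_bigscape_network(path)
        assert table.get("A", "B") == 1.0

    def test_multiple_files_are_unioned(self, tmp_path):
        p1 = _network_file(tmp_path, [("A", "B", 0.2)], name="pks.network")
        p2 = _network_file(tmp_path, [("C", "D", 0.1)], name="nrps.network")
        table = read_bigscape_network([p1, p2])
        assert table.get("A", "B") == pytest.approx(0.8)
        assert table.get("C", "D") == pytest.approx(0.9)


class TestAssignGcfs:
    def _bgcs(self, ids):
        return [BgcRecord(bgc_id=i, genome_id="G") for i in ids]

    def test_transitive_component_is_one_family(self):
        sims = SimilarityTable()
        sims.set("A", "B", 0.9)
        sims.set("B", "C", 0.75)
        labels = assign_gcfs(self._bgcs("ABC"), sims)
        assert labels["A"] == labels["B"] == labels["C"]

    def test_strict_threshold_boundary(self):
        sims = SimilarityTable()
        sims.set("A", "B", 0.69)
        labels = assign_gcfs(self._bgcs("AB"), sims, NetworkParams(0.7))
        assert labels["A"] != labels["B"]
        sims.set("A", "B", 0.7)
        labels = assign_gcfs(self._bgcs("AB"), sims, NetworkParams(0.7))
        assert labels["A"] == labels["B"]

    def test_labels_numbered_by_smallest_member(self):
        sims = SimilarityTable()
        sims.set("Z1", "Z2", 0.9)
        sims.set("A1", "A2", 0.9)
        labels = assign_gcfs(self._bgcs(["Z1", "Z2", "A1", "A2", "M"]), sims)
        assert labels["A1"] == "GCF1"
        assert labels["M"] == "GCF2"
        assert labels["Z1"] == "GCF3"

    def test_matches_union_find_oracle_on_random_graph(self):
        rng = np.random.default_rng(42)
        ids = [f"N{i:02d}" for i in range(20)]
        sims = SimilarityTable()
        uf = UnionFind(ids)
        for _ in range(30):
            a, b = rng.choice(ids, 2, replace=False)
            s = float(rng.uniform(0.4, 1.0))
            sims.set(a, b, s)
            if s >= 0.7:
                uf.union(a, b)
        labels = assign_gcfs(self._bgcs(ids), sims)
        for a in ids:
            for b in ids:
                assert (labels[a] == labels[b]) == (uf.find(a) == uf.find(b))

    def test_invariant_to_input_ordering(self):
        rng = np.random.default_rng(1)
        ids = [f"N{i}" for i in range(12)]
        pairs = [(a, b, float(rng.uniform(0.5, 1.0))) for a, b in
                 [tuple(rng.choice(ids, 2, replace=False)) for _ in range(15)]]
        s1, s2 = SimilarityTable(), SimilarityTable()
        for a, b, s in pairs:
            s1.set(a, b, s)
        for a, b, s in reversed(pairs):
            s2.set(a, b, s)
        bgcs = self._bgcs(ids)
        assert assign_gcfs(bgcs, s1) == assign_gcfs(list(reversed(bgcs)), s2)

    def test_no_above_cutoff_edge_crosses_families(self):
        rng = np.random.default_rng(9)
        ids = [f"N{i}" for i in range(15)]
        sims = SimilarityTable()
        for _ in range(25):
            a, b = rng.choice(ids, 2, replace=False)
            sims.set(a, b, float(rng.uniform(0.3, 1.0)))
        labels = assign_gcfs(self._bgcs(ids), sims)
        for a, b, s in sims.pairs():
            if s >= 0.7:
                assert labels[a] == labels[b]

    def test_external_labels_override(self):
        sims = SimilarityTable()
        sims.set("A", "B", 0.9)
        labels = assign_gcfs(self._bgcs("AB"), sims, external_labels={"A": "FAM_X"})
        assert labels["A"] == "FAM_X"
        assert labels["B"] == "GCF1"

    def test_unknown_bgc_in_similarities_rejected(self):
        sims = SimilarityTable()
        sims.set("A", "GHOST", 0.9)
        with pytest.raises(ValueError, match="GHOST"):
            assign_gcfs(self._bgcs("A"), sims)


class TestDomainJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"d1", "d2"}, {"d1", "d2"}, 1.0),
            ({"d1"}, {"d2"}, 0.0),
            ({"d1", "d2", "d3"}, {"d2", "d3", "d4"}, 0.5),
            (set(), set(), 0.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert domain_jaccard_similarity(a, b) == expected


def test_bgc_and_label_table_readers(tmp_path):
    bgcs_path = tmp_path / "bgcs.tsv"
    pd.DataFrame(
        [("B1", "G1"), ("B2", "G2")], columns=["bgc_id", "genome_id"]
    ).to_csv(bgcs_path, sep="\t", index=False)
    records = read_bgc_table(bgcs_path)
    assert [r.bgc_id for r in records] == ["B1", "B2"]

    labels_path = tmp_path / "gcf_labels.tsv"
    pd.DataFrame([("B1", "GCF9")], columns=["bgc_id", "gcf_label"]).to_csv(
        labels_path, sep="\t", index=False
    )
    assert read_gcf_labels(labels_path) == {"B1": "GCF9"}
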
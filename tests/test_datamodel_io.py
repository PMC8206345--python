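import json

import numpy as np
import pytest

from tracs import (
    ClusterAssignment,
    GeneSetCollection,
    TimeGrid,
    TimeSeriesMatrix,
    build_network,
    fit_cluster_gps,
)
from tracs.io import (
    read_expression,
    read_gmt,
    read_labels,
    read_network,
    write_expression,
    write_gmt,
    write_labels,
    write_network,
)


class TestTimeGrid:
    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeGrid([0, 2, 1])

    def test_interpolation_grid_spans_and_includes_observed(self):
        g = TimeGrid([0, 6, 12, 24], interpolation_step=5)
        dense = g.interpolation_grid()
        assert dense[0] == 0 and dense[-1] == 24
        # multiples of 5 in range, union observed points
        assert set(np.round(dense, 6)) == {0, 5, 6, 10, 12, 15, 20, 24}

    def test_unit_step_grid_is_integer_range(self):
        g = TimeGrid([0, 6, 12, 24, 36, 48, 72, 96])
        assert np.array_equal(g.interpolation_grid(), np.arange(97.0))


class TestTimeSeriesMatrix:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene ids.*'a'"):
            TimeSeriesMatrix(["a", "a"], np.zeros((2, 3, 1)), TimeGrid([0, 1, 2]))

    def test_shape_checked_against_grid(self):
        with pytest.raises(ValueError, match="time points"):
            TimeSeriesMatrix(["a"], np.zeros((1, 4, 1)), TimeGrid([0, 1, 2]))

    def test_averaged_values_ignores_nan(self):
        v = np.array([[[1.0, 3.0], [1.0, np.nan], [np.nan, np.nan]]])
        m = TimeSeriesMatrix(["a"], v, TimeGrid([0, 1, 2]))
        avg = m.averaged_values()
        assert avg[0, 0] == 2.0 and avg[0, 1] == 1.0 and np.isnan(avg[0, 2])


class TestClusterAssignment:
    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty clusters"):
            ClusterAssignment({"a": 0, "b": 0}, k=2)

    def test_members(self):
        a = ClusterAssignment({"a": 0, "b": 1, "c": 0}, k=2)
        assert sorted(a.members(0)) == ["a", "c"]
        assert a.cluster_sizes() == [2, 1]


class TestReadExpression:
    def _write(self, tmp_path, text, name="m.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_basic_parse(self, tmp_path):
        p = self._write(
            tmp_path,
            "gene\tt0\tt1\tt2\tt3\tt4\n"
            + "\n".join(f"g{i}\t" + "\t".join("1 2 3 4 5".split()) for i in range(3)),
        )
        m = read_expression(p, times=[0, 1, 2, 3, 4])
        assert (m.n_genes, m.n_timepoints, m.n_replicates) == (3, 5, 1)
        assert m.values[0, 4, 0] == 5.0

    def test_duplicate_gene_error_names_id(self, tmp_path):
        p = self._write(tmp_path, "gene\tt0\tt1\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ValueError, match="g1"):
            read_expression(p, times=[0, 1])

    def test_non_numeric_cell_named(self, tmp_path):
        p = self._write(tmp_path, "gene\tt0\tt1\ng1\t1\toops\n")
        with pytest.raises(ValueError, match="oops"):
            read_expression(p, times=[0, 1])

    def test_column_count_mismatch(self, tmp_path):
        p = self._write(tmp_path, "gene\tt0\tt1\ng1\t1\t2\n")
        with pytest.raises(ValueError, match="2 value columns"):
            read_expression(p, times=[0, 1, 2])

    def test_17_point_grid_at_10_unit_spacing(self, tmp_path):
        times = list(range(0, 170, 10))
        row = "\t".join(str(v) for v in range(17))
        p = self._write(
            tmp_path, "gene\t" + "\t".join(f"t{t}" for t in times) + f"\ng1\t{row}\ng2\t{row}\n"
        )
        m = read_expression(p, times=times)
        assert len(m.grid.points) == 17
        assert m.grid.points[1] - m.grid.points[0] == 10

    def test_replicate_layout_time_major(self, tmp_path):
        p = self._write(tmp_path, "gene\tt0r0\tt0r1\tt1r0\tt1r1\ng1\t1\t2\t3\t4\n")
        m = read_expression(p, times=[0, 1], n_replicates=2)
        assert m.values[0, 0].tolist() == [1, 2]
        assert m.values[0, 1].tolist() == [3, 4]

    def test_round_trip(self, tmp_path, small_matrix):
        p = tmp_path / "rt.tsv"
        write_expression(small_matrix, p)
        back = read_expression(p, times=small_matrix.grid.points)
        assert back.gene_ids == small_matrix.gene_ids
        np.testing.assert_allclose(back.values, small_matrix.values, rtol=0, atol=1e-12)


class TestGMT:
    def test_single_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("sce04111\tcell cycle\tCDC6\tMCM2\n")
        sets = read_gmt(p)
        assert len(sets) == 1
        assert sets.genes("sce04111") == {"CDC6", "MCM2"}
        assert sets.name("sce04111") == "cell cycle"

    def test_empty_file_and_blank_lines(self, tmp_path):
        p = tmp_path / "e.gmt"
        p.write_text("\n\n")
        assert len(read_gmt(p)) == 0

    def test_short_line_reports_line_number(self, tmp_path):
        p = tmp_path / "b.gmt"
        p.write_text("ok\tdesc\tg1\nbad\tdesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(p)

    def test_sets_may_share_genes(self, tmp_path):
        p = tmp_path / "o.gmt"
        p.write_text("p1\ta\tg1\tg2\np2\tb\tg2\tg3\np3\tc\tg4\n")
        sets = read_gmt(p)
        assert "g2" in sets.genes("p1") and "g2" in sets.genes("p2")

    def test_round_trip(self, tmp_path):
        sets = GeneSetCollection.from_mapping({"p1": ["a", "b"], "p2": ["b", "c", "d"]})
        p = tmp_path / "rt.gmt"
        write_gmt(sets, p)
        back = read_gmt(p)
        assert {pid: back.genes(pid) for pid in back.ids()} == {
            "p1": {"a", "b"}, "p2": {"b", "c", "d"},
        }


class TestNetworkSerialization:
    @pytest.fixture
    def chain_network(self, small_matrix):
        assign = ClusterAssignment(
            {g: (0 if i < 4 else 1 if i < 8 else 2) for i, g in enumerate(small_matrix.gene_ids)},
            k=3, method="manual",
        )
        fits = fit_cluster_gps(small_matrix, assign, seed=0)
        from tracs.network import EdgeAnnotation

        ann = {(2, 0): [EdgeAnnotation("p1", "pathway one", 0.01, 0.2, 0.3)]}
        return build_network(assign, fits, [2, 0, 1], ann, seed=7)

    def test_json_round_trip_is_lossless(self, tmp_path, chain_network):
        p = tmp_path / "net.json"
        write_network(chain_network, p, "json")
        assert read_network(p) == chain_network

    def test_three_node_chain_shape(self, tmp_path, chain_network):
        p = tmp_path / "net.json"
        write_network(chain_network, p, "json")
        d = json.loads(p.read_text())
        assert len(d["nodes"]) == 3 and len(d["edges"]) == 2
        assert d["order"] == [2, 0, 1]

    def test_annotated_edge_record(self, tmp_path, chain_network):
        p = tmp_path / "net.json"
        write_network(chain_network, p, "json")
        d = json.loads(p.read_text())
        ann = d["edges"][0]["annotations"][0]
        assert ann["pathway_id"] == "p1" and ann["p_union"] == 0.01

    def test_single_cluster_network(self, tmp_path, small_matrix):
        assign = ClusterAssignment({g: 0 for g in small_matrix.gene_ids}, k=1, method="manual")
        fits = fit_cluster_gps(small_matrix, assign, seed=0)
        net = build_network(assign, fits, [0])
        p = tmp_path / "one.json"
        write_network(net, p, "json")
        d = json.loads(p.read_text())
        assert len(d["nodes"]) == 1 and d["edges"] == []

    def test_graphml_and_dot_written(self, tmp_path, chain_network):
        write_network(chain_network, tmp_path / "net.graphml", "graphml")
        write_network(chain_network, tmp_path / "net.dot", "dot")
        assert "c2 -> c0" in (tmp_path / "net.dot").read_text()
        assert (tmp_path / "net.graphml").stat().st_size > 0

    def test_unknown_format_rejected(self, tmp_path, chain_network):
        with pytest.raises(ValueError, match="unknown network format"):
            write_network(chain_network, tmp_path / "x", "yaml")


def test_labels_round_trip(tmp_path):
    labels = {"g1": 0, "g2": 2, "g3": 1}
    p = tmp_path / "labels.tsv"
    write_labels(labels, p)
    assert read_labels(p) == labels
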
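import numpy as np
import pytest

from connmotif.errors import CollapseError, ParseError, PaletteError
from connmotif.fixtures import FixtureSpec, make_graph
from connmotif.graph_model import (
    CHEMICAL_ELECTRICAL,
    MONO,
    ConnectomeGraph,
    EdgeColorPalette,
    classify_strength,
    collapse_multi_edges,
    induced_subgraph,
    load_adjacency_matrix,
    load_edge_list,
    prune_weak_edges,
    write_edge_list,
)


class TestPalette:
    def test_codes_follow_declaration_order(self):
        pal = CHEMICAL_ELECTRICAL
        assert [pal.code_of(n) for n in ("chemical", "electrical", "both")] == [1, 2, 3]
        assert pal.name_of(2) == "electrical"
        assert pal.combined_code == 3

    def test_rejects_duplicates_and_unknown_names(self):
        with pytest.raises(PaletteError):
            EdgeColorPalette(("a", "a"))
        with pytest.raises(PaletteError):
            MONO.code_of("nope")
        with pytest.raises(PaletteError):
            EdgeColorPalette(("a",), combined="b")

    def test_rejects_more_than_35_colors(self):
        with pytest.raises(PaletteError):
            EdgeColorPalette(tuple(f"c{i}" for i in range(36)))


class TestEdgeListIO:
    def test_dense_ids_in_first_appearance_order(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("source,target\na,b\nb,c\n")
        g = load_edge_list(f)
        assert g.n == 3 and g.num_edges == 2
        assert g.vertex_name == ["a", "b", "c"]
        assert (0, 1) in g.edges and (1, 2) in g.edges

    def test_header_only_gives_empty_graph(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("source,target,weight,color\n")
        g = load_edge_list(f)
        assert g.n == 0 and g.num_edges == 0

    def test_parallel_rows_collapse_to_combined_color(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("source,target,weight,color\na,b,2,chemical\na,b,1,electrical\n")
        g = load_edge_list(f, CHEMICAL_ELECTRICAL)
        assert g.num_edges == 1
        color, weight = g.edges[(0, 1)]
        assert g.palette.name_of(color) == "both" and weight == 3

    def test_malformed_row_names_line(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("source,target,weight\na,b,1\na,b,oops\n")
        with pytest.raises(ParseError, match=":3"):
            load_edge_list(f)

    def test_color_outside_palette_rejected(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("source,target,weight,color\na,b,1,purple\n")
        with pytest.raises(PaletteError):
            load_edge_list(f, CHEMICAL_ELECTRICAL)

    def test_zero_weight_edges_dropped(self, tmp_path):
        f = tmp_path / "g.csv"
        f.write_text("source,target,weight\na,b,0\nb,c,2\n")
        g = load_edge_list(f)
        assert g.num_edges == 1 and (1, 2) in g.edges

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_preserves_edges_colors_weights(self, tmp_path, seed):
        g = make_graph(FixtureSpec(model="erdos-renyi", n=15, p=0.2, num_colors=3,
                                   self_loop_p=0.2, seed=seed))
        f = tmp_path / "g.csv"
        write_edge_list(g, f)
        # names in g are vertex ids as strings; reload maps by first appearance
        h = load_edge_list(f, g.palette)
        orig = {(g.vertex_name[u], g.vertex_name[v]): cw for (u, v), cw in g.edges.items()}
        back = {(h.vertex_name[u], h.vertex_name[v]): cw for (u, v), cw in h.edges.items()}
        assert orig == back

    def test_writer_is_byte_stable(self, tmp_path):
        g = make_graph(FixtureSpec(model="erdos-renyi", n=10, p=0.3, seed=4))
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_edge_list(g, f1)
        write_edge_list(g, f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestAdjacencyMatrix:
    def test_colored_single_entry(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("0,1\n0,0\n")
        g = load_adjacency_matrix(f)
        assert g.n == 2 and g.edges == {(0, 1): (1, 1.0)}

    def test_zero_matrix_is_edgeless(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("0,0,0\n0,0,0\n0,0,0\n")
        g = load_adjacency_matrix(f)
        assert g.n == 3 and g.num_edges == 0

    def test_diagonal_entry_becomes_self_loop(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("0,0,0\n0,0,0\n0,0,1\n")
        g = load_adjacency_matrix(f)
        assert (2, 2) in g.edges

    def test_non_square_rejected(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("0,1,0\n0,0,1\n")
        with pytest.raises(ParseError, match="square"):
            load_adjacency_matrix(f)

    def test_weighted_dialect_keeps_weights(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("0,7\n2,0\n")
        g = load_adjacency_matrix(f, dialect="weighted")
        assert g.edges[(0, 1)] == (1, 7.0) and g.edges[(1, 0)] == (1, 2.0)

    def test_colored_entry_outside_palette_rejected(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("0,5\n0,0\n")
        with pytest.raises(PaletteError):
            load_adjacency_matrix(f, MONO, dialect="colored")


class TestCollapse:
    def test_single_row_is_identity(self):
        assert collapse_multi_edges([(0, 1, 2.0, 1)], CHEMICAL_ELECTRICAL) == (0, 1, 2.0, 1)

    def test_same_color_rows_sum_weights(self):
        assert collapse_multi_edges([(0, 1, 1.0, 1), (0, 1, 1.0, 1)], CHEMICAL_ELECTRICAL) \
            == (0, 1, 2.0, 1)

    def test_conflicting_colors_get_combined_color(self):
        u, v, w, c = collapse_multi_edges([(0, 1, 2.0, 1), (0, 1, 1.0, 2)], CHEMICAL_ELECTRICAL)
        assert (w, c) == (3.0, CHEMICAL_ELECTRICAL.code_of("both"))

    def test_conflict_without_combined_color_errors(self):
        pal = EdgeColorPalette(("chemical", "electrical"))
        with pytest.raises(CollapseError):
            collapse_multi_edges([(0, 1, 1.0, 1), (0, 1, 1.0, 2)], pal)

    def test_order_independence(self):
        rows = [(0, 1, 2.0, 1), (0, 1, 1.0, 2), (0, 1, 4.0, 1)]
        import itertools
        results = {collapse_multi_edges(list(p), CHEMICAL_ELECTRICAL)
                   for p in itertools.permutations(rows)}
        assert len(results) == 1


class TestStrength:
    @pytest.mark.parametrize("count,expected", [
        (0, "weak"), (3, "weak"),
        (4, "moderate"), (5, "moderate"), (9, "moderate"),
        (10, "strong"), (100, "strong"),
    ])
    def test_threshold_partition(self, count, expected):
        assert classify_strength(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_strength(-1)

    def test_prune_removes_exactly_weak_edges(self):
        g = ConnectomeGraph(4)
        g.add_edge(0, 1, 1, 2)
        g.add_edge(1, 2, 1, 4)
        g.add_edge(2, 3, 1, 10)
        p = prune_weak_edges(g)
        assert p.n == 4
        assert set(p.edges) == {(1, 2), (2, 3)}
        assert set(p.edges) == {e for e, (_, w) in g.edges.items() if w >= 4}

    def test_prune_all_weak_leaves_vertices(self):
        g = ConnectomeGraph(3)
        g.add_edge(0, 1, 1, 1)
        p = prune_weak_edges(g)
        assert p.n == 3 and p.num_edges == 0

    def test_strength_recoloring(self):
        g = ConnectomeGraph(3)
        g.add_edge(0, 1, 1, 5)
        g.add_edge(1, 2, 1, 12)
        p = prune_weak_edges(g, strength_palette=True)
        assert p.palette.names == ("moderate", "strong")
        assert p.edges[(0, 1)][0] == 1 and p.edges[(1, 2)][0] == 2

    def test_directions_pruned_independently(self):
        g = ConnectomeGraph(2)
        g.add_edge(0, 1, 1, 2)
        g.add_edge(1, 0, 1, 8)
        p = prune_weak_edges(g)
        assert set(p.edges) == {(1, 0)}


class TestInducedSubgraph:
    def test_path_read_off(self):
        g = ConnectomeGraph(3)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        np.testing.assert_array_equal(
            induced_subgraph(g, {0, 1, 2}),
            [[0, 1, 0], [0, 0, 1], [0, 0, 0]],
        )

    def test_singleton_without_loop(self):
        g = ConnectomeGraph(2)
        np.testing.assert_array_equal(induced_subgraph(g, {1}), [[0]])

    def test_colored_pair(self):
        g = ConnectomeGraph(5, CHEMICAL_ELECTRICAL)
        g.add_edge(1, 3, 2)
        g.add_edge(3, 1, 1)
        np.testing.assert_array_equal(induced_subgraph(g, {1, 3}), [[0, 2], [1, 0]])

    def test_diagonal_carries_self_loops(self):
        g = ConnectomeGraph(3)
        g.add_edge(2, 2)
        np.testing.assert_array_equal(induced_subgraph(g, {1, 2}), [[0, 0], [0, 1]])

    def test_unknown_vertex_rejected(self):
        g = ConnectomeGraph(2)
        with pytest.raises(IndexError):
            induced_subgraph(g, {0, 5})
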
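"""Food-web construction, I/O round-trips and sub-web induction."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trophoweb import (
    FoodWeb,
    FoodWebError,
    SpeciesSet,
    add_species,
    induced_subweb,
    read_graphml,
    read_web,
    shared_unique,
    write_graphml,
    write_report,
)
from trophoweb.core import read_species_set, write_attributes, write_edge_list

from conftest import random_web


class TestConstruction:
    def test_basic_counts(self):
        web = FoodWeb([("a", "b"), ("b", "c")])
        assert web.S == 3 and web.L == 2

    def test_duplicate_links_collapse_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            web = FoodWeb([("a", "b"), ("a", "b")])
        assert web.L == 1
        assert "duplicate" in caplog.text

    def test_self_links_allowed_and_counted_once_in_degree(self):
        web = FoodWeb([("a", "a"), ("a", "b")])
        assert ("a", "a") in web.links
        assert web.degree_of("a") == 2  # self-link once + link to b

    def test_invalid_habitat_code_rejected(self):
        with pytest.raises(FoodWebError, match="habitat"):
            FoodWeb([("a", "b")], habitat={"a": "X"})

    def test_invalid_group_code_rejected(self):
        with pytest.raises(FoodWebError, match="group"):
            FoodWeb([("a", "b")], group={"a": "algae"})

    def test_isolated_nodes_retained(self):
        web = FoodWeb([("a", "b")], nodes=["c"])
        assert web.S == 3


class TestIO:
    def test_read_web_counts(self, tmp_path):
        p = tmp_path / "web.csv"
        p.write_text("prey,predator\na,b\nb,c\n")
        web = read_web(p)
        assert web.S == 3 and web.L == 2

    def test_read_web_duplicate_row_collapses(self, tmp_path, caplog):
        p = tmp_path / "web.csv"
        p.write_text("prey,predator\na,b\na,b\n")
        with caplog.at_level(logging.WARNING):
            web = read_web(p)
        assert web.L == 1

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "web.csv"
        p.write_text("prey,predator\na,b\nonlyprey\n")
        with pytest.raises(FoodWebError, match=":3"):
            read_web(p)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "web.csv"
        p.write_text("from,to\na,b\n")
        with pytest.raises(FoodWebError, match="header"):
            read_web(p)

    def test_attributes_add_isolated_nodes_and_validate(self, tmp_path):
        p = tmp_path / "web.csv"
        p.write_text("prey,predator\na,b\n")
        attrs = tmp_path / "attrs.csv"
        attrs.write_text("id,habitat,group\na,P,basal\nb,BP,fish\nlonely,B,benthos\n")
        web = read_web(p, attrs)
        assert web.S == 3
        assert web.habitat_of("lonely") == "B"
        bad = tmp_path / "bad.csv"
        bad.write_text("id,habitat,group\na,Q,fish\n")
        with pytest.raises(FoodWebError, match="habitat"):
            read_web(p, bad)

    def test_edge_list_attribute_round_trip(self, tmp_path):
        web = FoodWeb(
            [("a", "b"), ("b", "c"), ("c", "c")],
            habitat={"a": "P", "b": "BP", "c": "B"},
            group={"a": "basal", "b": "fish", "c": "benthos"},
        )
        write_edge_list(web, tmp_path / "e.csv")
        write_attributes(web, tmp_path / "a.csv")
        back = read_web(tmp_path / "e.csv", tmp_path / "a.csv")
        assert back == web

    def test_graphml_round_trip(self, tmp_path):
        web = FoodWeb([("a", "b"), ("b", "c")], habitat={"a": "P"}, name="toy")
        path = tmp_path / "web.graphml"
        write_graphml(web, path)
        back = read_graphml(path)
        assert back.nodes == web.nodes and back.links == web.links
        assert back.habitat_of("a") == "P"

    def test_graphml_readable_by_independent_parser(self, tmp_path):
        igraph = pytest.importorskip("igraph")
        web = FoodWeb([("a", "b"), ("b", "c"), ("a", "c")], name="toy")
        path = tmp_path / "web.graphml"
        write_graphml(web, path)
        g = igraph.Graph.Read_GraphML(str(path))
        assert g.vcount() == web.S and g.ecount() == web.L

    def test_report_json_keys(self, tmp_path):
        write_report({"S": 3, "L": 2, "LD": 2 / 3, "C": 2 / 9}, tmp_path / "r.json")
        import json

        data = json.loads((tmp_path / "r.json").read_text())
        assert set(data) == {"S", "L", "LD", "C"}

    def test_species_set_file(self, tmp_path):
        p = tmp_path / "set.txt"
        p.write_text("a\nb\n\na\n")
        ss = read_species_set(p)
        assert ss.members == frozenset({"a", "b"})


class TestSubwebs:
    def test_induced_keeps_internal_links_only(self):
        meta = FoodWeb([("a", "b"), ("b", "c"), ("a", "c")])
        sub = induced_subweb(meta, SpeciesSet("s", {"a", "b"}))
        assert sub.links == {("a", "b")} and sub.nodes == {"a", "b"}

    def test_induced_full_subset_is_identity(self):
        meta = FoodWeb([("a", "b"), ("b", "c"), ("c", "c")], habitat={"a": "P"})
        sub = induced_subweb(meta, SpeciesSet("all", meta.nodes))
        assert sub == meta

    def test_unknown_member_error_lists_offenders(self):
        meta = FoodWeb([("a", "b")])
        with pytest.raises(FoodWebError, match="ghost"):
            induced_subweb(meta, SpeciesSet("s", {"a", "ghost"}))

    def test_empty_subset_rejected(self):
        with pytest.raises(FoodWebError, match="empty"):
            SpeciesSet("s", set())

    def test_induced_matches_brute_force_filter(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            meta = random_web(rng, 10, 0.25)
            members = set(
                rng.choice(sorted(meta.nodes), size=5, replace=False).tolist()
            )
            sub = induced_subweb(meta, SpeciesSet("s", members))
            expected = {
                (u, v) for u, v in meta.links if u in members and v in members
            }
            assert sub.links == expected

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_add_species_equals_union_induction(self, data):
        """add_species(sub(X), meta, Y) == induced(meta, X|Y) on small metas."""
        n = data.draw(st.integers(4, 8))
        names = [f"n{i}" for i in range(n)]
        links = data.draw(
            st.sets(
                st.tuples(st.sampled_from(names), st.sampled_from(names)),
                min_size=1,
                max_size=20,
            )
        )
        meta = FoodWeb(links, nodes=names)
        x = data.draw(st.sets(st.sampled_from(names), min_size=1))
        y = data.draw(st.sets(st.sampled_from(names), min_size=1))
        base = induced_subweb(meta, SpeciesSet("x", x))
        grown = add_species(base, meta, SpeciesSet("y", y))
        direct = induced_subweb(meta, SpeciesSet("xy", x | y))
        assert grown.nodes == direct.nodes and grown.links == direct.links

    def test_add_species_idempotent_for_residents(self):
        meta = FoodWeb([("a", "b"), ("b", "c")])
        sub = induced_subweb(meta, SpeciesSet("s", {"a", "b"}))
        again = add_species(sub, meta, SpeciesSet("y", {"a"}))
        assert again.nodes == sub.nodes and again.links == sub.links

    def test_newcomer_links_counted_by_enumeration(self):
        meta = FoodWeb([("a", "b"), ("c", "b"), ("a", "c"), ("d", "a")])
        sub = induced_subweb(meta, SpeciesSet("s", {"a", "b"}))
        grown = add_species(sub, meta, SpeciesSet("y", {"c"}))
        # c's meta links into {a, b, c}: (c,b) and (a,c)
        assert grown.L == sub.L + 2

    def test_monotone_links(self):
        rng = np.random.default_rng(5)
        meta = random_web(rng, 8, 0.3)
        nodes = sorted(meta.nodes)
        small = set(nodes[:4])
        big = set(nodes[:6])
        sub_small = induced_subweb(meta, SpeciesSet("a", small))
        sub_big = induced_subweb(meta, SpeciesSet("b", big))
        assert sub_small.links <= sub_big.links
        for n in small:
            assert sub_small.degree_of(n) <= meta.degree_of(n)


class TestSharedUnique:
    def test_identical_and_disjoint(self):
        a = FoodWeb([("a", "b")])
        assert shared_unique(a, a) == (2, 0)
        b = FoodWeb([("x", "y")])
        assert shared_unique(a, b) == (0, 4)

    def test_partial_overlap(self):
        a = FoodWeb([("a", "b"), ("b", "c")])
        b = FoodWeb([("b", "c"), ("c", "d")])
        assert shared_unique(a, b) == (2, 2)
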
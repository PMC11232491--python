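"""Parsers and writers: format conformance, normalization, round-trips."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmcite import Corpus, Document, Probe, normalize_symbol
from swarmcite.errors import InputFormatError
from swarmcite.io import (
    packaged_data,
    read_corpus,
    read_gene_sets,
    read_matrix,
    read_overlap_fixture,
    read_ppi_edgelist,
    read_proteomes,
    read_table1_fixture,
    write_corpus,
    write_matrix,
    write_ppi_edgelist,
    write_proteomes,
)


class TestSymbolNormalization:
    def test_uppercase_strip(self):
        assert normalize_symbol(" nedd4l ") == "NEDD4L"

    def test_hyphen_preserved(self):
        assert normalize_symbol("MT-CYB") == "MT-CYB"

    @pytest.mark.parametrize("bad", ["", "  ", "A B"])
    def test_rejects_empty_and_whitespace(self, bad):
        with pytest.raises(InputFormatError):
            normalize_symbol(bad)


class TestPPIReader:
    def test_symmetric_duplicate_collapses(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tA\n")
        net = read_ppi_edgelist(p)
        assert len(net.edges) == 1 and net.edges == {frozenset({"A", "B"})}

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "e.tsv"
        p.write_text("A\tA\n")
        with caplog.at_level("WARNING"):
            net = read_ppi_edgelist(p)
        assert len(net.edges) == 0 and net.nodes == {"A"}
        assert any("self-loop" in r.message for r in caplog.records)

    def test_max_weight_kept(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t0.2\nB\tA\t0.9\n")
        net = read_ppi_edgelist(p)
        assert net.graph.edges["A", "B"]["weight"] == 0.9

    @pytest.mark.parametrize("row,lineno", [("A\tB\tC\tD", 2), ("A\tB\t1.5", 2), ("A", 2)])
    def test_malformed_row_names_line(self, tmp_path, row, lineno):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\n" + row + "\n")
        with pytest.raises(InputFormatError, match=f"line {lineno}"):
            read_ppi_edgelist(p)

    def test_pdia3_fixture_unique_partners(self):
        """The printed partner sentence has 14 tokens, one duplicated, and
        names the receptor itself; parsing yields 13 unique symbols but
        only 12 physical neighbors (the self pair is a dropped loop)."""
        net = read_ppi_edgelist(packaged_data("pdia3_interactors.tsv"))
        assert len(net.nodes) == 13
        assert len(net.neighbors("PDIA3")) == 12


class TestCorpusReader:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text("")
        assert len(read_corpus(p)) == 0

    def test_three_documents_mentions_deduplicated(self, tmp_path):
        p = tmp_path / "c.jsonl"
        recs = [
            {"doc_id": f"d{i}", "probe_mentions": ["x", "x"], "protein_mentions": ["akt1", "AKT1"]}
            for i in range(3)
        ]
        p.write_text("\n".join(json.dumps(r) for r in recs) + "\n")
        corpus = read_corpus(p)
        assert len(corpus) == 3
        assert corpus.documents[0].protein_mentions == frozenset({"AKT1"})
        assert corpus.documents[0].probe_mentions == frozenset({"x"})

    def test_missing_doc_id_names_line(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text(json.dumps({"probe_mentions": [], "protein_mentions": []}) + "\n")
        with pytest.raises(InputFormatError, match="line 1"):
            read_corpus(p)

    def test_duplicate_doc_id_rejected(self, tmp_path):
        p = tmp_path / "c.jsonl"
        rec = {"doc_id": "d", "probe_mentions": [], "protein_mentions": []}
        p.write_text(json.dumps(rec) + "\n" + json.dumps(rec) + "\n")
        with pytest.raises(InputFormatError, match="duplicate doc_id"):
            read_corpus(p)


class TestGeneSets:
    def test_two_member_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("autophagy\tna\tATG5\tBECN1\n")
        (gs,) = read_gene_sets(p)
        assert gs.proteins == frozenset({"ATG5", "BECN1"})

    def test_duplicate_member_deduplicated(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("s\tna\tATG5\tatg5\n")
        assert len(read_gene_sets(p)[0].proteins) == 1

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("autophagy\tATG5\n")
        with pytest.raises(InputFormatError):
            read_gene_sets(p)

    def test_packaged_function_sets(self):
        sets = read_gene_sets(packaged_data("fig4_functions.gmt"))
        assert [s.name for s in sets] == [
            "atherosclerosis",
            "macrophage polarization",
            "macrophage autophagy",
        ]


class TestPrintedTableFixtures:
    def test_toy_two_columns(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("c1\tc2\nA\tB\nC\t\n")
        fx = read_table1_fixture(p)
        assert fx.cluster_labels == ["c1", "c2"]
        assert fx.columns["c1"] == ["A", "C"] and fx.columns["c2"] == ["B"]

    def test_duplicate_label_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("c1\tc1\nA\tB\n")
        with pytest.raises(InputFormatError, match="duplicate cluster label"):
            read_table1_fixture(p)

    def test_repeated_symbol_preserved(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("c1\tc2\nA\tB\nA\tC\n")
        assert read_table1_fixture(p).columns["c1"] == ["A", "A"]

    def test_packaged_table1_cluster_count(self):
        fx = read_table1_fixture(packaged_data("table1.tsv"))
        assert fx.n_clusters == 29

    @pytest.mark.parametrize("name,n_rows", [("table2.tsv", 29), ("table3.tsv", 50), ("table4.tsv", 19)])
    def test_packaged_overlap_grids(self, name, n_rows):
        grid = read_overlap_fixture(packaged_data(name))
        assert grid.shape == (n_rows, 11)
        assert list(grid.columns) == list("ABCDEFGHIJK")

    def test_table4_macrophage_autophagy_column_empty(self):
        """The non-genomic receptor's cluster grid has no macrophage
        autophagy members — the contrast the overlap analysis turns on."""
        grid = read_overlap_fixture(packaged_data("table4.tsv"))
        assert not grid["D"].any()

    def test_table2_grid_contains_mtor_autophagy_mark(self):
        # transcription fidelity: the printed grid marks MTOR in D and E
        grid = read_overlap_fixture(packaged_data("table2.tsv"))
        assert grid.loc["MTOR", "D"] and grid.loc["MTOR", "E"]


class TestMatrixRoundTrip:
    def test_integer_exact(self, tmp_path):
        m = pd.DataFrame([[1, 2], [3, 4]], index=["r1", "r2"], columns=["c1", "c2"])
        write_matrix(m, tmp_path / "m.tsv")
        back = read_matrix(tmp_path / "m.tsv")
        assert back.equals(m)

    def test_real_within_1e12(self, tmp_path):
        m = pd.DataFrame([[1 / 3]], index=["r"], columns=["c"])
        write_matrix(m, tmp_path / "m.tsv")
        back = read_matrix(tmp_path / "m.tsv")
        assert abs(back.iloc[0, 0] - 1 / 3) < 1e-12

    def test_empty_matrix(self, tmp_path):
        m = pd.DataFrame()
        write_matrix(m, tmp_path / "m.tsv")
        assert read_matrix(tmp_path / "m.tsv").empty

    def test_duplicate_labels_rejected(self, tmp_path):
        m = pd.DataFrame([[1], [2]], index=["r", "r"], columns=["c"])
        with pytest.raises(InputFormatError):
            write_matrix(m, tmp_path / "m.tsv")


# ------------------------------------------------------- property round-trips

symbols = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789-", min_size=1, max_size=6)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    docs=st.lists(
        st.tuples(st.sets(symbols, max_size=4), st.sets(symbols, max_size=6)),
        max_size=12,
    )
)
def test_corpus_round_trip(tmp_path_factory, docs):
    corpus = Corpus()
    for i, (probe_ids, proteins) in enumerate(docs):
        corpus.documents.append(
            Document(
                doc_id=f"d{i}",
                probe_mentions=frozenset(probe_ids),
                protein_mentions=frozenset(proteins),
            )
        )
        for pid in probe_ids:
            corpus.probe_registry.setdefault(pid, Probe(probe_id=pid))
    path = tmp_path_factory.mktemp("rt") / "c.jsonl"
    write_corpus(corpus, path)
    back = read_corpus(path)
    assert [d.doc_id for d in back.documents] == [d.doc_id for d in corpus.documents]
    assert all(
        a.probe_mentions == b.probe_mentions and a.protein_mentions == b.protein_mentions
        for a, b in zip(back.documents, corpus.documents)
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_matrix_round_trip_random(tmp_path_factory, data):
    nr = data.draw(st.integers(1, 5))
    nc = data.draw(st.integers(1, 5))
    values = data.draw(
        st.lists(
            st.lists(st.floats(0, 1e6, allow_nan=False, width=32), min_size=nc, max_size=nc),
            min_size=nr,
            max_size=nr,
        )
    )
    m = pd.DataFrame(values, index=[f"r{i}" for i in range(nr)], columns=[f"c{j}" for j in range(nc)])
    path = tmp_path_factory.mktemp("rt") / "m.tsv"
    write_matrix(m, path)
    back = read_matrix(path)
    np.testing.assert_allclose(back.to_numpy(float), m.to_numpy(float), rtol=1e-11, atol=1e-300)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    edges=st.sets(
        st.tuples(st.integers(0, 12), st.integers(0, 12)).filter(lambda e: e[0] != e[1]),
        max_size=20,
    )
)
def test_ppi_round_trip_random(tmp_path_factory, edges):
    from swarmcite import PPINetwork

    net = PPINetwork()
    for a, b in edges:
        net.add_edge(f"N{a}", f"N{b}")
    if len(net) == 0:
        return
    path = tmp_path_factory.mktemp("rt") / "e.tsv"
    write_ppi_edgelist(net, path)
    back = read_ppi_edgelist(path)
    assert back.nodes == net.nodes and back.edges == net.edges


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    tissues=st.dictionaries(
        st.sampled_from(["T1", "T2", "T3"]), st.sets(symbols, min_size=1, max_size=8), min_size=1
    )
)
def test_proteome_round_trip_random(tmp_path_factory, tissues):
    from swarmcite import TissueProteome

    proteomes = [TissueProteome(t, frozenset(ps)) for t, ps in tissues.items()]
    path = tmp_path_factory.mktemp("rt") / "p.tsv"
    write_proteomes(proteomes, path)
    back = read_proteomes(path)
    assert {p.tissue_id: p.proteins for p in back} == {p.tissue_id: p.proteins for p in proteomes}
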
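"""Term frequencies and co-occurrence network construction/export."""

import pytest

from pmcindex import (
    Corpus,
    CorpusGenSpec,
    Document,
    build_network,
    corpus_from_texts,
    export_network,
    generate_corpus,
    read_network,
    term_frequencies,
)


def corpus_of(*units):
    return Corpus(documents=(Document(id="d1", units=tuple(tuple(u) for u in units)),))


class TestTermFrequencies:
    def test_direct_counts(self):
        stats = term_frequencies(corpus_of(["service", "older", "service"]))
        assert stats == {"service": 2, "older": 1}

    def test_stopwords_filtered(self):
        stats = term_frequencies(corpus_of(["service", "older", "service"]), {"older"})
        assert stats == {"service": 2}

    def test_empty_corpus(self):
        assert term_frequencies(Corpus(documents=())) == {}

    def test_corpus_from_texts_splits_units(self):
        corpus = corpus_from_texts({"d": "a b。c d\ne f"})
        assert [list(u) for u in corpus.documents[0].units] == [
            ["a", "b"], ["c", "d"], ["e", "f"]
        ]


class TestBuildNetwork:
    def test_edge_weight_counts_shared_units(self):
        corpus = corpus_of(["a", "b"], ["a", "b", "c"], ["a", "c"])
        net = build_network(corpus, top_n=10)
        assert net.edges[("a", "b")] == 2
        assert net.edges[("a", "c")] == 2
        assert net.edges[("b", "c")] == 1

    def test_undirected_no_self_loops(self):
        corpus = corpus_of(["a", "a", "b"], ["b", "a"])
        net = build_network(corpus, top_n=5)
        assert not any(a == b for a, b in net.edges)
        assert net.graph.has_edge("a", "b") and net.graph.has_edge("b", "a")

    def test_top_n_selects_most_frequent_with_lexicographic_ties(self):
        corpus = corpus_of(["b", "c", "a"], ["c"])
        net = build_network(corpus, top_n=2)
        assert set(net.nodes) == {"a", "c"}  # c (2), then a before b on the tie

    def test_single_node_network(self):
        net = build_network(corpus_of(["a", "b"]), top_n=1)
        assert len(net.nodes) == 1 and not net.edges

    def test_node_weights_are_term_frequencies(self):
        corpus = corpus_of(["a", "a", "b"], ["a"])
        net = build_network(corpus, top_n=5)
        freqs = term_frequencies(corpus)
        assert net.nodes == {t: freqs[t] for t in net.nodes}

    def test_edge_weight_bounded_by_unit_presence(self):
        corpus = corpus_of(["a", "a", "b"], ["a"], ["b"])
        net = build_network(corpus, top_n=5)
        # 'a' appears in 2 units, 'b' in 2, together in 1
        assert net.edges[("a", "b")] == 1

    def test_window_option_restricts_pairs(self):
        corpus = corpus_of(["a", "x", "x", "x", "b"])
        assert ("a", "b") in build_network(corpus, top_n=5).edges
        assert ("a", "b") not in build_network(corpus, top_n=5, window=3).edges

    def test_stopword_filtering_commutes_with_top_n(self):
        corpus = corpus_of(["the", "a", "b"], ["the", "a"], ["b", "c"])
        net = build_network(corpus, stopwords={"the"}, top_n=2)
        assert "the" not in net.nodes and len(net.nodes) == 2


class TestPlantedHub:
    def test_hub_dominates_weighted_degree(self):
        spec = CorpusGenSpec(
            vocabulary=tuple("abcdefghij") + ("hub",),
            hub_terms=("hub",),
            n_documents=5,
            units_per_document=10,
            fillers_per_unit=3,
            seed=7,
        )
        net = build_network(generate_corpus(spec), top_n=11)
        hub_degree = net.weighted_degree("hub")
        assert all(
            hub_degree >= net.weighted_degree(t) for t in net.nodes if t != "hub"
        )


class TestExport:
    @pytest.fixture()
    def network(self):
        corpus = corpus_of(["a", "b"], ["a", "b", "c"], ["d"])
        return build_network(corpus, top_n=4)

    @pytest.mark.parametrize("format", ["edge-list", "graphml"])
    def test_round_trip_preserves_weights(self, network, format, tmp_path):
        dest = tmp_path / f"net.{format}"
        export_network(network, dest, format=format)
        again = read_network(dest, format=format)
        assert again.nodes == network.nodes
        assert again.edges == network.edges

    def test_isolated_nodes_survive(self, network):
        assert "d" in read_network(export_network(network), format="edge-list").nodes

    def test_empty_network_is_header_only(self):
        from pmcindex import CooccurrenceNetwork

        text = export_network(CooccurrenceNetwork())
        assert text.strip().splitlines() == ["kind\ta\tb\tweight"]

    def test_unknown_format_rejected(self, network):
        with pytest.raises(ValueError):
            export_network(network, format="dot")
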
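"""Term-frequency and keyword co-occurrence network analysis.

A corpus is a list of documents, each split into *co-occurrence units*
(by default one sentence/line). Two terms co-occur when they appear in the
same unit; the semantic network is the weighted undirected graph whose
nodes are the most frequent non-stopword terms (node weight = frequency)
and whose edge weights count co-occurring units.

Tokenization is pluggable: the default assumes pre-segmented,
whitespace-separated text, so any external segmenter (for Chinese, jieba
or similar) can be run upstream.
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Literal, Mapping

import networkx as nx

__all__ = [
    "Document",
    "Corpus",
    "CooccurrenceNetwork",
    "corpus_from_texts",
    "term_frequencies",
    "build_network",
    "export_network",
    "read_network",
]

Tokenizer = Callable[[str], list[str]]

_UNIT_SPLIT = re.compile(r"[\n。！？!?；;]+")


@dataclass(frozen=True)
class Document:
    """One policy text, pre-split into ordered co-occurrence units."""

    id: str
    units: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of tokenised documents."""

    documents: tuple[Document, ...]

    def iter_units(self) -> Iterator[tuple[str, ...]]:
        for doc in self.documents:
            yield from doc.units

    @property
    def n_documents(self) -> int:
        return len(self.documents)


def corpus_from_texts(
    texts: Mapping[str, str],
    tokenizer: Tokenizer = str.split,
    unit_pattern: re.Pattern = _UNIT_SPLIT,
) -> Corpus:
    """Build a corpus from raw text, one co-occurrence unit per
    sentence/line (split on newlines and CJK/Latin sentence enders)."""
    documents = []
    for doc_id, text in texts.items():
        units = tuple(
            tuple(tokenizer(chunk))
            for chunk in unit_pattern.split(text)
            if chunk.strip()
        )
        documents.append(Document(id=str(doc_id), units=units))
    return Corpus(documents=tuple(documents))


def term_frequencies(
    corpus: Corpus, stopwords: Iterable[str] = ()
) -> Counter[str]:
    """Occurrence counts over all tokens, with stopwords removed."""
    stop = frozenset(stopwords)
    counts: Counter[str] = Counter()
    for unit in corpus.iter_units():
        counts.update(tok for tok in unit if tok and tok not in stop)
    return counts


@dataclass
class CooccurrenceNetwork:
    """Weighted undirected keyword graph.

    Node attribute ``weight`` is the term's corpus frequency; edge
    attribute ``weight`` counts units where both endpoints occur. No
    self-loops exist; zero-weight edges are never stored.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> dict[str, int]:
        return {n: int(d["weight"]) for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> dict[tuple[str, str], int]:
        return {
            tuple(sorted((a, b))): int(d["weight"])
            for a, b, d in self.graph.edges(data=True)
        }

    def weighted_degree(self, term: str) -> int:
        """Sum of incident edge weights — the centrality reported here."""
        return int(self.graph.degree(term, weight="weight"))


def build_network(
    corpus: Corpus,
    stopwords: Iterable[str] = (),
    top_n: int = 50,
    window: int | None = None,
) -> CooccurrenceNetwork:
    """Build the co-occurrence network over the ``top_n`` most frequent
    non-stopword terms.

    Frequency ties are broken lexicographically. With ``window=None``
    (default) two kept terms co-occur when they share a unit; with an
    integer window they must appear within ``window`` consecutive tokens
    of each other inside a unit (counted at most once per unit).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    freqs = term_frequencies(corpus, stopwords)
    kept = sorted(freqs, key=lambda t: (-freqs[t], t))[:top_n]
    kept_set = set(kept)
    graph = nx.Graph()
    for term in kept:
        graph.add_node(term, weight=int(freqs[term]))
    pair_counts: Counter[tuple[str, str]] = Counter()
    for unit in corpus.iter_units():
        if window is None:
            present = sorted({t for t in unit if t in kept_set})
            pairs = {
                (a, b) for i, a in enumerate(present) for b in present[i + 1 :]
            }
        else:
            pairs = set()
            toks = list(unit)
            for i, a in enumerate(toks):
                if a not in kept_set:
                    continue
                for b in toks[i + 1 : i + window]:
                    if b in kept_set and b != a:
                        pairs.add(tuple(sorted((a, b))))
        pair_counts.update(pairs)
    for (a, b), count in sorted(pair_counts.items()):
        graph.add_edge(a, b, weight=int(count))
    return CooccurrenceNetwork(graph=graph)


def export_network(
    network: CooccurrenceNetwork,
    dest: str | Path | None = None,
    format: Literal["edge-list", "graphml"] = "edge-list",
) -> str:
    """Lossless export of nodes, node weights and edge weights.

    ``edge-list`` is a TSV with ``node`` rows (term, weight) followed by
    ``edge`` rows (term a, term b, weight); isolated nodes survive the
    round-trip. ``graphml`` delegates to networkx.
    """
    if format == "edge-list":
        lines = ["kind\ta\tb\tweight"]
        for term, weight in sorted(network.nodes.items()):
            lines.append(f"node\t{term}\t\t{weight}")
        for (a, b), weight in sorted(network.edges.items()):
            lines.append(f"edge\t{a}\t{b}\t{weight}")
        text = "\n".join(lines) + "\n"
    elif format == "graphml":
        buffer = io.BytesIO()
        nx.write_graphml(network.graph, buffer)
        text = buffer.getvalue().decode("utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")
    if dest is not None:
        Path(dest).write_text(text, encoding="utf-8")
    return text


def read_network(
    source: str | Path,
    format: Literal["edge-list", "graphml"] = "edge-list",
) -> CooccurrenceNetwork:
    """Inverse of :func:`export_network`."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    if format == "edge-list":
        graph = nx.Graph()
        lines = text.strip().splitlines()
        for line in lines[1:]:  # skip header
            kind, a, b, weight = line.split("\t")
            if kind == "node":
                graph.add_node(a, weight=int(weight))
            elif kind == "edge":
                graph.add_edge(a, b, weight=int(weight))
            else:
                raise ValueError(f"unknown row kind {kind!r}")
        return CooccurrenceNetwork(graph=graph)
    if format == "graphml":
        graph = nx.read_graphml(io.BytesIO(text.encode("utf-8")))
        clean = nx.Graph()
        for n, d in graph.nodes(data=True):
            clean.add_node(n, weight=int(d["weight"]))
        for a, b, d in graph.edges(data=True):
            clean.add_edge(a, b, weight=int(d["weight"]))
        return CooccurrenceNetwork(graph=clean)
    raise ValueError(f"unknown format {format!r}")
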
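"""Keyword co-occurrence network from a small policy-like corpus.

Builds a toy corpus (whitespace-tokenised; for Chinese text run a
segmenter upstream), counts term frequencies, and builds the weighted
co-occurrence network over the most frequent terms. Edge weights count
sentences where both terms appear; weighted degree is the centrality
reported.
"""

from pmcindex import build_network, corpus_from_texts, export_network, term_frequencies

texts = {
    "d1": "smart care service platform。care service subsidy。device network security",
    "d2": "older adults care service。smart device pilot。care subsidy policy",
    "d3": "service platform pilot。smart care training",
}
stopwords = {"policy"}

corpus = corpus_from_texts(texts)
freqs = term_frequencies(corpus, stopwords)
print("term frequencies:", dict(freqs.most_common(5)), "...")

net = build_network(corpus, stopwords, top_n=8)
for term in sorted(net.nodes, key=net.weighted_degree, reverse=True):
    print(f"{term:<10} freq={net.nodes[term]:<3} weighted degree={net.weighted_degree(term)}")
# "care" and "service" sit at the centre: they co-occur with nearly everything.

print("\nedge list export:")
print(export_network(net, format="edge-list"))
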
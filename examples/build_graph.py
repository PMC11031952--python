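"""Build the heterogeneous k-mer/sequence graph and read off its statistics.

The graph has one node per unique 5-mer and one per sequence, and three
edge types: similarity (near-identical k-mers), coexisting (k-mer pairs
that travel together across positive sequences, beyond chance), and
inclusive (k-mer occurs in sequence).  The coexisting probability — how
often one k-mer directly follows another — is what later chains motif
seeds into longer sites.
"""

import numpy as np

from motifgat import PlantedMotifSpec, build_graph, generate_ppm, generate_synthetic
from motifgat.hetgraph import coexist_probability

rng = np.random.default_rng(1)
spec = PlantedMotifSpec(ppm=generate_ppm(8, 1.5, rng))
records, _ = generate_synthetic(spec, n_pos=200, seq_len=101, rng_seed=1)
graph = build_graph(records, lenk=5)

print(f"m = {graph.m} unique 5-mers, n = {graph.n} sequences")
print(f"similarity edges: {graph.W_sim.nnz}  (Hamming distance 1, weight 0.8)")
print(f"coexisting edges: {graph.W_co.nnz}  (above-chance co-occurrence)")
print(f"inclusive edges:  {graph.W_inclu.nnz}")

# the planted motif's overlapping 5-mer windows follow each other with high
# probability, while random pairs almost never do
cons = spec.consensus
a, b = graph.vocab.index[cons[0:5]], graph.vocab.index[cons[1:6]]
print(f"coexist probability {cons[0:5]} -> {cons[1:6]}: "
      f"{coexist_probability(graph.coexist, a, b):.3f}")
x = graph.vocab.index[graph.vocab.kmers[0]]
print(f"coexist probability {graph.vocab[x]} -> {cons[1:6]}: "
      f"{coexist_probability(graph.coexist, x, b):.3f}")
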
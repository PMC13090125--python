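"""Build a similarity atlas over embeddings and collapse redundancy.

Plants tight clusters of near-duplicate embeddings, builds the 3-NN graph,
collapses neighborhoods above 0.9 cosine similarity, and measures shortest
paths from queries to "library" nodes.
"""

import numpy as np

from dreams.atlas import build_knn_graph, collapse_neighborhoods, library_path_stats, rebuild_on_representatives

rng = np.random.default_rng(0)
emb, labels = [], []
for c_idx in range(6):
    center = rng.standard_normal(16)
    center /= np.linalg.norm(center)
    for _ in range(10):
        v = center + rng.normal(0, 0.02, size=16)
        emb.append(v / np.linalg.norm(v))
        labels.append(c_idx)
emb = np.asarray(emb)

graph = build_knn_graph(emb, k=3)
assignment = collapse_neighborhoods(graph, threshold=0.9)
clusters = assignment.clusters()
print(f"{len(emb)} embeddings -> {len(clusters)} collapsed nodes "
      f"(planted {max(labels) + 1} groups)")

rebuilt, reps = rebuild_on_representatives(graph, assignment, k=2)
stats = library_path_stats(rebuilt, query_nodes=[0], library_nodes=[len(reps) - 1])
hops, bottleneck = stats[0]
print(f"shortest path from query to library node: {hops:.0f} hops, "
      f"weakest edge similarity {bottleneck:.2f}")
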
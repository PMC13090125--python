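"""Embedding similarity graphs and neighborhood collapsing.

The atlas of a spectrum collection is a directed k-nearest-neighbor graph
over embeddings with cosine-similarity edge weights. Redundant neighborhoods
(mutual similarity above a threshold, 0.9 by default) are collapsed to their
highest-degree node by breadth-first search, and the graph can be rebuilt on
the surviving representatives; spectral-library annotations then propagate to
unannotated spectra along short high-similarity paths.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

BLANK_NAME_MARKERS = ("blank", "no_inj", "noinj", "empty", "solvent", "wash")


@dataclass
class EmbeddingGraph:
    """Directed k-NN graph: ``neighbors[i]`` / ``similarities[i]`` hold the
    out-edges of node i, most similar first; no self-edges."""

    embeddings: np.ndarray
    neighbors: np.ndarray  # (n, k) int
    similarities: np.ndarray  # (n, k) float in [-1, 1]
    payload: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.neighbors)

    def edges(self):
        for i in range(len(self)):
            for j, s in zip(self.neighbors[i], self.similarities[i]):
                yield int(i), int(j), float(s)

    def undirected_adjacency(self) -> dict[int, dict[int, float]]:
        adj: dict[int, dict[int, float]] = {i: {} for i in range(len(self))}
        for i, j, s in self.edges():
            adj[i][j] = max(adj[i].get(j, -np.inf), s)
            adj[j][i] = max(adj[j].get(i, -np.inf), s)
        return adj


def exclude_blank_samples(names: Sequence[str]) -> np.ndarray:
    """Boolean mask keeping samples whose names carry no blank-run marker
    (case-insensitive substring match)."""
    return np.asarray(
        [not any(m in n.lower() for m in BLANK_NAME_MARKERS) for n in names]
    )


def build_knn_graph(embeddings: np.ndarray, k: int = 3) -> EmbeddingGraph:
    """Exact k-nearest-neighbor graph by cosine similarity.

    Neighbor search is exact (it agrees with brute force at any n this
    package targets); ties are resolved deterministically by index.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2 or len(emb) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} embeddings")
    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine", algorithm="brute")
    nn.fit(emb)
    dist, idx = nn.kneighbors(emb)
    neighbors = np.empty((len(emb), k), dtype=np.int64)
    sims = np.empty((len(emb), k), dtype=np.float64)
    for i in range(len(emb)):
        row = [(int(j), 1.0 - float(d)) for j, d in zip(idx[i], dist[i]) if j != i]
        row = row[:k]
        while len(row) < k:  # duplicate points can shadow the self-match
            candidates = set(j for j, _ in row) | {i}
            extra = next(j for j in range(len(emb)) if j not in candidates)
            sim = 1.0 - float(
                np.clip(
                    1
                    - emb[i]
                    @ emb[extra]
                    / max(np.linalg.norm(emb[i]) * np.linalg.norm(emb[extra]), 1e-12),
                    0,
                    2,
                )
            )
            row.append((extra, sim))
        neighbors[i] = [j for j, _ in row]
        sims[i] = [s for _, s in row]
    return EmbeddingGraph(embeddings=emb, neighbors=neighbors, similarities=sims)


def _pairwise_cosine(emb: np.ndarray, i: int, j: int) -> float:
    denom = max(np.linalg.norm(emb[i]) * np.linalg.norm(emb[j]), 1e-12)
    return float(emb[i] @ emb[j] / denom)


@dataclass
class ClusterAssignment:
    representative: dict[int, int]

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for node, rep in self.representative.items():
            out.setdefault(rep, []).append(node)
        return out


def collapse_neighborhoods(
    graph: EmbeddingGraph, threshold: float = 0.9
) -> ClusterAssignment:
    """Collapse high-similarity neighborhoods by BFS.

    Nodes are visited in descending degree (ties by index). From each
    unassigned node a BFS expands over undirected edges; a candidate joins
    only if the edge similarity and its similarity to the starting node are
    both >= threshold. Visited nodes collapse to the start node.
    """
    adj = graph.undirected_adjacency()
    degree = np.array([len(adj[i]) for i in range(len(graph))])
    order = sorted(range(len(graph)), key=lambda i: (-degree[i], i))
    rep: dict[int, int] = {}
    for start in order:
        if start in rep:
            continue
        rep[start] = start
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for cand, sim in adj[node].items():
                if cand in rep:
                    continue
                if sim < threshold:
                    continue
                if _pairwise_cosine(graph.embeddings, start, cand) < threshold:
                    continue
                rep[cand] = start
                queue.append(cand)
    return ClusterAssignment(representative=rep)


def rebuild_on_representatives(
    graph: EmbeddingGraph, assignment: ClusterAssignment, k: int = 3
) -> tuple[EmbeddingGraph, np.ndarray]:
    """Second stage of the pipeline: re-run the k-NN construction on the
    representatives' own embeddings (not centroids)."""
    reps = sorted(set(assignment.representative.values()))
    sub = graph.embeddings[reps]
    return build_knn_graph(sub, k=min(k, len(reps) - 1)), np.asarray(reps)


def query_graph(
    graph: EmbeddingGraph, queries: np.ndarray, k: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest atlas nodes for new embeddings not present in the graph.

    Returns ``(neighbors, similarities)`` of shape (n_queries, k), most
    similar node first.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    nn = NearestNeighbors(n_neighbors=k, metric="cosine", algorithm="brute")
    nn.fit(graph.embeddings)
    dist, idx = nn.kneighbors(queries)
    return idx, 1.0 - dist


def library_path_stats(
    graph: EmbeddingGraph,
    query_nodes: Sequence[int],
    library_nodes: Sequence[int],
) -> list[tuple[float, float]]:
    """Per query: (shortest hop count to any library node, and the best
    bottleneck similarity over shortest paths).

    BFS hop distance on the undirected view; among all shortest paths to the
    nearest library node, report the maximum over paths of the minimum edge
    similarity along the path. Unreachable queries report (inf, nan).
    """
    q_set, lib_set = set(map(int, query_nodes)), set(map(int, library_nodes))
    if q_set & lib_set:
        raise ValueError("query and library node sets must be disjoint")
    adj = graph.undirected_adjacency()
    out = []
    for q in query_nodes:
        # layered BFS keeping, per node, the best bottleneck similarity
        dist = {int(q): 0}
        bottleneck = {int(q): np.inf}
        frontier = [int(q)]
        hops = 0
        found: Optional[int] = None
        while frontier and found is None:
            hops += 1
            nxt: dict[int, float] = {}
            for node in frontier:
                for nb, sim in adj[node].items():
                    cand_b = min(bottleneck[node], sim)
                    if nb in dist and dist[nb] < hops:
                        continue
                    if nb not in nxt or cand_b > nxt[nb]:
                        nxt[nb] = cand_b
            for nb, b in nxt.items():
                dist[nb] = hops
                bottleneck[nb] = max(bottleneck.get(nb, -np.inf), b)
            hits = [nb for nb in nxt if nb in lib_set]
            if hits:
                found = hops
            frontier = list(nxt)
        if found is None:
            out.append((float("inf"), float("nan")))
        else:
            best = max(bottleneck[nb] for nb in lib_set if dist.get(nb) == found)
            out.append((float(found), float(best)))
    return out
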
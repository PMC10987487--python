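"""Edge representations: five node-embedding views plus classical features.

Each edge gets six fixed-length vectors.  Views 1–5 are Hadamard products of
endpoint node embeddings produced by five in-package estimators covering the
main embedding families:

* ``n2v``  — sampled random-walk co-occurrence counts, log-compressed and
  factorised by truncated SVD (walks are actually sampled, as in
  node2vec/DeepWalk training; counts keep node popularity).
* ``dw``   — closed-form factorisation of the walk co-occurrence matrix
  (the NetMF identity for the skip-gram objective), no sampling.
* ``line`` — first- plus second-order proximity via truncated SVD of the
  adjacency and of the one-step transition PPMI.
* ``sdne`` — a small autoencoder on adjacency rows with non-zero entries
  over-weighted; the bottleneck activation is the embedding.
* ``s2v``  — structural-role features (degree, clustering, neighbour-degree
  statistics and log-binned neighbour-degree histograms) projected by PCA,
  so structurally equivalent nodes embed near each other regardless of
  distance in the graph.

View 6 is a vector of eleven classical edge features computed on the final
topology, standardised column-wise over edges.  All views are symmetric in
endpoint order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np
import scipy.sparse as sp

from ._nn import MLP
from .network import Edge, Node, TemporalNetwork, canonical_edge

EMBED_METHODS = ("n2v", "dw", "line", "sdne", "s2v")

CLASSICAL_FEATURES = (
    "common_neighbors",
    "jaccard",
    "adamic_adar",
    "resource_allocation",
    "preferential_attachment",
    "degree_sum",
    "degree_diff",
    "degree_min",
    "degree_max",
    "clustering_sum",
    "edge_triangles",
)


@dataclass
class NodeEmbedding:
    method: str
    dim: int
    nodes: List[Node]
    matrix: np.ndarray  # (n_nodes, dim)
    seed: int

    def __post_init__(self) -> None:
        self._index = {u: i for i, u in enumerate(self.nodes)}
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding contains non-finite entries")

    def vector(self, node: Node) -> np.ndarray:
        try:
            return self.matrix[self._index[node]]
        except KeyError:
            raise KeyError(f"node {node!r} not embedded") from None


def edge_vector(emb: NodeEmbedding, edge: Edge) -> np.ndarray:
    """Hadamard product of the endpoint vectors; symmetric in endpoint order."""
    u, v = edge
    return emb.vector(u) * emb.vector(v)


# ---------------------------------------------------------------------------
# embedding estimators (all dense; intended for networks up to a few thousand
# nodes, the scale of this package's study systems)
# ---------------------------------------------------------------------------

def _svd_embed(m: np.ndarray, dim: int) -> np.ndarray:
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    k = min(dim, s.shape[0])
    out = np.zeros((m.shape[0], dim))
    out[:, :k] = u[:, :k] * np.sqrt(s[:k])
    # deterministic sign: largest-magnitude loading positive per component
    for c in range(k):
        j = int(np.argmax(np.abs(out[:, c])))
        if out[j, c] < 0:
            out[:, c] = -out[:, c]
    return out


def _sample_walks(adj: sp.csr_matrix, n_walks: int, walk_len: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Vectorised uniform random walks: (n_nodes * n_walks, walk_len)."""
    n = adj.shape[0]
    deg = np.diff(adj.indptr)
    starts = np.tile(np.arange(n), n_walks)
    walks = np.empty((starts.shape[0], walk_len), dtype=np.int64)
    walks[:, 0] = starts
    cur = starts.copy()
    for t in range(1, walk_len):
        d = deg[cur]
        stuck = d == 0
        offs = (rng.random(cur.shape[0]) * np.maximum(d, 1)).astype(np.int64)
        nxt = adj.indices[adj.indptr[cur] + offs]
        nxt[stuck] = cur[stuck]
        walks[:, t] = nxt
        cur = nxt
    return walks


def _walk_cooccurrence(walks: np.ndarray, n: int, window: int) -> np.ndarray:
    counts = np.zeros((n, n))
    for off in range(1, window + 1):
        a = walks[:, :-off].ravel()
        b = walks[:, off:].ravel()
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    return counts


def _embed_walk_counts(adj: sp.csr_matrix, dim: int, rng: np.random.Generator,
                       n_walks: int = 10, walk_len: int = 40, window: int = 5) -> np.ndarray:
    """Factorise log-compressed walk co-occurrence counts.  Unlike a PMI
    transform, raw counts retain node popularity (walk visitation scales with
    degree), which is the part of the geometry that survives cross-network
    alignment."""
    walks = _sample_walks(adj, n_walks, walk_len, rng)
    counts = _walk_cooccurrence(walks, adj.shape[0], window)
    return _svd_embed(np.log1p(counts), dim)


def _embed_netmf(adj: sp.csr_matrix, dim: int, window: int = 5) -> np.ndarray:
    a = adj.toarray().astype(float)
    deg = a.sum(axis=1)
    vol = deg.sum()
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-12), 0.0)
    p = a * inv_deg[:, None]
    acc = np.zeros_like(a)
    pk = np.eye(a.shape[0])
    for _ in range(window):
        pk = pk @ p
        acc += pk
    m = (vol / window) * acc * inv_deg[None, :]
    m = np.log(np.maximum(m, 1.0))
    return _svd_embed(m, dim)


def _embed_line(adj: sp.csr_matrix, dim: int) -> np.ndarray:
    a = adj.toarray().astype(float)
    d1 = dim // 2
    first = _svd_embed(a, d1)
    deg = a.sum(axis=1)
    vol = deg.sum()
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-12), 0.0)
    m = vol * (a * inv_deg[:, None]) * inv_deg[None, :]
    second = _svd_embed(np.log(np.maximum(m, 1.0)), dim - d1)
    return np.hstack([first, second])


def _embed_autoencoder(adj: sp.csr_matrix, dim: int, rng: np.random.Generator,
                       beta: float = 5.0, epochs: int = 30, batch: int = 64,
                       lr: float = 1e-3) -> np.ndarray:
    a = adj.toarray().astype(float)
    n = a.shape[0]
    net = MLP([n, dim, n], rng)
    weight = np.where(a > 0, beta, 1.0)
    idx = np.arange(n)
    for _ in range(epochs):
        rng.shuffle(idx)
        for s in range(0, n, batch):
            rows = idx[s:s + batch]
            x = a[rows]
            out, acts = net.forward(x)
            g = 2.0 * weight[rows] * (out - x) / x.shape[0]
            gw, gb = net.backward(acts, g)
            net.adam_step(gw, gb, lr=lr)
        lr *= 0.98
    hidden = np.tanh(a @ net.W[0] + net.b[0])
    return hidden


def _embed_structural(g: nx.Graph, nodes: Sequence[Node], dim: int) -> np.ndarray:
    """Structural-role coordinates: degree, coreness, clustering and one- and
    two-hop neighbour-degree statistics (log-compressed), standardised and
    rotated to principal axes.  Comparable across networks by construction."""
    deg = dict(g.degree())
    clus = nx.clustering(g)
    core = nx.core_number(g)
    n_bins = 8
    feats = []
    for u in nodes:
        nbrs = list(g.neighbors(u))
        nd = np.array([deg[w] for w in nbrs], dtype=float)
        ncore = np.array([core[w] for w in nbrs], dtype=float)
        two_hop = set()
        for w in nbrs:
            two_hop.update(g.neighbors(w))
        two_hop.discard(u)
        row = [
            math.log1p(deg[u]),
            math.log1p(core[u]),
            clus[u],
            math.log1p(nd.mean()) if nd.size else 0.0,
            math.log1p(nd.min()) if nd.size else 0.0,
            math.log1p(nd.max()) if nd.size else 0.0,
            math.log1p(nd.sum()) if nd.size else 0.0,
            math.log1p(ncore.mean()) if nd.size else 0.0,
            math.log1p(len(two_hop)),
            math.log1p(sum(deg[w] for w in two_hop)),
        ]
        hist = np.zeros(n_bins)
        if nd.size:
            bins = np.minimum(np.floor(np.log2(np.maximum(nd, 1.0))).astype(int), n_bins - 1)
            np.add.at(hist, bins, 1.0)
            hist /= nd.size
        feats.append(row + hist.tolist())
    f = np.asarray(feats)
    mu, sd = f.mean(axis=0), f.std(axis=0)
    f = np.where(sd > 0, (f - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return _svd_embed(f, dim)


def embed_nodes(net: TemporalNetwork, method: str, dim: int = 64,
                seed: int = 0) -> NodeEmbedding:
    """Embed all nodes of the final topology with one of the five estimators.

    Deterministic given ``seed``; isolated nodes receive zero vectors.
    """
    if method not in EMBED_METHODS:
        raise ValueError(f"unknown embedding method {method!r}; choose from {EMBED_METHODS}")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    nodes = net.nodes
    if not nodes:
        raise ValueError("cannot embed an empty network")
    g = net.graph()
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=float)
    adj = sp.csr_matrix(adj)
    rng = np.random.default_rng(seed)
    if method == "n2v":
        mat = _embed_walk_counts(adj, dim, rng)
    elif method == "dw":
        mat = _embed_netmf(adj, dim)
    elif method == "line":
        mat = _embed_line(adj, dim)
    elif method == "sdne":
        mat = _embed_autoencoder(adj, dim, rng)
    else:
        mat = _embed_structural(g, nodes, dim)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    mat[deg == 0] = 0.0
    return NodeEmbedding(method=method, dim=dim, nodes=list(nodes), matrix=mat, seed=seed)


# ---------------------------------------------------------------------------
# classical edge features
# ---------------------------------------------------------------------------

def classical_edge_features(net: TemporalNetwork, edge: Edge) -> np.ndarray:
    """The eleven classical features of one edge of the final topology."""
    e = canonical_edge(*edge)
    if e not in set(net.edges):
        raise ValueError(f"edge {edge!r} not in network")
    g = net.graph()
    return _features_for_edges(g, [e])[0]


def _features_for_edges(g: nx.Graph, edges: Sequence[Edge]) -> np.ndarray:
    deg = dict(g.degree())
    clus = nx.clustering(g)
    out = np.empty((len(edges), len(CLASSICAL_FEATURES)))
    for k, (u, v) in enumerate(edges):
        nu, nv = set(g.neighbors(u)), set(g.neighbors(v))
        common = nu & nv
        union = nu | nv
        cn = float(len(common))
        jac = cn / len(union) if union else 0.0
        aa = sum(1.0 / math.log(deg[w]) for w in common if deg[w] > 1)
        ra = sum(1.0 / deg[w] for w in common if deg[w] > 0)
        ku, kv = deg[u], deg[v]
        out[k] = (cn, jac, aa, ra, float(ku * kv), float(ku + kv),
                  float(abs(ku - kv)), float(min(ku, kv)), float(max(ku, kv)),
                  clus[u] + clus[v], cn)
    return out


# ---------------------------------------------------------------------------
# the six-view bundle
# ---------------------------------------------------------------------------

@dataclass
class EdgeViewSet:
    """Six vector representations per edge, aligned with ``edges`` order.

    ``views[l]`` for l = 0..4 are Hadamard edge vectors of the five embedding
    methods (in ``EMBED_METHODS`` order); ``views[5]`` is the standardised
    classical-feature matrix.  ``classical_raw`` keeps the unstandardised
    feature values for the best-feature comparator.
    """

    edges: List[Edge]
    views: List[np.ndarray]
    feature_names: Tuple[str, ...]
    classical_raw: np.ndarray
    node_embeddings: Dict[str, NodeEmbedding]
    dim: int
    seed: int
    _index: Dict[Edge, int] = field(init=False)

    def __post_init__(self) -> None:
        self._index = {e: i for i, e in enumerate(self.edges)}
        for v in self.views:
            if v.shape[0] != len(self.edges) or not np.all(np.isfinite(v)):
                raise ValueError("malformed view matrix")

    def edge_index(self, edge: Edge) -> int:
        return self._index[canonical_edge(*edge)]


def standardize_columns(m: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance columns; zero-variance columns become zeros."""
    mu = m.mean(axis=0)
    sd = m.std(axis=0)
    out = np.where(sd > 0, (m - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def hadamard_edge_matrix(emb: NodeEmbedding, edges: Sequence[Edge]) -> np.ndarray:
    iu = np.array([emb._index[u] for u, _ in edges])
    iv = np.array([emb._index[v] for _, v in edges])
    return emb.matrix[iu] * emb.matrix[iv]


def build_edge_views(net: TemporalNetwork, dim: int = 64, seed: int = 0) -> EdgeViewSet:
    """Run all five embedders plus classical features on the final topology."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(EMBED_METHODS))]
    node_embs: Dict[str, NodeEmbedding] = {}
    views: List[np.ndarray] = []
    for method, s in zip(EMBED_METHODS, child_seeds):
        emb = embed_nodes(net, method, dim=dim, seed=s)
        node_embs[method] = emb
        views.append(hadamard_edge_matrix(emb, net.edges))
    raw = _features_for_edges(net.graph(), net.edges)
    views.append(standardize_columns(raw))
    return EdgeViewSet(edges=list(net.edges), views=views,
                       feature_names=CLASSICAL_FEATURES, classical_raw=raw,
                       node_embeddings=node_embs, dim=dim, seed=seed)
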
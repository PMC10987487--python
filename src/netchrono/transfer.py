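"""Cross-network transfer of a trained order model.

A model trained on network A (where some history exists) is applied to a
history-less network B by aligning B's embedding spaces to A's.  Nodes are
matched by degree quantiles: both node sets are sorted by degree descending
(stable in node id) and, when the sizes differ, ranks of the smaller list are
matched to proportionally scaled ranks of the larger.  For each embedding
view, a linear map L minimising ||H_B L - H_A||_F over the matched rows is
found by least squares (normal equations L = (H_B' H_B)^{-1} H_B' H_A, solved
with a pseudo-inverse fallback when H_B is rank-deficient).  B's node vectors
are mapped through L before Hadamard edge construction; the classical-feature
view is simply re-standardised on B.  Direct validation skips the alignment
and feeds B's raw representations into A's ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .embeddings import (EMBED_METHODS, EdgeViewSet, NodeEmbedding,
                         hadamard_edge_matrix, standardize_columns,
                         _features_for_edges)
from .network import Node, TemporalNetwork
from .ordermodel import (LabeledPairs, PairwiseOrderModel, RestoredSequence,
                         pairwise_accuracy, restore_network, sample_test_pairs)


@dataclass
class AlignmentMap:
    """Least-squares map L for one embedding view, with provenance."""

    L: np.ndarray
    correspondence: List[Tuple[Node, Node]]  # (source node, target node)
    residual: float
    rank_deficient: bool = False


def _degree_sorted(net: TemporalNetwork) -> List[Node]:
    g = net.graph()
    return sorted(g.nodes, key=lambda u: (-g.degree(u), str(u)))


def correspond_nodes_by_degree(net_a: TemporalNetwork,
                               net_b: TemporalNetwork) -> List[Tuple[Node, Node]]:
    """Match nodes across networks at equal degree quantiles.

    Returns ``min(N_A, N_B)`` pairs (source node, target node).  The larger
    network is subsampled at scaled ranks: rank ``r`` of the smaller list is
    matched to rank ``floor(r * N_large / N_small)`` of the larger.
    """
    sa, sb = _degree_sorted(net_a), _degree_sorted(net_b)
    if not sa or not sb:
        raise ValueError("both networks must be non-empty")
    na, nb = len(sa), len(sb)
    k = min(na, nb)
    if na == nb:
        return list(zip(sa, sb))
    pairs: List[Tuple[Node, Node]] = []
    for r in range(k):
        scaled = min(int(r * max(na, nb) / k), max(na, nb) - 1)
        if na > nb:
            pairs.append((sa[scaled], sb[r]))
        else:
            pairs.append((sa[r], sb[scaled]))
    return pairs


def align_embeddings(h_b: np.ndarray, h_a: np.ndarray,
                     correspondence: Optional[List[Tuple[Node, Node]]] = None) -> AlignmentMap:
    """Least-squares L minimising ||H_B L - H_A||_F over matched rows."""
    if h_b.shape[0] != h_a.shape[0]:
        raise ValueError("matched matrices must have the same number of rows")
    rank = np.linalg.matrix_rank(h_b)
    deficient = rank < h_b.shape[1]
    if deficient:
        L = np.linalg.pinv(h_b) @ h_a
    else:
        L, *_ = np.linalg.lstsq(h_b, h_a, rcond=None)
    residual = float(np.linalg.norm(h_b @ L - h_a))
    return AlignmentMap(L=L, correspondence=correspondence or [],
                        residual=residual, rank_deficient=deficient)


def _matched_rows(emb: NodeEmbedding, nodes: List[Node]) -> np.ndarray:
    return np.stack([emb.vector(u) for u in nodes])


def fit_alignment(views_a: EdgeViewSet, views_b: EdgeViewSet,
                  net_a: TemporalNetwork, net_b: TemporalNetwork) -> Dict[str, AlignmentMap]:
    """One alignment map per embedding view, from degree-quantile matching."""
    corr = correspond_nodes_by_degree(net_a, net_b)
    maps: Dict[str, AlignmentMap] = {}
    for method in EMBED_METHODS:
        ea, eb = views_a.node_embeddings[method], views_b.node_embeddings[method]
        h_a = _matched_rows(ea, [a for a, _ in corr])
        h_b = _matched_rows(eb, [b for _, b in corr])
        maps[method] = align_embeddings(h_b, h_a, corr)
    return maps


def aligned_target_views(views_b: EdgeViewSet, alignment: Dict[str, AlignmentMap],
                         net_b: TemporalNetwork) -> EdgeViewSet:
    """Target edge views after pushing node vectors through each view's L."""
    views: List[np.ndarray] = []
    node_embs: Dict[str, NodeEmbedding] = {}
    for method in EMBED_METHODS:
        if method not in alignment:
            raise ValueError(f"missing alignment for view {method!r}")
        eb = views_b.node_embeddings[method]
        mapped = NodeEmbedding(method=method, dim=eb.dim, nodes=list(eb.nodes),
                               matrix=eb.matrix @ alignment[method].L, seed=eb.seed)
        node_embs[method] = mapped
        views.append(hadamard_edge_matrix(mapped, views_b.edges))
    raw = views_b.classical_raw
    views.append(standardize_columns(raw))
    return EdgeViewSet(edges=list(views_b.edges), views=views,
                       feature_names=views_b.feature_names, classical_raw=raw,
                       node_embeddings=node_embs, dim=views_b.dim, seed=views_b.seed)


def transfer_restore(net_b: TemporalNetwork, views_b: EdgeViewSet,
                     source_model: PairwiseOrderModel,
                     alignment: Dict[str, AlignmentMap],
                     test_pairs: Optional[LabeledPairs] = None,
                     restore: bool = True) -> dict:
    """Apply a source-trained ensemble to an aligned target network.

    Returns the restored sequence (unless ``restore=False``) and, when the
    target has ground truth to score against, the transfer accuracy ``x_T``.
    """
    aligned = aligned_target_views(views_b, alignment, net_b)
    out: dict = {"views": aligned}
    if test_pairs is not None:
        out["accuracy"] = pairwise_accuracy(source_model, aligned, test_pairs)
    if restore:
        out["sequence"] = restore_network(source_model, aligned)
    return out


def direct_validate(net_b: TemporalNetwork, views_b: EdgeViewSet,
                    source_model: PairwiseOrderModel,
                    test_pairs: LabeledPairs) -> float:
    """Accuracy x_D of the source ensemble on B's unaligned representations."""
    return pairwise_accuracy(source_model, views_b, test_pairs)
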
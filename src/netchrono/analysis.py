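"""Growth-mechanism analysis and link prediction on restored sequences.

Given an edge ordering (restored or true), this module replays the growth to:

* estimate the cumulative preferential-attachment function ``kappa(k)`` —
  the integral of the exposure-normalised attachment kernel; on log-log axes
  a slope of 1 means attachment is degree-blind, superlinear growth means PA;
* track structural metrics (modularity, assortativity, mean local
  clustering, mean shortest path over connected pairs) along checkpoints,
  against random-order and pure-PA baselines;
* build meso-level label-by-label adjacency matrices (same-label edges count
  on the diagonal);
* score future links by truncated SVD of a temporally decayed adjacency
  ``X(u, v) = theta^(max(alpha_hat) - alpha_hat_i)`` and evaluate hits@r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .network import Edge, Node, TemporalNetwork, canonical_edge
from .ordermodel import RestoredSequence

TRAJECTORY_METRICS = ("modularity", "assortativity", "clustering", "shortest_path")


def _edges_in_order(net: TemporalNetwork, order: Optional[RestoredSequence]) -> List[Edge]:
    if order is None:
        return list(net.edges)
    if set(order.edges) != set(net.edges):
        raise ValueError("order does not cover the network's edges")
    return order.edges_in_restored_order()


# ---------------------------------------------------------------------------
# cumulative preferential-attachment function
# ---------------------------------------------------------------------------

@dataclass
class PAKernel:
    degrees: np.ndarray          # sorted degrees k with exposure
    kappa: np.ndarray            # cumulative kernel, kappa(k_max) = 1
    attachments: Dict[int, float] = field(default_factory=dict)
    exposure: Dict[int, float] = field(default_factory=dict)

    def loglog_slope(self, k_min: int = 2, k_max: Optional[int] = None) -> float:
        """Least-squares slope of log kappa vs log k over [k_min, k_max]."""
        sel = self.degrees >= k_min
        if k_max is not None:
            sel &= self.degrees <= k_max
        sel &= self.kappa > 0
        k = np.log(self.degrees[sel].astype(float))
        y = np.log(self.kappa[sel])
        if k.size < 2:
            raise ValueError("not enough degree classes for a slope")
        return float(np.polyfit(k, y, 1)[0])


def cumulative_pa(net: TemporalNetwork, order: Optional[RestoredSequence] = None,
                  k_min: int = 2) -> PAKernel:
    """Replay growth in the given order and estimate the attachment kernel.

    For every arriving edge, each endpoint already present (degree >= 1 just
    before the arrival) counts as one attachment to its current degree class;
    exposure of class k accumulates the number of degree-k nodes present at
    each arrival event.  ``pi(k) = attachments(k) / exposure(k)`` and
    ``kappa`` is its running sum normalised to 1 at the largest degree.

    Degree classes below ``k_min`` are excluded from the kernel: when a
    newcomer adds several edges in one arrival step, its own later edges
    register as attachments to a transient tiny-degree class whose exposure
    is near zero, which would swamp the kernel with an artefactual spike.
    """
    edges = _edges_in_order(net, order)
    deg: Dict[Node, int] = {}
    hist: Dict[int, int] = {}
    attach: Dict[int, float] = {}
    expo: Dict[int, float] = {}
    for u, v in edges:
        for k, n_k in hist.items():
            expo[k] = expo.get(k, 0.0) + n_k
        for w in (u, v):
            k = deg.get(w, 0)
            if k >= 1:
                attach[k] = attach.get(k, 0.0) + 1.0
        for w in (u, v):
            k = deg.get(w, 0)
            if k >= 1:
                hist[k] -= 1
                if hist[k] == 0:
                    del hist[k]
            deg[w] = k + 1
            hist[k + 1] = hist.get(k + 1, 0) + 1
    ks = np.array([k for k in sorted(expo) if k >= k_min])
    pi = np.array([attach.get(int(k), 0.0) / expo[int(k)] for k in ks])
    kappa = np.cumsum(pi)
    if kappa[-1] > 0:
        kappa = kappa / kappa[-1]
    return PAKernel(degrees=ks, kappa=kappa, attachments=attach, exposure=expo)


# ---------------------------------------------------------------------------
# structural trajectories
# ---------------------------------------------------------------------------

@dataclass
class GrowthTrajectory:
    metric: str
    checkpoints: List[int]
    values: Dict[str, List[Optional[float]]]  # ordering source -> values


def _mean_shortest_path_connected(g: nx.Graph) -> Optional[float]:
    """Average shortest path over pairs of nodes that can be connected."""
    total, count = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            count += len(dists) - 1
    if count == 0:
        return None
    return total / count


def _metric_value(g: nx.Graph, metric: str, seed: int = 0) -> Optional[float]:
    if g.number_of_edges() == 0:
        return None
    if metric == "modularity":
        comms = nx.community.greedy_modularity_communities(g)
        return float(nx.community.modularity(g, comms))
    if metric == "assortativity":
        degs = [d for _, d in g.degree()]
        if np.std(degs) == 0:
            return None  # undefined on regular checkpoints
        val = nx.degree_assortativity_coefficient(g)
        return None if not np.isfinite(val) else float(val)
    if metric == "clustering":
        return float(nx.average_clustering(g))
    if metric == "shortest_path":
        return _mean_shortest_path_connected(g)
    raise ValueError(f"unknown metric {metric!r}")


def structural_trajectory(net: TemporalNetwork, metric: str,
                          checkpoints: Sequence[int],
                          orders: Dict[str, Optional[RestoredSequence]],
                          seed: int = 0) -> GrowthTrajectory:
    """Metric values of the first-c-edges subgraphs under several orderings.

    ``orders`` maps a source name (e.g. ``"restored"``, ``"true"``,
    ``"random"``, ``"pure_pa"``) to a RestoredSequence (or None for the
    network's own arrival order).  Undefined values are None, never NaN.
    """
    if metric not in TRAJECTORY_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {TRAJECTORY_METRICS}")
    cps = sorted(int(c) for c in checkpoints)
    if not cps or cps[0] < 1 or cps[-1] > net.n_edges:
        raise ValueError("checkpoints must lie in [1, E]")
    values: Dict[str, List[Optional[float]]] = {}
    for name, order in orders.items():
        seq = _edges_in_order(net, order)
        vals: List[Optional[float]] = []
        for c in cps:
            g = nx.Graph()
            g.add_edges_from(seq[:c])
            vals.append(_metric_value(g, metric, seed=seed))
        values[name] = vals
    return GrowthTrajectory(metric=metric, checkpoints=cps, values=values)


def random_order(net: TemporalNetwork, seed: int) -> RestoredSequence:
    """A uniformly random edge ordering, as the null baseline."""
    rng = np.random.default_rng(seed)
    positions = rng.permutation(net.n_edges) + 1
    return RestoredSequence(edges=list(net.edges), positions=positions,
                            borda=positions - 1, source=f"random(seed={seed})")


def modularity_trajectory(net: TemporalNetwork, checkpoints: Sequence[int],
                          orders: Dict[str, Optional[RestoredSequence]],
                          seed: int = 0) -> GrowthTrajectory:
    """Greedy-partition Newman modularity along the growth checkpoints."""
    return structural_trajectory(net, "modularity", checkpoints, orders, seed=seed)


def meso_adjacency(net: TemporalNetwork, checkpoints: Sequence[int],
                   order: Optional[RestoredSequence] = None) -> Dict[int, pd.DataFrame]:
    """Label-by-label edge-count matrices at each checkpoint.

    Same-label edges land on the diagonal; each matrix's total equals the
    checkpoint edge count.  Requires every node to be labelled.
    """
    if net.node_labels is None:
        raise ValueError("network has no node labels")
    seq = _edges_in_order(net, order)
    labels = sorted(set(net.node_labels.values()))
    pos = {lab: k for k, lab in enumerate(labels)}
    out: Dict[int, pd.DataFrame] = {}
    mat = np.zeros((len(labels), len(labels)))
    done = 0
    for c in sorted(int(x) for x in checkpoints):
        if not 1 <= c <= len(seq):
            raise ValueError("checkpoint out of range")
        for u, v in seq[done:c]:
            for w in (u, v):
                if w not in net.node_labels:
                    raise ValueError(f"node {w!r} is unlabelled")
            a, b = pos[net.node_labels[u]], pos[net.node_labels[v]]
            if a == b:
                mat[a, a] += 1
            else:
                mat[a, b] += 1
                mat[b, a] += 1
        done = c
        df = pd.DataFrame(mat.copy(), index=labels, columns=labels)
        out[c] = df
    return out


def meso_total(df: pd.DataFrame) -> float:
    """Edge count represented by a meso matrix (off-diagonal stored twice)."""
    m = df.to_numpy()
    return float(np.trace(m) + (m.sum() - np.trace(m)) / 2.0)


# ---------------------------------------------------------------------------
# link prediction via the collapsed weighted tensor
# ---------------------------------------------------------------------------

@dataclass
class TemporalScoreMatrix:
    nodes: List[Node]
    X: np.ndarray
    theta: float


def collapsed_tensor(net: TemporalNetwork, order: Optional[RestoredSequence] = None,
                     theta: float = 0.5, allow_theta_one: bool = False) -> TemporalScoreMatrix:
    """Temporally decayed adjacency: entry ``theta^(E - alpha_hat_i)`` on each
    edge, so the newest edge has weight exactly 1.  ``theta = 1`` (the plain
    binary adjacency) must be requested explicitly."""
    if allow_theta_one and theta == 1.0:
        pass
    elif not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    edges = _edges_in_order(net, order)
    nodes = net.nodes
    idx = {u: i for i, u in enumerate(nodes)}
    e = len(edges)
    x = np.zeros((len(nodes), len(nodes)))
    for pos, (u, v) in enumerate(edges, start=1):
        w = theta ** (e - pos)
        x[idx[u], idx[v]] = w
        x[idx[v], idx[u]] = w
    return TemporalScoreMatrix(nodes=nodes, X=x, theta=theta)


def tsvd_link_scores(tsm: TemporalScoreMatrix, rank: int) -> pd.DataFrame:
    """Rank-r SVD reconstruction scores for all candidate (non-)edges.

    Returns a DataFrame (u, v, score) sorted by descending score; existing
    edges are excluded from the candidates.
    """
    x = tsm.X
    if not 1 <= rank <= min(x.shape):
        raise ValueError("rank out of range")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
    recon = (recon + recon.T) / 2.0
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    existing = x[iu, ju] > 0
    cand_i, cand_j = iu[~existing], ju[~existing]
    scores = recon[cand_i, cand_j]
    order = np.lexsort((cand_i, cand_j, -scores))
    nodes = tsm.nodes
    return pd.DataFrame({
        "u": [nodes[i] for i in cand_i[order]],
        "v": [nodes[j] for j in cand_j[order]],
        "score": scores[order],
    })


def hits_at_r(scores: pd.DataFrame, held_out: Iterable[Edge], r: int) -> int:
    """Number of held-out edges among the top-r scored candidates."""
    if r < 0:
        raise ValueError("r must be >= 0")
    held = {canonical_edge(u, v) for u, v in held_out}
    top = scores.head(r)
    return sum(1 for u, v in zip(top["u"], top["v"]) if canonical_edge(u, v) in held)


def hits_curve(scores: pd.DataFrame, held_out: Iterable[Edge],
               r_values: Sequence[int]) -> List[int]:
    return [hits_at_r(scores, held_out, r) for r in r_values]


def tune_link_prediction(net: TemporalNetwork, order: Optional[RestoredSequence],
                         val_edges: List[Edge],
                         thetas: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
                         ranks: Sequence[int] = (2, 4, 8, 16, 32),
                         r_eval: int = 100) -> Tuple[float, int]:
    """Grid search (theta, rank) maximising hits@r_eval on validation edges."""
    best = (float(thetas[0]), int(ranks[0]))
    best_hits = -1
    for th in thetas:
        tsm = collapsed_tensor(net, order, theta=float(th))
        for rk in ranks:
            if rk > min(tsm.X.shape):
                continue
            scores = tsvd_link_scores(tsm, rk)
            h = hits_at_r(scores, val_edges, r_eval)
            if h > best_hits:
                best_hits, best = h, (float(th), int(rk))
    return best
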